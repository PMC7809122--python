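"""Check Q-model calibration on simulated cohorts.

A Q-model that ranks well but is badly calibrated still biases
G-computation, because the ACE averages predicted probabilities.  This
example bins the fitted outcome probabilities into deciles and compares the
mean prediction with the observed event rate per bin.
"""

import gcompml as g
from gcompml.design import transform_design

scenario = g.simplistic_scenario()
dataset = g.simulate_cohort(scenario, 500, seed=3)

config = g.RunConfig(learner_id="LLR", grid_length=10, n_folds=5,
                     n_boot=1, seed=3)
fit = g.gc_point_estimate(dataset.cohort, config)
predicted = fit.model.predict_proba(
    transform_design(fit.design, dataset.cohort, "observed"))

curve = g.calibration_curve(predicted, dataset.cohort.outcome, n_bins=10)
print(f"{'mean predicted':>14}  {'observed rate':>13}  {'count':>5}")
for mean_pred, rate, count in curve:
    bar = "#" * int(round(rate * 40))
    print(f"{mean_pred:14.3f}  {rate:13.3f}  {count:5d}  {bar}")
print()
print("Points close to the diagonal (mean predicted = observed rate) mean")
print("the fitted probabilities are trustworthy inputs to standardization.")
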