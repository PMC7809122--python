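# gcompml

G-computation with machine-learning Q-models for estimating the **average
causal effect (ACE)** of a binary exposure on a binary outcome, designed to
behave well in small and medium cohorts (a few hundred subjects).

## The problem and the method

For potential outcomes Y(1), Y(0) of a binary exposure Z with pre-exposure
covariates X = (X1, …, Xk), the estimand is the marginal risk difference

    ACE = E[Y(1) − Y(0)].

G-computation (standardization) estimates it in three steps:

1. fit an outcome regression — the **Q-model** — f(Y | Z, X);
2. predict each subject's outcome probability with the exposure forced to 1
   and to 0 while holding the covariates at their observed values,
   Ŷᵢ(1) = f̂(Y | 1, Xᵢ) and Ŷᵢ(0) = f̂(Y | 0, Xᵢ);
3. average: ACÊ = n⁻¹ Σᵢ [Ŷᵢ(1) − Ŷᵢ(0)].

The Q-model can be any of six candidates, each tuned by maximising the mean
out-of-fold AUC of ten-fold cross-validation over a grid of 20 candidate
parameter combinations:

| id    | Q-model                                   | tuned parameters |
|-------|-------------------------------------------|------------------|
| LLR   | lasso logistic regression (b-splines + all Z×X interactions) | penalty strength |
| ELR   | elastic-net logistic regression (same design) | penalty strength, L1/L2 mix |
| NN    | one-hidden-layer neural network           | hidden-layer size |
| SVM   | RBF-kernel support vector machine         | cost, kernel width |
| BCART | boosted classification trees              | trees, depth, learning rate, node size |
| SL    | **super learner**: convex combination of LLR, ELR, NN, SVM logits, weights chosen to maximise out-of-fold AUC on the simplex | member weights |

Uncertainty comes from **bootstrap cross-validation**: tuning parameters are
frozen from the full sample; each of B = 500 iterations refits the Q-model
on a resample drawn with replacement and evaluates the ACE on the
out-of-bag rows only (≈ 36.8% of subjects), guarding the interval against
overfitting. The SE is the SD of the draws; the CI is the percentile
interval.

The package also ships the full simulation-study machinery: two
logit-linear data-generating scenarios (a *realistic* one with 22 correlated
covariates, non-linear effects and one exposure×covariate interaction, and a
*simplistic* one with 9 independent covariates and linear effects), the
Monte-Carlo *theoretical ACE* (exposure randomized independently of the
covariates), and seven performance criteria: mean bias (MB), RMSE,
empirical and asymptotic SDs (ESD, ASD), variance-estimation bias (VEB),
95% CI coverage and power.

## Worked example

```python
import gcompml as g

scenario = g.simplistic_scenario()          # 9 covariates, true ACE ~ 0.14
cohort = g.simulate_cohort(scenario, 300, seed=42).cohort

config = g.RunConfig(learner_id="LLR", grid_length=10, n_folds=5,
                     n_boot=100, seed=42)
fit = g.gc_point_estimate(cohort, config)
estimate = g.bootstrap_ace(cohort, config, point_fit=fit)
print(fit.model.chosen_params, estimate.ace_hat, estimate.ci_lo, estimate.ci_hi)
```

Running `python examples/estimate_from_csv.py` (the same analysis routed
through the CSV reader) prints:

```
chosen lasso penalty: 0.2154 (CV AUC 0.649)
ACE estimate: +0.1819
bootstrap SE: 0.0551
95% percentile CI: (+0.0919, +0.3105)
```

Exposure is estimated to raise the outcome risk by about 18 percentage
points in this 300-subject cohort; the interval excludes zero and covers
the generating truth (~0.14). The other scripts in `examples/` demonstrate
super-learner weighting, a small replicate simulation study, and
calibration curves.

A command-line interface wraps the same library calls:

```sh
gcompml estimate --cohort cohort.csv --learner SL --boot 500 --seed 1 --out report.csv
gcompml simulate --scenario realistic --n 500 --reps 100 --seed 7 --out sims/
gcompml evaluate --scenario simplistic --n 500 --reps 200 --learner LLR --out metrics.csv
```

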