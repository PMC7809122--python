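"""G-computation: counterfactual prediction, the ACE, and bootstrap variance.

The estimator is standardization with a fitted Q-model: fit f(Y|Z,X), predict
each individual's outcome probability with the exposure forced to 1 and to 0
while holding the covariates at their observed values, and average the
difference,

    ACE_hat = n^-1 * sum_i [ Yhat_i(1) - Yhat_i(0) ].

Uncertainty comes from bootstrap cross-validation: tuning parameters are
chosen once on the full sample; each bootstrap iteration refits the Q-model
on a resample drawn with replacement and evaluates the ACE on the
out-of-bag rows only, so overfitting of the flexible learners does not leak
into the interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cohort import CohortTable, RunConfig
from .design import (DegenerateCovariateError, DesignSpec, ExpandedDesign,
                     fit_design, transform_design)
from .learners import (LearnerSpec, SlWeights, SuperLearner, TunedModel, auc,
                       combine_predictions, fit_model, fit_superlearner,
                       make_cv_plan, optimize_sl_weights, tune_learner)

__all__ = [
    "CounterfactualPredictions",
    "AceEstimate",
    "GcFit",
    "estimate_ace",
    "gc_point_estimate",
    "bootstrap_ace",
]

logger = logging.getLogger(__name__)

#: maximum redraw attempts when a bootstrap resample loses an outcome or
#: exposure class, or leaves an empty out-of-bag set.
MAX_REDRAWS = 100


@dataclass(frozen=True)
class CounterfactualPredictions:
    """Per-individual predicted outcomes under exposure and non-exposure."""

    y1_hat: np.ndarray
    y0_hat: np.ndarray
    row_id: np.ndarray = None

    def __post_init__(self):
        y1 = np.asarray(self.y1_hat, dtype=float)
        y0 = np.asarray(self.y0_hat, dtype=float)
        object.__setattr__(self, "y1_hat", y1)
        object.__setattr__(self, "y0_hat", y0)
        if len(y1) != len(y0):
            raise ValueError("y1_hat and y0_hat lengths differ")
        if len(y1) == 0:
            raise ValueError("empty counterfactual predictions")
        for label, v in (("y1_hat", y1), ("y0_hat", y0)):
            if np.any((v <= 0.0) | (v >= 1.0)):
                raise ValueError(f"{label} must lie strictly inside (0, 1)")
        if self.row_id is None:
            object.__setattr__(self, "row_id", np.arange(len(y1)))


@dataclass(frozen=True)
class AceEstimate:
    """Point estimate with bootstrap draws, SE and interval."""

    ace_hat: float
    boot_draws: np.ndarray
    se: float
    ci_lo: float
    ci_hi: float
    ci_level: float
    n_boot_completed: int
    seed: int
    learner_id: str
    n_redraws: int = 0

    def __post_init__(self):
        object.__setattr__(self, "boot_draws", np.asarray(self.boot_draws, dtype=float))
        if self.ci_lo > self.ci_hi:
            raise ValueError("ci_lo must not exceed ci_hi")


@dataclass
class GcFit:
    """Result of a full-sample G-computation fit."""

    model: object                     # TunedModel or SuperLearner
    design: ExpandedDesign
    cf: CounterfactualPredictions
    ace_hat: float
    config: RunConfig


def estimate_ace(cf: CounterfactualPredictions) -> float:
    """Mean per-individual difference between the two counterfactual
    predictions; lies in [-1, 1] by construction."""
    return float(np.mean(cf.y1_hat - cf.y0_hat))


def _fit_qmodel(design, outcome, config: RunConfig, seed: int,
                learner_ranges=None):
    if config.learner_id == "LR":   # nothing to tune: plain logistic fit
        return fit_model("LR", {}, design.matrix, outcome, seed=seed)
    plan = make_cv_plan(outcome, config.n_folds, seed=seed)
    ranges = learner_ranges or {}
    if config.learner_id == "SL":
        library = [LearnerSpec(lid, ranges.get(lid, {})) for lid in config.sl_library]
        return fit_superlearner(design, outcome, library, plan,
                                grid_length=config.grid_length, seed=seed,
                                combination_scale=config.sl_combination_scale)
    spec = LearnerSpec(config.learner_id, ranges.get(config.learner_id, {}))
    return tune_learner(design, outcome, spec, plan,
                        grid_length=config.grid_length, seed=seed)


def _counterfactuals(model, design, cohort) -> CounterfactualPredictions:
    X1 = transform_design(design, cohort, "all_one")
    X0 = transform_design(design, cohort, "all_zero")
    return CounterfactualPredictions(model.predict_proba(X1),
                                     model.predict_proba(X0),
                                     row_id=cohort.row_id)


def gc_point_estimate(cohort: CohortTable, config: RunConfig,
                      design_spec: DesignSpec = None,
                      learner_ranges=None) -> GcFit:
    """Fit the configured Q-model on the full cohort and standardize.

    Tuning (cross-validated AUC over the configured grid, super-learner
    weight estimation) happens here, on the full sample.  Deterministic
    given ``config.seed``.
    """
    design_spec = design_spec or DesignSpec()
    design = fit_design(cohort, design_spec)
    model = _fit_qmodel(design, cohort.outcome, config, seed=config.seed,
                        learner_ranges=learner_ranges)
    cf = _counterfactuals(model, design, cohort)
    return GcFit(model=model, design=design, cf=cf,
                 ace_hat=estimate_ace(cf), config=config)


def _refit_frozen(model, X, y, seed: int, config: RunConfig, frozen_weights):
    """Refit the full-sample model on a bootstrap resample with tuning
    parameters frozen; super-learner weights are re-estimated from
    out-of-fold predictions inside the resample unless configured off."""
    if not isinstance(model, SuperLearner):
        return fit_model(model.learner_id, model.chosen_params, X, y, seed=seed)

    members = [fit_model(m.learner_id, m.chosen_params, X, y, seed=seed + i)
               for i, m in enumerate(model.members)]
    weights = frozen_weights
    if config.sl_refit_weights_in_bootstrap:
        plan = make_cv_plan(y, config.n_folds, seed=seed)
        oof = np.full((len(y), len(members)), np.nan)
        ok = True
        for train_idx, held_idx in plan.split():
            if len(np.unique(y[train_idx])) < 2:
                ok = False
                break
            for j, m in enumerate(model.members):
                fold_fit = fit_model(m.learner_id, m.chosen_params,
                                     X[train_idx], y[train_idx], seed=seed + j)
                oof[held_idx, j] = fold_fit.predict_proba(X[held_idx])
        if ok:
            weights = optimize_sl_weights(
                oof, y, seed=seed,
                combination_scale=config.sl_combination_scale)
            weights = SlWeights(weights.weights,
                                member_ids=frozen_weights.member_ids,
                                combination_scale=config.sl_combination_scale)
        else:
            logger.debug("bootstrap fold lost a class; keeping full-sample SL weights")
    return SuperLearner(members=members, sl_weights=weights)


def bootstrap_ace(cohort: CohortTable, config: RunConfig,
                  point_fit: GcFit = None, design_spec: DesignSpec = None,
                  learner_ranges=None) -> AceEstimate:
    """Bootstrap-cross-validation variance for the G-computation ACE.

    For each of ``config.n_boot`` iterations: draw n rows with replacement,
    refit the Q-model on the resample (tuning parameters frozen from the
    full sample), predict both counterfactuals for the out-of-bag rows and
    record their ACE.  The SE is the sample SD of the draws and the interval
    is the percentile interval (normal approximation behind ``ci_type``).

    Degenerate resamples (single outcome or exposure class, empty
    out-of-bag set) are redrawn, at most :data:`MAX_REDRAWS` times each.
    """
    design_spec = design_spec or DesignSpec()
    if point_fit is None:
        point_fit = gc_point_estimate(cohort, config, design_spec,
                                      learner_ranges=learner_ranges)
    model = point_fit.model
    frozen_weights = model.sl_weights if isinstance(model, SuperLearner) else None

    n = cohort.n
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_boot)
    draws = np.empty(config.n_boot)
    total_redraws = 0
    for b in range(config.n_boot):
        rng = np.random.default_rng(children[b])
        fit_seed = int(children[b].generate_state(1)[0] % (2 ** 31))
        for attempt in range(MAX_REDRAWS + 1):
            idx = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), idx)
            y_b, z_b = cohort.outcome[idx], cohort.exposure[idx]
            if (len(oob) > 0 and len(np.unique(y_b)) == 2
                    and len(np.unique(z_b)) == 2):
                break
            total_redraws += 1
        else:
            raise RuntimeError(
                f"bootstrap iteration {b}: no valid resample in {MAX_REDRAWS} attempts")
        boot = cohort.subset(idx)
        try:
            design_b = fit_design(boot, design_spec)
        except DegenerateCovariateError:
            # vanishingly rare at n >= 20; count as a redraw and resample
            total_redraws += 1
            rng2 = np.random.default_rng(children[b].spawn(1)[0])
            idx = rng2.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), idx)
            boot = cohort.subset(idx)
            design_b = fit_design(boot, design_spec)
        model_b = _refit_frozen(model, design_b.matrix, boot.outcome,
                                seed=fit_seed, config=config,
                                frozen_weights=frozen_weights)
        cf_b = _counterfactuals(model_b, design_b, cohort.subset(oob))
        draws[b] = estimate_ace(cf_b)
    if total_redraws:
        logger.info("bootstrap: %d degenerate resamples redrawn", total_redraws)

    se = float(np.std(draws, ddof=1)) if len(draws) > 1 else 0.0
    alpha = 1.0 - config.ci_level
    if config.ci_type == "percentile":
        ci_lo, ci_hi = np.percentile(draws, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    else:
        from scipy.stats import norm
        zcrit = norm.ppf(1 - alpha / 2)
        ci_lo = point_fit.ace_hat - zcrit * se
        ci_hi = point_fit.ace_hat + zcrit * se
    ci_lo = float(np.clip(ci_lo, -1.0, 1.0))
    ci_hi = float(np.clip(ci_hi, -1.0, 1.0))
    return AceEstimate(ace_hat=point_fit.ace_hat, boot_draws=draws, se=se,
                       ci_lo=ci_lo, ci_hi=ci_hi, ci_level=config.ci_level,
                       n_boot_completed=len(draws), seed=config.seed,
                       learner_id=config.learner_id, n_redraws=total_redraws)
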