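"""Q-model candidates, cross-validated AUC tuning and the super learner.

Six candidate Q-models are supported: lasso logistic regression (LLR),
elastic-net logistic regression (ELR), a single-hidden-layer neural network
(NN), a radial-basis-function support vector machine (SVM), boosted
classification trees (BCART), and a plain unpenalized logistic regression
(LR) for correctly specified reference fits.  Each tunable learner selects
its parameters by maximising the average out-of-fold AUC over a shared
stratified V-fold plan; the super learner (SL) combines the tuned members
with simplex-constrained weights chosen to maximise the AUC of the weighted
out-of-fold linear predictor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit
from scipy.stats import qmc, rankdata
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "LearnerSpec",
    "CvPlan",
    "TunedModel",
    "SlWeights",
    "SuperLearner",
    "UndefinedAUCError",
    "default_learner_spec",
    "make_tuning_grid",
    "make_cv_plan",
    "auc",
    "tune_learner",
    "fit_model",
    "fit_superlearner",
    "optimize_sl_weights",
]

#: Probabilities are clipped to this range before any logit, so ensemble
#: combination can never see an infinite linear predictor.
PROB_CLIP = 1e-6


class UndefinedAUCError(ValueError):
    """AUC requested with a single-class label vector."""


# ---------------------------------------------------------------------------
# learner specifications and tuning grids


@dataclass(frozen=True)
class LearnerSpec:
    """A learner identifier plus its tunable-parameter ranges.

    Ranges are (low, high) bounds; penalty strengths, costs and kernel
    widths are explored on a log scale, the neural-network size on the
    integers.  The defaults below are deliberately wide and documented; the
    ranges are configurable because no single choice suits every cohort.
    """

    learner_id: str
    ranges: dict = field(default_factory=dict)

    def __post_init__(self):
        defaults = _DEFAULT_RANGES.get(self.learner_id)
        if defaults is None:
            raise ValueError(f"unknown learner id {self.learner_id!r}")
        merged = {**defaults, **self.ranges}
        for key, (lo, hi) in merged.items():
            if not lo < hi and self.learner_id != "LR":
                raise ValueError(f"{self.learner_id}.{key}: empty range ({lo}, {hi})")
        object.__setattr__(self, "ranges", merged)


# parameter ranges: (low, high); interpretation is per-learner.
_DEFAULT_RANGES = {
    # penalty strength lambda; the fitted C is 1/lambda
    "LLR": {"penalty": (1e-4, 1e2)},
    "ELR": {"penalty": (1e-4, 1e2), "l1_ratio": (0.0, 1.0)},
    # hidden-layer size, integer
    "NN": {"size": (1, 20)},
    # misclassification cost and kernel-width multiplier, both log2 scale
    "SVM": {"cost": (2.0 ** -5, 2.0 ** 10), "width_mult": (2.0 ** -3, 2.0 ** 3)},
    "BCART": {
        "n_trees": (50, 1000),
        "depth": (1, 4),
        "learning_rate": (0.001, 0.3),
        "min_node": (5, 20),
    },
    "LR": {},
}

# which parameters live on a log scale
_LOG_PARAMS = {"penalty", "cost", "width_mult", "learning_rate"}
# which parameters are integers
_INT_PARAMS = {"size", "n_trees", "depth", "min_node"}


def default_learner_spec(learner_id: str) -> LearnerSpec:
    return LearnerSpec(learner_id)


def make_tuning_grid(spec: LearnerSpec, grid_length: int, seed: int = 0) -> list:
    """Candidate parameter combinations for one learner.

    Single-parameter learners get ``grid_length`` distinct values spanning
    the range (log-spaced where the range is a scale, consecutive integers
    for the network size).  Multi-parameter learners get ``grid_length``
    combinations from a seeded Latin hypercube over the ranges — a
    per-parameter Cartesian product would explode for the four BCART
    parameters.  ``grid_length == 1`` yields the range midpoints.
    """
    if grid_length < 1:
        raise ValueError("grid_length must be >= 1")
    names = list(spec.ranges)
    if not names:                      # LR: nothing to tune
        return [{}]
    if grid_length == 1:
        return [{k: _from_unit(0.5, k, spec.ranges[k]) for k in names}]
    if len(names) == 1:
        name = names[0]
        lo, hi = spec.ranges[name]
        if name in _INT_PARAMS:
            hi = max(hi, lo + grid_length - 1)
            vals = np.unique(np.round(np.linspace(lo, hi, grid_length)).astype(int))
        elif name in _LOG_PARAMS:
            vals = np.geomspace(lo, hi, grid_length)
        else:
            vals = np.linspace(lo, hi, grid_length)
        return [{name: (int(v) if name in _INT_PARAMS else float(v))} for v in vals]
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    unit = sampler.random(grid_length)
    return [
        {name: _from_unit(u, name, spec.ranges[name]) for name, u in zip(names, row)}
        for row in unit
    ]


def _from_unit(u: float, name: str, bounds) -> float:
    lo, hi = bounds
    if name in _LOG_PARAMS:
        val = float(np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo))))
    else:
        val = float(lo + u * (hi - lo))
    return int(round(val)) if name in _INT_PARAMS else val


def _complexity_key(learner_id: str, params: dict) -> tuple:
    """Sort key for tie-breaking: smaller key = simpler model.

    Parsimony under equal CV score: largest penalty, smallest network,
    smallest cost, fewest trees.
    """
    if learner_id == "LLR":
        return (-params["penalty"],)
    if learner_id == "ELR":
        return (-params["penalty"], -params["l1_ratio"])
    if learner_id == "NN":
        return (params["size"],)
    if learner_id == "SVM":
        return (params["cost"], params["width_mult"])
    if learner_id == "BCART":
        return (params["n_trees"], params["depth"],
                params["learning_rate"], -params["min_node"])
    return ()


# ---------------------------------------------------------------------------
# cross-validation plans


@dataclass(frozen=True)
class CvPlan:
    """Outcome-stratified fold assignment, labels 1..V."""

    fold_assignment: np.ndarray
    n_folds: int
    seed: int

    def __post_init__(self):
        object.__setattr__(self, "fold_assignment", np.asarray(self.fold_assignment))

    def split(self):
        for v in range(1, self.n_folds + 1):
            held = self.fold_assignment == v
            yield np.flatnonzero(~held), np.flatnonzero(held)


def make_cv_plan(outcome, n_folds: int, seed: int = 0) -> CvPlan:
    """Stratified fold labels: within each outcome class, fold sizes differ
    by at most one."""
    outcome = np.asarray(outcome)
    rng = np.random.default_rng(seed)
    labels = np.zeros(len(outcome), dtype=int)
    offset = 0
    for cls in np.unique(outcome):
        idx = np.flatnonzero(outcome == cls)
        rng.shuffle(idx)
        # cycle fold labels, rotating the start so overall sizes balance
        labels[idx] = (np.arange(len(idx)) + offset) % n_folds + 1
        offset += len(idx)
    return CvPlan(fold_assignment=labels, n_folds=n_folds, seed=seed)


# ---------------------------------------------------------------------------
# AUC


def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC; tied scores count half a concordance
    per tied positive-negative pair."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n1 = int(np.sum(labels == 1))
    n0 = int(np.sum(labels == 0))
    if n1 == 0 or n0 == 0:
        raise UndefinedAUCError("AUC undefined: labels contain a single class")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


# ---------------------------------------------------------------------------
# learner backends


class _SvmBackend:
    """RBF-kernel SVM with training-data standardization and a
    median-heuristic kernel width scaled by the tuned multiplier.

    Probabilities come from the internal Platt calibration of
    :class:`~sklearn.svm.SVC`.
    """

    def __init__(self, cost: float, width_mult: float, seed: int):
        self.cost = cost
        self.width_mult = width_mult
        self.seed = seed

    def fit(self, X, y):
        self.scaler_ = StandardScaler().fit(X)
        Xs = self.scaler_.transform(X)
        self.gamma_ = self.width_mult * _median_heuristic_gamma(Xs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            self.svc_ = SVC(C=self.cost, gamma=self.gamma_, kernel="rbf",
                            probability=True, random_state=self.seed)
            self.svc_.fit(Xs, y)
        return self

    def predict_proba1(self, X):
        return self.svc_.predict_proba(self.scaler_.transform(X))[:, 1]

    def decision_scores(self, X):
        return self.svc_.decision_function(self.scaler_.transform(X))


def _median_heuristic_gamma(X, max_rows: int = 200) -> float:
    """1 / median pairwise squared distance, on a deterministic subsample."""
    n = X.shape[0]
    if n > max_rows:
        X = X[np.linspace(0, n - 1, max_rows).astype(int)]
    sq = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
    med = np.median(sq[np.triu_indices_from(sq, k=1)])
    return 1.0 / med if med > 0 else 1.0


class _NnBackend:
    """One-hidden-layer perceptron on standardized inputs."""

    def __init__(self, size: int, seed: int):
        self.size = size
        self.seed = seed

    def fit(self, X, y):
        self.scaler_ = StandardScaler().fit(X)
        self.mlp_ = MLPClassifier(hidden_layer_sizes=(self.size,), max_iter=500,
                                  random_state=self.seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.mlp_.fit(self.scaler_.transform(X), y)
        return self

    def predict_proba1(self, X):
        return self.mlp_.predict_proba(self.scaler_.transform(X))[:, 1]


class _GlmBackend:
    """Unpenalized logistic regression by damped Newton (IRLS).

    Converges to the exact MLE at machine precision — the saturated-model
    standardization identity relies on it (quasi-Newton solvers stall a few
    digits short) — with negligible per-call overhead, which matters because
    the bootstrap refits this model hundreds of times per replicate.
    Step-halving guards against divergence; near-separated data saturate
    harmlessly (predictions are clipped downstream).
    """

    max_iter = 100
    tol = 1e-12

    def fit(self, X, y):
        X = np.column_stack([np.ones(len(X)), np.asarray(X, dtype=float)])
        y = np.asarray(y, dtype=float)
        beta = np.zeros(X.shape[1])
        eta = X @ beta
        loglik = -np.sum(np.logaddexp(0.0, -(2.0 * y - 1.0) * eta))
        for _ in range(self.max_iter):
            mu = expit(eta)
            w = np.clip(mu * (1.0 - mu), 1e-12, None)
            grad = X.T @ (y - mu)
            hess = X.T @ (X * w[:, None])
            try:
                step = np.linalg.solve(hess, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(hess, grad, rcond=None)[0]
            scale = 1.0
            for _half in range(30):
                cand = beta + scale * step
                eta_c = X @ cand
                ll_c = -np.sum(np.logaddexp(0.0, -(2.0 * y - 1.0) * eta_c))
                if ll_c >= loglik - 1e-12:
                    break
                scale *= 0.5
            beta, eta, prev = cand, eta_c, loglik
            loglik = ll_c
            if np.max(np.abs(scale * step)) < self.tol or loglik - prev < 1e-13:
                break
        self.beta_ = beta
        return self

    def predict_proba1(self, X):
        X = np.column_stack([np.ones(len(X)), np.asarray(X, dtype=float)])
        return expit(X @ self.beta_)


class _SklearnBackend:
    def __init__(self, est):
        self.est = est

    def fit(self, X, y):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.est.fit(X, y)
        return self

    def predict_proba1(self, X):
        return self.est.predict_proba(X)[:, 1]


def make_backend(learner_id: str, params: dict, seed: int = 0):
    if learner_id == "LLR":
        # loose tolerance: penalized-path solvers converge in objective long
        # before the default coefficient tolerance, and ranking (AUC) is
        # insensitive to the residual coefficient wobble
        return _SklearnBackend(LogisticRegression(
            solver="liblinear", l1_ratio=1.0, C=1.0 / params["penalty"],
            max_iter=1000, tol=1e-2, random_state=seed))
    if learner_id == "ELR":
        return _SklearnBackend(LogisticRegression(
            solver="saga", l1_ratio=params["l1_ratio"], C=1.0 / params["penalty"],
            max_iter=1000, tol=1e-3, random_state=seed))
    if learner_id == "NN":
        return _NnBackend(size=params["size"], seed=seed)
    if learner_id == "SVM":
        return _SvmBackend(cost=params["cost"], width_mult=params["width_mult"],
                           seed=seed)
    if learner_id == "BCART":
        return _SklearnBackend(GradientBoostingClassifier(
            n_estimators=params["n_trees"], max_depth=params["depth"],
            learning_rate=params["learning_rate"],
            min_samples_leaf=params["min_node"], random_state=seed))
    if learner_id == "LR":
        return _GlmBackend()
    raise ValueError(f"unknown learner id {learner_id!r}")


# ---------------------------------------------------------------------------
# tuned models


@dataclass
class TunedModel:
    """A fitted Q-model with its chosen tuning parameters.

    ``oof_pred`` holds the cross-validated (out-of-fold) probability
    predictions at the chosen parameters, used by the super learner;
    ``cv_auc`` is the mean held-out-fold AUC at those parameters.
    """

    learner_id: str
    chosen_params: dict
    backend: object
    cv_auc: float = float("nan")
    oof_pred: np.ndarray = None
    seed: int = 0

    def predict_proba(self, X) -> np.ndarray:
        if self.backend is None:
            raise RuntimeError("model not fitted")
        return np.clip(self.backend.predict_proba1(np.asarray(X)),
                       PROB_CLIP, 1.0 - PROB_CLIP)


def _resolve_grid(spec, grid_length, seed):
    if isinstance(spec, str):
        spec = LearnerSpec(spec)
    return spec, make_tuning_grid(spec, grid_length, seed)


def _check_plan(y, plan):
    """Every fold must retain both outcome classes; one re-stratification is
    attempted before giving up."""
    for v in range(1, plan.n_folds + 1):
        train = y[plan.fold_assignment != v]
        held = y[plan.fold_assignment == v]
        if len(np.unique(train)) < 2 or len(np.unique(held)) < 2:
            return False
    return True


def tune_learner(design, outcome, spec, plan: CvPlan,
                 grid_length: int = 20, seed: int = 0) -> TunedModel:
    """Select tuning parameters by maximum mean out-of-fold AUC, then refit
    on all rows.

    ``design`` may be an :class:`~gcompml.design.ExpandedDesign` or a plain
    matrix.  Ties in mean AUC go to the simplest combination (largest
    penalty, smallest network, smallest cost, fewest trees).
    """
    X = design.matrix if hasattr(design, "matrix") else np.asarray(design)
    y = np.asarray(outcome)
    spec, grid = _resolve_grid(spec, grid_length, seed)
    if not _check_plan(y, plan):
        plan = make_cv_plan(y, plan.n_folds, seed=plan.seed + 1)
        if not _check_plan(y, plan):
            raise UndefinedAUCError(
                "a cross-validation fold lost an outcome class even after "
                "re-stratification; too few events for this fold count")

    best = None
    for params in grid:
        fold_aucs = []
        oof = np.full(len(y), np.nan)
        for train_idx, held_idx in plan.split():
            backend = make_backend(spec.learner_id, params, seed=seed)
            backend.fit(X[train_idx], y[train_idx])
            pred = backend.predict_proba1(X[held_idx])
            oof[held_idx] = np.clip(pred, PROB_CLIP, 1.0 - PROB_CLIP)
            fold_aucs.append(auc(pred, y[held_idx]))
        mean_auc = float(np.mean(fold_aucs))
        key = (-mean_auc, _complexity_key(spec.learner_id, params))
        if best is None or key < best[0]:
            best = (key, params, mean_auc, oof)

    _, params, cv_auc, oof = best
    backend = make_backend(spec.learner_id, params, seed=seed).fit(X, y)
    return TunedModel(learner_id=spec.learner_id, chosen_params=params,
                      backend=backend, cv_auc=cv_auc, oof_pred=oof, seed=seed)


def fit_model(learner_id: str, params: dict, X, y, seed: int = 0) -> TunedModel:
    """Refit a learner with frozen tuning parameters (bootstrap resamples)."""
    backend = make_backend(learner_id, params, seed=seed).fit(np.asarray(X), np.asarray(y))
    return TunedModel(learner_id=learner_id, chosen_params=dict(params),
                      backend=backend, seed=seed)


# ---------------------------------------------------------------------------
# super learner


@dataclass(frozen=True)
class SlWeights:
    """Simplex-constrained ensemble weights, one per library member."""

    weights: np.ndarray
    member_ids: tuple
    combination_scale: str = "logit"

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < -1e-12) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")
        object.__setattr__(self, "weights", np.clip(w, 0.0, None) / np.clip(w, 0.0, None).sum())


@dataclass
class SuperLearner:
    """AUC-weighted convex ensemble of tuned Q-models.

    Member predictions are combined as a weighted linear predictor: each
    probability is clipped, sent to the logit scale, averaged with the
    simplex weights and mapped back (``combination_scale='probability'``
    averages probabilities directly instead).
    """

    members: list
    sl_weights: SlWeights
    cv_auc: float = float("nan")

    @property
    def learner_id(self):
        return "SL"

    @property
    def chosen_params(self):
        return {m.learner_id: m.chosen_params for m in self.members}

    def predict_proba(self, X) -> np.ndarray:
        member_probs = np.column_stack([m.predict_proba(X) for m in self.members])
        out = combine_predictions(member_probs, self.sl_weights)
        return np.clip(out, PROB_CLIP, 1.0 - PROB_CLIP)


def combine_predictions(member_probs: np.ndarray, sl_weights: SlWeights) -> np.ndarray:
    probs = np.clip(member_probs, PROB_CLIP, 1.0 - PROB_CLIP)
    w = sl_weights.weights
    if sl_weights.combination_scale == "logit":
        return expit(logit(probs) @ w)
    return probs @ w


def optimize_sl_weights(oof_probs: np.ndarray, outcome, seed: int = 0,
                        combination_scale: str = "logit",
                        n_random_starts: int = 30) -> SlWeights:
    """Maximise the out-of-fold AUC of the convex member combination.

    The AUC of a convex combination is piecewise constant in the weights, so
    the search is gradient-free: candidate starts are the uniform point,
    every vertex of the simplex, and seeded Dirichlet draws; the best start
    (strict improvement only, so exact ties keep the uniform combination) is
    refined by pairwise mass transfers with a shrinking step.  Vertices being
    candidates guarantees the combined AUC is never below the best member's.
    """
    oof_probs = np.asarray(oof_probs, dtype=float)
    y = np.asarray(outcome)
    n_members = oof_probs.shape[1]
    if n_members == 1:
        return SlWeights(np.ones(1), member_ids=("m0",),
                         combination_scale=combination_scale)

    scores = logit(np.clip(oof_probs, PROB_CLIP, 1.0 - PROB_CLIP)) \
        if combination_scale == "logit" else np.clip(oof_probs, PROB_CLIP, 1.0 - PROB_CLIP)

    def objective(w):
        return auc(scores @ w, y)

    rng = np.random.default_rng(seed)
    starts = [np.full(n_members, 1.0 / n_members)]
    starts += [np.eye(n_members)[i] for i in range(n_members)]
    starts += list(rng.dirichlet(np.ones(n_members), size=n_random_starts))

    best_w, best_val = starts[0], objective(starts[0])
    for w in starts[1:]:
        val = objective(w)
        if val > best_val + 1e-12:
            best_w, best_val = w, val

    w = best_w.copy()
    for step in (0.25, 0.1, 0.05, 0.02):
        improved = True
        while improved:
            improved = False
            for i in range(n_members):
                for j in range(n_members):
                    if i == j or w[j] < step - 1e-12:
                        continue
                    cand = w.copy()
                    cand[i] += step
                    cand[j] -= step
                    val = objective(cand)
                    if val > best_val + 1e-12:
                        w, best_val, improved = cand, val, True
    return SlWeights(w, member_ids=tuple(f"m{i}" for i in range(n_members)),
                     combination_scale=combination_scale)


def fit_superlearner(design, outcome, library, plan: CvPlan,
                     grid_length: int = 20, seed: int = 0,
                     combination_scale: str = "logit") -> SuperLearner:
    """Tune every library member on the shared fold plan, estimate simplex
    weights from the members' out-of-fold predictions, and return the
    ensemble of full-data refits."""
    if not library:
        raise ValueError("super-learner library must be non-empty")
    y = np.asarray(outcome)
    members = []
    for offset, spec in enumerate(library):
        members.append(tune_learner(design, y, spec, plan,
                                    grid_length=grid_length, seed=seed + offset))
    oof = np.column_stack([m.oof_pred for m in members])
    sl_weights = optimize_sl_weights(oof, y, seed=seed,
                                     combination_scale=combination_scale)
    sl_weights = SlWeights(sl_weights.weights,
                           member_ids=tuple(m.learner_id for m in members),
                           combination_scale=combination_scale)
    cv_auc = auc(combine_predictions(oof, sl_weights), y)
    return SuperLearner(members=members, sl_weights=sl_weights, cv_auc=cv_auc)
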