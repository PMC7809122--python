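"""Simulation scenarios: data generation and the theoretical ACE.

Datasets are generated from logit-linear mechanisms: covariates are drawn
sequentially (each may depend linearly on covariates already generated, so
the dependence graph is acyclic by construction), then the exposure and the
outcome are Bernoulli draws whose logits are linear in the covariates and in
(covariates, exposure) respectively.  Covariate effects on the outcome may
be linear, quadratic (centred square) or step (threshold indicator), and a
covariate may modify the exposure effect through an exposure x covariate
interaction.

Two presets are shipped.  ``realistic_scenario`` has 22 correlated
covariates with 9 in the outcome model (4 linear, 3 quadratic, 2 step) and
one exposure x covariate interaction; ``simplistic_scenario`` has 9
independent covariates with 6 linear outcome effects and no interaction.
Both are synthetic calibrations: the coefficient values are this package's
own illustrative choices, selected once to give moderate exposure/outcome
prevalences and a positive risk difference of roughly 0.1-0.15, with
genuine confounding.  The two structures bracket the difficulty range a
Q-model faces in practice — many correlated covariates with non-linear
effects versus few independent covariates with linear effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import CohortTable

__all__ = [
    "CovariateSpec",
    "EffectTerm",
    "OutcomeModel",
    "ScenarioConfig",
    "SimulatedDataset",
    "TheoreticalAce",
    "realistic_scenario",
    "simplistic_scenario",
    "get_scenario",
    "simulate_cohort",
    "theoretical_ace",
    "generate_replicates",
    "oracle_cohort",
    "scenario_to_dict",
    "scenario_from_dict",
    "save_scenario",
    "load_scenario",
]


@dataclass(frozen=True)
class CovariateSpec:
    """One covariate: marginal family plus linear dependence on earlier ones.

    For ``family='normal'`` the draw is ``intercept + deps . X + N(0, sd)``;
    for ``family='bernoulli'`` it is Bernoulli with logit
    ``intercept + deps . X``.
    """

    name: str
    family: str = "normal"
    intercept: float = 0.0
    depends: dict = field(default_factory=dict)
    sd: float = 1.0

    def __post_init__(self):
        if self.family not in ("normal", "bernoulli"):
            raise ValueError(f"unknown covariate family {self.family!r}")


@dataclass(frozen=True)
class EffectTerm:
    """A typed covariate effect in the outcome logit.

    kind 'linear': coef * x; 'quadratic': coef * (x - center)^2;
    'step': coef * 1[x > threshold].
    """

    covariate: str
    kind: str
    coef: float
    center: float = 0.0
    threshold: float = 0.0

    def __post_init__(self):
        if self.kind not in ("linear", "quadratic", "step"):
            raise ValueError(f"unknown effect kind {self.kind!r}")

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        if self.kind == "linear":
            return self.coef * x
        if self.kind == "quadratic":
            return self.coef * (x - self.center) ** 2
        return self.coef * (x > self.threshold)


@dataclass(frozen=True)
class OutcomeModel:
    """Logit-linear outcome mechanism with typed covariate effects and
    optional exposure x covariate interactions (on the raw covariate)."""

    intercept: float
    exposure_coef: float
    terms: tuple
    interactions: tuple = ()           # (covariate name, coefficient)


@dataclass(frozen=True)
class ScenarioConfig:
    name: str
    covariates: tuple
    exposure_intercept: float
    exposure_coefs: dict               # covariate name -> logit coefficient
    outcome: OutcomeModel

    def __post_init__(self):
        seen = set()
        for spec in self.covariates:
            if spec.name in seen:
                raise ValueError(f"duplicate covariate {spec.name!r}")
            unknown = set(spec.depends) - seen
            if unknown:
                raise ValueError(
                    f"covariate {spec.name!r} depends on not-yet-generated "
                    f"covariates {sorted(unknown)}")
            seen.add(spec.name)
        for name in self.exposure_coefs:
            if name not in seen:
                raise ValueError(f"exposure model names unknown covariate {name!r}")
        for term in self.outcome.terms:
            if term.covariate not in seen:
                raise ValueError(f"outcome model names unknown covariate {term.covariate!r}")
        for name, _ in self.outcome.interactions:
            if name not in seen:
                raise ValueError(f"interaction names unknown covariate {name!r}")

    @property
    def k(self) -> int:
        return len(self.covariates)

    @property
    def binary_covariates(self) -> tuple:
        return tuple(s.name for s in self.covariates if s.family == "bernoulli")

    # -- mechanism evaluation ------------------------------------------------
    def draw_covariates(self, n: int, rng) -> dict:
        X = {}
        for spec in self.covariates:
            eta = np.full(n, spec.intercept, dtype=float)
            for dep, coef in spec.depends.items():
                eta += coef * X[dep]
            if spec.family == "normal":
                X[spec.name] = eta + rng.normal(0.0, spec.sd, size=n)
            else:
                X[spec.name] = (rng.random(n) < expit(eta)).astype(float)
        return X

    def exposure_logit(self, X: dict) -> np.ndarray:
        n = len(next(iter(X.values())))
        eta = np.full(n, self.exposure_intercept, dtype=float)
        for name, coef in self.exposure_coefs.items():
            eta += coef * X[name]
        return eta

    def outcome_logit(self, X: dict, z: np.ndarray) -> np.ndarray:
        om = self.outcome
        eta = om.intercept + om.exposure_coef * z
        for term in om.terms:
            eta = eta + term.evaluate(X[term.covariate])
        for name, coef in om.interactions:
            eta = eta + coef * z * X[name]
        return eta


@dataclass(frozen=True)
class SimulatedDataset:
    cohort: CohortTable
    seed: int
    scenario_name: str


@dataclass(frozen=True)
class TheoreticalAce:
    """Monte-Carlo true marginal effect with its Monte-Carlo SE."""

    ace: float
    mc_se: float
    n_datasets: int
    n_per_dataset: int

    def __float__(self):
        return self.ace


# ---------------------------------------------------------------------------
# presets (synthetic calibrations; see module docstring)


def simplistic_scenario() -> ScenarioConfig:
    """Nine mutually independent covariates; six linear outcome effects,
    no interaction.  Coefficients are synthetic and illustrative; see the
    module docstring."""
    covs = (
        CovariateSpec("X1"), CovariateSpec("X2"), CovariateSpec("X3"),
        CovariateSpec("X4"), CovariateSpec("X5"),
        CovariateSpec("X6", family="bernoulli", intercept=0.0),
        CovariateSpec("X7", family="bernoulli", intercept=-0.847),
        CovariateSpec("X8", family="bernoulli", intercept=-0.405),
        CovariateSpec("X9", family="bernoulli", intercept=0.0),
    )
    outcome = OutcomeModel(
        intercept=-0.9, exposure_coef=0.7,
        terms=(
            EffectTerm("X1", "linear", 0.35),
            EffectTerm("X2", "linear", -0.40),
            EffectTerm("X3", "linear", 0.45),
            EffectTerm("X5", "linear", 0.40),
            EffectTerm("X6", "linear", -0.50),
            EffectTerm("X7", "linear", 0.60),
        ),
    )
    return ScenarioConfig(
        name="simplistic", covariates=covs,
        exposure_intercept=-0.4,
        exposure_coefs={"X1": 0.4, "X2": 0.3, "X3": -0.4, "X4": 0.3,
                        "X6": 0.5, "X9": -0.3},
        outcome=outcome,
    )


def realistic_scenario() -> ScenarioConfig:
    """Twenty-two sequentially dependent covariates; nine in the outcome
    model (4 linear, 3 quadratic, 2 step) and one exposure x covariate
    interaction.  Coefficients are synthetic and illustrative; see the
    module docstring."""
    covs = (
        CovariateSpec("X1"),
        CovariateSpec("X2", depends={"X1": 0.4}),
        CovariateSpec("X3", family="bernoulli", depends={"X1": 0.5, "X2": -0.3}),
        CovariateSpec("X4", depends={"X3": 0.6}),
        CovariateSpec("X5", depends={"X2": 0.3, "X4": 0.3}),
        CovariateSpec("X6", family="bernoulli", depends={"X5": 0.4}),
        CovariateSpec("X7", depends={"X1": -0.3, "X6": 0.5}),
        CovariateSpec("X8", family="bernoulli", intercept=-0.4, depends={"X7": 0.4}),
        CovariateSpec("X9", depends={"X8": 0.5}),
        CovariateSpec("X10", family="bernoulli", depends={"X2": 0.4}),
        CovariateSpec("X11", depends={"X10": 0.5}),
        CovariateSpec("X12", depends={"X11": 0.3, "X3": 0.4}),
        CovariateSpec("X13", family="bernoulli", depends={"X12": -0.4}),
        CovariateSpec("X14", depends={"X13": 0.5}),
        CovariateSpec("X15", family="bernoulli", intercept=-0.6, depends={"X14": 0.3}),
        CovariateSpec("X16", depends={"X15": 0.4, "X1": 0.2}),
        CovariateSpec("X17", family="bernoulli", depends={"X16": -0.3}),
        CovariateSpec("X18", depends={"X17": 0.5}),
        CovariateSpec("X19", family="bernoulli", depends={"X18": 0.3}),
        CovariateSpec("X20", depends={"X19": 0.4, "X5": 0.2}),
        CovariateSpec("X21", family="bernoulli", intercept=0.3, depends={"X20": -0.3}),
        CovariateSpec("X22", family="bernoulli", depends={"X21": 0.4}),
    )
    outcome = OutcomeModel(
        intercept=-1.0, exposure_coef=0.65,
        terms=(
            EffectTerm("X2", "linear", 0.40),
            EffectTerm("X5", "linear", -0.35),
            EffectTerm("X8", "linear", 0.50),
            EffectTerm("X11", "linear", 0.30),
            EffectTerm("X1", "quadratic", 0.25, center=0.0),
            EffectTerm("X7", "quadratic", -0.20, center=0.0),
            EffectTerm("X14", "quadratic", 0.30, center=0.0),
            EffectTerm("X4", "step", 0.60, threshold=0.0),
            EffectTerm("X12", "step", -0.50, threshold=0.0),
        ),
        interactions=(("X5", 0.40),),
    )
    return ScenarioConfig(
        name="realistic", covariates=covs,
        exposure_intercept=-0.5,
        exposure_coefs={"X1": 0.3, "X2": -0.35, "X4": 0.4, "X6": 0.4,
                        "X8": -0.3, "X11": 0.3, "X14": 0.25, "X17": 0.3},
        outcome=outcome,
    )


_PRESETS = {"realistic": realistic_scenario, "simplistic": simplistic_scenario}


def get_scenario(name: str) -> ScenarioConfig:
    try:
        return _PRESETS[name]()
    except KeyError:
        raise ValueError(f"unknown scenario {name!r}; presets: {sorted(_PRESETS)}")


# ---------------------------------------------------------------------------
# generation


def _draw_xyz(scenario: ScenarioConfig, n: int, rng, z_prob=None):
    """One raw dataset; ``z_prob`` overrides the exposure mechanism with an
    independent Bernoulli (used for the theoretical ACE)."""
    X = scenario.draw_covariates(n, rng)
    if z_prob is None:
        z = (rng.random(n) < expit(scenario.exposure_logit(X))).astype(int)
    else:
        z = (rng.random(n) < z_prob).astype(int)
    y = (rng.random(n) < expit(scenario.outcome_logit(X, z))).astype(int)
    return X, z, y


def simulate_cohort(scenario: ScenarioConfig, n: int, seed: int) -> SimulatedDataset:
    """Generate one cohort from the scenario mechanism; reproducible given
    the seed.  Draws are retried (with a derived seed) in the rare event a
    small sample comes out single-class in Y or Z."""
    if n < 20:
        raise ValueError("n must be >= 20")
    ss = np.random.SeedSequence(seed)
    for attempt in range(100):
        rng = np.random.default_rng(ss)
        X, z, y = _draw_xyz(scenario, n, rng)
        if len(np.unique(y)) == 2 and len(np.unique(z)) == 2:
            break
        ss = np.random.SeedSequence(seed, spawn_key=(attempt + 1,))
    else:
        raise RuntimeError("scenario persistently produces single-class samples")
    cohort = CohortTable(
        outcome=y, exposure=z,
        covariates=pd.DataFrame({s.name: X[s.name] for s in scenario.covariates}),
        binary_covariates=scenario.binary_covariates,
    )
    return SimulatedDataset(cohort=cohort, seed=seed, scenario_name=scenario.name)


def generate_replicates(scenario: ScenarioConfig, n: int, n_reps: int,
                        master_seed: int):
    """Stream of independent replicate datasets.

    Per-replicate seeds derive from (master_seed, replicate index), so
    replicate r is identical no matter how many replicates are requested or
    in which order they are consumed.
    """
    for r in range(n_reps):
        seed = int(np.random.SeedSequence(master_seed, spawn_key=(r,))
                   .generate_state(1)[0] % (2 ** 31))
        yield simulate_cohort(scenario, n, seed)


def theoretical_ace(scenario: ScenarioConfig, n_datasets: int = 1000,
                    n_per_dataset: int = 10000, z_prob: float = 0.5,
                    seed: int = 0) -> TheoreticalAce:
    """True marginal risk difference of the scenario, by Monte Carlo.

    Each dataset is generated from the scenario mechanism except that Z is
    Bernoulli(z_prob) independent of the covariates; the per-dataset effect
    is the fitted univariate logistic contrast expit(b0 + b1) - expit(b0),
    which for a logistic model of Y on Z alone equals (in closed form, at
    the maximum likelihood estimate) the difference of outcome means between
    the two exposure arms.  The returned value averages the per-dataset
    effects; its Monte-Carlo SE makes the precision checkable.
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    ss = np.random.SeedSequence(seed)
    estimates = np.empty(n_datasets)
    done = 0
    attempts = 0
    while done < n_datasets:
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(attempts,)))
        attempts += 1
        if attempts > 10 * n_datasets + 100:
            raise RuntimeError("scenario persistently produces degenerate datasets")
        X, z, y = _draw_xyz(scenario, n_per_dataset, rng, z_prob=z_prob)
        n1 = z.sum()
        if n1 == 0 or n1 == len(z):
            continue                    # degenerate: an exposure arm is empty
        p1, p0 = y[z == 1].mean(), y[z == 0].mean()
        if (p1 in (0.0, 1.0)) and (p0 in (0.0, 1.0)) and p1 == p0:
            continue                    # single-class outcome: logistic fit undefined
        estimates[done] = p1 - p0
        done += 1
    mc_se = float(np.std(estimates, ddof=1) / np.sqrt(n_datasets)) if n_datasets > 1 else float("nan")
    return TheoreticalAce(ace=float(estimates.mean()), mc_se=mc_se,
                          n_datasets=n_datasets, n_per_dataset=n_per_dataset)


def scenario_to_dict(scenario: ScenarioConfig) -> dict:
    """Flat declarative form: one block per covariate, one per model."""
    return {
        "name": scenario.name,
        "covariates": [
            {"name": s.name, "family": s.family, "intercept": s.intercept,
             "sd": s.sd, "depends": dict(s.depends)}
            for s in scenario.covariates],
        "exposure_model": {"intercept": scenario.exposure_intercept,
                           "coefs": dict(scenario.exposure_coefs)},
        "outcome_model": {
            "intercept": scenario.outcome.intercept,
            "exposure_coef": scenario.outcome.exposure_coef,
            "terms": [
                {"covariate": t.covariate, "kind": t.kind, "coef": t.coef,
                 "center": t.center, "threshold": t.threshold}
                for t in scenario.outcome.terms],
            "interactions": [{"covariate": c, "coef": v}
                             for c, v in scenario.outcome.interactions],
        },
    }


def scenario_from_dict(raw: dict) -> ScenarioConfig:
    return ScenarioConfig(
        name=raw["name"],
        covariates=tuple(
            CovariateSpec(name=c["name"], family=c.get("family", "normal"),
                          intercept=c.get("intercept", 0.0),
                          depends=dict(c.get("depends", {}) or {}),
                          sd=c.get("sd", 1.0))
            for c in raw["covariates"]),
        exposure_intercept=raw["exposure_model"]["intercept"],
        exposure_coefs=dict(raw["exposure_model"].get("coefs", {}) or {}),
        outcome=OutcomeModel(
            intercept=raw["outcome_model"]["intercept"],
            exposure_coef=raw["outcome_model"]["exposure_coef"],
            terms=tuple(
                EffectTerm(covariate=t["covariate"], kind=t["kind"],
                           coef=t["coef"], center=t.get("center", 0.0),
                           threshold=t.get("threshold", 0.0))
                for t in raw["outcome_model"].get("terms", ())),
            interactions=tuple(
                (i["covariate"], i["coef"])
                for i in raw["outcome_model"].get("interactions", ()))),
    )


def save_scenario(scenario: ScenarioConfig, path) -> None:
    import yaml
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(scenario), fh, sort_keys=False)


def load_scenario(path) -> ScenarioConfig:
    import yaml
    with open(path) as fh:
        return scenario_from_dict(yaml.safe_load(fh))


def oracle_cohort(scenario: ScenarioConfig, dataset: SimulatedDataset) -> CohortTable:
    """Cohort whose covariates are the outcome model's own term columns.

    Fitting a plain logistic regression (learner 'LR', no spline expansion,
    no interactions) on this table is the correctly specified Q-model for a
    scenario without exposure x covariate interactions; scenarios with
    interactions additionally need ``include_interactions`` in the design.
    """
    cohort = dataset.cohort
    cols = {}
    binary = []
    for term in scenario.outcome.terms:
        x = cohort.covariates[term.covariate].to_numpy(dtype=float)
        name = f"{term.covariate}_{term.kind}"
        if term.kind == "linear":
            cols[name] = x
        elif term.kind == "quadratic":
            cols[name] = (x - term.center) ** 2
        else:
            cols[name] = (x > term.threshold).astype(float)
            binary.append(name)
    for cov, _ in scenario.outcome.interactions:
        name = f"{cov}_linear"
        if name not in cols:
            cols[name] = cohort.covariates[cov].to_numpy(dtype=float)
    return CohortTable(outcome=cohort.outcome, exposure=cohort.exposure,
                       covariates=pd.DataFrame(cols),
                       binary_covariates=tuple(binary), row_id=cohort.row_id)
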