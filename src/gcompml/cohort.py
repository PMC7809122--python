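"""Cohort tables and run configurations.

The canonical in-memory container is :class:`CohortTable`: a binary outcome
``Y``, a binary exposure ``Z`` (1 = exposed) and ``k`` pre-exposure
covariates ``X1..Xk``, each tagged continuous or binary.  Validation is
strict — missing values and out-of-range codes are rejected rather than
imputed or coerced.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CohortTable",
    "RunConfig",
    "CohortValidationError",
    "ConfigurationError",
    "read_cohort_csv",
    "read_run_config",
    "write_estimate_report",
    "read_estimate_report",
]

#: Learners usable as the Q-model.  "LR" is a plain (unpenalized) logistic
#: regression, provided for correctly specified reference fits.
LEARNER_IDS = ("LLR", "ELR", "NN", "SVM", "BCART", "SL", "LR")

#: Minimum cohort size: below this, ten-fold plans and bootstrap out-of-bag
#: sets degenerate too often to be meaningful.
MIN_ROWS = 20


class CohortValidationError(ValueError):
    """A cohort table violates a structural invariant."""


class ConfigurationError(ValueError):
    """A run configuration is malformed or incomplete."""


@dataclass(frozen=True)
class CohortTable:
    """Validated cohort of (Y, Z, X1..Xk) rows.

    Parameters
    ----------
    outcome : ndarray of int
        Binary outcome ``Y``; values in {0, 1}.
    exposure : ndarray of int
        Binary exposure ``Z``; 1 = exposed.
    covariates : DataFrame
        ``n x k`` covariate table, column order preserved from the source.
    binary_covariates : tuple of str
        Names of covariate columns tagged binary; the remainder are
        continuous.  Tagging is explicit, never inferred, so that 0/1-coded
        continuous scores cannot be silently misclassified.
    row_id : ndarray
        Stable row identifiers (defaults to 0..n-1).
    """

    outcome: np.ndarray
    exposure: np.ndarray
    covariates: pd.DataFrame
    binary_covariates: tuple = ()
    row_id: np.ndarray = None

    def __post_init__(self):
        outcome = np.asarray(self.outcome)
        exposure = np.asarray(self.exposure)
        object.__setattr__(self, "outcome", outcome)
        object.__setattr__(self, "exposure", exposure)
        if self.row_id is None:
            object.__setattr__(self, "row_id", np.arange(len(outcome)))
        else:
            object.__setattr__(self, "row_id", np.asarray(self.row_id))
        self._validate()

    # -- container protocol -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.outcome)

    @property
    def k(self) -> int:
        return self.covariates.shape[1]

    @property
    def covariate_names(self) -> tuple:
        return tuple(self.covariates.columns)

    @property
    def continuous_covariates(self) -> tuple:
        return tuple(c for c in self.covariates.columns if c not in self.binary_covariates)

    def is_binary(self, name: str) -> bool:
        return name in self.binary_covariates

    def subset(self, idx) -> "CohortTable":
        """Row subset (bootstrap resamples, out-of-bag sets).

        Skips re-validation: resamples may transiently violate class-balance
        invariants, which the caller is responsible for checking.
        """
        idx = np.asarray(idx)
        new = object.__new__(CohortTable)
        object.__setattr__(new, "outcome", self.outcome[idx])
        object.__setattr__(new, "exposure", self.exposure[idx])
        object.__setattr__(new, "covariates", self.covariates.iloc[idx].reset_index(drop=True))
        object.__setattr__(new, "binary_covariates", self.binary_covariates)
        object.__setattr__(new, "row_id", self.row_id[idx])
        return new

    # -- validation ----------------------------------------------------------
    def _validate(self):
        n = len(self.outcome)
        if len(self.exposure) != n or len(self.covariates) != n or len(self.row_id) != n:
            raise CohortValidationError("outcome, exposure, covariates and row_id lengths differ")
        if n < MIN_ROWS:
            raise CohortValidationError(f"cohort has {n} rows; at least {MIN_ROWS} required")
        for label, vec in (("outcome", self.outcome), ("exposure", self.exposure)):
            arr = np.asarray(vec, dtype=float)
            if np.isnan(arr).any():
                row = int(np.flatnonzero(np.isnan(arr))[0])
                raise CohortValidationError(f"missing value in {label} at row {row}")
            bad = ~np.isin(arr, (0.0, 1.0))
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise CohortValidationError(
                    f"non-binary value {arr[row]!r} in {label} at row {row}"
                )
        if len(np.unique(self.outcome)) < 2:
            raise CohortValidationError("outcome has a single class")
        if len(np.unique(self.exposure)) < 2:
            raise CohortValidationError("both exposure groups must be non-empty")
        unknown = set(self.binary_covariates) - set(self.covariates.columns)
        if unknown:
            raise CohortValidationError(f"binary tags name unknown columns: {sorted(unknown)}")
        for col in self.covariates.columns:
            vals = self.covariates[col].to_numpy()
            if not np.issubdtype(np.asarray(vals).dtype, np.number):
                raise CohortValidationError(f"covariate {col!r} is non-numeric")
            vals = vals.astype(float)
            if np.isnan(vals).any():
                row = int(np.flatnonzero(np.isnan(vals))[0])
                raise CohortValidationError(f"missing value in covariate {col!r} at row {row}")
            if col in self.binary_covariates:
                bad = ~np.isin(vals, (0.0, 1.0))
                if bad.any():
                    row = int(np.flatnonzero(bad)[0])
                    raise CohortValidationError(
                        f"covariate {col!r} tagged binary holds {vals[row]!r} at row {row}"
                    )
            elif len(np.unique(vals)) < 2:
                raise CohortValidationError(
                    f"continuous covariate {col!r} is constant"
                )


@dataclass(frozen=True)
class RunConfig:
    """Estimation run configuration.

    Defaults follow common practice for this estimator: ten-fold
    cross-validation, tuning grids of 20 candidate combinations, 500
    bootstrap iterations and 95% percentile intervals.
    """

    learner_id: str = "SL"
    n_folds: int = 10
    grid_length: int = 20
    n_boot: int = 500
    ci_level: float = 0.95
    seed: int = 0
    sl_library: tuple = ("LLR", "ELR", "NN", "SVM")
    #: combine super-learner members on the logit scale (the default) or on
    #: the probability scale.
    sl_combination_scale: str = "logit"
    #: re-estimate super-learner weights inside each bootstrap resample
    #: (member tuning parameters always stay frozen from the full sample).
    sl_refit_weights_in_bootstrap: bool = True
    #: percentile bootstrap interval by default; "normal" uses a
    #: normal-approximation interval from the bootstrap SE.
    ci_type: str = "percentile"

    def __post_init__(self):
        if self.learner_id not in LEARNER_IDS:
            raise ConfigurationError(
                f"unknown learner {self.learner_id!r}; expected one of {LEARNER_IDS}"
            )
        if self.n_folds < 2:
            raise ConfigurationError("n_folds must be >= 2")
        if self.grid_length < 1:
            raise ConfigurationError("grid_length must be >= 1")
        if self.n_boot < 1:
            raise ConfigurationError("n_boot must be >= 1")
        if not 0.0 < self.ci_level < 1.0:
            raise ConfigurationError("ci_level must lie strictly between 0 and 1")
        lib = tuple(self.sl_library)
        object.__setattr__(self, "sl_library", lib)
        if not lib:
            raise ConfigurationError("sl_library must be non-empty")
        if "BCART" in lib:
            raise ConfigurationError("BCART is excluded from the super-learner library")
        bad = set(lib) - {"LLR", "ELR", "NN", "SVM"}
        if bad:
            raise ConfigurationError(f"sl_library holds unknown learners: {sorted(bad)}")
        if self.sl_combination_scale not in ("logit", "probability"):
            raise ConfigurationError("sl_combination_scale must be 'logit' or 'probability'")
        if self.ci_type not in ("percentile", "normal"):
            raise ConfigurationError("ci_type must be 'percentile' or 'normal'")

    def with_(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# file I/O


def read_cohort_csv(path, outcome_col, exposure_col, covariate_cols,
                    binary_covariates=()) -> CohortTable:
    """Read a cohort from an RFC-4180 CSV with a header row.

    Parameters
    ----------
    covariate_cols : sequence of str
        Covariate columns, in the order they should appear in the table.
    binary_covariates : sequence of str
        Subset of ``covariate_cols`` tagged binary; the rest are continuous.

    Reading is deterministic and order-preserving: the same file always
    yields the identical table.
    """
    df = pd.read_csv(path)
    covariate_cols = list(covariate_cols)
    missing = [c for c in [outcome_col, exposure_col, *covariate_cols] if c not in df.columns]
    if missing:
        raise ConfigurationError(f"columns not found in {path}: {missing}")
    for label, col in (("outcome", outcome_col), ("exposure", exposure_col)):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.index[vals.isna()][0])
            raise CohortValidationError(
                f"missing or non-numeric {label} value in column {col!r} at row {row}"
            )
    return CohortTable(
        outcome=df[outcome_col].to_numpy(dtype=float).astype(int),
        exposure=df[exposure_col].to_numpy(dtype=float).astype(int),
        covariates=df[covariate_cols].astype(float),
        binary_covariates=tuple(binary_covariates),
    )


def read_run_config(path) -> RunConfig:
    """Read a flat YAML (or JSON) run-configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config file {path} is not a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    if "sl_library" in raw:
        raw["sl_library"] = tuple(raw["sl_library"])
    return RunConfig(**raw)


def write_estimate_report(estimate, path) -> None:
    """Write an ACE estimate as a flat key/value report.

    Floats are serialised at 12 significant digits so that a write/read
    round-trip reproduces the estimate exactly at that precision.
    """
    fields = {
        "ace_hat": estimate.ace_hat,
        "se": estimate.se,
        "ci_lo": estimate.ci_lo,
        "ci_hi": estimate.ci_hi,
        "ci_level": estimate.ci_level,
        "n_boot": estimate.n_boot_completed,
        "learner_id": estimate.learner_id,
        "seed": estimate.seed,
    }
    with open(path, "w") as fh:
        for key, val in fields.items():
            if isinstance(val, float):
                fh.write(f"{key},{_fmt(val)}\n")
            else:
                fh.write(f"{key},{val}\n")


def read_estimate_report(path) -> dict:
    """Read back a flat key/value estimate report."""
    out = {}
    with open(path) as fh:
        for line in fh:
            key, _, val = line.rstrip("\n").partition(",")
            try:
                num = float(val)
                out[key] = int(num) if key in ("n_boot", "seed") else num
            except ValueError:
                out[key] = val
    return out


def _fmt(x: float) -> str:
    if not math.isfinite(x):
        return repr(x)
    return f"{x:.12g}"
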