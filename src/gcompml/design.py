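"""Q-model design matrices.

The outcome regression f(Y|Z,X) is made flexible by expanding every
continuous covariate into a cubic b-spline basis and pairing every
covariate-derived column with an exposure interaction column.  The fitted
expansion (knots, standardization moments) is learned on training data only
and then applied unchanged to counterfactual or out-of-bag rows, with
out-of-range values clamped to the training boundary knots to avoid wild
cubic extrapolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .cohort import CohortTable

__all__ = [
    "DesignSpec",
    "ExpandedDesign",
    "DegenerateCovariateError",
    "spline_basis",
    "make_knots",
    "fit_design",
    "transform_design",
]

Z_OVERRIDES = ("observed", "all_one", "all_zero")


class DegenerateCovariateError(ValueError):
    """A continuous covariate is constant in the training data."""


@dataclass(frozen=True)
class DesignSpec:
    """How to expand the covariates into the Q-model feature matrix.

    ``spline_df`` is the number of basis columns per continuous covariate
    (0 disables expansion and passes the raw value through).  With
    ``spline_df == spline_degree`` the basis has no interior knots — the
    minimal flexible cubic default.  ``standardize`` records the training
    z-score moments so scale-sensitive learners (NN, SVM) can request a
    standardized matrix; penalized regressions standardize internally.
    """

    spline_degree: int = 3
    spline_df: int = 3
    include_interactions: bool = True
    standardize: bool = False

    def __post_init__(self):
        if self.spline_df != 0 and self.spline_df < self.spline_degree:
            raise ValueError("spline_df must be >= spline_degree (or 0 to disable)")
        if self.spline_degree < 1:
            raise ValueError("spline_degree must be >= 1")


@dataclass
class ExpandedDesign:
    """A fitted design expansion plus the matrix it produced on its training data.

    ``column_meta`` rows carry per-column provenance: source covariate,
    basis index, and whether the column is the exposure main effect or an
    exposure interaction.  ``knots``/``means``/``sds`` are the fitted state
    reused for every subsequent transform.
    """

    spec: DesignSpec
    covariate_names: tuple
    binary_covariates: tuple
    knots: dict                       # continuous covariate -> knot vector
    column_meta: pd.DataFrame
    means: np.ndarray
    sds: np.ndarray
    matrix: np.ndarray                # training matrix, observed exposure

    @property
    def p(self) -> int:
        return len(self.column_meta)

    def standardized(self, matrix: np.ndarray) -> np.ndarray:
        """Apply the training z-score; exact inverse of :meth:`unstandardized`."""
        return (matrix - self.means) / self.sds

    def unstandardized(self, matrix: np.ndarray) -> np.ndarray:
        return matrix * self.sds + self.means


def make_knots(x: np.ndarray, df: int, degree: int) -> np.ndarray:
    """Knot vector with boundary knots at the training min/max (multiplicity
    degree+1) and ``df - degree`` interior knots at equally spaced quantiles."""
    lo, hi = float(np.min(x)), float(np.max(x))
    if lo == hi:
        raise DegenerateCovariateError("constant covariate: cannot place spline knots")
    n_interior = df - degree
    if n_interior > 0:
        probs = np.arange(1, n_interior + 1) / (n_interior + 1)
        interior = np.quantile(x, probs)
    else:
        interior = np.empty(0)
    return np.concatenate([np.full(degree + 1, lo), interior, np.full(degree + 1, hi)])


def spline_basis(x, knots, degree: int) -> np.ndarray:
    """B-spline basis of ``x`` with the constant column excluded.

    The full basis is a partition of unity; dropping its first column leaves
    the intercept to the learner.  Values outside the boundary knots are
    clamped before evaluation, so all entries lie in [0, 1].
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    if np.any(np.diff(knots) < 0):
        raise ValueError("knots must be non-decreasing")
    lo, hi = knots[degree], knots[-degree - 1]
    xc = np.clip(x, lo, hi)
    full = BSpline.design_matrix(xc, knots, degree).toarray()
    return full[:, 1:]


def fit_design(cohort: CohortTable, spec: DesignSpec) -> ExpandedDesign:
    """Fit the expansion on a training cohort.

    Column layout: exposure main effect, covariate blocks in cohort order
    (binary covariates pass through unexpanded), then one interaction column
    per covariate-derived column when interactions are on, in the same order.
    """
    knots = {}
    for name in cohort.continuous_covariates:
        if spec.spline_df > 0:
            x = cohort.covariates[name].to_numpy(dtype=float)
            if np.min(x) == np.max(x):
                raise DegenerateCovariateError(
                    f"continuous covariate {name!r} is constant in the training data"
                )
            knots[name] = make_knots(x, spec.spline_df, spec.spline_degree)

    meta = [{"name": "Z", "source": "Z", "basis_index": -1,
             "is_exposure_main": True, "is_interaction": False}]
    for name in cohort.covariate_names:
        if name in knots:
            for j in range(spec.spline_df):
                meta.append({"name": f"{name}_bs{j + 1}", "source": name,
                             "basis_index": j, "is_exposure_main": False,
                             "is_interaction": False})
        else:
            meta.append({"name": name, "source": name, "basis_index": -1,
                         "is_exposure_main": False, "is_interaction": False})
    if spec.include_interactions:
        for row in list(meta[1:]):
            meta.append({"name": f"Z:{row['name']}", "source": row["source"],
                         "basis_index": row["basis_index"],
                         "is_exposure_main": False, "is_interaction": True})
    column_meta = pd.DataFrame(meta)

    design = ExpandedDesign(
        spec=spec,
        covariate_names=cohort.covariate_names,
        binary_covariates=tuple(cohort.binary_covariates),
        knots=knots,
        column_meta=column_meta,
        means=np.zeros(len(column_meta)),
        sds=np.ones(len(column_meta)),
        matrix=np.empty((0, len(column_meta))),
    )
    matrix = transform_design(design, cohort, "observed")
    design.matrix = matrix
    if spec.standardize:
        design.means = matrix.mean(axis=0)
        sds = matrix.std(axis=0, ddof=0)
        sds[sds == 0.0] = 1.0
        design.sds = sds
    return design


def transform_design(fitted: ExpandedDesign, cohort: CohortTable,
                     z_override: str = "observed") -> np.ndarray:
    """Evaluate the fitted expansion on (possibly new) rows.

    ``z_override`` replaces the exposure column — and hence every interaction
    column — by all ones or all zeros while leaving covariate-only columns
    untouched; this is how counterfactual design matrices are built.
    """
    if z_override not in Z_OVERRIDES:
        raise ValueError(f"z_override must be one of {Z_OVERRIDES}")
    if (cohort.covariate_names != fitted.covariate_names
            or tuple(cohort.binary_covariates) != fitted.binary_covariates):
        raise ValueError(
            "covariate schema mismatch: expected "
            f"{fitted.covariate_names} (binary {fitted.binary_covariates}), got "
            f"{cohort.covariate_names} (binary {tuple(cohort.binary_covariates)})"
        )
    n = cohort.n
    if z_override == "all_one":
        z = np.ones(n)
    elif z_override == "all_zero":
        z = np.zeros(n)
    else:
        z = cohort.exposure.astype(float)

    blocks = [z[:, None]]
    for name in cohort.covariate_names:
        x = cohort.covariates[name].to_numpy(dtype=float)
        if name in fitted.knots:
            blocks.append(spline_basis(x, fitted.knots[name], fitted.spec.spline_degree))
        else:
            blocks.append(x[:, None])
    main = np.hstack(blocks)
    if fitted.spec.include_interactions:
        main = np.hstack([main, main[:, 1:] * z[:, None]])
    return main
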