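"""Performance criteria for replicate simulation studies, plus calibration curves.

Seven criteria score a set of replicate ACE estimates against the
theoretical ACE:

* MB   — mean bias, reported in percentage points: 100 x mean(est - true);
* RMSE — root mean square error (n denominator);
* ESD  — empirical SD of the estimates across replicates (n-1 denominator);
* ASD  — asymptotic SD: the mean of the per-replicate bootstrap SEs;
* VEB  — variance estimation bias, 100 x (ASD - ESD) / ESD, on the SD scale;
* coverage — % of nominal CIs containing the true ACE;
* power    — % of CIs excluding zero.

With the denominators above, RMSE^2 = (MB/100)^2 + ESD_n^2 exactly, where
ESD_n is the uncorrected-denominator variant (also exposed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ReplicateResult",
    "PerformanceReport",
    "compute_report",
    "calibration_curve",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReplicateResult:
    """One replicate's ACE estimate, bootstrap SE and interval."""

    ace_hat: float
    se: float
    ci_lo: float
    ci_hi: float
    seed: int = 0

    def __post_init__(self):
        if self.ci_lo > self.ci_hi:
            raise ValueError("ci_lo must not exceed ci_hi")

    @classmethod
    def from_estimate(cls, est) -> "ReplicateResult":
        return cls(ace_hat=est.ace_hat, se=est.se, ci_lo=est.ci_lo,
                   ci_hi=est.ci_hi, seed=est.seed)


@dataclass(frozen=True)
class PerformanceReport:
    mb_pct: float
    rmse: float
    esd: float
    esd_uncorrected: float
    asd: float
    veb_pct: float
    veb_pct_variance_scale: float
    coverage_pct: float
    power_pct: float
    n_reps: int
    true_ace: float

    def to_dict(self) -> dict:
        return {
            "mb_pct": self.mb_pct, "rmse": self.rmse, "esd": self.esd,
            "asd": self.asd, "veb_pct": self.veb_pct,
            "coverage_pct": self.coverage_pct, "power_pct": self.power_pct,
            "n_reps": self.n_reps, "true_ace": self.true_ace,
        }


def compute_report(results, true_ace: float) -> PerformanceReport:
    """Score replicate estimates against the true (theoretical) ACE."""
    results = list(results)
    if len(results) < 2:
        raise ValueError("at least 2 replicate results required (SDs undefined)")
    est = np.array([r.ace_hat for r in results], dtype=float)
    se = np.array([r.se for r in results], dtype=float)
    lo = np.array([r.ci_lo for r in results], dtype=float)
    hi = np.array([r.ci_hi for r in results], dtype=float)

    bias = float(np.mean(est - true_ace))
    rmse = float(np.sqrt(np.mean((est - true_ace) ** 2)))
    esd = float(np.std(est, ddof=1))
    esd_n = float(np.std(est, ddof=0))
    asd = float(np.mean(se))
    veb = 100.0 * (asd - esd) / esd if esd > 0 else float("nan")
    veb_var = 100.0 * (asd ** 2 - esd ** 2) / esd ** 2 if esd > 0 else float("nan")
    coverage = 100.0 * float(np.mean((lo <= true_ace) & (true_ace <= hi)))
    power = 100.0 * float(np.mean((lo > 0.0) | (hi < 0.0)))
    return PerformanceReport(
        mb_pct=100.0 * bias, rmse=rmse, esd=esd, esd_uncorrected=esd_n,
        asd=asd, veb_pct=veb, veb_pct_variance_scale=veb_var,
        coverage_pct=coverage, power_pct=power,
        n_reps=len(results), true_ace=float(true_ace),
    )


def calibration_curve(predicted, observed, n_bins: int = 10):
    """Equal-frequency calibration curve.

    Bins the predictions into ``n_bins`` quantile bins and returns one
    ``(mean predicted, observed event rate, count)`` triple per non-empty
    bin.  When there are fewer distinct predictions than requested bins,
    coincident quantile edges merge bins (logged).
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if len(predicted) != len(observed):
        raise ValueError("predicted and observed lengths differ")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    edges = np.unique(np.quantile(predicted, np.linspace(0, 1, n_bins + 1)))
    if len(edges) < n_bins + 1:
        logger.info("calibration bins merged: %d distinct edges for %d bins",
                    len(edges) - 1, n_bins)
    if len(edges) == 1:                 # constant predictions: one bin
        return [(float(predicted.mean()), float(observed.mean()), len(predicted))]
    which = np.clip(np.searchsorted(edges, predicted, side="right") - 1,
                    0, len(edges) - 2)
    out = []
    for b in range(len(edges) - 1):
        mask = which == b
        if mask.any():
            out.append((float(predicted[mask].mean()),
                        float(observed[mask].mean()), int(mask.sum())))
    return out
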