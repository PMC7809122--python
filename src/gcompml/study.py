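"""Simulation-study driver: replicate generation -> estimation -> scoring.

Runs the full pipeline for one (scenario, learner, sample size) cell:
generate replicate cohorts, estimate the ACE with bootstrap intervals on
each, and score the seven performance criteria against the scenario's
theoretical ACE.  Per-replicate results can be cached on disk so an
interrupted run resumes without recomputing finished replicates.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass

import numpy as np

from .cohort import RunConfig
from .design import DesignSpec
from .engine import bootstrap_ace, gc_point_estimate
from .metrics import PerformanceReport, ReplicateResult, compute_report
from .simulate import (ScenarioConfig, generate_replicates, oracle_cohort,
                       theoretical_ace)

__all__ = ["StudyCell", "run_replicate", "run_study"]


@dataclass(frozen=True)
class StudyCell:
    """One row of a study grid: scenario x learner x sample size."""

    scenario: ScenarioConfig
    config: RunConfig
    n: int
    n_reps: int
    #: 'flexible' expands splines + interactions; 'oracle' fits the
    #: correctly specified linear predictor with a plain logistic regression.
    design: str = "flexible"

    def design_spec(self) -> DesignSpec:
        if self.design == "oracle":
            interactions = bool(self.scenario.outcome.interactions)
            return DesignSpec(spline_df=0, include_interactions=interactions)
        return DesignSpec()


def run_replicate(cell: StudyCell, dataset) -> ReplicateResult:
    cohort = dataset.cohort
    if cell.design == "oracle":
        cohort = oracle_cohort(cell.scenario, dataset)
    config = cell.config.with_(seed=dataset.seed)
    spec = cell.design_spec()
    fit = gc_point_estimate(cohort, config, spec)
    est = bootstrap_ace(cohort, config, point_fit=fit, design_spec=spec)
    return ReplicateResult.from_estimate(est)


def _cache_key(cell: StudyCell, seed: int) -> str:
    payload = json.dumps({
        "scenario": cell.scenario.name, "n": cell.n, "seed": seed,
        "design": cell.design,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cell.config).items() if k != "seed"},
    }, sort_keys=True)
    return hashlib.sha1(payload.encode()).hexdigest()


def run_study(cell: StudyCell, master_seed: int, true_ace: float = None,
              cache_dir: str = None, theo_kwargs: dict = None,
              progress=None) -> PerformanceReport:
    """Run one study cell end to end and score it.

    ``true_ace`` defaults to the scenario's Monte-Carlo theoretical ACE
    (``theo_kwargs`` are forwarded to :func:`~gcompml.simulate.theoretical_ace`).
    Replicate seeds derive from (master_seed, replicate index), so results
    are independent of execution order and resume safely from ``cache_dir``.
    """
    if true_ace is None:
        true_ace = theoretical_ace(cell.scenario, seed=master_seed,
                                   **(theo_kwargs or {})).ace
    if cache_dir:
        os.makedirs(cache_dir, exist_ok=True)
    results = []
    for dataset in generate_replicates(cell.scenario, cell.n, cell.n_reps,
                                       master_seed):
        cache_path = None
        if cache_dir:
            cache_path = os.path.join(cache_dir,
                                      _cache_key(cell, dataset.seed) + ".json")
            if os.path.exists(cache_path):
                with open(cache_path) as fh:
                    results.append(ReplicateResult(**json.load(fh)))
                continue
        res = run_replicate(cell, dataset)
        if cache_path:
            with open(cache_path, "w") as fh:
                json.dump(asdict(res), fh)
        results.append(res)
        if progress is not None:
            progress(len(results))
    return compute_report(results, true_ace)
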