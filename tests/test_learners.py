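"""Tuning grids, CV plans, rank-based AUC and CV-AUC learner tuning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gcompml import (DesignSpec, LearnerSpec, UndefinedAUCError, auc,
                     fit_design, make_cv_plan, make_tuning_grid, tune_learner)
from gcompml.learners import fit_model

from conftest import build_cohort


def pairwise_auc(scores, labels):
    """Brute-force concordance over every positive-negative pair (oracle)."""
    scores = np.asarray(scores, dtype=float)
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_separation_is_one(self):
        assert auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_is_half(self):
        assert auc([0.5] * 10, [0, 1] * 5) == 0.5

    def test_worked_example(self):
        scores, labels = (0.1, 0.4, 0.35, 0.8), (0, 0, 1, 1)
        assert auc(scores, labels) == pytest.approx(0.75)
        assert auc(scores, labels) == pytest.approx(pairwise_auc(scores, labels))

    def test_single_class_raises(self):
        with pytest.raises(UndefinedAUCError):
            auc([0.1, 0.2], [1, 1])

    @given(st.data())
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_equals_pairwise_concordance(self, data):
        """Oracle equivalence on arbitrary instances up to n = 200,
        including heavy ties."""
        n = data.draw(st.integers(4, 200))
        labels = np.array(data.draw(st.lists(st.integers(0, 1),
                                             min_size=n, max_size=n)))
        if len(np.unique(labels)) < 2:
            labels[0], labels[1] = 0, 1
        # coarse score values force ties
        scores = np.array(data.draw(st.lists(
            st.sampled_from([0.0, 0.1, 0.25, 0.5, 0.5, 0.9, 1.0]),
            min_size=n, max_size=n)))
        assert auc(scores, labels) == pytest.approx(pairwise_auc(scores, labels),
                                                    abs=1e-12)


class TestTuningGrid:
    def test_nn_grid_of_20_distinct_integer_sizes(self):
        grid = make_tuning_grid(LearnerSpec("NN"), 20, seed=0)
        sizes = [g["size"] for g in grid]
        assert len(sizes) == 20 and len(set(sizes)) == 20
        assert all(isinstance(s, int) and s >= 1 for s in sizes)

    def test_grid_of_one_is_range_midpoint(self):
        (g,) = make_tuning_grid(LearnerSpec("LLR"), 1, seed=0)
        lo, hi = LearnerSpec("LLR").ranges["penalty"]
        assert g["penalty"] == pytest.approx(np.sqrt(lo * hi))  # log-midpoint

    def test_same_seed_same_grid(self):
        a = make_tuning_grid(LearnerSpec("BCART"), 20, seed=5)
        b = make_tuning_grid(LearnerSpec("BCART"), 20, seed=5)
        assert a == b
        c = make_tuning_grid(LearnerSpec("BCART"), 20, seed=6)
        assert a != c

    @pytest.mark.parametrize("learner_id,n_params", [
        ("ELR", 2), ("SVM", 2), ("BCART", 4)])
    def test_latin_hypercube_grids_cover_ranges(self, learner_id, n_params):
        spec = LearnerSpec(learner_id)
        grid = make_tuning_grid(spec, 20, seed=1)
        assert len(grid) == 20
        for combo in grid:
            assert len(combo) == n_params
            for name, value in combo.items():
                lo, hi = spec.ranges[name]
                assert lo - 1e-9 <= value <= hi + 1e-9


class TestCvPlan:
    @pytest.mark.parametrize("n,prev,folds", [(100, 0.3, 10), (47, 0.5, 5), (23, 0.25, 3)])
    def test_stratified_fold_sizes_within_one_per_class(self, n, prev, folds):
        rng = np.random.default_rng(0)
        y = (rng.random(n) < prev).astype(int)
        plan = make_cv_plan(y, folds, seed=1)
        assert set(np.unique(plan.fold_assignment)) <= set(range(1, folds + 1))
        for cls in (0, 1):
            counts = np.bincount(plan.fold_assignment[y == cls], minlength=folds + 1)[1:]
            assert counts.max() - counts.min() <= 1

    def test_split_covers_all_rows_once(self):
        y = (np.arange(40) % 2)
        plan = make_cv_plan(y, 4, seed=0)
        held = np.concatenate([h for _, h in plan.split()])
        assert sorted(held) == list(range(40))


class TestTuneLearner:
    def _design(self, n=200, seed=0, separable=False):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        if separable:
            y = (x > 0).astype(int)
        else:
            y = (rng.random(n) < 0.5).astype(int)
            y[:2] = [0, 1]
        z = (np.arange(n) % 2)
        cohort = build_cohort(y, z, {"X1": x})
        return fit_design(cohort, DesignSpec()), cohort.outcome

    def test_grid_of_one_reports_that_combination(self):
        design, y = self._design()
        plan = make_cv_plan(y, 5, seed=0)
        model = tune_learner(design, y, "LLR", plan, grid_length=1, seed=0)
        (expected,) = make_tuning_grid(LearnerSpec("LLR"), 1)
        assert model.chosen_params == expected
        assert 0.0 <= model.cv_auc <= 1.0

    def test_separable_data_reaches_high_cv_auc(self):
        design, y = self._design(separable=True)
        plan = make_cv_plan(y, 10, seed=0)
        model = tune_learner(design, y, "LLR", plan, grid_length=10, seed=0)
        assert model.cv_auc >= 0.95

    def test_tie_break_prefers_strongest_penalty(self):
        """When all grid points give identical CV AUC (here: penalties so
        strong every fit is intercept-only), the most parsimonious
        combination is selected."""
        design, y = self._design()
        plan = make_cv_plan(y, 5, seed=0)
        spec = LearnerSpec("LLR", ranges={"penalty": (1e4, 1e6)})
        model = tune_learner(design, y, spec, plan, grid_length=5, seed=0)
        assert model.chosen_params["penalty"] == pytest.approx(1e6)

    def test_reproducible_given_seed(self):
        design, y = self._design(separable=True)
        plan = make_cv_plan(y, 5, seed=3)
        a = tune_learner(design, y, "NN", plan, grid_length=3, seed=3)
        b = tune_learner(design, y, "NN", plan, grid_length=3, seed=3)
        assert a.chosen_params == b.chosen_params
        np.testing.assert_allclose(a.predict_proba(design.matrix),
                                   b.predict_proba(design.matrix), atol=1e-10)

    def test_predictions_strictly_inside_unit_interval(self):
        design, y = self._design(separable=True)
        plan = make_cv_plan(y, 5, seed=0)
        model = tune_learner(design, y, "LLR", plan, grid_length=5, seed=0)
        probs = model.predict_proba(design.matrix)
        assert np.all(probs > 0) and np.all(probs < 1)

    def test_too_few_events_for_folds_raises(self):
        rng = np.random.default_rng(0)
        y = np.zeros(30, dtype=int)
        y[:2] = 1                      # 2 events cannot stratify 5 folds
        design, _ = self._design(n=30)
        plan = make_cv_plan(y, 5, seed=0)
        with pytest.raises(UndefinedAUCError, match="fold"):
            tune_learner(design, y, "LLR", plan, grid_length=2, seed=0)

    @pytest.mark.parametrize("learner_id", ["ELR", "NN", "SVM", "BCART"])
    def test_every_learner_fits_and_predicts(self, learner_id):
        design, y = self._design(n=60, separable=True)
        plan = make_cv_plan(y, 3, seed=0)
        model = tune_learner(design, y, learner_id, plan, grid_length=2, seed=0)
        probs = model.predict_proba(design.matrix)
        assert probs.shape == (60,)
        assert np.all((probs > 0) & (probs < 1))
        assert model.oof_pred.shape == (60,)
        assert not np.isnan(model.oof_pred).any()


class TestFitModel:
    def test_frozen_refit_uses_given_params(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 3))
        y = (X[:, 0] > 0).astype(int)
        model = fit_model("LLR", {"penalty": 1.0}, X, y, seed=0)
        assert model.chosen_params == {"penalty": 1.0}
        assert np.isnan(model.cv_auc)
        assert model.predict_proba(X).shape == (50,)
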