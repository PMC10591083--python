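"""Ensemble niche model: members, evaluation, consensus projection."""

import numpy as np
import pytest

from cwrgap.rasters import EnvStack
from cwrgap.sdm import (
    EnsembleConfig,
    EnsembleSDM,
    FittedModel,
    ensemble_project,
    evaluate,
    fit_envelope,
    fit_logistic,
    sample_pseudo_absences,
)


class TestPseudoAbsences:
    def test_disjoint_correct_size_and_reproducible(self, small_env):
        presences = {(0, 0), (5, 5), (10, 10)}
        pa = sample_pseudo_absences(presences, small_env, n_sets=3, n_per_set=7, seed=42)
        assert len(pa.absence_sets) == 3
        for absences in pa.absence_sets:
            assert len(absences) == 7
            assert absences.isdisjoint(presences)
        again = sample_pseudo_absences(presences, small_env, n_sets=3, n_per_set=7, seed=42)
        assert pa.absence_sets == again.absence_sets
        other = sample_pseudo_absences(presences, small_env, n_sets=3, n_per_set=7, seed=43)
        assert pa.absence_sets != other.absence_sets

    def test_insufficient_candidates_raise(self, small_env):
        presences = {(0, 0)}
        with pytest.raises(ValueError, match="pseudo-absences"):
            sample_pseudo_absences(presences, small_env, n_sets=1, n_per_set=10**6)


class TestEnvelope:
    def test_q0_envelope_contains_its_support(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(10, 20, size=(50, 3))
        model = fit_envelope(X, q=0)
        assert np.all(model.suitability(X) == 1.0)

    def test_outside_envelope_scores_zero(self):
        X = np.array([[10.0], [20.0]])
        model = fit_envelope(X, q=0)
        assert model.suitability(np.array([[25.0]]))[0] == 0.0

    def test_percentile_bounds_on_uniform_sample(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 1, size=(20000, 1))
        model = fit_envelope(X, q=5)
        assert model.lower[0] == pytest.approx(0.05, abs=0.01)
        assert model.upper[0] == pytest.approx(0.95, abs=0.01)

    def test_empty_presences_rejected(self):
        with pytest.raises(ValueError):
            fit_envelope(np.empty((0, 2)), q=0)


class TestLogistic:
    def test_separable_layout_reaches_tss_one(self):
        X = np.concatenate([np.linspace(0, 1, 20), np.linspace(2, 3, 20)])[:, None]
        y = np.array([0] * 20 + [1] * 20)
        model = fit_logistic(X, y)
        tss, auc, th = evaluate(model.suitability(X), y, split=0, reps=0)
        assert tss == 1.0 and auc == 1.0

    def test_labels_independent_of_layers_give_no_skill(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(400, 2))
        y = rng.integers(0, 2, size=400)
        model = fit_logistic(X, y)
        assert np.all(np.abs(model.coef) < 0.3)
        tss, auc, _ = evaluate(model.suitability(X), y, split=0, reps=0)
        assert abs(auc - 0.5) < 0.1

    def test_constant_layer_gives_prevalence(self):
        X = np.ones((10, 1))
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        with pytest.warns(UserWarning, match="constant"):
            model = fit_logistic(X, y)
        assert model.suitability(X) == pytest.approx(np.full(10, 0.3))

    def test_complete_separation_is_bounded_and_flagged(self):
        X = np.concatenate([np.zeros(20), np.ones(20)])[:, None]
        y = np.array([0] * 20 + [1] * 20)
        model = fit_logistic(X, y)
        assert model.separation_flagged
        assert np.all(np.isfinite(model.coef))


class TestEvaluate:
    def test_perfect_separation(self):
        tss, auc, _ = evaluate([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], split=0, reps=0)
        assert (tss, auc) == (1.0, 1.0)

    def test_uninformative_scores(self):
        tss, auc, _ = evaluate([0.5] * 8, [0, 1] * 4, split=0, reps=0)
        assert tss == 0.0 and auc == 0.5

    def test_four_point_worked_example(self):
        # candidate thresholds are 0, midpoints .25/.5/.75, 1; TSS peaks at .5
        tss, auc, th = evaluate([0.1, 0.4, 0.6, 0.9], [0, 0, 1, 1], split=0, reps=0)
        assert tss == 1.0
        assert th == 0.5

    def test_tie_resolves_to_lower_threshold(self):
        # both 0 and the midpoint give TSS 0 -> keep 0
        tss, _, th = evaluate([0.4, 0.4], [0, 1], split=0, reps=0)
        assert tss == 0.0 and th == 0.0

    def test_permutation_invariance(self):
        scores = np.array([0.1, 0.7, 0.3, 0.9, 0.2, 0.8])
        labels = np.array([0, 1, 0, 1, 0, 1])
        perm = np.array([3, 1, 4, 0, 5, 2])
        assert evaluate(scores, labels, split=0, reps=0) == evaluate(
            scores[perm], labels[perm], split=0, reps=0
        )

    def test_auc_of_flipped_labels_is_complement(self):
        rng = np.random.default_rng(5)
        scores = rng.random(40)
        labels = rng.integers(0, 2, 40)
        _, auc, _ = evaluate(scores, labels, split=0, reps=0)
        _, auc_flipped, _ = evaluate(scores, 1 - labels, split=0, reps=0)
        assert auc + auc_flipped == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            evaluate([0.1, 0.9], [1, 1], split=0, reps=0)

    def test_holdout_reproducible(self):
        rng = np.random.default_rng(6)
        scores = rng.random(60)
        labels = (scores + rng.normal(0, 0.2, 60) > 0.5).astype(int)
        a = evaluate(scores, labels, split=0.3, reps=5, seed=9)
        b = evaluate(scores, labels, split=0.3, reps=5, seed=9)
        assert a == b


class TestEnsembleProjection:
    def test_single_member_identity(self, small_env):
        member = FittedModel(
            kind="envelope",
            model=fit_envelope(np.array([[5.0, 0.0], [15.0, 1000.0]]), q=0),
            tss=0.9, auc=0.9, threshold=0.5, pa_set=0,
        )
        suit, cells = ensemble_project([member], small_env, tss_cutoff=0.7)
        grid = member.suitability_grid(small_env)
        assert np.array_equal(suit, grid, equal_nan=True)

    def test_two_identical_members_match_either(self, small_env):
        member = FittedModel(
            kind="envelope",
            model=fit_envelope(np.array([[5.0, 0.0], [15.0, 1000.0]]), q=0),
            tss=0.8, auc=0.9, threshold=0.5, pa_set=0,
        )
        suit1, cells1 = ensemble_project([member], small_env, tss_cutoff=0.7)
        suit2, cells2 = ensemble_project([member, member], small_env, tss_cutoff=0.7)
        assert np.allclose(suit1, suit2, equal_nan=True)
        assert cells1 == cells2

    def test_no_admitted_member_errors_with_best_score(self, small_env):
        member = FittedModel(
            kind="envelope",
            model=fit_envelope(np.array([[5.0, 0.0], [15.0, 1000.0]]), q=0),
            tss=0.42, auc=0.6, threshold=0.5, pa_set=0,
        )
        with pytest.raises(ValueError, match="0.420"):
            ensemble_project([member], small_env, tss_cutoff=0.7)


class TestEnsembleSDMModel:
    @pytest.fixture
    def fitted(self, small_env):
        rng = np.random.default_rng(2)
        # presences where bio1 in [5, 12] (columns ~15..36 of 0..20 gradient)
        suitable = [
            (r, c)
            for r in range(small_env.grid.n_rows)
            for c in range(small_env.grid.n_cols)
            if 5.0 <= small_env.layer("bio1")[r, c] <= 12.0
        ]
        idx = rng.choice(len(suitable), size=40, replace=False)
        presences = {suitable[i] for i in idx}
        model = EnsembleSDM(presences, small_env, EnsembleConfig(envelope_q=0.0))
        return model.fit(seed=4)

    def test_suitabilities_bounded_and_masked(self, fitted, small_env):
        suit, cells = fitted.project()
        valid = suit[small_env.mask]
        assert np.all((valid >= 0) & (valid <= 1))
        for cell in cells:
            assert small_env.mask[cell]

    def test_projection_on_identical_future_is_identical(self, fitted, small_env):
        twin = EnvStack(
            small_env.grid,
            {name: small_env.layer(name).copy() for name in small_env.names},
        )
        suit_now, cells_now = fitted.project(small_env)
        suit_fut, cells_fut = fitted.project(twin)
        assert np.array_equal(suit_now, suit_fut, equal_nan=True)
        assert cells_now == cells_fut

    def test_summary_lists_all_members(self, fitted):
        text = fitted.summary()
        assert "TSS" in text
        assert text.count("envelope") + text.count("logistic") == len(fitted.members)

    def test_manifest_round_trips_config(self, fitted):
        manifest = fitted.to_manifest()
        assert manifest["config"]["tss_cutoff"] == 0.7
        assert len(manifest["members"]) == len(fitted.members)
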