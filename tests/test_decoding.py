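"""Classifier correctness (against brute-force decision rules and a
hand-solved LDA system), cross-validation fold structure, and invariances."""

import numpy as np
import pytest

from streakmvpa.decoding import (
    LinearModel,
    cross_generalize,
    full_matrix,
    leave_one_run_out_cv,
    matrix_cells,
    train,
)
from streakmvpa.preprocessing import PatternSet, build_pattern_set


def make_pset(patterns, labels, stim="static", runs=None, roi="V1"):
    patterns = np.asarray(patterns, dtype=float)
    n = len(patterns)
    return PatternSet(
        patterns=patterns,
        class_label=np.asarray(labels, dtype=int),
        stimulus_type=np.asarray([stim] * n, dtype=object) if isinstance(stim, str) else np.asarray(stim, dtype=object),
        run_index=np.arange(1, n + 1) if runs is None else np.asarray(runs, dtype=int),
        roi_id=roi,
    )


def brute_force_correlation(train_X, train_y, X):
    """Nearest class-mean template by Pearson correlation; ties -> 45."""
    t45 = train_X[train_y == 45].mean(axis=0)
    t135 = train_X[train_y == 135].mean(axis=0)
    preds = []
    for x in np.atleast_2d(X):
        r45 = np.corrcoef(x, t45)[0, 1]
        r135 = np.corrcoef(x, t135)[0, 1]
        preds.append(135 if r135 - r45 > 0 else 45)
    return np.array(preds)


def brute_force_lda(train_X, train_y, X, shrinkage=0.1):
    """Pooled-covariance discriminant with identity shrinkage; ties -> 45."""
    mu45 = train_X[train_y == 45].mean(axis=0)
    mu135 = train_X[train_y == 135].mean(axis=0)
    devs = np.concatenate([train_X[train_y == 45] - mu45, train_X[train_y == 135] - mu135])
    pooled = devs.T @ devs / max(len(train_X) - 2, 1)
    p = pooled.shape[0]
    S = (1 - shrinkage) * pooled + shrinkage * (np.trace(pooled) / p) * np.eye(p)
    w = np.linalg.solve(S, mu135 - mu45)
    preds = []
    for x in np.atleast_2d(X):
        d = float(w @ (x - (mu45 + mu135) / 2))
        preds.append(135 if d > 0 else 45)
    return np.array(preds)


class TestTrain:
    @pytest.mark.parametrize("kind", ["svm", "correlation", "lda"])
    def test_separable_clusters_fit_perfectly(self, kind, rng):
        X = np.vstack([rng.normal(0, 0.1, (10, 4)) + [5, 0, 0, 0], rng.normal(0, 0.1, (10, 4)) + [0, 5, 0, 0]])
        y = [45] * 10 + [135] * 10
        model = train(make_pset(X, y), kind)
        assert (model.predict(X) == y).all()

    def test_correlation_template_identity(self, rng):
        X = rng.normal(size=(6, 8))
        y = [45, 45, 45, 135, 135, 135]
        model = train(make_pset(X, y), "correlation")
        assert model.predict(model.templates[45][None, :])[0] == 45
        assert model.predict(model.templates[135][None, :])[0] == 135

    def test_lda_matches_hand_solved_two_voxel_system(self):
        # class 45: (1,0),(0,1); class 135: (3,2),(2,3).  Pooled covariance
        # [[.5,-.5],[-.5,.5]] shrunk by 0.1 -> [[.5,-.45],[-.45,.5]];
        # solving S w = mu135 - mu45 = (2,2) by hand gives w = (40, 40).
        X = [[1, 0], [0, 1], [3, 2], [2, 3]]
        model = train(make_pset(X, [45, 45, 135, 135]), "lda", lda_shrinkage=0.1)
        np.testing.assert_allclose(model.weights, [40.0, 40.0], atol=1e-9)
        assert model.bias == pytest.approx(-120.0)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            train(make_pset(rng.normal(size=(4, 3)), [45] * 4), "correlation")

    def test_unknown_kind_rejected(self, rng):
        with pytest.raises(ValueError):
            train(make_pset(rng.normal(size=(4, 3)), [45, 45, 135, 135]), "quadratic")

    def test_tie_broken_toward_45(self):
        model = LinearModel(classifier_kind="lda", weights=np.zeros(3), bias=0.0)
        assert (model.predict(np.ones((2, 3))) == 45).all()


class TestOracleEquivalence:
    """Each in-repo classifier's predictions equal a brute-force evaluation
    of its stated decision rule on small toy sets."""

    @pytest.mark.parametrize("seed", range(10))
    def test_correlation_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        train_X = rng.normal(size=(n, 5))
        train_y = np.array([45, 135] * (n // 2) + [45] * (n % 2))
        X = rng.normal(size=(6, 5))
        model = train(make_pset(train_X, train_y), "correlation")
        np.testing.assert_array_equal(model.predict(X), brute_force_correlation(train_X, train_y, X))

    @pytest.mark.parametrize("seed", range(10))
    def test_lda_matches_brute_force(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(4, 9))
        train_X = rng.normal(size=(n, 3))
        train_y = np.array([45, 135] * (n // 2) + [45] * (n % 2))
        X = rng.normal(size=(6, 3))
        model = train(make_pset(train_X, train_y), "lda")
        np.testing.assert_array_equal(model.predict(X), brute_force_lda(train_X, train_y, X))


class TestLeaveOneRunOut:
    def test_default_design_gives_20_predictions(self, small_session):
        pset = build_pattern_set(small_session.roi_runs["V1"])
        res = leave_one_run_out_cv(pset, "static", "correlation")
        assert res.n_total == 20  # 10 folds x 2 test patterns
        test_runs = sorted({r for _, _, r in res.per_fold_predictions})
        assert test_runs == list(range(1, 11))

    def test_noise_free_static_decoding_is_perfect(self):
        from streakmvpa.synthetic_data import EncodingParams, SessionDesign, generate_session

        params = EncodingParams(
            rois=("V1",), n_voxels_per_roi=30, roi_gain={"V1": 1.0},
            shared_weight_fast={"V1": 0.5}, shared_weight_slow={"V1": 0.0},
            noise_sd=1e-9, run_offset_sd=0.0,
        )
        session = generate_session(params, SessionDesign(n_runs=3), participant_seed=1)
        pset = build_pattern_set(session.roi_runs["V1"])
        for kind in ("correlation", "lda"):
            assert leave_one_run_out_cv(pset, "static", kind).accuracy == 1.0

    def test_missing_class_in_a_run_rejected(self, rng):
        X = rng.normal(size=(6, 4))
        pset = make_pset(X, [45, 135, 45, 135, 45, 45], runs=[1, 1, 2, 2, 3, 3])
        with pytest.raises(ValueError):
            leave_one_run_out_cv(pset, "static", "correlation")


class TestCrossGeneralize:
    def test_same_type_rejected_and_unknown_scheme(self, small_session):
        pset = build_pattern_set(small_session.roi_runs["V1"])
        with pytest.raises(ValueError):
            cross_generalize(pset, "static", "static")
        with pytest.raises(ValueError):
            cross_generalize(pset, "static", "fast", scheme="bootstrap")

    def test_full_sharing_noise_free_generalizes_perfectly(self):
        from streakmvpa.synthetic_data import EncodingParams, SessionDesign, generate_session

        params = EncodingParams(
            rois=("V2",), n_voxels_per_roi=30, roi_gain={"V2": 1.0},
            shared_weight_fast={"V2": 1.0}, shared_weight_slow={"V2": 0.0},
            noise_sd=1e-9, run_offset_sd=0.0,
        )
        session = generate_session(params, SessionDesign(n_runs=3), participant_seed=6)
        pset = build_pattern_set(session.roi_runs["V2"])
        for scheme in ("all-blocks", "run-matched"):
            assert cross_generalize(pset, "static", "fast", "correlation", scheme).accuracy == 1.0

    def test_both_directions_reported_separately(self, small_session):
        pset = build_pattern_set(small_session.roi_runs["V2"])
        fwd = cross_generalize(pset, "static", "fast")
        rev = cross_generalize(pset, "fast", "static")
        assert (fwd.train_type, fwd.test_type) == ("static", "fast")
        assert (rev.train_type, rev.test_type) == ("fast", "static")
        assert fwd.n_total == rev.n_total == 20

    def test_run_matched_mirrors_loro_folds(self, small_session):
        pset = build_pattern_set(small_session.roi_runs["V2"])
        res = cross_generalize(pset, "static", "fast", scheme="run-matched")
        assert sorted({r for _, _, r in res.per_fold_predictions}) == list(range(1, 11))


class TestInvariances:
    def test_accuracy_invariant_to_voxel_permutation(self, small_session, rng):
        pset = build_pattern_set(small_session.roi_runs["V1"])
        perm = rng.permutation(pset.n_voxels)
        shuffled = PatternSet(
            patterns=pset.patterns[:, perm],
            class_label=pset.class_label,
            stimulus_type=pset.stimulus_type,
            run_index=pset.run_index,
            roi_id=pset.roi_id,
        )
        for kind in ("correlation", "lda"):
            assert (
                leave_one_run_out_cv(pset, "static", kind).accuracy
                == leave_one_run_out_cv(shuffled, "static", kind).accuracy
            )

    @pytest.mark.parametrize("kind", ["correlation", "lda"])
    def test_accuracy_invariant_to_common_affine_rescaling(self, small_session, kind):
        pset = build_pattern_set(small_session.roi_runs["V1"])
        rescaled = PatternSet(
            patterns=2.5 * pset.patterns + 7.0,
            class_label=pset.class_label,
            stimulus_type=pset.stimulus_type,
            run_index=pset.run_index,
            roi_id=pset.roi_id,
        )
        assert (
            leave_one_run_out_cv(pset, "static", kind).accuracy
            == leave_one_run_out_cv(rescaled, "static", kind).accuracy
        )

    def test_correlation_invariant_to_per_pattern_affine(self, small_session, rng):
        pset = build_pattern_set(small_session.roi_runs["V1"])
        scales = rng.uniform(0.5, 2.0, size=(pset.n_blocks, 1))
        offsets = rng.normal(size=(pset.n_blocks, 1))
        rescaled = PatternSet(
            patterns=scales * pset.patterns + offsets,
            class_label=pset.class_label,
            stimulus_type=pset.stimulus_type,
            run_index=pset.run_index,
            roi_id=pset.roi_id,
        )
        assert (
            leave_one_run_out_cv(pset, "static", "correlation").accuracy
            == leave_one_run_out_cv(rescaled, "static", "correlation").accuracy
        )


class TestFullMatrix:
    def test_nine_by_five_cells(self, small_session):
        assert len(matrix_cells()) == 9
        psets = {roi: build_pattern_set(runs) for roi, runs in small_session.roi_runs.items()}
        df = full_matrix(psets, kinds=("correlation",))
        assert len(df) == 45  # 9 cells x 5 ROIs
        assert set(df["roi"]) == set(small_session.rois)
        within = df[df["train_type"] == df["test_type"]]
        assert (within["n_total"] == 20).all()
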