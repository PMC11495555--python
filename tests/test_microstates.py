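"""Modified k-means clustering, K selection, and back-fitting."""

import numpy as np
import pytest
from scipy.linalg import eigh
from scipy.optimize import linear_sum_assignment

from msbridge import (
    EEGRecording,
    TemplateSet,
    backfit_sequence,
    generate_templates,
    modified_kmeans_fit,
    read_templates,
    select_k,
    spatial_correlation,
    two_level_fit,
    write_templates,
)
from msbridge.exceptions import InvalidParameterError, SchemaError
from tests.conftest import best_template_matching


def _orthonormal_maps(n_channels, K, seed=0):
    """Zero-mean, mutually orthogonal unit-norm maps."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_channels, K + 1))
    X -= X.mean(axis=0)
    q, _ = np.linalg.qr(X)
    # columns of q are orthonormal but may have nonzero mean; re-project
    cols = []
    for k in range(K):
        c = q[:, k] - q[:, k].mean()
        cols.append(c / np.linalg.norm(c))
    return np.vstack(cols)


class TestModifiedKMeans:
    def test_noiseless_orthogonal_templates_full_gev(self):
        A = _orthonormal_maps(10, 3)
        rng = np.random.default_rng(1)
        idx = rng.integers(0, 3, 120)
        signs = rng.choice([-1.0, 1.0], 120)
        V = A[idx] * signs[:, None]
        fit = modified_kmeans_fit(V, 3, restarts=5, seed=0)
        assert fit.gev == pytest.approx(1.0, abs=1e-9)
        assert fit.residual_noise == pytest.approx(0.0, abs=1e-12)

    def test_polarity_invariance(self):
        rng = np.random.default_rng(2)
        A = _orthonormal_maps(8, 2)
        V = A[rng.integers(0, 2, 100)] + rng.normal(scale=0.05, size=(100, 8))
        fit_pos = modified_kmeans_fit(V, 2, restarts=5, seed=3)
        fit_neg = modified_kmeans_fit(-V, 2, restarts=5, seed=3)
        for a, b in zip(fit_pos.maps, fit_neg.maps):
            assert abs(spatial_correlation(a, b)) == pytest.approx(1.0, abs=1e-9)

    def test_recovery_matches_eigendecomposition_oracle(self):
        """Fitted templates match the principal eigenvector of each
        ground-truth cluster's scatter matrix (the closed-form optimum)."""
        rng = np.random.default_rng(3)
        A = generate_templates(8, 2, seed=4)
        n = 500
        idx = np.repeat([0, 1], n // 2)
        signs = rng.choice([-1.0, 1.0], n)
        V = A[idx] * signs[:, None] + rng.normal(scale=0.1 / np.sqrt(8), size=(n, 8))
        V -= V.mean(axis=1, keepdims=True)
        fit = modified_kmeans_fit(V, 2, restarts=10, seed=5)
        oracle = []
        for k in (0, 1):
            S = V[idx == k].T @ V[idx == k]
            _, vec = eigh(S, subset_by_index=(7, 7))
            oracle.append(vec[:, 0])
        corrs = best_template_matching(fit.maps, np.vstack(oracle))
        assert min(corrs) > 0.99

    def test_scaling_invariance_of_labels(self):
        rng = np.random.default_rng(6)
        V = rng.normal(size=(60, 6))
        a = modified_kmeans_fit(V, 2, restarts=3, seed=7)
        b = modified_kmeans_fit(10.0 * V, 2, restarts=3, seed=7)
        for ma, mb in zip(a.maps, b.maps):
            assert abs(spatial_correlation(ma, mb)) == pytest.approx(1.0, abs=1e-9)

    def test_k_not_below_n_rejected(self):
        with pytest.raises(InvalidParameterError):
            modified_kmeans_fit(np.random.default_rng(0).normal(size=(4, 6)), 4)

    def test_templates_unit_norm_zero_mean(self):
        V = np.random.default_rng(8).normal(size=(50, 7))
        fit = modified_kmeans_fit(V, 3, restarts=3, seed=9)
        np.testing.assert_allclose(np.linalg.norm(fit.maps, axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(fit.maps.mean(axis=1), 0.0, atol=1e-9)


class TestTwoLevelFit:
    def test_single_subject_group_equals_subject(self):
        rng = np.random.default_rng(10)
        A = generate_templates(8, 3, seed=11)
        V = A[rng.integers(0, 3, 200)] + rng.normal(scale=0.03, size=(200, 8))
        group = two_level_fit([V], 3, restarts=10, seed=12)
        single = modified_kmeans_fit(V, 3, restarts=10, seed=12)
        corrs = best_template_matching(group.maps, single.maps)
        assert min(corrs) > 0.999

    def test_shared_generators_recovered_across_subjects(self):
        rng = np.random.default_rng(13)
        A = generate_templates(10, 4, seed=14)
        cohort = []
        for s in range(5):
            idx = rng.integers(0, 4, 300)
            signs = rng.choice([-1.0, 1.0], 300)
            cohort.append(A[idx] * signs[:, None]
                          + rng.normal(scale=0.1 / np.sqrt(10), size=(300, 10)))
        group = two_level_fit(cohort, 4, restarts=10, seed=15)
        corrs = best_template_matching(group.maps, A)
        assert np.mean(corrs) >= 0.95

    def test_disjoint_populations_union_recovered(self):
        """Two subpopulations with different maps: with K = union size every
        generator map is matched (Hungarian assignment on |corr|)."""
        rng = np.random.default_rng(16)
        A = generate_templates(12, 4, seed=17)
        cohort = []
        for s in range(4):
            gens = A[:2] if s < 2 else A[2:]
            idx = rng.integers(0, 2, 300)
            cohort.append(gens[idx] + rng.normal(scale=0.05, size=(300, 12)))
        group = two_level_fit(cohort, 4, restarts=20, seed=18)
        C = np.abs(np.array([[spatial_correlation(g, a) for g in group.maps] for a in A]))
        rows, cols = linear_sum_assignment(-C)
        assert all(C[r, c] >= 0.9 for r, c in zip(rows, cols))

    def test_bit_reproducible(self):
        rng = np.random.default_rng(19)
        cohort = [rng.normal(size=(100, 8)) for _ in range(3)]
        a = two_level_fit(cohort, 3, restarts=5, seed=20)
        b = two_level_fit(cohort, 3, restarts=5, seed=20)
        np.testing.assert_array_equal(a.maps, b.maps)


class TestSelectK:
    def test_noiseless_single_template_ties_to_one(self):
        A = _orthonormal_maps(8, 1)
        rng = np.random.default_rng(21)
        V = A[np.zeros(100, int)] * rng.choice([-1.0, 1.0], 100)[:, None]
        fit = select_k([V], range(1, 5), restarts=3, seed=22)
        assert np.allclose(fit.table["residual_noise"], 0.0, atol=1e-12)
        assert fit.selected_K == 1

    def test_recovers_true_k_on_synthetic_cohort(self):
        rng = np.random.default_rng(23)
        A = generate_templates(12, 4, seed=24)
        cohort = []
        for s in range(4):
            idx = rng.integers(0, 4, 400)
            signs = rng.choice([-1.0, 1.0], 400)
            cohort.append(A[idx] * signs[:, None]
                          + rng.normal(scale=0.1 / np.sqrt(12), size=(400, 12)))
        fit = select_k(cohort, range(2, 8), restarts=10, seed=25)
        assert fit.selected_K == 4

    def test_cv_finite_positive_with_noise(self):
        rng = np.random.default_rng(26)
        fit = select_k([rng.normal(size=(200, 8))], range(1, 5), restarts=3, seed=27)
        assert (fit.table["cv"] > 0).all()
        assert np.isfinite(fit.table["cv"]).all()

    def test_k_beyond_cv_definition_skipped(self, caplog):
        rng = np.random.default_rng(28)
        fit = select_k([rng.normal(size=(50, 5))], [2, 3, 4, 5], restarts=2, seed=29)
        assert fit.table["K"].max() <= 3  # C - 1 = 4 undefined and above


class TestBackfit:
    @pytest.fixture()
    def templates(self):
        A = _orthonormal_maps(6, 3)
        return TemplateSet(maps=A, gev=1.0, residual_noise=0.0)

    def test_negated_template_gets_own_label(self, templates):
        rec = EEGRecording(data=(-templates.maps[2])[:, None], srate=100.0)
        seq = backfit_sequence(rec, templates)
        assert seq.labels[0] == 2

    def test_equidistant_tie_breaks_low(self, templates):
        v = templates.maps[0] + templates.maps[1]
        rec = EEGRecording(data=v[:, None], srate=100.0)
        assert backfit_sequence(rec, templates).labels[0] == 0

    def test_noiseless_path_reproduced(self, templates):
        rng = np.random.default_rng(30)
        path = rng.integers(0, 3, 200)
        signs = rng.choice([-1.0, 1.0], 200)
        rec = EEGRecording(data=(templates.maps[path] * signs[:, None]).T, srate=100.0)
        np.testing.assert_array_equal(backfit_sequence(rec, templates).labels, path)

    def test_each_template_maps_to_itself(self, templates):
        rec = EEGRecording(data=templates.maps.T, srate=100.0)
        np.testing.assert_array_equal(backfit_sequence(rec, templates).labels, [0, 1, 2])

    def test_channel_mismatch_lists_missing(self, templates):
        templates.channel_names = [f"E{i}" for i in range(6)]
        rec = EEGRecording(data=np.zeros((6, 5)), srate=100.0,
                           channel_names=[f"E{i}" for i in range(5)] + ["X"])
        with pytest.raises(SchemaError, match="E5"):
            backfit_sequence(rec, templates)


def test_template_csv_round_trip(tmp_path):
    V = np.random.default_rng(31).normal(size=(80, 6))
    fit = modified_kmeans_fit(V, 3, restarts=3, seed=32)
    fit.channel_names = [f"ch{i}" for i in range(6)]
    write_templates(fit, tmp_path / "templates.csv")
    back = read_templates(tmp_path / "templates.csv")
    np.testing.assert_allclose(back.maps, fit.maps)
    assert back.K == fit.K and back.gev == pytest.approx(fit.gev)
    assert back.channel_names == fit.channel_names
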