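import numpy as np
import pytest

from bridgethemes.structure import (classify_similarity, compute_metrics,
                                    contact_map_change, drmsd,
                                    fit_rmsd_mixture, ss_agreement,
                                    superpose_rmsd)
from bridgethemes.synthetic import build_domain
from oracles import contact_change_by_enumeration, grid_search_rmsd


def random_rigid(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q, rng.normal(size=3) * 10


class TestSuperpose:
    def test_identical_coordinates(self):
        a = np.arange(30, dtype=float).reshape(10, 3)
        _, _, r = superpose_rmsd(a, a)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self, rigid_transform_rng):
        rng = rigid_transform_rng
        for _ in range(20):
            a = rng.normal(size=(rng.integers(3, 40), 3)) * 8
            R, t = random_rigid(rng)
            b = a @ R.T + t
            _, _, r = superpose_rmsd(a, b)
            assert r <= 1e-8
            assert drmsd(a, b) <= 1e-8

    def test_rotated_translated_square(self):
        a = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
        theta = np.pi / 2
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        b = a @ R.T + [3, 4, 5]
        _, _, r = superpose_rmsd(a, b)
        assert r == pytest.approx(0.0, abs=1e-9)

    def test_displaced_corner_matches_grid_search(self):
        """RMSD of a unit square with one displaced corner must match an
        exhaustive rotation-grid search."""
        a = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
        b = a.copy()
        b[2] += [1.0, 0.0, 0.0]
        _, _, r = superpose_rmsd(a, b)
        assert r == pytest.approx(grid_search_rmsd(a, b), abs=1e-3)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            superpose_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_transform_maps_b_onto_a(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(12, 3)) * 5
        R0, t0 = random_rigid(rng)
        b = a @ R0.T + t0
        R, t, _ = superpose_rmsd(a, b)
        assert np.allclose(b @ R.T + t, a, atol=1e-8)


class TestDrmsd:
    def test_identical_and_rigidly_moved(self):
        a = np.array([[0, 0, 0], [3, 0, 0], [0, 4, 0]], dtype=float)
        assert drmsd(a, a) == 0.0
        assert drmsd(a, a + [1, 2, 3]) == pytest.approx(0.0, abs=1e-12)

    def test_three_point_hand_calculation(self):
        """Sides (3,4,5) vs (3,4,6): one distance differs by 1, so
        dRMSD = sqrt(1/3)."""
        a = np.array([[0, 0, 0], [3, 0, 0], [0, 4, 0]], dtype=float)
        x = (9 + 16 - 36) / 6.0
        y = np.sqrt(16 - x**2)
        b = np.array([[0, 0, 0], [3, 0, 0], [x, y, 0]])
        assert drmsd(a, b) == pytest.approx(np.sqrt(1 / 3), abs=1e-9)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            drmsd(np.zeros((1, 3)), np.zeros((1, 3)))


class TestContactMap:
    def test_identical_zero_change(self):
        a = np.random.default_rng(0).normal(size=(6, 3)) * 6
        assert contact_map_change(a, a, 9.0) == 0.0

    def test_all_vs_none_changes_off_diagonal(self):
        # l=3: tight cluster vs spread triangle; diagonal is 1 on both
        # sides, so 6 of 9 entries differ
        a = np.zeros((3, 3))
        b = np.array([[0, 0, 0], [100, 0, 0], [0, 100, 0]], dtype=float)
        assert contact_map_change(a, b, 9.0) == pytest.approx(100 * 6 / 9)

    def test_matches_pair_enumeration(self):
        a = np.array([[0, 0, 0], [5, 0, 0], [0, 8, 0], [10, 10, 0]], dtype=float)
        b = np.array([[0, 0, 0], [12, 0, 0], [0, 8, 0], [3, 3, 0]], dtype=float)
        for thr in (9.0, 11.0):
            assert contact_map_change(a, b, thr) == pytest.approx(
                contact_change_by_enumeration(a, b, thr))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            contact_map_change(np.zeros((0, 3)), np.zeros((0, 3)), 9.0)


class TestSsAgreement:
    def test_identical(self):
        pct, n = ss_agreement("HHEECC", "HHEECC", [(i, i) for i in range(6)])
        assert pct == 100.0 and n == 6

    def test_opposite(self):
        pct, _ = ss_agreement("HHHH", "EEEE", [(i, i) for i in range(4)])
        assert pct == 0.0

    def test_hand_count(self):
        pct, n = ss_agreement("HHHECCC", "HHHHCCC", [(i, i) for i in range(7)])
        assert n == 7
        assert pct == pytest.approx(100 * 6 / 7)

    def test_eight_state_collapse(self):
        # G and I are helix-like, B is strand-like, T/S are coil
        pct, _ = ss_agreement("GIB", "HHE", [(0, 0), (1, 1), (2, 2)])
        assert pct == 100.0
        pct, _ = ss_agreement("TS", "CC", [(0, 0), (1, 1)])
        assert pct == 100.0

    def test_out_of_range_pairs_skipped(self):
        pct, n = ss_agreement("HH", "HH", [(0, 0), (5, 5)])
        assert n == 1 and pct == 100.0


class TestClassify:
    @pytest.mark.parametrize("rmsd,similar", [
        (3.3, True), (9.8, False), (6.0, False), (5.999, True),
    ])
    def test_threshold(self, rmsd, similar):
        assert classify_similarity(rmsd) is similar


class TestMixture:
    def test_loglik_monotone(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(3.3, 1.0, 300), rng.normal(9.8, 2.0, 700)])
        fit = fit_rmsd_mixture(x, seed=1)
        trace = np.array(fit.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-9)
        assert fit.converged

    def test_weights_sum_to_one_and_ordered(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(2, 0.5, 200), rng.normal(8, 1, 200)])
        fit = fit_rmsd_mixture(x, seed=2)
        assert sum(fit.weights) == pytest.approx(1.0, abs=1e-9)
        assert fit.means[0] < fit.means[1]
        assert min(fit.sds) > 0

    def test_single_cluster_degenerates_gracefully(self):
        rng = np.random.default_rng(2)
        x = rng.normal(5.0, 1.0, 500)
        fit = fit_rmsd_mixture(x, seed=3)
        # either one component swallows (almost) everything or the fit
        # reports non-convergence
        assert max(fit.weights) > 0.95 or not fit.converged

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_rmsd_mixture(np.full(50, 4.2), seed=0)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            fit_rmsd_mixture(np.arange(5), seed=0)

    def test_matches_sklearn_reference(self):
        """Independent cross-check against sklearn's GaussianMixture on a
        well-separated sample."""
        from sklearn.mixture import GaussianMixture
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(3, 1, 1000), rng.normal(10, 2, 2000)])
        fit = fit_rmsd_mixture(x, seed=5)
        gm = GaussianMixture(2, n_init=5, random_state=0, tol=1e-8).fit(x[:, None])
        order = np.argsort(gm.means_.ravel())
        assert fit.means == pytest.approx(tuple(gm.means_.ravel()[order]), abs=0.05)
        assert fit.weights == pytest.approx(tuple(gm.weights_[order]), abs=0.01)


class TestComputeMetrics:
    theme = "ACDEFHIKLMNPQRSTVWYACDEFHIKLM"  # no glycine: every residue has a CB

    def _pair(self, conf_a, conf_b, seed_a=1, seed_b=2):
        da, _, (s, e) = build_domain("da", self.theme, "MKVMK", "QWEQW",
                                     "1.101.1.1", conf_a, seed=seed_a)
        db, _, _ = build_domain("db", self.theme, "MKVMK", "QWEQW",
                                "2.205.1.1", conf_b, seed=seed_b)
        pairs = [(s + i, s + i) for i in range(len(self.theme))]
        return da, db, pairs

    def test_same_conformation_similar(self):
        da, db, pairs = self._pair("helix", "helix")
        m = compute_metrics(da, db, pairs)
        assert m.rmsd_ca == pytest.approx(0.0, abs=1e-6)
        assert m.similar
        assert m.drmsd == pytest.approx(0.0, abs=1e-6)
        assert m.cm_change_9 == 0.0
        assert m.ss_agreement == 100.0

    def test_different_conformation_dissimilar(self):
        da, db, pairs = self._pair("helix", "strand")
        m = compute_metrics(da, db, pairs)
        assert not m.similar
        assert m.rmsd_ca > 6.0
        assert m.ss_agreement == 0.0
        assert m.n_used == len(self.theme)

    def test_zero_rmsd_implies_zero_everything(self):
        da, db, pairs = self._pair("strand", "strand")
        m = compute_metrics(da, db, pairs)
        assert m.rmsd_ca == pytest.approx(0.0, abs=1e-6)
        assert m.drmsd == pytest.approx(0.0, abs=1e-6)
        assert m.cm_change_9 == 0.0 and m.cm_change_11 == 0.0
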