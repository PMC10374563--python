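import numpy as np
import pytest

import svgrank as sv
from svgrank.hotspots import LocalMoranResult


def brute_force_local_moran(values, lattice):
    """Independent direct-formula local Moran statistic (plain loops)."""
    values = np.asarray(values, float)
    n = values.size
    z = values - values.mean()
    m2 = sum(zi**2 for zi in z) / n
    I = np.empty(n)
    for i in range(n):
        lag = sum(z[j] for j in lattice.neighbor_idx[i]) / lattice.K
        I[i] = z[i] * lag / m2
    return I


def brute_force_permutation_p(values, lattice, n_permutations, seed):
    """Independently coded conditional-permutation pseudo p-values.

    Same sampling scheme as the implementation documents (one rng stream,
    spots in index order, rng.permutation(n-1)[:K] per draw), statistic and
    counting recomputed from scratch.
    """
    values = np.asarray(values, float)
    n = values.size
    z = values - values.mean()
    m2 = (z**2).sum() / n
    # recompute the observed statistic with numpy's reduction order so that
    # exact ties in the discrete permutation distribution compare equally
    I_obs = np.array(
        [z[i] * z[lattice.neighbor_idx[i]].mean() / m2 for i in range(n)]
    )
    np.testing.assert_allclose(I_obs, brute_force_local_moran(values, lattice),
                               atol=1e-9)
    rng = np.random.default_rng(seed)
    p = np.empty(n)
    for i in range(n):
        others = np.array([z[j] for j in range(n) if j != i])
        count = 0
        for _ in range(n_permutations):
            pick = rng.permutation(n - 1)[: lattice.K]
            lag = others[pick].mean()
            if z[i] * lag / m2 >= I_obs[i]:
                count += 1
        p[i] = (count + 1) / (n_permutations + 1)
    return p


class TestLocalMoran:
    def test_constant_values_give_p_one_everywhere(self, grid5):
        lattice = sv.build_knn(grid5, K=4)
        res = sv.local_morans_i(np.full(25, 3.3), lattice, seed=0)
        assert res.constant
        assert (res.p_raw == 1.0).all()
        assert (res.I == 0.0).all()

    def test_single_high_spot_on_hex_patch_is_high_low_not_hotspot(self, hex7):
        # center high, ring zero: center lag is negative -> I < 0
        lattice = sv.build_knn(hex7, K=6)
        values = np.array([7.0, 0, 0, 0, 0, 0, 0])
        z = values - 1.0
        m2 = (z**2).sum() / 7
        expected_center = z[0] * z[1:].mean() / m2  # = 6*(-1)/m2
        res = sv.local_morans_i(values, lattice, n_permutations=99, seed=1)
        assert res.I[0] == pytest.approx(expected_center)
        assert res.I[0] < 0
        hm = sv.call_hotspots([res])
        assert hm.X[0, 0] == 0

    def test_statistic_matches_brute_force(self, grid5):
        rng = np.random.default_rng(5)
        lattice = sv.build_knn(grid5, K=4)
        values = rng.gamma(2.0, size=25)
        res = sv.local_morans_i(values, lattice, analytic=True)
        np.testing.assert_allclose(
            res.I, brute_force_local_moran(values, lattice), atol=1e-9
        )

    def test_permutation_p_matches_oracle_at_matched_seed(self, grid5):
        rng = np.random.default_rng(11)
        lattice = sv.build_knn(grid5, K=4)
        values = rng.poisson(3.0, size=25).astype(float)
        res = sv.local_morans_i(values, lattice, n_permutations=199, seed=99)
        expected = brute_force_permutation_p(values, lattice, 199, seed=99)
        np.testing.assert_array_equal(res.p_raw, expected)

    def test_permutation_is_bit_reproducible(self, grid5):
        lattice = sv.build_knn(grid5, K=4)
        values = np.random.default_rng(3).normal(size=25)
        a = sv.local_morans_i(values, lattice, n_permutations=99, seed=7)
        b = sv.local_morans_i(values, lattice, n_permutations=99, seed=7)
        np.testing.assert_array_equal(a.p_raw, b.p_raw)

    def test_analytic_and_permutation_modes_agree(self, grid5):
        # a clear corner block of high values: both modes flag the same
        # strongly significant spots
        lattice = sv.build_knn(grid5, K=4)
        values = np.zeros(25)
        block = [0, 1, 5, 6, 2, 7, 10, 11, 12]
        values[block] = 10.0
        perm = sv.local_morans_i(values, lattice, n_permutations=999, seed=0)
        ana = sv.local_morans_i(values, lattice, analytic=True)
        strong = ana.p_raw < 0.01
        assert strong.any()
        assert (perm.p_raw[strong] <= 0.05).all()

    def test_matrix_mode_equals_per_gene_analytic(self, grid5):
        rng = np.random.default_rng(8)
        counts = rng.poisson(2.0, size=(6, 25))
        counts[0, :5] += 20
        cm = sv.CountMatrix(counts, [f"g{i}" for i in range(6)],
                            [f"s{i}" for i in range(25)])
        nm = sv.normalize(cm)
        lattice = sv.build_knn(grid5, K=4)
        batch = sv.local_morans_i_matrix(nm, lattice)
        for g, r in enumerate(batch):
            single = sv.local_morans_i(
                nm.dense()[g], lattice, analytic=True, gene_id=r.gene_id
            )
            np.testing.assert_allclose(r.I, single.I, atol=1e-12)
            np.testing.assert_allclose(r.p_raw, single.p_raw, atol=1e-12)

    def test_mean_of_local_equals_global_moran(self, grid5):
        rng = np.random.default_rng(21)
        lattice = sv.build_knn(grid5, K=4)
        values = rng.normal(size=25)
        res = sv.local_morans_i(values, lattice, analytic=True)
        assert res.I.mean() == pytest.approx(
            sv.global_morans_i(values, lattice), abs=1e-9
        )


def brute_force_bh(p):
    """Direct step-up BH with monotonicity, coded from the definition."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return adj


class TestBHAdjust:
    def test_equally_spaced_example(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(sv.bh_adjust(p), [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_and_singleton(self):
        np.testing.assert_array_equal(sv.bh_adjust(np.ones(5)), np.ones(5))
        np.testing.assert_array_equal(sv.bh_adjust(np.array([0.3])), [0.3])

    def test_matches_step_up_oracle_on_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 40))
            np.testing.assert_allclose(
                sv.bh_adjust(p), brute_force_bh(p), atol=1e-12
            )

    def test_adjusted_never_below_raw_and_in_unit_interval(self):
        rng = np.random.default_rng(23)
        p = rng.uniform(1e-4, 1.0, size=200)
        adj = sv.bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        assert (adj > 0).all() and (adj <= 1).all()

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [0.5, 1.5], [-0.1]])
    def test_rejects_out_of_range_p(self, bad):
        with pytest.raises(ValueError):
            sv.bh_adjust(np.array(bad))


class TestCallHotspots:
    def _result(self, p_raw, z, lag):
        p_raw = np.asarray(p_raw, float)
        return LocalMoranResult(
            "g", np.zeros(p_raw.size), np.asarray(z, float),
            np.asarray(lag, float), p_raw, sv.bh_adjust(p_raw),
        )

    def test_all_null_gene_gets_empty_row(self):
        res = self._result(np.ones(10), np.ones(10), np.ones(10))
        hm = sv.call_hotspots([res])
        assert (hm.X == 0).all()

    def test_high_high_quadrant_required(self):
        p = np.array([0.001, 0.001, 0.9])
        res = self._result(p, z=[1.0, -1.0, 1.0], lag=[1.0, -1.0, 1.0])
        hm = sv.call_hotspots([res])
        # significant low-low spot is not a hotspot; lag flag can relax it
        assert list(hm.X[0]) == [1, 0, 0]

    def test_lag_condition_is_optional(self):
        p = np.array([0.001, 0.5, 0.5])
        res = self._result(p, z=[1.0, 1.0, 1.0], lag=[-0.5, 1.0, 1.0])
        strict = sv.call_hotspots([res])
        relaxed = sv.call_hotspots([res], require_positive_lag=False)
        assert strict.X[0, 0] == 0
        assert relaxed.X[0, 0] == 1

    def test_monotone_in_fdr_threshold(self, grid5):
        rng = np.random.default_rng(31)
        lattice = sv.build_knn(grid5, K=4)
        values = rng.poisson(2.0, 25) + np.where(np.arange(25) < 8, 6, 0)
        res = sv.local_morans_i(values.astype(float), lattice, analytic=True)
        tight = sv.call_hotspots([res], fdr_threshold=0.01)
        loose = sv.call_hotspots([res], fdr_threshold=0.05)
        assert (tight.X <= loose.X).all()

    def test_planted_patch_is_recovered(self, benchmark):
        res = benchmark["res"]
        truth = benchmark["truth"]
        hm = res.hotspot_matrix
        gi = hm.gene_ids.index("svg_r1_00")
        in_region = truth.region_labels == 1
        hot = hm.X[gi].astype(bool)
        # hotspots concentrate in the planted disk
        assert hot.sum() > 0.5 * in_region.sum()
        assert (hot & in_region).sum() / hot.sum() > 0.9

    def test_round_trip_through_long_tsv(self, tmp_path, grid5):
        from svgrank.hotspots import read_hotspots, write_hotspots

        rng = np.random.default_rng(2)
        lattice = sv.build_knn(grid5, K=4)
        results = [
            sv.local_morans_i(rng.poisson(3.0, 25).astype(float), lattice,
                              analytic=True, gene_id=f"g{i}")
            for i in range(3)
        ]
        hm = sv.call_hotspots(results)
        path = tmp_path / "hotspots.tsv"
        write_hotspots(hm, path)
        back = read_hotspots(path)
        np.testing.assert_array_equal(back.X, hm.X)
        np.testing.assert_allclose(back.p_raw, hm.p_raw)
        assert back.gene_ids == hm.gene_ids

    def test_round_trip_through_sparse_mtx(self, tmp_path, grid5):
        from svgrank.hotspots import read_hotspots_mtx, write_hotspots_mtx

        rng = np.random.default_rng(6)
        lattice = sv.build_knn(grid5, K=4)
        values = rng.poisson(2.0, 25).astype(float)
        values[:6] += 9
        res = sv.local_morans_i(values, lattice, analytic=True, gene_id="g")
        hm = sv.call_hotspots([res])
        write_hotspots_mtx(hm, tmp_path)
        back = read_hotspots_mtx(tmp_path)
        np.testing.assert_array_equal(back.X, hm.X)
        assert back.gene_ids == hm.gene_ids and back.spot_ids == hm.spot_ids
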