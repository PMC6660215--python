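import numpy as np
import pytest

from avrecal import cluster_stats as cst
from avrecal.errors import DataError
from avrecal.synthetic import SourceGrid, _correlated_noise


def flood_fill_components(grid: SourceGrid, suprathreshold: np.ndarray, connectivity: int):
    """Brute-force connected components over the inside-mask lattice."""
    idx = grid.lattice_index
    on = {tuple(ijk) for v, ijk in enumerate(idx) if suprathreshold[v]}
    pos_to_voxel = {tuple(ijk): v for v, ijk in enumerate(idx)}
    if connectivity == 26:
        offsets = [
            (a, b, c)
            for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
            if (a, b, c) != (0, 0, 0)
        ]
    else:
        offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    components = []
    remaining = set(on)
    while remaining:
        seed = remaining.pop()
        stack, comp = [seed], {seed}
        while stack:
            i, j, k = stack.pop()
            for a, b, c in offsets:
                nxt = (i + a, j + b, k + c)
                if nxt in remaining:
                    remaining.remove(nxt)
                    comp.add(nxt)
                    stack.append(nxt)
        components.append(frozenset(pos_to_voxel[p] for p in comp))
    return set(components)


class TestFormClusters:
    def test_minimum_size_six(self):
        """Five contiguous suprathreshold voxels never form a cluster; six do."""
        grid = SourceGrid((8, 8, 8))
        stat = np.zeros(grid.n_voxels)
        line = [v for v, (i, j, k) in enumerate(grid.lattice_index) if j == 4 and k == 4]
        stat[line[:5]] = 3.0
        assert not cst.form_clusters(stat, 2.0, grid).clusters
        stat[line[:6]] = 3.0
        cs = cst.form_clusters(stat, 2.0, grid)
        assert len(cs.clusters) == 1
        assert cs.clusters[0].sum_stat == pytest.approx(18.0)

    def test_positive_and_negative_kept_separately(self):
        grid = SourceGrid((8, 8, 8))
        stat = np.zeros(grid.n_voxels)
        line = [v for v, (i, j, k) in enumerate(grid.lattice_index) if j == 4 and k == 4]
        stat[line[:6]] = 3.0
        col = [v for v, (i, j, k) in enumerate(grid.lattice_index) if j == 2 and k == 4]
        stat[col[:6]] = -3.0
        cs = cst.form_clusters(stat, 2.0, grid)
        assert sorted(c.sign for c in cs.clusters) == [-1, 1]

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_flood_fill_oracle_on_random_maps(self, connectivity):
        grid = SourceGrid((6, 6, 6))
        rng = np.random.default_rng(11)
        for _ in range(20):
            stat = rng.normal(0, 1, grid.n_voxels)
            cs = cst.form_clusters(stat, 0.5, grid, connectivity=connectivity, min_size=1)
            ours = {frozenset(map(int, c.members)) for c in cs.clusters if c.sign == 1}
            oracle = flood_fill_components(grid, stat > 0.5, connectivity)
            assert ours == oracle

    def test_diagonal_touching_blobs(self):
        """Two blobs touching only diagonally: one cluster under
        26-connectivity, two under 6-connectivity."""
        grid = SourceGrid((8, 8, 8))
        lookup = grid.voxel_lookup()
        stat = np.zeros(grid.n_voxels)
        for p in [(3, 3, 3), (4, 4, 4)]:  # touch only along the space diagonal
            stat[lookup[p]] = 2.0
        assert len(cst.form_clusters(stat, 1.0, grid, connectivity=26, min_size=1).clusters) == 1
        assert len(cst.form_clusters(stat, 1.0, grid, connectivity=6, min_size=1).clusters) == 2

    def test_partition_of_suprathreshold_set(self):
        grid = SourceGrid((6, 6, 6))
        stat = np.random.default_rng(3).normal(0, 2, grid.n_voxels)
        cs = cst.form_clusters(stat, 1.0, grid, min_size=1)
        seen = []
        for c in cs.clusters:
            seen.extend(c.members.tolist())
        assert len(seen) == len(set(seen))
        assert len(seen) == int(np.sum(np.abs(stat) > 1.0))


class TestThresholds:
    def test_parametric_threshold_df23(self):
        assert cst.parametric_threshold(23, 0.01) == pytest.approx(2.81, abs=0.005)

    def test_normal_limit(self):
        assert cst.parametric_threshold(10**7, 0.05) == pytest.approx(1.96, abs=0.001)

    def test_elevated_visual_threshold_constant(self):
        assert cst.TCRIT_VISUAL_AV == 6.60

    def test_auc_threshold_uniform_null(self):
        rng = np.random.default_rng(0)
        assert cst.auc_threshold(rng.random(200_000)) == pytest.approx(0.99, abs=0.002)

    def test_auc_threshold_quantile_convention(self):
        values = np.arange(1.0, 101.0)
        assert cst.auc_threshold(values) == pytest.approx(np.percentile(values, 99))

    def test_all_equal_null(self):
        assert cst.auc_threshold(np.full(500, 0.7)) == pytest.approx(0.7)


class TestSignFlipNull:
    def test_all_zero_effects_degenerate(self):
        grid = SourceGrid((6, 6, 6))
        effects = np.zeros((8, grid.n_voxels))
        scheme = cst.PermutationScheme(100, seed=0, statistic="mean")
        null = cst.signflip_null(effects, scheme, grid=grid, threshold=0.5)
        assert np.all(null.max_cluster_stats == 0.0)

    def test_global_sign_flip_invariance(self):
        """Flipping every subject's map gives the identical two-sided result."""
        grid = SourceGrid((6, 6, 6))
        rng = np.random.default_rng(1)
        effects = _correlated_noise(rng, grid, 10, 1, 12.0)[:, :, 0] + 0.3
        scheme = cst.PermutationScheme(200, seed=3, statistic="t")
        cs1, _, _ = cst.cluster_inference(effects, grid, scheme, threshold=2.5)
        cs2, _, _ = cst.cluster_inference(-effects, grid, scheme, threshold=2.5)
        assert len(cs1.clusters) == len(cs2.clusters)
        for c1, c2 in zip(cs1.clusters, cs2.clusters):
            assert set(c1.members) == set(c2.members)
            assert c1.sum_stat == pytest.approx(-c2.sum_stat)
            assert c1.p_fwe == pytest.approx(c2.p_fwe)

    def test_subject_order_invariance_of_observed_map(self):
        grid = SourceGrid((6, 6, 6))
        rng = np.random.default_rng(2)
        effects = rng.normal(0.2, 1, (9, grid.n_voxels))
        m1 = cst._group_stat(effects, "t")
        m2 = cst._group_stat(effects[::-1], "t")
        np.testing.assert_allclose(m1, m2, atol=1e-12)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(DataError):
            cst.signflip_null(np.zeros((1, 10)), cst.PermutationScheme(100, 0, "mean"))

    def test_too_few_permutations_rejected(self):
        with pytest.raises(DataError):
            cst.PermutationScheme(50, 0, "mean")


class TestFWEPValues:
    def test_extreme_and_median_ranks(self):
        grid = SourceGrid((8, 8, 8))
        stat = np.zeros(grid.n_voxels)
        line = [v for v, (i, j, k) in enumerate(grid.lattice_index) if j == 4 and k == 4]
        stat[line[:6]] = 5.0
        cs = cst.form_clusters(stat, 2.0, grid)
        null = np.zeros(199)
        cst.fwe_pvalues(cs, null)
        assert cs.clusters[0].p_fwe == pytest.approx(1 / 200)
        null_median = np.linspace(0, 60, 199)
        cst.fwe_pvalues(cs, null_median)
        assert cs.clusters[0].p_fwe == pytest.approx(0.5, abs=0.01)

    def test_p_never_zero(self):
        grid = SourceGrid((6, 6, 6))
        rng = np.random.default_rng(5)
        effects = _correlated_noise(rng, grid, 8, 1, 12.0)[:, :, 0] + 2.0
        scheme = cst.PermutationScheme(100, seed=1, statistic="mean")
        cs, _, _ = cst.cluster_inference(effects, grid, scheme, threshold=0.5)
        assert all(c.p_fwe > 0 for c in cs.clusters)


class TestMasksAndOverlap:
    def _cluster(self, members, p):
        c = cst.Cluster(members=np.array(members), sum_stat=10.0, sign=1)
        c.p_fwe = p
        return c

    def test_apriori_mask_union_and_fallback(self):
        cs = cst.ClusterSet([self._cluster([1, 2, 3], 0.01), self._cluster([7, 8], 0.2)], threshold=1.0)
        mask = cst.apriori_mask(cs, 10)
        assert set(np.flatnonzero(mask)) == {1, 2, 3}
        empty = cst.ClusterSet([self._cluster([1], 0.5)], threshold=1.0)
        with pytest.warns(UserWarning):
            full = cst.apriori_mask(empty, 10)
        assert full.all()

    def test_overlap_rules(self):
        a = [self._cluster([0, 1, 2], 0.01)]
        b = [self._cluster([2, 3], 0.01)]
        overlap = cst.overlap_map({"ra": a, "rb": b}, 6)
        assert set(np.flatnonzero(overlap)) == {2}
        assert not cst.overlap_map({"ra": a, "rb": [self._cluster([4], 0.01)]}, 6).any()
        same = cst.overlap_map({"ra": a, "rb": a}, 6)
        assert set(np.flatnonzero(same)) == {0, 1, 2}

    def test_masked_inference_confined_to_mask(self):
        grid = SourceGrid((6, 6, 6))
        rng = np.random.default_rng(9)
        effects = _correlated_noise(rng, grid, 10, 1, 12.0)[:, :, 0] + 1.0
        mask = np.zeros(grid.n_voxels, dtype=bool)
        mask[: grid.n_voxels // 2] = True
        scheme = cst.PermutationScheme(100, seed=2, statistic="mean")
        cs, _, _ = cst.cluster_inference(effects, grid, scheme, threshold=0.3, mask=mask)
        for c in cs.clusters:
            assert mask[c.members].all()
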