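"""Field entropy, gating, regions, kNN density co-occurrence, bootstraps."""

import numpy as np
import pandas as pd
import pytest

from cycplex import spatial


def _table(xy, **cols):
    df = pd.DataFrame({"cell_id": np.arange(len(xy)),
                       "centroid_x": xy[:, 0], "centroid_y": xy[:, 1]})
    for name, v in cols.items():
        df[name] = v
    return df


class TestGridFields:
    def test_single_field(self):
        xy = np.random.default_rng(0).uniform(0, 50, (20, 2))
        grid = spatial.grid_fields(_table(xy), 100, 100)
        assert grid.counts.index.tolist() == [(0, 0)]
        assert grid.counts.iloc[0] == 20

    def test_boundary_floor_convention(self):
        xy = np.array([[100.0, 0.0], [99.999, 0.0]])
        grid = spatial.grid_fields(_table(xy), 100, 100)
        assert grid.field_ids.iloc[0] == (0, 1)
        assert grid.field_ids.iloc[1] == (0, 0)

    def test_uniform_counts_within_poisson(self):
        rng = np.random.default_rng(1)
        n = 4000
        xy = rng.uniform(0, 400, (n, 2))
        grid = spatial.grid_fields(_table(xy), 100, 100)
        expected = n / 16
        assert np.all(np.abs(grid.counts.to_numpy() - expected) < 4 * np.sqrt(expected))

    def test_positive_dims_required(self):
        with pytest.raises(ValueError):
            spatial.grid_fields(_table(np.zeros((1, 2))), 0, 10)


class TestFieldEntropy:
    def test_uniform_intensities_reach_maximum(self):
        e = spatial.field_entropy(np.full(2000, 7.0), n_sample=1000, seed=0)
        assert e == pytest.approx(np.log(1000), abs=1e-9)

    def test_one_hot_gives_zero(self):
        v = np.zeros(1500)
        v[0] = 4.2
        # find a seed whose sample includes the single bright cell
        for seed in range(50):
            e = spatial.field_entropy(v, n_sample=1000, seed=seed)
            rng = np.random.default_rng(seed)
            picked = 0 in rng.choice(1500, 1000, replace=False)
            if picked:
                assert e == pytest.approx(0.0, abs=1e-12)
                return
        pytest.fail("no sample contained the bright cell")

    def test_matches_brute_force_summation(self):
        rng = np.random.default_rng(2)
        v = rng.lognormal(3, 1, 3000)
        seed = 5
        e = spatial.field_entropy(v, n_sample=1000, seed=seed)
        s = v[np.random.default_rng(seed).choice(3000, 1000, replace=False)]
        p = s**2 / np.sum(s**2)
        brute = -sum(pi * np.log(pi) for pi in p if pi > 0)
        assert e == pytest.approx(brute, abs=1e-12)

    def test_entropy_bounds(self):
        rng = np.random.default_rng(3)
        v = rng.lognormal(0, 2, 1500)
        e = spatial.field_entropy(v, n_sample=1000, seed=1)
        assert 0.0 <= e <= np.log(1000) + 1e-12

    def test_small_fields_excluded(self):
        with pytest.raises(ValueError, match="requires more"):
            spatial.field_entropy(np.ones(1000), n_sample=1000, seed=0)

    def test_all_zero_intensities_flagged(self):
        with pytest.raises(ValueError, match="zero"):
            spatial.field_entropy(np.zeros(1200), n_sample=1000, seed=0)


class TestNormalizeEntropy:
    def test_ratios(self):
        out = spatial.normalize_entropy(np.array([6.9, 0.0]), 6.9)
        assert out[0] == pytest.approx(1.0) and out[1] == 0.0

    def test_homogeneous_tissue_concentrates_near_one(self):
        rng = np.random.default_rng(4)
        all_v = rng.lognormal(4, 0.3, 40000)
        e_sample = spatial.field_entropy(all_v, 1000, seed=0)
        fields = [
            spatial.field_entropy(all_v[i * 2000 : (i + 1) * 2000], 1000, seed=i)
            for i in range(20)
        ]
        norm = spatial.normalize_entropy(np.array(fields), e_sample)
        assert norm.std() < 0.1
        assert abs(norm.mean() - 1.0) < 0.05

    def test_positive_sample_entropy_required(self):
        with pytest.raises(ValueError):
            spatial.normalize_entropy(np.array([1.0]), 0.0)


class TestGating:
    def test_bimodal_marker_recovered(self):
        rng = np.random.default_rng(5)
        neg = rng.lognormal(np.log(50), 0.4, 700)
        pos = rng.lognormal(np.log(2000), 0.4, 300)
        v = np.concatenate([neg, pos])
        truth = np.concatenate([np.zeros(700, bool), np.ones(300, bool)])
        tab = _table(np.zeros((1000, 2)), marker=v)
        gate = spatial.gate_positive(tab, "marker", strategy="otsu")
        tp = (gate & truth).sum()
        f1 = 2 * tp / (gate.sum() + truth.sum())
        assert f1 > 0.95

    def test_fixed_threshold_above_all(self):
        tab = _table(np.zeros((10, 2)), marker=np.arange(10.0))
        gate = spatial.gate_positive(tab, "marker", strategy="fixed", threshold=100.0)
        assert not gate.any()

    def test_conjunction_is_subset(self):
        rng = np.random.default_rng(6)
        tab = _table(np.zeros((200, 2)), m1=rng.uniform(0, 1, 200), m2=rng.uniform(0, 1, 200))
        g1 = spatial.gate_positive(tab, "m1", "fixed", 0.5)
        g2 = spatial.gate_positive(tab, "m2", "fixed", 0.5)
        both = g1 & g2
        assert both.sum() <= min(g1.sum(), g2.sum())
        assert np.all(~both | g1) and np.all(~both | g2)

    def test_missing_column(self):
        with pytest.raises(KeyError):
            spatial.gate_positive(_table(np.zeros((5, 2))), "nope")


class TestAssignRegions:
    def test_half_plane_contrast_recovered(self):
        rng = np.random.default_rng(7)
        xy = rng.uniform(0, 400, (2000, 2))
        stroma = xy[:, 0] >= 200  # right half is marker-high
        marker = np.where(stroma, 1000.0, 100.0) * rng.lognormal(0, 0.2, 2000)
        tab = _table(xy, aSMA=marker)
        labels, mask = spatial.assign_regions(tab, "aSMA", canvas_shape=(400, 400))
        correct = (labels == np.where(stroma, "stroma", "tumor")).mean()
        assert correct >= 0.95
        assert len(labels) == len(tab)

    def test_uniform_marker_degenerates_to_one_region(self):
        xy = np.random.default_rng(8).uniform(0, 100, (300, 2))
        tab = _table(xy, aSMA=np.full(300, 5.0))
        labels, mask = spatial.assign_regions(tab, "aSMA", canvas_shape=(100, 100))
        assert set(labels) == {"tumor"}
        assert not mask.any()


class TestKnnDensity:
    def test_uniform_density_within_15pct(self):
        rng = np.random.default_rng(9)
        pts = rng.uniform(0, 1, (2000, 2))
        g = np.linspace(0.25, 0.75, 21)
        df = spatial.knn_density(pts, g, g, k=4)
        assert abs(df.density.mean() - 1.0) < 0.15  # true uniform density = 1

    def test_cluster_decays_outward(self):
        rng = np.random.default_rng(10)
        pts = rng.normal([50, 50], 2.0, (500, 2))
        gx = np.arange(50, 100, 2.0)
        gy = np.array([50.0, 52.0])
        df = spatial.knn_density(pts, gy, gx, k=4)
        ray = df.density[0]
        assert ray.argmax() == 0
        assert ray[0] > ray[5] > ray[15]

    def test_density_scales_with_point_count(self):
        rng = np.random.default_rng(11)
        pts = rng.uniform(0, 1, (1500, 2))
        extra = rng.uniform(0, 1, (1500, 2))
        g = np.linspace(0.3, 0.7, 15)
        d1 = spatial.knn_density(pts, g, g, k=4).density.mean()
        d2 = spatial.knn_density(np.vstack([pts, extra]), g, g, k=4).density.mean()
        # probability density stays ~1 regardless of n; point density = n * rho
        assert 2 * 3000 * d2 / (2 * 1500 * d1) == pytest.approx(2.0, rel=0.15)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            spatial.knn_density(np.zeros((2, 2)), np.arange(3.0), np.arange(3.0), k=4)


class TestCooccurrence:
    @staticmethod
    def _grids():
        g = np.arange(0, 100, 4.0)
        return g, g

    def test_identical_point_sets_peak_together(self):
        rng = np.random.default_rng(12)
        pts = rng.normal([30, 30], 5, (300, 2))
        gy, gx = self._grids()
        d = spatial.knn_density(pts, gy, gx, 4)
        mask = np.ones(d.density.shape, bool)
        cooc, means, hot = spatial.cooccurrence_map(d, d, {"all": mask})
        assert np.unravel_index(cooc.argmax(), cooc.shape) == np.unravel_index(
            d.density.argmax(), d.density.shape
        )

    def test_disjoint_populations_have_negligible_cooccurrence(self):
        # populations on far-apart unit squares: gap ~10x the support size.
        # The kNN estimator has 1/d^2 tails, so "zero" is relative: the
        # disjoint product must sit orders of magnitude below the product the
        # same points give when the two populations coincide.
        rng = np.random.default_rng(13)
        a = rng.uniform([0, 0], [1, 1], (400, 2))
        b = rng.uniform([10, 10], [11, 11], (400, 2))
        g = np.arange(0, 11.01, 0.25)
        da = spatial.knn_density(a, g, g, 4)
        db = spatial.knn_density(b, g, g, 4)
        mask = np.ones(da.density.shape, bool)
        cooc_disjoint, _, _ = spatial.cooccurrence_map(da, db, {"all": mask})
        cooc_colocated, _, _ = spatial.cooccurrence_map(da, da, {"all": mask})
        assert cooc_disjoint.max() < 1e-3 * cooc_colocated.max()

    def test_region_probabilities_sum_to_one(self):
        rng = np.random.default_rng(14)
        pts = rng.uniform(0, 100, (500, 2))
        gy, gx = self._grids()
        d = spatial.knn_density(pts, gy, gx, 4)
        left = np.zeros(d.density.shape, bool)
        left[:, : left.shape[1] // 2] = True
        for mask in (left, ~left):
            p = d.density[mask]
            assert (p / p.sum()).sum() == pytest.approx(1.0, abs=1e-6)

    def test_fold_enrichment_scale_invariant(self):
        rng = np.random.default_rng(15)
        a = rng.uniform(0, 100, (400, 2))
        b = rng.normal([25, 25], 8, (400, 2))
        gy, gx = self._grids()
        da = spatial.knn_density(a, gy, gx, 4)
        db = spatial.knn_density(b, gy, gx, 4)
        left = np.zeros(da.density.shape, bool)
        left[:, : left.shape[1] // 2] = True
        masks = {"L": left, "R": ~left}
        _, m1, _ = spatial.cooccurrence_map(da, db, masks)
        da_scaled = spatial.DensityField(da.grid_y, da.grid_x, da.density * 37.0,
                                         da.k, da.n_points)
        _, m2, _ = spatial.cooccurrence_map(da_scaled, db, masks)
        f1 = spatial.fold_enrichment(m1, "L", "R")
        f2 = spatial.fold_enrichment(m2, "L", "R")
        assert f1 == pytest.approx(f2, rel=1e-9)


class TestBootstrapCounts:
    def test_all_positive_zero_sem(self):
        xy = np.zeros((40, 2))
        tab = _table(xy)
        out = spatial.bootstrap_counts(
            tab, {"g": np.ones(40, bool)}, np.array(["r"] * 40), n_boot=50, seed=0
        )
        assert out["mean"].iloc[0] == 40.0
        assert out["sem"].iloc[0] == 0.0

    def test_binomial_expectation(self):
        rng = np.random.default_rng(16)
        m, p = 500, 0.3
        gate = rng.uniform(0, 1, m) < p
        tab = _table(np.zeros((m, 2)))
        out = spatial.bootstrap_counts(
            tab, {"g": gate}, np.array(["r"] * m), n_boot=100, seed=1
        )
        row = out.iloc[0]
        assert abs(row["mean"] - gate.sum()) < 3 * row["sem"] * np.sqrt(100) + 1e-9

    def test_deterministic_for_seed(self):
        rng = np.random.default_rng(17)
        gate = rng.uniform(0, 1, 100) < 0.5
        tab = _table(np.zeros((100, 2)))
        a = spatial.bootstrap_counts(tab, {"g": gate}, np.array(["r"] * 100), 20, seed=9)
        b = spatial.bootstrap_counts(tab, {"g": gate}, np.array(["r"] * 100), 20, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_nboot_validated(self):
        with pytest.raises(ValueError):
            spatial.bootstrap_counts(
                _table(np.zeros((5, 2))), {}, np.array(["r"] * 5), n_boot=1
            )
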