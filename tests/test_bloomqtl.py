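"""LOD scans, permutation-FDR thresholds, forward selection, interactions."""

import numpy as np
import pytest

from phenobench import bloomqtl, simdata
from phenobench.dataio import HAPLOID, GenotypeMatrix
from phenobench.simdata import GenomeMap, TraitArchitecture


def make_geno(values, mapping=None):
    values = np.asarray(values, dtype=float)
    return GenotypeMatrix(
        values=values,
        coding=HAPLOID,
        sample_ids=[f"s{i}" for i in range(values.shape[0])],
        marker_ids=[f"m{j}" for j in range(values.shape[1])],
        mapping=mapping,
    )


def lod_ss_oracle(g, r):
    """Independent LOD via the residual-sum-of-squares ratio of two OLS fits."""
    n = len(r)
    ss0 = ((r - r.mean()) ** 2).sum()
    X = np.column_stack([np.ones(n), g])
    beta, *_ = np.linalg.lstsq(X, r, rcond=None)
    ss1 = ((r - X @ beta) ** 2).sum()
    return (n / 2.0) * np.log10(ss0 / ss1)


class TestLODScan:
    def test_null_marker_lod_small(self):
        rng = np.random.default_rng(1)
        G = make_geno(rng.integers(2, size=(500, 10)).astype(float))
        r = rng.normal(size=500)
        scan = bloomqtl.lod_scan(G, r)
        assert (scan.lod < 2.0).all() and np.median(scan.lod) < 0.5

    def test_dual_formula_agreement(self):
        # correlation form vs SS-ratio form on a small worked instance
        g = np.array([0, 1, 0, 1, 1, 0], dtype=float)
        r = np.array([0.2, 1.1, -0.3, 0.9, 1.4, 0.1])
        G = make_geno(g[:, None])
        scan = bloomqtl.lod_scan(G, r)
        assert abs(scan.lod[0] - lod_ss_oracle(g, r)) < 1e-10

    def test_duplicated_markers_identical_lod(self):
        rng = np.random.default_rng(3)
        col = rng.integers(2, size=100).astype(float)
        G = make_geno(np.column_stack([col, col]))
        scan = bloomqtl.lod_scan(G, rng.normal(size=100) + col)
        assert scan.lod[0] == scan.lod[1]

    def test_constant_marker_scored_zero(self):
        G = make_geno(np.column_stack([np.ones(50), np.arange(50) % 2]).astype(float))
        scan = bloomqtl.lod_scan(G, np.random.default_rng(5).normal(size=50))
        assert scan.lod[0] == 0.0

    def test_collinear_marker_capped_finite(self):
        g = np.arange(20) % 2
        G = make_geno(g[:, None].astype(float))
        scan = bloomqtl.lod_scan(G, g.astype(float))
        assert np.isfinite(scan.lod[0]) and scan.lod[0] > 50


class TestPermutationThreshold:
    def test_degenerate_level_returns_min_lod(self):
        rng = np.random.default_rng(7)
        G = make_geno(rng.integers(2, size=(100, 20)).astype(float))
        r = rng.normal(size=100)
        null = bloomqtl.permutation_threshold(G, r, B=20, fdr_level=1.0, seed=1)
        assert np.isclose(null.threshold, bloomqtl.lod_scan(G, r).lod.min())

    def test_null_traits_rarely_selected(self):
        # pure-noise traits yield no selection at 5% FDR in >= 90% of reps
        gmap = GenomeMap.regular(2, 1.0, 30)
        G = simdata.simulate_cross(gmap, 200, seed=9)
        clean = 0
        reps = 50
        for rep in range(reps):
            r = np.random.default_rng(100 + rep).normal(size=200)
            null = bloomqtl.permutation_threshold(G, r, B=50, fdr_level=0.05, seed=rep)
            obs = bloomqtl.lod_scan(G, r).lod
            if not np.isfinite(null.threshold) or (obs >= null.threshold).sum() == 0:
                clean += 1
        assert clean >= int(0.9 * reps)

    def test_strong_qtl_detected(self):
        gmap = GenomeMap.regular(2, 1.0, 30)
        G = simdata.simulate_cross(gmap, 300, seed=11)
        hits = 0
        for rep in range(20):
            arch = TraitArchitecture("t", additive={15: 1.0}, h2=0.9)
            y = simdata.simulate_trait(G, arch, seed=200 + rep)
            null = bloomqtl.permutation_threshold(G, y, B=50, fdr_level=0.05, seed=rep)
            obs = bloomqtl.lod_scan(G, y).lod
            sig = np.flatnonzero(obs >= null.threshold)
            if any(abs(s - 15) <= 5 for s in sig):
                hits += 1
        assert hits >= 19  # >= 95% of repetitions


class TestForwardSelection:
    def test_null_trait_mostly_empty_model(self):
        gmap = GenomeMap.regular(2, 1.0, 25)
        G = simdata.simulate_cross(gmap, 150, seed=13)
        empty = 0
        for rep in range(20):
            y = np.random.default_rng(300 + rep).normal(size=150)
            model = bloomqtl.bloom_forward_selection(G, y, B=50, seed=rep)
            if model.n_markers == 0:
                empty += 1
        assert empty >= 16

    def test_self_consistency_exact_refit(self, cross):
        # a trait generated from a fitted model's own linear predictor with
        # zero noise is recovered exactly
        arch = TraitArchitecture("t", additive={10: 1.0, 55: 0.7}, h2=0.9)
        y = simdata.simulate_trait(cross, arch, seed=15)
        model = bloomqtl.bloom_forward_selection(cross, y, B=50, seed=1)
        assert model.n_markers >= 1
        y_clean = bloomqtl.predict_qtl(model, cross)
        refit = bloomqtl.bloom_forward_selection(cross, y_clean, B=50, seed=2)
        pred = bloomqtl.predict_qtl(refit, cross)
        assert np.max(np.abs(pred - y_clean)) < 1e-6

    def test_fdr_monotone_in_level(self, cross, additive_trait):
        y, _ = additive_trait
        sizes = []
        for level in (0.20, 0.05, 0.01):
            model = bloomqtl.bloom_forward_selection(
                cross, y, B=60, fdr_level=level, seed=5
            )
            sizes.append(model.n_markers)
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_stage_cap_respected(self, cross, additive_trait):
        y, _ = additive_trait
        model = bloomqtl.bloom_forward_selection(cross, y, max_stages=2, B=40, seed=3)
        assert all(s <= 2 for s in model.stages)

    def test_peak_reduction_one_marker_per_ld_block(self):
        # tightly linked significant markers collapse to a single peak
        gmap = GenomeMap(
            chromosomes=[("c", 0.05)], positions={"c": np.linspace(0, 0.05, 20)}
        )
        G = simdata.simulate_cross(gmap, 400, seed=17)
        arch = TraitArchitecture("t", additive={10: 1.0}, h2=0.9)
        y = simdata.simulate_trait(G, arch, seed=18)
        model = bloomqtl.bloom_forward_selection(G, y, B=60, seed=4)
        stage1 = [m for m, s in zip(model.marker_ids, model.stages) if s == 1]
        assert len(stage1) == 1


class TestInteractionScan:
    def test_lr_statistic_matches_nested_ols_oracle(self):
        rng = np.random.default_rng(19)
        vals = rng.integers(2, size=(8, 3)).astype(float)
        y = rng.normal(size=8) + vals[:, 0] * vals[:, 1]
        G = make_geno(vals)
        model = bloomqtl.QTLModel(
            marker_ids=["m0"], coefficients=np.array([1.0]), intercept=0.0, stages=[1]
        )
        stats, pairs = bloomqtl.interaction_lr_stats(G, y, model)
        n = 8
        for stat, (m, j) in zip(stats, pairs):
            base = np.column_stack([np.ones(n), vals[:, [0]], vals[:, [j]]])
            full = np.column_stack([base, (vals[:, m] * vals[:, j])[:, None]])

            def rss(X):
                beta, *_ = np.linalg.lstsq(X, y, rcond=None)
                res = y - X @ beta
                return res @ res

            expected = n * np.log(max(rss(base), 1e-300) / max(rss(full), 1e-300))
            assert abs(stat - max(expected, 0.0)) < 1e-8

    def test_additive_trait_rarely_yields_interactions(self):
        gmap = GenomeMap.regular(2, 1.0, 15)
        G = simdata.simulate_cross(gmap, 200, seed=21)
        kept = 0
        for rep in range(10):
            arch = TraitArchitecture("t", additive={5: 1.0, 20: 0.8}, h2=0.8)
            y = simdata.simulate_trait(G, arch, seed=400 + rep)
            add = bloomqtl.bloom_forward_selection(G, y, B=40, seed=rep)
            if add.n_markers == 0:
                continue
            aug = bloomqtl.interaction_scan(G, y, add, B=40, seed=rep)
            if aug.interactions:
                kept += 1
        assert kept <= 1  # >= 90% of runs keep zero interactions

    def test_epistatic_pair_detected(self):
        gmap = GenomeMap.regular(2, 1.0, 20)
        G = simdata.simulate_cross(gmap, 500, seed=23)
        found = 0
        reps = 10
        for rep in range(reps):
            arch = TraitArchitecture(
                "t",
                additive={5: 0.6, 30: 0.6},
                interactions={(5, 30): 1.2},
                h2=0.85,
            )
            y = simdata.simulate_trait(G, arch, seed=500 + rep)
            add = bloomqtl.bloom_forward_selection(G, y, B=40, seed=rep)
            if add.n_markers == 0:
                continue
            aug = bloomqtl.interaction_scan(G, y, add, B=40, seed=rep)
            pos = {m: i for i, m in enumerate(G.marker_ids)}
            for ma, mb in aug.interactions:
                ia, ib = sorted((pos[ma], pos[mb]))
                if abs(ia - 5) <= 3 and abs(ib - 30) <= 3:
                    found += 1
                    break
        assert found >= int(0.8 * reps)


class TestPrediction:
    def test_empty_model_predicts_intercept(self, cross):
        model = bloomqtl.QTLModel(intercept=2.5)
        assert np.allclose(bloomqtl.predict_qtl(model, cross), 2.5)

    def test_prediction_ignores_unselected_markers(self, cross):
        model = bloomqtl.QTLModel(
            marker_ids=["chr1_m5"], coefficients=np.array([1.5]), intercept=0.0,
            stages=[1],
        )
        p1 = bloomqtl.predict_qtl(model, cross)
        perturbed = cross.subset_markers(list(cross.marker_ids))
        perturbed.values = perturbed.values.copy()
        j = perturbed.marker_ids.index("chr2_m10")
        perturbed.values[:, j] = 1 - perturbed.values[:, j]
        assert np.array_equal(p1, bloomqtl.predict_qtl(model, perturbed))

    def test_missing_model_marker_errors(self, cross):
        model = bloomqtl.QTLModel(
            marker_ids=["nope"], coefficients=np.array([1.0]), intercept=0.0, stages=[1]
        )
        with pytest.raises(ValueError, match="lacks model markers"):
            bloomqtl.predict_qtl(model, cross)


def test_training_fold_only_no_leakage(cross, additive_trait):
    """Perturbing held-out phenotypes never changes the fitted model."""
    y, _ = additive_trait
    tr = np.arange(0, 300)
    G_tr = cross.subset_samples(tr)
    m1 = bloomqtl.bloom_forward_selection(G_tr, y[tr], B=40, seed=9)
    # the rest of the data plays no role whatsoever in fitting
    y_perturbed = y.copy()
    y_perturbed[300:] = -999.0
    m2 = bloomqtl.bloom_forward_selection(G_tr, y_perturbed[tr], B=40, seed=9)
    assert m1.marker_ids == m2.marker_ids
    assert np.array_equal(m1.coefficients, m2.coefficients)
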