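"""cvR², cross-validation protocol, degradation operators, multi-task stacking."""

import numpy as np
import pandas as pd
import pytest

from phenobench import evalbench, simdata
from phenobench.dataio import PhenotypeTable
from phenobench.evalbench import DegradationPlan
from phenobench.learners import FAST_POLICY


class TestCvR2:
    def test_perfect_prediction_is_one(self):
        y = np.array([1.0, 2.0, 5.0])
        assert evalbench.compute_cvR2(y, y) == 1.0

    def test_mean_prediction_is_zero(self):
        y = np.array([1.0, 2.0, 5.0])
        assert evalbench.compute_cvR2(y, np.full(3, y.mean())) == 0.0

    def test_worked_example(self):
        assert evalbench.compute_cvR2([1, 2, 3], [1, 2, 2]) == 0.5

    def test_constant_response_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            evalbench.compute_cvR2([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])

    def test_agrees_with_sklearn_r2(self):
        from sklearn.metrics import r2_score

        rng = np.random.default_rng(1)
        y, p = rng.normal(size=50), rng.normal(size=50)
        assert np.isclose(evalbench.compute_cvR2(y, p), r2_score(y, p))


class TestRunCV:
    def test_mean_baseline_nonpositive(self, cross, additive_trait):
        y, _ = additive_trait
        res = evalbench.run_cv(cross, y, "mean", k_folds=5, seed=1)
        assert res.cvr2 <= 0.0

    def test_every_sample_predicted_once(self, cross, additive_trait):
        y, _ = additive_trait
        res = evalbench.run_cv(cross, y, "mean", k_folds=7, seed=2)
        counts = np.bincount(res.fold_assignment, minlength=7)
        assert counts.sum() == len(y) and (counts > 0).all()
        assert np.isfinite(res.predictions).all()

    def test_heritability_ceiling_for_lasso(self):
        # out-of-fold accuracy sits below h² and above chance on a polygenic
        # additive trait with h² = 0.5
        gmap = simdata.GenomeMap.regular(4, 1.0, 25)
        G = simdata.simulate_cross(gmap, 600, seed=71)
        arch = simdata.TraitArchitecture(
            "t", additive={i * 5: 0.5 for i in range(20)}, h2=0.5
        )
        vals = []
        for s in range(3):
            y = simdata.simulate_trait(G, arch, seed=800 + s)
            vals.append(
                evalbench.run_cv(G, y, "lasso", k_folds=5, policy=FAST_POLICY, seed=s).cvr2
            )
        assert 0.3 <= np.mean(vals) <= 0.6

    def test_shuffled_phenotype_control(self, cross, additive_trait):
        y, _ = additive_trait
        y_shuf = np.random.default_rng(3).permutation(y)
        res = evalbench.run_cv(cross, y_shuf, "lasso", k_folds=5, policy=FAST_POLICY, seed=3)
        assert res.cvr2 <= 0.05

    def test_missing_phenotypes_dropped(self, cross, additive_trait):
        y, _ = additive_trait
        y2 = y.copy()
        y2[:50] = np.nan
        res = evalbench.run_cv(cross, y2, "mean", k_folds=5, seed=4)
        assert len(res.y) == len(y) - 50

    def test_repeats_averaged(self, cross, additive_trait):
        y, _ = additive_trait
        res = evalbench.run_cv(
            cross, y, "lasso", k_folds=5, n_repeats=3, policy=FAST_POLICY, seed=5
        )
        assert len(res.per_run) == 3
        assert np.isclose(res.cvr2, np.mean(res.per_run))

    def test_tiny_fold_rejected(self, cross, additive_trait):
        y, _ = additive_trait
        with pytest.raises(ValueError, match="fewer than 2"):
            evalbench.run_cv(cross, y, "mean", k_folds=250, seed=6)


class TestTrainTest:
    def test_deterministic_given_seed(self, cross, additive_trait):
        y, _ = additive_trait
        r1 = evalbench.run_train_test(cross, y, "lasso", policy=FAST_POLICY, seed=7)
        r2 = evalbench.run_train_test(cross, y, "lasso", policy=FAST_POLICY, seed=7)
        assert r1.cvr2 == r2.cvr2
        assert np.array_equal(r1.predictions, r2.predictions)

    def test_shuffled_control(self, cross, additive_trait):
        y, _ = additive_trait
        y_shuf = np.random.default_rng(8).permutation(y)
        res = evalbench.run_train_test(cross, y_shuf, "lasso", policy=FAST_POLICY, seed=8)
        assert res.cvr2 <= 0.1


class TestDegradation:
    def test_plan_validation(self):
        with pytest.raises(ValueError):
            DegradationPlan("class-noise", fractions=(0.5, 0.2))
        with pytest.raises(ValueError):
            DegradationPlan("typo", fractions=(0.1,))

    def test_full_contamination_shifts_everything_two_sigma(self, additive_trait, cross):
        y, _ = additive_trait
        plan = DegradationPlan("class-noise", fractions=(0.5, 1.0), repetitions=2, seed=1)
        for levels in evalbench.apply_degradation(cross, y, plan):
            f, _, y2 = levels[-1]
            assert f == 1.0
            shift = np.abs(y2 - y)
            assert np.allclose(shift, 2.0 * np.std(y, ddof=1), atol=1e-12)

    def test_noise_fraction_respected(self, additive_trait, cross):
        y, _ = additive_trait
        plan = DegradationPlan("class-noise", fractions=(0.25,), repetitions=1, seed=2)
        (_, _, y2), = evalbench.apply_degradation(cross, y, plan)[0]
        assert np.isclose((y2 != y).mean(), 0.25, atol=0.01)

    def test_marker_deletion_nested(self, cross, additive_trait):
        y, _ = additive_trait
        plan = DegradationPlan(
            "marker-deletion", fractions=(0.1, 0.25, 0.5), repetitions=2, seed=3
        )
        for levels in evalbench.apply_degradation(cross, y, plan):
            sets = [set(G2.marker_ids) for _, G2, _ in levels]
            assert sets[2] < sets[1] < sets[0]

    def test_sample_deletion_counts(self, cross, additive_trait):
        y, _ = additive_trait
        plan = DegradationPlan("sample-deletion", fractions=(0.5,), repetitions=1, seed=4)
        (_, G2, y2), = evalbench.apply_degradation(cross, y, plan)[0]
        assert G2.n_samples == len(y2) == cross.n_samples // 2

    def test_curves_ratio_one_at_baseline_and_nan_guard(self):
        df = pd.DataFrame(
            {
                "trait": ["t"] * 4 + ["z"] * 2,
                "method": ["rf"] * 4 + ["rf"] * 2,
                "repetition": [0, 0, 1, 1, 0, 0],
                "fraction": [0.0, 0.5, 0.0, 0.5, 0.0, 0.5],
                "r2": [0.8, 0.4, 0.8, 0.2, 0.0, 0.1],
            }
        )
        curves = evalbench.degradation_curves(df)
        t = curves[curves["trait"] == "t"]
        assert t.loc[t["fraction"] == 0.0, "ratio"].iloc[0] == 1.0
        assert np.isclose(t.loc[t["fraction"] == 0.5, "ratio"].iloc[0], 0.3 / 0.8)
        z = curves[curves["trait"] == "z"]
        assert z["ratio"].isna().all()

    def test_run_degradation_end_to_end(self, cross, additive_trait):
        y, _ = additive_trait
        plan = DegradationPlan("class-noise", fractions=(0.9,), repetitions=2, seed=5)
        df = evalbench.run_degradation(
            cross, y, ["lasso"], plan, policy=FAST_POLICY, seed=5, trait="t"
        )
        curves = evalbench.degradation_curves(df)
        base = curves.loc[curves["fraction"] == 0.0, "r2"].iloc[0]
        noisy = curves.loc[curves["fraction"] == 0.9, "r2"].iloc[0]
        assert noisy < base  # heavy class noise destroys accuracy


class TestLassoSupport:
    def test_null_trait_near_zero_support(self, cross):
        y = np.random.default_rng(9).normal(size=cross.n_samples)
        support, r2 = evalbench.lasso_support_size(cross, y, seed=9, policy=FAST_POLICY)
        # min-MSE CV tuning keeps a few spurious coefficients on pure noise;
        # "near zero" means a small fraction of the 90 markers, with no signal
        assert support <= 0.1 * cross.n_markers and r2 < 0.1

    def test_single_qtl_small_support_high_r2(self, cross):
        arch = simdata.TraitArchitecture("t", additive={10: 1.0}, h2=0.95)
        y = simdata.simulate_trait(cross, arch, seed=10)
        support, r2 = evalbench.lasso_support_size(cross, y, seed=10, policy=FAST_POLICY)
        assert support <= 10 and r2 > 0.7


class TestMultiTask:
    def test_single_trait_group_is_identity_plus_indicator(self, cross, additive_trait):
        y, arch = additive_trait
        P = PhenotypeTable(traits=pd.DataFrame({"t": y}, index=cross.sample_ids))
        mt = evalbench.build_multitask(cross, P, ["t"])
        assert mt.G_stacked.n_samples == cross.n_samples
        assert mt.G_stacked.n_markers == cross.n_markers + 1
        assert (mt.G_stacked.values[:, -1] == 1.0).all()
        assert np.array_equal(mt.G_stacked.values[:, :-1], cross.values)

    def test_row_count_is_sum_of_observed(self, cross, additive_trait):
        y, _ = additive_trait
        y2 = y.copy()
        y2[:100] = np.nan
        P = PhenotypeTable(
            traits=pd.DataFrame({"a": y, "b": y2}, index=cross.sample_ids)
        )
        mt = evalbench.build_multitask(cross, P, ["a", "b"])
        assert len(mt.y) == len(y) + (len(y) - 100)

    def test_empty_group_rejected(self, cross):
        P = PhenotypeTable(traits=pd.DataFrame(index=cross.sample_ids))
        with pytest.raises(ValueError, match="empty"):
            evalbench.build_multitask(cross, P, [])

    def test_shared_qtl_group_benefits_rf(self):
        # two traits driven by the same loci with correlated effects: the
        # grouped fit matches or beats the single-trait fits on average
        gmap = simdata.GenomeMap.regular(3, 1.0, 20)
        G = simdata.simulate_cross(gmap, 500, seed=81)
        shared = {5: 1.0, 25: 0.8, 45: 0.9}
        arch_a = simdata.TraitArchitecture("a", additive=shared, h2=0.6)
        arch_b = simdata.TraitArchitecture(
            "b", additive={k: v * 0.9 for k, v in shared.items()}, h2=0.6
        )
        ya = simdata.simulate_trait(G, arch_a, seed=82)
        yb = simdata.simulate_trait(G, arch_b, seed=83)
        P = PhenotypeTable(traits=pd.DataFrame({"a": ya, "b": yb}, index=G.sample_ids))
        mt = evalbench.build_multitask(G, P, ["a", "b"])
        grouped = evalbench.run_multitask_train_test(
            mt, "rf", policy=FAST_POLICY, seed=84
        )
        singles = []
        for t, y in (("a", ya), ("b", yb)):
            singles.append(
                evalbench.run_train_test(G, y, "rf", policy=FAST_POLICY, seed=84).cvr2
            )
        grouped_mean = np.mean(list(grouped["per_trait_r2"].values()))
        assert grouped_mean >= np.mean(singles) - 0.05
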