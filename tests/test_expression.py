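import warnings

import numpy as np
import pandas as pd
import pytest

from grnexpress.expression import (
    EffectEstimates,
    ModelFit,
    PerformanceRecord,
    assemble_features,
    average_effects,
    compare_models,
    fit_enet,
    quintile_bins,
    repeat_fit,
)


def recovery_data(seed=3, n=500, p=10, beta1=2.0, noise=0.01):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.normal(size=(n, p)),
        index=[f"g{i}" for i in range(n)],
        columns=[f"x{j}" for j in range(p)],
    )
    y = beta1 * X["x0"] + rng.normal(0.0, noise, n)
    return X, y


class TestAssembleFeatures:
    def test_single_edge(self):
        edges = pd.DataFrame({"tf": ["t1"], "gene": ["g1"], "weight": [0.5]})
        feats = assemble_features(edges, ["g1"], ["t1"])
        assert feats.at["g1", "t1"] == 0.5

    def test_order_invariance_and_zero_fill(self):
        edges = pd.DataFrame(
            {"tf": ["t2", "t1", "t1"], "gene": ["g1", "g2", "g1"], "weight": [3.0, 2.0, 1.0]}
        )
        a = assemble_features(edges, ["g1", "g2"], ["t1", "t2"])
        b = assemble_features(edges.iloc[::-1].reset_index(drop=True), ["g1", "g2"], ["t1", "t2"])
        pd.testing.assert_frame_equal(a, b)
        assert a.at["g2", "t2"] == 0.0

    def test_duplicate_edges_rejected(self):
        edges = pd.DataFrame(
            {"tf": ["t1", "t1"], "gene": ["g1", "g1"], "weight": [1.0, 2.0]}
        )
        with pytest.raises(ValueError):
            assemble_features(edges, ["g1"], ["t1"])


class TestFitEnet:
    def test_parameter_recovery(self):
        X, y = recovery_data()
        fit, perf = fit_enet(X, y, seed=5)
        sd = X["x0"].to_numpy().std(ddof=0)
        assert fit.coefficients["x0"] == pytest.approx(2.0 * sd, rel=0.10)
        assert (fit.coefficients.drop("x0").abs() < 0.05).all()
        assert perf.pcc > 0.99 and perf.mse < 0.01

    def test_degenerate_features_pcc_zero(self):
        X, y = recovery_data()
        with pytest.warns(RuntimeWarning, match="PCC"):
            _, perf = fit_enet(X * 0.0, y, seed=5)
        assert perf.pcc == 0.0

    def test_sparsity_pattern_lasso_vs_ridge(self):
        X, y = recovery_data()
        lasso, _ = fit_enet(X, y, alpha_ratio=1.0, seed=5)
        ridge, _ = fit_enet(X, y, alpha_ratio=0.0, seed=5)
        assert (lasso.coefficients == 0.0).sum() >= 8
        assert (ridge.coefficients == 0.0).sum() == 0

    def test_constant_response_rejected(self):
        X, _ = recovery_data(n=50)
        with pytest.raises(ValueError, match="constant"):
            fit_enet(X, pd.Series(1.0, index=X.index), seed=0)

    def test_too_many_inner_folds_rejected(self):
        X, y = recovery_data(n=30)
        with pytest.raises(ValueError, match="inner_folds"):
            fit_enet(X, y, inner_folds=25, seed=0)

    def test_too_few_genes_rejected(self):
        X, y = recovery_data(n=20)
        with pytest.raises(ValueError, match="25"):
            fit_enet(X, y, seed=0)


class TestRepeatFit:
    def test_single_iteration_matches_fit_enet(self):
        X, y = recovery_data(n=100)
        fits, perfs = repeat_fit(X, y, iterations=1, base_seed=9)
        fit, perf = fit_enet(X, y, seed=9)
        pd.testing.assert_series_equal(fits[0].coefficients, fit.coefficients)
        assert perfs[0].mse == perf.mse and perfs[0].pcc == perf.pcc

    def test_determinism(self):
        X, y = recovery_data(n=100)
        _, p1 = repeat_fit(X, y, iterations=3, base_seed=4)
        _, p2 = repeat_fit(X, y, iterations=3, base_seed=4)
        assert [(r.mse, r.pcc) for r in p1] == [(r.mse, r.pcc) for r in p2]

    def test_recovery_simulation_median_pcc(self):
        X, y = recovery_data(noise=0.5)
        _, perfs = repeat_fit(X, y, iterations=5, base_seed=0)
        assert np.median([r.pcc for r in perfs]) > 0.9


class TestCompareModels:
    def test_identical_lists_p_one(self):
        a = [PerformanceRecord(i, 1.0 + i, 0.1 * i) for i in range(5)]
        out = compare_models(a, a)
        assert out["pcc"][1] == pytest.approx(1.0)
        assert out["mse"][1] == pytest.approx(1.0)

    def test_exact_enumeration_n3(self):
        # most extreme labeling at n=3,3: two-sided exact p = 2/C(6,3) = 0.1
        a = [PerformanceRecord(i, float(m), 0.01 * m) for i, m in enumerate([1, 2, 3])]
        b = [PerformanceRecord(i, float(m), 0.01 * m) for i, m in enumerate([10, 20, 30])]
        out = compare_models(a, b)
        assert out["mse"][1] == pytest.approx(0.1)
        assert out["pcc"][1] == pytest.approx(0.1)

    def test_shifted_lists_complete_separation(self):
        a = [PerformanceRecord(i, float(i), 0.0) for i in range(6)]
        b = [PerformanceRecord(i, float(i) + 100.0, 0.5) for i in range(6)]
        stat, p = compare_models(a, b)["mse"]
        assert stat == 0.0  # every A value below every B value
        assert p < 0.01

    def test_too_few_records(self):
        a = [PerformanceRecord(0, 1.0, 0.1)]
        with pytest.raises(ValueError):
            compare_models(a, a)


class TestEffects:
    def make_fits(self, columns, rows):
        return [
            ModelFit(
                coefficients=pd.Series(row, index=columns),
                intercept=0.0,
                iteration_id=i,
                alpha_ratio=0.5,
                penalty_strength=0.1,
            )
            for i, row in enumerate(rows)
        ]

    def test_single_fit_identity(self):
        fits = self.make_fits(["a", "b"], [[0.3, -0.1]])
        eff = average_effects(fits)
        assert eff.beta_mean.tolist() == [0.3, -0.1]

    def test_mean_over_fits(self):
        fits = self.make_fits(["a"], [[0.1], [0.3]])
        assert average_effects(fits).beta_mean["a"] == pytest.approx(0.2)

    def test_planted_hand_mean(self):
        vals = [0.6, 0.6, 0.7, 0.6334 * 4 - 1.9]
        fits = self.make_fits(["a"], [[v] for v in vals])
        assert average_effects(fits).beta_mean["a"] == pytest.approx(np.mean(vals))

    def test_mismatched_features_rejected(self):
        fits = self.make_fits(["a"], [[0.1]]) + self.make_fits(["b"], [[0.2]])
        with pytest.raises(ValueError, match="mismatched"):
            average_effects(fits)


class TestQuintileBins:
    def bins_for(self, values):
        eff = EffectEstimates(
            beta_mean=pd.Series(values, index=[f"t{i}" for i in range(len(values))])
        )
        return quintile_bins(eff)

    def test_ten_tfs_bins_of_two(self):
        eff = self.bins_for(list(np.linspace(-1, 1, 10)))
        assert eff.bins.value_counts().sort_index().tolist() == [2, 2, 2, 2, 2]

    def test_seven_tfs_remainder_from_bin_one(self):
        eff = self.bins_for(list(np.linspace(-1, 1, 7)))
        counts = eff.bins.value_counts().sort_index()
        assert counts.tolist() == [2, 2, 1, 1, 1]

    def test_most_negative_in_bin_one(self):
        eff = self.bins_for([0.5, -0.9, 0.1, 0.9, -0.1, 0.3, -0.5, 0.7, 0.2, -0.3])
        assert eff.bins[eff.beta_mean.idxmin()] == 1
        assert eff.bins[eff.beta_mean.idxmax()] == 5

    def test_ties_stay_in_lower_bin(self):
        # counting oracle: 0.0 appears at positions 4..6 after sorting; the
        # nominal boundary between bins 3 and 4 falls inside the tie group
        values = [-0.4, -0.3, -0.2, -0.1, 0.0, 0.0, 0.0, 0.1, 0.2, 0.3]
        eff = self.bins_for(values)
        tied = eff.bins[eff.beta_mean == 0.0]
        assert tied.nunique() == 1
        assert tied.iloc[0] == 3

    def test_too_few_tfs(self):
        with pytest.raises(ValueError):
            self.bins_for([0.1, 0.2, 0.3, 0.4])
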