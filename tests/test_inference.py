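"""Mixed models, Wald tests, FDR, marginal effects, outlier scan."""
import numpy as np
import pandas as pd
import pytest

from driftld.inference import (
    ModelResult,
    bh_fdr,
    fit_lmm,
    fit_sift_model,
    marginal_increase,
    outlier_scan,
    paired_t_test,
    per_distance_models,
    population_level_stats,
    significant_run,
)


def make_meta(n_pops=30, rng=None, selfing_effect=True):
    rng = rng or np.random.default_rng(0)
    return pd.DataFrame({
        "pop": [f"p{i}" for i in range(n_pops)],
        "cluster": ["east" if i % 2 else "west" for i in range(n_pops)],
        "log10_expansion_distance": np.log10(
            rng.uniform(10, 2000, n_pops)),
        "F_IS": rng.uniform(0, 0.9, n_pops),
    })


def simulate_response(meta, n_regions=30, beta_dist=0.4, beta_fis=0.3,
                      sd_pop=0.05, sd_resid=0.1, seed=0):
    rng = np.random.default_rng(seed)
    pop_eff = dict(zip(meta["pop"], rng.normal(0, sd_pop, len(meta))))
    rows = []
    for _, m in meta.iterrows():
        for r in range(n_regions):
            y = (beta_dist * m["log10_expansion_distance"]
                 + beta_fis * m["F_IS"] + pop_eff[m["pop"]]
                 + rng.normal(0, sd_resid))
            rows.append({**m.to_dict(), "region_id": f"g{r}", "y": y})
    return pd.DataFrame(rows)


class TestFitLmm:
    def test_parameter_recovery_with_population_noise(self):
        meta = make_meta(50)
        data = simulate_response(meta, n_regions=20, seed=1)
        res = fit_lmm(data, "y",
                      ["cluster", "log10_expansion_distance", "F_IS"],
                      group="pop")
        assert res.converged
        b_dist = res.coef("log10_expansion_distance")
        b_fis = res.coef("F_IS")
        assert b_dist["beta"] > 0 and b_fis["beta"] > 0
        assert abs(b_dist["beta"] - 0.4) < 2 * b_dist["se"]
        assert abs(b_fis["beta"] - 0.3) < 2 * b_fis["se"]

    def test_wald_chi2_equals_beta_over_se_squared(self):
        meta = make_meta(20)
        data = simulate_response(meta, n_regions=5, seed=2)
        res = fit_lmm(data, "y", ["log10_expansion_distance", "F_IS"],
                      group="pop")
        for term in ("log10_expansion_distance", "F_IS"):
            row = res.coef(term)
            assert row["chi2"] == pytest.approx(
                (row["beta"] / row["se"]) ** 2, abs=1e-8)

    def test_single_population_degrades_to_ols(self):
        meta = make_meta(1)
        data = simulate_response(meta, n_regions=30, seed=3)
        res = fit_lmm(data, "y", ["log10_expansion_distance"], group="pop")
        assert res.converged
        assert "OLS" in res.random_structure

    def test_all_failures_flagged_not_silent(self):
        data = pd.DataFrame({"y": [1.0, 1.0], "x": [2.0, 2.0],
                             "pop": ["a", "b"]})
        res = fit_lmm(data, "y", ["x"], group="pop")
        # constant predictor: either a (degenerate) fit or an explicit flag
        assert isinstance(res, ModelResult)


class TestSiftModel:
    def make_sift_data(self, interaction=0.0, seed=0, n_pops=30,
                       per_cell=4):
        rng = np.random.default_rng(seed)
        meta = make_meta(n_pops, rng)
        rows = []
        for _, m in meta.iterrows():
            for cat, code in [("DD", 0), ("DT", 1), ("TT", 2)]:
                for _ in range(per_cell):
                    y = (0.3 * m["log10_expansion_distance"]
                         + 0.2 * m["F_IS"] - 0.05 * code
                         + interaction * code * m["log10_expansion_distance"]
                         + rng.normal(0, 0.05))
                    rows.append({**m.to_dict(), "pair_category": cat,
                                 "corrected_r2": y,
                                 "log10_gene_density": 3.0})
        return pd.DataFrame(rows)

    def test_absent_category_rejected(self):
        data = self.make_sift_data()
        with pytest.raises(ValueError, match="DD"):
            fit_sift_model(data[data["pair_category"] != "DD"])

    def test_no_interaction_betas_near_zero(self):
        res = fit_sift_model(self.make_sift_data(interaction=0.0, seed=4))
        for term in ("log10_expansion_distance:sift_type", "F_IS:sift_type"):
            row = res.coef(term)
            assert abs(row["beta"]) < 2 * row["se"]

    def test_interaction_sign_recovered(self):
        hits = 0
        for seed in range(10):
            res = fit_sift_model(
                self.make_sift_data(interaction=0.04, seed=seed))
            row = res.coef("log10_expansion_distance:sift_type")
            hits += row["beta"] > 0
        assert hits >= 8


class TestFdr:
    def test_bh_hand_computation(self):
        out = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(out, 0.04)

    def test_all_ones_stay_one(self):
        assert np.allclose(bh_fdr(np.ones(5)), 1.0)

    def test_monotone_and_order_invariant(self, rng):
        p = rng.random(50)
        adj = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        perm = rng.permutation(50)
        assert np.allclose(bh_fdr(p[perm]), adj[perm])

    def test_nan_passthrough(self):
        out = bh_fdr(np.array([0.01, np.nan, 0.02]))
        assert np.isnan(out[1]) and np.isfinite(out[0])


class TestPerDistanceModels:
    def make_delta(self, effect=0.0, n_pops=12, n_ind=2, bins=8, seed=0):
        rng = np.random.default_rng(seed)
        meta = make_meta(n_pops, rng)
        rows = []
        for _, m in meta.iterrows():
            for i in range(n_ind):
                for d in range(100, 100 * (bins + 1), 100):
                    scaled = 10 ** (
                        -0.5 + effect * m["F_IS"] + rng.normal(0, 0.05))
                    rows.append({"individual": f"{m['pop']}_i{i}",
                                 "pop": m["pop"], "d": d, "scaled": scaled})
        return pd.DataFrame(rows), meta

    def test_null_gives_no_consistent_run(self):
        delta, meta = self.make_delta(effect=0.0, seed=5)
        out = per_distance_models(delta, meta)
        frac_sig = out[out["term"] == "F_IS"]["significant"].mean()
        assert frac_sig < 0.5

    def test_injected_mating_effect_found_in_every_bin(self):
        delta, meta = self.make_delta(effect=1.2, n_pops=20, seed=6)
        out = per_distance_models(delta, meta)
        fis = out[out["term"] == "F_IS"]
        assert fis["significant"].all()
        assert significant_run(out, "F_IS") == fis["d"].max()

    def test_sparse_bins_skipped(self):
        delta, meta = self.make_delta(n_pops=2)
        out = per_distance_models(delta, meta, min_pops=3)
        assert out.empty


class TestPopulationStats:
    def test_perfect_correlation(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
        out = population_level_stats(df, [("a", "b")])
        assert out.iloc[0]["rho"] == pytest.approx(1.0)

    def test_too_few_populations_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2]})
        with pytest.raises(ValueError):
            population_level_stats(df, [("a", "a")])

    def test_paired_t_identical_vectors(self):
        res = paired_t_test(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        assert res["t"] == 0.0 and res["degenerate"]

    def test_paired_t_known_direction(self):
        a = np.array([1.0, 2, 3, 4, 5])
        res = paired_t_test(a + 1, a)
        assert res["degenerate"] or res["t"] > 0
        assert res["mean_diff"] == pytest.approx(1.0)


class TestMarginalIncrease:
    def fit_simple(self, slope, intercept=0.02, n=200, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.uniform(1, 3, n)
        data = pd.DataFrame({
            "y": intercept + slope * x + rng.normal(0, 1e-3, n),
            "x": x, "pop": np.repeat([f"p{i}" for i in range(10)], n // 10)})
        return fit_lmm(data, "y", ["x"], group="pop"), data

    def test_zero_slope_zero_percent(self):
        res, data = self.fit_simple(0.0)
        # estimated slope is within noise of zero -> percent change near 0
        assert marginal_increase(res, data, "x") == pytest.approx(0.0,
                                                                  abs=5.0)

    def test_five_hundred_percent_case(self):
        # y ranges from 0.01 at x_min to 0.06 at x_max -> +500%
        res, data = self.fit_simple(slope=0.025, intercept=0.01 - 0.025)
        data_span = data.copy()
        data_span.loc[data_span["x"].idxmin(), "x"] = 1.0
        data_span.loc[data_span["x"].idxmax(), "x"] = 3.0
        pct = marginal_increase(res, data_span, "x")
        assert pct == pytest.approx(500.0, rel=0.05)

    def test_sign_follows_slope(self):
        res, data = self.fit_simple(-0.004, intercept=0.05)
        assert marginal_increase(res, data, "x") < 0


class TestOutlierScan:
    def make_gene_data(self, n_pops=30, n_genes=40, outlier_genes=(),
                       beta=0.0, per_pop=3, seed=0, sd=0.05):
        rng = np.random.default_rng(seed)
        meta = make_meta(n_pops, rng)
        rows = []
        for g in range(n_genes):
            slope = beta * (2.0 if f"g{g}" in outlier_genes else 1.0)
            for _, m in meta.iterrows():
                for _ in range(per_pop):
                    y = slope * m["log10_expansion_distance"] + rng.normal(
                        0, sd)
                    rows.append({"region_id": f"g{g}", "pop": m["pop"],
                                 "corrected_r2": y})
        return pd.DataFrame(rows), meta

    def genomewide(self, data, meta):
        df = data.merge(meta, on="pop")
        return fit_lmm(df, "corrected_r2",
                       ["cluster", "log10_expansion_distance", "F_IS"],
                       group="pop")

    def test_identical_genes_not_flagged(self):
        # every gene follows the same (null) model: with the sd band no
        # gene can be both FDR-significant and outside the spread of betas
        data, meta = self.make_gene_data(beta=0.0, n_genes=20, seed=7)
        gw = self.genomewide(data, meta)
        out = outlier_scan(data, meta, gw, min_populations=10,
                          band_mode="sd")
        assert out["outlier_log10_expansion_distance"].sum() <= 1

    def test_doubled_slope_genes_flagged(self):
        outliers = {"g1", "g5", "g9"}
        data, meta = self.make_gene_data(
            beta=0.05, outlier_genes=outliers, n_genes=20, seed=8,
            sd=0.02)
        gw = self.genomewide(data, meta)
        out = outlier_scan(data, meta, gw, min_populations=10)
        flagged = set(out.loc[out["outlier_log10_expansion_distance"],
                              "gene"])
        assert outliers <= flagged

    def test_theta_comparison_direction(self):
        from driftld.inference import outlier_theta_comparison

        outliers = pd.DataFrame({
            "gene": ["g0", "g1", "g2", "g3"],
            "outlier_log10_expansion_distance": [True, True, False, False]})
        # flagged genes carry systematically lower diversity
        rows = []
        rng = np.random.default_rng(0)
        for pop in ("p1", "p2", "p3", "p4", "p5"):
            for g in range(4):
                base = 0.004 if g < 2 else 0.006
                rows.append(("genic", f"g{g}", pop,
                             base + rng.normal(0, 1e-4)))
        theta = pd.DataFrame(rows, columns=[
            "region_type", "region_id", "pop", "theta_w"])
        res = outlier_theta_comparison(outliers, theta)
        assert res["n_outliers"] == 2
        assert res["mean_diff"] < 0       # outliers minus background
        assert res["t"] < 0

    def test_theta_comparison_no_outliers(self):
        from driftld.inference import outlier_theta_comparison

        outliers = pd.DataFrame({
            "gene": ["g0"], "outlier_log10_expansion_distance": [False]})
        theta = pd.DataFrame({
            "region_type": ["genic"], "region_id": ["g0"],
            "pop": ["p1"], "theta_w": [0.005]})
        res = outlier_theta_comparison(outliers, theta)
        assert res["n_outliers"] == 0 and res["degenerate"]

    def test_band_modes_and_flag_rules(self):
        data, meta = self.make_gene_data(beta=0.03, n_genes=12, seed=9)
        gw = self.genomewide(data, meta)
        strict = outlier_scan(data, meta, gw, band_mode="se",
                              flag_rule="and")
        loose = outlier_scan(data, meta, gw, band_mode="se", flag_rule="or")
        n_strict = strict["outlier_log10_expansion_distance"].sum()
        n_loose = loose["outlier_log10_expansion_distance"].sum()
        assert n_loose >= n_strict
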