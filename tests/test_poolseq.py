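"""Pooled LD: the direct r2 estimator, filters, regions, aggregation."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from driftld.config import FilterConfig
from driftld.poolseq import (
    aggregate_regions,
    assign_regions,
    build_region_table,
    categorize_pairs,
    filter_pairs,
    fit_distance_correction,
    r2_direct,
    r2_direct_table,
)

from conftest import random_pair_counts


def pearson_r2_of_indicators(n11, n12, n21, n22):
    """Independent oracle: squared Pearson correlation of the two 0/1
    allele indicators enumerated over the n read pairs."""
    x = np.repeat([0, 0, 1, 1], [n11, n12, n21, n22])
    y = np.repeat([0, 1, 0, 1], [n11, n12, n21, n22])
    if len(set(x)) < 2 or len(set(y)) < 2:
        return np.nan
    return np.corrcoef(x, y)[0, 1] ** 2


class TestR2Direct:
    @pytest.mark.parametrize("counts,expected", [
        ((5, 0, 0, 5), 1.0),          # perfect coupling
        ((25, 25, 25, 25), 0.0),      # independence
        ((6, 2, 2, 6), 0.25),         # hand-evaluated
    ])
    def test_known_tables(self, counts, expected):
        assert r2_direct(*counts) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("counts", [
        (10, 0, 5, 0),   # locus 2 monomorphic
        (10, 5, 0, 0),   # locus 1 monomorphic
        (0, 0, 0, 0),    # no co-covering pairs
    ])
    def test_undefined_is_nan_not_zero(self, counts):
        assert np.isnan(r2_direct(*counts))

    def test_matches_pearson_oracle_on_random_tables(self, rng):
        tab = random_pair_counts(rng, n_tables=300)
        for _, r in tab.iterrows():
            mine = r2_direct(r.n11, r.n12, r.n21, r.n22)
            oracle = pearson_r2_of_indicators(r.n11, r.n12, r.n21, r.n22)
            if np.isnan(oracle):
                assert np.isnan(mine)
            else:
                assert mine == pytest.approx(oracle, abs=1e-12)

    def test_vectorised_table_matches_scalar(self, rng):
        tab = random_pair_counts(rng, n_tables=200)
        out = r2_direct_table(tab)
        for (_, row), r2 in zip(tab.iterrows(), out["r2"]):
            scalar = r2_direct(row.n11, row.n12, row.n21, row.n22)
            assert (np.isnan(r2) and np.isnan(scalar)) or \
                r2 == pytest.approx(scalar, abs=1e-14)

    @given(st.tuples(*[st.integers(0, 30)] * 4))
    @settings(max_examples=200, deadline=None)
    def test_invariant_to_allele_and_locus_swaps(self, counts):
        n11, n12, n21, n22 = counts
        base = r2_direct(n11, n12, n21, n22)
        swapped = [
            r2_direct(n21, n22, n11, n12),   # swap alleles at locus 1
            r2_direct(n12, n11, n22, n21),   # swap alleles at locus 2
            r2_direct(n22, n21, n12, n11),   # swap both
            r2_direct(n11, n21, n12, n22),   # swap loci
        ]
        for s in swapped:
            if np.isnan(base):
                assert np.isnan(s)
            else:
                assert s == pytest.approx(base, abs=1e-12)


def _counts_table(rows):
    return pd.DataFrame(
        rows, columns=["pop", "scaffold", "pos", "ref_count", "alt_count"]
    ).assign(ref="A", alt="T", depth=lambda d: d.ref_count + d.alt_count)


class TestFilterPairs:
    def make_est(self, n11=10, n12=10, n21=10, n22=10, pos1=100, pos2=200):
        pairs = pd.DataFrame([{
            "pop": "p1", "scaffold": "s1", "pos1": pos1, "pos2": pos2,
            "n11": n11, "n12": n12, "n21": n21, "n22": n22}])
        return r2_direct_table(pairs)

    def counts_for(self, maf1=0.4, maf2=0.4, pos1=100, pos2=200):
        return _counts_table([
            ("p1", "s1", pos1, int(100 * (1 - maf1)), int(100 * maf1)),
            ("p1", "s1", pos2, int(100 * (1 - maf2)), int(100 * maf2)),
        ])

    def test_depth_greater_than_five_is_strict(self):
        # exactly 5 co-covering pairs -> dropped; 6 -> kept
        est5 = self.make_est(2, 1, 1, 1)
        est6 = self.make_est(2, 2, 1, 1)
        counts = self.counts_for()
        assert len(filter_pairs(est5, counts)) == 0
        assert len(filter_pairs(est6, counts)) == 1

    def test_maf_both_loci_reading(self):
        est = self.make_est()
        counts = self.counts_for(maf1=0.10, maf2=0.40)
        assert len(filter_pairs(est, counts)) == 0
        any_mode = FilterConfig(maf_mode="any")
        assert len(filter_pairs(est, counts, any_mode)) == 1

    @pytest.mark.parametrize("pos2,kept", [(601, 0), (600, 1)])
    def test_distance_window_upper_bound(self, pos2, kept):
        est = self.make_est(pos1=100, pos2=pos2)
        counts = self.counts_for(pos2=pos2)
        assert len(filter_pairs(est, counts)) == kept

    def test_missing_locus_dropped(self):
        est = self.make_est()
        counts = self.counts_for().iloc[:1]
        assert len(filter_pairs(est, counts)) == 0


class TestRegions:
    @pytest.fixture()
    def regions(self):
        genes = pd.DataFrame({
            "scaffold": ["s1", "s1"],
            "start": [1000, 3000], "end": [2000, 4000],
            "gene_id": ["gA", "gB"],
        })
        return build_region_table(genes, {"s1": 5000})

    def test_region_table_alternates(self, regions):
        assert list(regions["region_type"]) == [
            "intergenic", "genic", "intergenic", "genic", "intergenic"]
        assert regions["start"].tolist() == [0, 1000, 2000, 3000, 4000]

    def test_overlapping_genes_rejected(self):
        genes = pd.DataFrame({
            "scaffold": ["s1", "s1"], "start": [100, 150],
            "end": [200, 250], "gene_id": ["gA", "gB"]})
        with pytest.raises(ValueError, match="overlap"):
            build_region_table(genes)

    def make_pairs(self, coords):
        return r2_direct_table(pd.DataFrame([
            {"pop": "p1", "scaffold": "s1", "pos1": a, "pos2": b,
             "n11": 5, "n12": 5, "n21": 5, "n22": 5} for a, b in coords]))

    def test_both_loci_in_same_gene(self, regions):
        out = assign_regions(self.make_pairs([(1100, 1500)]), regions)
        assert out.iloc[0]["region_id"] == "gA"
        assert out.iloc[0]["region_type"] == "genic"

    def test_cross_boundary_pairs_dropped(self, regions):
        out = assign_regions(self.make_pairs([(1900, 2100)]), regions)
        assert out.empty

    def test_interval_start_included_half_open(self, regions):
        # gene gA spans [1000, 2000) 0-based; 1-based position 1001 is its
        # first base, 1-based 2000 its last; 1-based 2001 is outside
        inside = assign_regions(self.make_pairs([(1001, 2000)]), regions)
        assert inside.iloc[0]["region_id"] == "gA"
        outside = assign_regions(self.make_pairs([(1001, 2001)]), regions)
        assert outside.empty


class TestDistanceCorrection:
    def test_constant_r2_zero_slope(self, rng):
        est = pd.DataFrame({
            "r2": 0.3, "distance": rng.integers(1, 500, 100),
            "region_type": "genic"})
        a, b, out = fit_distance_correction(est, "genic")
        assert b == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(out["corrected_r2"], 0.0, atol=1e-12)

    def test_residuals_sum_to_zero(self, rng):
        est = pd.DataFrame({
            "r2": rng.random(2000), "distance": rng.integers(1, 500, 2000),
            "region_type": "genic"})
        _, _, out = fit_distance_correction(est, "genic")
        assert abs(out["corrected_r2"].sum()) < 1e-8

    def test_slope_recovery(self, rng):
        d = rng.integers(1, 501, 10_000)
        r2 = 0.8 - 0.2 * np.log10(d) + rng.normal(0, 0.01, len(d))
        est = pd.DataFrame({"r2": r2, "distance": d, "region_type": "genic"})
        _, b, _ = fit_distance_correction(est, "genic")
        assert b == pytest.approx(-0.2, abs=0.02)

    def test_single_distance_rejected(self):
        est = pd.DataFrame({"r2": [0.1, 0.2], "distance": [100, 100],
                            "region_type": "genic"})
        with pytest.raises(ValueError, match="distinct"):
            fit_distance_correction(est, "genic")


class TestAggregate:
    def make(self, per_pop_counts, region="gA", rtype="genic"):
        rows = []
        for pop, k in per_pop_counts.items():
            for i in range(k):
                rows.append({"region_id": region, "region_type": rtype,
                             "pop": pop, "r2": 0.2 + 0.1 * i,
                             "corrected_r2": 0.0})
        return pd.DataFrame(rows)

    def test_fewer_than_five_estimates_removed(self):
        est = self.make({f"p{i}": 4 for i in range(4)})
        assert aggregate_regions(est, [f"p{i}" for i in range(4)]).empty

    def test_half_missing_boundary_is_strict(self):
        # present in 26 of 52 populations = 50% missing, not < 50% -> removed
        pops = [f"p{i}" for i in range(52)]
        est = self.make({p: 6 for p in pops[:26]})
        assert aggregate_regions(est, pops).empty
        # 27 of 52 -> kept
        est = self.make({p: 6 for p in pops[:27]})
        assert not aggregate_regions(est, pops).empty

    def test_mean_of_five_estimates(self):
        est = pd.DataFrame({
            "region_id": "gA", "region_type": "genic", "pop": "p1",
            "r2": [0.2, 0.3, 0.4, 0.5, 0.6], "corrected_r2": 0.0})
        out = aggregate_regions(est, ["p1"])
        assert out.iloc[0]["mean_r2"] == pytest.approx(0.4)
        assert out.iloc[0]["n_estimates"] == 5


class TestCategorize:
    @pytest.fixture()
    def labels(self):
        return pd.DataFrame({
            "scaffold": "s1", "pos": [10, 20, 30],
            "label": ["DELETERIOUS", "TOLERATED", "DELETERIOUS"]})

    def make(self, coords):
        return pd.DataFrame([
            {"pop": "p1", "scaffold": "s1", "pos1": a, "pos2": b}
            for a, b in coords])

    def test_dt_symmetric(self, labels):
        out = categorize_pairs(self.make([(10, 20), (20, 30)]), labels)
        assert list(out["pair_category"]) == ["DT", "DT"]

    def test_unlabeled_pairs_unannotated(self, labels):
        out = categorize_pairs(self.make([(10, 99), (98, 99)]), labels)
        assert list(out["pair_category"]) == ["unannotated", "unannotated"]

    def test_partition_identity(self, rng, labels):
        positions = [10, 20, 30, 99]
        coords = [(a, b) for a in positions for b in positions if a < b]
        out = categorize_pairs(self.make(coords), labels)
        labeled = {10, 20, 30}
        n_full = sum(1 for a, b in coords if a in labeled and b in labeled)
        cats = out["pair_category"].value_counts()
        assert (cats.get("DD", 0) + cats.get("DT", 0)
                + cats.get("TT", 0)) == n_full
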