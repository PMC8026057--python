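"""Pooled-sequencing LD: direct r-squared from read-pair haplotype counts.

Because pooled libraries lose individual identity, two-locus haplotypes can
only be read off single sequenced fragments that cover both SNPs; the
"direct" estimator computes r-squared from the 2x2 haplotype counts so
observed.  This module applies the filtering cascade (co-covering depth,
minor allele frequency, distance window), assigns SNP pairs to genic or
intergenic regions, regresses out the log10-distance decay, aggregates per
region and population, and classes pairs by deleterious/tolerated
annotation.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import FilterConfig

log = logging.getLogger(__name__)

PAIR_COLS = ["n11", "n12", "n21", "n22"]


def r2_direct(n11: float, n12: float, n21: float, n22: float) -> float:
    """Direct-estimate r-squared from 2x2 read-pair haplotype counts.

    Returns NaN (undefined, never 0) when there are no co-covering pairs or
    either locus is monomorphic among them.  Index 1 is the reference
    allele; r-squared is invariant to that labelling.
    """
    n = n11 + n12 + n21 + n22
    if n == 0:
        return np.nan
    p11 = n11 / n
    p1_ = (n11 + n12) / n
    p_1 = (n11 + n21) / n
    denom = p1_ * (1.0 - p1_) * p_1 * (1.0 - p_1)
    if denom == 0.0:
        return np.nan
    D = p11 - p1_ * p_1
    return (D * D) / denom


def r2_direct_table(pairs: pd.DataFrame) -> pd.DataFrame:
    """Vectorised ``r2_direct`` over a pair-counts table.

    Adds columns ``n`` (co-covering read pairs), ``distance`` and ``r2``;
    monomorphic pairs get NaN.
    """
    out = pairs.copy()
    n11, n12, n21, n22 = (out[c].to_numpy(dtype=float) for c in PAIR_COLS)
    n = n11 + n12 + n21 + n22
    with np.errstate(divide="ignore", invalid="ignore"):
        p11 = n11 / n
        p1_ = (n11 + n12) / n
        p_1 = (n11 + n21) / n
        denom = p1_ * (1 - p1_) * p_1 * (1 - p_1)
        D = p11 - p1_ * p_1
        r2 = np.where(denom > 0, (D * D) / np.where(denom > 0, denom, 1.0),
                      np.nan)
    out["n"] = n.astype(np.int64)
    out["distance"] = out["pos2"] - out["pos1"]
    out["r2"] = r2
    return out


def population_frequencies(counts: pd.DataFrame) -> pd.DataFrame:
    """Per (pop, scaffold, pos) alternate-allele and minor-allele frequency."""
    df = counts.copy()
    tot = df["ref_count"] + df["alt_count"]
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = np.where(tot > 0, df["alt_count"] / tot, np.nan)
    df["alt_freq"] = alt_freq
    df["maf"] = np.minimum(df["alt_freq"], 1.0 - df["alt_freq"])
    return df[["pop", "scaffold", "pos", "alt_freq", "maf", "depth"]]


def filter_pairs(estimates: pd.DataFrame, counts: pd.DataFrame,
                 filters: FilterConfig | None = None) -> pd.DataFrame:
    """Apply the depth / MAF / distance filtering cascade.

    Keeps pairs with co-covering read-pair depth strictly greater than
    ``min_pair_depth``, population minor allele frequency strictly greater
    than ``min_maf`` at both loci ("both" mode; "any" keeps pairs where at
    least one locus passes), defined r-squared, and distance inside
    [min_distance, max_distance].  Loci absent from the allele-count table
    are dropped and counted.
    """
    if filters is None:
        filters = FilterConfig()
    freqs = population_frequencies(counts)
    key = ["pop", "scaffold"]
    m1 = estimates.merge(
        freqs.rename(columns={"pos": "pos1", "maf": "maf1"}),
        on=key + ["pos1"], how="left")[["maf1"]]
    m2 = estimates.merge(
        freqs.rename(columns={"pos": "pos2", "maf": "maf2"}),
        on=key + ["pos2"], how="left")[["maf2"]]
    df = estimates.copy()
    df["maf1"] = m1["maf1"].to_numpy()
    df["maf2"] = m2["maf2"].to_numpy()

    n0 = len(df)
    missing = df["maf1"].isna() | df["maf2"].isna()
    if missing.any():
        log.info("filter_pairs: %d pairs dropped (locus missing from "
                 "allele-count table)", int(missing.sum()))
    df = df[~missing]
    depth_ok = df["n"] > filters.min_pair_depth
    if filters.maf_mode == "both":
        maf_ok = (df["maf1"] > filters.min_maf) & (df["maf2"] > filters.min_maf)
    else:
        maf_ok = (df["maf1"] > filters.min_maf) | (df["maf2"] > filters.min_maf)
    dist_ok = (df["distance"] >= filters.min_distance) & (
        df["distance"] <= filters.max_distance)
    defined = df["r2"].notna()
    kept = df[depth_ok & maf_ok & dist_ok & defined].copy()
    log.info("filter_pairs: kept %d of %d pairs (depth %d, maf %d, "
             "distance %d, undefined %d failed)", len(kept), n0,
             int((~depth_ok).sum()), int((~maf_ok).sum()),
             int((~dist_ok).sum()), int((~defined).sum()))
    return kept.drop(columns=["maf1", "maf2"])


def build_region_table(genes: pd.DataFrame,
                       scaffold_lengths: dict[str, int] | None = None,
                       ) -> pd.DataFrame:
    """Genic and intergenic intervals from a gene table.

    ``genes`` needs columns scaffold, start, end (0-based half-open),
    gene_id.  Intergenic regions span the gaps between adjacent genes and,
    when scaffold lengths are given, the flanks.  Raises on overlapping
    gene models.
    """
    rows = []
    for scaffold, grp in genes.groupby("scaffold"):
        grp = grp.sort_values("start")
        overl = grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]
        if overl.any():
            bad = grp.iloc[1:][overl]["gene_id"].tolist()
            raise ValueError(f"overlapping gene models on {scaffold}: {bad}")
        prev_end = 0 if scaffold_lengths else None
        prev_gene = "start"
        for _, g in grp.iterrows():
            if prev_end is not None and g["start"] > prev_end:
                rows.append((scaffold, prev_end, g["start"],
                             f"{prev_gene}|{g['gene_id']}", "intergenic"))
            rows.append((scaffold, g["start"], g["end"], g["gene_id"], "genic"))
            prev_end = g["end"]
            prev_gene = g["gene_id"]
        if scaffold_lengths and prev_end < scaffold_lengths.get(scaffold, 0):
            rows.append((scaffold, prev_end, scaffold_lengths[scaffold],
                         f"{prev_gene}|end", "intergenic"))
    return pd.DataFrame(
        rows, columns=["scaffold", "start", "end", "region_id", "region_type"])


def assign_regions(estimates: pd.DataFrame,
                   regions: pd.DataFrame) -> pd.DataFrame:
    """Assign each SNP pair to the region containing *both* loci.

    Regions are 0-based half-open intervals; SNP positions are 1-based.
    Pairs whose loci fall in different regions (or outside any region) are
    dropped and counted.
    """
    out = estimates.reset_index(drop=True).copy()
    out["region_id"] = pd.NA
    out["region_type"] = pd.NA
    for scaffold, reg in regions.groupby("scaffold"):
        reg = reg.sort_values("start")
        starts = reg["start"].to_numpy()
        ends = reg["end"].to_numpy()
        sel = out["scaffold"] == scaffold
        if not sel.any():
            continue
        p1 = out.loc[sel, "pos1"].to_numpy() - 1  # to 0-based
        p2 = out.loc[sel, "pos2"].to_numpy() - 1
        i1 = np.searchsorted(starts, p1, side="right") - 1
        i2 = np.searchsorted(starts, p2, side="right") - 1
        ok1 = (i1 >= 0) & (p1 < ends[np.clip(i1, 0, None)])
        ok2 = (i2 >= 0) & (p2 < ends[np.clip(i2, 0, None)])
        same = ok1 & ok2 & (i1 == i2)
        idx = out.index[sel]
        out.loc[idx[same], "region_id"] = reg["region_id"].to_numpy()[i1[same]]
        out.loc[idx[same], "region_type"] = (
            reg["region_type"].to_numpy()[i1[same]])
    dropped = out["region_id"].isna()
    if dropped.any():
        log.info("assign_regions: %d cross-boundary/unassigned pairs dropped",
                 int(dropped.sum()))
    return out[~dropped].copy()


def fit_distance_correction(estimates: pd.DataFrame,
                            scope: str | None = None,
                            ) -> tuple[float, float, pd.DataFrame]:
    """OLS of r-squared on log10 distance; returns (intercept, slope, table).

    The fit pools all populations within ``scope`` (a region_type, or all
    estimates when None); the returned table carries the residuals as
    ``corrected_r2``.  Raises if fewer than two distinct distances.
    """
    df = estimates if scope is None else (
        estimates[estimates["region_type"] == scope].copy())
    if df["distance"].nunique() < 2:
        raise ValueError("distance correction needs >= 2 distinct distances")
    x = np.log10(df["distance"].to_numpy(dtype=float))
    y = df["r2"].to_numpy(dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    df = df.copy()
    df["corrected_r2"] = y - (intercept + slope * x)
    return float(intercept), float(slope), df


def aggregate_regions(estimates: pd.DataFrame,
                      populations: list[str] | None = None,
                      filters: FilterConfig | None = None) -> pd.DataFrame:
    """Per-(region, population) mean r2 and mean corrected r2.

    A region/population cell needs at least ``min_estimates_per_region``
    estimates, else it is missing for that population; regions missing in
    >= ``max_missing_fraction`` of populations are removed entirely.
    """
    if filters is None:
        filters = FilterConfig()
    if populations is None:
        populations = sorted(estimates["pop"].unique())
    value_cols = {"r2": "mean_r2"}
    if "corrected_r2" in estimates.columns:
        value_cols["corrected_r2"] = "mean_corrected_r2"
    agg = (estimates
           .groupby(["region_id", "region_type", "pop"], observed=True)
           .agg(n_estimates=("r2", "size"), **{
               out: (col, "mean") for col, out in value_cols.items()})
           .reset_index())
    agg = agg[agg["n_estimates"] >= filters.min_estimates_per_region]
    n_pop = len(populations)
    present = agg.groupby("region_id")["pop"].nunique()
    missing_frac = 1.0 - present / n_pop
    keep_regions = missing_frac[missing_frac < filters.max_missing_fraction]
    return agg[agg["region_id"].isin(keep_regions.index)].reset_index(drop=True)


def categorize_pairs(estimates: pd.DataFrame,
                     sift_labels: pd.DataFrame) -> pd.DataFrame:
    """Class SNP pairs as DD / DT / TT from per-SNP deleterious labels.

    ``sift_labels`` maps (scaffold, pos) to DELETERIOUS or TOLERATED; pairs
    with any unlabeled locus become "unannotated".  DT is symmetric in
    locus order.
    """
    lab = sift_labels.set_index(["scaffold", "pos"])["label"]
    key1 = pd.MultiIndex.from_frame(estimates[["scaffold", "pos1"]])
    key2 = pd.MultiIndex.from_frame(estimates[["scaffold", "pos2"]])
    l1 = key1.map(lab).to_numpy()
    l2 = key2.map(lab).to_numpy()
    cat = np.full(len(estimates), "unannotated", dtype=object)
    both = pd.notna(l1) & pd.notna(l2)
    n_del = ((l1 == "DELETERIOUS").astype(int)
             + (l2 == "DELETERIOUS").astype(int))
    cat[both & (n_del == 2)] = "DD"
    cat[both & (n_del == 1)] = "DT"
    cat[both & (n_del == 0)] = "TT"
    out = estimates.copy()
    out["pair_category"] = cat
    return out
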