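"""Population-genetic summaries: Watterson's theta, mutational load, and
gene-density covariates.

Watterson's theta is S / (a_n * L) with a_n the harmonic number of
(n_chrom - 1); for pooled data n_chrom defaults to twice the pool size.
Mutational load is Pn*fn / (Ps*fs): the count of polymorphic nonsynonymous
(deleterious-class) sites times their mean derived-allele frequency, over
the same product for synonymous-class sites.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


def harmonic(n: int) -> float:
    """a_n = sum_{i=1}^{n} 1/i."""
    return float(np.sum(1.0 / np.arange(1, n + 1)))


def watterson_theta(counts: pd.DataFrame, regions: pd.DataFrame,
                    n_chrom: int = 50,
                    min_maf: float = 0.0) -> pd.DataFrame:
    """Per-(region, population) Watterson estimate from allele counts.

    A site is segregating for a population if both alleles are observed
    (and its MAF exceeds ``min_maf`` when given).  The callable length is
    the annotated region length.  Returns columns region_id, region_type,
    pop, S, L_callable, theta_w.
    """
    if n_chrom < 2:
        raise ValueError("n_chrom must be >= 2")
    a_n = harmonic(n_chrom - 1)
    df = counts.copy()
    tot = df["ref_count"] + df["alt_count"]
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(tot > 0, df["alt_count"] / tot, np.nan)
    maf = np.minimum(af, 1 - af)
    df["segregating"] = (df["ref_count"] > 0) & (df["alt_count"] > 0) & (
        maf > min_maf)

    rows = []
    for _, reg in regions.iterrows():
        length = reg["end"] - reg["start"]
        in_reg = (df["scaffold"] == reg["scaffold"]) & \
                 (df["pos"] - 1 >= reg["start"]) & (df["pos"] - 1 < reg["end"])
        sub = df[in_reg]
        for pop, grp in sub.groupby("pop"):
            S = int(grp["segregating"].sum())
            theta = np.nan if length == 0 else S / (a_n * length)
            rows.append((reg["region_id"], reg["region_type"], pop, S,
                         length, theta))
        if sub.empty:
            continue
    out = pd.DataFrame(rows, columns=[
        "region_id", "region_type", "pop", "S", "L_callable", "theta_w"])
    return out


def mutational_load(counts: pd.DataFrame, site_classes: pd.DataFrame,
                    nonsyn_classes: tuple[str, ...] = ("deleterious",),
                    syn_classes: tuple[str, ...] = ("synonymous",),
                    min_maf: float = 0.03) -> pd.DataFrame:
    """Pn*fn / (Ps*fs) per population.

    ``site_classes`` maps (scaffold, pos) to a functional class; the
    derived allele is the alternate (the simulator's ancestral state is the
    reference).  A site counts as polymorphic when both alleles are
    observed and its minor allele frequency exceeds ``min_maf`` (default
    0.03, the usual pooled SNP-calling floor).  Returns one row per
    population with Pn, fn, Ps, fs and the load ratio (NaN with a reason
    when Ps*fs = 0).
    """
    cls = site_classes.set_index(["scaffold", "pos"])["functional_class"]
    df = counts.copy()
    key = pd.MultiIndex.from_frame(df[["scaffold", "pos"]])
    df["functional_class"] = key.map(cls).to_numpy()
    tot = df["ref_count"] + df["alt_count"]
    with np.errstate(invalid="ignore", divide="ignore"):
        df["derived_freq"] = np.where(tot > 0, df["alt_count"] / tot, np.nan)
    maf = np.minimum(df["derived_freq"], 1.0 - df["derived_freq"])
    df["polymorphic"] = (df["ref_count"] > 0) & (df["alt_count"] > 0) & (
        maf > min_maf)

    rows = []
    for pop, grp in df.groupby("pop"):
        poly = grp[grp["polymorphic"]]
        non = poly[poly["functional_class"].isin(nonsyn_classes)]
        syn = poly[poly["functional_class"].isin(syn_classes)]
        P_n, P_s = len(non), len(syn)
        f_n = float(non["derived_freq"].mean()) if P_n else np.nan
        f_s = float(syn["derived_freq"].mean()) if P_s else np.nan
        denom = P_s * f_s if P_s else 0.0
        if not denom:
            load, reason = np.nan, "no synonymous polymorphism"
        else:
            load, reason = (P_n * f_n) / denom, None
        rows.append((pop, P_n, f_n, P_s, f_s, load, reason))
    return pd.DataFrame(rows, columns=[
        "pop", "P_n", "f_n", "P_s", "f_s", "load", "reason"])


def gene_density(regions: pd.DataFrame) -> pd.DataFrame:
    """Gene-density covariate per region.

    Genic regions get the mean gap to the up- and downstream neighbouring
    genes (terminal genes use their single gap; a lone gene on a scaffold
    is undefined and logged); intergenic regions get their own length.
    Gaps are measured between adjacent gene interval boundaries.
    """
    rows = []
    for scaffold, reg in regions.groupby("scaffold"):
        genes = reg[reg["region_type"] == "genic"].sort_values("start")
        starts = genes["start"].to_numpy()
        ends = genes["end"].to_numpy()
        for i, (_, g) in enumerate(genes.iterrows()):
            gaps = []
            if i > 0:
                gaps.append(starts[i] - ends[i - 1])
            if i < len(genes) - 1:
                gaps.append(starts[i + 1] - ends[i])
            if not gaps:
                log.info("gene_density: lone gene %s on %s has no neighbour",
                         g["region_id"], scaffold)
                value = np.nan
            else:
                value = float(np.mean(gaps))
            rows.append((g["region_id"], "genic", value))
        for _, r in reg[reg["region_type"] == "intergenic"].iterrows():
            rows.append((r["region_id"], "intergenic",
                         float(r["end"] - r["start"])))
    out = pd.DataFrame(rows, columns=["region_id", "region_type", "value"])
    with np.errstate(invalid="ignore", divide="ignore"):
        out["log10_value"] = np.where(out["value"] > 0,
                                      np.log10(out["value"]), np.nan)
    return out
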