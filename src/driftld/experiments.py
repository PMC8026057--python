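"""Replication experiments on simulated range expansions.

These are the study-scale analyses the package exists for, bundled as
reusable functions: the drift gradient of pooled LD and diversity along the
expansion axis, the coupling of LD with mutational load, the concordance of
pooled r-squared with the individual-genome correlation of zygosity, the
paired selfing-versus-outcrossing contrast, and calibration experiments for
the mixed-model layer (type-I error, sign recovery, outlier-scan FDR and
power).  Problem sizes are scaled to a desk-top budget; the defaults are
the package's standard study conditions.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from . import poolseq, zygosity
from .config import FilterConfig, SimConfig
from .inference import fit_lmm, outlier_scan
from .popstats import mutational_load, watterson_theta
from .poolseq import build_region_table
from .simcore import SCAFFOLD, emit_individuals, emit_poolseq, simulate_expansion

log = logging.getLogger(__name__)

# the emulator's Poisson coverage is uniform; see docs/methods.md
DEPTH_WINDOW = (0.5, 2.0)


def standard_config(seed: int, **overrides) -> SimConfig:
    """The standard selected expansion: 10 demes, K=4, purifying selection
    on deleterious genic mutations."""
    kw = dict(selection_coefficient=0.05, seed=seed)
    kw.update(overrides)
    return SimConfig(**kw)


def gene_table(config: SimConfig) -> pd.DataFrame:
    return pd.DataFrame(
        [(SCAFFOLD, s, e, f"gene_{i}")
         for i, (s, e) in enumerate(config.gene_intervals())],
        columns=["scaffold", "start", "end", "gene_id"])


def _deme_scaled_delta(pop, deme, config, n_individuals=8,
                       max_d=500) -> float:
    """Mean scaled zygosity correlation over d <= max_d, averaged over
    individuals with defined profiles."""
    gt = emit_individuals(pop, deme, n_individuals, config)
    steps = np.arange(1, max_d + 1)
    vals = []
    for ind, grp in gt.groupby("individual"):
        mask = zygosity.callable_mask(
            grp, float(grp["DP"].mean()), config.genome_length,
            depth_window=DEPTH_WINDOW)
        prof = zygosity.zygosity_curve(grp, mask, steps, individual=ind)
        if prof.defined and len(prof.curve):
            vals.append(float(prof.curve["scaled"].mean()))
    return float(np.mean(vals)) if vals else np.nan


def expansion_batch(n_seeds: int = 20, base_seed: int = 0,
                    n_individuals: int = 8) -> pd.DataFrame:
    """Per-seed summaries of the standard expansion.

    Columns: seed, rho_r2 (Spearman of mean pooled r2 vs deme index),
    rho_theta, rho_load (load vs deme index), r_load_ld (Pearson of mean
    corrected r2 vs load across demes), r_concordance (Pearson of mean
    pooled r2 vs mean scaled Delta), plus the per-deme point clouds for
    pooled correlations.
    """
    rows = []
    points = []
    for i in range(n_seeds):
        cfg = standard_config(base_seed + i)
        pop = simulate_expansion(cfg)
        regions = build_region_table(gene_table(cfg),
                                     {SCAFFOLD: cfg.genome_length})
        site_classes = pop.site_table.rename(
            columns={"position": "pos"}).copy()
        site_classes["pos"] += 1
        counts_frames, pair_frames, dz = [], [], []
        for d in range(cfg.n_demes):
            ac, pc = emit_poolseq(pop, d, cfg)
            counts_frames.append(ac)
            pair_frames.append(pc)
            dz.append(_deme_scaled_delta(pop, d, cfg, n_individuals))
        counts = pd.concat(counts_frames, ignore_index=True)
        est = poolseq.r2_direct_table(
            pd.concat(pair_frames, ignore_index=True))
        est = poolseq.filter_pairs(est, counts, FilterConfig())
        _, _, est = poolseq.fit_distance_correction(est)
        idx = [f"pop{d}" for d in range(cfg.n_demes)]
        mr = est.groupby("pop")["r2"].mean().reindex(idx)
        mc = est.groupby("pop")["corrected_r2"].mean().reindex(idx)
        th = watterson_theta(counts, regions, n_chrom=2 * cfg.pool_size)
        th = th.groupby("pop")["theta_w"].mean().reindex(idx)
        load = mutational_load(counts, site_classes)
        load = load.set_index("pop")["load"].reindex(idx)
        deme_idx = np.arange(cfg.n_demes)
        rows.append({
            "seed": cfg.seed,
            "rho_r2": spearmanr(deme_idx, mr).statistic,
            "rho_theta": spearmanr(deme_idx, th).statistic,
            "rho_load": spearmanr(deme_idx, load).statistic,
            "r_load_ld": pearsonr(mc, load).statistic,
            "r_concordance": pearsonr(mr, dz).statistic,
        })
        points.append(pd.DataFrame({
            "seed": cfg.seed, "deme": deme_idx, "mean_r2": mr.to_numpy(),
            "mean_corrected_r2": mc.to_numpy(), "theta": th.to_numpy(),
            "load": load.to_numpy(), "scaled_delta": dz}))
    out = pd.DataFrame(rows)
    out.attrs["points"] = pd.concat(points, ignore_index=True)
    return out


def pooled_concordance(batch: pd.DataFrame) -> float:
    """Pearson correlation of mean pooled r2 with mean scaled Delta over
    every simulated deme of the batch."""
    pts = batch.attrs["points"].dropna(subset=["mean_r2", "scaled_delta"])
    return float(pearsonr(pts["mean_r2"], pts["scaled_delta"]).statistic)


# ---------------------------------------------------------------------------
# selfing contrast

def selfing_config(seed: int, selfing: float) -> SimConfig:
    """Two-deme expansion whose daughter deme shifts (or not) to selfing at
    its founding; higher mutation supplies the heterozygosity the zygosity
    curve needs at toy genome size."""
    return SimConfig(
        seed=seed, n_demes=2, generations_between_foundings=15,
        burn_in_generations=250, per_bp_mutation=8e-5,
        selfing_rate_per_deme=[0.0, selfing])


def _deme_decay_length(pop, deme, config, n_individuals=32,
                       max_d=12_000) -> float:
    """Decay length of the deme-pooled scaled zygosity curve.

    Site and pair counts are pooled across sampled genomes
    (:func:`zygosity.pooled_zygosity_curve`), so the between-genome
    inbreeding variance of a selfing deme contributes to the curve.  +inf
    when the pooled curve never falls to the threshold inside the window;
    NaN when the deme carries too little heterozygosity to measure.
    """
    gt = emit_individuals(pop, deme, n_individuals, config)
    steps = zygosity.default_steps(max_d)
    per_ind = []
    for ind, grp in gt.groupby("individual"):
        mask = zygosity.callable_mask(
            grp, float(grp["DP"].mean()), config.genome_length,
            depth_window=DEPTH_WINDOW)
        per_ind.append((grp, mask))
    prof = zygosity.pooled_zygosity_curve(
        per_ind, steps, bin_width=101, population=f"pop{deme}",
        min_het_sites=60)
    if not prof.defined:
        return np.nan
    d = zygosity.decay_length(prof, require_initial_above=True)
    if np.isnan(d):
        smoothed = prof.curve["scaled"].rolling(
            11, center=True, min_periods=1).median()
        return np.inf if (smoothed > 0.1).any() else np.nan
    return float(d)


def selfing_contrast(n_seeds: int = 20, base_seed: int = 0) -> pd.DataFrame:
    """Paired selfing (s=0.95) vs outcrossing daughter demes, same seeds."""
    rows = []
    for i in range(n_seeds):
        rec = {"seed": base_seed + i}
        for label, s in (("out", 0.0), ("self", 0.95)):
            cfg = selfing_config(base_seed + i, s)
            pop = simulate_expansion(cfg)
            ac, pc = emit_poolseq(pop, 1, cfg)
            est = poolseq.r2_direct_table(pc)
            est = poolseq.filter_pairs(est, ac, FilterConfig())
            rec[f"r2_{label}"] = float(est["r2"].mean()) if len(est) else np.nan
            rec[f"decay_{label}"] = _deme_decay_length(pop, 1, cfg)
        rows.append(rec)
    out = pd.DataFrame(rows)
    out["r2_win"] = out["r2_self"] > out["r2_out"]
    out["decay_win"] = out["decay_self"] > out["decay_out"]
    return out


# ---------------------------------------------------------------------------
# mixed-model calibration

def _synthetic_meta(n_pops: int, rng: np.random.Generator) -> pd.DataFrame:
    return pd.DataFrame({
        "pop": [f"p{i}" for i in range(n_pops)],
        "cluster": ["east" if i % 2 else "west" for i in range(n_pops)],
        "log10_expansion_distance": np.log10(rng.uniform(10, 2000, n_pops)),
        "F_IS": rng.uniform(0, 0.9, n_pops),
    })


def lmm_type_one_error(n_replicates: int = 500, seed: int = 0,
                       n_pops: int = 40, n_regions: int = 10,
                       alpha: float = 0.05) -> dict:
    """Share of null replicates where each fixed effect is called
    significant; the response is pure noise."""
    rng = np.random.default_rng(seed)
    fixed = ["cluster", "log10_expansion_distance", "F_IS"]
    hits = {t: 0 for t in fixed}
    n_done = 0
    for _ in range(n_replicates):
        meta = _synthetic_meta(n_pops, rng)
        data = meta.loc[meta.index.repeat(n_regions)].reset_index(drop=True)
        data["y"] = rng.normal(0, 1, len(data))
        res = fit_lmm(data, "y", fixed, group="pop")
        if not res.converged:
            continue
        n_done += 1
        for t in fixed:
            hits[t] += res.table.loc[t, "p"] < alpha
    rates = {t: hits[t] / n_done for t in fixed}
    rates["overall"] = float(np.mean(list(rates.values())))
    rates["n_replicates"] = n_done
    return rates


def lmm_sign_recovery(n_replicates: int = 60, seed: int = 0,
                      beta_dist: float = 0.04, beta_fis: float = 0.03,
                      n_pops: int = 40, n_regions: int = 10,
                      sd_pop: float = 0.01, sd_resid: float = 0.05) -> dict:
    """Fraction of replicates recovering the signs of injected expansion
    and mating-system effects."""
    rng = np.random.default_rng(seed)
    ok_dist = ok_fis = n_done = 0
    for _ in range(n_replicates):
        meta = _synthetic_meta(n_pops, rng)
        pop_eff = rng.normal(0, sd_pop, n_pops)
        data = meta.loc[meta.index.repeat(n_regions)].reset_index(drop=True)
        data["y"] = (beta_dist * data["log10_expansion_distance"]
                     + beta_fis * data["F_IS"]
                     + np.repeat(pop_eff, n_regions)
                     + rng.normal(0, sd_resid, len(data)))
        res = fit_lmm(data, "y",
                      ["cluster", "log10_expansion_distance", "F_IS"],
                      group="pop")
        if not res.converged:
            continue
        n_done += 1
        ok_dist += res.table.loc["log10_expansion_distance", "beta"] > 0
        ok_fis += res.table.loc["F_IS", "beta"] > 0
    return {"sign_accuracy_expansion": ok_dist / n_done,
            "sign_accuracy_fis": ok_fis / n_done,
            "n_replicates": n_done}


# ---------------------------------------------------------------------------
# outlier-scan calibration

def _gene_scan_data(rng, n_pops=52, n_genes=100, per_pop=3,
                    beta=0.0, outlier_frac=0.0, sd=0.02):
    meta = _synthetic_meta(n_pops, rng)
    n_out = int(round(outlier_frac * n_genes))
    outliers = {f"g{i}" for i in range(n_out)}
    rows = []
    for g in range(n_genes):
        slope = beta * (2.0 if f"g{g}" in outliers else 1.0)
        y = (slope * np.tile(
            meta["log10_expansion_distance"].to_numpy(), per_pop)
            + rng.normal(0, sd, n_pops * per_pop))
        rows.append(pd.DataFrame({
            "region_id": f"g{g}",
            "pop": np.tile(meta["pop"].to_numpy(), per_pop),
            "corrected_r2": y}))
    return pd.concat(rows, ignore_index=True), meta, outliers


def outlier_scan_calibration(n_seeds: int = 20, seed: int = 0,
                             n_genes: int = 100, n_pops: int = 52) -> dict:
    """Null false-discovery proportion and power of the gene scan.

    Null: no gene responds to any predictor; FDP = flagged / tested.
    Power: a genome-wide expansion effect with 5% of genes at double
    slope; power = share of doubled genes flagged.
    """
    rng = np.random.default_rng(seed)
    term = "log10_expansion_distance"
    fdps, powers = [], []
    for _ in range(n_seeds):
        data, meta, _ = _gene_scan_data(rng, n_pops=n_pops,
                                        n_genes=n_genes, beta=0.0)
        gw = fit_lmm(data.merge(meta, on="pop"), "corrected_r2",
                     ["cluster", term, "F_IS"], group="pop")
        scan = outlier_scan(data, meta, gw, min_populations=10)
        flagged = int(scan[f"outlier_{term}"].sum()) if len(scan) else 0
        fdps.append(flagged / max(len(scan), 1))

        data, meta, outliers = _gene_scan_data(
            rng, n_pops=n_pops, n_genes=n_genes, beta=0.04,
            outlier_frac=0.05)
        gw = fit_lmm(data.merge(meta, on="pop"), "corrected_r2",
                     ["cluster", term, "F_IS"], group="pop")
        scan = outlier_scan(data, meta, gw, min_populations=10)
        hit = scan.loc[scan["gene"].isin(outliers), f"outlier_{term}"]
        powers.append(float(hit.mean()) if len(hit) else 0.0)
    return {"mean_null_fdp": float(np.mean(fdps)),
            "mean_power": float(np.mean(powers)),
            "n_seeds": n_seeds}
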