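"""End-to-end driver: simulate, estimate, model, report.

Stages: simulate -> pooled LD -> zygosity -> population statistics -> HMM
segmentation -> expansion distances -> genome-wide mixed models -> outlier
scan.  Every stage writes its tables under the output directory and the
run ends with a manifest (config, seed, per-file digests, filter counts)
whose bytes are reproducible for identical configurations.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, geo, hmm, inference, poolseq, popstats, simcore, zygosity
from .config import PipelineConfig, SimConfig
from .simcore import SCAFFOLD

log = logging.getLogger(__name__)


def demo_config(seed: int = 0) -> PipelineConfig:
    """Study-shaped demo: a 10-deme expansion in which some demes shifted
    to mixed mating or selfing, with purifying selection on deleterious
    genic mutations."""
    sim = SimConfig(
        selfing_rate_per_deme=[0.0, 0.0, 0.5, 0.0, 0.95,
                               0.0, 0.0, 0.5, 0.0, 0.95],
        selection_coefficient=0.05,
        seed=seed,
    )
    return PipelineConfig(sim=sim, seed=seed, outlier_min_populations=8)


def fis_from_selfing(s: float) -> float:
    """Inbreeding equilibrium F_IS = s / (2 - s) of a partial selfer."""
    return s / (2.0 - s)


def simulate_stage(config: PipelineConfig, outdir: Path) -> dict:
    """Run the simulator and write all seven input surrogates."""
    sim = config.sim
    pop = simcore.simulate_expansion(sim)
    data = outdir / "data"
    data.mkdir(parents=True, exist_ok=True)

    counts_frames, pair_frames, geno_frames = [], [], []
    for d in range(pop.n_demes):
        ac, pc = simcore.emit_poolseq(pop, d, sim)
        counts_frames.append(ac)
        pair_frames.append(pc)
        geno_frames.append(simcore.emit_individuals(
            pop, d, config.n_individuals_per_pop, sim))
    counts = pd.concat(counts_frames, ignore_index=True)
    pairs = pd.concat(pair_frames, ignore_index=True)
    genotypes = pd.concat(geno_frames, ignore_index=True)
    io.write_tsv(counts, data / "allele_counts.tsv")
    io.write_tsv(pairs, data / "pair_counts.tsv")
    io.write_tsv(genotypes, data / "genotypes.tsv")

    genes = pd.DataFrame(
        [(SCAFFOLD, s, e, f"gene_{i}") for i, (s, e) in
         enumerate(sim.gene_intervals())],
        columns=["scaffold", "start", "end", "gene_id"])
    io.write_gff3(genes, data / "genes.gff3")

    site_classes = pop.site_table.rename(columns={"position": "pos"}).copy()
    site_classes["pos"] = site_classes["pos"] + 1
    io.write_tsv(site_classes[["scaffold", "pos", "functional_class"]],
                 data / "site_classes.tsv")
    sift = site_classes[site_classes["functional_class"].isin(
        ["deleterious", "synonymous"])].copy()
    sift["label"] = np.where(sift["functional_class"] == "deleterious",
                             "DELETERIOUS", "TOLERATED")
    io.write_tsv(sift[["scaffold", "pos", "label"]],
                 data / "sift_labels.tsv")

    # map geography: demes along the equator, one step per deme
    km_per_deg = geo.EARTH_RADIUS_KM * np.pi / 180.0
    pops = [f"pop{d}" for d in range(pop.n_demes)]
    coords = [(0.0, d * sim.deme_step_km / km_per_deg)
              for d in range(pop.n_demes)]
    newick, coord_tab = geo.build_chain_tree(pops, coords)
    (data / "tree.nwk").write_text(newick + "\n")
    io.write_tsv(coord_tab, data / "node_coords.tsv")

    selfing = sim.selfing_rates()
    meta = pd.DataFrame({
        "pop": pops,
        "cluster": ["east" if d % 2 else "west" for d in range(pop.n_demes)],
        "lat": [c[0] for c in coords],
        "lon": [c[1] for c in coords],
        "F_IS": [fis_from_selfing(s) for s in selfing],
        "is_old": False,
    })
    meta["mating_class"] = pd.cut(
        meta["F_IS"], [-np.inf, 0.1, 0.5, np.inf],
        labels=["outcrossing", "mixed", "selfing"]).astype(str)
    io.write_tsv(meta, data / "population_meta.tsv")
    return {"n_sites": len(pop.positions), "n_pairs": len(pairs)}


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage; returns the manifest dictionary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_info: dict[str, dict] = {}
    try:
        stage_info["simulate"] = simulate_stage(config, outdir)
        data = outdir / "data"

        # --- pooled LD ---------------------------------------------------
        counts = io.read_tsv(data / "allele_counts.tsv")
        pairs = io.read_tsv(data / "pair_counts.tsv")
        genes = io.read_gff3(data / "genes.gff3")
        regions = poolseq.build_region_table(
            genes, {SCAFFOLD: config.sim.genome_length})
        est = poolseq.r2_direct_table(pairs)
        est = poolseq.filter_pairs(est, counts, config.filters)
        est = poolseq.assign_regions(est, regions)
        corrected = []
        for scope in ("genic", "intergenic"):
            if (est["region_type"] == scope).any():
                _, _, sub = poolseq.fit_distance_correction(est, scope)
                corrected.append(sub)
        est = pd.concat(corrected, ignore_index=True)
        sift_path = data / "sift_labels.tsv"
        if sift_path.exists():
            est = poolseq.categorize_pairs(est, io.read_tsv(sift_path))
        else:
            log.info("no deleterious/tolerated labels: SNP-type model skipped")
        region_ld = poolseq.aggregate_regions(est, filters=config.filters)
        io.write_tsv(est, outdir / "ld_estimates.tsv")
        io.write_tsv(region_ld, outdir / "region_ld.tsv")
        stage_info["poolseq"] = {
            "n_estimates": len(est), "n_region_cells": len(region_ld)}

        # --- zygosity ----------------------------------------------------
        genotypes = io.read_tsv(data / "genotypes.tsv")
        scopes = {
            "genic": config.sim.gene_intervals(),
            "intergenic": config.sim.intergenic_intervals(),
        }
        steps = zygosity.default_steps(config.zygosity_max_distance)
        profiles = []
        for ind, grp in genotypes.groupby("individual"):
            pop_id = ind.split("_")[0]
            mean_dp = float(grp["DP"].mean())
            for scope, intervals in scopes.items():
                # the 2x-5x default window targets the skewed coverage of
                # real resequencing; the emulator's Poisson coverage is
                # uniform, so the equivalent guard is (0.5-2)x the mean
                mask = zygosity.callable_mask(
                    grp, mean_dp, config.sim.genome_length, intervals,
                    depth_window=(0.5, 2.0))
                profiles.append(zygosity.zygosity_curve(
                    grp, mask, steps, intervals, individual=ind,
                    population=pop_id, scope=scope))
        zsum = zygosity.profile_summary(profiles)
        io.write_tsv(zsum, outdir / "zygosity_summary.tsv")
        curves = pd.concat(
            [p.to_frame().assign(pop=p.population)
             for p in profiles if p.defined],
            ignore_index=True)
        io.write_tsv(curves, outdir / "zygosity_curves.tsv")
        stage_info["zygosity"] = {
            "n_profiles": len(profiles),
            "n_defined": int(zsum["defined"].sum())}

        # --- population statistics ---------------------------------------
        theta = popstats.watterson_theta(
            counts, regions, n_chrom=2 * config.sim.pool_size)
        site_classes = io.read_tsv(data / "site_classes.tsv")
        load = popstats.mutational_load(counts, site_classes)
        density = popstats.gene_density(regions)
        io.write_tsv(theta, outdir / "theta.tsv")
        io.write_tsv(load, outdir / "load.tsv")
        io.write_tsv(density, outdir / "gene_density.tsv")
        stage_info["popstats"] = {"n_theta": len(theta)}

        # --- HMM segmentation ---------------------------------------------
        runs_rows = []
        models = {}
        reg_sorted = regions.sort_values(["scaffold", "start"])
        for pop_id, grp in region_ld.groupby("pop"):
            for rtype in ("genic", "intergenic"):
                ordered = reg_sorted[reg_sorted["region_type"] == rtype]
                seq = (grp[grp["region_type"] == rtype]
                       .set_index("region_id")["mean_r2"]
                       .reindex(ordered["region_id"]).dropna())
                if len(seq) < 4:
                    continue
                model = hmm.fit_baum_welch(seq.to_numpy(), seed=config.seed)
                path = hmm.viterbi(model, seq.to_numpy())
                runs = hmm.extended_high_regions(
                    path, list(seq.index), min_run=config.hmm_min_run)
                runs["pop"] = pop_id
                runs["region_type"] = rtype
                runs_rows.append(runs)
                models[f"{pop_id}:{rtype}"] = model.to_dict()
        runs_table = (pd.concat(runs_rows, ignore_index=True) if runs_rows
                      else pd.DataFrame())
        io.write_tsv(runs_table, outdir / "hmm_runs.tsv")
        with open(outdir / "hmm_models.json", "w") as fh:
            json.dump(models, fh, indent=2, sort_keys=True)
        stage_info["segmentation"] = {"n_extended_runs": len(runs_table)}

        # --- expansion distances -------------------------------------------
        meta = io.read_tsv(data / "population_meta.tsv")
        tree = geo.GeoTree.from_files(
            data / "tree.nwk", data / "node_coords.tsv",
            core={c: "node_0" for c in meta["cluster"].unique()})
        meta = geo.expansion_distance(tree, meta)
        meta["log10_expansion_distance"] = np.log10(
            meta["expansion_distance"].clip(lower=1.0))
        if config.exclude_old_populations:
            meta = meta[~meta["is_old"]]
        io.write_tsv(meta, outdir / "population_meta_distances.tsv")

        # --- genome-wide models --------------------------------------------
        dens = density.rename(columns={"log10_value": "log10_gene_density"})
        model_tables = []
        gw_models: dict[str, inference.ModelResult] = {}
        for rtype in ("genic", "intergenic"):
            df = (est[est["region_type"] == rtype]
                  .merge(meta, on="pop")
                  .merge(dens[["region_id", "log10_gene_density"]],
                         on="region_id"))
            if df.empty:
                continue
            res = inference.fit_lmm(
                df, "corrected_r2",
                ["cluster", "log10_expansion_distance", "F_IS",
                 "log10_gene_density"],
                group="pop", vc={"region": "0 + C(region_id)"},
                model_id=f"genomewide_{rtype}")
            gw_models[rtype] = res
            tab = res.table.reset_index()
            tab.insert(0, "model", f"genomewide_{rtype}")
            tab["random_structure"] = res.random_structure
            model_tables.append(tab)
            if res.converged:
                # re-anchor residual-scale predictions at the mean r2 so
                # the percentages refer to LD at the reference distance
                anchor = float(df["r2"].mean())
                stage_info.setdefault("marginal_increase_pct", {})[rtype] = {
                    "expansion": inference.marginal_increase(
                        res, df, "log10_expansion_distance", offset=anchor),
                    "mating": inference.marginal_increase(
                        res, df, "F_IS", offset=anchor),
                }
        if "pair_category" in est.columns:
            df = (est[(est["region_type"] == "genic")
                      & est["pair_category"].isin(["DD", "DT", "TT"])]
                  .merge(meta, on="pop")
                  .merge(dens[["region_id", "log10_gene_density"]],
                         on="region_id"))
            cats = set(df["pair_category"].unique())
            if cats == {"DD", "DT", "TT"}:
                res = inference.fit_sift_model(df)
                tab = res.table.reset_index()
                tab.insert(0, "model", "sift_interaction")
                tab["random_structure"] = res.random_structure
                model_tables.append(tab)
            else:
                log.info("SNP-type model skipped: categories %s present",
                         sorted(cats))
        coef = pd.concat(model_tables, ignore_index=True)
        io.write_tsv(coef, outdir / "model_coefficients.tsv")
        stage_info["fit"] = {"n_models": len(model_tables)}

        # --- population-level statistics -----------------------------------
        pop_sum = meta[["pop", "F_IS", "expansion_distance"]].copy()
        for rtype in ("genic", "intergenic"):
            sub = est[est["region_type"] == rtype]
            pop_sum = pop_sum.merge(
                sub.groupby("pop")["corrected_r2"].mean().rename(
                    f"mean_corrected_r2_{rtype}"), on="pop", how="left")
            ths = theta[theta["region_type"] == rtype]
            pop_sum = pop_sum.merge(
                ths.groupby("pop")["theta_w"].mean().rename(
                    f"theta_{rtype}"), on="pop", how="left")
            zs = zsum[(zsum["scope"] == rtype) & zsum["defined"]]
            pop_sum = pop_sum.merge(
                zs.groupby("pop")["mean_scaled_short"].mean().rename(
                    f"scaled_delta_{rtype}"), on="pop", how="left")
        pop_sum = pop_sum.merge(load[["pop", "load"]], on="pop", how="left")
        corr_pairs = [
            ("mean_corrected_r2_genic", "theta_intergenic"),
            ("mean_corrected_r2_intergenic", "theta_intergenic"),
            ("mean_corrected_r2_genic", "load"),
            ("mean_corrected_r2_intergenic", "load"),
            ("mean_corrected_r2_genic", "scaled_delta_genic"),
        ]
        corr = inference.population_level_stats(pop_sum, corr_pairs)
        paired = {}
        both = pop_sum.dropna(subset=["mean_corrected_r2_genic",
                                      "mean_corrected_r2_intergenic"])
        if len(both) >= 2:
            paired["corrected_r2_genic_vs_intergenic"] = \
                inference.paired_t_test(
                    both["mean_corrected_r2_genic"].to_numpy(),
                    both["mean_corrected_r2_intergenic"].to_numpy())
        io.write_tsv(pop_sum, outdir / "population_summaries.tsv")
        io.write_tsv(corr, outdir / "population_correlations.tsv")
        stage_info["population_stats"] = {
            "n_correlations": len(corr),
            "paired_tests": {k: {kk: (None if vv is None or
                                      (isinstance(vv, float) and np.isnan(vv))
                                      else vv)
                                 for kk, vv in v.items()}
                             for k, v in paired.items()}}

        # --- per-distance-bin models of the zygosity correlation -----------
        delta_long = curves[(curves["scope"] == "genic")
                            & (curves["d"] % 250 == 0)]
        if len(delta_long):
            pdm = inference.per_distance_models(
                delta_long[["individual", "pop", "d", "scaled"]], meta)
            io.write_tsv(pdm, outdir / "per_distance_models.tsv")
            stage_info["per_distance"] = {
                "n_bins": int(pdm["d"].nunique()) if len(pdm) else 0}

        # --- outlier scan --------------------------------------------------
        genic_est = est[est["region_type"] == "genic"]
        if "genic" in gw_models and gw_models["genic"].converged:
            outliers = inference.outlier_scan(
                genic_est, meta, gw_models["genic"],
                min_populations=min(config.outlier_min_populations,
                                    meta["pop"].nunique()),
                band_mode=config.band_mode)
            io.write_tsv(outliers, outdir / "outlier_scan.tsv")
            n_flag = (int(outliers["outlier_log10_expansion_distance"].sum())
                      if not outliers.empty else 0)
            stage_info["outliers"] = {
                "n_genes_tested": len(outliers),
                "n_expansion_outliers": n_flag}
            if not outliers.empty:
                theta_cmp = inference.outlier_theta_comparison(
                    outliers, theta)
                stage_info["outliers"]["theta_comparison"] = {
                    k: (None if isinstance(v, float) and np.isnan(v) else v)
                    for k, v in theta_cmp.items()}
    except Exception as err:
        log.error("pipeline failed in stage %s: %s",
                  list(stage_info)[-1] if stage_info else "simulate", err)
        raise

    manifest = {
        "package": "driftld",
        "config": config.to_dict(),
        "stages": stage_info,
        "files": {
            str(p.relative_to(outdir)): io.sha256_file(p)
            for p in sorted(outdir.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    io.write_manifest(manifest, outdir / "manifest.json")
    return manifest
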