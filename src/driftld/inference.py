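"""Mixed-model inference layer: genome-wide REML models of LD on
demographic predictors, SNP-type interaction models, per-distance-bin
models of the zygosity correlation, population-level correlations and
paired t-tests, marginal-effect predictions, and the gene-level outlier
scan.

The REML optimiser is statsmodels' MixedLM; everything around it --
sum-to-zero contrasts, type-III Wald chi-square tests, BH-FDR, the
coefficient band test and marginal effects -- lives here.  On a singular or
non-converging fit the random structure is simplified stepwise down to OLS
and the structure actually used is recorded in the result.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


@dataclass
class ModelResult:
    """Coefficient table and fit metadata of one (mixed) linear model."""

    table: pd.DataFrame             # index: term; beta, se, chi2, p
    converged: bool
    n_obs: int
    random_structure: str
    formula: str
    model_id: str = ""
    fit: object | None = field(default=None, repr=False)

    def coef(self, term: str) -> pd.Series:
        return self.table.loc[term]


def _term_name(param: str) -> str:
    """Collapse patsy parameter names to their model term."""
    name = param.split("[")[0]
    if name.startswith("C(") and name.endswith(")"):
        name = name[2:-1].split(",")[0].strip()
    # interactions: normalise each side
    if ":" in param:
        parts = [
            p.split("[")[0].replace("C(", "").split(",")[0].rstrip(")").strip()
            for p in param.split(":")
        ]
        name = ":".join(parts)
    return name


def wald_table(params: pd.Series, cov: pd.DataFrame,
               drop: tuple[str, ...] = ("Intercept",)) -> pd.DataFrame:
    """Type-III Wald chi-square per model term.

    Single-df terms use (beta/se)^2; multi-column terms (multi-level
    factors under sum-to-zero coding) use the quadratic form
    beta' V^-1 beta with df = number of columns.
    """
    terms: dict[str, list[str]] = {}
    for p in params.index:
        t = _term_name(p)
        if t in drop or p in drop:
            continue
        terms.setdefault(t, []).append(p)
    rows = []
    for term, cols in terms.items():
        b = params[cols].to_numpy()
        V = cov.loc[cols, cols].to_numpy()
        df_ = len(cols)
        try:
            chi2 = float(b @ np.linalg.solve(V, b))
        except np.linalg.LinAlgError:
            chi2 = np.nan
        p = float(stats.chi2.sf(chi2, df_)) if np.isfinite(chi2) else np.nan
        beta = float(b[0]) if df_ == 1 else np.nan
        se = float(np.sqrt(V[0, 0])) if df_ == 1 else np.nan
        rows.append((term, beta, se, df_, chi2, p))
    return pd.DataFrame(
        rows, columns=["term", "beta", "se", "df", "chi2", "p"]
    ).set_index("term")


def build_formula(response: str, fixed_effects: list[str],
                  data: pd.DataFrame) -> str:
    """Model formula with sum-to-zero coding for categorical predictors."""
    parts = []
    for term in fixed_effects:
        if ":" in term:
            sides = [
                f"C({t}, Sum)" if data[t].dtype == object else t
                for t in term.split(":")
            ]
            parts.append(":".join(sides))
        elif data[term].dtype == object or isinstance(
                data[term].dtype, pd.CategoricalDtype):
            parts.append(f"C({term}, Sum)")
        else:
            parts.append(term)
    return f"{response} ~ " + " + ".join(parts)


def fit_lmm(data: pd.DataFrame, response: str, fixed_effects: list[str],
            group: str | None = "pop",
            vc: dict[str, str] | None = None,
            model_id: str = "") -> ModelResult:
    """REML linear mixed model with type-III Wald tests.

    Random structure: random intercept per ``group`` plus optional variance
    components ``vc`` (name -> formula, e.g. {"region": "0 + C(region_id)"}).
    Fallback chain on failure: drop variance components, then drop the
    random intercept (plain OLS), recording the structure used.  Data are
    reduced to complete cases over the used columns.
    """
    cols = {response}
    for t in fixed_effects:
        cols.update(t.split(":"))
    if group:
        cols.add(group)
    if vc:
        for f in vc.values():
            for tok in f.replace("C(", "").replace(")", "").replace(
                    "0 +", "").split("+"):
                tok = tok.split(",")[0].strip()
                if tok:
                    cols.add(tok)
    df = data[sorted(cols)].dropna().copy()
    formula = build_formula(response, fixed_effects, df)

    attempts: list[tuple[str, dict]] = []
    if group is not None and df[group].nunique() > 1:
        if vc:
            attempts.append((f"intercept({group}) + vc({','.join(vc)})",
                             {"groups": group, "vc_formula": vc}))
        attempts.append((f"intercept({group})", {"groups": group}))
    attempts.append(("none (OLS)", {}))

    def _mixed_fit(mod):
        # lbfgs is fast but can crash or stall at the variance boundary;
        # powell is the derivative-free rescue so boundary-null datasets
        # still get a proper REML fit instead of silently degrading
        for method, maxiter in (("lbfgs", 200), ("powell", 500)):
            try:
                res = mod.fit(reml=True, method=method, maxiter=maxiter)
            except Exception:
                continue
            if not res.converged:
                continue
            fe = res.fe_params
            cov = res.cov_params().loc[fe.index, fe.index]
            diag = np.diag(cov.to_numpy())
            if np.all(np.isfinite(diag)) and np.all(diag > 0):
                return res, fe, cov
        raise RuntimeError("MixedLM did not converge")

    last_err: Exception | None = None
    for structure, kw in attempts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if kw:
                    mod = smf.mixedlm(formula, df, groups=df[kw["groups"]],
                                      vc_formula=kw.get("vc_formula"))
                    res, fe, cov = _mixed_fit(mod)
                else:
                    mod = smf.ols(formula, df)
                    res = mod.fit()
                    fe = res.params
                    cov = res.cov_params()
                    diag = np.diag(cov.to_numpy())
                    if not np.all(np.isfinite(diag)) or np.any(diag <= 0):
                        raise RuntimeError("singular fixed-effect covariance")
            table = wald_table(fe, cov)
            return ModelResult(
                table=table, converged=True, n_obs=len(df),
                random_structure=structure, formula=formula,
                model_id=model_id, fit=res)
        except Exception as err:  # noqa: BLE001 - fall through the chain
            last_err = err
            continue
    log.warning("fit_lmm(%s): all random structures failed (%s)",
                model_id or formula, last_err)
    return ModelResult(
        table=pd.DataFrame(columns=["beta", "se", "df", "chi2", "p"]),
        converged=False, n_obs=len(df), random_structure="failed",
        formula=formula, model_id=model_id)


SIFT_CODING = {"DD": 0, "DT": 1, "TT": 2}


def fit_sift_model(data: pd.DataFrame, response: str = "corrected_r2",
                   coding: dict[str, int] | None = None,
                   group: str = "pop",
                   vc: dict[str, str] | None = None) -> ModelResult:
    """Genic model with numerically coded SNP-pair type and interactions.

    ``pair_category`` must contain DD, DT and TT (all three); it is coded
    0/1/2 (DD < DT < TT by default) and enters with its interactions with
    expansion distance and mating system.
    """
    coding = coding or SIFT_CODING
    present = set(data["pair_category"].unique())
    for cat in coding:
        if cat not in present:
            raise ValueError(f"pair category {cat} absent from the data")
    df = data[data["pair_category"].isin(coding)].copy()
    df["sift_type"] = df["pair_category"].map(coding).astype(float)
    fixed = ["cluster", "log10_expansion_distance", "F_IS",
             "log10_gene_density", "sift_type",
             "log10_expansion_distance:sift_type", "F_IS:sift_type"]
    fixed = [f for f in fixed if all(
        c in df.columns for c in f.split(":"))]
    return fit_lmm(df, response, fixed, group=group, vc=vc,
                   model_id="sift_interaction")


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaNs passed through)."""
    p = np.asarray(pvals, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def per_distance_models(delta_long: pd.DataFrame, meta: pd.DataFrame,
                        response: str = "log10_scaled",
                        alpha: float = 0.05,
                        min_pops: int = 3) -> pd.DataFrame:
    """One mixed model per base-pair distance bin of the zygosity curve.

    ``delta_long`` needs columns individual, pop, d, scaled; the response
    is log10 of the scaled correlation (non-positive values are dropped).
    Fixed effects: cluster, log10 expansion distance, F_IS; random
    intercept per population.  Returns one row per (d, term) with BH-FDR
    adjusted p-values per term across bins.
    """
    df = delta_long.merge(meta, on="pop")
    df = df[df["scaled"] > 0].copy()
    df[response] = np.log10(df["scaled"])
    fixed = ["cluster", "log10_expansion_distance", "F_IS"]
    rows = []
    for d, grp in df.groupby("d"):
        if grp["pop"].nunique() < min_pops:
            log.info("per_distance_models: bin d=%s skipped (<%d populations)",
                     d, min_pops)
            continue
        res = fit_lmm(grp, response, fixed, group="pop",
                      model_id=f"delta_d{d}")
        if not res.converged:
            continue
        for term, r in res.table.iterrows():
            rows.append((d, term, r["beta"], r["se"], r["chi2"], r["p"]))
    out = pd.DataFrame(
        rows, columns=["d", "term", "beta", "se", "chi2", "p"])
    out["p_fdr"] = np.nan
    for term in out["term"].unique():
        sel = out["term"] == term
        out.loc[sel, "p_fdr"] = bh_fdr(out.loc[sel, "p"].to_numpy())
    out["significant"] = out["p_fdr"] < alpha
    return out.sort_values(["term", "d"]).reset_index(drop=True)


def significant_run(per_distance: pd.DataFrame, term: str) -> float:
    """Largest d of the initial consecutive run of significant bins."""
    sub = per_distance[per_distance["term"] == term].sort_values("d")
    run_end = np.nan
    for _, r in sub.iterrows():
        if r["significant"]:
            run_end = float(r["d"])
        else:
            break
    return run_end


def population_level_stats(summary: pd.DataFrame,
                           pairs: list[tuple[str, str]] | None = None,
                           ) -> pd.DataFrame:
    """Pearson correlations between per-population summaries.

    ``summary`` has one row per population.  Each requested column pair
    yields rho, the t statistic and p; needs >= 3 populations.
    """
    if len(summary) < 3:
        raise ValueError("population-level statistics need >= 3 populations")
    rows = []
    for x, y in pairs or []:
        sub = summary[[x, y]].dropna()
        n = len(sub)
        if n < 3:
            rows.append((x, y, n, np.nan, np.nan, np.nan))
            continue
        rho, p = stats.pearsonr(sub[x], sub[y])
        t = rho * np.sqrt((n - 2) / max(1e-300, 1 - rho ** 2))
        rows.append((x, y, n, rho, t, p))
    return pd.DataFrame(rows, columns=["x", "y", "n", "rho", "t", "p"])


def paired_t_test(a: np.ndarray, b: np.ndarray) -> dict:
    """Paired t-test; flags the degenerate zero-variance case."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    diff = a - b
    if np.allclose(diff.std(ddof=1) if len(diff) > 1 else 0.0, 0.0):
        t = 0.0 if np.allclose(diff, 0.0) else np.inf
        return {"t": t, "p": np.nan, "n": len(diff),
                "mean_diff": float(diff.mean()), "degenerate": True}
    t, p = stats.ttest_rel(a, b)
    return {"t": float(t), "p": float(p), "n": len(diff),
            "mean_diff": float(diff.mean()), "degenerate": False}


def marginal_increase(result: ModelResult, data: pd.DataFrame,
                      predictor: str, offset: float = 0.0) -> float:
    """Model-predicted relative change (%) of the response between the
    smallest and largest observed value of ``predictor``, all other
    predictors held at their means (categoricals averaged over levels).

    ``offset`` is added to every prediction before the ratio: a model of
    distance-corrected (residual-scale) LD is re-anchored by the grand
    mean r2, so the percentage refers to LD at the reference distance.
    Undefined (NaN) when the prediction at the minimum is <= 0.
    """
    if not result.converged or result.fit is None:
        raise ValueError("marginal_increase needs a converged model")
    lo, hi = float(data[predictor].min()), float(data[predictor].max())

    def predict_at(value: float) -> float:
        base = {}
        cat_cols = []
        for col in data.columns:
            if col == predictor:
                continue
            if data[col].dtype == object:
                cat_cols.append(col)
            elif np.issubdtype(data[col].dtype, np.number):
                base[col] = float(data[col].mean())
        rows = []
        if cat_cols:
            levels = [sorted(data[c].dropna().unique()) for c in cat_cols]
            from itertools import product
            for combo in product(*levels):
                row = dict(base)
                row.update(dict(zip(cat_cols, combo)))
                row[predictor] = value
                rows.append(row)
        else:
            rows.append({**base, predictor: value})
        new = pd.DataFrame(rows)
        # build the fixed-effects design for the new points explicitly:
        # MixedLM's predict omits the intercept handling we need
        from patsy import build_design_matrices

        design_info = result.fit.model.data.design_info
        X = np.asarray(build_design_matrices([design_info], new)[0])
        fe = getattr(result.fit, "fe_params", None)
        params = fe.to_numpy() if fe is not None else \
            result.fit.params.to_numpy()[: X.shape[1]]
        return float(np.mean(X @ params)) + offset

    y0, y1 = predict_at(lo), predict_at(hi)
    if y0 <= 0:
        log.info("marginal_increase(%s): prediction at minimum <= 0", predictor)
        return np.nan
    return 100.0 * (y1 - y0) / y0


def outlier_scan(estimates: pd.DataFrame, meta: pd.DataFrame,
                 genomewide: ModelResult,
                 response: str = "corrected_r2",
                 min_populations: int = 10,
                 alpha: float = 0.05,
                 band_mode: str = "se",
                 flag_rule: str = "and") -> pd.DataFrame:
    """Gene-by-gene scan for LD responses to expansion and mating system.

    Per gene: mixed model ``response ~ cluster + log10 expansion distance +
    F_IS + expansion x F_IS`` with a population random intercept, fitted on
    the gene's estimates across populations (genes with fewer than
    ``min_populations`` populations are skipped).  P-values are BH-FDR
    adjusted per coefficient across converged genes.  A gene is flagged for
    a coefficient when its FDR p < alpha AND (default rule) the per-gene
    coefficient lies outside the genome-wide coefficient band: beta +/-
    2*SE of the genome-wide fit (band_mode="se") or +/- 2*SD of the
    per-gene coefficients (band_mode="sd").  flag_rule="or" relaxes to
    either condition.
    """
    df = estimates.merge(meta, on="pop")
    fixed = ["cluster", "log10_expansion_distance", "F_IS",
             "log10_expansion_distance:F_IS"]
    terms = ["log10_expansion_distance", "F_IS"]
    rows = []
    skipped = []
    for gene, grp in df.groupby("region_id"):
        if grp["pop"].nunique() < min_populations:
            skipped.append((gene, "too few populations"))
            continue
        res = fit_lmm(grp, response, fixed, group="pop",
                      model_id=f"gene:{gene}")
        if not res.converged:
            skipped.append((gene, "no convergence"))
            continue
        row = {"gene": gene, "n_pops": grp["pop"].nunique()}
        for term in terms + ["log10_expansion_distance:F_IS"]:
            if term in res.table.index:
                row[f"beta_{term}"] = res.table.loc[term, "beta"]
                row[f"se_{term}"] = res.table.loc[term, "se"]
                row[f"p_{term}"] = res.table.loc[term, "p"]
        rows.append(row)
    if skipped:
        log.info("outlier_scan: %d genes skipped/unfit", len(skipped))
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    for term in terms:
        out[f"p_fdr_{term}"] = bh_fdr(out[f"p_{term}"].to_numpy())
        gw_beta = genomewide.table.loc[term, "beta"]
        if band_mode == "se":
            half = 2.0 * genomewide.table.loc[term, "se"]
        elif band_mode == "sd":
            half = 2.0 * float(out[f"beta_{term}"].std(ddof=1))
        else:
            raise ValueError("band_mode must be 'se' or 'sd'")
        out[f"band_lo_{term}"] = gw_beta - half
        out[f"band_hi_{term}"] = gw_beta + half
        outside = (out[f"beta_{term}"] < gw_beta - half) | (
            out[f"beta_{term}"] > gw_beta + half)
        sig = out[f"p_fdr_{term}"] < alpha
        if flag_rule == "and":
            out[f"outlier_{term}"] = sig & outside
        elif flag_rule == "or":
            out[f"outlier_{term}"] = sig | outside
        else:
            raise ValueError("flag_rule must be 'and' or 'or'")
    return out


def outlier_theta_comparison(outliers: pd.DataFrame, theta: pd.DataFrame,
                             term: str = "log10_expansion_distance") -> dict:
    """Paired (per population) t-test of mean theta in outlier versus
    non-outlier genes for one scanned coefficient."""
    flagged = set(outliers.loc[outliers[f"outlier_{term}"], "gene"])
    if not flagged:
        return {"t": np.nan, "p": np.nan, "n": 0, "mean_diff": np.nan,
                "degenerate": True, "n_outliers": 0}
    th = theta[theta["region_type"] == "genic"]
    per_pop = th.groupby(["pop", th["region_id"].isin(flagged)])[
        "theta_w"].mean().unstack()
    per_pop = per_pop.dropna()
    if per_pop.shape[1] < 2 or len(per_pop) < 2:
        return {"t": np.nan, "p": np.nan, "n": len(per_pop),
                "mean_diff": np.nan, "degenerate": True,
                "n_outliers": len(flagged)}
    res = paired_t_test(per_pop[True].to_numpy(), per_pop[False].to_numpy())
    res["n_outliers"] = len(flagged)
    return res
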