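"""Correlation of zygosity: long-range LD from a single diploid genome.

Along one genome, code each callable site z = 1 if heterozygous, 0
otherwise.  The correlation of zygosity at distance d,

    Delta(d) = (Pi(d) - theta^2) / (theta * (1 - theta)),

with theta the genome-wide heterozygosity (mean of z) and Pi(d) the mean of
z_i * z_{i+d} over callable pairs, measures how far the heterozygous state
is correlated; Delta(d)/theta approximates r-squared.  The decay length is
the distance at which the scaled curve first falls to a low threshold
(default 0.1) and stays there.

Pair and site counts are computed exactly by FFT autocorrelation of the
callable mask and heterozygosity indicator within each region-scope
interval, so pairs never span scope gaps.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.fft import next_fast_len, rfft, irfft


def default_steps(max_distance: int = 50_000) -> np.ndarray:
    """1 bp steps to 5 kb, then 100 bp steps to ``max_distance``."""
    fine = np.arange(1, min(5_000, max_distance) + 1)
    if max_distance <= 5_000:
        return fine
    coarse = np.arange(5_100, max_distance + 1, 100)
    return np.concatenate([fine, coarse])


@dataclass
class ZygosityProfile:
    """Zygosity-correlation curve of one individual in one region scope."""

    individual: str
    population: str
    scope: str                      # "genic", "intergenic" or "all"
    theta: float
    curve: pd.DataFrame             # columns: d, delta, scaled, n_pairs
    undefined_reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.undefined_reason is None

    def to_frame(self) -> pd.DataFrame:
        df = self.curve.copy()
        df.insert(0, "scope", self.scope)
        df.insert(0, "individual", self.individual)
        df["theta"] = self.theta
        return df


def callable_mask(genotypes: pd.DataFrame, mean_depth: float,
                  genome_length: int,
                  intervals: list[tuple[int, int]] | None = None,
                  min_gq: int = 28,
                  depth_window: tuple[float, float] = (2.0, 5.0),
                  all_sites_callable: bool = True) -> np.ndarray:
    """Boolean callable mask over the genome for one individual.

    A listed site is callable iff GQ >= ``min_gq`` and its depth lies in
    the closed window [lo * mean_depth, hi * mean_depth].  Positions not
    listed in the genotype table are homozygous-reference background; with
    ``all_sites_callable`` they count as callable (an all-sites mask), so
    theta is a per-bp rate.  ``intervals`` (0-based half-open) restrict the
    mask to a region scope.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    lo, hi = depth_window
    mask = np.full(genome_length, bool(all_sites_callable))
    pos = genotypes["pos"].to_numpy().astype(np.int64) - 1
    ok = (genotypes["GQ"].to_numpy() >= min_gq) & \
         (genotypes["DP"].to_numpy() >= lo * mean_depth) & \
         (genotypes["DP"].to_numpy() <= hi * mean_depth)
    mask[pos] = ok
    if intervals is not None:
        scope = np.zeros(genome_length, dtype=bool)
        for start, end in intervals:
            scope[start:end] = True
        mask &= scope
    return mask


def _lagged_counts(vec: np.ndarray, max_lag: int) -> np.ndarray:
    """Sum over i of vec[i] * vec[i+d] for d = 0..max_lag via FFT."""
    n = len(vec)
    if n == 0:
        return np.zeros(max_lag + 1)
    size = next_fast_len(2 * n)
    f = rfft(vec.astype(float), size)
    corr = irfft(f * np.conj(f), size)[: max_lag + 1]
    return np.rint(corr)


def _accumulate_lags(genotypes: pd.DataFrame, mask: np.ndarray,
                     intervals: list[tuple[int, int]], max_lag: int):
    """Callable and co-heterozygous pair counts per lag for one genome."""
    het_pos = genotypes.loc[
        genotypes["genotype"] == "0/1", "pos"].to_numpy().astype(np.int64) - 1
    z = np.zeros(len(mask), dtype=bool)
    z[het_pos] = True
    z &= mask
    n_callable = 0
    n_het = 0
    pair_n = np.zeros(max_lag + 1)
    pair_het = np.zeros(max_lag + 1)
    for start, end in intervals:
        m = mask[start:end]
        n_callable += int(m.sum())
        zz = z[start:end]
        n_het += int(zz.sum())
        lag = min(max_lag, end - start - 1)
        if lag >= 1:
            pair_n[: lag + 1] += _lagged_counts(m, lag)
            pair_het[: lag + 1] += _lagged_counts(zz, lag)
    return n_callable, n_het, pair_n, pair_het


def zygosity_curve(genotypes: pd.DataFrame, mask: np.ndarray,
                   steps: np.ndarray | None = None,
                   intervals: list[tuple[int, int]] | None = None,
                   individual: str = "", population: str = "",
                   scope: str = "all", bin_width: int = 1,
                   min_het_sites: int = 30) -> ZygosityProfile:
    """Compute theta and Delta(d) for one individual.

    ``mask`` is the callable mask over the genome; heterozygous sites come
    from the genotype calls ("0/1").  When ``intervals`` is given, pairs are
    confined within single intervals (no pair spans a scope gap); otherwise
    the whole mask is one interval.  ``bin_width`` > 1 pools pairs from a
    window of that many distances centred on each step — necessary for
    sparse genomes where exact-distance pair counts are tiny.

    A genome with fewer than ``min_het_sites`` callable heterozygous sites
    cannot support the correlation estimate (a nearly fully homozygous
    selfer, say) and yields an undefined profile.
    """
    if steps is None:
        steps = default_steps()
    max_lag = int(steps.max()) + bin_width // 2
    if intervals is None:
        intervals = [(0, len(mask))]
    n_callable, n_het, pair_n, pair_het = _accumulate_lags(
        genotypes, mask, intervals, max_lag)

    if n_callable == 0:
        return ZygosityProfile(individual, population, scope, np.nan,
                               pd.DataFrame(), "no callable sites")
    theta = n_het / n_callable
    if theta == 0.0:
        return ZygosityProfile(individual, population, scope, 0.0,
                               pd.DataFrame(), "no heterozygous sites")
    if n_het < min_het_sites:
        return ZygosityProfile(individual, population, scope, theta,
                               pd.DataFrame(), "too few heterozygous sites")

    d = steps
    if bin_width > 1:
        half = bin_width // 2
        csum_n = np.concatenate([[0.0], np.cumsum(pair_n)])
        csum_h = np.concatenate([[0.0], np.cumsum(pair_het)])
        lo = np.maximum(d - half, 1)
        hi = np.minimum(d + half, max_lag)
        npairs = csum_n[hi + 1] - csum_n[lo]
        het = csum_h[hi + 1] - csum_h[lo]
    else:
        npairs = pair_n[d]
        het = pair_het[d]
    with np.errstate(invalid="ignore", divide="ignore"):
        pi_d = np.where(npairs > 0, het / np.where(npairs > 0, npairs, 1),
                        np.nan)
        delta = (pi_d - theta ** 2) / (theta * (1.0 - theta))
    curve = pd.DataFrame({
        "d": d, "delta": delta, "scaled": delta / theta,
        "n_pairs": npairs.astype(np.int64),
    })
    curve = curve[curve["n_pairs"] > 0].reset_index(drop=True)
    return ZygosityProfile(individual, population, scope, theta, curve)


def pooled_zygosity_curve(per_individual, steps: np.ndarray | None = None,
                          intervals: list[tuple[int, int]] | None = None,
                          bin_width: int = 1, population: str = "",
                          scope: str = "all",
                          min_het_sites: int = 30) -> ZygosityProfile:
    """Deme-level zygosity correlation pooled across genomes.

    ``per_individual`` yields (genotype table, callable mask) pairs.  The
    estimator is a ratio of sums: each genome's co-heterozygous pair
    counts are centred by its own theta squared before pooling,

        Delta(d) = sum_i [het_i(d) - n_i(d) theta_i^2]
                   / sum_i [n_i(d) theta_i (1 - theta_i)],

    so genomes contribute in proportion to their information, nearly
    homozygous genomes add almost nothing, and the between-genome
    variance in inbreeding does not masquerade as distance-dependent
    correlation.  The scaled curve divides by the pooled heterozygosity.
    """
    if steps is None:
        steps = default_steps()
    max_lag = int(steps.max()) + bin_width // 2
    tot_callable = tot_het = 0
    num = np.zeros(max_lag + 1)
    den = np.zeros(max_lag + 1)
    pair_n = np.zeros(max_lag + 1)
    for genotypes, mask in per_individual:
        iv = intervals if intervals is not None else [(0, len(mask))]
        nc, nh, pn, ph = _accumulate_lags(genotypes, mask, iv, max_lag)
        tot_callable += nc
        tot_het += nh
        if nc == 0 or nh == 0:
            continue
        theta_i = nh / nc
        num += ph - pn * theta_i ** 2
        den += pn * theta_i * (1.0 - theta_i)
        pair_n += pn
    if tot_callable == 0:
        return ZygosityProfile("pooled", population, scope, np.nan,
                               pd.DataFrame(), "no callable sites")
    theta = tot_het / tot_callable
    if theta == 0.0:
        return ZygosityProfile("pooled", population, scope, 0.0,
                               pd.DataFrame(), "no heterozygous sites")
    if tot_het < min_het_sites:
        return ZygosityProfile("pooled", population, scope, theta,
                               pd.DataFrame(), "too few heterozygous sites")
    d = steps
    if bin_width > 1:
        half = bin_width // 2
        cs_num = np.concatenate([[0.0], np.cumsum(num)])
        cs_den = np.concatenate([[0.0], np.cumsum(den)])
        cs_n = np.concatenate([[0.0], np.cumsum(pair_n)])
        lo = np.maximum(d - half, 1)
        hi = np.minimum(d + half, max_lag)
        num_b = cs_num[hi + 1] - cs_num[lo]
        den_b = cs_den[hi + 1] - cs_den[lo]
        npairs = cs_n[hi + 1] - cs_n[lo]
    else:
        num_b, den_b, npairs = num[d], den[d], pair_n[d]
    with np.errstate(invalid="ignore", divide="ignore"):
        delta = np.where(den_b > 0,
                         num_b / np.where(den_b > 0, den_b, 1.0), np.nan)
    curve = pd.DataFrame({
        "d": d, "delta": delta, "scaled": delta / theta,
        "n_pairs": npairs.astype(np.int64)})
    curve = curve[curve["n_pairs"] > 0].reset_index(drop=True)
    return ZygosityProfile("pooled", population, scope, theta, curve)


def decay_length(profile: ZygosityProfile, threshold: float = 0.1,
                 window: int = 11, persistence: int = 10,
                 smooth: bool = True,
                 require_initial_above: bool = False) -> float:
    """Distance where the scaled zygosity curve falls to ``threshold``.

    Returns the smallest d at which the rolling-median-smoothed scaled
    curve is <= threshold and remains so for the next ``persistence`` bins;
    NaN when the curve never decays (LD extends beyond the measured range)
    or the profile is undefined.  ``smooth=False`` uses the raw crossing.

    With ``require_initial_above`` a curve that never rises above the
    threshold is reported as NaN: there is no decay to locate, only a
    signal too sparse to measure.
    """
    if not profile.defined or profile.curve.empty:
        return np.nan
    c = profile.curve["scaled"]
    if smooth:
        c = c.rolling(window, center=True, min_periods=1).median()
    if require_initial_above and not (c > threshold).any():
        return np.nan
    below = (c <= threshold).to_numpy()
    d = profile.curve["d"].to_numpy()
    for i in np.nonzero(below)[0]:
        j = min(i + persistence + 1, len(below))
        if below[i:j].all():
            return float(d[i])
    return np.nan


def profile_summary(profiles: list[ZygosityProfile],
                    short_range: int = 500,
                    threshold: float = 0.1) -> pd.DataFrame:
    """Per-profile theta, short-range mean scaled Delta and decay length."""
    rows = []
    for p in profiles:
        short = np.nan
        if p.defined and not p.curve.empty:
            sel = p.curve[p.curve["d"] <= short_range]
            if len(sel):
                short = float(sel["scaled"].mean())
        rows.append({
            "individual": p.individual,
            "pop": p.population,
            "scope": p.scope,
            "theta": p.theta,
            "mean_scaled_short": short,
            "decay_length": decay_length(p, threshold=threshold),
            "defined": p.defined,
        })
    return pd.DataFrame(rows)
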