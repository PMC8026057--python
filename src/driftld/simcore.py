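"""Forward-time Wright-Fisher stepping-stone simulator of range expansion.

Demes are founded serially along a one-dimensional axis: deme 0 (the core)
evolves alone for a burn-in, then every ``generations_between_foundings``
generations the next deme is seeded with ``founder_size`` diploids drawn
from the previous deme; the founders repopulate the colony to its carrying
capacity ``core_size`` in one generation (a single-generation propagule
bottleneck).  Offspring are produced by selfing with the deme's selfing
probability, otherwise by random outcrossing; parents are drawn with
probability proportional to fitness, which is multiplicative across
deleterious loci (1 - h*s heterozygous, 1 - s homozygous derived).

Mutation follows the infinite-sites model on an alternating gene/intergenic
layout: genic mutations are deleterious with probability
``fraction_deleterious_in_genic`` and synonymous-like (tolerated) otherwise;
intergenic mutations are neutral.  Recombination is uniform per bp.

The emitters turn a simulated deme into the two observation types the
analysis consumes: pooled paired-end reads (allele counts plus two-locus
read-pair haplotype counts) and individually sequenced diploid genomes
(genotype calls with depth and quality).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimConfig

SCAFFOLD = "scaffold_1"

NEUTRAL = "neutral"
SYNONYMOUS = "synonymous"
DELETERIOUS = "deleterious"


class ExtinctionError(RuntimeError):
    """A deme's total fitness collapsed to zero."""


@dataclass
class SimulatedMetapopulation:
    """All demes of one simulated range expansion.

    ``haplotypes[d]`` is a (2*N_d, S) uint8 matrix of derived-allele
    indicators over the S segregating sites shared across demes;
    ``site_table`` has one row per segregating site (position is 0-based);
    ``deme_meta`` carries deme index, distance from the core in km, and the
    deme's selfing rate.
    """

    haplotypes: list[np.ndarray]
    positions: np.ndarray
    site_table: pd.DataFrame
    deme_meta: pd.DataFrame
    config: SimConfig

    @property
    def n_demes(self) -> int:
        return len(self.haplotypes)

    def deme_frequencies(self, deme: int) -> np.ndarray:
        H = self.haplotypes[deme]
        if H.shape[0] == 0:
            return np.zeros(H.shape[1])
        return H.mean(axis=0)


def _site_classes(positions: np.ndarray, config: SimConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Functional class per new site from the genic layout."""
    genic = np.zeros(len(positions), dtype=bool)
    for start, end in config.gene_intervals():
        genic |= (positions >= start) & (positions < end)
    cls = np.full(len(positions), NEUTRAL, dtype=object)
    u = rng.random(len(positions))
    cls[genic & (u < config.fraction_deleterious_in_genic)] = DELETERIOUS
    cls[genic & (u >= config.fraction_deleterious_in_genic)] = SYNONYMOUS
    return cls


def _fitness(H: np.ndarray, del_weights: np.ndarray, s: float,
             h: float) -> np.ndarray:
    """Multiplicative fitness per diploid from deleterious genotypes.

    ``del_weights`` is a float32 0/1 vector marking deleterious columns;
    heterozygous and homozygous-derived counts come from cheap bitwise
    haplotype combinations followed by a BLAS dot product.
    """
    n = H.shape[0] // 2
    if s == 0.0 or not del_weights.any():
        return np.ones(n)
    h0, h1 = H[0::2], H[1::2]
    n_het = (h0 ^ h1).astype(np.float32) @ del_weights
    n_hom = (h0 & h1).astype(np.float32) @ del_weights
    with np.errstate(divide="ignore"):
        logw = n_het * np.log1p(-h * s) + (
            n_hom * (np.log(1.0 - s) if s < 1.0 else -np.inf)
        )
    return np.exp(logw)


def _gametes(H: np.ndarray, parents: np.ndarray, positions: np.ndarray,
             rho_total: float, rng: np.random.Generator,
             L: int) -> np.ndarray:
    """One recombinant gamete per entry of ``parents`` (individual indices).

    Crossovers form a Poisson process along the chromosome (no
    interference); each gamete draws its crossover count, breakpoints are
    uniform, and the haplotype alternates between the parent's two copies
    across the resulting segments.
    """
    n = len(parents)
    S = H.shape[1]
    start = rng.integers(0, 2, n)
    out = H[2 * parents + start].copy()
    if S == 0 or rho_total == 0.0:
        return out
    k = rng.poisson(rho_total, n)
    rec = np.nonzero(k)[0]
    if rec.size == 0:
        return out
    cuts_all = np.searchsorted(
        positions, rng.integers(1, L, int(k[rec].sum())))
    off = 0
    for i in rec:
        ki = int(k[i])
        bounds = sorted(cuts_all[off:off + ki].tolist())
        bounds.append(S)
        off += ki
        prev = 0
        other = H[2 * parents[i] + (1 - start[i])]
        for seg, cut in enumerate(bounds):
            if seg % 2 == 1 and prev < cut:
                out[i, prev:cut] = other[prev:cut]
            prev = cut
    return out


def _choose_parents(w: np.ndarray, n_off: int, selfing: float,
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    total = w.sum()
    if total == 0.0:
        raise ExtinctionError("all individuals have zero fitness")
    p = w / total
    a = rng.choice(len(w), size=n_off, p=p)
    b = rng.choice(len(w), size=n_off, p=p)
    selfed = rng.random(n_off) < selfing
    b[selfed] = a[selfed]
    return a, b


def simulate_expansion(config: SimConfig) -> SimulatedMetapopulation:
    """Run the serial-founding expansion and return all demes.

    Deterministic given ``config.seed``.  The returned site table contains
    only sites still segregating somewhere in the metapopulation.
    """
    rng = np.random.default_rng(config.seed)
    L = config.genome_length
    rho_total = config.per_bp_recombination * (L - 1)
    mu_total = config.per_bp_mutation * L
    s_del = config.selection_coefficient
    h = config.dominance
    selfing = config.selfing_rates()

    positions = np.empty(0, dtype=np.int64)
    classes = np.empty(0, dtype=object)
    demes: list[np.ndarray] = [np.zeros((2 * config.core_size, 0), dtype=np.uint8)]

    def del_weights() -> np.ndarray:
        return (classes == DELETERIOUS).astype(np.float32)

    def prune() -> None:
        nonlocal positions, classes, demes
        if positions.size == 0:
            return
        counts = np.zeros(positions.size, dtype=np.int64)
        fixed_everywhere = np.ones(positions.size, dtype=bool)
        for H in demes:
            c = H.sum(axis=0, dtype=np.int64)
            counts += c
            fixed_everywhere &= c == H.shape[0]
        keep = (counts > 0) & ~fixed_everywhere
        if not keep.all():
            positions = positions[keep]
            classes = classes[keep]
            demes = [H[:, keep] for H in demes]

    def step(generation_demes: list[np.ndarray]) -> list[np.ndarray]:
        nonlocal positions, classes
        dcols = del_weights()
        new = []
        mut_targets: list[tuple[int, int]] = []  # (deme, gamete row)
        for d, H in enumerate(generation_demes):
            # propagule colonisation: the K founders repopulate the deme to
            # carrying capacity in a single generation
            n_off = config.core_size
            w = _fitness(H, dcols, s_del, h)
            a, b = _choose_parents(w, n_off, selfing[d], rng)
            gam = _gametes(H, np.concatenate([a, b]), positions,
                           rho_total, rng, L)
            Hn = np.empty((2 * n_off, positions.size), dtype=np.uint8)
            Hn[0::2] = gam[:n_off]
            Hn[1::2] = gam[n_off:]
            new.append(Hn)
            n_mut = rng.poisson(2 * n_off * mu_total)
            rows = rng.integers(0, 2 * n_off, n_mut)
            mut_targets.extend((d, r) for r in rows)
        if mut_targets:
            pos_new = rng.integers(0, L, len(mut_targets))
            # infinite sites: drop the rare collision with an existing or
            # same-batch site
            first_hit = np.zeros(len(pos_new), dtype=bool)
            first_hit[np.unique(pos_new, return_index=True)[1]] = True
            fresh = ~np.isin(pos_new, positions) & first_hit
            pos_new = pos_new[fresh]
            targets = [t for t, f in zip(mut_targets, fresh) if f]
            if len(pos_new):
                k = len(pos_new)
                order_new = np.argsort(pos_new, kind="stable")
                pos_sorted = pos_new[order_new]
                targets_sorted = [targets[j] for j in order_new]
                cls_new = _site_classes(pos_sorted, config, rng)
                ins = np.searchsorted(positions, pos_sorted)
                final_idx = ins + np.arange(k)
                positions = np.insert(positions, ins, pos_sorted)
                classes = np.insert(classes, ins, cls_new)
                new = [np.insert(Hd, ins, 0, axis=1) for Hd in new]
                for j, (d, r) in enumerate(targets_sorted):
                    new[d][r, final_idx[j]] = 1
        return new

    # burn-in: core deme alone
    for g in range(config.burn_in_generations):
        demes = step(demes)
        if g % 5 == 4:
            prune()

    # expansion phase: found deme i at local generation i*gbf (deme 1 founded
    # immediately), then keep stepping until the last deme has existed for a
    # full inter-founding interval
    gbf = config.generations_between_foundings
    total = (config.n_demes - 1) * gbf + gbf if config.n_demes > 1 else 0
    for g in range(total):
        if g % gbf == 0 and len(demes) < config.n_demes:
            src = demes[-1]
            n_src = src.shape[0] // 2
            founders = rng.choice(n_src, size=min(config.founder_size, n_src),
                                  replace=False)
            rows = np.empty(2 * len(founders), dtype=np.int64)
            rows[0::2] = 2 * founders
            rows[1::2] = 2 * founders + 1
            demes.append(src[rows].copy())
        demes = step(demes)
        if g % 5 == 4:
            prune()
    prune()

    site_table = pd.DataFrame({
        "scaffold": SCAFFOLD,
        "position": positions,
        "functional_class": classes,
    })
    site_table["genic"] = site_table["functional_class"] != NEUTRAL
    deme_meta = pd.DataFrame({
        "deme": np.arange(config.n_demes),
        "distance_km": np.arange(config.n_demes) * config.deme_step_km,
        "selfing_rate": selfing,
    })
    return SimulatedMetapopulation(
        haplotypes=demes, positions=positions, site_table=site_table,
        deme_meta=deme_meta, config=config,
    )


# ---------------------------------------------------------------------------
# observation emitters

def emit_poolseq(pop: SimulatedMetapopulation, deme: int, config: SimConfig,
                 rng: np.random.Generator | None = None,
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample pooled paired-end reads from one deme.

    Returns ``(allele_counts, pair_counts)``: per-site depths and
    reference/alternate counts, and 2x2 read-pair haplotype counts for every
    SNP pair co-covered by at least one read pair.  In the pair table the
    first allele index refers to the reference (ancestral) allele, so
    ``n11`` counts read pairs carrying reference at both loci.
    """
    if deme >= pop.n_demes or pop.haplotypes[deme].shape[0] == 0:
        raise ValueError(f"deme {deme} is empty or absent")
    if rng is None:
        rng = np.random.default_rng(config.seed + 7_000_003 + deme)
    H = pop.haplotypes[deme]
    n_ind = H.shape[0] // 2
    pool = rng.choice(n_ind, size=min(config.pool_size, n_ind), replace=False)
    rows = np.empty(2 * len(pool), dtype=np.int64)
    rows[0::2] = 2 * pool
    rows[1::2] = 2 * pool + 1
    Hp = H[rows]
    positions = pop.positions
    L = config.genome_length
    rl = config.read_length

    n_pairs = int(round(config.pool_depth * L / (2 * rl)))
    hap = rng.integers(0, Hp.shape[0], n_pairs)
    insert = np.maximum(
        np.rint(rng.normal(config.insert_mean, config.insert_sd, n_pairs)), 0
    ).astype(np.int64)
    frag = 2 * rl + insert
    ok = frag <= L
    hap, insert, frag = hap[ok], insert[ok], frag[ok]
    start = (rng.random(len(hap)) * (L - frag + 1)).astype(np.int64)

    # covered segregating-site index ranges for each mate
    a0 = np.searchsorted(positions, start)
    a1 = np.searchsorted(positions, start + rl)
    b0 = np.searchsorted(positions, start + rl + insert)
    b1 = np.searchsorted(positions, start + frag)

    S = len(positions)
    err = config.seq_error

    # per-site depths and allele counts: each site is covered by a
    # Binomial(n fragments, covered bp / L) number of reads, and each read
    # draws a random pool haplotype with per-base error -- sampled directly
    # per site, which is equivalent to (and far cheaper than) tallying the
    # same virtual fragments
    n_frag = len(hap)
    depth = rng.binomial(n_frag, min(1.0, 2 * rl / L), S).astype(np.int64)
    f_pool = Hp.mean(axis=0)
    f_read = f_pool * (1 - err) + (1 - f_pool) * err
    alt = rng.binomial(depth, f_read).astype(np.int64)

    # two-locus haplotype counts from the fragments proper, restricted to
    # sites segregating in the sampled pool: the positions a SNP caller
    # would report for this population
    pool_ac = Hp.sum(axis=0, dtype=np.int64)
    is_snp = (pool_ac > 0) & (pool_ac < Hp.shape[0])
    snp_cum = np.concatenate([[0], np.cumsum(is_snp)])
    snp_pos_idx = np.nonzero(is_snp)[0]

    def _expand(lo: np.ndarray, hi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lens = hi - lo
        tot = int(lens.sum())
        if tot == 0:
            return (np.empty(0, dtype=np.int64),) * 2
        site = np.repeat(hi - np.cumsum(lens), lens) + np.arange(tot)
        frag = np.repeat(np.arange(len(lo)), lens)
        return site, frag

    # covered SNP index ranges (in SNP-compressed coordinates)
    sa, fa = _expand(snp_cum[a0], snp_cum[a1])
    sb, fb = _expand(snp_cum[b0], snp_cum[b1])
    site_idx = snp_pos_idx[np.concatenate([sa, sb])]
    frag_idx = np.concatenate([fa, fb])
    order = np.argsort(frag_idx, kind="stable")
    site_idx, frag_idx = site_idx[order], frag_idx[order]
    alleles = Hp[hap[frag_idx], site_idx].astype(np.int64)
    if err > 0:
        flips = rng.random(len(alleles)) < err
        alleles = np.where(flips, 1 - alleles, alleles)

    # all within-fragment SNP pairs, vectorised per fragment size
    pair_i = []
    pair_j = []
    pair_ai = []
    pair_aj = []
    if len(frag_idx):
        uniq, counts = np.unique(frag_idx, return_counts=True)
        offsets = np.concatenate([[0], np.cumsum(counts)])
        for size in np.unique(counts):
            if size < 2:
                continue
            sel = np.nonzero(counts == size)[0]
            starts = offsets[sel]
            block = starts[:, None] + np.arange(size)[None, :]
            s_blk = site_idx[block]          # (n_groups, size)
            a_blk = alleles[block]
            iu, ju = np.triu_indices(size, k=1)
            pair_i.append(s_blk[:, iu].ravel())
            pair_j.append(s_blk[:, ju].ravel())
            pair_ai.append(a_blk[:, iu].ravel())
            pair_aj.append(a_blk[:, ju].ravel())
    pair_rows = None
    if pair_i:
        arr_i = np.concatenate(pair_i)
        arr_j = np.concatenate(pair_j)
        arr_a = np.concatenate(pair_ai)
        arr_b = np.concatenate(pair_aj)
        pair_rows = (arr_i, arr_j, arr_a, arr_b)

    pop_id = f"pop{deme}"
    allele_counts = pd.DataFrame({
        "scaffold": SCAFFOLD,
        "pos": positions + 1,
        "ref": "A",
        "alt": "T",
        "pop": pop_id,
        "ref_count": depth - alt,
        "alt_count": alt,
        "depth": depth,
    })

    if pair_rows is not None:
        arr_i, arr_j, arr_a, arr_b = pair_rows
        cell = 2 * (1 - arr_a) + (1 - arr_b)  # 0: alt-alt .. 3: ref-ref
        key = arr_i * S + arr_j
        df = pd.DataFrame({"key": key, "cell": cell})
        tab = df.groupby(["key", "cell"]).size().unstack(fill_value=0)
        tab = tab.reindex(columns=[3, 2, 1, 0], fill_value=0)
        tab.columns = ["n11", "n12", "n21", "n22"]  # 1 = reference allele
        tab = tab.reset_index()
        i = tab["key"] // S
        j = tab["key"] % S
        pair_counts = pd.DataFrame({
            "pop": pop_id,
            "scaffold": SCAFFOLD,
            "pos1": positions[i] + 1,
            "pos2": positions[j] + 1,
            "n11": tab["n11"],
            "n12": tab["n12"],
            "n21": tab["n21"],
            "n22": tab["n22"],
        })
    else:
        pair_counts = pd.DataFrame(
            columns=["pop", "scaffold", "pos1", "pos2",
                     "n11", "n12", "n21", "n22"])
    return allele_counts, pair_counts


def _genotype_calls(g_true: np.ndarray, depth: np.ndarray, err: float,
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Call genotypes from simulated read counts; return (calls, GQ).

    Per-site alternate-read counts are binomial in the true allele dosage
    with sequencing error ``err``; genotype likelihoods are the matching
    binomials and GQ is the phred gap to the second-best genotype, capped
    at 40.
    """
    from scipy.special import xlogy

    p_alt = np.array([err, 0.5, 1.0 - err])
    p_true = p_alt[g_true]
    alt_reads = rng.binomial(depth, p_true)
    ref_reads = depth - alt_reads
    # binomial log likelihoods without the combinatorial term, which
    # cancels in the genotype ranking and the phred gap
    with np.errstate(divide="ignore"):
        ll = np.stack([
            xlogy(alt_reads, p_alt[g]) + xlogy(ref_reads, 1.0 - p_alt[g])
            for g in range(3)
        ])
    calls = ll.argmax(axis=0)
    ll_sorted = np.sort(ll, axis=0)
    gap = (ll_sorted[-1] - ll_sorted[-2]) * 10.0 / np.log(10.0)
    gq = np.minimum(np.rint(gap), 40).astype(np.int64)
    gq[depth == 0] = 0
    calls[depth == 0] = 0
    return calls, gq


def emit_individuals(pop: SimulatedMetapopulation, deme: int,
                     n_individuals: int, config: SimConfig,
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Emit diploid genotype calls for individuals sampled from one deme.

    Returns a table (individual, scaffold, pos, genotype, GQ, DP) over the
    segregating sites; positions are 1-based.  Genotype strings follow VCF
    ("0/0", "0/1", "1/1").
    """
    H = pop.haplotypes[deme]
    n_avail = H.shape[0] // 2
    if n_individuals > n_avail:
        raise ValueError(f"deme {deme} has only {n_avail} individuals")
    cols = ["individual", "scaffold", "pos", "genotype", "GQ", "DP"]
    if n_individuals == 0:
        return pd.DataFrame(columns=cols)
    if rng is None:
        rng = np.random.default_rng(config.seed + 9_000_017 + deme)
    chosen = rng.choice(n_avail, size=n_individuals, replace=False)
    frames = []
    gt_str = np.array(["0/0", "0/1", "1/1"])
    for ind in chosen:
        g_true = (H[2 * ind].astype(np.int64) + H[2 * ind + 1])
        depth = rng.poisson(config.individual_depth_mean, len(g_true))
        calls, gq = _genotype_calls(g_true, depth, config.seq_error, rng)
        frames.append(pd.DataFrame({
            "individual": f"pop{deme}_ind{ind}",
            "scaffold": SCAFFOLD,
            "pos": pop.positions + 1,
            "genotype": gt_str[calls],
            "GQ": gq,
            "DP": depth,
        }))
    return pd.concat(frames, ignore_index=True)


def true_heterozygosity(pop: SimulatedMetapopulation, deme: int,
                        individual: int) -> float:
    """Fraction of the genome heterozygous in one true diploid genome."""
    H = pop.haplotypes[deme]
    het = (H[2 * individual] != H[2 * individual + 1]).sum()
    return het / pop.config.genome_length
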