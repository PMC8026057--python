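"""Configuration objects for the simulator and the analysis pipeline."""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class SimConfig:
    """Parameters of the forward-time range-expansion simulation.

    The genome is tiled as alternating intergenic and genic blocks:
    ``n_genes`` genes of ``gene_length`` bp separated (and flanked) by
    ``n_genes + 1`` intergenic blocks of ``intergenic_length`` bp, which
    must tile ``genome_length`` exactly.

    Rates are per base pair per generation.  ``selfing_rate_per_deme`` may
    be a scalar (broadcast to all demes) or one probability per deme.
    """

    n_demes: int = 10
    core_size: int = 80
    founder_size: int = 4
    generations_between_foundings: int = 10
    burn_in_generations: int = 400
    selfing_rate_per_deme: float | Sequence[float] = 0.0
    genome_length: int = 82_500
    n_genes: int = 16
    gene_length: int = 2_500
    intergenic_length: int = 2_500
    per_bp_recombination: float = 1e-5
    per_bp_mutation: float = 2e-5
    fraction_deleterious_in_genic: float = 0.4
    selection_coefficient: float = 0.0
    dominance: float = 0.3
    pool_size: int = 25
    pool_depth: int = 300
    read_length: int = 100
    insert_mean: float = 150.0
    insert_sd: float = 60.0
    seq_error: float = 0.002
    individual_depth_mean: float = 20.0
    deme_step_km: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            "fraction_deleterious_in_genic": self.fraction_deleterious_in_genic,
            "dominance": self.dominance,
            "seq_error": self.seq_error,
            "selection_coefficient": self.selection_coefficient,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}={p} outside [0, 1]")
        for s in self.selfing_rates():
            if not 0.0 <= s <= 1.0:
                raise ConfigError(f"selfing rate {s} outside [0, 1]")
        if self.founder_size > self.core_size:
            raise ConfigError("founder_size must not exceed core_size")
        layout = (
            self.n_genes * self.gene_length
            + (self.n_genes + 1) * self.intergenic_length
        )
        if layout != self.genome_length:
            raise ConfigError(
                f"gene/intergenic layout tiles {layout} bp, not genome_length="
                f"{self.genome_length}"
            )
        if self.per_bp_recombination < 0 or self.per_bp_mutation < 0:
            raise ConfigError("recombination and mutation rates must be >= 0")
        if self.n_demes < 1 or self.core_size < 1:
            raise ConfigError("need at least one deme and one individual")

    def selfing_rates(self) -> list[float]:
        s = self.selfing_rate_per_deme
        if isinstance(s, (int, float)):
            return [float(s)] * self.n_demes
        rates = [float(x) for x in s]
        if len(rates) != self.n_demes:
            raise ConfigError(
                f"selfing_rate_per_deme has {len(rates)} entries for "
                f"{self.n_demes} demes"
            )
        return rates

    def gene_intervals(self) -> list[tuple[int, int]]:
        """0-based half-open [start, end) intervals of the genic blocks."""
        out = []
        pos = self.intergenic_length
        for _ in range(self.n_genes):
            out.append((pos, pos + self.gene_length))
            pos += self.gene_length + self.intergenic_length
        return out

    def intergenic_intervals(self) -> list[tuple[int, int]]:
        out = []
        pos = 0
        for _ in range(self.n_genes):
            out.append((pos, pos + self.intergenic_length))
            pos += self.intergenic_length + self.gene_length
        out.append((pos, pos + self.intergenic_length))
        return out

    def to_dict(self) -> dict:
        d = asdict(self)
        d["selfing_rate_per_deme"] = self.selfing_rates()
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class FilterConfig:
    """Thresholds of the pooled-LD filtering cascade."""

    min_pair_depth: int = 5          # strict: kept if n > min_pair_depth
    min_maf: float = 0.15            # strict: kept if MAF > min_maf
    maf_mode: str = "both"           # "both" or "any" locus must pass
    min_distance: int = 1
    max_distance: int = 500
    min_estimates_per_region: int = 5
    max_missing_fraction: float = 0.5  # strict: kept if missing < this

    def __post_init__(self) -> None:
        if self.maf_mode not in ("both", "any"):
            raise ConfigError("maf_mode must be 'both' or 'any'")
        if self.min_distance < 1 or self.max_distance < self.min_distance:
            raise ConfigError("invalid distance window")


@dataclass
class PipelineConfig:
    """Everything the end-to-end driver needs."""

    sim: SimConfig = field(default_factory=SimConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    n_individuals_per_pop: int = 2
    zygosity_max_distance: int = 5_000
    hmm_min_run: int = 3
    exclude_old_populations: bool = False
    band_mode: str = "se"            # "se" or "sd" outlier band
    outlier_min_populations: int = 10
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        filters = FilterConfig(**raw.pop("filters", {}))
        return cls(sim=sim, filters=filters, **raw)

    def to_dict(self) -> dict:
        d = {
            "sim": self.sim.to_dict(),
            "filters": asdict(self.filters),
        }
        for k in (
            "n_individuals_per_pop", "zygosity_max_distance", "hmm_min_run",
            "exclude_old_populations", "band_mode",
            "outlier_min_populations", "seed",
        ):
            d[k] = getattr(self, k)
        return d
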