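"""Configuration for the synthetic two-channel CGH generator.

The generator emulates an EST-based two-color genomic-DNA hybridization:
a reference strain and one or more diverged test strains are co-hybridized
to an array on which every EST sequence is represented by a handful of
unique long oligo probes. The tunable knobs are the array geometry
(supercontigs, genes, probes per sequence, unplaced fraction, UTR share),
per-strain divergence (expected mismatches per probe), family- and
region-specific rate multipliers, copy-number events, and the signal model
(baseline log2 intensity, per-channel noise, intensity-dependent dye bias,
attenuation of hybridization signal per mismatch).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["FamilySpec", "CnvEvent", "DyeBias", "SimulationConfig", "ConfigError"]

#: label used for probes that could not be placed on the genome
VIRTUAL_CHROM = "VIRTUAL"


class ConfigError(ValueError):
    """Raised when a simulation configuration field is invalid."""


@dataclass(frozen=True)
class FamilySpec:
    """A gene family: a fraction of sequences sharing a divergence multiplier."""

    label: str
    fraction: float
    rate_multiplier: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ConfigError(f"family {self.label!r}: fraction must be in [0,1], got {self.fraction}")
        if self.rate_multiplier < 0:
            raise ConfigError(f"family {self.label!r}: rate_multiplier must be >= 0")


@dataclass(frozen=True)
class CnvEvent:
    """A copy-number event spanning a contiguous run of genes on one supercontig.

    ``first_gene``/``last_gene`` are inclusive gene indices within the
    supercontig; every probe of every gene in the span gets ``copy_ratio``.
    """

    strain: str
    supercontig: int
    first_gene: int
    last_gene: int
    copy_ratio: float

    def __post_init__(self) -> None:
        if self.copy_ratio <= 0:
            raise ConfigError(f"cnv_event on supercontig {self.supercontig}: copy_ratio must be > 0")
        if self.last_gene < self.first_gene:
            raise ConfigError("cnv_event: last_gene < first_gene")


@dataclass(frozen=True)
class DyeBias:
    """Smooth intensity-dependent additive bias on M as a function of A.

    bias(A) = offset + linear * z + cubic * z**3 with z = (A - center) / scale.
    A mild cubic is the default shape; all-zero coefficients disable it.
    """

    linear: float = 0.15
    cubic: float = 0.10
    center: float = 10.0
    scale: float = 3.0
    offset: float = 0.0

    def __call__(self, a):
        z = (a - self.center) / self.scale
        return self.offset + self.linear * z + self.cubic * z**3


def _default_divergences() -> dict[str, float]:
    # Expected mismatches per 60-mer probe (base rate; UTR/family
    # multipliers apply on top). Strain 2 is nearly identical to the
    # reference; 3 and 4 are diverged at ecotype scale; 5 is an outgroup
    # species divergent enough to break population-based normalization
    # (majority of probes divergent).
    return {"strain2": 0.04, "strain3": 0.35, "strain4": 0.28, "strain5": 3.0}


def _default_families() -> list[FamilySpec]:
    # TE-like families diverge far faster than background, GST-like ones
    # match it. "HV" is a generic hypervariable quarter of the genome,
    # shared across strains: real inter-strain divergence is strongly
    # overdispersed (fast-evolving sequences are fast in every lineage),
    # and without it a single Poisson rate cannot give both a dominant
    # conserved probe population and realistic log2-ratio spread.
    return [
        FamilySpec("TE", 0.020, 8.0),
        FamilySpec("FCP", 0.010, 4.0),
        FamilySpec("GST", 0.010, 1.0),
        FamilySpec("HV", 0.250, 6.0),
    ]


def _default_cnvs() -> list[CnvEvent]:
    # One half-copy deletion and one 2x duplication, each ~11 genes (~44
    # probes at 4 probes/gene) so the 30-probe segment filter can see them.
    return [
        CnvEvent("strain3", 2, 10, 20, 0.5),
        CnvEvent("strain4", 5, 30, 40, 2.0),
    ]


@dataclass
class SimulationConfig:
    """Full parameterization of the synthetic CGH study.

    Defaults describe the emulated array: four unique probes per EST
    sequence, ~3.9% of probes unplaced on the genome (collected on a
    virtual chromosome), 62% of probes in UTRs, UTR probes diverging twice
    as fast as CDS probes, and TE-like families far more variable than the
    background while GST-like families match it.
    """

    n_supercontigs: int = 25
    genes_per_supercontig: int = 60
    probes_per_sequence: int = 4
    frac_unplaced: float = 0.039
    frac_utr_probes: float = 0.62
    strain_divergences: dict[str, float] = field(default_factory=_default_divergences)
    utr_rate_multiplier: float = 2.0
    family_specs: list[FamilySpec] = field(default_factory=_default_families)
    cnv_events: list[CnvEvent] = field(default_factory=_default_cnvs)
    attenuation_per_mismatch: float = 0.4
    attenuation_floor: float = -4.0
    baseline_mean: float = 10.0
    baseline_sd: float = 1.2
    noise_sd: float = 0.212
    dye_bias: DyeBias = field(default_factory=DyeBias)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_supercontigs < 1:
            raise ConfigError("n_supercontigs must be >= 1")
        if self.genes_per_supercontig < 1:
            raise ConfigError("genes_per_supercontig must be >= 1")
        if self.probes_per_sequence < 1:
            raise ConfigError("probes_per_sequence must be >= 1")
        if not 0.0 <= self.frac_unplaced < 1.0:
            raise ConfigError(f"frac_unplaced must be in [0,1), got {self.frac_unplaced}")
        if not 0.0 <= self.frac_utr_probes <= 1.0:
            raise ConfigError(f"frac_utr_probes must be in [0,1], got {self.frac_utr_probes}")
        for strain, d in self.strain_divergences.items():
            if d < 0:
                raise ConfigError(f"strain_divergences[{strain!r}] must be >= 0, got {d}")
        if self.utr_rate_multiplier < 1.0:
            raise ConfigError("utr_rate_multiplier must be >= 1")
        if sum(f.fraction for f in self.family_specs) > 1.0 + 1e-9:
            raise ConfigError("family_specs fractions sum to more than 1")
        if self.attenuation_per_mismatch < 0:
            raise ConfigError("attenuation_per_mismatch must be >= 0")
        if self.attenuation_floor > 0:
            raise ConfigError("attenuation_floor must be <= 0")
        if self.noise_sd < 0 or self.baseline_sd < 0:
            raise ConfigError("noise_sd and baseline_sd must be >= 0")

    @property
    def n_sequences(self) -> int:
        return self.n_supercontigs * self.genes_per_supercontig

    @property
    def n_probes(self) -> int:
        return self.n_sequences * self.probes_per_sequence

    def strains(self) -> list[str]:
        return list(self.strain_divergences)
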