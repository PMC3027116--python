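"""Synthetic two-channel gDNA hybridization generator with known ground truth.

The generative model, per probe:

* mismatches ``m ~ Poisson(lambda)`` with
  ``lambda = strain_divergence * utr_mult (if UTR) * family_mult (if tagged)``;
* copy ratio ``c`` is 1 except inside configured CNV events;
* true expected log2-ratio
  ``M = log2(c) - min(attenuation_per_mismatch * m, |attenuation_floor|)``;
* reference channel log2-intensity = baseline + noise,
  test channel = baseline + M + dye_bias(A) + noise, with independent
  Gaussian noise per channel and a probe-specific baseline drawn once.

Intensities are persisted on the linear scale; everything downstream works
in log2. All draws flow from a single seed, so a dataset is reproducible
byte-for-byte.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .arrayio import CDS, UTR, ArrayDesign, PairTable
from .config import VIRTUAL_CHROM, ConfigError, SimulationConfig

__all__ = ["GroundTruth", "build_design", "simulate_strain", "simulate_hybridization", "write_truth", "read_truth"]

#: genomic spacing (bp) between consecutive probes of a supercontig
_PROBE_SPACING = 500


@dataclass
class GroundTruth:
    """Per-probe generative truth for one strain."""

    strain: str
    table: pd.DataFrame  # probe_id, mismatches, copy_ratio, expected_M

    def __len__(self) -> int:
        return len(self.table)

    @property
    def expected_m(self) -> np.ndarray:
        return self.table["expected_M"].to_numpy(float)


def _seed_for(config: SimulationConfig, *key: object) -> np.random.Generator:
    """Independent, reproducible stream for one generator stage.

    Uses a CRC of the key so streams are stable across processes (unlike
    built-in ``hash``, which is salted).
    """
    tag = zlib.crc32(repr(key).encode()) % (2**31)
    ss = np.random.SeedSequence([config.seed, tag])
    return np.random.default_rng(ss)


def build_design(config: SimulationConfig) -> ArrayDesign:
    """Generate the probe catalog.

    Probes are emitted in genomic order within each supercontig; each gene
    (EST sequence) carries exactly ``probes_per_sequence`` probes. A
    fraction ``frac_unplaced`` of probes is reassigned to the virtual
    chromosome in random order. Family tags partition sequences by the
    configured fractions; CDS/UTR labels are drawn i.i.d. per probe.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n_seq = config.n_sequences
    k = config.probes_per_sequence

    sctg = np.repeat(np.arange(config.n_supercontigs), config.genes_per_supercontig * k)
    gene = np.repeat(np.arange(n_seq), k)
    probe_in_gene = np.tile(np.arange(k), n_seq)
    probe_id = np.array([f"P{g:05d}_{i}" for g, i in zip(gene, probe_in_gene)])
    seq_id = np.array([f"SEQ{g:05d}" for g in gene])
    chrom = np.array([f"Sctg_{s:02d}" for s in sctg])
    # position within supercontig, evenly spaced, in genomic order
    idx_in_sctg = np.arange(len(gene)) % (config.genes_per_supercontig * k)
    position = idx_in_sctg * _PROBE_SPACING

    region = np.where(rng.random(len(probe_id)) < config.frac_utr_probes, UTR, CDS)

    # family labels per sequence: contiguous blocks of a shuffled sequence order
    fam_of_seq = np.array([""] * n_seq, dtype=object)
    order = rng.permutation(n_seq)
    start = 0
    for spec in config.family_specs:
        n_fam = int(round(spec.fraction * n_seq))
        fam_of_seq[order[start : start + n_fam]] = spec.label
        start += n_fam
    families = fam_of_seq[gene]

    # unplaced probes -> VIRTUAL chromosome, random order
    n_virtual = int(round(config.frac_unplaced * len(probe_id)))
    virtual_idx = rng.choice(len(probe_id), size=n_virtual, replace=False)
    chrom = chrom.astype(object)
    chrom[virtual_idx] = VIRTUAL_CHROM
    vorder = rng.permutation(n_virtual)
    position = position.astype(int).copy()
    position[virtual_idx] = vorder * _PROBE_SPACING

    return ArrayDesign(
        pd.DataFrame(
            {
                "probe_id": probe_id,
                "seq_id": seq_id,
                "region": region,
                "chrom": chrom,
                "position": position,
                "families": families,
            }
        )
    )


def _family_multiplier(config: SimulationConfig, labels: pd.Series) -> np.ndarray:
    mult = {spec.label: spec.rate_multiplier for spec in config.family_specs}
    return np.array([mult.get(f, 1.0) if f else 1.0 for f in labels])


def simulate_strain(design: ArrayDesign, config: SimulationConfig, strain: str) -> GroundTruth:
    """Draw per-probe mismatch counts and copy ratios for one test strain."""
    if strain not in config.strain_divergences:
        raise ConfigError(
            f"unknown strain {strain!r}; configured strains: {sorted(config.strain_divergences)}"
        )
    rng = _seed_for(config, "strain", strain)
    t = design.table
    lam = np.full(len(t), config.strain_divergences[strain], dtype=float)
    lam[(t["region"] == UTR).to_numpy()] *= config.utr_rate_multiplier
    lam *= _family_multiplier(config, t["families"])
    mism = rng.poisson(lam)

    copy_ratio = np.ones(len(t))
    gene_index = t["seq_id"].str.removeprefix("SEQ").astype(int) % config.genes_per_supercontig
    sctg_index = t["chrom"].str.removeprefix("Sctg_")
    for ev in config.cnv_events:
        if ev.strain != strain:
            continue
        on_sctg = (sctg_index == f"{ev.supercontig:02d}").to_numpy()
        in_span = (gene_index >= ev.first_gene).to_numpy() & (gene_index <= ev.last_gene).to_numpy()
        copy_ratio[on_sctg & in_span] = ev.copy_ratio

    attn = np.minimum(config.attenuation_per_mismatch * mism, abs(config.attenuation_floor))
    expected_m = np.log2(copy_ratio) - attn
    return GroundTruth(
        strain=strain,
        table=pd.DataFrame(
            {
                "probe_id": t["probe_id"].to_numpy(),
                "mismatches": mism,
                "copy_ratio": copy_ratio,
                "expected_M": expected_m,
            }
        ),
    )


def simulate_hybridization(
    design: ArrayDesign, truth: GroundTruth, config: SimulationConfig
) -> tuple[PairTable, PairTable]:
    """Produce (reference channel, test channel) pair tables for one strain.

    Both channels share a probe-specific baseline; the test channel adds the
    true M, an intensity-dependent dye bias evaluated at the baseline, and
    its own noise. Intensities are linear-scale 2**(log2 value).
    """
    if len(truth) != len(design) or not (truth.table["probe_id"].to_numpy() == design.table["probe_id"].to_numpy()).all():
        raise ValueError("ground truth and design describe different probe sets")
    rng = _seed_for(config, "hyb", truth.strain)
    n = len(design)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, n)
    noise_ref = rng.normal(0.0, config.noise_sd, n)
    noise_test = rng.normal(0.0, config.noise_sd, n)
    bias = config.dye_bias(baseline) if config.dye_bias is not None else 0.0
    log_ref = baseline + noise_ref
    log_test = baseline + truth.expected_m + bias + noise_test
    cols = {"probe_id": design.table["probe_id"].to_numpy(), "seq_id": design.table["seq_id"].to_numpy()}
    ref = PairTable(pd.DataFrame({**cols, "intensity": 2.0**log_ref}), channel="Cy5", strain="reference")
    test = PairTable(pd.DataFrame({**cols, "intensity": 2.0**log_test}), channel="Cy3", strain=truth.strain)
    return ref, test


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# strain={truth.strain}\n")
        fh.write("probe_id\tmismatches\tcopy_ratio\texpected_M\n")
        for pid, m, c, em in zip(
            truth.table["probe_id"], truth.table["mismatches"], truth.table["copy_ratio"], truth.table["expected_M"]
        ):
            fh.write(f"{pid}\t{int(m)}\t{c:g}\t{em:.6f}\n")


def read_truth(path: str | Path) -> GroundTruth:
    strain = ""
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for tok in first[1:].split():
                if tok.startswith("strain="):
                    strain = tok.split("=", 1)[1]
    df = pd.read_csv(path, sep="\t", comment="#")
    return GroundTruth(strain=strain, table=df)
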