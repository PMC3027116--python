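"""Probe masking and sequence-level conservation classification.

A probe is masked for a strain when its normalized |M| exceeds a chosen
threshold (stringent 0.5 for direct cross-strain comparisons, 1.0 when
only within-strain contrasts are planned). Exceedance is strict: |M|
exactly at the threshold is kept.

At the sequence level (each EST contig/singleton is represented by four
probes), a sequence is *conserved* for a strain when none of its probes
has |M| > 1, *variable* when two or more do, and *intermediate*
otherwise. Cross-strain intersections of the conserved sets give the
core-conserved sequences and the full Venn decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .arrayio import ArrayDesign, MaskList
from .normalize import RatioTrack, histogram_m

__all__ = [
    "CONSERVED",
    "VARIABLE",
    "INTERMEDIATE",
    "ClassificationTable",
    "StrainSummary",
    "VennReport",
    "percent",
    "build_mask_list",
    "classify_sequence",
    "classify_track",
    "retained_sequences",
    "core_conserved",
    "strain_summary",
]

CONSERVED = "conserved"
VARIABLE = "variable"
INTERMEDIATE = "intermediate"


def percent(k: float, n: float, decimals: int = 0) -> float:
    """Percentage with half-up rounding (report convention)."""
    if n == 0:
        return float("nan")
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(100.0 * k / n).quantize(q, rounding=ROUND_HALF_UP))


def build_mask_list(track: RatioTrack, threshold: float) -> MaskList:
    """Probes whose normalized |M| strictly exceeds the threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    exceed = np.abs(track.m) > threshold
    probes = frozenset(track.table.loc[exceed, "probe_id"])
    return MaskList(threshold=threshold, strain=track.strain, probe_ids=probes)


def classify_sequence(probe_ms) -> str:
    """Conservation status of one sequence from its probes' M values.

    conserved: no probe with |M| > 1; variable: >= 2 probes with |M| > 1;
    intermediate: exactly one. Exceedance is strict.
    """
    ms = np.asarray(list(probe_ms), float)
    if ms.size == 0:
        raise ValueError("classify_sequence needs at least one probe")
    n_exc = int((np.abs(ms) > 1.0).sum())
    if n_exc == 0:
        return CONSERVED
    if n_exc >= 2:
        return VARIABLE
    return INTERMEDIATE


@dataclass
class ClassificationTable:
    """Per-sequence conservation status for one strain."""

    strain: str
    table: pd.DataFrame  # seq_id, status, n_probes, n_exceeding, all_probes_cds

    def conserved_set(self) -> frozenset:
        return frozenset(self.table.loc[self.table["status"] == CONSERVED, "seq_id"])

    def variable_set(self) -> frozenset:
        return frozenset(self.table.loc[self.table["status"] == VARIABLE, "seq_id"])

    def status_counts(self) -> dict[str, int]:
        return self.table["status"].value_counts().to_dict()


def classify_track(track: RatioTrack, design: ArrayDesign, threshold: float = 1.0) -> ClassificationTable:
    """Classify every sequence of the design from one strain's track."""
    t = design.table.merge(track.table[["probe_id", "M"]], on="probe_id", how="inner")
    exc = (t["M"].abs() > threshold).astype(int)
    grp = t.assign(exc=exc, cds=(t["region"] == "CDS").astype(int)).groupby("seq_id", sort=True)
    agg = grp.agg(n_probes=("probe_id", "size"), n_exceeding=("exc", "sum"), n_cds=("cds", "sum")).reset_index()
    status = np.where(agg["n_exceeding"] == 0, CONSERVED, np.where(agg["n_exceeding"] >= 2, VARIABLE, INTERMEDIATE))
    out = pd.DataFrame(
        {
            "seq_id": agg["seq_id"],
            "status": status,
            "n_probes": agg["n_probes"],
            "n_exceeding": agg["n_exceeding"],
            "all_probes_cds": agg["n_cds"] == agg["n_probes"],
        }
    )
    return ClassificationTable(strain=track.strain, table=out)


def retained_sequences(
    mask: MaskList, design: ArrayDesign, min_probes_per_seq: int = 1
) -> tuple[frozenset, float]:
    """Sequences with at least ``min_probes_per_seq`` unmasked probes.

    Returns the retained set and its share of all sequences (fraction).
    """
    t = design.table
    unmasked = ~t["probe_id"].isin(mask.probe_ids)
    per_seq = unmasked.groupby(t["seq_id"]).sum()
    retained = frozenset(per_seq.index[per_seq >= min_probes_per_seq])
    return retained, len(retained) / design.n_sequences


@dataclass
class VennReport:
    """Venn decomposition of conserved sequences across strains."""

    strains: list[str]
    regions: dict[tuple[bool, ...], int]  # membership tuple (per strain) -> count
    core: frozenset
    all_cds_share: dict[tuple[bool, ...], float] = field(default_factory=dict)

    def region_count(self, *member_strains: str) -> int:
        key = tuple(s in member_strains for s in self.strains)
        return self.regions.get(key, 0)


def core_conserved(
    classifications: dict[str, ClassificationTable], design: ArrayDesign | None = None
) -> VennReport:
    """Intersect conserved sequence sets across strains.

    All classifications must cover the same sequence universe. Returns all
    2^k - 1 non-empty-membership Venn region counts, the all-strains core
    set, and per region the share of sequences whose probes are all CDS
    (when a design is supplied).
    """
    strains = sorted(classifications)
    if len(strains) < 2:
        raise ValueError("core_conserved needs classifications for at least 2 strains")
    universes = [frozenset(classifications[s].table["seq_id"]) for s in strains]
    if any(u != universes[0] for u in universes[1:]):
        raise ValueError("classification tables cover different sequence universes")
    conserved = {s: classifications[s].conserved_set() for s in strains}

    all_cds: dict[str, bool] = {}
    if design is not None:
        cds = design.table.assign(is_cds=design.table["region"] == "CDS").groupby("seq_id")["is_cds"].all()
        all_cds = cds.to_dict()

    regions: dict[tuple[bool, ...], int] = {}
    cds_counts: dict[tuple[bool, ...], int] = {}
    for seq in universes[0]:
        key = tuple(seq in conserved[s] for s in strains)
        if not any(key):
            continue
        regions[key] = regions.get(key, 0) + 1
        if all_cds.get(seq, False):
            cds_counts[key] = cds_counts.get(key, 0) + 1
    core = frozenset.intersection(*conserved.values())
    share = {k: cds_counts.get(k, 0) / n for k, n in regions.items()}
    return VennReport(strains=strains, regions=regions, core=core, all_cds_share=share)


@dataclass
class StrainSummary:
    strain: str
    sd: float
    sd_1dp: float
    histogram: pd.DataFrame = field(repr=False)
    n_probes: int = 0
    n_gt_half: int = 0
    n_gt_one: int = 0

    @property
    def pct_gt_half(self) -> float:
        return percent(self.n_gt_half, self.n_probes, decimals=2)

    @property
    def pct_gt_one(self) -> float:
        return percent(self.n_gt_one, self.n_probes, decimals=2)


def strain_summary(track: RatioTrack, bin_width: float = 0.2) -> StrainSummary:
    """Spread of a strain's normalized log2-ratios.

    Reports the SD at full precision and rounded to one decimal (report
    convention), the 0.2-wide M histogram, and how many probes exceed the
    0.5 and 1.0 masking thresholds.
    """
    m = track.m
    sd = float(np.std(m, ddof=1)) if m.size > 1 else 0.0
    sd_1dp = float(Decimal(sd).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    return StrainSummary(
        strain=track.strain,
        sd=sd,
        sd_1dp=sd_1dp,
        histogram=histogram_m(m, bin_width),
        n_probes=int(m.size),
        n_gt_half=int((np.abs(m) > 0.5).sum()),
        n_gt_one=int((np.abs(m) > 1.0).sum()),
    )
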