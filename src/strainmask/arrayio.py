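"""Probe-level file formats and containers.

Three tab-separated dialects are handled:

* **pair** files — per-channel raw probe intensities (``PROBE_ID``,
  ``SEQ_ID``, ``PM``), one file per dye channel, ``#``-comment header
  carrying channel/strain metadata. The full scanner header (IMAGE_ID,
  MATCH_INDEX, X, Y, ...) is accepted on read; the writer emits the
  minimal form.
* **pos** files — probe placement on genomic supercontigs
  (``probe_id``, ``chrom``, ``position``; 1-based positions on disk).
  Probes absent from the pos file are collected on a virtual chromosome.
* **annotation** files — probe → EST sequence, CDS/UTR region, and
  comma-joined family tags.

Plus mask lists (one probe per line) and the pre-normalization probe
removal utility `apply_mask`.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import VIRTUAL_CHROM

__all__ = [
    "ArrayDesign",
    "PairTable",
    "MaskList",
    "PairFileError",
    "read_pair",
    "write_pair",
    "read_pos",
    "read_annotation",
    "write_pos",
    "write_annotation",
    "read_mask",
    "write_mask",
    "apply_mask",
]

log = logging.getLogger(__name__)

CDS = "CDS"
UTR = "UTR"


class PairFileError(ValueError):
    """Malformed probe-level file."""


@dataclass
class ArrayDesign:
    """Probe catalog: probe → sequence, region, genomic placement, families.

    ``table`` columns: probe_id, seq_id, region (CDS/UTR), chrom, position,
    families (comma-joined labels, '' for none). Probes with
    ``chrom == VIRTUAL`` are unplaced; their positions carry no ordering
    guarantee.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"probe_id", "seq_id", "region", "chrom", "position", "families"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"ArrayDesign table missing columns: {sorted(missing)}")
        if self.table["probe_id"].duplicated().any():
            dup = self.table.loc[self.table["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise ValueError(f"duplicate probe_id in design: {dup!r}")
        bad = ~self.table["region"].isin([CDS, UTR])
        if bad.any():
            raise ValueError(f"invalid region labels: {sorted(self.table.loc[bad, 'region'].unique())}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def probe_ids(self) -> pd.Series:
        return self.table["probe_id"]

    @property
    def n_sequences(self) -> int:
        return self.table["seq_id"].nunique()

    def virtual_fraction(self) -> float:
        return float((self.table["chrom"] == VIRTUAL_CHROM).mean())

    def family_probes(self, label: str) -> pd.Series:
        """Probe IDs whose sequence carries the family tag ``label``."""
        has = self.table["families"].str.split(",").apply(lambda fs: label in fs)
        return self.table.loc[has, "probe_id"]

    def placed(self) -> pd.DataFrame:
        """Placed probes sorted by (chrom, position); VIRTUAL excluded."""
        t = self.table[self.table["chrom"] != VIRTUAL_CHROM]
        return t.sort_values(["chrom", "position"], kind="mergesort").reset_index(drop=True)


@dataclass
class PairTable:
    """One channel's raw probe intensities (linear scale, > 0)."""

    table: pd.DataFrame  # columns: probe_id, seq_id, intensity
    channel: str = "Cy3"
    strain: str = ""

    def __post_init__(self) -> None:
        required = {"probe_id", "intensity"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"PairTable missing columns: {sorted(missing)}")
        if "seq_id" not in self.table.columns:
            self.table = self.table.assign(seq_id="")
        dup = self.table["probe_id"].duplicated()
        if dup.any():
            raise PairFileError(
                f"duplicate probe_id {self.table.loc[dup, 'probe_id'].iloc[0]!r} in pair table"
            )
        if (self.table["intensity"] <= 0).any():
            i = int(np.argmax(self.table["intensity"].to_numpy() <= 0))
            raise PairFileError(f"non-positive intensity at row {i} (probe {self.table['probe_id'].iat[i]!r})")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def probe_ids(self) -> pd.Series:
        return self.table["probe_id"]

    @property
    def intensities(self) -> np.ndarray:
        return self.table["intensity"].to_numpy(float)


@dataclass
class MaskList:
    """Probes exceeding an absolute log2-ratio threshold in one strain."""

    threshold: float
    strain: str
    probe_ids: frozenset = field(default_factory=frozenset)

    def __len__(self) -> int:
        return len(self.probe_ids)


# ---------------------------------------------------------------------------
# pair files

_PAIR_ALIASES = {"probe_id": ["PROBE_ID", "probe_id"], "seq_id": ["SEQ_ID", "seq_id"], "intensity": ["PM", "SIGNAL", "intensity"]}


def _find_column(header: list[str], aliases: list[str], path) -> str:
    for a in aliases:
        if a in header:
            return a
    raise PairFileError(f"{path}: missing required column (one of {aliases})")


def read_pair(path: str | Path) -> PairTable:
    """Read a pair-format intensity file.

    Accepts the full scanner header but requires only the probe-ID,
    sequence-ID and signal columns. ``# channel=`` / ``# strain=`` comment
    metadata is honored.
    """
    path = Path(path)
    channel, strain = "Cy3", ""
    text = path.read_text()
    body_start = 0
    for line in text.splitlines(keepends=True):
        if not line.startswith("#"):
            break
        for tok in line[1:].split():
            if tok.startswith("channel="):
                channel = tok.split("=", 1)[1]
            elif tok.startswith("strain="):
                strain = tok.split("=", 1)[1]
        body_start += len(line)
    df = pd.read_csv(io.StringIO(text[body_start:]), sep="\t", dtype=str)
    header = list(df.columns)
    cols = {k: _find_column(header, v, path) for k, v in _PAIR_ALIASES.items()}
    out = pd.DataFrame(
        {
            "probe_id": df[cols["probe_id"]],
            "seq_id": df[cols["seq_id"]],
        }
    )
    try:
        out["intensity"] = df[cols["intensity"]].astype(float)
    except ValueError as e:
        raise PairFileError(f"{path}: malformed numeric signal value ({e})") from None
    bad = ~np.isfinite(out["intensity"]) | (out["intensity"] <= 0)
    if bad.any():
        i = int(np.argmax(bad.to_numpy()))
        raise PairFileError(f"{path}: non-positive or non-finite intensity at data line {i + 1}")
    return PairTable(out, channel=channel, strain=strain)


def write_pair(table: PairTable, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# channel={table.channel} strain={table.strain}\n")
        fh.write("PROBE_ID\tSEQ_ID\tPM\n")
        for pid, sid, pm in zip(table.table["probe_id"], table.table["seq_id"], table.table["intensity"]):
            fh.write(f"{pid}\t{sid}\t{pm:.6f}\n")


# ---------------------------------------------------------------------------
# pos / annotation files


def read_pos(path: str | Path) -> pd.DataFrame:
    """Read a probe-placement table (probe_id, chrom, position; 1-based)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"probe_id": str, "chrom": str})
    for col in ("probe_id", "chrom", "position"):
        if col not in df.columns:
            raise PairFileError(f"{path}: missing column {col!r}")
    try:
        # internal coordinates are 0-based
        df["position"] = df["position"].astype(int) - 1
    except ValueError as e:
        raise PairFileError(f"{path}: malformed position ({e})") from None
    if (df["position"] < 0).any():
        raise PairFileError(f"{path}: positions must be >= 1 on disk")
    return df


def write_pos(design: ArrayDesign, path: str | Path) -> None:
    """Write placed probes only; unplaced probes are simply absent."""
    placed = design.table[design.table["chrom"] != VIRTUAL_CHROM]
    with open(path, "w") as fh:
        fh.write("# positions are 1-based\n")
        fh.write("probe_id\tchrom\tposition\n")
        for pid, chrom, p in zip(placed["probe_id"], placed["chrom"], placed["position"]):
            fh.write(f"{pid}\t{chrom}\t{int(p) + 1}\n")


def write_annotation(design: ArrayDesign, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("probe_id\tseq_id\tregion\tfamilies\n")
        for pid, sid, reg, fams in zip(
            design.table["probe_id"], design.table["seq_id"], design.table["region"], design.table["families"]
        ):
            fh.write(f"{pid}\t{sid}\t{reg}\t{fams}\n")


def read_annotation(path: str | Path, pos: pd.DataFrame | None = None) -> ArrayDesign:
    """Build an ArrayDesign from an annotation table plus optional placements.

    Probes absent from ``pos`` land on the virtual chromosome; the fraction
    of such probes is logged. Probes present in ``pos`` but missing from the
    annotation raise a warning with a count.
    """
    ann = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna({"families": ""})
    for col in ("probe_id", "seq_id", "region"):
        if col not in ann.columns:
            raise PairFileError(f"{path}: missing column {col!r}")
    if "families" not in ann.columns:
        ann["families"] = ""
    ann["families"] = ann["families"].fillna("")
    if pos is None:
        chrom = pd.Series(VIRTUAL_CHROM, index=ann.index)
        position = pd.Series(range(len(ann)), index=ann.index)
    else:
        unknown = ~pos["probe_id"].isin(ann["probe_id"])
        if unknown.any():
            warnings.warn(
                f"{int(unknown.sum())} probes in pos file are absent from the annotation",
                stacklevel=2,
            )
        placed = pos.set_index("probe_id")
        chrom = ann["probe_id"].map(placed["chrom"]).fillna(VIRTUAL_CHROM)
        position = ann["probe_id"].map(placed["position"])
        # virtual probes get arbitrary consecutive positions (random order upstream)
        position = position.fillna(pd.Series(range(len(ann)), index=ann.index)).astype(int)
    design = ArrayDesign(
        pd.DataFrame(
            {
                "probe_id": ann["probe_id"],
                "seq_id": ann["seq_id"],
                "region": ann["region"],
                "chrom": chrom,
                "position": position.astype(int),
                "families": ann["families"],
            }
        )
    )
    vfrac = design.virtual_fraction()
    log.info("read_annotation: %d probes, %.4f unplaced (virtual)", len(design), vfrac)
    return design


# ---------------------------------------------------------------------------
# mask lists


def write_mask(mask: MaskList, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# threshold={mask.threshold} strain={mask.strain}\n")
        for pid in sorted(mask.probe_ids):
            fh.write(f"{pid}\n")


def read_mask(path: str | Path) -> MaskList:
    threshold, strain = float("nan"), ""
    probes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if tok.startswith("threshold="):
                        threshold = float(tok.split("=", 1)[1])
                    elif tok.startswith("strain="):
                        strain = tok.split("=", 1)[1]
            else:
                probes.append(line)
    return MaskList(threshold=threshold, strain=strain, probe_ids=frozenset(probes))


def apply_mask(pair: PairTable, mask: MaskList) -> PairTable:
    """Remove masked probes from a raw pair table, prior to normalization.

    Rows whose probe_id is in the mask are dropped; input order is
    preserved. Mask entries absent from the table produce a warning, not an
    error.
    """
    present = pair.table["probe_id"].isin(mask.probe_ids)
    n_absent = len(mask.probe_ids) - int(present.sum())
    if n_absent > 0:
        warnings.warn(f"{n_absent} masked probes not present in pair table", stacklevel=2)
    out = pair.table[~present].reset_index(drop=True)
    log.info("apply_mask: removed %d of %d probes", int(present.sum()), len(pair))
    return PairTable(out, channel=pair.channel, strain=pair.strain)
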