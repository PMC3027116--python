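"""Two-color ratio computation and population-based lowess normalization.

Raw per-probe values are M = log2(test/reference) and
A = (log2 test + log2 reference)/2, with no background subtraction.

Normalization follows the population-lowess idea for samples where copy
number or sequence divergence breaks the usual "most probes are equal"
assumption: rather than fitting the intensity-dependent trend on all
probes, the probes are sorted by M, the sorted sequence is segmented by
circular binary segmentation (change-point significance ``cp_alpha``),
adjacent segments with similar means are merged, and the most populous
segment — the dominant signal population — is the only one used to fit
the robust lowess of M on A. The fitted curve is then subtracted from
every probe. This keeps large divergent or copy-altered minorities from
dragging the normalization curve toward themselves.

The procedure is a reconstruction of the published one-line description
of population lowess (population = dominant segment of the sorted-M
change-point segmentation); the population-selection step is pluggable
via ``population_indices``.

A post-hoc diagnostic (`normalization_bias_check`) flags tracks whose
normalized M histogram does not peak near zero — the failure mode of any
population-based normalization when the majority of probes are divergent,
as with a sufficiently distant outgroup strain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .arrayio import PairTable
from .segment import cbs_segment

__all__ = [
    "RatioTrack",
    "LowessCurve",
    "BiasDiagnostic",
    "raw_log2",
    "lowess_fit",
    "population_indices",
    "poplowess_normalize",
    "normalization_bias_check",
    "histogram_m",
]


@dataclass
class RatioTrack:
    """Per-probe M/A values for one strain, raw or normalized."""

    table: pd.DataFrame  # probe_id, M, A [, M_raw, in_population]
    strain: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        missing = {"probe_id", "M", "A"} - set(self.table.columns)
        if missing:
            raise ValueError(f"RatioTrack missing columns: {sorted(missing)}")
        if not np.isfinite(self.table["M"].to_numpy(float)).all():
            raise ValueError("RatioTrack M values must be finite")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def m(self) -> np.ndarray:
        return self.table["M"].to_numpy(float)

    @property
    def a(self) -> np.ndarray:
        return self.table["A"].to_numpy(float)


def raw_log2(test: PairTable, ref: PairTable) -> RatioTrack:
    """Raw M/A track from two channels (no background subtraction)."""
    test_ids = test.table["probe_id"]
    ref_ids = ref.table["probe_id"]
    if len(test) != len(ref) or set(test_ids) != set(ref_ids):
        discordant = sorted(set(test_ids).symmetric_difference(ref_ids))[:10]
        raise ValueError(f"probe sets differ between channels; first discordant IDs: {discordant}")
    ref_aligned = ref.table.set_index("probe_id").loc[test_ids, "intensity"].to_numpy(float)
    lt = np.log2(test.intensities)
    lr = np.log2(ref_aligned)
    return RatioTrack(
        pd.DataFrame({"probe_id": test_ids.to_numpy(), "M": lt - lr, "A": 0.5 * (lt + lr)}),
        strain=test.strain,
        normalized=False,
    )


@dataclass
class LowessCurve:
    """A fitted M̂(A) curve, evaluated by linear interpolation."""

    x: np.ndarray
    y: np.ndarray
    fallback_median: bool = False

    def __call__(self, a) -> np.ndarray:
        return np.interp(a, self.x, self.y)


def lowess_fit(m: np.ndarray, a: np.ndarray, span: float = 1.0 / 3.0, iterations: int = 4, delta: float = 0.1) -> LowessCurve:
    """Robust locally weighted regression of M on A.

    ``span`` is the smoother span (fraction of points per local fit),
    ``iterations`` the robustifying reweighting passes, and ``delta`` the
    interpolation shortcut distance on the A axis, in A units.
    Degenerate input (all A identical) falls back to the median of M,
    flagged on the returned curve.
    """
    m = np.asarray(m, float)
    a = np.asarray(a, float)
    if m.size < 10:
        raise ValueError("lowess_fit requires at least 10 probes")
    if not 0.0 < span <= 1.0:
        raise ValueError("span must be in (0,1]")
    if np.ptp(a) == 0:
        return LowessCurve(x=np.array([a[0] - 1, a[0] + 1]), y=np.full(2, np.median(m)), fallback_median=True)
    fitted = _sm_lowess(m, a, frac=span, it=iterations, delta=delta, return_sorted=True)
    x, y = fitted[:, 0], fitted[:, 1]
    # collapse duplicate x for interpolation
    x, idx = np.unique(x, return_index=True)
    return LowessCurve(x=x, y=y[idx])


def population_indices(
    m: np.ndarray,
    cp_alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = 0,
    max_seg_points: int = 1000,
    gap_factor: float = 20.0,
) -> np.ndarray:
    """Indices of the dominant signal population.

    Sorts M, segments the sorted sequence with CBS at significance
    ``cp_alpha``, merges adjacent segments belonging to the same smooth
    population (CBS on sorted order statistics otherwise shreds a single
    population into shells), and returns the original indices of the most
    populous merged segment. A segment boundary is kept — segments stay
    apart — only where the sorted values show an empirical density gap:
    the spacing across the boundary exceeds ``gap_factor`` times the
    median point spacing. Ties on size go to the segment whose median M
    is closest to 0. Sequences longer than ``max_seg_points`` are
    uniformly decimated for the segmentation step and boundaries scaled
    back.
    """
    m = np.asarray(m, float)
    n = m.size
    order = np.argsort(m, kind="mergesort")
    ms = m[order]
    step = max(1, int(np.ceil(n / max_seg_points)))
    sub = ms[::step]
    segments = cbs_segment(sub, alpha=cp_alpha, n_perm=n_perm, seed=seed, chrom="sortedM")
    bounds = [s.start_index * step for s in segments] + [n]
    bounds[-1] = n
    # merge adjacent segments unless a true density gap separates them;
    # CBS may place a boundary a few points off the gap, so look for the
    # widest spacing in a small neighborhood and split there
    spacing = np.diff(ms)
    med_spacing = float(np.median(spacing)) + 1e-15 if n > 1 else 1e-15
    halo = 3 * step + 2
    merged = [(bounds[0], bounds[1])]
    for lo, hi in zip(bounds[1:-1], bounds[2:]):
        w0, w1 = max(lo - halo, 1), min(lo + halo, n - 1)
        local = spacing[w0 - 1 : w1]
        k = int(np.argmax(local))
        if local[k] > gap_factor * med_spacing:
            cut = min(max(w0 + k, merged[-1][0] + 1), hi - 1)
            merged[-1] = (merged[-1][0], cut)
            merged.append((cut, hi))
        else:
            merged[-1] = (merged[-1][0], hi)
    sizes = [hi - lo for lo, hi in merged]
    best = max(
        range(len(merged)),
        key=lambda i: (sizes[i], -abs(float(np.median(ms[merged[i][0] : merged[i][1]])))),
    )
    lo, hi = merged[best]
    return order[lo:hi]


def poplowess_normalize(
    track: RatioTrack,
    cp_alpha: float = 0.05,
    span: float = 1.0 / 3.0,
    iterations: int = 4,
    delta: float = 0.1,
    n_perm: int = 1000,
    seed: int | None = 0,
) -> tuple[RatioTrack, frozenset]:
    """Normalize M by a lowess of M on A fitted on the dominant population.

    Returns the normalized track (with ``M_raw`` and ``in_population``
    columns) and the population's probe IDs. A population smaller than 20%
    of the probes triggers a prominent diagnostic warning but the
    normalization proceeds.
    """
    if len(track) < 100:
        raise ValueError("poplowess_normalize requires at least 100 probes")
    m, a = track.m, track.a
    pop = population_indices(m, cp_alpha=cp_alpha, n_perm=n_perm, seed=seed)
    if pop.size < 0.2 * m.size:
        warnings.warn(
            f"normalization population is only {pop.size}/{m.size} probes "
            "(< 20%); the dominant-population assumption looks violated",
            stacklevel=2,
        )
    curve = lowess_fit(m[pop], a[pop], span=span, iterations=iterations, delta=delta)
    m_norm = m - curve(a)
    out = track.table.copy()
    out["M_raw"] = m
    out["M"] = m_norm
    in_pop = np.zeros(len(out), dtype=bool)
    in_pop[pop] = True
    out["in_population"] = in_pop
    pop_ids = frozenset(out.loc[in_pop, "probe_id"])
    return RatioTrack(out, strain=track.strain, normalized=True), pop_ids


# ---------------------------------------------------------------------------
# diagnostics


def histogram_m(m: np.ndarray, bin_width: float = 0.2) -> pd.DataFrame:
    """Histogram of M with bins centered on multiples of ``bin_width``."""
    m = np.asarray(m, float)
    k_lo = int(np.floor(m.min() / bin_width + 0.5))
    k_hi = int(np.floor(m.max() / bin_width + 0.5))
    centers = np.arange(k_lo, k_hi + 1) * bin_width
    edges = np.concatenate([centers - bin_width / 2, [centers[-1] + bin_width / 2]])
    counts, _ = np.histogram(m, bins=edges)
    return pd.DataFrame({"center": centers, "count": counts})


@dataclass
class BiasDiagnostic:
    mode: float
    warn: bool
    histogram: pd.DataFrame = field(repr=False)


def normalization_bias_check(track: RatioTrack, bin_width: float = 0.2, warn_mode: float = 0.5) -> BiasDiagnostic:
    """Flag a normalized track whose M histogram does not peak near zero.

    The modal bin of a well-normalized gDNA track sits at M = 0; a mode at
    |M| >= ``warn_mode`` indicates that too many probes were divergent for
    population-based normalization to find the true null population.
    """
    hist = histogram_m(track.m, bin_width)
    mode = float(hist.loc[hist["count"].idxmax(), "center"])
    warn = abs(mode) >= warn_mode
    if warn:
        warnings.warn(
            f"normalized M histogram peaks at {mode:+.2f}, not 0: "
            "normalization likely biased (too many divergent probes)",
            stacklevel=2,
        )
    return BiasDiagnostic(mode=mode, warn=warn, histogram=hist)
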