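"""Detect a planted deletion with circular binary segmentation.

Plants a half-copy deletion (true log2-ratio -1) spanning 11 genes,
segments each supercontig, and applies the working filter (>= 30 probes,
|mean M| >= 1, Bonferroni p cutoff) calibrated to yield zero false calls
on the virtual chromosome of unplaced probes.
"""

import numpy as np

import strainmask as sm
from strainmask.config import DyeBias

cfg = sm.SimulationConfig(
    n_supercontigs=3,
    genes_per_supercontig=50,
    strain_divergences={"s": 0.0},
    family_specs=[],
    utr_rate_multiplier=1.0,
    dye_bias=DyeBias(0.0, 0.0),
    noise_sd=0.18,
    cnv_events=[sm.CnvEvent("s", 1, 15, 25, 0.5)],
    seed=11,
)
design = sm.build_design(cfg)
truth = sm.simulate_strain(design, cfg, "s")
ref, test = sm.simulate_hybridization(design, truth, cfg)
track = sm.raw_log2(test, ref)

scan = sm.sliding_window_scan(track, design, window=30)
filt = sm.SegmentFilter.from_bonferroni(0.05, scan.n_tests)
print(f"{scan.n_tests} sliding 30-probe windows -> p cutoff {filt.p_cutoff:.2e}")

m_by_probe = track.table.set_index("probe_id")["M"]
for chrom, grp in design.placed().groupby("chrom"):
    m = grp["probe_id"].map(m_by_probe).to_numpy(float)
    segments = sm.cbs_segment(m, alpha=0.05, n_perm=2000, seed=11, chrom=chrom)
    for seg in sm.filter_segments(segments, filt):
        print(
            f"accepted segment on {chrom}: probes [{seg.start_index}:{seg.end_index}] "
            f"mean M = {seg.mean_M:+.2f} (p = {seg.p_value:.1e})"
        )
print("true deletion: Sctg_01 probes [60:104], mean M = -1 (log2 of copy ratio 0.5)")
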