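"""Generate a synthetic two-channel CGH dataset with known ground truth.

Builds a small EST-style array design (4 probes per sequence, ~4% of
probes unplaced, 62% UTR probes), simulates a diverged strain against the
reference, and writes the pair/pos/annotation/truth files the rest of the
pipeline consumes.
"""

from pathlib import Path

import numpy as np

import strainmask as sm

cfg = sm.SimulationConfig(n_supercontigs=6, genes_per_supercontig=40, seed=42)
design = sm.build_design(cfg)
truth = sm.simulate_strain(design, cfg, "strain3")
ref, test = sm.simulate_hybridization(design, truth, cfg)

out = Path("example_data")
out.mkdir(exist_ok=True)
sm.write_annotation(design, out / "annotation.tsv")
sm.write_pos(design, out / "probes.pos")
sm.write_pair(ref, out / "pair_strain3_ref.tsv")
sm.write_pair(test, out / "pair_strain3_test.tsv")
sm.write_truth(truth, out / "truth_strain3.tsv")

print(f"probes on array:      {len(design)} ({design.n_sequences} sequences x {cfg.probes_per_sequence} probes)")
print(f"unplaced (virtual):   {design.virtual_fraction():.1%} of probes")
print(f"UTR probes:           {(design.table['region'] == 'UTR').mean():.1%}")
print(f"mean mismatches/probe: {truth.table['mismatches'].mean():.2f} (strain3 divergence)")
print(f"mean true log2-ratio:  {truth.expected_m.mean():+.2f} (mismatches attenuate the test-channel signal)")
print(f"files written to {out}/")
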