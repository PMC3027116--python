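# Methods

## Signal model of the synthetic generator

The generator emulates a two-color genomic-DNA hybridization on an
EST-based expression array: every EST sequence (contig or singleton) is
represented by `probes_per_sequence = 4` unique long-oligo probes; a
fraction `frac_unplaced = 0.039` of probes has no genomic placement and
is collected, in random order, on a virtual chromosome; 62% of probes
fall in UTRs (`frac_utr_probes = 0.62`). Probes are emitted in genomic
order along supercontigs at a fixed 500 bp spacing (the spacing is
cosmetic — all downstream analysis is probe-index based).

Per probe and test strain, the number of mismatches to the reference is

    m ~ Poisson(d · u · f)

with `d` the strain's expected mismatches per probe, `u` the UTR
multiplier (default 2.0) when the probe lies in a UTR, and `f` the
family multiplier when the probe's sequence carries a family tag. The
true expected log2-ratio is

    M* = log2(c) − min(0.4 · m, 4)

where `c` is the copy ratio (1 outside configured CNV events). The
0.4 log2-units-per-mismatch slope and the −4 floor (≈ background) are
conventions: no published mapping from oligo mismatch count to
hybridization signal loss exists for this platform; a linear-with-floor
model is monotone, simple, and produces the long negative ratio tails
seen in real cross-strain tracks. Channels are simulated as

    log2 I_ref  = b + ε1,   log2 I_test = b + M* + bias(b) + ε2

with a shared probe baseline b ~ N(10, 1.2²) (log2 scale), independent
channel noise ε ~ N(0, 0.212²) — chosen so a null track has
SD(M) = 0.212·√2 ≈ 0.3, the replicate-hybridization concordance level —
and a mild cubic intensity-dependent dye bias evaluated at the baseline
(the generator's A-proxy). Intensities are persisted on the linear
scale; everything downstream is log2.

### Default study conditions

Strain divergences default to {strain2: 0.04, strain3: 0.35,
strain4: 0.28, strain5: 3.0} expected mismatches per probe. Family tags
partition sequences into TE-like (2% of sequences, rate ×8), FCP-like
(1%, ×4), GST-like (1%, ×1) and a generic hypervariable quarter "HV"
(25%, ×6). The HV family exists because a single per-probe Poisson rate
cannot reproduce two features of real inter-strain data at once: a
dominant conserved probe population (which population-based
normalization needs, and which real moderately-diverged strains show)
and log2-ratio SDs near 0.7–0.8. Real divergence is overdispersed and
lineage-shared — fast-evolving sequences are fast in every strain — and
a shared hypervariable family is the simplest expression of that within
the per-probe Poisson model. Under these defaults the normalized SDs
come out ≈ 0.3 / 0.8 / 0.7 for strains 2–4 and the conserved-sequence
ordering strain2 ≫ strain4 > strain3 holds; strain 5 (outgroup, most
probes divergent) reliably defeats the normalization and trips the bias
diagnostic. CNV defaults plant one 0.5× deletion (strain 3) and one 2×
duplication (strain 4), each 11 genes ≈ 44 probes, so both signs of
region call are exercised.

What the generator does **not** emulate: probe thermodynamics (GC
content, secondary structure), spatial array artifacts, organellar
copy-number variation, cross-hybridization between paralogs, and
correlated placement of UTR probes at sequence ends. Passing tests
therefore show the *analysis logic* is correct under a plausible signal
model, not that the pipeline is robust to every artifact of scanned
arrays.

## Population-lowess normalization

Raw ratios are normalized by a reconstruction of population-based
lowess: (1) sort probes by M; (2) segment the sorted sequence with CBS
(change-point significance 0.05); (3) take the most populous segment as
the normalization population; (4) fit a robust lowess of M on A (span
1/3, 4 robustifying iterations, interpolation shortcut δ = 0.1 in A
units) on the population only; (5) subtract the fitted curve, linearly
interpolated, from every probe. The published description of the
algorithm is one sentence; two reconstruction details are ours:

* CBS applied to sorted order statistics shatters one smooth population
  into dozens of thin shells. Adjacent segments are therefore re-merged
  unless an *empirical density gap* separates them — the spacing between
  sorted values across the boundary exceeds 20× the median point
  spacing (the boundary is relocated to the widest spacing within a few
  points, since CBS may land just off the gap). A smooth unimodal track
  merges back to essentially one population; genuinely separated
  populations (copy-number classes, divergence piles) stay apart,
  whatever their share of the global spread.
* Ties on population size go to the segment whose median M is closest
  to 0; the population-selection step is pluggable
  (`population_indices`).

For tracks above 1,000 probes the sorted vector is uniformly decimated
to ≤ 1,000 points for the segmentation step (boundaries scaled back);
population boundaries move by at most the decimation step, which is
negligible against population sizes. A population under 20% of probes
raises a diagnostic warning.

Shift-equivariance holds exactly: adding a constant to all M moves the
population fit by the same constant, leaving the output unchanged.

The post-normalization **bias check** histograms M in 0.2-wide bins
centered on multiples of 0.2 and warns when the modal bin center is
≥ 0.5 in absolute value. When a majority of probes is divergent, the
population selection cannot find a null population and the normalized
histogram peaks away from zero. In simulation the warning fires for the
outgroup strain in ~90% of random seeds; in the remainder the divergent
hump is broad enough that its (unstable) mode lands within half a unit
of zero — a limitation of the per-probe Poisson divergence model, whose
moderate-divergence tracks are less sharply bimodal than real ones.

## Circular binary segmentation

For an ordered signal, the statistic of an arc (i, j) of the
circularized sequence is |mean(arc) − mean(rest)| / √(1/l + 1/(n−l)).
Since the statistic is symmetric between an arc and its complement, the
circular maximum equals the maximum over all contiguous linear windows,
computed exactly (vectorized per window length; ties break to the
earliest arc). A split is accepted when a permutation test (label
permutations of the values) gives p < alpha; recursion continues on the
pieces. The permutation loop stops early in both directions — once
enough exceedances guarantee p > alpha, or once zero exceedances over
≥ 128 permutations bound p ≤ alpha/5 — mirroring the sequential-stopping
practice of standard CBS implementations. Afterwards, weak splits are
undone: adjacent segments merge while their standardized mean difference
is below `undo_sd = 3` noise SDs (noise estimated robustly from first
differences). Without this pruning, genuine CNV plateaus occasionally
shatter into shards and boundary recovery drops below the 95% design
point; with it, a planted 40-probe half-copy deletion is recovered with
≤ 2 probes boundary error in ≥ 98/100 seeded runs.

Each reported segment carries p = min(permutation p of the split that
created it, analytic p), the analytic part being a pooled two-sample t
tail for segment-vs-rest, Bonferroni-corrected over all n(n−1)/2 tested
arcs. The analytic component exists because permutation p-values are
bounded below by 1/(n_perm+1) and can never reach genome-wide cutoffs
near 1e-7; it is an analog of — not a claim about — the per-segment
p-values of commercial CBS tools, and it is very conservative (a true
40-probe CNV at noise 0.25 scores p ≈ 1e-40).

`cbs_segment` defaults to 10,000 permutations; the pipeline, tests and
acceptance script pass 2,000, whose p-resolution (5 × 10⁻⁴) is far below
the 0.05 split threshold, so decisions are unchanged and runtimes stay
at desk scale.

### Segment filter and virtual-chromosome calibration

Candidate segments pass when they have ≥ 30 probes, |mean M| ≥ 1 and
p ≤ 7.4 × 10⁻⁷ — 0.05 Bonferroni-corrected over the sliding 30-probe
window count (a 68,269-probe placed complement yields 68,240 windows;
the printed cutoff 7.4e-7 is kept verbatim as the default even though
0.05/68,240 rounds to 7.3e-7). `calibrate_virtual_chromosome` runs the
segmentation on the randomly ordered unplaced probes, where any accepted
segment is by construction a false positive, and picks the least
stringent candidate filter achieving zero.

One boundary effect deserves note: a deletion at copy ratio exactly 0.5
has true mean M = −1.0, *exactly* the filter's mean threshold, so its
empirical segment mean clears the filter in only ~half of random
replicates regardless of segment length (the mean is symmetric around
the cutoff). The filter is a precision device — zero false calls — not a
recall guarantee at threshold-sized effects; effects even slightly
beyond 2-fold are accepted with high probability.

## Masking, classification, intersections

A probe is masked at threshold τ when |M| > τ strictly; |M| = τ is
kept. A sequence is retained for expression profiling when ≥ 1 of its
probes is unmasked (configurable `min_probes_per_seq`; the most
permissive reading consistent with published retention percentages).
Sequence status uses the four-probe rule — conserved: no probe |M| > 1;
variable: ≥ 2 probes; intermediate: exactly 1 — and cross-strain Venn
regions are counted exhaustively over membership patterns, with the
share of all-CDS sequences reported per region. Percentages are
reported at full precision and under half-up rounding (nearest integer
or one/two decimals) to match reporting conventions.

## Enrichment

Family tests are exact one-sided binomial tails P(X ≥ k | n, p0), with
the background proportion p0 computed over all non-family probes and,
separately, over non-family UTR probes. Excluding the family's own
probes from its background is the default (the alternative is a flag);
with small families the difference is negligible. One-sided "greater"
is the default direction since the scientific question is
over-representation; two-sided is available. The dual-background
monotonicity — an all-UTR family tested against the (more variable)
UTR-only background can only get a *larger* p-value — follows from the
binomial tail being increasing in p0 and is asserted as an invariant.
The generic category test is a per-label hypergeometric tail with
Benjamini–Hochberg control; no ontology-graph propagation is applied
(labels are taken as flat annotations).

## Pipeline

`run_pipeline` executes simulate → normalize (+ bias check) → segment
(+ virtual-chromosome calibration) → masks (τ = 0.5, 1.0) →
classification + Venn → enrichment from one YAML config. A single run
seed fans out to per-stage seeds through a recorded SeedSequence
derivation, so stages can be rerun in isolation. The JSON manifest
stores the config hash and per-stage input/output SHA-256 checksums; a
stage whose inputs are unchanged and whose outputs are intact is skipped
on rerun. Strains failing the bias check are excluded from
classification, Venn and enrichment (the correct handling for samples
too divergent to normalize), and any stage error aborts with the stage
name after saving the manifest of completed stages.

## Problem sizes

Defaults run a 25-supercontig × 60-gene × 4-probe design (6,000 probes,
1,500 sequences) — a deliberate desk-scale stand-in for a ~68,000-probe
array that keeps the full pipeline in tens of seconds while leaving all
rates (unplaced share, UTR share, family fractions) at full-scale
values. CNV-recovery experiments use 2 × 200-probe chromosomes with
40-probe events; window-count checks use a full-size 68,269-probe
chromosome directly (cumulative sums make this instant). All runs are
reproducible from a single integer seed.

## Known limitations

* The attenuation constants (0.4/mismatch, floor −4) are conventions,
  not measured platform physics; absolute divergence estimates from
  simulated M values inherit them.
* Per-probe Poisson mismatches understate within-sequence correlation
  of divergence; sequence-level "variable" rates are conservative
  relative to real data, and the outgroup failure signature is less
  sharply bimodal than real outgroup tracks (see the bias-check note).
* Segment p-values are an analog of the original per-segment
  statistics, suitable for ranking and thresholding, not a
  reimplementation of any commercial tool.
* The category test ignores label hierarchies.
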