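# Methods

## The estimation problem

A B chromosome contributes sequence that is partially homologous to the
reference assembly. In an individual carrying extra (or fewer) copies of
such a fragment, short reads originating from every copy align to the one
reference locus, so the locus' depth of coverage is proportional to the
fragment's total copy number in that individual's genome. The pipeline
turns depth into copy number in four steps — windowing, depth accumulation,
GC correction, control calibration — and then aggregates windows to
fragments and individuals to populations.

Assumptions: depth is the only signal used (no split reads, no insert
sizes); copy number is expressed per diploid genome, so 2 means the normal
two copies — chosen because the designated control regions read ~2 on this
scale; repeat-masked and N bases are excluded everywhere because alignment
there is unreliable.

## Pipeline details and numerical choices

**Windows.** A window is exactly W = 1000 *unmasked, non-N* bases, not 1000
genomic bases: masked gaps are skipped and the window's genomic span grows
accordingly. This follows the read-depth segmental-duplication tradition;
fixed unmasked length keeps the depth denominator constant so masked gaps
cannot dilute the signal. The final sub-W remainder of each contig is
dropped. Windows never share unmasked bases.

**Depth.** Every reported alignment counts, including secondary alignments
of multi-mapping reads (the all-alignments reporting mode of the external
aligner the pipeline accepts SAM from); duplicates are not removed. The
built-in mapper places error-free reads at *every* exact full-length match
using a 64-bit rolling-hash index with explicit verification of candidate
hits, so it reports the same multi-placements an `-a`-mode aligner would on
error-free data; reads with no exact match (junction-spanning or mutated)
are dropped and counted. Per-base depth from internal placements is exact;
a brute-force per-position recount is the oracle in tests.

**GC correction.** Binned scaling: corrected = raw · μ/μ_b with GC bins of
width 0.025. Bin means are fit on putatively *diploid* windows: windows
whose raw depth deviates from the median by more than 3 robust standard
deviations (1.4826·MAD) are excluded, iterated to convergence (≤ 3
rounds). Without this, copy-number-variable windows contaminate their own
GC bin — homozygous-deletion windows drag bin means down and high-CN
fragments inflate them — which we measured as CN-10 fragments mis-estimated
by up to ±1.2 copies. Bins with fewer than 20 windows borrow the nearest
reliable bin's mean (extrapolating the monotone GC trend) rather than
falling back to "no correction", which would leave tail-GC windows with
their full bias; if no bin is reliable the global mean stands. When no
window is trimmed and all bins are reliable, the correction preserves the
global mean depth exactly.

**Calibration.** control_depth is the *median* corrected depth over windows
whose genomic span lies fully inside a control interval (median rather than
mean for robustness to residual CNV in controls); at least 5 control
windows are required. CN = 2·corrected/control_depth.

**Aggregation and bands.** Fragment CN is the unweighted mean over windows
fully inside the fragment; fragments containing no complete window are
reported missing, never zero. The printed one-decimal copy-number bands
become continuous intervals: absent [0, 0.1), homozygous deletion
[0.1, 1.5), heterozygous deletion [1.5, 2.6), normal diploid [2.6, 4.0],
heterozygous duplication (4.0, 6.0], multiple duplication (6.0, ∞) — the
upper bound of the heterozygous-duplication band (one extra diploid copy
beyond normal) is our choice since no printed bound exists. A fragment
counts as *variable* in a population if any individual falls outside the
normal-control band [1.5, 3], and as *multiplied* if any individual exceeds
3 — the band the controls themselves are required to occupy, since no
explicit variability criterion is printed.

**Pseudo-scaffolds.** Consensus fragments are maximal intervals with
per-base read support ≥ 3 and length ≥ 200 bp; the consensus base is the
majority base among covering reads with ties resolved to the reference.
Chaining runs over an ascending spacer ladder {100, 1,000, 10,000} bp —
the final value fixed by the 10 kb-joined convention, the earlier rungs our
choice — merging adjacent same-chromosome chains whose genomic gap is at or
below the rung; because the ladder ascends, the result provably equals a
single pass at the final rung (asserted against a brute-force partition in
tests), and chaining is idempotent. Members are joined with 10 kb runs of
`N`; spacer bases are excluded from every annotation denominator (GC,
repeat fraction, gene and SNV densities). Chains never cross chromosomes.

**Scalars.** 2C DNA content in pg is the standard's 2C times the
fluorescence ratio; bp = pg · 0.978 × 10⁹, rounded to the nearest base.
The SNV-density worked example treats the printed denominator "361,036 kb"
as bp — the printed unit is internally inconsistent with the per-kb value
it yields, and bp reproduces it; the report flags this. Group DNA contents
are compared with a pooled-variance (not Welch) two-sided Student t-test,
matching the named test; all sizes are 2C values.

## The synthetic cohort generator

The generator emulates the features of the real study that the estimator
depends on, with everything a pure function of `SimConfig` (seed
included):

* **Reference** (default 2 Mb, single contig): blockwise GC levels
  {0.35, 0.45, 0.55, 0.65} over 20 kb blocks so GC bias is identifiable;
  17% of the genome annotated as repeat (2 kb blocks), mirroring a ~16.75%
  genome-wide repeat content; 30 B-derived fragments of 1–5 kb; two 2 kb
  single-exon control genes and one 400 kb control fragment, all placed
  disjointly in unmasked sequence.
* **Cohort** (default 12 individuals): three populations emulating the
  species' native range with decreasing CN variance — a high-variance
  population (CNs 0–24), an intermediate one (1–10) and a near-diploid one
  (2–4). The real per-population CN distributions are not published;
  these defaults are chosen once to reproduce the qualitative
  high > medium > low ordering only.
* **Planting:** diploid CN *c* is realized per individual as haplotype 1
  keeping its copy iff c ≥ 1, haplotype 2 iff c ≥ 2, and c − min(c, 2)
  extra copies inserted *dispersed* at random unmasked loci outside
  controls and other fragments — depth, not structure, carries the signal,
  and placing copies away from other functional intervals keeps their
  depth signals independent.
* **Reads:** single-end, fixed 100 bp, error-free by default (the built-in
  exact mapper then suffices; non-zero error rates are supported for the
  external-SAM path). Read count is set so expected depth at an
  unduplicated, bias-free locus equals the configured coverage (7×).
  Diploidy is simulated by sampling from the two haplotypes jointly rather
  than emitting separate libraries. GC bias multiplies each candidate
  start's weight by exp(gc_bias_strength · (gc_read − 0.5) · 2), normalized
  over the pool (default strength 0.5, ≈ ±15% depth across the GC range) —
  monotone and invertible by binned correction.

What the generator does **not** emulate — and hence what passing tests do
not demonstrate about real data: paired ends, indels/structural breakpoint
realism, base-quality models, strand sampling (forward only), mappability
structure inside repeats (repeats are annotation, not repetitive sequence),
cross-sample batch effects, and intra-individual mosaicism of B counts.

## Problem sizes used by tests and analyses

The default study conditions (2 Mb, 12 individuals, 7×) run in ~30 s and
are used by the acceptance script and the control-diploidy check. The unit
and property suites use scaled-down cohorts (300–800 kb genomes, 60–100 kb
control fragments) chosen so every effect under test remains measurable:
the recovery experiment plants CNs {0, 1, 2, 4, 6, 10} uniformly over 18
fragments of 4–6 kb (so most fragments carry ≥ 3 complete windows), and
the population-ordering experiment repeats a 9-individual, 400 kb cohort
over 20 seeds.

## Known limitations

* Estimates for planted CN 4 and 6 straddle the *closed* upper edges of
  the normal-diploid and heterozygous-duplication bands (4.0 and 6.0). An
  unbiased estimator therefore classifies such fragments into the adjacent
  band with probability ≈ ½ however small the noise; band assignment is
  only reliable for copy numbers in band interiors.
* Residual CN noise grows with copy number (multiplicative depth errors,
  ~3–4% common-mode per fragment at GC bias 0.5), so very high CNs carry
  absolute errors of several tenths.
* Single-window control genes are noisy calibrator *checks* (SD ≈ 0.2);
  calibration itself is driven by the many-window control fragment.
* The generator and mapper assume a single reference contig per run;
  multi-contig inputs are processed contig by contig.
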