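# bchromcnv

Read-depth copy-number analysis of B-chromosome-derived genome fragments.

B chromosomes are dispensable, supernumerary chromosomes that occur in
variable numbers between cells, individuals and populations, on top of the
standard (A) chromosome set. When fragments of a B chromosome are homologous
to regions of the reference assembly, their per-individual abundance can be
read out from whole-genome sequencing as excess depth of coverage. This
package implements that personalized read-depth pipeline end to end, along
with the two companion analyses usually run next to it — pseudo-scaffold
construction from chromosome-derived reads, and flow-cytometry genome-size
arithmetic — and a synthetic-cohort generator so the whole study can be
exercised with known planted truth and no external data.

## Model

For an individual sequenced to coverage *c*, the genome is tiled into
windows of exactly **W = 1000 unmasked, non-N bases** (masked bases are
skipped, so a window may span a longer genomic interval; the final sub-W
remainder per contig is dropped). Every reported alignment of every read
contributes to per-base depth (multi-mapping reads count at all their
placements, as with an aligner's report-all mode), so extra copies of a
fragment elsewhere in an individual's genome pile up on the fragment's
reference locus. Window depth is corrected for GC bias by binned scaling,

> corrected = raw · μ / μ(gc-bin),  bins of 0.025 GC,

where bin means are fit on putatively diploid windows (depth outliers
beyond 3 robust SDs of the median are excluded iteratively, and sparse bins
borrow the nearest well-populated bin). Depth is calibrated into diploid
copy-number units against designated control regions assumed CN = 2 in all
individuals (two single-exon control genes and one ~400 kb control
fragment), using the median control window:

> CN = 2 · corrected / median(corrected over control windows).

Fragment-level CN is the unweighted mean over windows fully inside the
fragment; window/fragment CNs classify into the standard bands
(homozygous deletion 0.1–1.4, heterozygous deletion 1.5–2.5, normal diploid
2.6–4, heterozygous duplication > 4, multiple duplications > 6), and
populations are summarized by per-fragment min/max/range/mean.

Pseudo-scaffolds are built by placing chromosome-derived reads on the
reference, calling maximal consensus intervals with depth ≥ 3 and length
≥ 200 bp, chaining them across an ascending gap ladder (100 / 1,000 /
10,000 bp), and joining chain members with 10 kb runs of `N`. Genome sizes
follow the fluorescence-ratio model `2C(pg) = 2C_standard · I_sample /
I_standard` with 1 pg = 0.978 × 10⁹ bp, and DNA-content groups are compared
with a pooled-variance two-sided Student t-test.

## Worked example

```python
from bchromcnv import SimConfig, run_cohort, snv_density, density_ratio, genome_size

res = run_cohort(SimConfig())          # 2 Mb genome, 12 individuals, 7x, GC bias on
print(res.control_window_means.min(), res.control_window_means.max())
# 2.0009507120411976 2.017829364533275   <- diploid controls calibrate to ~2

print(res.population_summary().groupby("population")["cn_range"].mean())
# australia_png          1.278981
# india                 11.070975
# seasia_philippines     5.667995       <- high > medium > low variance design

print(snv_density(2901, 361_036))      # 8.035209785173778  (~eight SNVs per kb)
print(density_ratio(30.2, 5.16))       # DensityRatio(ratio=5.852713..., nearest_int=6)
print(genome_size(1.0, 1.0, 1.0).size_bp)  # 978000000
```

The same numbers fall out of the narrative drivers under `analysis/`
(`01_simulate_cohort.py` … `05_densities_genome_size.py`), which write
their tables to `results/`. A thin CLI mirrors the stages:

```bash
bchromcnv simulate --out cohort/ --write-reads
bchromcnv depth --ref cohort/reference.fa --mask cohort/mask.bed \
    --controls cohort/controls.bed --reads cohort/ind_001.fastq --out ind_001.tsv
bchromcnv population --windows ind_001.tsv --fragments cohort/fragments.bed \
    --controls cohort/controls.bed --cohort cohort.tsv --out pop/
bchromcnv scaffold --reads b_reads.fastq --ref cohort/reference.fa --out scaffold/
bchromcnv run --config config.json --out study/
```

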