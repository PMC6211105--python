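"""Synthetic cohort generator for read-depth copy-number analysis.

Builds everything the downstream pipeline needs without any external data:

* a single-contig reference genome with block-wise varying GC content,
  annotated repeat intervals (the mask), gene intervals, two diploid
  "control genes" plus one large diploid control fragment, and a set of
  B-chromosome-derived fragments;
* a cohort of individuals in three populations with planted, population-
  structured diploid copy numbers for every B fragment (extra copies
  dispersed at random unmasked loci, deletions excised per haplotype);
* error-free short reads at a target fold coverage with an optional
  monotone GC sampling bias.

Every output is a pure function of :class:`SimConfig` (including its seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import decode, encode


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class PlacementError(RuntimeError):
    """Requested intervals cannot be placed disjointly on the genome."""


@dataclass(frozen=True)
class PopulationSpec:
    """A population label with its cohort size and discrete CN distribution.

    ``cn_values`` are diploid copy numbers (2 = normal diploid); draws are
    i.i.d. across individuals and fragments.
    """

    label: str
    n_individuals: int
    cn_values: tuple[int, ...]
    cn_probs: tuple[float, ...]

    def validate(self) -> None:
        if self.n_individuals < 0:
            raise ConfigError(f"negative cohort size for {self.label}")
        if len(self.cn_values) != len(self.cn_probs):
            raise ConfigError(f"cn_values/cn_probs length mismatch for {self.label}")
        if any(v < 0 or int(v) != v for v in self.cn_values):
            raise ConfigError(f"copy numbers must be non-negative integers ({self.label})")
        if abs(sum(self.cn_probs) - 1.0) > 1e-9:
            raise ConfigError(f"cn_probs must sum to 1 ({self.label})")


# Defaults emulate the qualitative population structure of the species'
# native range: a high-variance Indian population, an intermediate
# South-East Asia + Philippines population, and a near-diploid
# Australia + Papua New Guinea population.
DEFAULT_POPULATIONS: tuple[PopulationSpec, ...] = (
    PopulationSpec(
        "india", 4,
        (0, 1, 2, 4, 6, 10, 16, 24),
        (0.05, 0.10, 0.30, 0.20, 0.15, 0.10, 0.07, 0.03),
    ),
    PopulationSpec(
        "seasia_philippines", 4,
        (1, 2, 4, 6, 10),
        (0.10, 0.45, 0.25, 0.12, 0.08),
    ),
    PopulationSpec(
        "australia_png", 4,
        (2, 3, 4),
        (0.80, 0.12, 0.08),
    ),
)


@dataclass(frozen=True)
class SimConfig:
    """Full specification of a synthetic cohort.

    Lengths are in bp, coverage in fold over the diploid genome. The
    defaults give a 2 Mb genome at ~17% repeat content carrying 30
    B-derived fragments of 1-5 kb, two 2 kb control genes plus a 400 kb
    control fragment, sequenced to 7x with a mild GC bias.
    """

    seed: int = 42
    genome_length: int = 2_000_000
    chrom: str = "chr1"
    gc_block_length: int = 20_000
    gc_levels: tuple[float, ...] = (0.35, 0.45, 0.55, 0.65)
    repeat_fraction: float = 0.17
    repeat_block_length: int = 2_000
    n_b_fragments: int = 30
    b_fragment_length: tuple[int, int] = (1_000, 5_000)
    control_gene_length: int = 2_000
    control_fragment_length: int = 400_000
    n_genes: int = 40
    gene_length: int = 1_000
    populations: tuple[PopulationSpec, ...] = DEFAULT_POPULATIONS
    coverage: float = 7.0
    read_length: int = 100
    gc_bias_strength: float = 0.5
    error_rate: float = 0.0

    def validate(self) -> None:
        if not 0 <= self.repeat_fraction < 1:
            raise ConfigError("repeat_fraction must be in [0, 1)")
        if self.coverage <= 0:
            raise ConfigError("coverage must be > 0")
        if self.read_length <= 0:
            raise ConfigError("read_length must be > 0")
        if self.gc_bias_strength < 0:
            raise ConfigError("gc_bias_strength must be >= 0")
        if not 0 <= self.error_rate < 1:
            raise ConfigError("error_rate must be in [0, 1)")
        if self.b_fragment_length[0] > self.b_fragment_length[1]:
            raise ConfigError("b_fragment_length range inverted")
        if any(not 0 < g < 1 for g in self.gc_levels):
            raise ConfigError("gc_levels must lie in (0, 1)")
        for pop in self.populations:
            pop.validate()
        if sum(p.n_individuals for p in self.populations) < 1:
            raise ConfigError("cohort must contain at least one individual")

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


@dataclass
class Reference:
    """Annotated reference genome (single contig, 0-based half-open coords)."""

    chrom: str
    codes: np.ndarray  # uint8 base codes
    mask: list[tuple[int, int]]
    genes: list[tuple[int, int]]
    controls: list[tuple[str, int, int]]  # (label, start, end)
    fragments: dict[str, tuple[int, int]]

    def __len__(self) -> int:
        return len(self.codes)

    @property
    def sequence(self) -> str:
        return decode(self.codes)

    @property
    def control_intervals(self) -> list[tuple[int, int]]:
        return [(s, e) for _, s, e in self.controls]

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        seq = self.sequence
        with open(path, "w") as fh:
            fh.write(f">{self.chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass
class CohortTruth:
    """Planted ground truth for a simulated cohort."""

    individuals: list[tuple[str, str]]  # (individual_id, population label)
    cn_truth: dict[tuple[str, str], int]  # (individual, fragment) -> diploid CN
    fragment_coords: dict[str, tuple[int, int]]
    control_coords: list[tuple[str, int, int]]
    mask_coords: list[tuple[int, int]]

    def to_frame(self) -> pd.DataFrame:
        pop = dict(self.individuals)
        rows = [
            {"individual": ind, "population": pop[ind], "fragment_id": frag, "cn_true": cn}
            for (ind, frag), cn in sorted(self.cn_truth.items())
        ]
        return pd.DataFrame(rows, columns=["individual", "population", "fragment_id", "cn_true"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_truth_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"individual": str, "fragment_id": str})


# ---------------------------------------------------------------------------
# reference construction


def _random_sequence(rng: np.random.Generator, config: SimConfig) -> np.ndarray:
    """Blockwise sequence where each block draws a GC level from the config."""
    length = config.genome_length
    n_blocks = -(-length // config.gc_block_length)
    levels = rng.choice(config.gc_levels, size=n_blocks)
    out = np.empty(length, dtype=np.uint8)
    for b in range(n_blocks):
        s = b * config.gc_block_length
        e = min(s + config.gc_block_length, length)
        g = levels[b]
        p = [(1 - g) / 2, g / 2, g / 2, (1 - g) / 2]  # A C G T
        out[s:e] = rng.choice(4, size=e - s, p=p).astype(np.uint8)
    return out


def _place(
    rng: np.random.Generator,
    occupied: np.ndarray,
    length: int,
    tag: str,
    max_tries: int = 10_000,
) -> tuple[int, int]:
    """Place one interval of `length` disjoint from `occupied`, or raise."""
    genome_length = occupied.size
    if length > genome_length:
        raise PlacementError(f"interval {tag!r} longer than the genome")
    for _ in range(max_tries):
        start = int(rng.integers(0, genome_length - length + 1))
        end = start + length
        if not occupied[start:end].any():
            occupied[start:end] = True
            return start, end
    raise PlacementError(f"could not place interval {tag!r} ({length} bp) disjointly")


def build_reference(config: SimConfig) -> Reference:
    """Construct the annotated reference genome for a configuration.

    Controls, B fragments and repeat blocks are mutually disjoint; extra
    gene intervals avoid repeats and controls but may fall inside B
    fragments. Deterministic for a fixed ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    codes = _random_sequence(rng, config)
    length = config.genome_length

    occupied = np.zeros(length, dtype=bool)
    controls: list[tuple[str, int, int]] = []
    if config.control_fragment_length > 0:
        s, e = _place(rng, occupied, config.control_fragment_length, "control_fragment")
        controls.append(("control_fragment", s, e))
    for i in range(2):
        s, e = _place(rng, occupied, config.control_gene_length, f"control_gene_{i + 1}")
        controls.append((f"control_gene_{i + 1}", s, e))

    fragments: dict[str, tuple[int, int]] = {}
    lo, hi = config.b_fragment_length
    frag_lengths = rng.integers(lo, hi + 1, size=config.n_b_fragments)
    for i, flen in enumerate(frag_lengths):
        fid = f"bfrag_{i + 1:03d}"
        fragments[fid] = _place(rng, occupied, int(flen), fid)

    mask: list[tuple[int, int]] = []
    n_repeat_blocks = int(round(config.repeat_fraction * length / config.repeat_block_length))
    for i in range(n_repeat_blocks):
        mask.append(_place(rng, occupied, config.repeat_block_length, f"repeat_{i + 1}"))
    mask.sort()

    # genes may overlap B fragments (B regions carry genes) but not repeats,
    # controls or each other
    gene_blocked = np.zeros(length, dtype=bool)
    for s, e in mask:
        gene_blocked[s:e] = True
    for _, s, e in controls:
        gene_blocked[s:e] = True
    genes: list[tuple[int, int]] = []
    for i in range(config.n_genes):
        genes.append(_place(rng, gene_blocked, config.gene_length, f"gene_{i + 1}"))
    genes.sort()

    return Reference(
        chrom=config.chrom,
        codes=codes,
        mask=mask,
        genes=genes,
        controls=controls,
        fragments=fragments,
    )


# ---------------------------------------------------------------------------
# copy-number planting


def draw_truth(reference: Reference, config: SimConfig) -> CohortTruth:
    """Draw per-individual fragment copy numbers from the population specs."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    individuals: list[tuple[str, str]] = []
    cn_truth: dict[tuple[str, str], int] = {}
    idx = 0
    for pop in config.populations:
        values = np.asarray(pop.cn_values)
        probs = np.asarray(pop.cn_probs, dtype=float)
        for _ in range(pop.n_individuals):
            idx += 1
            ind = f"ind_{idx:03d}"
            individuals.append((ind, pop.label))
            draws = rng.choice(values, size=len(reference.fragments), p=probs)
            for frag, cn in zip(sorted(reference.fragments), draws):
                if cn < 0:
                    raise ConfigError(f"negative copy number for {ind}/{frag}")
                cn_truth[(ind, frag)] = int(cn)
    return CohortTruth(
        individuals=individuals,
        cn_truth=cn_truth,
        fragment_coords=dict(reference.fragments),
        control_coords=list(reference.controls),
        mask_coords=list(reference.mask),
    )


def _insertion_sites(reference: Reference) -> np.ndarray:
    """Positions where extra fragment copies may be inserted: unmasked and
    outside controls and B fragments (so no planted copy disturbs another
    region's depth signal)."""
    blocked = np.zeros(len(reference), dtype=bool)
    for s, e in reference.mask:
        blocked[s:e] = True
    for _, s, e in reference.controls:
        blocked[s:e] = True
    for s, e in reference.fragments.values():
        blocked[s:e] = True
    return np.flatnonzero(~blocked)


def individual_genome(
    reference: Reference,
    truth: CohortTruth,
    individual: str,
    config: SimConfig,
    _sites: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Build the two haplotype sequences realizing an individual's planted CNs.

    Diploid copy number c for a fragment is realized as: haplotype 1 keeps
    its reference copy iff c >= 1, haplotype 2 iff c >= 2, and the remaining
    c - min(c, 2) copies are inserted, dispersed, at random allowed loci.
    """
    ids = [i for i, _ in truth.individuals]
    ind_index = ids.index(individual)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2, ind_index]))
    sites = _insertion_sites(reference) if _sites is None else _sites

    # events per haplotype: ("del", s, e) or ("ins", pos, frag_codes)
    events: list[list[tuple]] = [[], []]
    for frag in sorted(reference.fragments):
        cn = truth.cn_truth[(individual, frag)]
        s, e = reference.fragments[frag]
        if cn < 1:
            events[0].append(("del", s, e))
        if cn < 2:
            events[1].append(("del", s, e))
        for _ in range(cn - min(cn, 2)):
            hap = int(rng.integers(2))
            pos = int(sites[rng.integers(sites.size)])
            events[hap].append(("ins", pos, reference.codes[s:e]))

    haps = []
    for ev in events:
        ev.sort(key=lambda t: t[1])
        parts, prev = [], 0
        for item in ev:
            if item[0] == "del":
                _, s, e = item
                parts.append(reference.codes[prev:s])
                prev = e
            else:
                _, pos, ins = item
                parts.append(reference.codes[prev:pos])
                parts.append(ins)
                prev = pos
        parts.append(reference.codes[prev:])
        haps.append(np.concatenate(parts))
    return haps


def plant_copy_numbers(
    reference: Reference, config: SimConfig
) -> tuple[CohortTruth, dict[str, list[np.ndarray]]]:
    """Draw the cohort truth and materialize every individual genome."""
    truth = draw_truth(reference, config)
    sites = _insertion_sites(reference)
    genomes = {
        ind: individual_genome(reference, truth, ind, config, _sites=sites)
        for ind, _ in truth.individuals
    }
    return truth, genomes


# ---------------------------------------------------------------------------
# read simulation


@dataclass
class Reads:
    """A batch of fixed-length reads as a codes matrix plus provenance."""

    codes: np.ndarray  # (n_reads, read_length) uint8
    pool_starts: np.ndarray  # start of each read in the concatenated diploid pool
    individual: str = "ind"

    @property
    def n_reads(self) -> int:
        return self.codes.shape[0]

    @property
    def read_length(self) -> int:
        return self.codes.shape[1]

    def sequences(self) -> list[str]:
        return [decode(row) for row in self.codes]

    def write_fastq(self, path: str | Path, quality: str = "I") -> None:
        qual = quality * self.read_length
        with open(path, "w") as fh:
            for i, row in enumerate(self.codes):
                fh.write(f"@{self.individual}_r{i}\n{decode(row)}\n+\n{qual}\n")

    def write_truth_bed(self, path: str | Path) -> None:
        """Truth placements in diploid-pool coordinates (contig 'pool')."""
        with open(path, "w") as fh:
            for i, s in enumerate(self.pool_starts):
                fh.write(f"pool\t{int(s)}\t{int(s) + self.read_length}\t{self.individual}_r{i}\n")


def read_fastq(path: str | Path) -> np.ndarray:
    """Read a FASTQ of equal-length reads into a codes matrix."""
    import pysam

    rows = [encode(rec.sequence) for rec in pysam.FastxFile(str(path))]
    if not rows:
        return np.empty((0, 0), dtype=np.uint8)
    return np.vstack(rows)


def simulate_reads(
    genome: list[np.ndarray],
    config: SimConfig,
    individual_index: int = 0,
    individual: str = "ind",
) -> Reads:
    """Sample GC-biased single-end reads from a diploid genome.

    The read count is set so the expected depth at an unduplicated,
    bias-free locus equals ``config.coverage``. Each candidate start is
    weighted by ``exp(gc_bias_strength * (gc_read - 0.5) * 2)`` and weights
    are normalized over the whole diploid pool.
    """
    config.validate()
    read_len = config.read_length
    if any(hap.size == 0 for hap in genome) or not genome:
        raise ConfigError("empty genome")
    if any(hap.size < read_len for hap in genome):
        raise ConfigError("read_length exceeds a haplotype length")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3, individual_index]))
    pool = np.concatenate(genome)
    pool_len = pool.size

    # valid start positions: within a haplotype, never across the junction
    valid = []
    offset = 0
    for hap in genome:
        valid.append(np.arange(offset, offset + hap.size - read_len + 1))
        offset += hap.size
    starts_all = np.concatenate(valid)

    is_gc = ((pool == 1) | (pool == 2)).astype(np.int64)
    csum = np.concatenate([[0], np.cumsum(is_gc)])
    gc_start = (csum[read_len:] - csum[:-read_len]) / read_len  # gc of window at p
    gc_valid = gc_start[starts_all]

    if config.gc_bias_strength > 0:
        w = np.exp(config.gc_bias_strength * (gc_valid - 0.5) * 2.0)
        w /= w.sum()
    else:
        w = np.full(starts_all.size, 1.0 / starts_all.size)

    n_reads = int(round(config.coverage * pool_len / (2.0 * read_len)))
    chosen = rng.choice(starts_all.size, size=n_reads, p=w)
    starts = starts_all[np.sort(chosen)]
    mat = pool[starts[:, None] + np.arange(read_len)]

    if config.error_rate > 0:
        err = rng.random(mat.shape) < config.error_rate
        shift = rng.integers(1, 4, size=mat.shape).astype(np.uint8)
        mat = np.where(err, (mat + shift) % 4, mat)

    return Reads(codes=mat, pool_starts=starts, individual=individual)


# ---------------------------------------------------------------------------
# cohort writer


def write_intervals_bed(
    path: str | Path, chrom: str, intervals, names: list[str] | None = None
) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if len(iv) == 3 and isinstance(iv[0], str):
                name, s, e = iv
            else:
                s, e = iv
                name = names[i] if names else f"iv_{i + 1}"
            fh.write(f"{chrom}\t{s}\t{e}\t{name}\n")


def write_cohort(
    outdir: str | Path,
    config: SimConfig,
    reference: Reference,
    truth: CohortTruth,
    genomes: dict[str, list[np.ndarray]] | None = None,
    write_reads: bool = False,
) -> None:
    """Persist a simulated cohort as plain-text files (FASTA/BED/TSV/JSON,
    optionally per-individual FASTQ)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    reference.write_fasta(out / "reference.fa")
    write_intervals_bed(out / "mask.bed", reference.chrom, reference.mask)
    write_intervals_bed(out / "genes.bed", reference.chrom, reference.genes)
    write_intervals_bed(out / "controls.bed", reference.chrom, reference.controls)
    write_intervals_bed(
        out / "fragments.bed",
        reference.chrom,
        [(fid, s, e) for fid, (s, e) in sorted(reference.fragments.items())],
    )
    truth.write_tsv(out / "truth.tsv")
    config.to_json(out / "config.json")
    if write_reads:
        genomes = genomes if genomes is not None else plant_copy_numbers(reference, config)[1]
        for i, (ind, _) in enumerate(truth.individuals):
            reads = simulate_reads(genomes[ind], config, individual_index=i, individual=ind)
            reads.write_fastq(out / f"{ind}.fastq")
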