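"""Pseudo-scaffold construction from chromosome-derived read placements.

Reads obtained from an isolated (e.g. microdissected) chromosome are placed
on the reference; maximal well-supported intervals become consensus
fragments, which are then chained across an increasing ladder of gap
thresholds and finally joined with fixed-length runs of 'N' (default
10 kb) into pseudo-scaffolds. Spacer bases are excluded from every
annotation denominator (repeat fraction, SNV and gene densities).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import decode
from .mapping import Placements

DEFAULT_SPACER = 10_000
DEFAULT_LADDER = (100, 1_000, 10_000)


@dataclass
class ConsensusFragment:
    """A maximal reference interval with read support >= min_support."""

    chrom: str
    start: int
    end: int
    support: int  # minimum per-base depth over the interval
    sequence: str

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class PseudoScaffold:
    """Ordered same-chrom fragments joined by fixed-length N spacers."""

    name: str
    members: list[ConsensusFragment]
    spacer_len: int = DEFAULT_SPACER

    @property
    def chrom(self) -> str:
        return self.members[0].chrom

    @property
    def member_len(self) -> int:
        return sum(len(m) for m in self.members)

    @property
    def total_len(self) -> int:
        return self.member_len + self.spacer_len * (len(self.members) - 1)

    @property
    def sequence(self) -> str:
        return ("N" * self.spacer_len).join(m.sequence for m in self.members)

    def member_intervals(self) -> list[tuple[int, int]]:
        return [(m.start, m.end) for m in self.members]


def call_consensus(
    placements: Placements,
    reads: np.ndarray,
    reference_codes: np.ndarray,
    min_support: int = 3,
    min_len: int = 200,
) -> list[ConsensusFragment]:
    """Maximal intervals with per-base depth >= min_support and length >=
    min_len; the consensus base is the majority base among covering reads,
    with ties resolved to the reference base."""
    n = reference_codes.size
    counts = np.zeros((4, n), dtype=np.int64)
    k = placements.read_length
    offs = np.arange(k)
    for ridx, pos in zip(placements.read_index, placements.positions):
        row = reads[ridx]
        acgt = row < 4
        np.add.at(counts, (row[acgt], (pos + offs)[acgt]), 1)
    depth = counts.sum(axis=0)

    ok = depth >= max(min_support, 1)
    edges = np.diff(ok.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if ok.size and ok[0]:
        starts = np.concatenate([[0], starts])
    if ok.size and ok[-1]:
        ends = np.concatenate([ends, [n]])

    fragments = []
    for s, e in zip(starts, ends):
        if e - s < min_len:
            continue
        sub = counts[:, s:e]
        best = sub.max(axis=0)
        tied = (sub == best).sum(axis=0) > 1
        cons = np.where(tied, reference_codes[s:e], sub.argmax(axis=0)).astype(np.uint8)
        fragments.append(
            ConsensusFragment(
                chrom=placements.chrom,
                start=int(s),
                end=int(e),
                support=int(depth[s:e].min()),
                sequence=decode(cons),
            )
        )
    return fragments


def chain(
    fragments: list[ConsensusFragment],
    spacer_ladder: tuple[int, ...] = DEFAULT_LADDER,
    spacer_len: int | None = None,
) -> list[PseudoScaffold]:
    """Chain sorted fragments across an ascending ladder of gap thresholds.

    At each ladder value s, adjacent same-chrom chains separated by a
    genomic gap <= s are merged; the final chains are emitted joined with
    spacer_len 'N's (default: the last ladder value). Because the ladder is
    ascending, the result equals single-pass merging at the final
    threshold — asserted as a documented invariant.
    """
    if list(spacer_ladder) != sorted(spacer_ladder):
        raise ValueError("spacer ladder must be ascending")
    spacer_len = spacer_ladder[-1] if spacer_len is None else spacer_len
    frags = sorted(fragments, key=lambda f: (f.chrom, f.start))
    for a, b in zip(frags, frags[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise ValueError(f"overlapping fragments at {a.chrom}:{b.start}")

    chains: list[list[ConsensusFragment]] = [[f] for f in frags]
    for s in spacer_ladder:
        merged: list[list[ConsensusFragment]] = []
        for ch in chains:
            if (
                merged
                and merged[-1][-1].chrom == ch[0].chrom
                and ch[0].start - merged[-1][-1].end <= s
            ):
                merged[-1].extend(ch)
            else:
                merged.append(ch)
        chains = merged
    return [
        PseudoScaffold(name=f"pseudoscaffold_{i + 1}", members=ch, spacer_len=spacer_len)
        for i, ch in enumerate(chains)
    ]


# ---------------------------------------------------------------------------
# annotation


def _overlap(intervals: list[tuple[int, int]], s: int, e: int) -> int:
    return sum(max(0, min(e, ie) - max(s, is_)) for is_, ie in intervals)


def annotate(
    scaffolds: list[PseudoScaffold],
    genes: list[tuple[int, int]] | None = None,
    repeats: list[tuple[int, int]] | None = None,
    variants: list[tuple[str, int]] | None = None,
) -> pd.DataFrame:
    """Per-scaffold gene counts, repeat fraction and SNV density.

    ``variants`` are (chrom, 0-based pos) sites; spacer bases never enter a
    denominator. The last row, ``__overall__``, aggregates all scaffolds.
    """
    genes = genes or []
    repeats = repeats or []
    variants = variants or []
    rows = []
    tot_member = tot_genes = tot_rep = tot_snv = 0
    for sc in scaffolds:
        member_bp = sc.member_len
        ivs = sc.member_intervals()
        n_genes = sum(
            1 for gs, ge in genes if any(gs < e and ge > s for s, e in ivs)
        )
        rep_bp = sum(_overlap(repeats, s, e) for s, e in ivs)
        n_snv = sum(
            1 for chrom, pos in variants
            if chrom == sc.chrom and any(s <= pos < e for s, e in ivs)
        )
        rows.append(
            {
                "scaffold": sc.name,
                "chrom": sc.chrom,
                "n_members": len(sc.members),
                "member_bp": member_bp,
                "total_len": sc.total_len,
                "gene_count": n_genes,
                "repeat_fraction": rep_bp / member_bp if member_bp else 0.0,
                "snv_count": n_snv,
                "snv_per_kb": n_snv / (member_bp / 1000) if member_bp else 0.0,
            }
        )
        tot_member += member_bp
        tot_genes += n_genes
        tot_rep += rep_bp
        tot_snv += n_snv
    rows.append(
        {
            "scaffold": "__overall__",
            "chrom": "*",
            "n_members": sum(len(sc.members) for sc in scaffolds),
            "member_bp": tot_member,
            "total_len": sum(sc.total_len for sc in scaffolds),
            "gene_count": tot_genes,
            "repeat_fraction": tot_rep / tot_member if tot_member else 0.0,
            "snv_count": tot_snv,
            "snv_per_kb": tot_snv / (tot_member / 1000) if tot_member else 0.0,
        }
    )
    return pd.DataFrame(rows)


def read_variant_sites(path: str | Path) -> list[tuple[str, int]]:
    """(chrom, 0-based pos) sites from a VCF; only CHROM/POS are used."""
    import pysam

    with pysam.VariantFile(str(path)) as vcf:
        return [(rec.chrom, rec.pos - 1) for rec in vcf]


def write_scaffold_fasta(scaffolds: list[PseudoScaffold], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for sc in scaffolds:
            fh.write(f">{sc.name}\n")
            seq = sc.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_members_bed(scaffolds: list[PseudoScaffold], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sc in scaffolds:
            for m in sc.members:
                fh.write(f"{m.chrom}\t{m.start}\t{m.end}\t{sc.name}\t{m.support}\n")
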