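"""Windowed read-depth copy-number estimation with GC correction.

The estimation follows the read-depth segmental-duplication tradition:

1. tile the repeat-masked genome into windows of exactly 1000 unmasked,
   non-N bases (a window may span a larger genomic interval when it skips
   masked gaps; the final sub-window remainder per contig is dropped);
2. accumulate per-base depth from all reported alignments of every read
   (multi-mappers count everywhere, emulating an aligner's report-all mode);
3. correct window depth for GC bias by binned scaling against the global
   mean depth;
4. calibrate corrected depth into diploid copy-number units against
   designated control regions assumed to be copy-number 2, using the
   median control window for robustness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .mapping import Placements

WINDOW_SIZE = 1000

WINDOW_COLUMNS = ["chrom", "start", "end", "gc", "raw_depth", "corrected_depth", "cn"]


class InputError(ValueError):
    """Inconsistent or malformed pipeline input."""


class CalibrationError(RuntimeError):
    """Depth cannot be calibrated into copy-number units."""


@dataclass
class Windows:
    """Tiled depth windows over one contig.

    ``table`` holds one row per complete window (chrom, start, end, gc and,
    once computed, raw/corrected depth and cn). ``members`` is the
    (n_windows, 1000) array of the unmasked reference positions belonging
    to each window, used to average per-base depth.
    """

    chrom: str
    table: pd.DataFrame
    members: np.ndarray

    @property
    def n_windows(self) -> int:
        return len(self.table)

    def add_depth(self, depth: np.ndarray) -> None:
        """Attach mean per-base raw depth over each window's unmasked bases."""
        self.table["raw_depth"] = (
            depth[self.members].mean(axis=1) if self.n_windows else np.empty(0)
        )

    def write_tsv(self, path: str | Path) -> None:
        cols = [c for c in WINDOW_COLUMNS if c in self.table.columns]
        self.table[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")


def tile_windows(
    reference_codes: np.ndarray,
    mask: list[tuple[int, int]],
    chrom: str = "chr1",
    window: int = WINDOW_SIZE,
) -> Windows:
    """Tile a contig into consecutive runs of `window` unmasked non-N bases.

    Masked intervals must be sorted, non-overlapping and within the contig.
    A contig with fewer than `window` unmasked bases yields zero windows.
    """
    n = reference_codes.size
    prev_end = 0
    unmasked = np.ones(n, dtype=bool)
    for s, e in mask:
        if s < prev_end or e > n or s > e:
            raise InputError(f"bad mask interval ({s}, {e})")
        unmasked[s:e] = False
        prev_end = e
    unmasked &= reference_codes < 4  # N bases are gaps

    idx = np.flatnonzero(unmasked)
    n_win = idx.size // window
    members = idx[: n_win * window].reshape(n_win, window)
    if n_win:
        is_gc = (reference_codes == 1) | (reference_codes == 2)
        table = pd.DataFrame(
            {
                "chrom": chrom,
                "start": members[:, 0],
                "end": members[:, -1] + 1,
                "gc": is_gc[members].mean(axis=1),
            }
        )
    else:
        table = pd.DataFrame(columns=["chrom", "start", "end", "gc"])
    return Windows(chrom=chrom, table=table, members=members)


# ---------------------------------------------------------------------------
# depth accumulation


def depth_from_placements(placements: Placements, contig_length: int) -> np.ndarray:
    """Per-base depth from internal exact placements (every hit counts)."""
    diff = np.zeros(contig_length + 1, dtype=np.int64)
    np.add.at(diff, placements.positions, 1)
    np.add.at(diff, placements.positions + placements.read_length, -1)
    return np.cumsum(diff[:-1])


def depth_from_sam(
    path: str | Path, chrom: str, contig_length: int
) -> np.ndarray:
    """Per-base depth from a SAM file, counting every reported alignment.

    Secondary alignments count (mirrors an aligner's report-all mode);
    unmapped records are skipped; duplicates are not removed. Gapped
    alignments contribute depth over their aligned blocks only.
    """
    import pysam

    diff = np.zeros(contig_length + 1, dtype=np.int64)
    n_records = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        if chrom in sam.references:
            declared = sam.get_reference_length(chrom)
            if declared != contig_length:
                raise InputError(
                    f"contig {chrom!r}: SAM header length {declared} != reference {contig_length}"
                )
        for rec in sam:
            if rec.is_unmapped:
                continue
            if rec.reference_name != chrom:
                raise InputError(f"alignment on unknown contig {rec.reference_name!r}")
            n_records += 1
            for s, e in rec.get_blocks():
                diff[s] += 1
                diff[min(e, contig_length)] -= 1
    if n_records == 0:
        warnings.warn("no alignments ingested; depth is all zero", stacklevel=2)
    return np.cumsum(diff[:-1])


def ingest_alignments(
    source: Placements | str | Path, chrom: str, contig_length: int
) -> np.ndarray:
    """Per-base depth from either internal placements or a SAM file."""
    if isinstance(source, Placements):
        if source.chrom != chrom:
            raise InputError(f"placements are on contig {source.chrom!r}, expected {chrom!r}")
        if source.n_placements == 0:
            warnings.warn("no alignments ingested; depth is all zero", stacklevel=2)
        return depth_from_placements(source, contig_length)
    return depth_from_sam(source, chrom, contig_length)


# ---------------------------------------------------------------------------
# GC correction


@dataclass
class GCModel:
    """Binned GC -> mean-depth model.

    Bins with fewer than ``min_bin_count`` windows are considered
    unreliable and borrow the nearest reliable bin's mean; when no bin is
    reliable everything falls back to the global mean (no correction).
    """

    bin_width: float = 0.025
    min_bin_count: int = 20
    bin_means: np.ndarray = field(default_factory=lambda: np.empty(0))
    global_mean: float = 0.0

    @property
    def n_bins(self) -> int:
        return self.bin_means.size

    def bin_of(self, gc: np.ndarray) -> np.ndarray:
        b = (np.asarray(gc) / self.bin_width).astype(int)
        return np.clip(b, 0, self.n_bins - 1)


def fit_gc_model(
    windows: Windows,
    bin_width: float = 0.025,
    min_bin_count: int = 20,
    trim_mads: float = 3.0,
    trim_iterations: int = 3,
) -> GCModel:
    """Fit per-GC-bin mean raw depth over putatively diploid windows.

    Windows whose depth deviates from the median by more than ``trim_mads``
    robust standard deviations (1.4826 * MAD) are iteratively excluded from
    the fit (but still get corrected), so genuinely duplicated or deleted
    regions cannot distort the GC curve of the diploid background. When no
    window is trimmed the fit reduces to plain per-bin means.
    """
    if "raw_depth" not in windows.table.columns or windows.n_windows == 0:
        raise CalibrationError("no windows with depth to fit")
    gc = windows.table["gc"].to_numpy()
    raw = windows.table["raw_depth"].to_numpy()
    if raw.mean() <= 0:
        raise CalibrationError("no coverage")

    keep = np.ones(raw.size, dtype=bool)
    for _ in range(max(trim_iterations, 0)):
        med = np.median(raw[keep])
        scale = 1.4826 * np.median(np.abs(raw[keep] - med))
        new_keep = np.abs(raw - med) <= trim_mads * scale if scale > 0 else raw == med
        if new_keep.sum() == 0 or (new_keep == keep).all():
            break
        keep = new_keep

    global_mean = float(raw[keep].mean())
    if global_mean <= 0:
        raise CalibrationError("no coverage")
    n_bins = int(np.ceil(1.0 / bin_width))
    model = GCModel(bin_width=bin_width, min_bin_count=min_bin_count,
                    bin_means=np.full(n_bins, global_mean), global_mean=global_mean)
    bins = model.bin_of(gc[keep])
    counts = np.bincount(bins, minlength=n_bins)
    sums = np.bincount(bins, weights=raw[keep], minlength=n_bins)
    reliable = counts >= min_bin_count
    model.bin_means[reliable] = sums[reliable] / counts[reliable]
    # sparse bins borrow the nearest reliable bin so tail-GC windows still
    # get the monotone trend extrapolated; with no reliable bin at all the
    # global mean (no correction) stands
    if reliable.any():
        ridx = np.flatnonzero(reliable)
        for b in np.flatnonzero(~reliable):
            model.bin_means[b] = model.bin_means[ridx[np.argmin(np.abs(ridx - b))]]
    return model


def gc_correct(windows: Windows, model: GCModel) -> None:
    """Rescale each window's depth so GC bins share the global mean depth:
    corrected = raw * global_mean / bin_mean(gc)."""
    gc = windows.table["gc"].to_numpy()
    raw = windows.table["raw_depth"].to_numpy()
    means = model.bin_means[model.bin_of(gc)]
    bad = (means <= 0) & (raw > 0)
    if bad.any():
        raise CalibrationError(
            f"GC bin with zero mean depth but nonzero window depth (gc={gc[bad][0]:.3f})"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corrected = np.where(raw > 0, raw * model.global_mean / means, 0.0)
    windows.table["corrected_depth"] = corrected


# ---------------------------------------------------------------------------
# control calibration and copy number


@dataclass
class Calibration:
    """Depth-to-copy-number scale anchored on diploid control regions."""

    control_depth: float
    diploid_cn: float = 2.0
    n_control_windows: int = 0


def windows_in_intervals(windows: Windows, intervals: list[tuple[int, int]]) -> np.ndarray:
    """Boolean mask of windows whose genomic span lies fully inside any interval."""
    start = windows.table["start"].to_numpy()
    end = windows.table["end"].to_numpy()
    inside = np.zeros(windows.n_windows, dtype=bool)
    for s, e in intervals:
        inside |= (start >= s) & (end <= e)
    return inside


def calibrate(
    windows: Windows, control_intervals: list[tuple[int, int]], min_windows: int = 5
) -> Calibration:
    """Median corrected depth over control windows; controls are diploid."""
    inside = windows_in_intervals(windows, control_intervals)
    depths = windows.table.loc[inside, "corrected_depth"].to_numpy()
    if depths.size < min_windows:
        raise CalibrationError(
            f"only {depths.size} control windows (need >= {min_windows})"
        )
    control_depth = float(np.median(depths))
    if control_depth <= 0:
        raise CalibrationError("control regions have zero depth")
    return Calibration(control_depth=control_depth, n_control_windows=int(depths.size))


def estimate_cn(windows: Windows, calibration: Calibration) -> None:
    """cn = diploid_cn * corrected_depth / control_depth."""
    windows.table["cn"] = (
        calibration.diploid_cn
        * windows.table["corrected_depth"]
        / calibration.control_depth
    )


def read_windows_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
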