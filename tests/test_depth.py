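"""Window tiling, depth ingestion, GC correction and CN calibration."""

import numpy as np
import pandas as pd
import pytest

from bchromcnv import depth as d
from bchromcnv.depth import (
    CalibrationError,
    GCModel,
    InputError,
    Windows,
    calibrate,
    estimate_cn,
    fit_gc_model,
    gc_correct,
    tile_windows,
)
from bchromcnv.mapping import Placements


def make_placements(positions, read_length=100, chrom="chr1", n_reads=None):
    pos = np.asarray(positions, dtype=np.int64)
    return Placements(
        chrom=chrom,
        read_index=np.arange(pos.size, dtype=np.int64),
        positions=pos,
        read_length=read_length,
        n_reads=n_reads or pos.size,
        n_unplaced=0,
    )


def make_windows(gc, raw=None, window=1000):
    gc = np.asarray(gc, dtype=float)
    table = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(gc.size) * window,
            "end": (np.arange(gc.size) + 1) * window,
            "gc": gc,
        }
    )
    if raw is not None:
        table["raw_depth"] = np.asarray(raw, dtype=float)
    return Windows(chrom="chr1", table=table, members=np.empty((0, window), dtype=np.int64))


class TestTileWindows:
    def test_unmasked_contig_tiles_plainly(self):
        codes = np.zeros(5000, dtype=np.uint8)
        w = tile_windows(codes, [], "chr1")
        assert w.n_windows == 5
        assert w.table["start"].tolist() == [0, 1000, 2000, 3000, 4000]
        assert w.table["end"].tolist() == [1000, 2000, 3000, 4000, 5000]

    def test_fully_masked_contig_has_no_windows(self):
        codes = np.zeros(3000, dtype=np.uint8)
        w = tile_windows(codes, [(0, 3000)], "chr1")
        assert w.n_windows == 0

    def test_window_skips_masked_gap(self):
        # 2500 bp contig, mask [500, 1000): window 1 = unmasked bases
        # 0..499 and 1000..1500, genomic span [0, 1500); the remaining 1000
        # unmasked bases form a second complete window
        codes = np.zeros(2500, dtype=np.uint8)
        w = tile_windows(codes, [(500, 1000)], "chr1")
        assert w.n_windows == 2
        assert w.table.loc[0, "start"] == 0 and w.table.loc[0, "end"] == 1500
        expected = np.concatenate([np.arange(0, 500), np.arange(1000, 1500)])
        assert np.array_equal(w.members[0], expected)
        assert np.array_equal(w.members[1], np.arange(1500, 2500))

    def test_windows_partition_unmasked_bases(self):
        rng = np.random.default_rng(2)
        codes = rng.integers(0, 4, size=20_000).astype(np.uint8)
        mask = [(3000, 4200), (9000, 9100), (15_000, 17_000)]
        w = tile_windows(codes, mask, "chr1")
        flat = w.members.ravel()
        assert np.unique(flat).size == flat.size  # no base in two windows
        masked = np.zeros(codes.size, dtype=bool)
        for s, e in mask:
            masked[s:e] = True
        assert not masked[flat].any()
        n_unmasked = int((~masked).sum())
        assert w.n_windows == n_unmasked // 1000

    def test_n_bases_count_as_gaps(self):
        codes = np.zeros(2000, dtype=np.uint8)
        codes[500:1500] = 4
        w = tile_windows(codes, [], "chr1")
        assert w.n_windows == 1
        assert w.table.loc[0, "end"] == 2000  # spans the N gap

    def test_bad_mask_rejected(self):
        with pytest.raises(InputError):
            tile_windows(np.zeros(100, dtype=np.uint8), [(50, 20)], "chr1")


class TestIngestAlignments:
    def test_single_read_depth(self):
        dep = d.depth_from_placements(make_placements([0]), 300)
        assert dep[:100].tolist() == [1] * 100
        assert dep[100:].sum() == 0

    def test_additivity_and_multi_hits(self):
        # two identical reads plus one read reported at two locations
        dep = d.depth_from_placements(make_placements([50, 50, 120, 180]), 400)
        assert (dep[50:120] >= 2).all()
        assert (dep[120:150] == 3).all()  # two stacked reads + the 120 hit
        assert (dep[180:220] == 2).all()  # overlap of the 120 and 180 hits

    def test_brute_force_recount_equivalence(self):
        rng = np.random.default_rng(8)
        n, k = 50_000, 100
        pos = rng.integers(0, n - k, size=3000)
        dep = d.depth_from_placements(make_placements(pos, k), n)
        oracle = np.zeros(n, dtype=int)
        for p in pos:
            oracle[p : p + k] += 1
        assert np.array_equal(dep, oracle)

    def test_sam_depth_counts_all_alignments(self, tmp_path):
        sam = tmp_path / "a.sam"
        sam.write_text(
            "@HD\tVN:1.6\n"
            "@SQ\tSN:chr1\tLN:1000\n"
            "r1\t0\tchr1\t1\t60\t100M\t*\t0\t0\t*\t*\n"
            "r1\t256\tchr1\t201\t0\t100M\t*\t0\t0\t*\t*\n"  # secondary hit counts
            "r2\t0\tchr1\t51\t60\t100M\t*\t0\t0\t*\t*\n"
            "r3\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*\n"  # unmapped, skipped
        )
        dep = d.depth_from_sam(sam, "chr1", 1000)
        oracle = np.zeros(1000, dtype=int)
        for s in (0, 200, 50):  # SAM is 1-based; internal coords 0-based
            oracle[s : s + 100] += 1
        assert np.array_equal(dep, oracle)

    def test_sam_contig_mismatch_named(self, tmp_path):
        sam = tmp_path / "a.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:chrX\tLN:1000\n"
            "r1\t0\tchrX\t1\t60\t100M\t*\t0\t0\t*\t*\n"
        )
        with pytest.raises(InputError, match="chrX"):
            d.depth_from_sam(sam, "chr1", 1000)

    def test_empty_input_warns_and_zeroes(self, tmp_path):
        sam = tmp_path / "a.sam"
        sam.write_text("@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:500\n")
        with pytest.warns(UserWarning, match="no alignments"):
            dep = d.depth_from_sam(sam, "chr1", 500)
        assert dep.sum() == 0

    def test_depth_conservation_over_windows(self):
        # sum(raw_depth * 1000) equals read bases overlapping window members
        rng = np.random.default_rng(4)
        codes = rng.integers(0, 4, size=12_000).astype(np.uint8)
        mask = [(2000, 2600)]
        w = tile_windows(codes, mask, "chr1")
        pos = rng.integers(0, codes.size - 100, size=400)
        dep = d.depth_from_placements(make_placements(pos), codes.size)
        w.add_depth(dep)
        member_set = set(w.members.ravel().tolist())
        overlap = sum(
            len(member_set.intersection(range(p, p + 100))) for p in pos
        )
        assert np.isclose(w.table["raw_depth"].sum() * 1000, overlap)


class TestGCModel:
    def test_uniform_depth_single_bin(self):
        w = make_windows([0.5] * 25, [7.0] * 25)
        m = fit_gc_model(w)
        assert m.global_mean == 7.0
        assert m.bin_means[m.bin_of(np.array([0.5]))[0]] == 7.0

    def test_two_gc_classes(self):
        gc = [0.3] * 25 + [0.6] * 25
        raw = [5.0] * 25 + [9.0] * 25
        m = fit_gc_model(make_windows(gc, raw))
        assert m.global_mean == pytest.approx(7.0)
        assert m.bin_means[m.bin_of(np.array([0.3]))[0]] == pytest.approx(5.0)
        assert m.bin_means[m.bin_of(np.array([0.6]))[0]] == pytest.approx(9.0)

    def test_sparse_bin_borrows_nearest_reliable_bin(self):
        gc = [0.3] * 25 + [0.6] * 25 + [0.9] * 3  # last bin < min_bin_count
        raw = [5.0] * 25 + [9.0] * 25 + [9.0] * 3
        m = fit_gc_model(make_windows(gc, raw), trim_iterations=0)
        assert m.bin_means[m.bin_of(np.array([0.9]))[0]] == pytest.approx(9.0)

    def test_no_reliable_bin_falls_back_to_global(self):
        gc = np.linspace(0.05, 0.95, 12)  # every bin sparse
        raw = np.linspace(5, 9, 12)
        m = fit_gc_model(make_windows(gc, raw), trim_iterations=0)
        assert np.allclose(m.bin_means, m.global_mean)

    def test_all_zero_depth_is_an_error(self):
        with pytest.raises(CalibrationError, match="no coverage"):
            fit_gc_model(make_windows([0.5] * 30, [0.0] * 30))

    def test_outlier_windows_do_not_distort_bins(self):
        # a duplicated region 10x deeper than background is trimmed out
        gc = [0.42] * 100 + [0.42] * 5
        raw = [7.0] * 100 + [70.0] * 5
        m = fit_gc_model(make_windows(gc, raw))
        assert m.bin_means[m.bin_of(np.array([0.42]))[0]] == pytest.approx(7.0)


class TestGCCorrect:
    def test_uniform_gc_is_identity(self):
        w = make_windows([0.5] * 25, [3.0, 7.0, 11.0] * 8 + [7.0])
        gc_correct(w, fit_gc_model(w))
        assert np.allclose(w.table["corrected_depth"], w.table["raw_depth"])

    def test_binned_scaling_formula(self):
        w = make_windows([0.5, 0.5], [10.0, 0.0])
        model = GCModel(bin_means=np.full(40, 14.0), global_mean=7.0)
        gc_correct(w, model)
        assert w.table["corrected_depth"].tolist() == [5.0, 0.0]

    def test_corrected_mean_preserves_global_mean(self):
        rng = np.random.default_rng(0)
        gc = np.repeat([0.31, 0.41, 0.51], 40)
        raw = rng.uniform(5, 9, size=gc.size)
        w = make_windows(gc, raw)
        m = fit_gc_model(w, trim_iterations=0)
        gc_correct(w, m)
        assert w.table["corrected_depth"].mean() == pytest.approx(m.global_mean, rel=1e-9)

    def test_zero_bin_with_depth_is_an_error(self):
        w = make_windows([0.5], [3.0])
        model = GCModel(bin_means=np.zeros(40), global_mean=7.0)
        with pytest.raises(CalibrationError):
            gc_correct(w, model)


class TestCalibration:
    def _with_corrected(self, corrected):
        w = make_windows([0.5] * len(corrected), [1.0] * len(corrected))
        w.table["corrected_depth"] = corrected
        return w

    def test_constant_controls(self):
        w = self._with_corrected([7.0] * 6)
        cal = calibrate(w, [(0, 6000)])
        assert cal.control_depth == 7.0

    def test_median_of_controls(self):
        w = self._with_corrected([6.0, 7.0, 8.0, 7.0, 7.0])
        assert calibrate(w, [(0, 5000)]).control_depth == 7.0

    def test_too_few_control_windows(self):
        w = self._with_corrected([7.0] * 6)
        with pytest.raises(CalibrationError, match="control windows"):
            calibrate(w, [(0, 3000)])

    def test_cn_fixpoint_and_linearity(self):
        w = self._with_corrected([7.0, 14.0, 0.0, 3.5, 7.0, 7.0])
        cal = calibrate(w, [(0, 6000)])
        estimate_cn(w, cal)
        assert w.table["cn"].tolist() == [2.0, 4.0, 0.0, 1.0, 2.0, 2.0]


class TestGCInvariance:
    def test_correction_removes_depth_gc_correlation(self, small_cohort):
        res = small_cohort
        ind = res.individuals[0]
        w = ind.windows.table
        # diploid background only: windows outside planted fragments
        frag_ivs = list(res.reference.fragments.values())
        in_frag = np.zeros(len(w), dtype=bool)
        for s, e in frag_ivs:
            in_frag |= (w["start"].to_numpy() < e) & (w["end"].to_numpy() > s)
        bg = w[~in_frag]
        r_before = np.corrcoef(bg["gc"], bg["raw_depth"])[0, 1]
        r_after = np.corrcoef(bg["gc"], bg["corrected_depth"])[0, 1]
        assert abs(r_before) > 0.25  # bias is material before correction
        assert abs(r_after) <= 0.1
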