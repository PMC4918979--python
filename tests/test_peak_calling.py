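"""Binning, signal ratios, peak calling and TSS metaprofiles."""

import numpy as np
import pytest

from bivalent_smad.genome_io import GenomicInterval, ReadSet, ValidationError
from bivalent_smad.peak_calling import (
    RatioTrack, SignalTrack, bin_reads, benchmark_peaks, call_peaks,
    ratio_track, robust_background, tss_metaprofile)
from conftest import make_gene


def reads_from_starts(starts, chrom="chr1", length=50):
    reads = tuple(GenomicInterval(chrom, int(s), int(s) + length)
                  for s in starts)
    return ReadSet("s", "Smad2/3", "TGFb_plus", reads, len(reads))


def uniform_track(count, n_bins=1000, bin_size=100, chrom="chr1"):
    counts = {chrom: np.full(n_bins, count, dtype=np.int64)}
    return SignalTrack(bin_size=bin_size, counts=counts,
                       library_size=int(count * n_bins))


class TestBinReads:
    def test_read_assigned_by_midpoint(self):
        rs = reads_from_starts([150], length=100)  # read [150,250), mid 200
        track = bin_reads(rs, {"chr1": 1_000}, 100)
        assert track.counts["chr1"][2] == 1
        assert track.counts["chr1"].sum() == 1

    def test_empty_readset(self):
        rs = reads_from_starts([])
        track = bin_reads(rs, {"chr1": 1_000}, 100)
        assert track.library_size == 0
        assert track.counts["chr1"].sum() == 0

    def test_count_conservation(self):
        rng = np.random.default_rng(1)
        rs = reads_from_starts(rng.integers(0, 99_000, 10_000))
        track = bin_reads(rs, {"chr1": 100_000}, 137)
        assert track.total_count() == 10_000

    def test_trailing_partial_bin_included(self):
        rs = reads_from_starts([940], length=50)  # mid 965 -> last bin
        track = bin_reads(rs, {"chr1": 990}, 100)
        assert len(track.counts["chr1"]) == 10
        assert track.counts["chr1"][9] == 1

    def test_unknown_chromosome_listed(self):
        rs = reads_from_starts([0], chrom="chrX")
        with pytest.raises(ValidationError, match="chrX"):
            bin_reads(rs, {"chr1": 1_000}, 100)


class TestRatioTrack:
    def test_identical_chip_and_control_give_unity(self):
        chip = uniform_track(7)
        ctrl = uniform_track(7)
        rt = ratio_track(chip, ctrl)
        np.testing.assert_allclose(rt.ratios["chr1"], 1.0)

    def test_no_control_uniform_chip_near_unity(self):
        rt = ratio_track(uniform_track(50))
        np.testing.assert_allclose(rt.ratios["chr1"], 1.0, atol=0.05)

    def test_control_mode_ratio_limit(self):
        # one bin 10x the control density, vanishing pseudocount
        chip = uniform_track(10)
        chip.counts["chr1"][5] = 100
        chip.library_size = int(chip.counts["chr1"].sum())
        ctrl = uniform_track(10)
        ctrl.library_size = chip.library_size  # equal libraries
        rt = ratio_track(chip, ctrl, pseudocount=1e-9)
        assert rt.ratios["chr1"][5] == pytest.approx(10.0, rel=1e-6)

    def test_trimmed_background_ignores_enriched_bins(self):
        track = uniform_track(5, n_bins=10_000)
        track.counts["chr1"][:100] = 50  # 1% strongly enriched
        track.library_size = int(track.counts["chr1"].sum())
        assert robust_background(track) == pytest.approx(5.0, rel=0.01)

    def test_mismatched_binning_rejected(self):
        chip = uniform_track(5)
        ctrl = uniform_track(5, bin_size=200)
        with pytest.raises(ValidationError):
            ratio_track(chip, ctrl)

    def test_empty_chip_yields_zero_ratios(self):
        rt = ratio_track(uniform_track(0))
        assert not rt.ratios["chr1"].any()


def ratio_of(values, bin_size=100):
    return RatioTrack(bin_size, {"chr1": np.asarray(values, dtype=float)})


class TestCallPeaks:
    def test_flat_unity_track_has_no_peaks(self):
        assert call_peaks(ratio_of(np.ones(100)), 8.0) == []

    def test_runs_within_merge_gap_are_merged(self):
        r = np.ones(30)
        r[5:8] = 9.0
        r[9:12] = 9.0  # 100 bp gap at bin 8 < merge_gap
        peaks = call_peaks(ratio_of(r), 8.0, merge_gap=200)
        assert len(peaks) == 1
        assert (peaks[0].region.start, peaks[0].region.end) == (500, 1_200)

    def test_runs_beyond_merge_gap_stay_split(self):
        r = np.ones(30)
        r[5:8] = 9.0
        r[12:15] = 9.0  # 400 bp gap
        peaks = call_peaks(ratio_of(r), 8.0, merge_gap=200)
        assert len(peaks) == 2

    def test_narrow_regions_dropped(self):
        r = np.ones(30)
        r[5] = 9.0
        assert call_peaks(ratio_of(r), 8.0, min_width=200) == []
        assert len(call_peaks(ratio_of(r), 8.0, min_width=100)) == 1

    def test_summit_is_leftmost_max_ratio_bin(self):
        r = np.ones(30)
        r[5:10] = [9.0, 12.0, 10.0, 12.0, 9.0]
        (peak,) = call_peaks(ratio_of(r), 8.0)
        assert peak.summit == 650  # centre of bin 6, leftmost of the 12s
        assert peak.max_ratio == 12.0

    def test_summit_ratio_equals_bruteforce_max(self):
        rng = np.random.default_rng(5)
        r = 1.0 + 10.0 * rng.random(500)
        peaks = call_peaks(ratio_of(r), 8.0)
        assert peaks
        for p in peaks:
            lo = p.region.start // 100
            hi = p.region.end // 100
            assert p.max_ratio == max(r[lo:hi])
            assert p.max_ratio >= 8.0

    def test_calling_is_idempotent_on_called_regions(self):
        rng = np.random.default_rng(6)
        r = 1.0 + 10.0 * rng.random(500)
        peaks = call_peaks(ratio_of(r), 8.0)
        restricted = np.zeros_like(r)
        for p in peaks:
            lo, hi = p.region.start // 100, p.region.end // 100
            restricted[lo:hi] = r[lo:hi]
        again = call_peaks(ratio_of(restricted), 8.0)
        assert [(p.region.start, p.region.end) for p in again] == \
               [(p.region.start, p.region.end) for p in peaks]

    def test_raising_threshold_refines_peaks(self):
        rng = np.random.default_rng(7)
        r = 1.0 + 12.0 * rng.random(1_000)
        low = call_peaks(ratio_of(r), 5.0)
        high = call_peaks(ratio_of(r), 9.0)
        for hp in high:
            assert any(lp.region.start <= hp.region.start
                       and hp.region.end <= lp.region.end for lp in low)

    def test_threshold_must_exceed_one(self):
        with pytest.raises(ValidationError):
            call_peaks(ratio_of(np.ones(10)), 0.5)

    def test_planted_region_recovered_with_high_overlap(self):
        # one 10-fold 1 kb region over Poisson background at high depth
        rng = np.random.default_rng(8)
        density, L = 0.05, 200_000
        starts = list(rng.integers(0, L - 50, rng.poisson(density * L)))
        planted = GenomicInterval("chr1", 50_000, 51_000)
        n_extra = rng.poisson(9 * density * planted.length)
        starts += list(rng.integers(planted.start, planted.end - 50,
                                    n_extra))
        track = bin_reads(reads_from_starts(starts), {"chr1": L}, 100)
        peaks = call_peaks(ratio_track(track), 8.0)
        result = benchmark_peaks(peaks, [planted], min_reciprocal=0.8)
        assert result["n_recovered"] == 1


class TestMetaprofile:
    def test_signal_at_tss_bin_peaks_at_centre(self):
        gene = make_gene("g", "chr1", 10_000, [(0, 500), (800, 200)], "+")
        counts = {"chr1": np.zeros(200, dtype=np.int64)}
        counts["chr1"][gene.tss // 100] = 50
        track = SignalTrack(100, counts, 50)
        mp = tss_metaprofile(track, [gene], flank=1_000)
        assert len(mp.offsets) == 20
        assert np.argmax(mp.mean_signal) == 10  # first bin downstream of TSS
        np.testing.assert_allclose(mp.offsets, -mp.offsets[::-1])

    def test_minus_strand_profile_mirrors_plus(self):
        plus = make_gene("p", "chr1", 10_000, [(0, 500), (800, 200)], "+")
        minus = make_gene("m", "chr1", 30_000 - 1_000,
                          [(0, 200), (500, 500)], "-")
        counts = {"chr1": np.zeros(400, dtype=np.int64)}
        # 300 bp downstream of each TSS (strand-oriented)
        counts["chr1"][(plus.tss + 300) // 100] = 10
        counts["chr1"][(minus.tss - 300) // 100] = 10
        track = SignalTrack(100, counts, 20)
        mp_p = tss_metaprofile(track, [plus], flank=1_000)
        mp_m = tss_metaprofile(track, [minus], flank=1_000)
        np.testing.assert_allclose(mp_p.mean_signal, mp_m.mean_signal)

    def test_profile_is_mean_over_genes(self):
        g1 = make_gene("a", "chr1", 10_000, [(0, 300), (600, 100)], "+")
        g2 = make_gene("b", "chr1", 30_000, [(0, 300), (600, 100)], "+")
        counts = {"chr1": np.zeros(400, dtype=np.int64)}
        counts["chr1"][g1.tss // 100 - 2] = 8
        counts["chr1"][g2.tss // 100 + 3] = 4
        track = SignalTrack(100, counts, 12)
        both = tss_metaprofile(track, [g1, g2], flank=500)
        only1 = tss_metaprofile(track, [g1], flank=500)
        only2 = tss_metaprofile(track, [g2], flank=500)
        np.testing.assert_allclose(
            both.mean_signal, (only1.mean_signal + only2.mean_signal) / 2)

    def test_uniform_track_gives_flat_profile(self):
        gene = make_gene("g", "chr1", 50_000, [(0, 300), (600, 400)], "+")
        track = uniform_track(5, n_bins=1_000)
        mp = tss_metaprofile(track, [gene], flank=2_000)
        np.testing.assert_allclose(mp.mean_signal, mp.mean_signal[0])

    def test_empty_gene_list_rejected(self):
        with pytest.raises(ValidationError):
            tss_metaprofile(uniform_track(5), [], flank=1_000)

    def test_flank_must_align_to_bins(self):
        gene = make_gene("g", "chr1", 50_000, [(0, 300), (600, 400)], "+")
        with pytest.raises(ValidationError):
            tss_metaprofile(uniform_track(5), [gene], flank=250)
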