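"""Peak caller, consensus peaks (vs per-base oracle), extension, FRiP."""

import numpy as np
import pytest

from damtrack.genome import GatcIndex, build_fragment_map
from damtrack.ingest import ExtendedFragment
from damtrack.normalize import RatioTrack
from damtrack.peaks import (
    ConsensusPeak,
    Peak,
    PeakCallConfig,
    PeakError,
    call_peaks_ratio,
    consensus_peaks,
    extend_and_clip,
    frip,
    read_narrowpeak,
    read_peaks_bed,
    write_peaks_bed,
)


def _uniform_fmap(n, frag=100):
    sites = np.arange(1, n, dtype=np.int64) * frag - 2
    return build_fragment_map(GatcIndex({"c1": sites}), {"c1": n * frag})


def _peak(contig, s, e, label=""):
    return Peak(contig, s, e, score=1.0, n_fragments=1, fdr_q=0.0, sample_label=label)


class TestCallPeaks:
    def test_all_below_threshold_yields_nothing(self):
        fmap = _uniform_fmap(50)
        t = RatioTrack("t", np.full(50, -1.0), np.zeros(50, bool))
        assert call_peaks_ratio(t, fmap, PeakCallConfig(rng_seed=1)) == []

    def test_planted_run_recovered(self):
        rng = np.random.default_rng(1)
        n = 5000
        vals = rng.normal(0, 0.5, n)
        vals[1000:1010] = 3.0
        fmap = _uniform_fmap(n)
        peaks = call_peaks_ratio(
            RatioTrack("t", vals, np.zeros(n, bool)), fmap, PeakCallConfig(rng_seed=1)
        )
        hits = [p for p in peaks if p.start < 1010 * 100 and p.end > 1000 * 100]
        assert hits and hits[0].fdr_q <= 0.05

    def test_deterministic_and_seed_only_changes_q(self):
        rng = np.random.default_rng(2)
        n = 500
        vals = rng.normal(0, 0.5, n)
        vals[100:108] = 2.5
        fmap = _uniform_fmap(n)
        t = RatioTrack("t", vals, np.zeros(n, bool))
        p1 = call_peaks_ratio(t, fmap, PeakCallConfig(rng_seed=7))
        p2 = call_peaks_ratio(t, fmap, PeakCallConfig(rng_seed=7))
        assert [(p.start, p.end, p.fdr_q) for p in p1] == [
            (p.start, p.end, p.fdr_q) for p in p2
        ]
        p3 = call_peaks_ratio(t, fmap, PeakCallConfig(rng_seed=8))
        assert [(p.start, p.end) for p in p1] == [(p.start, p.end) for p in p3]

    def test_runs_broken_by_excluded_fragments(self):
        n = 60
        vals = np.full(n, 2.0)
        excl = np.zeros(n, bool)
        excl[30] = True
        vals[excl] = np.nan
        fmap = _uniform_fmap(n)
        peaks = call_peaks_ratio(
            RatioTrack("t", vals, excl), fmap, PeakCallConfig(rng_seed=1, fdr_threshold=1.0)
        )
        assert len(peaks) == 2
        assert peaks[0].end == 30 * 100 and peaks[1].start == 31 * 100

    def test_degenerate_track_is_error(self):
        fmap = _uniform_fmap(20)
        excl = np.ones(20, bool)
        excl[:5] = False
        vals = np.where(excl, np.nan, 1.0)
        with pytest.raises(PeakError, match="degenerate"):
            call_peaks_ratio(RatioTrack("t", vals, excl), fmap, PeakCallConfig(rng_seed=1))

    def test_min_fragments_respected(self):
        n = 100
        vals = np.zeros(n)
        vals[50] = 5.0  # single-fragment spike
        fmap = _uniform_fmap(n)
        peaks = call_peaks_ratio(
            RatioTrack("t", vals, np.zeros(n, bool)),
            fmap,
            PeakCallConfig(rng_seed=1, fdr_threshold=1.0, min_score_threshold=0.5),
        )
        assert peaks == []


def _consensus_oracle(peak_sets, min_support, extra_extension, length):
    """Per-base coverage counting + envelope extension + merge, brute force."""
    cov = np.zeros(length, dtype=int)
    for peaks in peak_sets:
        sample_cov = np.zeros(length, dtype=bool)
        for p in peaks:
            sample_cov[p.start : p.end] = True
        cov += sample_cov
    ok = cov >= min_support
    cores = []
    i = 0
    while i < length:
        if ok[i]:
            j = i
            while j < length and ok[j]:
                j += 1
            cores.append((i, j))
            i = j
        else:
            i += 1
    intervals = []
    for cs, ce in cores:
        overl = [
            (p.start, p.end, si)
            for si, peaks in enumerate(peak_sets)
            for p in peaks
            if p.start < ce and p.end > cs
        ]
        samples = {si for _, _, si in overl}
        s = min(x for x, _, _ in overl)
        e = max(x for _, x, _ in overl)
        intervals.append([s, e, len(samples)])
    # merge strict overlaps (support = max of merged supports)
    def merge(ivals):
        ivals = sorted(ivals, key=lambda x: (x[0], x[1]))
        out = []
        for iv in ivals:
            if out and iv[0] < out[-1][1]:
                out[-1][1] = max(out[-1][1], iv[1])
                out[-1][2] = max(out[-1][2], iv[2])
            else:
                out.append(list(iv))
        return out

    intervals = merge(intervals)
    if extra_extension:
        intervals = [
            [max(0, s - extra_extension), min(length, e + extra_extension), sup]
            for s, e, sup in intervals
        ]
        intervals = merge(intervals)
    return [(s, e, sup) for s, e, sup in intervals]


class TestConsensus:
    def test_worked_three_sample_example(self):
        sets = [[_peak("c1", 100, 200)], [_peak("c1", 150, 250)], [_peak("c1", 160, 180)]]
        out = consensus_peaks(sets, min_support=2)
        assert len(out) == 1
        c = out[0]
        assert (c.start, c.end) == (100, 250)
        assert (c.core_start, c.core_end) == (150, 200)
        assert c.support == 3

    def test_single_sample_identity(self):
        sets = [[_peak("c1", 10, 20), _peak("c1", 50, 70)]]
        out = consensus_peaks(sets, min_support=1)
        assert [(c.start, c.end, c.support) for c in out] == [(10, 20, 1), (50, 70, 1)]

    def test_unreachable_support_empty(self):
        sets = [[_peak("c1", 10, 20)], [_peak("c1", 100, 120)]]
        assert consensus_peaks(sets, min_support=2) == []

    def test_min_support_one_reproduces_merged_union(self):
        rng = np.random.default_rng(13)
        sets = []
        for _ in range(3):
            peaks, pos = [], 0
            for _ in range(5):
                s = pos + int(rng.integers(10, 200))
                e = s + int(rng.integers(10, 150))
                peaks.append(_peak("c1", s, e))
                pos = e
            sets.append(peaks)
        out = consensus_peaks(sets, min_support=1)
        oracle = _consensus_oracle(sets, 1, 0, 5000)
        assert [(c.start, c.end) for c in out] == [(s, e) for s, e, _ in oracle]

    def test_matches_perbase_oracle_on_random_instances(self):
        rng = np.random.default_rng(14)
        for _ in range(200):
            n_samples = int(rng.integers(1, 7))
            length = 10_000
            sets = []
            for _ in range(n_samples):
                peaks, pos = [], 0
                for _ in range(int(rng.integers(0, 31))):
                    s = pos + int(rng.integers(1, 400))
                    if s >= length - 2:
                        break
                    e = min(length, s + int(rng.integers(1, 300)))
                    peaks.append(_peak("c1", s, e))
                    pos = e + 1
                sets.append(peaks)
            min_support = int(rng.integers(1, n_samples + 1))
            ext = int(rng.choice([0, 0, 25]))
            out = consensus_peaks(
                sets, min_support=min_support, extra_extension=ext, lengths={"c1": length}
            )
            oracle = _consensus_oracle(sets, min_support, ext, length)
            assert [(c.start, c.end, c.support) for c in out] == oracle

    def test_core_coverage_monotone_in_min_support(self):
        rng = np.random.default_rng(15)
        for _ in range(30):
            sets = []
            for _ in range(4):
                peaks, pos = [], 0
                for _ in range(8):
                    s = pos + int(rng.integers(1, 200))
                    e = s + int(rng.integers(5, 200))
                    peaks.append(_peak("c1", s, e))
                    pos = e + 1
                sets.append(peaks)
            prev = None
            for ms in range(1, 5):
                out = consensus_peaks(sets, min_support=ms)
                covered = sum(c.core_end - c.core_start for c in out)
                if prev is not None:
                    assert covered <= prev
                prev = covered

    def test_invalid_min_support_is_error(self):
        with pytest.raises(PeakError):
            consensus_peaks([[_peak("c1", 0, 10)]], min_support=2)


class TestExtendAndClip:
    def test_basic_extension(self):
        out = extend_and_clip([_peak("c1", 10, 20)], 5, {"c1": 100})
        assert (out[0].start, out[0].end) == (5, 25)

    def test_clipping_at_contig_start(self):
        out = extend_and_clip([_peak("c1", 2, 10)], 5, {"c1": 100})
        assert (out[0].start, out[0].end) == (0, 15)

    def test_zero_is_identity_and_merging(self):
        peaks = [_peak("c1", 10, 20), _peak("c1", 22, 30)]
        assert [(p.start, p.end) for p in extend_and_clip(peaks, 0, {"c1": 100})] == [
            (10, 20),
            (22, 30),
        ]
        merged = extend_and_clip(peaks, 2, {"c1": 100})
        assert [(p.start, p.end) for p in merged] == [(8, 32)]


class TestFrip:
    def test_all_inside_genome_spanning_peak(self):
        frags = [ExtendedFragment("c1", i * 10, i * 10 + 5) for i in range(10)]
        assert frip(frags, [_peak("c1", 0, 1000)]) == 1.0

    def test_no_peaks_zero(self):
        frags = [ExtendedFragment("c1", 0, 10)]
        assert frip(frags, []) == 0.0

    def test_matches_midpoint_oracle(self):
        rng = np.random.default_rng(16)
        frags = [
            ExtendedFragment("c1", s, s + int(rng.integers(10, 100)))
            for s in rng.integers(0, 5000, 200)
        ]
        peaks = [_peak("c1", int(s), int(s) + 150) for s in rng.integers(0, 5000, 5)]
        expected = np.mean(
            [
                any(p.start <= (f.start + f.end) // 2 < p.end for p in peaks)
                for f in frags
            ]
        )
        assert frip(frags, peaks) == pytest.approx(expected)

    def test_zero_fragments_is_error(self):
        with pytest.raises(PeakError):
            frip([], [_peak("c1", 0, 10)])


class TestPeakBedIO:
    def test_peaks_round_trip(self, tmp_path):
        peaks = [
            Peak("c1", 100, 200, 1.234, 3, 0.01, "s1"),
            Peak("c2", 50, 80, -0.5, 2, 0.2, "s1"),
        ]
        p = tmp_path / "p.bed"
        write_peaks_bed(peaks, p, seed=42)
        back = read_peaks_bed(p, sample_label="s1")
        assert [(b.contig, b.start, b.end) for b in back] == [
            (q.contig, q.start, q.end) for q in peaks
        ]
        assert back[0].score == pytest.approx(1.234)
        assert back[0].fdr_q == pytest.approx(0.01)

    def test_narrowpeak_import(self, tmp_path):
        p = tmp_path / "m.narrowPeak"
        p.write_text("c1\t10\t90\tmacs_peak_1\t500\t.\t4.5\t10.0\t8.0\t40\n")
        peaks = read_narrowpeak(p, sample_label="macs")
        assert peaks[0].start == 10 and peaks[0].end == 90
        assert peaks[0].fdr_q == pytest.approx(1e-8)
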