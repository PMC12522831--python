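"""Fragment counting, pairings, ratio tracks, quantile normalisation, bedGraph I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from damtrack.genome import GatcIndex, build_fragment_map
from damtrack.ingest import ExtendedFragment
from damtrack.normalize import (
    FragmentCounts,
    NormalizeError,
    RatioTrack,
    count_reads_per_fragment,
    delog_track,
    enumerate_pairings,
    mean_track,
    normalize_pair,
    quantile_normalize,
    read_bedgraph,
    write_bedgraph,
)


def _fmap(boundaries, length):
    sites = np.asarray(boundaries, dtype=int) - 2
    return build_fragment_map(GatcIndex({"c1": sites}), {"c1": length})


class TestCounting:
    def test_full_containment(self):
        fmap = _fmap([200], 400)
        fc = count_reads_per_fragment([ExtendedFragment("c1", 0, 100)], fmap)
        assert list(fc.counts) == [1.0, 0.0]

    def test_proportional_split(self):
        fmap = _fmap([200], 400)
        fc = count_reads_per_fragment([ExtendedFragment("c1", 150, 250)], fmap)
        assert fc.counts == pytest.approx([0.5, 0.5])

    def test_conservation_on_random_fragments(self):
        rng = np.random.default_rng(2)
        sites = np.sort(rng.choice(np.arange(10, 9990, 7), 50, replace=False))
        fmap = build_fragment_map(GatcIndex({"c1": sites}), {"c1": 10_000})
        frags = []
        for _ in range(1000):
            s = int(rng.integers(0, 9700))
            frags.append(ExtendedFragment("c1", s, s + int(rng.integers(1, 300))))
        fc = count_reads_per_fragment(frags, fmap)
        assert fc.total == pytest.approx(1000, abs=1e-6)

    def test_unknown_contig_is_error(self, toy_fmap):
        with pytest.raises(NormalizeError, match="unknown contig"):
            count_reads_per_fragment([ExtendedFragment("chrZ", 0, 10)], toy_fmap)


class TestPairings:
    @pytest.mark.parametrize("nf,nd", [(3, 2), (1, 1), (6, 6)])
    def test_cardinality(self, nf, nd):
        pairs = enumerate_pairings([f"f{i}" for i in range(nf)], [f"d{j}" for j in range(nd)])
        assert len(pairs) == nf * nd
        assert len({lab for _, _, lab in pairs}) == nf * nd

    def test_fusion_major_order(self):
        assert [(f, d) for f, d, _ in enumerate_pairings(["a", "b"], ["x"])] == [
            ("a", "x"),
            ("b", "x"),
        ]

    def test_empty_list_is_error(self):
        with pytest.raises(NormalizeError, match="Dam-only"):
            enumerate_pairings(["a"], [])


class TestNormalizePair:
    def _counts(self, vec, sid="s", role="fusion"):
        return FragmentCounts(sid, role, np.asarray(vec, float))

    def test_identity_gives_zero(self):
        x = self._counts([5, 2, 9, 1, 3, 8, 2, 4, 6, 7])
        t = normalize_pair(x, x)
        assert t.defined_values() == pytest.approx(0.0, abs=1e-12)
        assert t.scale_offset == pytest.approx(0.0, abs=1e-12)

    def test_swap_negates(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = self._counts(rng.poisson(5.0, 50))
            b = self._counts(rng.poisson(5.0, 50), role="dam_only")
            t1 = normalize_pair(a, b)
            t2 = normalize_pair(b, a)
            assert np.array_equal(t1.excluded_mask, t2.excluded_mask)
            np.testing.assert_allclose(
                t1.values[~t1.excluded_mask], -t2.values[~t2.excluded_mask], atol=1e-6
            )
            assert t1.scale_offset == pytest.approx(-t2.scale_offset, abs=1e-6)

    def test_doubled_counts_equal_after_cpm(self):
        # oracle: CPM scaling makes 2x-scaled counts identical -> log ratios 0
        d = np.array([10.0, 20.0, 30.0, 25.0, 15.0])
        t = normalize_pair(
            self._counts(2 * d), self._counts(d, role="dam_only"), offset_method="none"
        )
        cpm_f = 2 * d / (2 * d).sum() * 1e6
        cpm_d = d / d.sum() * 1e6
        expected = np.log2((cpm_f + 0.5) / (cpm_d + 0.5))
        np.testing.assert_allclose(t.values, expected, atol=1e-12)
        assert np.abs(t.values).max() < 1e-9

    def test_exclusion_of_double_zero_fragments(self):
        t = normalize_pair(
            self._counts([0, 5, 0, 3]), self._counts([0, 2, 1, 0], role="dam_only")
        )
        assert list(t.excluded_mask) == [True, False, False, False]
        assert np.isnan(t.values[0])

    def test_all_excluded_is_error(self):
        with pytest.raises(NormalizeError):
            normalize_pair(self._counts([0, 0]), self._counts([0, 0]))

    def test_offset_centres_background_mode(self):
        # bulk of fragments unchanged, a few enriched: offset should track the bulk
        rng = np.random.default_rng(9)
        d = rng.poisson(50.0, 500).astype(float) + 1
        f = d * 2.0
        f[:25] *= 16  # enriched minority
        t = normalize_pair(self._counts(f), self._counts(d, role="dam_only"))
        assert abs(np.median(t.values[25:])) < 0.1


class TestQuantileNormalize:
    def _track(self, vals, excluded=None, label="t"):
        vals = np.asarray(vals, float)
        excl = np.zeros(len(vals), bool) if excluded is None else np.asarray(excluded, bool)
        v = vals.copy()
        v[excl] = np.nan
        return RatioTrack(label, v, excl)

    def test_worked_tie_example(self):
        a, b = self._track([5, 2, 3], label="A"), self._track([4, 1, 4], label="B")
        qa, qb = quantile_normalize([a, b])
        np.testing.assert_allclose(qa.values, [4.5, 1.5, 3.5])
        np.testing.assert_allclose(qb.values, [4.0, 1.5, 4.0])

    def test_sorted_vectors_identical_without_ties(self):
        rng = np.random.default_rng(4)
        tracks = [self._track(rng.normal(size=200), label=f"t{i}") for i in range(4)]
        out = quantile_normalize(tracks)
        ref = np.sort(out[0].values)
        for t in out[1:]:
            np.testing.assert_allclose(np.sort(t.values), ref, atol=1e-9)

    def test_idempotent_without_ties(self):
        rng = np.random.default_rng(5)
        tracks = [self._track(rng.normal(size=100), label=f"t{i}") for i in range(3)]
        once = quantile_normalize(tracks)
        twice = quantile_normalize(once)
        for t1, t2 in zip(once, twice):
            np.testing.assert_allclose(t1.values, t2.values, atol=1e-12)

    def test_identical_tracks_fixed_point(self):
        v = np.array([0.5, -1.0, 2.0, 0.0])
        tracks = [self._track(v, label="a"), self._track(v.copy(), label="b")]
        out = quantile_normalize(tracks)
        for t in out:
            np.testing.assert_allclose(t.values, v, atol=1e-12)

    def test_restricted_to_shared_fragments(self):
        a = self._track([1.0, 2.0, 3.0, 9.0], excluded=[False, False, False, True])
        b = self._track([3.0, 1.0, 2.0, 5.0], excluded=[False, False, False, False])
        qa, qb = quantile_normalize([a, b])
        # fragment 3 is not shared: a stays excluded, b keeps its value
        assert np.isnan(qa.values[3]) and qb.values[3] == 5.0
        np.testing.assert_allclose(np.sort(qa.values[:3]), np.sort(qb.values[:3]))

    def test_rank_order_preserved_within_sample(self):
        rng = np.random.default_rng(6)
        tracks = [self._track(rng.normal(size=50), label=f"t{i}") for i in range(3)]
        out = quantile_normalize(tracks)
        for before, after in zip(tracks, out):
            assert np.array_equal(np.argsort(before.values), np.argsort(after.values))

    def test_too_few_tracks_is_error(self):
        with pytest.raises(NormalizeError):
            quantile_normalize([self._track([1, 2, 3])])


class TestTrackUtilities:
    def test_mean_of_single_track_is_identity(self):
        t = RatioTrack("a", np.array([1.0, np.nan]), np.array([False, True]))
        m = mean_track([t])
        np.testing.assert_allclose(m.values[0], 1.0)
        assert m.excluded_mask[1]

    def test_mean_of_track_and_negation_is_zero(self):
        v = np.array([1.0, -2.0, 0.5])
        t1 = RatioTrack("a", v, np.zeros(3, bool))
        t2 = RatioTrack("b", -v, np.zeros(3, bool))
        np.testing.assert_allclose(mean_track([t1, t2]).values, 0.0, atol=1e-12)

    def test_mean_matches_elementwise_oracle(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(size=(3, 30))
        tracks = [RatioTrack(f"t{i}", vals[i], np.zeros(30, bool)) for i in range(3)]
        np.testing.assert_allclose(mean_track(tracks).values, vals.mean(axis=0), atol=1e-12)

    def test_mean_excluded_only_where_all_excluded(self):
        t1 = RatioTrack("a", np.array([np.nan, 2.0]), np.array([True, False]))
        t2 = RatioTrack("b", np.array([4.0, np.nan]), np.array([False, True]))
        m = mean_track([t1, t2])
        np.testing.assert_allclose(m.values, [4.0, 2.0])
        assert not m.excluded_mask.any()

    @pytest.mark.parametrize("v,expected", [(0.0, 1.0), (1.0, 2.0), (-1.0, 0.5)])
    def test_delog_values(self, v, expected):
        t = RatioTrack("a", np.array([v]), np.array([False]))
        assert delog_track(t)[0] == pytest.approx(expected)

    def test_delog_round_trip(self):
        rng = np.random.default_rng(10)
        v = rng.normal(size=20)
        t = RatioTrack("a", v, np.zeros(20, bool))
        np.testing.assert_allclose(np.log2(delog_track(t)), v, atol=1e-12)


class TestBedgraphIO:
    def test_line_format(self, tmp_path):
        fmap = _fmap([], 6)
        t = RatioTrack("x", np.array([0.25]), np.array([False]))
        p = tmp_path / "t.bedgraph"
        write_bedgraph(t, fmap, p)
        lines = p.read_text().splitlines()
        assert lines[1] == "c1\t0\t6\t0.25"

    def test_round_trip_and_excluded_intervals(self, tmp_path):
        rng = np.random.default_rng(11)
        sites = np.sort(rng.choice(np.arange(10, 990, 5), 20, replace=False))
        fmap = build_fragment_map(GatcIndex({"c1": sites}), {"c1": 1000})
        n = fmap.n_fragments
        excl = rng.random(n) < 0.3
        vals = rng.normal(size=n)
        vals[excl] = np.nan
        t = RatioTrack("pair1", vals, excl, scale_offset=0.3)
        p = tmp_path / "t.bedgraph"
        write_bedgraph(t, fmap, p)
        back = read_bedgraph(p, fmap)
        assert back.pair_label == "pair1"
        assert np.array_equal(back.excluded_mask, excl)
        np.testing.assert_allclose(
            back.values[~excl], t.values[~excl], atol=1e-6, rtol=1e-5
        )

    def test_malformed_line_names_line_number(self, tmp_path, toy_fmap):
        p = tmp_path / "bad.bedgraph"
        p.write_text("c1\t0\t6\t0.5\nc1\tnot_a_number\n")
        with pytest.raises(NormalizeError, match="line 2"):
            read_bedgraph(p, toy_fmap)
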