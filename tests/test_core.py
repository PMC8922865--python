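"""Unit and property tests for ranking, chord fitting, perpendicular
distances and cutoff identification."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import rankcutoff as rc
from conftest import random_profile

finite = st.floats(allow_nan=False, allow_infinity=False, width=64)


# ---------------------------------------------------------------- ranking


class TestRankProfile:
    def test_sorts_ascending_and_assigns_ranks(self):
        p = rc.rank_profile(
            [rc.ValueRecord("g1", 10), rc.ValueRecord("g2", 0), rc.ValueRecord("g3", 1)]
        )
        assert p.identifiers == ("g2", "g3", "g1")
        assert p.values.tolist() == [0, 1, 10]
        assert p.ranks.tolist() == [1, 2, 3]

    def test_ties_broken_by_identifier(self):
        p = rc.rank_profile(
            [rc.ValueRecord("b", 5), rc.ValueRecord("a", 5), rc.ValueRecord("c", 0)]
        )
        assert p.identifiers == ("c", "a", "b")

    def test_too_few_records_is_size_error(self):
        with pytest.raises(rc.SizeError):
            rc.rank_profile([rc.ValueRecord("a", 1), rc.ValueRecord("b", 2)])

    @pytest.mark.parametrize("bad", [-1.0, float("nan"), float("inf")])
    def test_invalid_value_names_offender(self, bad):
        recs = [rc.ValueRecord("ok1", 1), rc.ValueRecord("bad", bad), rc.ValueRecord("ok2", 2)]
        with pytest.raises(rc.ValidationError, match="bad"):
            rc.rank_profile(recs)

    def test_empty_identifier_rejected(self):
        recs = [rc.ValueRecord("", 1), rc.ValueRecord("b", 2), rc.ValueRecord("c", 3)]
        with pytest.raises(rc.ValidationError):
            rc.rank_profile(recs)


# ---------------------------------------------------------------- chord


class TestFitChord:
    def test_two_point_line(self):
        p = rc.rank_profile([rc.ValueRecord(c, v) for c, v in [("a", 0), ("b", 1), ("c", 10)]])
        ch = rc.fit_chord(p)
        assert ch.m_b == pytest.approx(5.0)
        assert ch.b_b == pytest.approx(-5.0)

    def test_passes_through_endpoints(self):
        rng = np.random.default_rng(7)
        p = random_profile(rng)
        ch = rc.fit_chord(p)
        assert ch.y_at(1) == pytest.approx(p.values[0], abs=1e-9)
        assert ch.y_at(p.n) == pytest.approx(p.values[-1], abs=1e-9)
        assert ch.m_b >= 0

    def test_flat_profile_is_degenerate(self, fixtures):
        p = rc.rank_profile(fixtures["flat"])
        with pytest.raises(rc.DegenerateProfileError):
            rc.fit_chord(p)

    def test_zero_minimum_gives_b_equals_minus_m(self, micro_profile):
        # data with V_min = 0: chord through (1, 0) forces b_B = -m_B
        ch = rc.fit_chord(micro_profile)
        assert ch.b_b == pytest.approx(-ch.m_b)


# ------------------------------------------------- perpendicular geometry


class TestPerpendicularGeometry:
    @pytest.mark.parametrize(
        "m, b, r, v, b_c, y_cb, x_cb",
        [
            (2.0, 0.0, 3.0, 4.0, 5.5, 4.4, 2.2),
            (1.0, 0.0, 2.0, 0.0, 2.0, 1.0, 1.0),
        ],
    )
    def test_stepwise_construction_examples(self, m, b, r, v, b_c, y_cb, x_cb):
        g = rc.perpendicular_geometry(r, v, rc.Chord(m, b))
        assert g.b_c == pytest.approx(b_c)
        assert g.y_cb == pytest.approx(y_cb)
        assert g.x_cb == pytest.approx(x_cb)

    def test_point_on_chord_is_its_own_foot(self):
        ch = rc.Chord(0.7, 1.3)
        g = rc.perpendicular_geometry(2.0, ch.y_at(2.0), ch)
        assert g.x_cb == pytest.approx(2.0)
        assert g.y_cb == pytest.approx(ch.y_at(2.0))

    @given(
        m=st.floats(min_value=1e-3, max_value=1e3),
        b=st.floats(min_value=-100, max_value=100),
        r=st.floats(min_value=1, max_value=1e4),
        v=st.floats(min_value=0, max_value=1e4),
    )
    def test_foot_on_chord_and_segment_perpendicular(self, m, b, r, v):
        ch = rc.Chord(m, b)
        g = rc.perpendicular_geometry(r, v, ch)
        scale = 1.0 + abs(g.y_cb)
        assert abs(g.y_cb - ch.y_at(g.x_cb)) <= 1e-9 * scale
        # direction of the segment dotted with direction of the chord
        dot = (g.x_cb - g.x_ac) * 1.0 + (g.y_cb - g.y_ac) * m
        assert abs(dot) <= 1e-6 * (1 + abs(v) + abs(m * r))

    def test_horizontal_chord_rejected(self):
        with pytest.raises(rc.DegenerateProfileError):
            rc.perpendicular_geometry(1.0, 1.0, rc.Chord(0.0, 1.0))


# ------------------------------------------------------ segment lengths


class TestSegmentLengths:
    @pytest.mark.parametrize(
        "m, b, r, v, expected",
        [
            (2.0, 0.0, 3.0, 4.0, math.sqrt(0.8)),
            (1.0, 0.0, 2.0, 0.0, math.sqrt(2.0)),
            (0.7, 1.3, 5.0, 0.7 * 5 + 1.3, 0.0),  # point on the chord
        ],
    )
    def test_both_routes_match_expected(self, m, b, r, v, expected):
        ch = rc.Chord(m, b)
        assert rc.segment_length_stepwise(r, v, ch) == pytest.approx(expected, abs=1e-12)
        assert rc.segment_length_closed(r, v, ch) == pytest.approx(expected, abs=1e-12)

    @given(
        m=st.one_of(
            st.floats(min_value=1e-4, max_value=1e4),
            st.floats(min_value=-1e4, max_value=-1e-4),
        ),
        b=st.floats(min_value=-1e4, max_value=1e4),
        r=st.floats(min_value=1, max_value=1e5),
        v=st.floats(min_value=0, max_value=1e6),
    )
    def test_closed_equals_stepwise_equals_residual_form(self, m, b, r, v):
        ch = rc.Chord(m, b)
        d_step = rc.segment_length_stepwise(r, v, ch)
        d_closed = rc.segment_length_closed(r, v, ch)
        d_resid = abs(v - m * r - b) / math.sqrt(1 + m * m)
        assert abs(d_closed - d_step) <= 1e-9 * (1 + d_step)
        assert d_closed == pytest.approx(d_resid, rel=1e-12, abs=1e-12)


# ------------------------------------------------------ distance profile


class TestDistanceProfile:
    def test_micro_example(self, micro_profile):
        ch = rc.fit_chord(micro_profile)
        d = rc.distance_profile(micro_profile, ch).distances
        # brute-force values from the stepwise construction at every rank
        expected = [0.0, 0.9284766909, 1.8569533817, 2.7854300726, 0.0]
        assert d == pytest.approx(expected, abs=1e-9)

    def test_perfect_line_all_zero(self, fixtures):
        p = rc.rank_profile(fixtures["perfect_line"])
        d = rc.distance_profile(p, rc.fit_chord(p)).distances
        assert np.all(d == 0)

    def test_scaling_preserves_argmax_and_scales_distances(self):
        rng = np.random.default_rng(11)
        p = random_profile(rng)
        d1 = rc.distance_profile(p, rc.fit_chord(p)).distances
        p10 = rc.rank_profile(
            [rc.ValueRecord(i, 10 * v) for i, v in zip(p.identifiers, p.values)]
        )
        d10 = rc.distance_profile(p10, rc.fit_chord(p10)).distances
        inner = slice(1, p.n - 1)
        ratios = d10[inner][d1[inner] > 0] / d1[inner][d1[inner] > 0]
        assert np.allclose(ratios, ratios[0])
        assert np.argmax(d1) == np.argmax(d10)

    def test_endpoints_are_zero(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = random_profile(rng)
            d = rc.distance_profile(p, rc.fit_chord(p)).distances
            assert abs(d[0]) <= 1e-9 and abs(d[-1]) <= 1e-9


# ------------------------------------------------------------ find_cutoff


class TestFindCutoff:
    def test_micro_example(self, micro_profile):
        c = rc.find_cutoff(micro_profile)
        assert c.cutoff_rank == 4
        assert c.shortlist_size == 1
        assert c.max_distance == pytest.approx(2.7854300726, abs=1e-9)

    def test_flat_profile_raises(self, fixtures):
        with pytest.raises(rc.DegenerateProfileError):
            rc.find_cutoff(rc.rank_profile(fixtures["flat"]))

    @pytest.mark.parametrize("n,k", [(10, 5), (100, 90), (1000, 997), (50, 3)])
    def test_exact_knee_on_piecewise_linear(self, n, k):
        spec = rc.BiphasicSpec(
            n=n, knee_rank=k,
            phase1=rc.PhaseModel("linear", 0.1),
            phase2=rc.PhaseModel("linear", 3.0),
        )
        p = rc.rank_profile(rc.generate_biphasic(spec))
        assert rc.find_cutoff(p).cutoff_rank == k

    def test_tie_rule_returns_largest_rank(self, fixtures):
        p = rc.rank_profile(fixtures["perfect_line"])
        c = rc.find_cutoff(p)
        assert c.cutoff_rank == p.n
        assert c.tie_count == p.n
        assert c.shortlist_size == 0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(23)
        p = random_profile(rng)
        recs = p.records()
        base = rc.find_cutoff(p)
        for seed in range(3):
            shuffled = list(recs)
            np.random.default_rng(seed).shuffle(shuffled)
            c = rc.find_cutoff(rc.rank_profile(shuffled))
            assert (c.cutoff_rank, c.cutoff_identifier) == (
                base.cutoff_rank,
                base.cutoff_identifier,
            )

    @given(
        a=st.floats(min_value=1e-3, max_value=1e3),
        c=st.floats(min_value=0, max_value=1e3),
        seed=st.integers(min_value=0, max_value=50),
    )
    def test_affine_invariance(self, a, c, seed):
        rng = np.random.default_rng(seed)
        p = random_profile(rng)
        base = rc.find_cutoff(p)
        pt = rc.rank_profile(
            [rc.ValueRecord(i, a * v + c) for i, v in zip(p.identifiers, p.values)]
        )
        ct = rc.find_cutoff(pt)
        assert ct.cutoff_rank == base.cutoff_rank
        assert ct.cutoff_identifier == base.cutoff_identifier


# -------------------------------------------------- shortlist and controls


class TestShortlist:
    def test_micro_example_single_record(self, micro_profile):
        c = rc.find_cutoff(micro_profile)
        sl = rc.extract_shortlist(micro_profile, c)
        assert len(sl) == 1
        assert sl[0].value == 10

    def test_strictly_above_cutoff_descending(self):
        spec = rc.BiphasicSpec(
            n=50, knee_rank=40,
            phase1=rc.PhaseModel("linear", 0.1), phase2=rc.PhaseModel("linear", 5.0),
        )
        p = rc.rank_profile(rc.generate_biphasic(spec))
        c = rc.find_cutoff(p)
        sl = rc.extract_shortlist(p, c)
        assert len(sl) == p.n - c.cutoff_rank
        assert c.cutoff_identifier not in {r.identifier for r in sl}
        values = [r.value for r in sl]
        assert values == sorted(values, reverse=True)

    def test_cutoff_at_n_gives_empty_shortlist(self, fixtures):
        p = rc.rank_profile(fixtures["perfect_line"])
        c = rc.find_cutoff(p)
        assert rc.extract_shortlist(p, c) == []

    def test_shortlist_size_conservation(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            p = random_profile(rng)
            c = rc.find_cutoff(p)
            assert c.shortlist_size + c.cutoff_rank == p.n


class TestLowTailControlList:
    def test_zeros_excluded(self):
        recs = [rc.ValueRecord(f"g{i}", v) for i, v in enumerate([0, 0, 1, 2, 3, 9])]
        p = rc.rank_profile(recs)
        ctl = rc.low_tail_control_list(p, 2)
        assert [r.value for r in ctl] == [1, 2]

    def test_size_equal_to_nonzero_count(self):
        recs = [rc.ValueRecord(f"g{i}", v) for i, v in enumerate([0, 0, 1, 2, 3, 9])]
        p = rc.rank_profile(recs)
        assert [r.value for r in rc.low_tail_control_list(p, 4)] == [1, 2, 3, 9]

    def test_oversize_request_is_size_error(self):
        recs = [rc.ValueRecord(f"g{i}", v) for i, v in enumerate([0, 0, 1, 2, 3, 9])]
        p = rc.rank_profile(recs)
        with pytest.raises(rc.SizeError):
            rc.low_tail_control_list(p, 5)

    def test_disjoint_from_shortlist(self):
        spec = rc.BiphasicSpec(
            n=100, knee_rank=90,
            phase1=rc.PhaseModel("linear", 0.1), phase2=rc.PhaseModel("linear", 5.0),
        )
        p = rc.rank_profile(rc.generate_biphasic(spec))
        c = rc.find_cutoff(p)
        sl = {r.identifier for r in rc.extract_shortlist(p, c)}
        ctl = {r.identifier for r in rc.low_tail_control_list(p, c.shortlist_size)}
        assert sl.isdisjoint(ctl)


# ---------------------------------------------------------- adjust_cutoff


class TestAdjustCutoff:
    @pytest.fixture
    def profile_100(self):
        spec = rc.BiphasicSpec(
            n=100, knee_rank=90,
            phase1=rc.PhaseModel("linear", 0.1), phase2=rc.PhaseModel("linear", 5.0),
        )
        return rc.rank_profile(rc.generate_biphasic(spec))

    def test_zero_offset_is_identity(self, profile_100):
        c = rc.find_cutoff(profile_100)
        adj = rc.adjust_cutoff(c, profile_100, 0.0)
        assert adj == c

    def test_positive_offset_shifts_rank(self, profile_100):
        c = rc.find_cutoff(profile_100)
        assert c.cutoff_rank == 90
        adj = rc.adjust_cutoff(c, profile_100, 0.05)
        assert adj.cutoff_rank == 95
        assert adj.reference_rank == 90
        assert adj.shortlist_size == 5

    def test_offset_clamps_at_n(self, profile_100):
        c = rc.find_cutoff(profile_100)
        forced = rc.adjust_cutoff(c, profile_100, 0.05)  # 95
        clamped = rc.adjust_cutoff(forced, profile_100, 0.06)  # 95 + 6 -> 100 (clamp)
        assert clamped.cutoff_rank == 100
        assert clamped.shortlist_size == 0

    @pytest.mark.parametrize("offset", [-1.0, 1.0, 1.5])
    def test_offset_out_of_range(self, profile_100, offset):
        c = rc.find_cutoff(profile_100)
        with pytest.raises(rc.ValidationError):
            rc.adjust_cutoff(c, profile_100, offset)
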