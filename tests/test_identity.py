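"""Attitude kernel, attitude matrices, and group statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from latacc.identity import (
    AcceptanceSegment,
    Agent,
    CulturalIdentity,
    Population,
    PositionGrid,
    UnresolvableSegmentError,
    attitude_matrix,
    group_of,
    group_stats,
    identity_attitude,
    position_attitude,
    segment_attitude,
)

from conftest import random_identity, random_segment


def seg(b, a, B):
    return AcceptanceSegment(b, a, B)


@st.composite
def segments(draw, min_margin=0.0):
    vals = sorted(
        draw(
            st.lists(
                st.floats(-1, 1, allow_nan=False), min_size=3, max_size=3
            )
        )
    )
    b, a, B = vals
    if a - b < min_margin or B - a < min_margin:
        b = max(-1.0, a - max(min_margin, a - b))
        B = min(1.0, a + max(min_margin, B - a))
    return AcceptanceSegment(b, a, B)


class TestPositionAttitude:
    @pytest.mark.parametrize(
        "segment, p, expected",
        [
            # worked example: wide upper margin values p=0.2 at tanh(-0.25)
            (seg(-0.85, -0.85, -0.15), 0.2, math.tanh(-0.25)),
            # narrower upper margin values the same position more negatively
            (seg(-0.85, -0.50, -0.15), 0.2, math.tanh(-0.5)),
            # strictly inside the segment: full acceptance
            (seg(-0.85, -0.50, -0.15), -0.5, 1.0),
            (seg(-0.85, -0.50, -0.15), -0.8, 1.0),
            # exactly at a bound: zero
            (seg(-0.85, -0.50, -0.15), -0.15, 0.0),
            (seg(-0.85, -0.50, -0.15), -0.85, 0.0),
            # below the lower bound: lower-branch sigmoid
            (seg(-0.2, 0.3, 0.6), -0.7, math.tanh((1 + (-0.7 - 0.3) / 0.5) / 2)),
        ],
    )
    def test_values(self, segment, p, expected):
        assert position_attitude(segment, p) == pytest.approx(expected, abs=1e-12)

    def test_rounds_to_published_two_decimals(
        self, wide_margin_segment, narrow_margin_segment
    ):
        assert round(position_attitude(wide_margin_segment, 0.2), 2) == -0.24
        assert round(position_attitude(narrow_margin_segment, 0.2), 2) == -0.46

    def test_degenerate_margin_returns_limit(self):
        s = seg(-0.3, -0.3, 0.5)  # zero lower margin
        assert position_attitude(s, -0.6) == -1.0
        s2 = seg(-0.5, 0.4, 0.4)  # zero upper margin
        assert position_attitude(s2, 0.9) == -1.0

    def test_monotone_decrease_toward_asymptote(self, narrow_margin_segment):
        p = np.linspace(-0.15, 1.0, 500)[1:]
        vals = position_attitude(narrow_margin_segment, p)
        assert np.all(np.diff(vals) < 0)
        assert np.all(vals > -1)
        assert vals[-1] < -0.46

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(segments(), st.floats(-1, 1, allow_nan=False))
    def test_reflection_symmetry(self, s, p):
        mirrored = AcceptanceSegment(
            -s.upper_bound, -s.ma_position, -s.lower_bound
        )
        assert position_attitude(s, p) == pytest.approx(
            position_attitude(mirrored, -p), abs=1e-12
        )

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(segments())
    def test_range_and_boundary_structure(self, s):
        p = np.linspace(-1, 1, 301)
        vals = position_attitude(s, p)
        assert np.all(vals >= -1) and np.all(vals <= 1)
        interior = (p > s.lower_bound) & (p < s.upper_bound)
        assert np.all(vals[interior] == 1.0)
        outside = ~interior & (p != s.lower_bound) & (p != s.upper_bound)
        assert np.all(vals[outside] <= 0)

    def test_smaller_margin_falls_faster(
        self, wide_margin_segment, narrow_margin_segment
    ):
        # same segment, narrower upper margin => more negative outside above
        p = np.linspace(-0.1, 1.0, 50)
        wide = position_attitude(wide_margin_segment, p)
        narrow = position_attitude(narrow_margin_segment, p)
        assert np.all(narrow < wide)


class TestSegmentAttitude:
    def test_identical_segments_give_one(self, grid):
        s = seg(-0.3, 0.1, 0.4)
        assert segment_attitude(s, s, grid) == 1.0

    def test_target_contained_in_observer_gives_one(self, grid):
        observer = seg(-0.8, 0.0, 0.8)
        target = seg(-0.2, 0.0, 0.2)
        assert segment_attitude(observer, target, grid) == 1.0

    def test_matches_direct_summation_oracle(self, grid):
        observer = seg(-0.85, -0.50, -0.15)
        target = seg(0.5, 0.7, 0.9)
        # independent direct evaluation of the ratio formula on the grid
        total = 0.0
        count = 0
        for p in grid.points:
            if 0.5 < p < 0.9:
                total += math.tanh((1 + (-0.5 - p) / 0.35) / 2)
                count += 1
        assert count > 0
        expected = total / count
        assert segment_attitude(observer, target, grid) == pytest.approx(
            expected, abs=1e-12
        )

    def test_unresolvable_target_raises(self):
        coarse = PositionGrid(5)  # spacing 0.5
        observer = seg(-0.8, 0.0, 0.8)
        target = seg(0.31, 0.40, 0.49)  # no grid point strictly inside
        with pytest.raises(UnresolvableSegmentError):
            segment_attitude(observer, target, coarse)

    def test_one_iff_target_interior_within_observer(self, grid):
        rng = np.random.default_rng(5)
        for _ in range(50):
            obs = random_segment(rng)
            tgt = random_segment(rng)
            val = segment_attitude(obs, tgt, grid)
            pts = grid.points
            interior = pts[(pts > tgt.lower_bound) & (pts < tgt.upper_bound)]
            contained = np.all(
                (interior > obs.lower_bound) & (interior < obs.upper_bound)
            )
            assert (val == 1.0) == bool(contained)

    def test_grid_convergence(self):
        rng = np.random.default_rng(11)
        g400, g4000 = PositionGrid(400), PositionGrid(4000)
        for _ in range(30):
            obs = random_segment(rng)
            tgt = random_segment(rng)
            assert segment_attitude(obs, tgt, g400) == pytest.approx(
                segment_attitude(obs, tgt, g4000), abs=0.01
            )


class TestIdentityAttitude:
    def test_self_attitude_is_one(self, grid):
        rng = np.random.default_rng(3)
        for _ in range(20):
            ident = random_identity(rng)
            assert identity_attitude(ident, ident, grid) == pytest.approx(1.0)

    def test_is_mean_of_per_worldview_values(self, grid):
        rng = np.random.default_rng(7)
        obs = random_identity(rng)
        tgt = random_identity(rng)
        per_k = [
            segment_attitude(obs.segments[k], tgt.segments[k], grid)
            for k in obs.worldviews
        ]
        assert identity_attitude(obs, tgt, grid) == pytest.approx(
            float(np.mean(per_k)), abs=1e-12
        )

    def test_error_names_worldview(self):
        coarse = PositionGrid(5)
        narrow = seg(0.31, 0.40, 0.49)
        wide = seg(-0.8, 0.0, 0.8)
        obs = CulturalIdentity({"M": wide, "C": wide, "A": wide})
        tgt = CulturalIdentity({"M": wide, "C": narrow, "A": wide})
        with pytest.raises(UnresolvableSegmentError, match="'C'"):
            identity_attitude(obs, tgt, coarse)


class TestGroupOf:
    @pytest.mark.parametrize(
        "a_vals, expected",
        [
            ({"M": 0.8, "C": -0.2, "A": 0.1}, "M"),
            ({"M": 0.5, "C": 0.5, "A": 0.1}, "M"),  # tie -> earliest in order
            ({"M": -0.1, "C": 0.0, "A": 0.7}, "A"),
        ],
    )
    def test_argmax_with_fixed_tie_order(self, a_vals, expected):
        ident = CulturalIdentity(
            {k: AcceptanceSegment(a - 0.1, a, a + 0.1) for k, a in a_vals.items()}
        )
        assert group_of(ident) == expected


class TestAttitudeMatrix:
    def test_single_agent(self, grid):
        rng = np.random.default_rng(1)
        pop = Population(
            agents=(Agent("solo", random_identity(rng), 1.0),)
        )
        m = attitude_matrix(pop, grid)
        assert m.values.shape == (1, 1)
        assert m.values[0, 0] == 1.0

    def test_identical_agents_all_ones(self, grid):
        rng = np.random.default_rng(2)
        ident = random_identity(rng)
        pop = Population(
            agents=(Agent("a", ident, 0.5), Agent("b", ident, 0.5))
        )
        m = attitude_matrix(pop, grid)
        assert np.allclose(m.values, 1.0)

    def test_matches_per_pair_oracle(self, six_agent_pop, grid):
        m = attitude_matrix(six_agent_pop, grid)
        for i, agi in enumerate(six_agent_pop.agents):
            for j, agj in enumerate(six_agent_pop.agents):
                expected = (
                    1.0
                    if i == j
                    else identity_attitude(agi.identity, agj.identity, grid)
                )
                assert m.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_entries_in_range_random_populations(self, grid):
        rng = np.random.default_rng(9)
        for _ in range(5):
            n = int(rng.integers(2, 6))
            agents = tuple(
                Agent(f"a{i}", random_identity(rng), 1.0 / n) for i in range(n)
            )
            m = attitude_matrix(Population(agents=agents), grid)
            assert np.all(m.values >= -1) and np.all(m.values <= 1)
            assert np.all(np.diag(m.values) == 1.0)


class TestGroupStats:
    def test_shared_identity_population(self, grid):
        rng = np.random.default_rng(4)
        ident = random_identity(rng)
        g = group_of(ident)
        pop = Population(
            agents=tuple(Agent(f"a{i}", ident, 0.25) for i in range(4))
        )
        stats = group_stats(pop, attitude_matrix(pop, grid))
        assert stats.mean.loc[g, g] == pytest.approx(1.0)
        assert stats.sd.loc[g, g] == pytest.approx(0.0, abs=1e-12)
        assert stats.fraction[g] == pytest.approx(1.0)
        # groups with no members have undefined (NaN) cells
        other = [k for k in stats.groups if k != g][0]
        assert math.isnan(stats.mean.loc[other, other])

    def test_two_singleton_groups(self, grid):
        m_ident = CulturalIdentity(
            {
                "M": seg(0.0, 0.5, 0.9),
                "C": seg(-0.9, -0.5, -0.1),
                "A": seg(-0.6, -0.2, 0.2),
            }
        )
        c_ident = CulturalIdentity(
            {
                "M": seg(-0.9, -0.4, 0.0),
                "C": seg(0.1, 0.6, 0.9),
                "A": seg(-0.5, -0.1, 0.4),
            }
        )
        pop = Population(
            agents=(Agent("m1", m_ident, 0.5), Agent("c1", c_ident, 0.5))
        )
        matrix = attitude_matrix(pop, grid)
        stats = group_stats(pop, matrix)
        assert stats.mean.loc["M", "C"] == pytest.approx(matrix.values[0, 1])
        assert stats.mean.loc["C", "M"] == pytest.approx(matrix.values[1, 0])
        assert stats.sd.loc["M", "C"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_weighted_oracle(self, six_agent_pop, grid):
        matrix = attitude_matrix(six_agent_pop, grid)
        stats = group_stats(six_agent_pop, matrix)
        agents = six_agent_pop.agents
        for g in stats.groups:
            for h in stats.groups:
                pairs = [
                    (ai.weight * aj.weight, matrix.values[i, j])
                    for i, ai in enumerate(agents)
                    for j, aj in enumerate(agents)
                    if group_of(ai.identity) == g and group_of(aj.identity) == h
                ]
                wsum = sum(w for w, _ in pairs)
                mean = sum(w * v for w, v in pairs) / wsum
                var = sum(w * (v - mean) ** 2 for w, v in pairs) / wsum
                assert stats.mean.loc[g, h] == pytest.approx(mean, abs=1e-12)
                assert stats.sd.loc[g, h] == pytest.approx(
                    math.sqrt(var), abs=1e-12
                )

    def test_exclude_self_option(self, six_agent_pop, grid):
        matrix = attitude_matrix(six_agent_pop, grid)
        incl = group_stats(six_agent_pop, matrix, include_self=True)
        excl = group_stats(six_agent_pop, matrix, include_self=False)
        for g in incl.groups:
            # self-pairs are at the maximum value 1, so dropping them cannot
            # raise the in-group mean
            assert excl.mean.loc[g, g] <= incl.mean.loc[g, g] + 1e-12
            assert excl.mean.loc[g, "M" if g != "M" else "C"] == pytest.approx(
                incl.mean.loc[g, "M" if g != "M" else "C"]
            )

    def test_terrorists_excluded(self, six_agent_pop, grid):
        from latacc.threat import make_terrorist

        with_t = Population(
            agents=six_agent_pop.agents + (make_terrorist(),)
        )
        m_with = attitude_matrix(with_t, grid)
        stats_with = group_stats(with_t, m_with)
        stats_without = group_stats(
            six_agent_pop, attitude_matrix(six_agent_pop, grid)
        )
        assert np.allclose(
            stats_with.mean.to_numpy(), stats_without.mean.to_numpy()
        )


class TestValidation:
    def test_segment_order_enforced(self):
        with pytest.raises(ValueError):
            AcceptanceSegment(0.5, 0.2, 0.4)

    def test_population_weights_must_normalize(self):
        rng = np.random.default_rng(0)
        ident = random_identity(rng)
        with pytest.raises(ValueError, match="sum to 1"):
            Population(agents=(Agent("a", ident, 0.5), Agent("b", ident, 0.4)))

    def test_population_agent_needs_positive_position(self):
        ident = CulturalIdentity(
            {
                k: AcceptanceSegment(-0.9, -0.5, -0.1)
                for k in ("M", "C", "A")
            }
        )
        with pytest.raises(ValueError, match="positive m.a.position"):
            Agent("a", ident, 1.0)
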