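import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from theildecomp import (
    DegenerateInputError,
    RegionPartition,
    ShareVector,
    ZeroResourceError,
    build_share_vector,
    decompose,
    theil_index,
    within_group_theil,
)
from theildecomp.theil import BETWEEN_ROW, TOTAL_ROW, WITHIN_ROW


def sv(p, y, names=None):
    p = np.asarray(p, float)
    y = np.asarray(y, float)
    names = names or tuple(f"u{i}" for i in range(len(p)))
    return ShareVector(tuple(names), p, y)


def brute_force_mld(p, y):
    """Independent oracle: term-by-term evaluation with math.log."""
    total = 0.0
    for pi, yi in zip(p, y):
        if pi > 0:
            total += pi * math.log(pi / yi)
    return total


# strategies for random normalized share pairs over 2..10 units
def _normalize(xs):
    arr = np.asarray(xs, float)
    return arr / arr.sum()


share_pairs = st.integers(2, 10).flatmap(
    lambda n: st.tuples(
        st.lists(st.floats(1e-3, 1e3), min_size=n, max_size=n),
        st.lists(st.floats(1e-3, 1e3), min_size=n, max_size=n),
    )
).map(lambda t: (_normalize(t[0]), _normalize(t[1])))


class TestTheilIndex:
    def test_proportional_allocation_is_zero(self):
        v = _normalize([3, 1, 4, 1, 5])
        assert theil_index(sv(v, v)) == pytest.approx(0.0, abs=1e-15)

    def test_hand_evaluated_two_unit_case(self):
        # 0.5·ln(0.5/0.9) + 0.5·ln(0.5/0.1), evaluated by hand
        expected = 0.5 * math.log(5 / 9) + 0.5 * math.log(5)
        t = theil_index(sv([0.5, 0.5], [0.9, 0.1]))
        assert t == pytest.approx(expected, abs=1e-12)
        assert t == pytest.approx(0.5108256238, abs=1e-9)

    def test_zero_population_share_contributes_nothing(self):
        # limit p·ln(p) → 0: the second unit's resources don't matter
        t = theil_index(sv([1.0, 0.0], [0.5, 0.5]))
        assert t == pytest.approx(math.log(2), abs=1e-12)

    def test_zero_resource_share_raises_by_default(self):
        with pytest.raises(ZeroResourceError, match="u1"):
            theil_index(sv([0.5, 0.5], [1.0, 0.0]))

    def test_epsilon_floor_gives_finite_flagged_result(self):
        vector = sv([0.5, 0.5], [1.0, 0.0])
        t = theil_index(vector, epsilon_floor=True)
        assert math.isfinite(t) and t > 0
        # flooring is monotone in epsilon: a higher floor means less inequality
        t_larger_eps = theil_index(vector, epsilon_floor=True, epsilon=1e-6)
        assert t_larger_eps < t

    @given(share_pairs)
    def test_non_negative_on_normalized_shares(self, pair):
        p, y = pair
        assert theil_index(sv(p, y)) >= 0.0

    @given(share_pairs)
    def test_matches_brute_force_oracle(self, pair):
        p, y = pair
        assert theil_index(sv(p, y)) == pytest.approx(
            brute_force_mld(p, y), abs=1e-12
        )

    @given(share_pairs, st.randoms(use_true_random=False))
    def test_permutation_invariance(self, pair, rnd):
        p, y = pair
        order = list(range(len(p)))
        rnd.shuffle(order)
        names = tuple(f"u{i}" for i in range(len(p)))
        t1 = theil_index(sv(p, y, names))
        t2 = theil_index(
            sv(p[order], y[order], tuple(names[i] for i in order))
        )
        assert t1 == pytest.approx(t2, abs=1e-12)

    def test_positive_when_shares_diverge(self):
        p = _normalize([1, 1, 1])
        y = p.copy()
        y[0] += 1e-4
        y = y / y.sum()
        assert theil_index(sv(p, y)) > 0


class TestWithinGroupTheil:
    def test_singleton_group_is_zero(self):
        vector = sv([0.2, 0.8], [0.6, 0.4])
        assert within_group_theil(vector, ["u0"]) == pytest.approx(0.0, abs=1e-15)

    def test_two_unit_group_matches_hand_value(self):
        # group renormalizes to p=(0.5,0.5), y=(0.9,0.1)
        vector = sv([0.1, 0.1, 0.8], [0.09, 0.01, 0.9])
        expected = 0.5 * math.log(5 / 9) + 0.5 * math.log(5)
        assert within_group_theil(vector, ["u0", "u1"]) == pytest.approx(
            expected, abs=1e-12
        )

    def test_eastern_personnel_2013(self, china_panel, china_regions):
        shares = build_share_vector(china_panel.year_slice(2013), "personnel")
        t_east = within_group_theil(shares, china_regions.members("east"))
        assert round(t_east, 4) == 0.0122

    def test_independent_of_parent_denominators(self, china_panel, china_regions,
                                                 national_totals_2013):
        normalized = build_share_vector(china_panel.year_slice(2013), "personnel")
        national = build_share_vector(
            china_panel.year_slice(2013),
            "personnel",
            population_total=national_totals_2013["population"],
            resource_total=national_totals_2013["personnel"],
        )
        members = china_regions.members("west")
        assert within_group_theil(normalized, members) == pytest.approx(
            within_group_theil(national, members), abs=1e-12
        )

    def test_zero_group_resource_is_degenerate(self):
        vector = sv([0.25, 0.25, 0.5], [0.0, 0.0, 1.0])
        with pytest.raises(DegenerateInputError):
            within_group_theil(vector, ["u0", "u1"])


def random_partition(names, n_groups, rnd):
    labels = [f"g{i}" for i in range(n_groups)]
    mapping = {u: labels[i % n_groups] for i, u in enumerate(names)}
    return RegionPartition(mapping, tuple(labels))


class TestDecompose:
    def test_single_group_puts_everything_within(self):
        p = _normalize([1, 2, 3])
        y = _normalize([3, 2, 1])
        vector = sv(p, y)
        part = RegionPartition({u: "all" for u in vector.unit_names})
        dec = decompose(vector, part)
        assert dec.between == pytest.approx(0.0, abs=1e-15)
        assert dec.within == pytest.approx(dec.total, abs=1e-15)
        assert dec.contribution_within == pytest.approx(1.0, abs=1e-12)

    def test_singleton_groups_put_everything_between(self):
        p = _normalize([1, 2, 3])
        y = _normalize([3, 2, 1])
        vector = sv(p, y)
        part = RegionPartition({u: u for u in vector.unit_names})
        dec = decompose(vector, part)
        assert dec.within == pytest.approx(0.0, abs=1e-15)
        assert dec.between == pytest.approx(dec.total, abs=1e-15)

    def test_regional_personnel_terms_2013(self, china_panel, china_regions):
        shares = build_share_vector(china_panel.year_slice(2013), "personnel")
        dec = decompose(shares, china_regions)
        terms = {g: round(t.t_g, 4) for g, t in dec.group_terms.items()}
        assert terms == {"east": 0.0122, "central": 0.0048, "west": 0.0100}
        assert dec.contribution_within + dec.contribution_between == pytest.approx(
            1.0, abs=1e-9
        )
        assert sum(t.p_g for t in dec.group_terms.values()) == pytest.approx(
            1.0, abs=1e-9
        )
        assert sum(t.y_g for t in dec.group_terms.values()) == pytest.approx(
            1.0, abs=1e-9
        )

    def test_zero_total_reports_undefined_contributions(self):
        v = _normalize([2, 3, 5])
        vector = sv(v, v)
        part = random_partition(vector.unit_names, 2, None)
        dec = decompose(vector, part)
        assert dec.total == pytest.approx(0.0, abs=1e-15)
        assert dec.contribution_within is None
        assert dec.contribution_between is None
        assert all(t.contribution is None for t in dec.group_terms.values())

    @given(share_pairs, st.integers(1, 4), st.randoms(use_true_random=False))
    def test_additivity_is_exact(self, pair, n_groups, rnd):
        p, y = pair
        vector = sv(p, y)
        n_groups = min(n_groups, len(p))
        dec = decompose(vector, random_partition(vector.unit_names, n_groups, rnd))
        assert abs(dec.total - (dec.within + dec.between)) < 1e-12
        assert dec.within >= -1e-15 and dec.between >= -1e-12

    @given(share_pairs, st.integers(1, 4))
    def test_total_matches_unpartitioned_oracle(self, pair, n_groups):
        p, y = pair
        vector = sv(p, y)
        n_groups = min(n_groups, len(p))
        dec = decompose(vector, random_partition(vector.unit_names, n_groups, None))
        assert dec.total == pytest.approx(brute_force_mld(p, y), abs=1e-12)

    @given(share_pairs)
    def test_merging_proportional_units_preserves_total(self, pair):
        # two units with equal per-capita level (y_i/p_i) merge losslessly
        p, y = pair
        ratio = y[0] / p[0]
        p2 = np.concatenate([[p[0] * 0.4, p[0] * 0.6], p[1:]])
        y2 = np.concatenate([[p[0] * 0.4 * ratio, p[0] * 0.6 * ratio], y[1:]])
        t_merged = theil_index(sv(p, y))
        t_split = theil_index(sv(p2, y2))
        assert t_merged == pytest.approx(t_split, abs=1e-12)

    def test_epsilon_floor_propagates_adjusted_flag(self):
        vector = sv([0.25, 0.25, 0.5], [0.5, 0.0, 0.5])
        part = RegionPartition({"u0": "a", "u1": "a", "u2": "b"})
        with pytest.raises(ZeroResourceError):
            decompose(vector, part)
        dec = decompose(vector, part, epsilon_floor=True)
        assert dec.adjusted
        assert abs(dec.total - (dec.within + dec.between)) < 1e-12

    def test_tidy_frame_layout(self, china_panel, china_regions):
        shares = build_share_vector(china_panel.year_slice(2013), "beds")
        frame = decompose(shares, china_regions).to_frame()
        assert list(frame.columns) == [
            "group", "p_g", "y_g", "t_g", "weighted_term", "contribution",
        ]
        assert list(frame["group"]) == [
            "east", "central", "west", WITHIN_ROW, BETWEEN_ROW, TOTAL_ROW,
        ]
        summary = frame.set_index("group")["weighted_term"]
        assert summary[TOTAL_ROW] == pytest.approx(
            summary[WITHIN_ROW] + summary[BETWEEN_ROW], abs=1e-12
        )
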