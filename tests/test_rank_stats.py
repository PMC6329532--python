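"""Ball-in-urn, joint combination, fixed cuts and the rank-order statistic."""

import math
from decimal import Decimal, getcontext
from fractions import Fraction
from itertools import combinations, permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from starc.ica import BinaryRankedArray
from starc.rank_stats import (
    ball_in_urn_pb,
    combine_joint,
    combine_joint_log,
    count_red,
    fixed_cut_score,
    log_ball_in_urn_pb,
    s_score,
    tau_stat,
)


class TestBallInUrn:
    @pytest.mark.parametrize(
        "D,d,R,expected",
        [
            (7, 5, 4, Fraction(11, 21)),
            (7, 5, 5, Fraction(1, 21)),
            (9, 4, 0, Fraction(1)),
            (5, 5, 5, Fraction(1)),
        ],
    )
    def test_exact_values(self, D, d, R, expected):
        assert ball_in_urn_pb(D, d, R) == float(expected)

    def test_matches_subset_enumeration_exactly(self):
        # urn of D balls, d red; draw d; P(>= R red) as an exact frequency
        for D in range(1, 8):
            for d in range(0, D + 1):
                draws = list(combinations(range(D), d))
                for R in range(0, d + 1):
                    hits = sum(
                        1 for drawn in draws if len([b for b in drawn if b < d]) >= R
                    )
                    expected = Fraction(hits, len(draws))
                    assert ball_in_urn_pb(D, d, R) == float(expected)

    def test_rejects_inconsistent_tally(self):
        with pytest.raises(ValueError):
            ball_in_urn_pb(7, 8, 1)
        with pytest.raises(ValueError):
            ball_in_urn_pb(7, 5, 6)

    def test_log_variant_agrees(self):
        for D, d, R in [(7, 5, 4), (50, 20, 15), (300, 150, 120)]:
            lp = log_ball_in_urn_pb(D, d, R)
            assert math.exp(lp) == pytest.approx(ball_in_urn_pb(D, d, R), rel=1e-12)


class TestCountRed:
    def test_worked_example_tally(self, worked_array):
        tally = count_red(worked_array, 7)
        assert (tally.D, tally.d, tally.R) == (7, 5, 4)

    def test_cut_at_end_gives_full_tally(self, worked_array):
        tally = count_red(worked_array, worked_array.L)
        assert tally.R == tally.d == tally.D

    def test_ideal_ranks_give_R_equal_d(self):
        arr = BinaryRankedArray.from_string("110100", ranks=[1, 2, 3])
        tally = count_red(arr, 4)
        assert tally.d == 3 and tally.R == 3


class TestCombineJoint:
    def test_unit_inputs(self):
        assert combine_joint(1.0, 1.0) == 1.0

    @pytest.mark.parametrize(
        "p1,p2,expected",
        [
            (0.1, 1.0, 0.1 * (1 + math.log(10))),
            (0.01, 0.5, 0.005 * (1 - math.log(0.005))),
        ],
    )
    def test_reference_points(self, p1, p2, expected):
        assert combine_joint(p1, p2) == pytest.approx(expected, rel=1e-14)

    def test_against_high_precision_decimal(self):
        getcontext().prec = 50
        for p1 in (0.9, 0.3, 1e-3, 1e-8):
            for p2 in (1.0, 0.7, 1e-2, 1e-10):
                q = Decimal(p1) * Decimal(p2)
                expected = float(q * (1 - q.ln()))
                assert combine_joint(p1, p2) == pytest.approx(expected, abs=1e-12)

    def test_log_space_survives_underflow(self):
        lq = combine_joint_log(-900 * math.log(10), -10 * math.log(10))
        # ln[q(1 - ln q)] = ln q + ln(1 - ln q)
        assert lq == pytest.approx(-910 * math.log(10) + math.log(1 + 910 * math.log(10)))

    @given(
        st.floats(min_value=1e-12, max_value=1.0),
        st.floats(min_value=1e-12, max_value=1.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_bounds_and_symmetry(self, p1, p2):
        v = combine_joint(p1, p2)
        assert p1 * p2 <= v <= 1.0
        assert v == combine_joint(p2, p1)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            combine_joint(0.0, 0.5)
        with pytest.raises(ValueError):
            combine_joint(1.5, 0.5)


class TestFixedCut:
    def test_worked_array_ppv_at_optimal_width(self, worked_array):
        # F chosen so that x = 7 on an 18-column query
        fc = fixed_cut_score(worked_array, F=7 / 18, ell=18)
        assert fc.x == 7
        assert fc.d_x == 5
        assert fc.PPV == pytest.approx(5 / 7)
        assert fc.S_F >= 0

    def test_worked_array_full_width(self, worked_array):
        fc = fixed_cut_score(worked_array, F=1.0, ell=18)
        assert fc.x == 18
        assert fc.PPV == pytest.approx(7 / 18)
        # d = D at the full cut: both tails are 1, so the joint p is 1
        assert fc.PF == 1.0

    def test_all_distinguished_prefix_gives_unit_ppv(self):
        arr = BinaryRankedArray.from_string("111000000000")
        fc = fixed_cut_score(arr, F=0.25, ell=12)
        assert fc.x == 3 and fc.PPV == 1.0

    def test_oversized_cut_clamps_with_warning(self, worked_array):
        with pytest.warns(UserWarning, match="clamp"):
            fc = fixed_cut_score(worked_array, F=2.0, ell=18)
        assert fc.x == worked_array.L

    def test_round_half_up(self, worked_array):
        fc = fixed_cut_score(worked_array, F=0.25, ell=18)  # 4.5 -> 5
        assert fc.x == 5


class TestSScore:
    def test_definition(self):
        assert s_score(1.0) == 0.0
        assert s_score(0.01) == pytest.approx(2.0)
        assert s_score(log_p=-862 * math.log(10)) == pytest.approx(862.0)

    def test_requires_exactly_one_input(self):
        with pytest.raises(ValueError):
            s_score(0.5, log_p=-1.0)
        with pytest.raises(ValueError):
            s_score()


class TestTau:
    def test_identity_is_zero(self):
        for d in (1, 3, 6):
            assert tau_stat(list(range(1, d + 1))).tau == 0

    def test_reversal_d3(self):
        st_ = tau_stat([3, 2, 1])
        assert st_.tau == 4

    def test_moments_match_enumeration(self):
        for d in range(2, 6):
            taus = []
            base = list(range(1, d + 1))
            for perm in permutations(base):
                taus.append(sum((p - i) ** 2 for p, i in zip(perm, base)) // 2)
            taus = np.array(taus, dtype=float)
            mu = (d**3 - d) / 12.0
            assert taus.mean() == pytest.approx(mu, abs=1e-12)
            st_ = tau_stat(base)
            assert st_.mu == pytest.approx(mu)
            # sigma = mu / sqrt(d-1) equals the population SD
            assert taus.std() == pytest.approx(st_.sigma, rel=1e-9)

    def test_exact_p_value_lower_tail(self):
        st_ = tau_stat([1, 2, 3])
        assert st_.exact and st_.p_value == pytest.approx(1 / 6)

    def test_gaussian_branch_above_exact_limit(self):
        pi = list(range(1, 15))
        st_ = tau_stat(pi, max_exact=10)
        assert not st_.exact
        assert 0 < st_.p_value < 0.01  # identity is far below the mean

    def test_rejects_non_permutation(self):
        with pytest.raises(ValueError):
            tau_stat([1, 2, 2])
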