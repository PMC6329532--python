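"""Rank-aware statistics: ball-in-urn P_b, joint p-values, fixed cuts, tau.

The initial-cluster p-value P_a ignores the distance ranking of the
distinguished elements.  The ball-in-urn statistic recovers it: colour red
the d closest (best-ranked) of the D distinguished pairs and ask how many of
the d left-distinguished pairs are red.  P_b is the hypergeometric
probability of at least the observed number of reds, independent of P_a by
construction, and the two combine as P_J = q(1 - ln q), q = P_a * P_b — the
exact tail of a product of two independent uniforms.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from itertools import permutations
from math import comb

import numpy as np

from .ica import BinaryRankedArray, log_hypergeom_tail

__all__ = [
    "RankTally",
    "JointScore",
    "FixedCutScore",
    "RankOrderStat",
    "ball_in_urn_pb",
    "count_red",
    "combine_joint",
    "combine_joint_log",
    "fixed_cut_score",
    "s_score",
    "tau_stat",
]

LOG10 = math.log(10.0)


@dataclass(frozen=True)
class RankTally:
    D: int
    d: int
    R: int

    def __post_init__(self):
        if not 0 <= self.R <= self.d <= self.D:
            raise ValueError(f"require 0 <= R <= d <= D, got {self}")


def ball_in_urn_pb(D: int, d: int, R: int) -> float:
    """P[at least R of d drawn balls are red | urn of D balls, d red].

    Exact integer/rational arithmetic (the counts involved are at most a few
    hundred in practice), returned as the correctly rounded float.
    """
    RankTally(D, d, R)  # validates
    if R == 0:
        return 1.0
    num = sum(comb(d, i) * comb(D - d, d - i) for i in range(R, d + 1))
    return float(Fraction(num, comb(D, d)))


def log_ball_in_urn_pb(D: int, d: int, R: int) -> float:
    """Natural log of :func:`ball_in_urn_pb` (exact arithmetic upstream)."""
    RankTally(D, d, R)
    if R == 0:
        return 0.0
    num = sum(comb(d, i) * comb(D - d, d - i) for i in range(R, d + 1))
    den = comb(D, d)
    # exact integer log difference; both fit in arbitrary precision
    return _log_int(num) - _log_int(den)


def _log_int(n: int) -> float:
    if n <= 0:
        return -math.inf
    # shift huge integers into float range first
    k = max(0, n.bit_length() - 900)
    return math.log(n >> k) + k * math.log(2.0)


def count_red(arr: BinaryRankedArray, X: int) -> RankTally:
    """Tally R: reds (the d best-ranked distinguished elements) at or before X."""
    if not 1 <= X <= arr.L:
        raise ValueError(f"cut X={X} outside 1..{arr.L}")
    flags = arr.flags
    d = int(flags[:X].sum())
    D = arr.D
    # red = rank among the d smallest distances over all distinguished elements
    red = flags & (arr.ranks >= 1) & (arr.ranks <= d)
    R = int(red[:X].sum())
    return RankTally(D=D, d=d, R=R)


def combine_joint(p1: float, p2: float) -> float:
    """Combine two independent p-values: q(1 - ln q) with q = p1*p2."""
    return math.exp(combine_joint_log(_checked_log(p1), _checked_log(p2)))


def _checked_log(p: float) -> float:
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p-value must be in (0, 1], got {p}")
    return math.log(p)


def combine_joint_log(lp1: float, lp2: float) -> float:
    """Log-space joint combination; exact for arbitrarily small inputs.

    Returns ln[q(1 - ln q)] = lq + ln(1 - lq) with lq = lp1 + lp2.
    """
    if lp1 > 0 or lp2 > 0:
        raise ValueError("log p-values must be <= 0")
    lq = lp1 + lp2
    if lq == 0.0:
        return 0.0
    return min(0.0, lq + math.log1p(-lq))


def s_score(p: float | None = None, *, log_p: float | None = None) -> float:
    """s-score S = -log10 P; pass ``log_p`` (natural log) for underflowing P."""
    if (p is None) == (log_p is None):
        raise ValueError("supply exactly one of p or log_p")
    if log_p is None:
        log_p = _checked_log(p)
    return max(0.0, -log_p / LOG10)


@dataclass(frozen=True)
class JointScore:
    """P_a, P_b, their joint P_J (all natural-log), and S from the corrected P."""

    log_Pa: float
    log_Pb: float | None
    log_PJ: float
    S: float
    with_pb: bool

    @property
    def Pa(self) -> float:
        return math.exp(self.log_Pa)

    @property
    def Pb(self) -> float | None:
        return None if self.log_Pb is None else math.exp(self.log_Pb)

    @property
    def PJ(self) -> float:
        return math.exp(self.log_PJ)


@dataclass(frozen=True)
class FixedCutScore:
    """Statistics at a constant cut x = round(F * ell) instead of the optimal X."""

    F: float
    ell: int
    x: int
    d_x: int
    log_Px: float
    log_Pb: float
    log_PF: float
    S_F: float
    PPV: float

    @property
    def Px(self) -> float:
        return math.exp(self.log_Px)

    @property
    def PF(self) -> float:
        return math.exp(self.log_PF)


def _round_half_up(v: float) -> int:
    return int(math.floor(v + 0.5))


def fixed_cut_score(arr: BinaryRankedArray, F: float, ell: int) -> FixedCutScore:
    """Score at the conventional constant cut x = F * ell (round half up).

    P_x is the hypergeometric tail of d_x at x; P_b uses the tally at the
    same cut x; PPV is the fraction of the top-x pairs that are contacts.
    """
    x = _round_half_up(F * ell)
    if x < 1:
        raise ValueError(f"F*ell = {F * ell:.3g} rounds below 1")
    if x > arr.L:
        warnings.warn(
            f"fixed cut x={x} exceeds array length L={arr.L}; clamping to L",
            stacklevel=2,
        )
        x = arr.L
    d_x = int(arr.flags[:x].sum())
    log_px = float(log_hypergeom_tail(arr.L, arr.D, [x], [d_x])[0])
    tally = count_red(arr, x)
    log_pb = log_ball_in_urn_pb(tally.D, tally.d, tally.R)
    log_pf = combine_joint_log(log_px, log_pb)
    return FixedCutScore(
        F=F,
        ell=ell,
        x=x,
        d_x=d_x,
        log_Px=log_px,
        log_Pb=log_pb,
        log_PF=log_pf,
        S_F=s_score(log_p=log_pf),
        PPV=d_x / x,
    )


@dataclass(frozen=True)
class RankOrderStat:
    """Half-sum-of-squared-displacements statistic of a permutation."""

    d: int
    tau: int
    mu: float
    sigma: float
    p_value: float | None = None
    exact: bool = False


def tau_stat(ranks, max_exact: int = 10) -> RankOrderStat:
    """tau(pi) = 1/2 sum (pi[i] - i)^2 for a permutation pi of 1..d.

    tau = 0 iff pi is the identity; over random permutations tau is
    symmetric about mu = (d^3 - d)/12 with sigma = mu / sqrt(d - 1).
    The reported p-value is the lower tail P[tau <= observed] (small tau
    means strong agreement): exact by enumeration for d <= ``max_exact``,
    Gaussian with continuity correction above.
    """
    pi = np.asarray(ranks, dtype=np.int64)
    d = pi.size
    if not np.array_equal(np.sort(pi), np.arange(1, d + 1)):
        raise ValueError("input must be a permutation of 1..d")
    tau2 = int(((pi - np.arange(1, d + 1)) ** 2).sum())
    if tau2 % 2:
        raise AssertionError("sum of squared displacements is always even")
    tau = tau2 // 2
    mu = (d**3 - d) / 12.0
    sigma = mu / math.sqrt(d - 1) if d > 1 else 0.0
    if d <= 1:
        return RankOrderStat(d=d, tau=tau, mu=mu, sigma=sigma, p_value=1.0, exact=True)
    if d <= max_exact:
        n_le = 0
        total = 0
        base = np.arange(1, d + 1)
        for perm in permutations(range(1, d + 1)):
            t = sum((p - i) ** 2 for p, i in zip(perm, base)) // 2
            n_le += t <= tau
            total += 1
        return RankOrderStat(
            d=d, tau=tau, mu=mu, sigma=sigma, p_value=n_le / total, exact=True
        )
    from scipy.stats import norm

    p = float(norm.cdf((tau + 0.5 - mu) / sigma))
    return RankOrderStat(d=d, tau=tau, mu=mu, sigma=sigma, p_value=p, exact=False)
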