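"""Null-model generators and empirical calibration of the s-score.

The shuffled-array null permutes the order of a binary ranked array, which
destroys any association between coupling rank and contact rank while
preserving L and D.  Scoring many such arrays and comparing the empirical
survival of the resulting s-scores against theory (the calibration curve
S-hat vs S) is the validity check for the whole statistic: S-hat should track
S to within binomial error.

Also provided: the column-permutation null for alignments (permute residues
within each column, then permute column order — preserves per-column residue
composition and hence relative entropies), and a synthetic structure +
coupling-score fixture generator with a planted contact signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .ica import (
    BinaryRankedArray,
    _log_rho_shape,
    _two_rate_llr,
    effective_trials,
    log_hypergeom_tail,
)
from .rank_stats import combine_joint_log

__all__ = [
    "shuffle_array",
    "column_permute_msa",
    "null_s_scores",
    "calibration_curve",
    "CalibrationCurve",
    "Fixture",
    "make_fixture",
]

LOG10 = math.log(10.0)


def shuffle_array(arr: BinaryRankedArray, seed) -> BinaryRankedArray:
    """Uniform random permutation of element order; flags and ranks travel
    with their elements, so L and D are preserved."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(arr.L)
    return BinaryRankedArray(
        flags=arr.flags[perm],
        ranks=arr.ranks[perm],
        labels=tuple(arr.labels[p] for p in perm) if arr.labels else (),
        scores=None if arr.scores is None else arr.scores[perm],
        distances=None if arr.distances is None else arr.distances[perm],
    )


def column_permute_msa(msa: list[str], seed) -> list[str]:
    """Permute residues within each column, then permute the column order.

    Preserves each column's residue multiset (and therefore the distribution
    of column relative entropies) while abolishing inter-column covariation.
    """
    if not msa:
        raise ValueError("empty alignment")
    width = len(msa[0])
    if any(len(row) != width for row in msa):
        raise ValueError("ragged alignment: all rows must have equal length")
    rng = np.random.default_rng(seed)
    mat = np.array([list(row) for row in msa])
    for j in range(width):
        mat[:, j] = mat[rng.permutation(mat.shape[0]), j]
    mat = mat[:, rng.permutation(width)]
    return ["".join(row) for row in mat]


def null_s_scores(
    L: int,
    D: int,
    n_rep: int,
    seed,
    with_pb: bool = True,
    chunk: int = 256,
) -> np.ndarray:
    """s-scores of the full statistic on ``n_rep`` shuffled null arrays.

    Vectorised across replicates: for each array the D candidate cuts sit at
    the (sorted) positions of the distinguished elements, the flattened-prior
    objective picks the cut, and the corrected joint p-value is converted to
    an s-score.  Equivalent to scoring ``shuffle_array`` outputs one by one
    through the pipeline, but orders of magnitude faster.
    """
    if D < 1 or D >= L:
        raise ValueError("require 1 <= D < L")
    rng = np.random.default_rng(seed)
    T = effective_trials(L, D)
    logT = math.log(T)
    d_grid = np.arange(1, D + 1, dtype=np.int64)
    out = np.empty(n_rep)
    done = 0
    while done < n_rep:
        m = min(chunk, n_rep - done)
        # candidate cut positions: sorted positions of the D ones (1-based)
        u = rng.random((m, L)).argpartition(D - 1, axis=1)[:, :D]
        pos = np.sort(u, axis=1) + 1
        d = np.broadcast_to(d_grid, (m, D))
        log_p = log_hypergeom_tail(L, D, pos.ravel(), d.ravel()).reshape(m, D)
        lam = _two_rate_llr(L, D, pos.ravel(), d.ravel()).reshape(m, D)
        obj = lam - _log_rho_shape(pos, L)
        k = np.argmax(obj, axis=1)
        rows = np.arange(m)
        lpa = log_p[rows, k]
        if with_pb:
            d_star = d_grid[k]
            # ranks are independent uniform: R | d ~ Hypergeom(D, d, d);
            # P_b is the same hypergeometric tail with population D
            R = rng.hypergeometric(d_star, D - d_star, d_star)
            lpb = _pb_log_tail(D, d_star, R)
            lpj = np.array(
                [combine_joint_log(a, b) for a, b in zip(lpa, lpb)]
            )
        else:
            lpj = lpa
        corrected = np.minimum(0.0, logT + lpj)
        out[done : done + m] = -corrected / LOG10
        done += m
    return out


def _pb_log_tail(D: int, d: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Vectorised log ball-in-urn tail: P[>= R red | urn D, d red, d drawn]."""
    res = np.zeros(len(d))
    nz = R > 0
    if np.any(nz):
        res[nz] = np.array(
            [
                float(log_hypergeom_tail(D, int(di), [int(di)], [int(Ri)])[0])
                for di, Ri in zip(d[nz], R[nz])
            ]
        )
    return res


@dataclass(frozen=True)
class CalibrationCurve:
    """Empirical survival calibration of the s-score against theory.

    ``S_hat[i]`` is -log10 of the fraction of null s-scores >= ``grid[i]``;
    the bands are the two-binomial-SD envelope of S-hat around perfect
    calibration (S_hat = S).  NaN where the empirical survival is zero.
    """

    grid: np.ndarray
    S_hat: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    n_rep: int
    seed: object

    def within_band(self) -> np.ndarray:
        ok = np.isfinite(self.S_hat)
        return ok & (self.S_hat >= self.lo) & (self.S_hat <= self.hi)

    def to_tsv(self) -> str:
        lines = ["S\tS_hat\tband_lo\tband_hi"]
        for g, s, a, b in zip(self.grid, self.S_hat, self.lo, self.hi):
            lines.append(f"{g:.3f}\t{s:.4f}\t{a:.4f}\t{b:.4f}")
        return "\n".join(lines) + "\n"


def calibration_curve(
    L: int,
    D: int,
    n_rep: int = 10_000,
    seed=0,
    grid=None,
    with_pb: bool = True,
) -> CalibrationCurve:
    """Empirical S-hat(S) from ``n_rep`` shuffled-array null replicates.

    At each grid point S the ideal survival is 10**-S; the two-SD binomial
    band on the observed count is translated into a band on S-hat.
    """
    if grid is None:
        grid = np.arange(2.0, 5.01, 0.5)
    grid = np.asarray(grid, dtype=float)
    s = null_s_scores(L, D, n_rep, seed, with_pb=with_pb)
    S_hat = np.full(len(grid), np.nan)
    lo = np.empty(len(grid))
    hi = np.empty(len(grid))
    for i, g in enumerate(grid):
        surv = np.count_nonzero(s >= g)
        if surv > 0:
            S_hat[i] = -math.log10(surv / n_rep)
        p = 10.0 ** (-g)
        sd = math.sqrt(n_rep * p * (1.0 - p))
        kmin = max(n_rep * p - 2.0 * sd, 0.5)
        kmax = n_rep * p + 2.0 * sd
        lo[i] = -math.log10(kmax / n_rep)
        hi[i] = -math.log10(kmin / n_rep)
    return CalibrationCurve(
        grid=grid, S_hat=S_hat, lo=lo, hi=hi, n_rep=n_rep, seed=seed
    )


@dataclass(frozen=True)
class Fixture:
    """Synthetic chain + coupling scores with a planted contact signal.

    Residues are placed by a persistent random walk confined to a sphere
    (step 3.8 A, the C-alpha virtual bond length), giving a compact fold with
    long-range contacts.  Each residue carries a single pseudo-sidechain
    atom.  Coupling scores are theta * 1[contact] + N(0, 1), so theta = 0 is
    an exact null.
    """

    n_res: int
    theta: float
    seed: object
    coords: np.ndarray                 # (n_res, 3) in Angstrom
    contacts: frozenset                # {(i, j)} 1-based, i < j
    records: tuple                     # ((i, j, score), ...) all pairs, sep-filtered
    r_max: float
    m: int

    @property
    def sequence(self) -> str:
        return "G" * self.n_res

    def to_pdb(self) -> str:
        """Minimal single-chain PDB text (CA-only glycine trace)."""
        lines = []
        for k, (x, y, z) in enumerate(self.coords, start=1):
            lines.append(
                f"ATOM  {k:5d}  CA  GLY A{k:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
        lines.append("END")
        return "\n".join(lines) + "\n"

    def to_score_list(self) -> str:
        """Scores in the three-column (i j score) pair-list dialect."""
        return "".join(f"{i} {j} {s:.6f}\n" for i, j, s in self.records)


def make_fixture(n_res: int, theta: float, seed, r_max: float = 5.0, m: int = 5,
                 radius: float | None = None) -> Fixture:
    """Generate a synthetic fold and coupling scores with planted signal.

    The confinement radius defaults to one packing residues at roughly
    protein-like density (about 6% of well-separated pairs in contact for
    n_res ~ 60).  Regeneration from identical parameters and seed is
    bit-identical.
    """
    if n_res < 10:
        raise ValueError("need at least 10 residues")
    if theta < 0:
        raise ValueError("signal strength theta must be >= 0")
    rng = np.random.default_rng(seed)
    if radius is None:
        radius = 13.0 * (n_res / 60.0) ** (1.0 / 3.0)
    step = 3.8
    coords = np.zeros((n_res, 3))
    direction = _rand_unit(rng)
    for k in range(1, n_res):
        # persistent walk: blend previous direction with a fresh one
        direction = direction + 0.8 * _rand_unit(rng)
        direction /= np.linalg.norm(direction)
        nxt = coords[k - 1] + step * direction
        # reflect back toward the origin when leaving the confinement sphere
        r = np.linalg.norm(nxt)
        if r > radius:
            direction = -nxt / r + 0.5 * _rand_unit(rng)
            direction /= np.linalg.norm(direction)
            nxt = coords[k - 1] + step * direction
        coords[k] = nxt
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    contacts = set()
    records = []
    for i in range(1, n_res + 1):
        for j in range(i + 1, n_res + 1):
            if j - i - 1 < m:
                continue
            is_contact = dist[i - 1, j - 1] <= r_max
            if is_contact:
                contacts.add((i, j))
            score = theta * is_contact + rng.standard_normal()
            records.append((i, j, score))
    return Fixture(
        n_res=n_res,
        theta=theta,
        seed=seed,
        coords=coords,
        contacts=frozenset(contacts),
        records=tuple(records),
        r_max=r_max,
        m=m,
    )


def _rand_unit(rng) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)
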