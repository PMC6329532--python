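"""End-to-end scoring: from coupling scores and a structure to an s-score.

The pipeline is: parse DC scores -> build the descending-score pair array ->
attach 3D distances and mark/rank contacts -> find the optimal initial
cluster (P_a) -> tally ranks at the cut (P_b) -> combine (P_J) -> correct
for the optimisation over cuts -> S = -log10 P.  Fixed-cut twins (S_F, PPV)
and a pattern-pair mode (distinguished set given a priori, no ranking) are
variants on the same array.  Method comparison across many analyses uses the
Wilcoxon signed-rank test on length-normalised s-scores.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.stats import norm

from . import dca_io
from .contacts import ContactSpec, build_distance_table, distinguish_and_rank, read_structure
from .ica import BinaryRankedArray, ICAResult, effective_trials, optimal_cut
from .rank_stats import (
    FixedCutScore,
    JointScore,
    combine_joint_log,
    count_red,
    fixed_cut_score,
    log_ball_in_urn_pb,
    s_score,
)

__all__ = [
    "StarcReport",
    "ComparisonResult",
    "score_array",
    "starc_score",
    "sf_score",
    "pattern_score",
    "fixture_array",
    "score_fixture",
    "compare_methods",
    "wilcoxon_signed_rank",
]


@dataclass(frozen=True)
class StarcReport:
    """Full scoring record for one analysis.

    ``S`` derives from the multiple-cut-corrected joint p-value; when
    ``with_pb`` is False the ball-in-urn term is omitted and S reflects the
    corrected P_a alone.  All p-values are retained as natural logs so that
    astronomically small values survive serialisation.
    """

    L: int
    D: int
    X: int
    d: int
    R: int | None
    log_Pa_raw: float
    log_Pb: float | None
    log_PJ_raw: float
    T_eff: float
    log_P: float           # corrected joint p-value (ln), clamped at 0
    S: float
    with_pb: bool
    ell: int | None = None
    mode: str = "structure"
    fixed_cuts: tuple = ()
    provenance: dict = field(default_factory=dict)

    @property
    def P(self) -> float:
        return math.exp(self.log_P)

    @property
    def Pa_raw(self) -> float:
        return math.exp(self.log_Pa_raw)

    @property
    def Pb(self) -> float | None:
        return None if self.log_Pb is None else math.exp(self.log_Pb)

    @property
    def F_opt(self) -> float | None:
        """The optimised cut expressed on the conventional F scale, X / ell."""
        return None if not self.ell else self.X / self.ell

    def to_dict(self) -> dict:
        out = {
            "L": self.L, "D": self.D, "X": self.X, "d": self.d, "R": self.R,
            "Pa_raw": math.exp(self.log_Pa_raw),
            "Pb": None if self.log_Pb is None else math.exp(self.log_Pb),
            "PJ_raw": math.exp(self.log_PJ_raw),
            "T_eff": self.T_eff,
            "P": self.P,
            "S": self.S,
            "with_pb": self.with_pb,
            "ell": self.ell,
            "F_opt": self.F_opt,
            "mode": self.mode,
            "provenance": self.provenance,
            "fixed_cuts": [
                {
                    "F": fc.F, "x": fc.x, "d_x": fc.d_x,
                    "Px": fc.Px, "PF": fc.PF, "S_F": fc.S_F, "PPV": fc.PPV,
                }
                for fc in self.fixed_cuts
            ],
        }
        return out

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)

    def to_tsv(self) -> str:
        head = ["L", "D", "X", "d", "R", "Pa_raw", "Pb", "PJ_raw", "P", "S"]
        vals = [
            self.L, self.D, self.X, self.d,
            "" if self.R is None else self.R,
            f"{math.exp(self.log_Pa_raw):.4g}",
            "" if self.log_Pb is None else f"{math.exp(self.log_Pb):.4g}",
            f"{math.exp(self.log_PJ_raw):.4g}",
            f"{self.P:.4g}",
            f"{self.S:.2f}",
        ]
        return "\t".join(head) + "\n" + "\t".join(str(v) for v in vals) + "\n"


def score_array(
    arr: BinaryRankedArray,
    with_pb: bool = True,
    ell: int | None = None,
    mode: str = "structure",
    provenance: dict | None = None,
) -> StarcReport:
    """Score a prepared binary ranked array.

    The cut is chosen ignoring ranks; ranks enter only through the
    ball-in-urn tally at the chosen cut.  The reported P is the joint
    p-value corrected by the effective number of independent cut trials
    (or the corrected P_a when ``with_pb`` is False).
    """
    if arr.D == 0:
        raise ValueError("no distinguished elements: no contacts at this threshold")
    ica: ICAResult = optimal_cut(arr)
    R = None
    log_pb = None
    if with_pb and arr.D < arr.L:
        tally = count_red(arr, ica.X)
        R = tally.R
        log_pb = log_ball_in_urn_pb(tally.D, tally.d, tally.R)
        log_pj = combine_joint_log(ica.log_Pa_raw, log_pb)
    else:
        log_pj = ica.log_Pa_raw
    log_p = min(0.0, math.log(ica.T_eff) + log_pj)
    return StarcReport(
        L=arr.L,
        D=arr.D,
        X=ica.X,
        d=ica.d,
        R=R,
        log_Pa_raw=ica.log_Pa_raw,
        log_Pb=log_pb,
        log_PJ_raw=log_pj,
        T_eff=ica.T_eff,
        log_P=log_p,
        S=s_score(log_p=log_p),
        with_pb=with_pb and log_pb is not None,
        ell=ell,
        mode=mode,
        provenance=provenance or {},
    )


def starc_score(
    dc_file,
    dialect: str,
    query: str,
    pdb_file,
    chain: str,
    spec: ContactSpec | None = None,
    interface_chain: str | None = None,
    with_pb: bool = True,
    F_list=(),
    position_map: dict | None = None,
) -> StarcReport:
    """File-level pipeline: coupling scores + structure -> scored report."""
    spec = spec or ContactSpec()
    records = dca_io.parse_dc_scores(dc_file, dialect, query=query)
    sarr = dca_io.build_array(records, query, m=spec.m)
    model = read_structure(
        pdb_file, chain, partner_chain=interface_chain, position_map=position_map
    )
    table = build_distance_table(model, spec)
    arr = distinguish_and_rank(sarr, table, spec)
    report = score_array(
        arr,
        with_pb=with_pb,
        ell=sarr.ell,
        provenance={
            "dc_file": str(dc_file),
            "dialect": dialect,
            "pdb_file": str(pdb_file),
            "chain": chain,
            "interface_chain": interface_chain,
            "r_min": spec.r_min,
            "r_max": spec.r_max,
            "m": spec.m,
        },
    )
    if F_list:
        fcs = sf_score(arr, F_list, sarr.ell)
        report = _with_fixed_cuts(report, fcs)
    return report


def _with_fixed_cuts(report: StarcReport, fcs) -> StarcReport:
    from dataclasses import replace

    return replace(report, fixed_cuts=tuple(fcs))


def sf_score(arr: BinaryRankedArray, F_list, ell: int) -> list[FixedCutScore]:
    """Fixed-cut scores for each F in ``F_list`` (conventional 0.5..1.5)."""
    out = []
    for F in F_list:
        if round(F * ell) < 1:
            import warnings

            warnings.warn(f"F={F} yields cut below 1 for ell={ell}; skipped",
                          stacklevel=2)
            continue
        out.append(fixed_cut_score(arr, F, ell))
    return out


def pattern_score(
    records,
    query: str,
    patterns: dca_io.PatternSet,
    m: int = 5,
) -> StarcReport:
    """Score the overlap of top couplings with pattern-residue pairs.

    The distinguished set is the pattern pairs; no distance ranking exists,
    so the report is the corrected P_a only (``with_pb=False``).
    """
    sarr = dca_io.build_array(records, query, m=m)
    distinguished = dca_io.pattern_pairs(patterns, m=m)
    flags = np.array([(r.i, r.j) in distinguished for r in sarr.records], dtype=bool)
    if not flags.any():
        raise ValueError("all pattern pairs were filtered out of the array")
    ranks = np.zeros(len(flags), dtype=np.int64)
    ranks[flags] = np.arange(1, int(flags.sum()) + 1)  # placeholder order, unused
    arr = BinaryRankedArray(
        flags=flags,
        ranks=ranks,
        labels=tuple((r.i, r.j) for r in sarr.records),
        scores=np.array([r.score for r in sarr.records]),
    )
    rep = score_array(arr, with_pb=False, ell=sarr.ell, mode="pattern")
    return rep


def fixture_array(fx) -> BinaryRankedArray:
    """Binary ranked array of a synthetic fixture (see simulate.make_fixture).

    The fixture's own coordinates serve as the reference structure (one
    pseudo-sidechain atom per residue), its generated coupling scores as the
    primary ordering.
    """
    records = [dca_io.DCRecord(i=i, j=j, score=s) for i, j, s in fx.records]
    sarr = dca_io.build_array(records, fx.sequence, m=fx.m)
    labels, flags, dists = [], [], []
    for r in sarr.records:
        d = float(np.linalg.norm(fx.coords[r.i - 1] - fx.coords[r.j - 1]))
        labels.append((r.i, r.j))
        flags.append(d <= fx.r_max)
        dists.append(d)
    flags = np.asarray(flags, dtype=bool)
    dists = np.asarray(dists)
    ranks = np.zeros(len(flags), dtype=np.int64)
    idx = np.flatnonzero(flags)
    order = idx[np.lexsort((idx, dists[idx]))]
    ranks[order] = np.arange(1, len(idx) + 1)
    return BinaryRankedArray(
        flags=flags, ranks=ranks, labels=tuple(labels),
        scores=np.array([r.score for r in sarr.records]),
        distances=np.where(flags, dists, np.nan),
    )


def score_fixture(fx, with_pb: bool = True) -> StarcReport:
    """Score a synthetic fixture end to end."""
    return score_array(
        fixture_array(fx), with_pb=with_pb, ell=fx.n_res, mode="fixture",
        provenance={"theta": fx.theta, "seed": str(fx.seed), "n_res": fx.n_res},
    )


@dataclass(frozen=True)
class ComparisonResult:
    """Wilcoxon signed-rank comparison of two methods over paired analyses."""

    method1: str
    method2: str
    n: int
    Z: float
    p_value: float
    normalization: str = "S/L"

    def __str__(self):
        return (
            f"{self.method1} vs {self.method2}: n={self.n}, "
            f"Z={self.Z:+.2f}, p={self.p_value:.2g}"
        )


def wilcoxon_signed_rank(diffs, exact_max: int = 12) -> tuple[float, float, int]:
    """Two-tailed Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (classic treatment); ties get average
    ranks.  For n <= ``exact_max`` the p-value is exact by enumerating all
    sign assignments; above, a tie-corrected, continuity-corrected normal
    approximation is used.  Returns (Z, p, n); Z > 0 means the first sample
    tends larger.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return 0.0, 1.0, 0
    absd = np.abs(d)
    order = absd.argsort(kind="mergesort")
    ranks = np.empty(n)
    # average ranks for ties
    sorted_abs = absd[order]
    r = np.arange(1, n + 1, dtype=float)
    uniq, inv, counts = np.unique(sorted_abs, return_inverse=True, return_counts=True)
    csum = np.cumsum(counts)
    avg = (csum - (counts - 1) / 2.0)
    ranks[order] = avg[inv]
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    tie_term = float((counts**3 - counts).sum())
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term / 48.0
    if var <= 0:
        return 0.0, 1.0, n
    # continuity correction toward the mean
    delta = w_plus - mu
    z = (delta - 0.5 * np.sign(delta)) / math.sqrt(var) if delta != 0 else 0.0
    if n <= exact_max:
        # exact null: every subset of ranks is equally likely to be positive
        obs = abs(delta)
        count = 0
        total = 1 << n
        for mask in range(total):
            w = 0.0
            mm = mask
            k = 0
            while mm:
                if mm & 1:
                    w += ranks[k]
                mm >>= 1
                k += 1
            if abs(w - mu) >= obs - 1e-12:
                count += 1
        p = count / total
    else:
        p = 2.0 * float(norm.sf(abs(z)))
    return float(z), min(1.0, p), n


def compare_methods(scores: dict, lengths=None, exact_max: int = 12) -> list[ComparisonResult]:
    """Pairwise Wilcoxon comparisons of per-analysis s-scores by method.

    ``scores`` maps method name -> sequence of s-scores (one per analysis,
    aligned across methods).  ``lengths`` gives the per-analysis array
    length L used to normalise each s-score (S/L); omit for pre-normalised
    scores.
    """
    methods = list(scores)
    sizes = {len(v) for v in scores.values()}
    if len(sizes) != 1:
        raise ValueError("all methods need the same number of analyses")
    norm_scores = {}
    for mth, vals in scores.items():
        v = np.asarray(vals, dtype=float)
        if lengths is not None:
            v = v / np.asarray(lengths, dtype=float)
        norm_scores[mth] = v
    out = []
    for m1, m2 in combinations(methods, 2):
        z, p, n = wilcoxon_signed_rank(norm_scores[m1] - norm_scores[m2], exact_max)
        out.append(ComparisonResult(method1=m1, method2=m2, n=n, Z=z, p_value=p))
    return out
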