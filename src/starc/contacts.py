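"""Sidechain contact maps from PDB coordinates.

Distances between residue pairs are the minimum over all pairs of sidechain
atoms, hydrogens included when the file provides them.  Backbone N, CA, C,
O, OXT and their attached hydrogens are excluded, with one exception: for
glycine the C-alpha and its attached hydrogens stand in for the missing
sidechain.  For homo-oligomer interfaces the trans distance of a pair (i, j)
is the shorter of the two cross-subunit pairings, and the effective distance
of a pair is the minimum of its internal and trans distances.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import is_aa, protein_letters_3to1_extended

__all__ = [
    "StructureModel",
    "ContactSpec",
    "PairDistanceTable",
    "read_structure",
    "sidechain_atoms",
    "min_pair_distance",
    "build_distance_table",
    "distinguish_and_rank",
]

BACKBONE_HEAVY = {"N", "CA", "C", "O", "OXT"}
# hydrogens riding on backbone N or CA (PDB v3 naming; glycine's HA2/HA3 are
# reclassified as sidechain by the glycine rule)
BACKBONE_H = {"H", "H1", "H2", "H3", "HA", "HN", "D", "D1", "D2", "D3", "DA"}


@dataclass(frozen=True)
class Residue:
    """One residue: author numbering, type, and atom records."""

    resname: str
    resseq: int
    icode: str
    atom_names: tuple
    coords: np.ndarray  # (n_atoms, 3)

    @property
    def one_letter(self) -> str:
        return protein_letters_3to1_extended.get(self.resname, "X")


@dataclass(frozen=True)
class StructureModel:
    """Residues of one (or two) chains keyed by query-sequence position."""

    chain_id: str
    residues: dict            # query position -> Residue (primary chain)
    partner_chain_id: str | None = None
    partner_residues: dict = field(default_factory=dict)


def _extract_chain(model, chain_id: str, position_map=None) -> dict:
    if chain_id not in [c.id for c in model]:
        raise ValueError(f"chain {chain_id!r} not found in structure")
    out = {}
    for res in model[chain_id]:
        het, resseq, icode = res.id
        if het != " " and res.get_resname() != "MSE":
            continue  # skip waters/ligands; keep selenomethionine
        if not (is_aa(res, standard=True) or res.get_resname() == "MSE"):
            continue
        names, xyz = [], []
        for atom in res:
            # disordered atoms resolve to the highest-occupancy conformer
            # (ties keep the first altloc encountered)
            names.append(atom.get_name())
            xyz.append(atom.get_coord())
        coords = np.asarray(xyz, dtype=float)
        if not np.all(np.isfinite(coords)):
            raise ValueError(f"non-finite coordinates in residue {resseq}{icode}")
        pos = position_map.get((resseq, icode.strip())) if position_map else resseq
        if pos is None:
            continue
        out[pos] = Residue(
            resname=res.get_resname(),
            resseq=resseq,
            icode=icode.strip(),
            atom_names=tuple(names),
            coords=coords,
        )
    return out


def read_structure(
    pdb_file,
    chain: str,
    partner_chain: str | None = None,
    position_map: dict | None = None,
) -> StructureModel:
    """Load one chain (plus an optional interface partner) from a PDB file.

    Only the first MODEL is read.  By default the author residue number is
    taken as the query-sequence position; supply ``position_map`` (mapping
    ``(resseq, icode)`` to position) when numbering differs.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(pdb_file))
    models = list(structure)
    if not models:
        raise ValueError(f"no coordinate models in {pdb_file}")
    model = models[0]
    residues = _extract_chain(model, chain, position_map)
    partner = {}
    if partner_chain is not None:
        partner = _extract_chain(model, partner_chain, position_map)
    return StructureModel(
        chain_id=chain,
        residues=residues,
        partner_chain_id=partner_chain,
        partner_residues=partner,
    )


def sidechain_atoms(residue: Residue) -> tuple[tuple, np.ndarray]:
    """Names and coordinates of the residue's sidechain atom set.

    Glycine's sidechain is its C-alpha plus attached hydrogens; any residue
    whose sidechain set comes up empty (stripped structures) falls back to
    C-alpha alone.  Nonstandard residues keep all non-backbone atoms.
    """
    names = residue.atom_names
    resname = residue.resname
    standard = resname in protein_letters_3to1_extended or resname == "MSE"
    keep = []
    if resname == "GLY":
        for k, n in enumerate(names):
            if n == "CA" or n.startswith("HA") or n in {"1HA", "2HA", "3HA"}:
                keep.append(k)
    else:
        if not standard:
            warnings.warn(
                f"nonstandard residue {resname}: using all non-backbone atoms",
                stacklevel=2,
            )
        for k, n in enumerate(names):
            if n in BACKBONE_HEAVY or n in BACKBONE_H:
                continue
            keep.append(k)
    if not keep and "CA" in names:
        keep = [names.index("CA")]
    kept_names = tuple(names[k] for k in keep)
    return kept_names, residue.coords[keep]


def min_pair_distance(res_i: Residue, res_j: Residue) -> float:
    """Minimum Euclidean distance between the two sidechain atom sets (A)."""
    _, a = sidechain_atoms(res_i)
    _, b = sidechain_atoms(res_j)
    if a.size == 0 or b.size == 0:
        return math.nan
    diff = a[:, None, :] - b[None, :, :]
    return float(np.sqrt((diff**2).sum(-1)).min())


@dataclass(frozen=True)
class ContactSpec:
    """Contact definition: distance window [r_min, r_max] in Angstrom and
    minimum number of intervening residues m.

    r_max = 5 is the default contact criterion; r_max = 2.6 restricts to
    hydrogen-bond range (hydrogen-acceptor upper bound) and only makes sense
    on structures that include hydrogens.
    """

    r_min: float = 0.0
    r_max: float = 5.0
    m: int = 5

    def __post_init__(self):
        if not 0 <= self.r_min < self.r_max:
            raise ValueError("require 0 <= r_min < r_max")
        if self.m < 0:
            raise ValueError("require m >= 0")


@dataclass(frozen=True)
class PairDistanceTable:
    """Per unordered pair (i < j): internal, trans and effective distances (A)."""

    internal: dict
    trans: dict
    has_interface: bool

    def effective(self, i: int, j: int) -> float:
        """min(internal, trans); NaN when neither is available."""
        key = (i, j) if i < j else (j, i)
        a = self.internal.get(key, math.nan)
        b = self.trans.get(key, math.nan)
        if math.isnan(a):
            return b
        if math.isnan(b):
            return a
        return min(a, b)

    def to_tsv(self) -> str:
        keys = sorted(set(self.internal) | set(self.trans))
        lines = ["i\tj\tinternal_A\ttrans_A\teffective_A"]

        def fmt(v):
            return "" if math.isnan(v) else f"{v:.3f}"

        for i, j in keys:
            a = self.internal.get((i, j), math.nan)
            b = self.trans.get((i, j), math.nan)
            lines.append(f"{i}\t{j}\t{fmt(a)}\t{fmt(b)}\t{fmt(self.effective(i, j))}")
        return "\n".join(lines) + "\n"


def _min_dist_matrix(res_a: dict, res_b: dict) -> tuple[np.ndarray, list, list]:
    """Dense matrix of minimum sidechain distances between two residue sets."""
    pos_a = sorted(res_a)
    pos_b = sorted(res_b)

    def stack(res_map, order):
        pts, owner = [], []
        for idx, p in enumerate(order):
            _, xyz = sidechain_atoms(res_map[p])
            pts.append(xyz)
            owner.append(np.full(len(xyz), idx))
        if not pts:
            return np.empty((0, 3)), np.empty(0, dtype=int)
        return np.concatenate(pts), np.concatenate(owner)

    A, oa = stack(res_a, pos_a)
    B, ob = stack(res_b, pos_b)
    out = np.full((len(pos_a), len(pos_b)), np.inf)
    if len(A) and len(B):
        chunk = max(1, 4_000_000 // max(len(B), 1))
        for s in range(0, len(A), chunk):
            d = np.sqrt(((A[s : s + chunk, None, :] - B[None, :, :]) ** 2).sum(-1))
            np.minimum.at(out, (oa[s : s + chunk][:, None], ob[None, :]), d)
    out[np.isinf(out)] = np.nan
    return out, pos_a, pos_b


def build_distance_table(model: StructureModel, spec: ContactSpec | None = None) -> PairDistanceTable:
    """All-pairs sidechain distance table for the model's primary chain.

    With an interface partner chain, the trans distance of (i, j) is the
    minimum of the two cross-subunit pairings d(i_A, j_B) and d(j_A, i_B),
    and the effective distance is the shorter of internal and trans.
    """
    if spec is not None and spec.r_max <= 2.6:
        if not any(
            n.startswith(("H", "D", "1H", "2H", "3H"))
            for r in model.residues.values()
            for n in r.atom_names
        ):
            warnings.warn(
                "hydrogen-bond distance window requested on a structure "
                "without hydrogens; distances will be heavy-atom only",
                stacklevel=2,
            )
    M, pos, _ = _min_dist_matrix(model.residues, model.residues)
    internal = {}
    for a in range(len(pos)):
        for b in range(a + 1, len(pos)):
            v = M[a, b]
            if not math.isnan(v):
                internal[(pos[a], pos[b])] = float(v)
    trans = {}
    if model.partner_chain_id is not None and model.partner_residues:
        T, pa, pb = _min_dist_matrix(model.residues, model.partner_residues)
        idx_a = {p: k for k, p in enumerate(pa)}
        idx_b = {p: k for k, p in enumerate(pb)}
        for a, i in enumerate(pa):
            for j in pb:
                if j <= i:
                    continue
                d1 = T[a, idx_b[j]]  # i in A vs j in B
                d2 = (
                    T[idx_a[j], idx_b[i]]  # j in A vs i in B
                    if (j in idx_a and i in idx_b)
                    else math.nan
                )
                vals = [v for v in (d1, d2) if not math.isnan(v)]
                if vals:
                    trans[(i, j)] = float(min(vals))
    return PairDistanceTable(
        internal=internal, trans=trans, has_interface=model.partner_chain_id is not None
    )


def distinguish_and_rank(arr, table: PairDistanceTable, spec: ContactSpec):
    """Turn a scored pair array plus a distance table into a binary ranked array.

    Pairs are dropped (the array shrinks) when they are closer in sequence
    than m intervening residues, have no measurable distance (unresolved
    residues), or sit below r_min.  Pairs with effective distance within
    [r_min, r_max] are distinguished and ranked by increasing distance,
    earlier array elements winning ties.
    """
    from .ica import BinaryRankedArray  # local import to avoid cycle at import time

    labels, scores, dists, flags = [], [], [], []
    for rec in arr.records:
        if rec.j - rec.i - 1 < spec.m:
            continue
        dist = table.effective(rec.i, rec.j)
        if math.isnan(dist) or dist < spec.r_min:
            continue
        labels.append((rec.i, rec.j))
        scores.append(rec.score)
        dists.append(dist)
        flags.append(dist <= spec.r_max)
    if not labels:
        raise ValueError("no pairs left after separation/distance filtering")
    flags = np.asarray(flags, dtype=bool)
    dists_arr = np.asarray(dists)
    ranks = np.zeros(len(labels), dtype=np.int64)
    idx = np.flatnonzero(flags)
    order = idx[np.lexsort((idx, dists_arr[idx]))]  # distance, then array position
    ranks[order] = np.arange(1, len(idx) + 1)
    ranks[~flags] = 0
    masked = np.where(flags, dists_arr, np.nan)
    return BinaryRankedArray(
        flags=flags,
        ranks=ranks,
        labels=tuple(labels),
        scores=np.asarray(scores),
        distances=masked,
    )
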