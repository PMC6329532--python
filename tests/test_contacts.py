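"""Structure parsing, sidechain sets, distance tables, array construction."""

import math

import numpy as np
import pytest

from starc.contacts import (
    ContactSpec,
    build_distance_table,
    distinguish_and_rank,
    min_pair_distance,
    read_structure,
    sidechain_atoms,
)
from starc.dca_io import DCRecord, ScoredPairArray

from .conftest import make_pdb


def simple_residue(resname, resseq, atoms):
    return (resname, resseq, atoms)


class TestReadStructure:
    def test_three_residue_roundtrip(self, pdb_writer):
        text = make_pdb(
            [
                ("ALA", 1, [("N", (0, 0, 0)), ("CA", (1.5, 0, 0)), ("CB", (2, 1, 0)),
                            ("C", (3, 0, 0)), ("O", (4, 0, 0))]),
                ("GLY", 2, [("N", (5, 0, 0)), ("CA", (6, 0, 0)), ("C", (7, 0, 0)),
                            ("O", (8, 0, 0))]),
                ("SER", 3, [("N", (9, 0, 0)), ("CA", (10, 0, 0)), ("CB", (10, 1, 0)),
                            ("OG", (10, 2, 0)), ("C", (11, 0, 0)), ("O", (12, 0, 0))]),
            ]
        )
        model = read_structure(pdb_writer(text), chain="A")
        assert sorted(model.residues) == [1, 2, 3]
        assert model.residues[3].one_letter == "S"
        np.testing.assert_allclose(
            model.residues[1].coords[model.residues[1].atom_names.index("CB")],
            [2, 1, 0],
        )

    def test_only_first_model_loaded(self, pdb_writer):
        body = make_pdb([("ALA", 1, [("CA", (0, 0, 0)), ("CB", (1, 0, 0))])])
        text = (
            "MODEL        1\n" + body.replace("END\n", "") + "ENDMDL\n"
            "MODEL        2\n"
            + make_pdb([("ALA", 9, [("CA", (5, 5, 5)), ("CB", (6, 5, 5))])]).replace("END\n", "")
            + "ENDMDL\nEND\n"
        )
        model = read_structure(pdb_writer(text), chain="A")
        assert sorted(model.residues) == [1]

    def test_missing_chain_is_explicit_error(self, pdb_writer):
        text = make_pdb([("ALA", 1, [("CA", (0, 0, 0))])])
        with pytest.raises(ValueError, match="chain 'B' not found"):
            read_structure(pdb_writer(text), chain="B")


class TestSidechainAtoms:
    def _residue(self, resname, atoms, pdb_writer):
        text = make_pdb([(resname, 1, atoms)])
        model = read_structure(pdb_writer(text), chain="A")
        return model.residues[1]

    def test_glycine_with_hydrogens(self, pdb_writer):
        res = self._residue(
            "GLY",
            [("N", (0, 0, 0)), ("CA", (1, 0, 0)), ("C", (2, 0, 0)), ("O", (3, 0, 0)),
             ("HA2", (1, 1, 0)), ("HA3", (1, -1, 0)), ("H", (0, 1, 0))],
            pdb_writer,
        )
        names, coords = sidechain_atoms(res)
        assert set(names) == {"CA", "HA2", "HA3"}
        assert coords.shape == (3, 3)

    def test_alanine_with_hydrogens(self, pdb_writer):
        res = self._residue(
            "ALA",
            [("N", (0, 0, 0)), ("CA", (1, 0, 0)), ("C", (2, 0, 0)), ("O", (3, 0, 0)),
             ("CB", (1, 1, 0)), ("HB1", (1, 2, 0)), ("HB2", (2, 1, 0)),
             ("HB3", (0, 1, 0)), ("HA", (1, 0, 1)), ("H", (0, 0, 1))],
            pdb_writer,
        )
        names, _ = sidechain_atoms(res)
        assert set(names) == {"CB", "HB1", "HB2", "HB3"}

    def test_glycine_without_hydrogens_falls_back_to_ca(self, pdb_writer):
        res = self._residue(
            "GLY",
            [("N", (0, 0, 0)), ("CA", (1, 0, 0)), ("C", (2, 0, 0)), ("O", (3, 0, 0))],
            pdb_writer,
        )
        names, _ = sidechain_atoms(res)
        assert set(names) == {"CA"}


class TestMinPairDistance:
    def _two(self, atoms_a, atoms_b, pdb_writer):
        text = make_pdb([("ALA", 1, atoms_a), ("ALA", 2, atoms_b)])
        model = read_structure(pdb_writer(text), chain="A")
        return model.residues[1], model.residues[2]

    def test_three_four_five(self, pdb_writer):
        a, b = self._two([("CB", (0, 0, 0))], [("CB", (3, 4, 0))], pdb_writer)
        assert min_pair_distance(a, b) == pytest.approx(5.0)
        assert min_pair_distance(b, a) == min_pair_distance(a, b)

    def test_identical_coordinates(self, pdb_writer):
        a, b = self._two([("CB", (1, 1, 1))], [("CB", (1, 1, 1))], pdb_writer)
        assert min_pair_distance(a, b) == 0.0

    def test_picks_closest_atom_pair(self, pdb_writer):
        a, b = self._two(
            [("CB", (0, 0, 0)), ("OG", (0, 0, 1.2))],
            [("CB", (0, 0, 5.3)), ("OG", (0, 0, 4.1))],
            pdb_writer,
        )
        assert min_pair_distance(a, b) == pytest.approx(2.9)


def _chain_of_cb(positions, resseq_start=1, resname="ALA"):
    return [
        (resname, resseq_start + k, [("CA", (x, y, z)), ("CB", (x, y, z))])
        for k, (x, y, z) in enumerate(positions)
    ]


class TestDistanceTable:
    def test_matches_naive_all_atom_double_loop(self, pdb_writer):
        rng = np.random.default_rng(5)
        residues = []
        for k in range(1, 13):
            base = rng.uniform(0, 20, 3)
            atoms = [("N", tuple(base)), ("CA", tuple(base + [1, 0, 0])),
                     ("C", tuple(base + [2, 0, 0])), ("O", tuple(base + [3, 0, 0])),
                     ("CB", tuple(base + rng.uniform(-1, 1, 3))),
                     ("CG", tuple(base + rng.uniform(-2, 2, 3)))]
            residues.append(("LEU", k, atoms))
        model = read_structure(pdb_writer(make_pdb(residues)), chain="A")
        table = build_distance_table(model)
        for i in range(1, 13):
            for j in range(i + 1, 13):
                _, a = sidechain_atoms(model.residues[i])
                _, b = sidechain_atoms(model.residues[j])
                naive = min(
                    float(np.linalg.norm(pa - pb)) for pa in a for pb in b
                )
                assert table.internal[(i, j)] == pytest.approx(naive, abs=1e-9)

    def test_homodimer_interface_takes_shorter_distance(self, pdb_writer):
        # internal (1,2) at 6.0 A; across subunits residue 1A-2B at 2.4 A
        chain_a = make_pdb(_chain_of_cb([(0, 0, 0), (6, 0, 0)]), chain="A")
        chain_b = make_pdb(_chain_of_cb([(20, 0, 0), (0, 2.4, 0)]), chain="B")
        text = chain_a.replace("END\n", "") + chain_b
        model = read_structure(pdb_writer(text), chain="A", partner_chain="B")
        table = build_distance_table(model)
        assert table.internal[(1, 2)] == pytest.approx(6.0)
        assert table.trans[(1, 2)] == pytest.approx(2.4)
        assert table.effective(1, 2) == pytest.approx(2.4)

    def test_no_interface_effective_equals_internal(self, pdb_writer):
        text = make_pdb(_chain_of_cb([(0, 0, 0), (6, 0, 0)]))
        model = read_structure(pdb_writer(text), chain="A")
        table = build_distance_table(model)
        assert table.effective(1, 2) == pytest.approx(6.0)
        assert not table.has_interface

    def test_unresolved_residue_yields_absent_distance(self, pdb_writer):
        text = make_pdb(_chain_of_cb([(0, 0, 0), (3, 0, 0)]))  # residues 1, 2 only
        model = read_structure(pdb_writer(text), chain="A")
        table = build_distance_table(model)
        assert math.isnan(table.effective(1, 5))


def _scored(records, ell=40):
    recs = [DCRecord(i=i, j=j, score=s) for i, j, s in records]
    recs.sort(key=lambda r: (-r.score, r.i, r.j))
    return ScoredPairArray(records=tuple(recs), ell=ell)


class TestDistinguishAndRank:
    def _table(self, pdb_writer, coords):
        model = read_structure(pdb_writer(make_pdb(_chain_of_cb(coords))), "A")
        return build_distance_table(model)

    def test_sub_rmin_pairs_are_removed_entirely(self, pdb_writer):
        # (1,10) at 2.4 A: below r_min=3 so the array shrinks
        coords = [(0, 0, 0)] + [(50 + 10 * k, 0, 0) for k in range(8)] + [(0, 2.4, 0)]
        table = self._table(pdb_writer, coords)
        arr_in = _scored([(1, 10, 5.0), (1, 9, 4.0), (2, 9, 3.0)])
        spec = ContactSpec(r_min=3.0, r_max=5.0, m=5)
        out = distinguish_and_rank(arr_in, table, spec)
        assert out.L == 2
        assert (1, 10) not in out.labels

    def test_separation_filter_convention(self, pdb_writer):
        coords = [(3.0 * k, 0, 0) for k in range(16)]
        table = self._table(pdb_writer, coords)
        arr_in = _scored([(10, 15, 2.0), (10, 16, 1.0)])
        out = distinguish_and_rank(arr_in, table, ContactSpec(m=5))
        assert (10, 15) not in out.labels  # 4 intervening
        assert (10, 16) in out.labels      # 5 intervening

    def test_tied_distances_rank_earlier_element_better(self, pdb_writer):
        coords = [(0, 0, 0), (100, 0, 0), (0, 2.6, 0), (200, 0, 0),
                  (300, 0, 0), (400, 0, 0), (500, 0, 0), (0, -2.6, 0)]
        table = self._table(pdb_writer, coords)
        # both (1,3)... wait for separation use pairs (1,8) and (1,3)?
        arr_in = _scored([(1, 8, 9.0), (1, 3, 8.0)], ell=40)
        out = distinguish_and_rank(arr_in, table, ContactSpec(m=1))
        # distances both exactly 2.6; the earlier array element (higher score)
        # gets rank 1
        k_first = out.labels.index((1, 8))
        k_second = out.labels.index((1, 3))
        assert out.ranks[k_first] == 1
        assert out.ranks[k_second] == 2

    def test_monotone_in_rmax_and_m(self, pdb_writer):
        rng = np.random.default_rng(11)
        coords = [tuple(rng.uniform(0, 25, 3)) for _ in range(20)]
        table = self._table(pdb_writer, coords)
        pairs = [(i, j, float(rng.standard_normal()))
                 for i in range(1, 21) for j in range(i + 1, 21)]
        arr_in = _scored(pairs)
        Ds, Ls = [], []
        for rmax in (4.0, 6.0, 9.0):
            out = distinguish_and_rank(arr_in, table, ContactSpec(r_max=rmax, m=2))
            Ds.append(out.D)
            Ls.append(out.L)
        assert Ds == sorted(Ds)
        assert len(set(Ls)) == 1  # r_max does not change L
        Lm = []
        for m in (0, 3, 6):
            out = distinguish_and_rank(arr_in, table, ContactSpec(r_max=6.0, m=m))
            Lm.append(out.L)
        assert Lm == sorted(Lm, reverse=True)

    def test_empty_after_filtering_signals(self, pdb_writer):
        table = self._table(pdb_writer, [(0, 0, 0), (3, 0, 0)])
        arr_in = _scored([(1, 2, 1.0)])
        with pytest.raises(ValueError, match="no pairs left"):
            distinguish_and_rank(arr_in, table, ContactSpec(m=5))
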