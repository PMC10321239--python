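"""Coordinate parsing and contact detection vs an all-pairs oracle."""

import numpy as np
import pytest

from sua5kit.records import InputError
from sua5kit.simulate import make_toy_structure
from sua5kit.structure import (
    SelectionError,
    hydrogen_bonds,
    interface_residues,
    map_numbering,
    min_distance,
    read_structure,
    salt_bridges,
)

_BASIC = {("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE"), ("LYS", "NZ")}
_ACIDIC = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}


def oracle_pairs(atoms, cutoff, chemistry):
    """Naive O(n^2) loop over atom pairs; shares no code with the package."""
    found = set()
    n = atoms.array_length()
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            key_i = (str(atoms.res_name[i]), str(atoms.atom_name[i]))
            key_j = (str(atoms.res_name[j]), str(atoms.atom_name[j]))
            if chemistry == "hbond":
                if atoms.element[i] not in "NO" or atoms.element[j] not in "NO":
                    continue
            else:
                if not (key_i in _BASIC and key_j in _ACIDIC):
                    continue
            same_res = (
                atoms.chain_id[i] == atoms.chain_id[j]
                and atoms.res_id[i] == atoms.res_id[j]
            )
            if same_res:
                continue
            d = float(np.sqrt(((atoms.coord[i] - atoms.coord[j]) ** 2).sum()))
            if d <= cutoff:
                found.add((min(i, j), max(i, j), round(d, 3)))
    return found


class TestReadStructure:
    def test_toy_pdb_roundtrips(self):
        text = make_toy_structure([("hbond", 2.4)])
        model = read_structure(text)
        assert model.atoms.array_length() == 2
        assert set(model.chains) == {"A", "B"}

    def test_garbage_rejected_with_parse_error(self):
        with pytest.raises(InputError):
            read_structure("this is not\na coordinate file\n")

    def test_selector_by_residue_range_and_atom_name(self):
        model = read_structure(make_toy_structure([("hbond", 2.4), ("hbond", 3.0)]))
        sel = model.select("A:1-2:ND2")
        assert sel.array_length() == 2
        with pytest.raises(SelectionError):
            model.select("C:*:*")


class TestMinDistance:
    def test_atom_against_itself_is_zero(self):
        model = read_structure(make_toy_structure([("hbond", 2.4)]))
        assert min_distance(model, "A:1:ND2", "A:1:ND2") == 0.0

    def test_planted_distance_recovered(self):
        model = read_structure(make_toy_structure([("hbond", 2.4)]))
        assert min_distance(model, "A:*:*", "B:*:*") == pytest.approx(2.4, abs=1e-3)

    def test_symmetric_in_selections(self):
        model = read_structure(make_toy_structure([("hbond", 2.4), ("salt_bridge", 3.2)]))
        assert min_distance(model, "A:*:*", "B:*:*") == min_distance(
            model, "B:*:*", "A:*:*"
        )

    def test_empty_selection_names_the_selector(self):
        model = read_structure(make_toy_structure([("hbond", 2.4)]))
        with pytest.raises(SelectionError, match="Z:9:XX"):
            min_distance(model, "Z:9:XX", "A:*:*")


class TestHydrogenBonds:
    def test_three_planted_pairs_found_exactly(self):
        dists = [2.2, 2.7, 3.3]
        model = read_structure(
            make_toy_structure([("hbond", d) for d in dists])
        )
        found = hydrogen_bonds(model, "A:*:*", "B:*:*", 3.5)
        assert [c.distance_reported for c in found] == sorted(dists)

    def test_pairs_beyond_cutoff_excluded(self):
        model = read_structure(make_toy_structure([("hbond", 2.4), ("hbond", 3.6)]))
        found = hydrogen_bonds(model, "A:*:*", "B:*:*", 3.5)
        assert [c.distance_reported for c in found] == [2.4]

    def test_matches_all_pairs_oracle(self):
        contacts = [("hbond", d) for d in (2.1, 2.5, 2.9, 3.4, 3.6)] + [
            ("salt_bridge", d) for d in (2.8, 3.9)
        ]
        model = read_structure(make_toy_structure(contacts))
        found = hydrogen_bonds(model, "*:*:*", "*:*:*", 3.5)
        expected = oracle_pairs(model.atoms, 3.5, "hbond")
        assert len(found) == len(expected)
        assert sorted(round(c.distance, 3) for c in found) == sorted(
            d for *_, d in expected
        )

    def test_empty_selection_is_an_error(self):
        model = read_structure(make_toy_structure([]))
        with pytest.raises(SelectionError):
            hydrogen_bonds(model, "A:*:*", "B:*:*", 3.5)


class TestSaltBridges:
    def test_structure_without_charged_residues_is_empty(self):
        model = read_structure(make_toy_structure([("hbond", 2.4)]))
        assert salt_bridges(model) == []

    def test_planted_bridge_at_3_angstrom(self):
        model = read_structure(make_toy_structure([("salt_bridge", 3.0)]))
        found = salt_bridges(model)
        assert len(found) == 1
        assert found[0].distance_reported == 3.0

    def test_cutoff_boundary(self):
        near = read_structure(make_toy_structure([("salt_bridge", 3.95)]))
        far = read_structure(make_toy_structure([("salt_bridge", 4.05)]))
        assert len(salt_bridges(near, 4.0)) == 1
        assert salt_bridges(far, 4.0) == []

    def test_matches_all_pairs_oracle(self):
        contacts = [("salt_bridge", d) for d in (2.9, 3.5, 3.95, 4.2)] + [
            ("hbond", 2.4)
        ]
        model = read_structure(make_toy_structure(contacts))
        found = salt_bridges(model, 4.0)
        expected = oracle_pairs(model.atoms, 4.0, "salt")
        assert sorted(round(c.distance, 3) for c in found) == sorted(
            d for *_, d in expected
        )


class TestMapNumbering:
    def test_reference_chain_maps_identically(self, refs):
        # a chain carrying the reference sequence maps author i -> ref i
        from sua5kit.simulate import _PAIR_SPACING  # placement constant

        import biotite.structure as struc
        import biotite.structure.io.pdb as pdbio
        import io

        seq = refs[1].sequence
        n = len(seq)
        from biotite.sequence import ProteinSequence

        arr = struc.AtomArray(n)
        arr.coord = np.array([[3.8 * i, 0, 0] for i in range(n)], dtype=np.float32)
        arr.chain_id = np.full(n, "A")
        arr.res_id = np.arange(1, n + 1)
        arr.res_name = np.array(
            [ProteinSequence.convert_letter_1to3(c).upper() for c in seq]
        )
        arr.atom_name = np.full(n, "CA")
        arr.element = np.full(n, "C")
        arr.hetero = np.zeros(n, dtype=bool)
        f = pdbio.PDBFile()
        f.set_structure(arr)
        buf = io.StringIO()
        f.write(buf)
        model = read_structure(buf.getvalue())
        mapping = map_numbering(model, "A", refs[1])
        assert all(mapping[i] == i for i in range(1, n + 1))

    def test_unrelated_chain_unmappable(self, refs):
        model = read_structure(make_toy_structure([("hbond", 2.4)]))
        with pytest.raises((InputError, SelectionError)):
            map_numbering(model, "A", refs[0])


class TestInterfaceResidues:
    def test_disjoint_spans_with_no_contact_is_empty(self):
        model = read_structure(make_toy_structure([("hbond", 2.4), ("hbond", 2.6)]))
        # pairs are 50 A apart: residues 1 vs 2 on chain A never touch
        assert interface_residues(model, (1, 1), (2, 2), 4.5, chain="A") == []

    def test_engineered_contact_found(self):
        # single-chain two-domain toy: residues 1-3 and 10-12 on a line,
        # with residue 11 bent back to touch residue 2 at 3.0 A
        import io

        import biotite.structure as struc
        import biotite.structure.io.pdb as pdbio

        res_ids = [1, 2, 3, 10, 11, 12]
        coords = [
            [0, 0, 0], [10, 0, 0], [20, 0, 0],
            [100, 0, 0], [10, 3.0, 0], [120, 0, 0],
        ]
        n = len(res_ids)
        arr = struc.AtomArray(n)
        arr.coord = np.array(coords, dtype=np.float32)
        arr.chain_id = np.full(n, "A")
        arr.res_id = np.array(res_ids)
        arr.res_name = np.full(n, "GLY")
        arr.atom_name = np.full(n, "CA")
        arr.element = np.full(n, "C")
        arr.hetero = np.zeros(n, dtype=bool)
        f = pdbio.PDBFile()
        f.set_structure(arr)
        buf = io.StringIO()
        f.write(buf)
        model = read_structure(buf.getvalue())
        found = interface_residues(model, (1, 3), (10, 12), 4.5, chain="A")
        assert len(found) == 1
        assert found[0].atom_a[2] == 2 and found[0].atom_b[2] == 11
        assert found[0].distance_reported == 3.0

    def test_overlapping_spans_rejected(self):
        model = read_structure(make_toy_structure([("hbond", 2.4)]))
        with pytest.raises(InputError):
            interface_residues(model, (1, 5), (3, 8), 4.5)
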