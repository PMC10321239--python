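"""Atomic-coordinate parsing and interdomain contact detection.

Hydrogen bonds are called on a heavy-atom donor/acceptor distance criterion
only (default 3.5 Angstrom, no angle term: crystal structures lack
hydrogens and the literature values being reproduced are bare distances).
Salt bridges pair the guanidinium/ammonium nitrogens of Arg/Lys with the
carboxylate oxygens of Asp/Glu at 4.0 Angstrom by default.

Selections use compact ``chain:residues:atoms`` strings, e.g. ``A:62:ND2``,
``A:100-110:*``, ``*:PPI:*`` (a residue field that is not a number or range
matches the residue name, which is how ligands are selected).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

import biotite.structure as struc
import biotite.structure.io.pdb as pdbio
import biotite.structure.io.pdbx as pdbxio
from biotite.sequence import ProteinSequence

from .align import ResidueMap, global_align, percent_identity, residue_map
from .annotation import ReferenceAnnotation
from .records import InputError

HBOND_CUTOFF = 3.5
SALT_BRIDGE_CUTOFF = 4.0
INTERFACE_CUTOFF = 4.5

#: Het-codes of the ligands of interest (pyrophosphate, carbamoyl
#: phosphate, ADP, free threonine, TC-AMP); overridable per call.
LIGAND_WHITELIST = {"PPI", "POP", "CP", "ADP", "THR", "TCA"}

_BASIC_ATOMS = {("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE"), ("LYS", "NZ")}
_ACIDIC_ATOMS = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}


class SelectionError(ValueError):
    """An atom selection matched nothing."""


@dataclass
class StructureModel:
    """First model of a coordinate file, altlocs resolved by occupancy."""

    atoms: struc.AtomArray
    source: str = ""

    @property
    def chains(self) -> list[str]:
        return sorted(set(self.atoms.chain_id))

    def chain_sequence(self, chain: str) -> tuple[str, list[int]]:
        """One-letter polymer sequence of a chain and its author residue ids."""
        sub = self.atoms[
            (self.atoms.chain_id == chain)
            & ~self.atoms.hetero
            & struc.filter_amino_acids(self.atoms)
        ]
        if sub.array_length() == 0:
            raise SelectionError(f"no polymer residues in chain {chain!r}")
        ids, names = struc.get_residues(sub)

        def one_letter(name3: str) -> str:
            try:
                letter = ProteinSequence.convert_letter_3to1(name3)
            except Exception:
                return "X"
            return letter if letter in "ACDEFGHIKLMNPQRSTVWY" else "X"

        seq = "".join(one_letter(n) for n in names)
        return seq, [int(i) for i in ids]

    def ligands(self, whitelist: set[str] | None = None) -> list[tuple[str, str, int]]:
        """(res_name, chain, res_id) for het-groups, optionally whitelisted."""
        het = self.atoms[self.atoms.hetero]
        out = []
        seen = set()
        for name, chain, rid in zip(het.res_name, het.chain_id, het.res_id):
            key = (str(name), str(chain), int(rid))
            if key not in seen:
                seen.add(key)
                out.append(key)
        if whitelist is not None:
            out = [k for k in out if k[0] in whitelist]
        return out

    def select(self, selector: str) -> struc.AtomArray:
        """Resolve a ``chain:residues:atoms`` selector to an atom array."""
        try:
            chain_spec, res_spec, atom_spec = selector.split(":")
        except ValueError as e:
            raise SelectionError(
                f"bad selector {selector!r}: expected chain:residues:atoms"
            ) from e
        mask = np.ones(self.atoms.array_length(), dtype=bool)
        if chain_spec != "*":
            mask &= self.atoms.chain_id == chain_spec
        if res_spec != "*":
            if "-" in res_spec and not res_spec.lstrip("-").isalpha():
                lo, hi = (int(x) for x in res_spec.split("-"))
                mask &= (self.atoms.res_id >= lo) & (self.atoms.res_id <= hi)
            elif res_spec.lstrip("-").isdigit():
                mask &= self.atoms.res_id == int(res_spec)
            else:
                mask &= self.atoms.res_name == res_spec.upper()
        if atom_spec != "*":
            names = [a.strip() for a in atom_spec.split(",")]
            mask &= np.isin(self.atoms.atom_name, names)
        sel = self.atoms[mask]
        if sel.array_length() == 0:
            raise SelectionError(f"selection {selector!r} matched no atoms")
        return sel


@dataclass
class ContactRecord:
    kind: str  # "hbond" | "salt_bridge" | "interface"
    atom_a: tuple[str, str, int, str]  # (chain, res_name, res_id, atom_name)
    atom_b: tuple[str, str, int, str]
    distance: float  # Angstrom, full precision

    @property
    def distance_reported(self) -> float:
        """Distance at literature precision (0.1 Angstrom)."""
        return round(self.distance, 1)


def _atom_addr(atoms: struc.AtomArray, i: int) -> tuple[str, str, int, str]:
    return (
        str(atoms.chain_id[i]),
        str(atoms.res_name[i]),
        int(atoms.res_id[i]),
        str(atoms.atom_name[i]),
    )


def read_structure(source: str | Path, fmt: str | None = None) -> StructureModel:
    """Parse PDB or mmCIF content (path or literal text); first model only.

    Alternate locations are resolved to the highest-occupancy conformer
    (ties go to altloc 'A', biotite's convention).
    """
    text, name = _read_text(source)
    if fmt is None:
        fmt = "cif" if text.lstrip().startswith("data_") or name.endswith(".cif") else "pdb"
    try:
        if fmt == "cif":
            f = pdbxio.CIFFile.read(io.StringIO(text))
            atoms = pdbxio.get_structure(f, model=1, altloc="occupancy")
        else:
            f = pdbio.PDBFile.read(io.StringIO(text))
            atoms = f.get_structure(model=1, altloc="occupancy")
    except Exception as e:
        raise InputError(f"cannot parse structure {name!r}: {e}") from e
    if atoms.array_length() == 0:
        raise InputError(f"structure {name!r} contains no atoms")
    return StructureModel(atoms=atoms, source=name)


def _read_text(source: str | Path) -> tuple[str, str]:
    if isinstance(source, Path) or (
        "\n" not in str(source) and Path(str(source)).exists()
    ):
        p = Path(source)
        return p.read_text(), p.name
    return str(source), "<string>"


def min_distance(
    model: StructureModel, sel_a: str | struc.AtomArray, sel_b: str | struc.AtomArray
) -> float:
    """Minimum Euclidean distance over the selection cross-product (Angstrom)."""
    a = model.select(sel_a) if isinstance(sel_a, str) else sel_a
    b = model.select(sel_b) if isinstance(sel_b, str) else sel_b
    return float(cdist(a.coord, b.coord).min())


def _pair_contacts(
    a: struc.AtomArray, b: struc.AtomArray, cutoff: float, kind: str
) -> list[ContactRecord]:
    d = cdist(a.coord, b.coord)
    out = []
    seen = set()
    for i, j in zip(*np.nonzero(d <= cutoff)):
        addr_a, addr_b = _atom_addr(a, int(i)), _atom_addr(b, int(j))
        if addr_a[:3] == addr_b[:3]:  # same residue: not an interaction
            continue
        key = tuple(sorted((addr_a, addr_b)))
        if key in seen:
            continue
        seen.add(key)
        out.append(ContactRecord(kind, addr_a, addr_b, float(d[i, j])))
    out.sort(key=lambda c: (c.distance, c.atom_a, c.atom_b))
    return out


def _polar_mask(atoms: struc.AtomArray) -> np.ndarray:
    return np.isin(atoms.element, ("N", "O"))


def hydrogen_bonds(
    model: StructureModel,
    sel_a: str,
    sel_b: str,
    cutoff: float = HBOND_CUTOFF,
) -> list[ContactRecord]:
    """Donor/acceptor-capable heavy-atom (N, O) pairs within the cutoff.

    Pairs within a single residue are excluded; results sorted by distance.
    """
    if cutoff <= 0:
        raise InputError("hydrogen_bonds: cutoff must be positive")
    a, b = model.select(sel_a), model.select(sel_b)
    a, b = a[_polar_mask(a)], b[_polar_mask(b)]
    if a.array_length() == 0 or b.array_length() == 0:
        raise SelectionError("no N/O heavy atoms in selection")
    return _pair_contacts(a, b, cutoff, "hbond")


def salt_bridges(
    model: StructureModel, cutoff: float = SALT_BRIDGE_CUTOFF
) -> list[ContactRecord]:
    """Arg/Lys nitrogen - Asp/Glu carboxylate oxygen pairs within the cutoff."""
    if cutoff <= 0:
        raise InputError("salt_bridges: cutoff must be positive")
    atoms = model.atoms
    keys = list(zip(atoms.res_name, atoms.atom_name))
    basic = np.array([k in _BASIC_ATOMS for k in keys])
    acidic = np.array([k in _ACIDIC_ATOMS for k in keys])
    if not basic.any() or not acidic.any():
        return []
    return _pair_contacts(atoms[basic], atoms[acidic], cutoff, "salt_bridge")


def map_numbering(
    model: StructureModel,
    chain: str,
    reference: ReferenceAnnotation,
    identity_floor: float = 20.0,
) -> dict[int, int]:
    """Author-numbering -> reference-numbering map via global alignment.

    Never an arithmetic offset: the chain's derived sequence is aligned to
    the reference chain and the residue map is read off the alignment.
    Raises if the alignment identity falls below ``identity_floor`` percent.
    """
    seq, author_ids = model.chain_sequence(chain)
    aln = global_align(reference.sequence, seq)
    if percent_identity(aln) < identity_floor:
        raise InputError(
            f"chain {chain!r} unmappable to {reference.reference_id} "
            f"(identity below {identity_floor}%)"
        )
    rmap = residue_map(aln)
    out = {}
    for ref_pos, q_pos in rmap.pairs:
        if q_pos is not None:
            out[author_ids[q_pos - 1]] = ref_pos
    return out


def interface_residues(
    model: StructureModel,
    span_a: tuple[int, int],
    span_b: tuple[int, int],
    cutoff: float = INTERFACE_CUTOFF,
    chain: str | None = None,
) -> list[ContactRecord]:
    """Residue-level contacts across two author-numbering spans.

    Spans are 1-based inclusive and must not overlap. Returns one record
    per residue pair (closest heavy-atom distance).
    """
    if not (span_a[1] < span_b[0] or span_b[1] < span_a[0]):
        raise InputError(f"overlapping spans {span_a} / {span_b}")
    ch = chain or model.chains[0]
    a = model.select(f"{ch}:{span_a[0]}-{span_a[1]}:*")
    b = model.select(f"{ch}:{span_b[0]}-{span_b[1]}:*")
    contacts = _pair_contacts(a, b, cutoff, "interface")
    best: dict[tuple, ContactRecord] = {}
    for c in contacts:  # sorted by distance: first hit per pair is closest
        key = (c.atom_a[:3], c.atom_b[:3])
        best.setdefault(key, c)
    return sorted(best.values(), key=lambda c: c.distance)


def contacts_to_rows(contacts: Sequence[ContactRecord]) -> list[dict]:
    return [
        {
            "kind": c.kind,
            "chain_a": c.atom_a[0], "res_a": f"{c.atom_a[1]}{c.atom_a[2]}",
            "atom_a": c.atom_a[3],
            "chain_b": c.atom_b[0], "res_b": f"{c.atom_b[1]}{c.atom_b[2]}",
            "atom_b": c.atom_b[3],
            "distance_A": c.distance_reported,
        }
        for c in contacts
    ]
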