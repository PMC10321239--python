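"""Protein sequence records and the FASTA / taxonomy-TSV interchange formats.

A :class:`ProteinRecord` is the unit every pipeline stage consumes: an
accession-like identifier, an amino-acid sequence over the 20 canonical
letters plus ``X``, an ordered taxonomy path (domain -> ... -> species) and,
for synthetic data, an optional ground-truth variant label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")
ALPHABET = CANONICAL_AA | {"X"}

#: Variant ground-truth / call labels used throughout the package.
VARIANTS = ("Sua5", "TsaC", "atypical_sua5", "non_member")


class InputError(ValueError):
    """Raised for malformed or empty user inputs."""


@dataclass
class ProteinRecord:
    id: str
    sequence: str
    taxon_path: tuple[str, ...] = ()
    truth_variant: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputError(f"record {self.id!r}: empty sequence")
        seq = self.sequence.upper()
        if "U" in seq:
            # Selenocysteine: closest canonical residue chemically is Cys.
            warnings.warn(
                f"record {self.id!r}: selenocysteine (U) mapped to C", stacklevel=2
            )
            seq = seq.replace("U", "C")
        bad = set(seq) - ALPHABET
        if bad:
            raise InputError(
                f"record {self.id!r}: non-canonical letters {sorted(bad)}"
            )
        self.sequence = seq
        self.taxon_path = tuple(self.taxon_path)
        if self.truth_variant is not None and self.truth_variant not in VARIANTS:
            raise InputError(f"unknown truth variant {self.truth_variant!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    def taxon_at(self, rank: int) -> str | None:
        """Label at 0-based rank index (0 = domain), or None if absent."""
        return self.taxon_path[rank] if rank < len(self.taxon_path) else None


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    records = [
        ProteinRecord(id=r.id, sequence=str(r.seq))
        for r in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise InputError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta")


def read_taxonomy(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Read an id -> taxonomy-path table (TSV, columns id, rank1..rankN)."""
    table: dict[str, tuple[str, ...]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "id":
            raise InputError(f"{path}: first column must be 'id'")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts == [""]:
                continue
            table[parts[0]] = tuple(p for p in parts[1:] if p)
    return table


def write_taxonomy(records: Sequence[ProteinRecord], path: str | Path) -> None:
    depth = max((len(r.taxon_path) for r in records), default=0)
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(f"rank{i + 1}" for i in range(depth)) + "\n")
        for r in records:
            padded = list(r.taxon_path) + [""] * (depth - len(r.taxon_path))
            fh.write(r.id + "\t" + "\t".join(padded) + "\n")


def attach_taxonomy(
    records: Sequence[ProteinRecord], table: dict[str, tuple[str, ...]]
) -> list[ProteinRecord]:
    out = []
    for r in records:
        out.append(
            ProteinRecord(
                id=r.id,
                sequence=r.sequence,
                taxon_path=table.get(r.id, r.taxon_path),
                truth_variant=r.truth_variant,
            )
        )
    return out
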