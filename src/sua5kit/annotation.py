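"""Reference annotation for the TsaC/Sua5 family.

The family is classified against two reference numberings: a two-domain Sua5
chain ("Pa-Sua5 numbering": catalytic TsaC-like domain, interdomain loop,
SUA5 domain) and a single-domain TsaC chain ("Ec-TsaC numbering"). The
annotation records, in those numberings:

* the catalytic tetrad K56-x-R58 / S-x-N (ATP binding) and the threonine
  site T33/S/R,
* the Sua5-specific conserved residues (Pro59, Asn62, His67, Pro142,
  His157, Asp161),
* the interdomain-interface motifs KPSPT ((K/R)149-P-S-P-T153) and GVE
  (G178-Hyd-E180, Hyd in {V,I,L}),
* the interdomain-loop motifs PGM (228-230) and HY (234-235),
* the SUA5-domain arginine anchors Arg301/Arg328,
* the single signature residue that separates the variants: Pro143 in the
  Sua5 numbering, Thr-or-Ser138 in the TsaC numbering.

Real reference sequences are not redistributed with the package; instead a
pair of SYNTHETIC template chains is built deterministically from the
annotation coordinates (every annotated residue planted at its coordinate,
all other positions drawn from a fixed seeded stream). The TsaC template is
derived from the catalytic domain of the Sua5 template by a five-residue
deletion (so that Sua5 position 143 aligns with TsaC position 138) plus
replacement of every Sua5-specific residue, mirroring how the two variants
differ in nature.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np

_AA20 = "ACDEFGHIKLMNPQRSTVWY"

# Synthetic-template construction constants: the five-residue deletion that
# converts Sua5 numbering 143 into TsaC numbering 138, and the TsaC-side
# replacements of Sua5-specific residues (Asn62->Lys is the substitution
# seen in natural TsaC variants).
_TSAC_DELETION = (120, 124)  # 1-based inclusive span removed from the Sua5 catalytic domain
_TSAC_REPLACEMENTS = {
    59: "A", 62: "K", 67: "A", 142: "L", 143: "T",
    149: "A", 150: "D", 151: "G", 152: "N", 153: "L",
    157: "Q", 161: "N", 178: "S", 179: "K", 180: "D",
}


@dataclass(frozen=True)
class Motif:
    name: str
    start: int  # 1-based position of the first residue
    residues: tuple[str, ...]  # allowed letters per position, e.g. ("KR","P",...)

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(range(self.start, self.start + len(self.residues)))


@dataclass(frozen=True)
class ReferenceAnnotation:
    reference_id: str
    sequence: str
    tetrad: tuple[tuple[str, int], ...]  # ((expected letter, position), ...)
    threonine_site: tuple[tuple[str, int], ...]
    signature_position: int
    signature_expected: str  # allowed letters
    sua5_specific: tuple[tuple[str, int], ...] = ()
    motifs: tuple[Motif, ...] = ()  # KPSPT, GVE, PGM, HY for the Sua5 reference
    sua5_domain_args: tuple[tuple[str, int], ...] = ()
    catalytic_span: tuple[int, int] = (0, 0)
    loop_span: tuple[int, int] | None = None
    sua5_domain_span: tuple[int, int] | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)

    def motif(self, name: str) -> Motif:
        for m in self.motifs:
            if m.name == name:
                return m
        raise KeyError(name)

    def annotated_positions(self) -> set[int]:
        """All positions carrying an annotated residue (1-based)."""
        pos = {p for _, p in self.tetrad}
        pos |= {p for _, p in self.threonine_site}
        pos |= {p for _, p in self.sua5_specific}
        pos |= {p for _, p in self.sua5_domain_args}
        pos.add(self.signature_position)
        for m in self.motifs:
            pos |= set(m.positions)
        return pos


def _load_json() -> dict:
    with resources.files("sua5kit.data").joinpath("reference_annotation.json").open() as fh:
        return json.load(fh)


def _build_sua5_template(spec: dict) -> str:
    """Deterministic synthetic Sua5 template with all annotated residues planted."""
    rng = np.random.default_rng(711)
    seq = list(rng.choice(list(_AA20), size=spec["length"]))
    planted: dict[int, str] = {}
    for letter, pos in spec["tetrad"].items():
        planted[pos] = letter
    for letter, pos in spec["threonine_site"].items():
        planted[pos] = letter
    for name, pos in spec["sua5_specific"].items():
        planted[pos] = name[0]
    for motif_spec in (spec["kpspt_motif"], spec["gve_motif"], *spec["loop_motifs"].values()):
        for i, allowed in enumerate(motif_spec["residues"]):
            planted[motif_spec["start"] + i] = allowed[0]
    for name, pos in spec["sua5_domain_args"].items():
        planted[pos] = name[0]
    planted[spec["signature"]["position"]] = spec["signature"]["expected"][0]
    for pos, letter in planted.items():
        seq[pos - 1] = letter
    # Background must not fake annotated residues elsewhere: not needed,
    # all detection is position-mapped, never scanned.
    return "".join(seq)


def _build_tsac_template(sua5_seq: str, tsac_spec: dict) -> str:
    lo, hi = _TSAC_DELETION
    seq = list(sua5_seq)
    for pos, letter in _TSAC_REPLACEMENTS.items():
        seq[pos - 1] = letter
    del seq[lo - 1 : hi]
    out = "".join(seq)[: tsac_spec["length"]]
    assert len(out) == tsac_spec["length"]
    return out


def _parse_reference(ref_id: str, spec: dict, sequence: str) -> ReferenceAnnotation:
    motifs = []
    if "kpspt_motif" in spec:
        motifs.append(Motif("KPSPT", spec["kpspt_motif"]["start"], tuple(spec["kpspt_motif"]["residues"])))
        motifs.append(Motif("GVE", spec["gve_motif"]["start"], tuple(spec["gve_motif"]["residues"])))
        for name, m in spec["loop_motifs"].items():
            motifs.append(Motif(name, m["start"], tuple(m["residues"])))
    return ReferenceAnnotation(
        reference_id=ref_id,
        sequence=sequence,
        tetrad=tuple(spec["tetrad"].items()),
        threonine_site=tuple(spec["threonine_site"].items()),
        signature_position=spec["signature"]["position"],
        signature_expected=spec["signature"]["expected"],
        sua5_specific=tuple((n[0], p) for n, p in spec.get("sua5_specific", {}).items()),
        motifs=tuple(motifs),
        sua5_domain_args=tuple((n[0], p) for n, p in spec.get("sua5_domain_args", {}).items()),
        catalytic_span=tuple(spec["catalytic_span"]),
        loop_span=tuple(spec["loop_span"]) if "loop_span" in spec else None,
        sua5_domain_span=tuple(spec["sua5_domain_span"]) if "sua5_domain_span" in spec else None,
    )


@lru_cache(maxsize=1)
def reference_pair() -> tuple[ReferenceAnnotation, ReferenceAnnotation]:
    """The (Sua5, TsaC) reference annotations with synthetic template chains."""
    data = _load_json()
    sua5_spec = data["references"]["Pa-Sua5"]
    tsac_spec = data["references"]["Ec-TsaC"]
    sua5_seq = _build_sua5_template(sua5_spec)
    tsac_seq = _build_tsac_template(sua5_seq, tsac_spec)
    return (
        _parse_reference("Pa-Sua5", sua5_spec, sua5_seq),
        _parse_reference("Ec-TsaC", tsac_spec, tsac_seq),
    )


def annotation_version() -> str:
    return _load_json()["version"]
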