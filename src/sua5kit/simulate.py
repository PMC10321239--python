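"""Ground-truthed synthetic data for every pipeline stage.

The generator emulates the study conditions end to end: motif-bearing
Sua5/TsaC sequences diverged along a known tree, cross-clade transfers
injected as near-copies of a donor, progressive loop/SUA5-domain erosion
series, and toy coordinate files with contacts at exactly known distances.

Annotated motif/signature positions are immune to mutation by default (a
conserved-site model): classifier accuracy is then testable independently
of the divergence level. A ``preserve_annotation=False`` stress mode lets
motifs decay. All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import numpy as np
from skbio.tree import TreeNode

from .annotation import reference_pair
from .records import (
    InputError,
    ProteinRecord,
    write_fasta,
    write_taxonomy,
)

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    n_taxa: int = 16
    tree_shape: str = "balanced"  # balanced | random
    subst_rate: float = 0.05  # per-site substitution probability per branch
    indel_rate: float = 0.1  # per-branch probability of one indel event
    n_hgt_events: int = 0
    erosion_fracs: tuple[float, ...] = ()
    seed: int = 0
    preserve_annotation: bool = True

    def __post_init__(self) -> None:
        for r in (self.subst_rate, self.indel_rate):
            if not 0.0 <= r <= 1.0:
                raise InputError(f"rate {r} outside [0, 1]")
        if self.n_hgt_events >= self.n_taxa:
            raise InputError("n_hgt_events must be < n_taxa")
        if self.tree_shape not in ("balanced", "random"):
            raise InputError(f"unknown tree shape {self.tree_shape!r}")
        if not self.preserve_annotation and self.subst_rate > 0.3:
            raise InputError(
                "subst_rate > 0.3 without annotation preservation would destroy motifs"
            )


def make_reference_templates() -> tuple[ProteinRecord, ProteinRecord]:
    """The synthetic (Sua5, TsaC) template records the generator evolves."""
    sua5, tsac = reference_pair()
    return (
        ProteinRecord("Sua5-template", sua5.sequence, truth_variant="Sua5"),
        ProteinRecord("TsaC-template", tsac.sequence, truth_variant="TsaC"),
    )


# ---------------------------------------------------------------------------
# Sequence evolution along a known tree
# ---------------------------------------------------------------------------

#: Internal sequence representation: list of (column id, residue). Template
#: positions get integer-valued column ids 1..L; insertions get Fraction
#: ids strictly between their neighbors, so the true multiple alignment is
#: recoverable by sorting column ids.
_Seq = list[tuple[Fraction, str]]


@dataclass
class EvolvedDataset:
    records: list[ProteinRecord]
    tree: TreeNode
    column_maps: dict[str, dict[int, int]]  # leaf -> {template pos -> 1-based leaf pos}
    spec: SyntheticDatasetSpec
    template_id: str
    hgt_truth: list[tuple[str, str]] = field(default_factory=list)  # (recipient, donor)

    def taxa_by_id(self) -> dict[str, tuple[str, ...]]:
        return {r.id: r.taxon_path for r in self.records}


def _topology(spec: SyntheticDatasetSpec, rng: np.random.Generator):
    """Nested-tuple topology over leaf indices 0..n-1."""

    def balanced(idx: list[int]):
        if len(idx) == 1:
            return idx[0]
        h = len(idx) // 2
        return (balanced(idx[:h]), balanced(idx[h:]))

    def random_split(idx: list[int]):
        if len(idx) == 1:
            return idx[0]
        k = int(rng.integers(1, len(idx)))
        return (random_split(idx[:k]), random_split(idx[k:]))

    idx = list(range(spec.n_taxa))
    return balanced(idx) if spec.tree_shape == "balanced" else random_split(idx)


def _taxon_paths(topo, n_taxa: int) -> dict[int, tuple[str, ...]]:
    """Taxonomy labels derived from tree position: the first three splits
    define domain / phylum / class; species is the leaf itself."""
    paths: dict[int, tuple[str, ...]] = {}

    def walk(node, address: tuple[int, ...]):
        if isinstance(node, int):
            dom = "dom" + "".join(map(str, address[:1])) if address else "dom0"
            phy = "phy" + "".join(map(str, address[:2]))
            cls = "cls" + "".join(map(str, address[:3]))
            paths[node] = (dom, phy, cls, f"sp{node}")
            return
        walk(node[0], address + (0,))
        walk(node[1], address + (1,))

    walk(topo, ())
    return paths


def _mutate_branch(
    seq: _Seq,
    conserved: set[int],
    spec: SyntheticDatasetSpec,
    rng: np.random.Generator,
) -> _Seq:
    out = list(seq)
    mutable = [
        i
        for i, (col, _) in enumerate(out)
        if not (spec.preserve_annotation and col.denominator == 1 and int(col) in conserved)
    ]
    # substitutions
    if spec.subst_rate > 0 and mutable:
        hits = np.asarray(mutable)[rng.random(len(mutable)) < spec.subst_rate]
        for i in hits:
            col, aa = out[i]
            choices = _AA20.replace(aa, "")
            out[i] = (col, choices[int(rng.integers(len(choices)))])
    # at most one indel event per branch
    if spec.indel_rate > 0 and rng.random() < spec.indel_rate and len(out) > 20:
        length = min(int(rng.geometric(0.35)), 8)
        if rng.random() < 0.5:  # deletion of a run of mutable positions
            for _ in range(8):  # a few placement attempts
                start = int(rng.integers(0, len(out) - length))
                run = list(range(start, start + length))
                if all(i in mutable for i in run):
                    out = [x for k, x in enumerate(out) if k not in set(run)]
                    break
        else:  # insertion between two existing columns
            pos = int(rng.integers(1, len(out)))
            lo, hi = out[pos - 1][0], out[pos][0]
            new = []
            for k in range(length):
                frac = Fraction(k + 1, length + 1)
                cid = lo + (hi - lo) * frac
                new.append((cid, _AA20[int(rng.integers(20))]))
            out = out[:pos] + new + out[pos:]
    return out


def evolve_sequences(
    template: ProteinRecord, spec: SyntheticDatasetSpec
) -> EvolvedDataset:
    """Evolve the template along a known tree; truth fully recorded."""
    rng = np.random.default_rng(spec.seed)
    sua5_ref, tsac_ref = reference_pair()
    ref = sua5_ref if template.truth_variant != "TsaC" else tsac_ref
    conserved = ref.annotated_positions()

    topo = _topology(spec, rng)
    paths = _taxon_paths(topo, spec.n_taxa)
    root_seq: _Seq = [
        (Fraction(i + 1), aa) for i, aa in enumerate(template.sequence)
    ]

    records: list[ProteinRecord] = []
    column_maps: dict[str, dict[int, int]] = {}

    def walk(node, seq: _Seq) -> TreeNode:
        if isinstance(node, int):
            name = f"t{node:03d}"
            letters = "".join(aa for _, aa in seq)
            records.append(
                ProteinRecord(
                    id=name,
                    sequence=letters,
                    taxon_path=paths[node],
                    truth_variant=template.truth_variant,
                )
            )
            column_maps[name] = {
                int(col): i + 1
                for i, (col, _) in enumerate(seq)
                if col.denominator == 1
            }
            return TreeNode(name=name, length=1.0)
        children = [
            walk(child, _mutate_branch(seq, conserved, spec, rng))
            for child in node
        ]
        parent = TreeNode(length=1.0)
        parent.extend(children)
        return parent

    tree = walk(topo, root_seq)
    tree.length = None
    # stable leaf order regardless of recursion details
    records.sort(key=lambda r: r.id)
    return EvolvedDataset(records, tree, column_maps, spec, template.id)


# ---------------------------------------------------------------------------
# HGT injection
# ---------------------------------------------------------------------------


def inject_hgt(
    dataset: EvolvedDataset,
    n_events: int,
    divergence_rank: int = 1,
    seed: int = 0,
    noise: float = 0.0,
) -> EvolvedDataset:
    """Replace ``n_events`` leaf sequences by near-copies of cross-group donors.

    The recipient keeps its taxonomy label; ``noise`` (<= 0.02 mimics the
    study's near-verbatim cases) is the per-site substitution probability
    applied to the copied sequence outside annotated positions. Truth
    records (recipient, donor) pairs.
    """
    if noise > 0.02:
        raise InputError("inject_hgt: noise must be <= 2%")
    rng = np.random.default_rng(seed)
    by_group: dict[str, list[ProteinRecord]] = {}
    for r in dataset.records:
        if divergence_rank >= len(r.taxon_path):
            raise InputError(f"record {r.id}: no label at rank {divergence_rank}")
        by_group.setdefault(r.taxon_path[divergence_rank], []).append(r)
    if len(by_group) < 2:
        raise InputError("inject_hgt: need >= 2 donor groups at the divergence rank")
    if n_events == 0:
        return dataset

    sua5_ref = reference_pair()[0]
    conserved = sua5_ref.annotated_positions()
    groups = sorted(by_group)
    recipients = [
        str(x)
        for x in rng.choice(
            [r.id for r in dataset.records], size=n_events, replace=False
        )
    ]
    by_id = {r.id: r for r in dataset.records}
    new_records = {r.id: r for r in dataset.records}
    truth: list[tuple[str, str]] = []
    used_donors: set[str] = set()
    for rid in recipients:
        rec = by_id[rid]
        own = rec.taxon_path[divergence_rank]
        # donors are distinct across events and never themselves recipients,
        # so each transfer has an unambiguous (recipient, donor) signal
        donor_pool = [
            r
            for g in groups
            if g != own
            for r in by_group[g]
            if r.id not in recipients and r.id not in used_donors
        ]
        if not donor_pool:
            raise InputError("inject_hgt: donor pool exhausted")
        donor = donor_pool[int(rng.integers(len(donor_pool)))]
        used_donors.add(donor.id)
        seq = list(donor.sequence)
        if noise > 0:
            cmap = dataset.column_maps[donor.id]
            protected = {cmap[p] - 1 for p in conserved if p in cmap}
            for i in range(len(seq)):
                if i not in protected and rng.random() < noise:
                    choices = _AA20.replace(seq[i], "")
                    seq[i] = choices[int(rng.integers(len(choices)))]
        new_records[rid] = ProteinRecord(
            id=rid,
            sequence="".join(seq),
            taxon_path=rec.taxon_path,  # label unchanged: that is the signal
            truth_variant=rec.truth_variant,
        )
        truth.append((str(rid), donor.id))
    return replace(
        dataset,
        records=[new_records[r.id] for r in dataset.records],
        hgt_truth=sorted(truth),
    )


# ---------------------------------------------------------------------------
# SUA5-domain erosion
# ---------------------------------------------------------------------------


@dataclass
class ErosionTruth:
    record: ProteinRecord
    loop_frac_planted: float  # percent actually deleted from the loop span
    sua5_frac_planted: float
    deleted_positions: tuple[int, ...]
    signature_mutated: bool


def _contiguous_deletions(
    span: tuple[int, int],
    n_delete: int,
    protected: set[int],
    rng: np.random.Generator,
) -> set[int]:
    """Pick ``n_delete`` span positions as contiguous-biased segments."""
    available = [p for p in range(span[0], span[1] + 1) if p not in protected]
    if n_delete > len(available):
        n_delete = len(available)
    deleted: set[int] = set()
    while len(deleted) < n_delete:
        seg = min(int(rng.geometric(0.25)), n_delete - len(deleted))
        start = int(rng.integers(0, len(available)))
        for k in range(seg):
            if start + k < len(available):
                deleted.add(available[start + k])
    return deleted


def erode_sua5(
    template: ProteinRecord,
    loop_frac: float,
    domain_frac: float,
    mutate_signature: bool = False,
    seed: int = 0,
    record_id: str | None = None,
) -> ErosionTruth:
    """Delete a fraction of loop / SUA5-domain positions from a Sua5 template.

    Deletions are contiguous-biased (geometric segment lengths), mimicking
    the indel pattern of eroding Archaeoglobi Sua5. The SUA5-domain
    arginine anchors are never deleted (their retention is the natural
    pattern). ``mutate_signature`` additionally applies the Archaeoglobi
    substitution set: signature Pro -> Thr, Asn62 -> Lys, His67 -> Val.

    Deletion patterns are rejection-sampled until the implied pairwise
    alignment against the template is unambiguous (a gap adjacent to an
    identical flanking residue can slide across a span boundary in a
    co-optimal alignment, which would make the planted fractions
    ill-defined); draws are deterministic in the seed.
    """
    from .align import global_align  # local import: no module cycle

    for f in (loop_frac, domain_frac):
        if not 0.0 <= f <= 1.0:
            raise InputError(f"fraction {f} outside [0, 1]")
    ref = reference_pair()[0]
    loop_span, dom_span = ref.loop_span, ref.sua5_domain_span
    protected = {p for _, p in ref.sua5_domain_args}
    loop_len = loop_span[1] - loop_span[0] + 1
    dom_len = dom_span[1] - dom_span[0] + 1

    seq = list(template.sequence)
    if mutate_signature:
        subs = {ref.signature_position: "T"}
        for letter, pos in ref.sua5_specific:
            if letter == "N":
                subs[pos] = "K"
            elif letter == "H" and pos < 100:
                subs[pos] = "V"
        for pos, aa in subs.items():
            seq[pos - 1] = aa
    full = "".join(seq)

    def span_gap_count(aln, span):
        ref_pos, missing = 0, 0
        for x, y in zip(aln.aligned_a, aln.aligned_b):
            if x == "-":
                continue
            ref_pos += 1
            if span[0] <= ref_pos <= span[1] and y == "-":
                missing += 1
        return missing

    best = None
    for attempt in range(30):
        rng = np.random.default_rng([seed, attempt])
        del_loop = _contiguous_deletions(
            loop_span, round(loop_frac * loop_len), protected, rng
        )
        del_dom = _contiguous_deletions(
            dom_span, round(domain_frac * dom_len), protected, rng
        )
        deleted = del_loop | del_dom
        letters = "".join(
            aa for i, aa in enumerate(full, start=1) if i not in deleted
        )
        best = (del_loop, del_dom, deleted, letters)
        if not deleted:
            break
        aln = global_align(full, letters)
        if span_gap_count(aln, loop_span) == len(del_loop) and span_gap_count(
            aln, dom_span
        ) == len(del_dom):
            break
    del_loop, del_dom, deleted, letters = best

    rec = ProteinRecord(
        id=record_id or f"eroded-{loop_frac:.2f}-{domain_frac:.2f}-s{seed}",
        sequence=letters,
        truth_variant="atypical_sua5" if (mutate_signature or deleted) else "Sua5",
    )
    return ErosionTruth(
        record=rec,
        loop_frac_planted=round(100.0 * len(del_loop) / loop_len, 1),
        sua5_frac_planted=round(100.0 * len(del_dom) / dom_len, 1),
        deleted_positions=tuple(sorted(deleted)),
        signature_mutated=mutate_signature,
    )


# ---------------------------------------------------------------------------
# Toy coordinate files
# ---------------------------------------------------------------------------

_CONTACT_ATOMS = {
    "hbond": (("ASN", "ND2", "N"), ("SER", "OG", "O")),
    "salt_bridge": (("ARG", "NH1", "N"), ("ASP", "OD1", "O")),
}
_PAIR_SPACING = 50.0  # Angstrom between planted pairs: far beyond any cutoff


def make_toy_structure(contacts: Sequence[tuple[str, float]]) -> str:
    """Minimal valid PDB text with each requested contact at its exact distance.

    Each contact (kind, distance) is realised by an isolated residue pair -
    partner atoms on chains A and B - placed on a widely spaced grid so no
    unrequested contact falls under default cutoffs.
    """
    import io

    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio

    rows = []
    if not contacts:
        # a valid but contact-free structure: two lone glycine CA atoms
        rows = [
            ("A", "GLY", 1, "CA", "C", (0.0, 0.0, 0.0)),
            ("B", "GLY", 2, "CA", "C", (_PAIR_SPACING, 0.0, 0.0)),
        ]
    for idx, (kind, dist) in enumerate(contacts):
        if kind not in _CONTACT_ATOMS:
            raise InputError(f"unknown contact kind {kind!r}")
        if dist <= 0:
            raise InputError(f"contact distance must be positive, got {dist}")
        if dist >= _PAIR_SPACING / 2:
            raise InputError(
                f"contact distance {dist} not realisable on the placement grid"
            )
        (resn_a, atom_a, el_a), (resn_b, atom_b, el_b) = _CONTACT_ATOMS[kind]
        x = _PAIR_SPACING * idx
        rows.append(("A", resn_a, idx + 1, atom_a, el_a, (x, 0.0, 0.0)))
        rows.append(("B", resn_b, idx + 1, atom_b, el_b, (x + dist, 0.0, 0.0)))

    arr = struc.AtomArray(len(rows))
    arr.coord = np.array([r[5] for r in rows], dtype=np.float32) if rows else np.zeros((0, 3), dtype=np.float32)
    arr.chain_id = np.array([r[0] for r in rows], dtype="U4")
    arr.res_name = np.array([r[1] for r in rows], dtype="U5")
    arr.res_id = np.array([r[2] for r in rows], dtype=int)
    arr.atom_name = np.array([r[3] for r in rows], dtype="U6")
    arr.element = np.array([r[4] for r in rows], dtype="U2")
    arr.hetero = np.zeros(len(rows), dtype=bool)
    f = pdbio.PDBFile()
    f.set_structure(arr)
    buf = io.StringIO()
    f.write(buf)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Bundle writer
# ---------------------------------------------------------------------------


def write_bundle(dataset: EvolvedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA + taxonomy TSV + newick truth tree + JSON truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "sequences.fasta",
        "taxonomy": outdir / "taxonomy.tsv",
        "tree": outdir / "true_tree.nwk",
        "truth": outdir / "truth.json",
    }
    write_fasta(dataset.records, paths["fasta"])
    write_taxonomy(dataset.records, paths["taxonomy"])
    dataset.tree.write(str(paths["tree"]))
    truth = {
        "template": dataset.template_id,
        "seed": dataset.spec.seed,
        "variants": {r.id: r.truth_variant for r in dataset.records},
        "hgt_events": dataset.hgt_truth,
    }
    paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True) + "\n")
    return paths
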