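"""Pairwise alignment primitives and reference-anchored residue mapping.

Everything downstream (motif read-out, erosion quantification, distance
matrices, structure numbering maps) is built on three primitives: global
(Needleman-Wunsch) alignment, local (Smith-Waterman) alignment, and a
reference-anchored star alignment. Scoring is BLOSUM62 with affine gap
penalties in the BLAST convention (a gap of length L costs open + L*extend);
``X`` is a wildcard scoring 0 against everything.

Residue numbering is 1-based in every user-facing position (the convention
used by crystallographers and by UniProt); internal coordinates are 0-based
half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .records import InputError

GAP = None  # sentinel for "maps to a gap"


@dataclass(frozen=True)
class ScoringSpec:
    """Substitution matrix + affine gap penalties (positive costs).

    BLAST-like defaults: BLOSUM62 with open/extend 11/1 for local and
    10/0.5 for global alignment.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5

    @classmethod
    def local_default(cls) -> "ScoringSpec":
        return cls(gap_open=11.0, gap_extend=1.0)


@dataclass
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    mode: str  # "global" | "local"
    coordinates: tuple[int, int, int, int]  # (start_a, end_a, start_b, end_b), 0-based half-open

    def __post_init__(self) -> None:
        assert len(self.aligned_a) == len(self.aligned_b)

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a)


def _load_matrix(name: str):
    m = substitution_matrices.load(name)
    m = m.copy()
    if "X" in m.alphabet:
        i = m.alphabet.index("X")
        m[i, :] = 0.0
        m[:, i] = 0.0
    return m


_MATRIX_CACHE: dict[str, object] = {}


def _aligner(params: ScoringSpec, mode: str) -> Align.PairwiseAligner:
    if params.matrix not in _MATRIX_CACHE:
        _MATRIX_CACHE[params.matrix] = _load_matrix(params.matrix)
    a = Align.PairwiseAligner()
    a.substitution_matrix = _MATRIX_CACHE[params.matrix]
    # Biopython charges open_gap_score for the first gapped column and
    # extend_gap_score for each further one; shift so a length-L gap costs
    # open + L*extend as in BLAST.
    a.open_gap_score = -(params.gap_open + params.gap_extend)
    a.extend_gap_score = -params.gap_extend
    a.mode = mode
    return a


def _first_alignment(aligner: Align.PairwiseAligner, a: str, b: str):
    # The aligner enumerates co-optimal tracebacks in a fixed order; taking
    # the first makes outputs bit-stable across runs.
    return aligner.align(a, b)[0]


def _to_result(aln, mode: str) -> AlignmentResult:
    sa, sb = str(aln[0]), str(aln[1])
    blocks = aln.aligned  # (2, n_blocks, 2)
    if blocks.shape[1] == 0:  # empty local alignment
        return AlignmentResult("", "", float(aln.score), mode, (0, 0, 0, 0))
    start_a, end_a = int(blocks[0][0][0]), int(blocks[0][-1][1])
    start_b, end_b = int(blocks[1][0][0]), int(blocks[1][-1][1])
    if mode == "local":
        # Biopython prints local alignments with flanking context in some
        # versions; rebuild the covered slice explicitly.
        sa, sb = _rebuild(aln, start_a, start_b)
    return AlignmentResult(sa, sb, float(aln.score), mode, (start_a, end_a, start_b, end_b))


def _rebuild(aln, start_a: int, start_b: int) -> tuple[str, str]:
    a, b = aln.sequences
    out_a, out_b = [], []
    pa, pb = start_a, start_b
    for (a0, a1), (b0, b1) in zip(aln.aligned[0], aln.aligned[1]):
        out_a.append("-" * (b0 - pb))
        out_b.append(b[pb:b0])
        out_a.append(a[pa:a0])
        out_b.append("-" * (a0 - pa))
        out_a.append(a[a0:a1])
        out_b.append(b[b0:b1])
        pa, pb = a1, b1
    return "".join(out_a), "".join(out_b)


def global_align(a: str, b: str, params: ScoringSpec | None = None) -> AlignmentResult:
    """Optimal global alignment (Needleman-Wunsch with affine gaps)."""
    if not a or not b:
        raise InputError("global_align: empty input sequence")
    params = params or ScoringSpec()
    return _to_result(_first_alignment(_aligner(params, "global"), a, b), "global")


def local_align(a: str, b: str, params: ScoringSpec | None = None) -> AlignmentResult:
    """Optimal local alignment (Smith-Waterman); may be empty."""
    if not a or not b:
        raise InputError("local_align: empty input sequence")
    params = params or ScoringSpec.local_default()
    try:
        aln = _first_alignment(_aligner(params, "local"), a, b)
    except IndexError:
        # no positive-scoring pair: the optimal local alignment is empty
        return AlignmentResult("", "", 0.0, "local", (0, 0, 0, 0))
    return _to_result(aln, "local")


def percent_identity(aln: AlignmentResult) -> float:
    """Identities over all alignment columns (gap columns included), x100.

    This is the BLASTp convention; one decimal of precision.
    """
    if aln.n_columns == 0:
        raise InputError("percent_identity: empty alignment")
    ident = sum(
        1 for x, y in zip(aln.aligned_a, aln.aligned_b) if x == y and x != "-"
    )
    return round(100.0 * ident / aln.n_columns, 1)


def identity_fraction(aln: AlignmentResult) -> float:
    """Un-rounded identity fraction in [0, 1] over all columns."""
    if aln.n_columns == 0:
        raise InputError("identity_fraction: empty alignment")
    ident = sum(
        1 for x, y in zip(aln.aligned_a, aln.aligned_b) if x == y and x != "-"
    )
    return ident / aln.n_columns


@dataclass
class ResidueMap:
    """Monotone map between 1-based positions of two ungapped sequences."""

    pairs: list[tuple[int, int | None]]

    def __post_init__(self) -> None:
        self._fwd = {r: q for r, q in self.pairs}
        self._rev = {q: r for r, q in self.pairs if q is not None}

    def to_query(self, ref_pos: int) -> int | None:
        if ref_pos not in self._fwd:
            raise IndexError(f"reference position {ref_pos} outside aligned region")
        return self._fwd[ref_pos]

    def to_ref(self, query_pos: int) -> int | None:
        return self._rev.get(query_pos)


def residue_map(aln: AlignmentResult) -> ResidueMap:
    """Per-position map sequence a (reference) -> sequence b (query)."""
    pairs: list[tuple[int, int | None]] = []
    pa, pb = aln.coordinates[0], aln.coordinates[2]
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x != "-" and y != "-":
            pairs.append((pa + 1, pb + 1))
            pa += 1
            pb += 1
        elif x != "-":
            pairs.append((pa + 1, None))
            pa += 1
        else:
            pb += 1
    return ResidueMap(pairs)


def map_residue(aln: AlignmentResult, ref_pos: int) -> int | None:
    """1-based position in b aligned to 1-based ``ref_pos`` of a, or GAP."""
    return residue_map(aln).to_query(ref_pos)


@dataclass
class StarAlignment:
    """Reference-anchored multiple alignment.

    Every query is pairwise-aligned to the reference; ``matrix[q][c]`` holds
    the query residue opposite reference column ``c`` (0-based; '-' when the
    query has a gap there). Insertions relative to the reference are kept
    per query but not mutually aligned - sufficient for reading out
    reference columns, the only use downstream.
    """

    reference: str
    ids: list[str]
    matrix: list[str]  # one gapped string of len(reference) per query
    insertions: list[dict[int, str]]  # after-ref-column -> inserted residues

    def column(self, ref_pos: int) -> list[str]:
        """Residues of all queries at 1-based reference position."""
        return [row[ref_pos - 1] for row in self.matrix]

    def as_matrix(self) -> np.ndarray:
        return np.array([list(row) for row in self.matrix])


def star_msa(
    queries: Sequence[tuple[str, str]] | Sequence[str],
    reference: str,
    params: ScoringSpec | None = None,
) -> StarAlignment:
    """Align each query globally to the reference and index by its columns.

    ``queries`` is a list of (id, sequence) pairs or bare sequences.
    """
    if not queries:
        raise InputError("star_msa: empty query set")
    norm = [
        q if isinstance(q, tuple) else (f"q{i}", q) for i, q in enumerate(queries)
    ]
    ids, rows, inserts = [], [], []
    for qid, qseq in norm:
        aln = global_align(reference, qseq, params)
        row = ["-"] * len(reference)
        ins: dict[int, str] = {}
        pr = 0  # consumed reference residues
        for x, y in zip(aln.aligned_a, aln.aligned_b):
            if x != "-":
                if y != "-":
                    row[pr] = y
                pr += 1
            else:
                ins[pr] = ins.get(pr, "") + y
        ids.append(qid)
        rows.append("".join(row))
        inserts.append(ins)
    return StarAlignment(reference, ids, rows, inserts)


def write_aligned_fasta(aln: AlignmentResult, ids: tuple[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in zip(ids, (aln.aligned_a, aln.aligned_b)):
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
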