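"""Variant classification of TsaC/Sua5 family members.

Classification is reference-anchored, never scan-based: a query is globally
aligned to both reference templates, the better-scoring alignment fixes the
numbering, and every annotated residue is read off the mapped column. A
sequence is a family member if it falls in the 100-400 aa length window and
carries the complete K-R-S-N catalytic tetrad; members are then split into

* ``Sua5``           - SUA5-domain evidence present, signature Pro;
* ``atypical_sua5``  - SUA5-domain evidence present but signature Thr/Ser
                       or interdomain-loop motifs lost (the Archaeoglobi
                       erosion syndrome);
* ``TsaC``           - no SUA5-domain evidence. A Pro-signature TsaC
                       (Brachyspira/Lactococcus/Erysipelothrix/Aquificae
                       type) is still TsaC, flagged ``proline_tsac``.

"SUA5-domain evidence" means at least 2 of the 4 markers {KPSPT motif, GVE
motif, Arg301, Arg328} are present at their mapped positions.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .align import AlignmentResult, ScoringSpec, global_align, residue_map
from .annotation import Motif, ReferenceAnnotation, reference_pair
from .records import InputError, ProteinRecord

logger = logging.getLogger(__name__)

LENGTH_WINDOW = (100, 400)
#: Markers whose joint presence constitutes SUA5-domain evidence.
SUA5_MARKERS = ("KPSPT", "GVE", "R301", "R328")
SUA5_EVIDENCE_MIN = 2
#: Minimum alignment score for a reference anchoring to count as mappable.
SCORE_FLOOR = 50.0


@dataclass
class Observation:
    """A single annotated residue read off a mapped query column."""

    item: str  # e.g. "tetrad:K56", "motif:KPSPT:150", "signature"
    ref_position: int
    query_position: int | None  # None when mapped to a gap
    observed: str  # residue letter or "-"
    expected: str  # allowed letters

    @property
    def matches(self) -> bool:
        return self.observed in self.expected


@dataclass
class VariantCall:
    record_id: str
    call: str  # Sua5 | TsaC | atypical_sua5 | non_member
    tetrad_complete: bool
    signature: str  # P | T | S | other | GAP
    signature_position: int | None
    sua5_motif_hits: dict[str, bool]
    length_ok: bool
    length: int
    anchor_ref: str | None
    evidence: list[Observation] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    @property
    def sua5_evidence_count(self) -> int:
        return sum(self.sua5_motif_hits.get(m, False) for m in SUA5_MARKERS)


def _observe(
    aln: AlignmentResult, query_seq: str, ref_pos: int, expected: str, item: str
) -> Observation:
    qpos = residue_map(aln).to_query(ref_pos)
    observed = query_seq[qpos - 1] if qpos is not None else "-"
    return Observation(item, ref_pos, qpos, observed, expected)


def anchor_alignments(
    query: ProteinRecord, params: ScoringSpec | None = None
) -> dict[str, AlignmentResult]:
    """Global alignments of the query against both reference templates.

    Keys are reference ids; alignments are reference-first (reference is
    sequence a), so residue maps run reference -> query.
    """
    sua5_ref, tsac_ref = reference_pair()
    return {
        ref.reference_id: global_align(ref.sequence, query.sequence, params)
        for ref in (sua5_ref, tsac_ref)
    }


def _pick_anchor(alns: dict[str, AlignmentResult]) -> str:
    # Ties break toward the longer Sua5 reference.
    best = max(alns, key=lambda k: (alns[k].score, k == "Pa-Sua5"))
    return best


def detect_tetrad(
    query: ProteinRecord,
    ref: ReferenceAnnotation,
    aln: AlignmentResult | None = None,
    lenient: bool = False,
) -> tuple[list[Observation], bool]:
    """Read the K-R-S-N tetrad off the mapped query columns.

    Strict mode (default) requires exactly K, R, S, N; the lenient mode
    additionally accepts the conservative swaps K<->R and S<->T.
    """
    aln = aln or global_align(ref.sequence, query.sequence)
    obs = []
    for letter, pos in ref.tetrad:
        allowed = letter
        if lenient:
            allowed = {"K": "KR", "R": "RK", "S": "ST", "N": "N"}[letter]
        obs.append(_observe(aln, query.sequence, pos, allowed, f"tetrad:{letter}{pos}"))
    return obs, all(o.matches for o in obs)


def signature_residue(
    query: ProteinRecord, params: ScoringSpec | None = None
) -> tuple[str, int | None]:
    """Signature-residue state {P, T, S, other, GAP} and its query position.

    The query column is the one mapped from Sua5 position 143 / TsaC
    position 138 by the better-scoring of the two reference alignments.
    """
    alns = anchor_alignments(query, params)
    if max(a.score for a in alns.values()) < SCORE_FLOOR:
        raise InputError(f"record {query.id!r}: unmappable to either reference")
    anchor = _pick_anchor(alns)
    ref = {r.reference_id: r for r in reference_pair()}[anchor]
    obs = _observe(
        alns[anchor], query.sequence, ref.signature_position, "PTS", "signature"
    )
    if obs.observed == "-":
        return "GAP", None
    state = obs.observed if obs.observed in "PTS" else "other"
    return state, obs.query_position


def _motif_observations(
    query: ProteinRecord, motif: Motif, aln: AlignmentResult
) -> list[Observation]:
    return [
        _observe(aln, query.sequence, pos, allowed, f"motif:{motif.name}:{pos}")
        for pos, allowed in zip(motif.positions, motif.residues)
    ]


def detect_sua5_motifs(
    query: ProteinRecord,
    ref: ReferenceAnnotation | None = None,
    aln: AlignmentResult | None = None,
) -> tuple[dict[str, bool], list[Observation]]:
    """Hit table for every Sua5-specific motif and residue.

    Keys: KPSPT, GVE, PGM, HY (motifs; hit = every constituent residue
    matches its allowed set), the six Sua5-specific residues (P59 ... D161)
    and the SUA5-domain arginines R301/R328.
    """
    ref = ref or reference_pair()[0]
    aln = aln or global_align(ref.sequence, query.sequence)
    hits: dict[str, bool] = {}
    evidence: list[Observation] = []
    for m in ref.motifs:
        obs = _motif_observations(query, m, aln)
        evidence.extend(obs)
        hits[m.name] = all(o.matches for o in obs)
    for letter, pos in ref.sua5_specific + ref.sua5_domain_args:
        o = _observe(aln, query.sequence, pos, letter, f"residue:{letter}{pos}")
        evidence.append(o)
        hits[f"{letter}{pos}"] = o.matches
    return hits, evidence


def classify_variant(
    query: ProteinRecord,
    params: ScoringSpec | None = None,
    lenient_tetrad: bool = False,
) -> VariantCall:
    """Full per-sequence classification with evidence."""
    sua5_ref, tsac_ref = reference_pair()
    length = len(query)
    length_ok = LENGTH_WINDOW[0] <= length <= LENGTH_WINDOW[1]
    base = dict(
        record_id=query.id,
        signature="GAP",
        signature_position=None,
        sua5_motif_hits={},
        length_ok=length_ok,
        length=length,
        anchor_ref=None,
    )
    if not length_ok:
        return VariantCall(
            call="non_member", tetrad_complete=False,
            flags=["length_out_of_window"], **base,
        )

    alns = anchor_alignments(query, params)
    if max(a.score for a in alns.values()) < SCORE_FLOOR:
        return VariantCall(
            call="non_member", tetrad_complete=False,
            flags=["unmappable"], **base,
        )
    anchor = _pick_anchor(alns)
    anchor_ref = sua5_ref if anchor == "Pa-Sua5" else tsac_ref
    base["anchor_ref"] = anchor

    tetrad_obs, complete = detect_tetrad(
        query, anchor_ref, alns[anchor], lenient=lenient_tetrad
    )
    sig_obs = _observe(
        alns[anchor], query.sequence, anchor_ref.signature_position, "PTS", "signature"
    )
    if sig_obs.observed == "-":
        signature = "GAP"
    else:
        signature = sig_obs.observed if sig_obs.observed in "PTS" else "other"
    base["signature"] = signature
    base["signature_position"] = sig_obs.query_position

    hits, motif_obs = detect_sua5_motifs(query, sua5_ref, alns["Pa-Sua5"])
    base["sua5_motif_hits"] = hits
    evidence = tetrad_obs + [sig_obs] + motif_obs

    if not complete:
        return VariantCall(
            call="non_member", tetrad_complete=False,
            evidence=evidence, flags=["tetrad_incomplete"], **base,
        )

    marker_count = sum(hits.get(m, False) for m in SUA5_MARKERS)
    loop_intact = hits.get("PGM", False) and hits.get("HY", False)
    flags: list[str] = []
    if marker_count >= SUA5_EVIDENCE_MIN:
        if signature in ("T", "S") or not loop_intact:
            call = "atypical_sua5"
        else:
            call = "Sua5"
            if signature != "P":
                flags.append("signature_anomaly")
    else:
        call = "TsaC"
        if signature == "P":
            # Pro-carrying TsaC exception (Brachyspira/Lactococcus/
            # Erysipelothrix/Aquificae type in nature).
            flags.append("proline_tsac")
            logger.info("record %s: Pro-signature TsaC exception", query.id)
    return VariantCall(
        call=call, tetrad_complete=True, evidence=evidence, flags=flags, **base
    )


def classify_all(
    records: Sequence[ProteinRecord], **kwargs
) -> list[VariantCall]:
    return [classify_variant(r, **kwargs) for r in records]


def signature_census(calls: Sequence[VariantCall]) -> dict:
    """Per-variant signature-residue frequencies and length histograms.

    Returns ``{"frequencies": DataFrame, "length_histogram": {class:
    Counter}}``; frequency rows are variant classes, columns are signature
    states P/T/S/other in percent (one decimal, summing to ~100 per row).
    """
    if not calls:
        raise InputError("signature_census: no calls")
    classes = ("Sua5", "TsaC", "atypical_sua5")
    rows = {}
    lengths: dict[str, Counter] = {}
    for cls in classes:
        sub = [c for c in calls if c.call == cls]
        if not sub:
            continue
        counts = Counter(c.signature if c.signature in "PTS" else "other" for c in sub)
        n = len(sub)
        rows[cls] = {
            state: round(100.0 * counts.get(state, 0) / n, 1)
            for state in ("P", "T", "S", "other")
        }
        rows[cls]["n"] = n
        lengths[cls] = Counter(c.length for c in sub)
    freq = pd.DataFrame.from_dict(rows, orient="index")
    return {"frequencies": freq, "length_histogram": lengths}


def calls_to_frame(calls: Iterable[VariantCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "id": c.record_id,
                "call": c.call,
                "length": c.length,
                "length_ok": c.length_ok,
                "tetrad_complete": c.tetrad_complete,
                "signature": c.signature,
                "signature_position": c.signature_position,
                "anchor_ref": c.anchor_ref,
                "sua5_evidence": c.sua5_evidence_count,
                "flags": ";".join(c.flags),
                **{f"hit_{k}": v for k, v in sorted(c.sua5_motif_hits.items())},
            }
        )
    return pd.DataFrame(rows)
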