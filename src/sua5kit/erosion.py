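"""Quantification of interdomain-loop and SUA5-domain erosion.

Atypical Sua5 proteins (the Archaeoglobi pattern) progressively lose
residues from the interdomain loop and the SUA5 domain. Erosion is measured
on archetype coordinates: the query is globally aligned to an archetype
Sua5 and the missing fraction of a span is the percentage of archetype span
positions that sit opposite a gap - i.e. "the query lacks N% of the span's
residues".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .align import ScoringSpec, global_align
from .annotation import reference_pair
from .motifs import detect_sua5_motifs
from .records import InputError, ProteinRecord

#: Motifs whose loss is reported in an erosion profile.
EROSION_MOTIFS = ("PGM", "HY", "KPSPT", "GVE")


@dataclass
class ErosionProfile:
    query_id: str
    archetype_id: str
    loop_missing_frac: float  # percent of archetype loop positions opposite gaps
    sua5_missing_frac: float  # percent of archetype SUA5-domain positions opposite gaps
    lost_motifs: tuple[str, ...]
    substitutions: list[tuple[str, str]] = field(default_factory=list)
    total_length: int = 0

    @property
    def composite(self) -> float:
        return self.loop_missing_frac + self.sua5_missing_frac


def _span_missing_frac(aligned_ref: str, aligned_qry: str, span: tuple[int, int]) -> float:
    lo, hi = span
    ref_pos = 0
    missing = 0
    for x, y in zip(aligned_ref, aligned_qry):
        if x == "-":
            continue
        ref_pos += 1
        if lo <= ref_pos <= hi and y == "-":
            missing += 1
    return round(100.0 * missing / (hi - lo + 1), 1)


def erosion_profile(
    query: ProteinRecord,
    archetype: ProteinRecord,
    loop_span: tuple[int, int] | None = None,
    sua5_span: tuple[int, int] | None = None,
    params: ScoringSpec | None = None,
) -> ErosionProfile:
    """Erosion of the query relative to an archetype Sua5.

    Spans are 1-based inclusive archetype coordinates; defaults come from
    the reference annotation (the archetype is expected to share the
    reference layout, which holds for synthetic archetypes and for any
    archetype numbered by the reference).
    """
    sua5_ref = reference_pair()[0]
    loop_span = loop_span or sua5_ref.loop_span
    sua5_span = sua5_span or sua5_ref.sua5_domain_span
    for span in (loop_span, sua5_span):
        if span[1] > len(archetype) or span[0] < 1:
            raise InputError(f"span {span} outside archetype length {len(archetype)}")
    aln = global_align(archetype.sequence, query.sequence, params)

    hits, evidence = detect_sua5_motifs(query)
    lost = tuple(m for m in EROSION_MOTIFS if not hits.get(m, False))
    subs = [
        (o.item.split(":", 1)[1], o.observed)
        for o in evidence
        if o.item.startswith("residue:") and not o.matches
    ]
    return ErosionProfile(
        query_id=query.id,
        archetype_id=archetype.id,
        loop_missing_frac=_span_missing_frac(aln.aligned_a, aln.aligned_b, loop_span),
        sua5_missing_frac=_span_missing_frac(aln.aligned_a, aln.aligned_b, sua5_span),
        lost_motifs=lost,
        substitutions=subs,
        total_length=len(query),
    )


def erosion_stage(profiles: Sequence[ErosionProfile]) -> list[ErosionProfile]:
    """Total order from most to least eroded.

    Key: combined missing fraction (loop + domain), then number of lost
    motifs, ties broken by total length ascending (a shorter protein is the
    more advanced erosion case).
    """
    if len(profiles) < 2:
        raise InputError("erosion_stage: need >= 2 profiles")
    archetypes = {p.archetype_id for p in profiles}
    if len(archetypes) != 1:
        raise InputError(f"erosion_stage: mixed archetypes {sorted(archetypes)}")
    return sorted(
        profiles,
        key=lambda p: (-p.composite, -len(p.lost_motifs), p.total_length, p.query_id),
    )


def profiles_to_frame(profiles: Sequence[ErosionProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "query": p.query_id,
                "archetype": p.archetype_id,
                "loop_missing_pct": p.loop_missing_frac,
                "sua5_missing_pct": p.sua5_missing_frac,
                "lost_motifs": ";".join(p.lost_motifs),
                "n_substitutions": len(p.substitutions),
                "total_length": p.total_length,
            }
            for p in profiles
        ]
    )
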