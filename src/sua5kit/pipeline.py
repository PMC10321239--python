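"""Pipeline orchestration: classify -> census -> mixed taxa -> HGT screen,
with optional erosion and structure-contact stages.

Outputs are a pure function of (inputs, config, seed): every table is
written with sorted rows and fixed float formatting so re-runs are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotation import annotation_version
from .erosion import erosion_profile, erosion_stage, profiles_to_frame
from .motifs import calls_to_frame, classify_all, signature_census
from .phylo import (
    DEFAULT_DIVERGENCE_RANK,
    hgt_screen,
    mixed_taxa,
)
from .records import (
    InputError,
    ProteinRecord,
    attach_taxonomy,
    read_fasta,
    read_taxonomy,
)
from .structure import (
    HBOND_CUTOFF,
    SALT_BRIDGE_CUTOFF,
    contacts_to_rows,
    hydrogen_bonds,
    read_structure,
    salt_bridges,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    fasta: str = ""
    taxonomy: str | None = None
    structures: list[str] = field(default_factory=list)
    outdir: str = "sua5kit-out"
    # thresholds (every quantitative choice is surfaced, nothing hidden)
    length_window: tuple[int, int] = (100, 400)
    divergence_rank: int = DEFAULT_DIVERGENCE_RANK
    census_rank: int = DEFAULT_DIVERGENCE_RANK
    hbond_cutoff: float = HBOND_CUTOFF
    salt_bridge_cutoff: float = SALT_BRIDGE_CUTOFF
    bootstrap_reps: int = 100
    seed: int = 0
    run_hgt: bool = True
    run_erosion: bool = False
    erosion_archetype: str | None = None  # record id; default: most complete Sua5
    lenient_tetrad: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        lo, hi = self.length_window
        if not (0 < lo < hi):
            raise InputError(f"bad length window {self.length_window}")
        for c in (self.hbond_cutoff, self.salt_bridge_cutoff):
            if not 0 < c < 10:
                raise InputError(f"contact cutoff {c} outside (0, 10) Angstrom")
        if self.bootstrap_reps < 1:
            raise InputError("bootstrap_reps must be >= 1")


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")


def summarize_distribution(
    variant_by_id: dict[str, str],
    taxa_by_id: dict[str, tuple[str, ...]],
    rank: int,
) -> pd.DataFrame:
    """Per-taxon Sua5:TsaC usage table (the 'ring graph' statistic).

    One row per group at ``rank``: counts of Sua5 users (atypical
    included) and TsaC users, percent Sua5, and the group class
    (exclusive-Sua5 / exclusive-TsaC / mixed). Non-members are excluded.
    """
    counts: dict[str, dict[str, int]] = {}
    for rid, call in variant_by_id.items():
        if call == "non_member":
            continue
        path = taxa_by_id.get(rid, ())
        if rank >= len(path):
            continue
        g = counts.setdefault(path[rank], {"Sua5": 0, "TsaC": 0})
        g["Sua5" if call in ("Sua5", "atypical_sua5") else "TsaC"] += 1
    rows = []
    for label in sorted(counts):
        n_s, n_t = counts[label]["Sua5"], counts[label]["TsaC"]
        pct = round(100.0 * n_s / (n_s + n_t), 1)
        cls = (
            "exclusive-Sua5"
            if n_t == 0
            else "exclusive-TsaC" if n_s == 0 else "mixed"
        )
        rows.append(
            {"group": label, "n_Sua5": n_s, "n_TsaC": n_t, "pct_Sua5": pct, "class": cls}
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run the configured stages; each stage's outputs land in the outdir.

    A stage failure aborts with the failing stage named; outputs already
    written are retained for inspection.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def stage(name):
        logger.info("stage: %s", name)
        return name

    try:
        stage("load")
        records = read_fasta(config.fasta)
        if config.taxonomy:
            records = attach_taxonomy(records, read_taxonomy(config.taxonomy))
    except Exception as e:
        raise InputError(f"stage 'load' failed: {e}") from e

    try:
        stage("classify")
        calls = classify_all(records, lenient_tetrad=config.lenient_tetrad)
        frame = calls_to_frame(calls).sort_values("id").reset_index(drop=True)
        written["calls"] = outdir / "calls.tsv"
        _write_tsv(frame, written["calls"])
    except InputError:
        raise
    except Exception as e:
        raise RuntimeError(f"stage 'classify' failed: {e}") from e

    variant_by_id = {c.record_id: c.call for c in calls}
    taxa_by_id = {r.id: r.taxon_path for r in records}

    try:
        stage("census")
        census = signature_census(calls)
        freq = census["frequencies"].rename_axis("variant").reset_index()
        written["census"] = outdir / "census.tsv"
        _write_tsv(freq, written["census"])
        if any(taxa_by_id.values()):
            dist = summarize_distribution(variant_by_id, taxa_by_id, config.census_rank)
            written["distribution"] = outdir / "distribution.tsv"
            _write_tsv(dist, written["distribution"])
    except Exception as e:
        raise RuntimeError(f"stage 'census' failed: {e}") from e

    if config.run_hgt and any(taxa_by_id.values()):
        try:
            stage("hgt")
            mixed = mixed_taxa(variant_by_id, taxa_by_id, config.divergence_rank)
            mixed_df = pd.DataFrame(
                [
                    {"group": g, "n_Sua5": c["Sua5"], "n_TsaC": c["TsaC"]}
                    for g, c in sorted(mixed.items())
                ]
            )
            written["mixed_taxa"] = outdir / "mixed_taxa.tsv"
            _write_tsv(mixed_df, written["mixed_taxa"])
            members = [r for r in records if variant_by_id[r.id] != "non_member"]
            candidates, tree = hgt_screen(members, config.divergence_rank)
            cand_df = pd.DataFrame(
                [
                    {
                        "id": c.record_id,
                        "neighbor": c.neighbor_id,
                        "identity_pct": c.identity,
                        "rank_of_divergence": c.rank_of_divergence,
                        "confirmed": bool(c.placement_confirmed),
                        "sister_clade": c.sister_clade_taxon or "",
                    }
                    for c in sorted(candidates, key=lambda c: c.record_id)
                ]
            )
            written["hgt_candidates"] = outdir / "hgt_candidates.tsv"
            _write_tsv(cand_df, written["hgt_candidates"])
            written["tree"] = outdir / "nj_tree.nwk"
            tree.write(str(written["tree"]))
        except Exception as e:
            raise RuntimeError(f"stage 'hgt' failed: {e}") from e

    if config.run_erosion:
        try:
            stage("erosion")
            sua5_calls = {
                c.record_id
                for c in calls
                if c.call in ("Sua5", "atypical_sua5")
            }
            pool = [r for r in records if r.id in sua5_calls]
            if len(pool) >= 2:
                by_id = {r.id: r for r in pool}
                if config.erosion_archetype:
                    arche = by_id[config.erosion_archetype]
                else:  # most complete = longest classical Sua5
                    classical = [
                        r for r in pool if variant_by_id[r.id] == "Sua5"
                    ] or pool
                    arche = max(classical, key=lambda r: (len(r), r.id))
                profiles = [
                    erosion_profile(r, arche)
                    for r in pool
                    if r.id != arche.id
                ]
                if len(profiles) >= 2:
                    profiles = erosion_stage(profiles)
                written["erosion"] = outdir / "erosion.tsv"
                _write_tsv(profiles_to_frame(profiles), written["erosion"])
        except Exception as e:
            raise RuntimeError(f"stage 'erosion' failed: {e}") from e

    if config.structures:
        try:
            stage("contacts")
            rows = []
            for spath in config.structures:
                model = read_structure(spath)
                for c in salt_bridges(model, config.salt_bridge_cutoff):
                    rows.append({"structure": Path(spath).name, **contacts_to_rows([c])[0]})
                for c in hydrogen_bonds(
                    model, "*:*:*", "*:*:*", config.hbond_cutoff
                ):
                    rows.append({"structure": Path(spath).name, **contacts_to_rows([c])[0]})
            written["contacts"] = outdir / "contacts.tsv"
            _write_tsv(pd.DataFrame(rows), written["contacts"])
        except Exception as e:
            raise RuntimeError(f"stage 'contacts' failed: {e}") from e

    stage("log")
    ann_file = resources.files("sua5kit.data").joinpath("reference_annotation.json")
    checksum = hashlib.sha256(ann_file.read_bytes()).hexdigest()
    log = {
        "sua5kit_version": __version__,
        "annotation_version": annotation_version(),
        "annotation_sha256": checksum,
        "config": asdict(config),
        "n_records": len(records),
        "outputs": {k: str(v) for k, v in sorted(written.items())},
    }
    written["log"] = outdir / "run_log.json"
    written["log"].write_text(json.dumps(log, indent=1, sort_keys=True) + "\n")
    return written
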