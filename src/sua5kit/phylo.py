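"""Distance trees, bootstrap support and the two-stage HGT screen.

Tree building is neighbor joining (Saitou-Nei) on identity-based distances
(d = 1 - identity fraction from global alignment). The horizontal-gene-
transfer screen mirrors best-hit practice: a sequence whose
maximum-identity neighbor belongs to a taxon that diverges from its own at
or above a rank threshold is an HGT candidate; candidates are confirmed by
tree placement (the smallest enclosing clade dominated by a foreign taxon).

Trees are :class:`skbio.TreeNode`; newick round-trips go through scikit-bio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import skbio
from skbio import DistanceMatrix as SkbioDM
from skbio.tree import TreeNode

from .align import ScoringSpec, StarAlignment, global_align, identity_fraction
from .records import InputError, ProteinRecord

logger = logging.getLogger(__name__)

#: Default taxonomy rank index used as the HGT divergence threshold
#: (0 = domain, 1 = phylum, ...).
DEFAULT_DIVERGENCE_RANK = 1
RANK_NAMES = ("domain", "phylum", "class", "order", "family", "genus", "species")


@dataclass
class DistanceMatrix:
    ids: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise InputError("duplicate ids in distance matrix")
        if self.data.shape != (n, n):
            raise InputError("distance matrix shape mismatch")
        if not np.allclose(self.data, self.data.T):
            raise InputError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.data), 0.0):
            raise InputError("distance matrix diagonal not zero")

    def to_skbio(self) -> SkbioDM:
        return SkbioDM(self.data, ids=self.ids)


def identity_matrix(
    records: Sequence[ProteinRecord], params: ScoringSpec | None = None
) -> tuple[list[str], np.ndarray]:
    """Pairwise global-alignment identity fractions (computed once per pair)."""
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise InputError("duplicate record ids")
    n = len(records)
    m = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            f = identity_fraction(
                global_align(records[i].sequence, records[j].sequence, params)
            )
            m[i, j] = m[j, i] = f
    return ids, m


def distance_matrix(
    records: Sequence[ProteinRecord], params: ScoringSpec | None = None
) -> DistanceMatrix:
    if len(records) < 3:
        raise InputError("distance_matrix: need >= 3 sequences")
    ids, m = identity_matrix(records, params)
    return DistanceMatrix(ids, 1.0 - m)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Canonical Saitou-Nei agglomeration with deterministic tie-breaking.

    Q-criterion ties are broken by the lowest (i, j) index pair in the
    current working order; negative branch-length estimates are clamped to
    zero (with a log message). On additive distances the true tree is
    recovered exactly.
    """
    n = len(dm.ids)
    if n < 2:
        raise InputError("neighbor_joining: need >= 2 taxa")
    nodes: list[TreeNode] = [TreeNode(name=i) for i in dm.ids]
    d = dm.data.astype(float).copy()

    def clamp(x: float) -> float:
        if x < 0:
            logger.debug("negative NJ branch length %.4g clamped to 0", x)
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index tie-break: argmin on the row-major flattened array
        flat = int(np.argmin(q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        new = TreeNode()
        nodes[i].length = clamp(li)
        nodes[j].length = clamp(lj)
        new.extend([nodes[i], nodes[j]])
        du = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d_new = np.zeros((m - 1, m - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = d_new[:-1, -1] = du[keep]
        nodes = [nodes[k] for k in keep] + [new]
        d = d_new

    root = TreeNode()
    if len(nodes) == 2:
        nodes[0].length = clamp(d[0, 1] / 2)
        nodes[1].length = clamp(d[0, 1] / 2)
        root.extend(nodes)
    else:
        l0 = clamp(0.5 * (d[0, 1] + d[0, 2] - d[1, 2]))
        l1 = clamp(0.5 * (d[0, 1] + d[1, 2] - d[0, 2]))
        l2 = clamp(0.5 * (d[0, 2] + d[1, 2] - d[0, 1]))
        for node, ln in zip(nodes, (l0, l1, l2)):
            node.length = ln
        root.extend(nodes)
    return root


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions of an (unrooted) tree, normalized.

    Each internal edge splits the leaves in two; the split is represented
    by the side NOT containing the lexicographically smallest leaf, so two
    trees over the same leaf set can be compared directly.
    """
    leaves = frozenset(t.name for t in tree.tips())
    anchor = min(leaves)
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(leaves) - 2:
            continue
        if anchor in side:
            side = leaves - side
        out.add(side)
    return out


def _msa_distance(rows: list[str], cols: np.ndarray | None = None) -> np.ndarray:
    """Pairwise p-distances over selected alignment columns (gap-aware)."""
    arr = np.array([list(r) for r in rows])
    if cols is not None:
        arr = arr[:, cols]
    n = arr.shape[0]
    d = np.zeros((n, n))
    gap = arr == "-"
    for i in range(n):
        for j in range(i + 1, n):
            valid = ~gap[i] & ~gap[j]
            nv = int(valid.sum())
            d[i, j] = d[j, i] = (
                float((arr[i, valid] != arr[j, valid]).mean()) if nv else 1.0
            )
    return d


def tree_from_msa(msa: StarAlignment) -> TreeNode:
    return neighbor_joining(DistanceMatrix(list(msa.ids), _msa_distance(msa.matrix)))


def bootstrap_support(
    msa: StarAlignment, reps: int = 100, seed: int = 0
) -> tuple[TreeNode, dict[frozenset, float]]:
    """NJ tree from the full alignment plus column-bootstrap supports.

    Columns (reference positions) are resampled with replacement per
    replicate; support for a bipartition of the full-alignment tree is the
    percentage of replicate trees containing it. Reproducible for a fixed
    seed. If all alignment rows are identical there is no conflicting
    signal and every support is 100 by convention.
    """
    if reps < 1:
        raise InputError("bootstrap_support: reps must be >= 1")
    ncol = len(msa.reference)
    if ncol < 2:
        raise InputError("bootstrap_support: need >= 2 alignment columns")
    tree = tree_from_msa(msa)
    splits = bipartitions(tree)
    if len(set(msa.matrix)) == 1:
        supports = {s: 100.0 for s in splits}
    else:
        rng = np.random.default_rng(seed)
        counts = {s: 0 for s in splits}
        for _ in range(reps):
            cols = rng.integers(0, ncol, size=ncol)
            rep_tree = neighbor_joining(
                DistanceMatrix(list(msa.ids), _msa_distance(msa.matrix, cols))
            )
            rep_splits = bipartitions(rep_tree)
            for s in splits:
                if s in rep_splits:
                    counts[s] += 1
        supports = {s: 100.0 * c / reps for s, c in counts.items()}
    # annotate internal nodes for newick export
    leaves = frozenset(msa.ids)
    anchor = min(leaves)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        key = leaves - side if anchor in side else side
        if key in supports:
            node.name = f"{supports[key]:.0f}"
    return tree, supports


# ---------------------------------------------------------------------------
# HGT screening
# ---------------------------------------------------------------------------


@dataclass
class HGTCandidate:
    record_id: str
    own_taxon: tuple[str, ...]
    neighbor_id: str
    neighbor_taxon: tuple[str, ...]
    identity: float  # percent
    rank_of_divergence: int  # 0 = domain, 1 = phylum, ...
    placement_confirmed: bool | None = None
    sister_clade_taxon: str | None = None


def first_divergence_rank(a: tuple[str, ...], b: tuple[str, ...]) -> int | None:
    """Index of the first rank at which two taxon paths differ, or None."""
    for i in range(max(len(a), len(b))):
        la = a[i] if i < len(a) else None
        lb = b[i] if i < len(b) else None
        if la != lb:
            return i
    return None


def mixed_taxa(
    variant_by_id: dict[str, str],
    taxa_by_id: dict[str, tuple[str, ...]],
    rank: int = DEFAULT_DIVERGENCE_RANK,
) -> dict[str, dict[str, int]]:
    """Taxa (labels at ``rank``) containing both Sua5 users and TsaC users.

    Atypical Sua5 counts as a Sua5 user; non-members are ignored. Records
    without a label at the rank are skipped with a warning.
    """
    counts: dict[str, dict[str, int]] = {}
    for rid, call in variant_by_id.items():
        if call == "non_member":
            continue
        path = taxa_by_id.get(rid, ())
        if rank >= len(path):
            logger.warning("record %s: no taxonomy label at rank %d, skipped", rid, rank)
            continue
        label = path[rank]
        group = counts.setdefault(label, {"Sua5": 0, "TsaC": 0})
        group["Sua5" if call in ("Sua5", "atypical_sua5") else "TsaC"] += 1
    return {
        label: c for label, c in counts.items() if c["Sua5"] > 0 and c["TsaC"] > 0
    }


def nearest_neighbor_screen(
    records: Sequence[ProteinRecord],
    divergence_rank: int = DEFAULT_DIVERGENCE_RANK,
    identity: tuple[list[str], np.ndarray] | None = None,
) -> list[HGTCandidate]:
    """Stage 1 of the HGT screen: maximum-identity neighbor outliers.

    A record is a candidate when its best (maximum-identity, non-self)
    neighbor's taxonomy diverges from its own at or above (i.e. at a more
    basal or equal index than) ``divergence_rank``.
    """
    if len(records) < 2:
        raise InputError("nearest_neighbor_screen: need >= 2 records")
    ids, m = identity if identity is not None else identity_matrix(records)
    by_id = {r.id: r for r in records}
    out = []
    work = m.copy()
    np.fill_diagonal(work, -1.0)
    for i, rid in enumerate(ids):
        j = int(np.argmax(work[i]))
        rec, nb = by_id[rid], by_id[ids[j]]
        rank = first_divergence_rank(rec.taxon_path, nb.taxon_path)
        if rank is not None and rank <= divergence_rank:
            out.append(
                HGTCandidate(
                    record_id=rid,
                    own_taxon=rec.taxon_path,
                    neighbor_id=nb.id,
                    neighbor_taxon=nb.taxon_path,
                    identity=round(100.0 * work[i, j], 1),
                    rank_of_divergence=rank,
                )
            )
    return out


def clade_placement_check(
    tree: TreeNode,
    candidate: HGTCandidate,
    taxa_by_id: dict[str, tuple[str, ...]],
    divergence_rank: int = DEFAULT_DIVERGENCE_RANK,
    near_copy_distance: float = 0.05,
    max_witnesses: int = 6,
) -> HGTCandidate:
    """Stage 2: confirm a candidate by incongruent tree placement.

    The candidate's local neighborhood in the (unrooted) tree votes on its
    origin: witnesses are the nearest other leaves by patristic distance,
    excluding near-copies of the candidate (patristic distance at or below
    ``near_copy_distance``) - a transfer counterpart is by construction
    almost identical and carries no information about the direction of the
    transfer, while its own neighborhood does. Starting from the two
    nearest witnesses, ties extend the vote to further witnesses (up to
    ``max_witnesses``). Confirmed iff a strict majority of the witnesses
    carries a taxon label at ``divergence_rank`` different from the
    candidate's own; the dominant label is reported as the sister clade.
    A transferred leaf grafted inside a donor clade thus sees a foreign
    majority, while the donor itself keeps its own-group neighbors and
    stays unconfirmed.
    """
    names = {t.name for t in tree.tips()}
    if candidate.record_id not in names:
        raise InputError(f"leaf {candidate.record_id!r} not in tree")
    own = (
        candidate.own_taxon[divergence_rank]
        if divergence_rank < len(candidate.own_taxon)
        else None
    )
    dm = tree.tip_tip_distances()
    dists = {
        other: float(dm[candidate.record_id, other])
        for other in dm.ids
        if other != candidate.record_id
    }
    witnesses = sorted(
        (
            (d, o)
            for o, d in dists.items()
            if d > near_copy_distance
            and divergence_rank < len(taxa_by_id.get(o, ()))
        ),
    )
    candidate.placement_confirmed = False
    candidate.sister_clade_taxon = None
    if len(witnesses) < 2:
        return candidate
    for k in range(2, min(max_witnesses, len(witnesses)) + 1):
        labels = [taxa_by_id[o][divergence_rank] for _, o in witnesses[:k]]
        values, counts = np.unique(labels, return_counts=True)
        best = int(np.argmax(counts))
        if counts[best] * 2 > len(labels):  # strict majority reached
            dominant = str(values[best])
            candidate.placement_confirmed = dominant != own
            candidate.sister_clade_taxon = (
                dominant if candidate.placement_confirmed else None
            )
            return candidate
    return candidate


def hgt_screen(
    records: Sequence[ProteinRecord],
    divergence_rank: int = DEFAULT_DIVERGENCE_RANK,
    params: ScoringSpec | None = None,
) -> tuple[list[HGTCandidate], TreeNode]:
    """Full two-stage screen: neighbor outliers, then placement on a NJ tree."""
    ids, m = identity_matrix(records, params)
    candidates = nearest_neighbor_screen(records, divergence_rank, identity=(ids, m))
    tree = neighbor_joining(DistanceMatrix(ids, 1.0 - m))
    taxa = {r.id: r.taxon_path for r in records}
    return (
        [clade_placement_check(tree, c, taxa, divergence_rank) for c in candidates],
        tree,
    )
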