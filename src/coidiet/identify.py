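"""From placements to identifications.

A query is *identified* when the pendant length of its best placement is
strictly shorter than the outlier threshold (the chosen quantile of the
reference tree's terminal branch lengths); otherwise it is an *outlier*
(likely non-target: decomposer, eDNA contaminant, or a taxon missing
from the reference). Identified queries are labelled with the species
of the leaf closest (by patristic distance) to the attachment point,
and treated downstream as OTUs rather than confirmed species.

The ID score compares the tree-based identification with two external
database identifications (e.g. BOLD and GenBank BLAST top hits): each
of the three unordered pairs contributes 6 for the same species, 5 for
the same genus, 3 for the same order, 1 for the same phylum, 0
otherwise; the total ranges 0-18.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .placement import Placement
from .refdb import OutlierThreshold, ReferenceDB, Taxonomy
from .tree import TreeNode

log = logging.getLogger(__name__)

__all__ = [
    "IdentificationResult",
    "DbHit",
    "IdScore",
    "classify_placement",
    "nearest_leaf",
    "multi_order_flag",
    "filter_db_hits",
    "id_score",
]

PAIR_SAME_SPECIES = 6
PAIR_SAME_GENUS = 5
PAIR_SAME_ORDER = 3
PAIR_SAME_PHYLUM = 1


@dataclass
class IdentificationResult:
    query_id: str
    sample_id: str
    n_reads: int
    status: str  # identified | outlier | unalignable
    otu_label: Optional[str] = None
    best_placement: Optional[Placement] = None
    alt_species: list[str] = field(default_factory=list)
    orders: set[str] = field(default_factory=set)
    pendant_length: float = float("nan")


@dataclass(frozen=True)
class DbHit:
    query_id: str
    db_name: str
    species: str
    percent_identity: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError(f"percent identity {self.percent_identity} outside [0,100]")


@dataclass(frozen=True)
class IdScore:
    query_id: str
    tree_species: Optional[str]
    db1_species: Optional[str]
    db2_species: Optional[str]
    pairwise: tuple[int, int, int]
    score: int


def _attachment_depth(tree_depths: dict, node: TreeNode, distal_from_child: float) -> float:
    return tree_depths[node] - distal_from_child


def _depths(refdb: ReferenceDB) -> dict:
    depths = getattr(refdb, "_depth_cache", None)
    if depths is None:
        depths = {}
        for node in refdb.tree.preorder():
            if node.parent is None:
                depths[node] = 0.0
            else:
                depths[node] = depths[node.parent] + (node.length or 0.0)
        refdb._depth_cache = depths  # type: ignore[attr-defined]
    return depths


def nearest_leaf(refdb: ReferenceDB, placement: Placement) -> str:
    """Species label of the leaf closest to the attachment point.

    Distance is the sum of branch lengths from the attachment point
    (sitting ``distal_length`` above the edge's child node) to the leaf,
    ignoring the pendant edge. Ties break lexicographically.
    """
    node = refdb.tree.node_by_edge_num(placement.edge_num)
    depths = _depths(refdb)
    a_depth = depths[node] - placement.distal_length

    # membership of each leaf in the subtree below the placement edge
    below: set[TreeNode] = set()
    stack = [node]
    while stack:
        n = stack.pop()
        below.add(n)
        stack.extend(n.children)

    best: Optional[tuple[float, str]] = None
    for leaf in refdb.tree.leaves():
        if leaf in below:
            dist = depths[leaf] - a_depth
        else:
            # walk up from the placement node to find the junction with
            # the path from the leaf to the root
            anc = node
            leaf_ancestors = set()
            n = leaf
            while n is not None:
                leaf_ancestors.add(n)
                n = n.parent
            while anc not in leaf_ancestors:
                anc = anc.parent
            dist = (a_depth - depths[anc]) + (depths[leaf] - depths[anc])
        key = (dist, leaf.name)
        if best is None or key < best:
            best = key
    return best[1]


def classify_placement(
    placements: Sequence[Placement],
    threshold: OutlierThreshold,
    refdb: ReferenceDB,
    n_reads: int = 1,
    sample_id: str = "",
    query_id: Optional[str] = None,
    lwr_report_cutoff: float = 0.999,
) -> IdentificationResult:
    """Turn a best-first placement list into an identification verdict.

    Identified iff the best placement's pendant length is strictly below
    the threshold ("shorter than"); equal-or-longer pendants are
    outliers; an empty placement list means the query was unalignable.
    Alternative species and the order set are derived from the reported
    placements (accumulated LWR up to the reporting cutoff).
    """
    if not placements:
        return IdentificationResult(
            query_id=query_id or "?", sample_id=sample_id, n_reads=n_reads,
            status="unalignable",
        )
    best = placements[0]
    qid = query_id or best.query_id
    reported: list[Placement] = []
    acc = 0.0
    for p in sorted(placements, key=lambda p: (-p.like_weight_ratio, p.edge_num)):
        reported.append(p)
        acc += p.like_weight_ratio
        if acc >= lwr_report_cutoff:
            break
    alt_species: list[str] = []
    for p in reported:
        sp = nearest_leaf(refdb, p)
        if sp not in alt_species:
            alt_species.append(sp)
    orders = {
        refdb.taxonomy.rank(sp, "order")
        for sp in alt_species
        if refdb.taxonomy.rank(sp, "order") is not None
    }
    identified = best.pendant_length < threshold.value
    return IdentificationResult(
        query_id=qid,
        sample_id=sample_id,
        n_reads=n_reads,
        status="identified" if identified else "outlier",
        otu_label=alt_species[0] if identified else None,
        best_placement=best,
        alt_species=alt_species,
        orders=orders,
        pendant_length=best.pendant_length,
    )


def multi_order_flag(result: IdentificationResult, taxonomy: Taxonomy) -> tuple[bool, set[str]]:
    """True iff the reported placements' nearest leaves span >1 order."""
    orders = {
        taxonomy.rank(sp, "order")
        for sp in result.alt_species
        if taxonomy.rank(sp, "order") is not None
    }
    return len(orders) > 1, orders


def filter_db_hits(hits: Sequence[DbHit], min_identity: float) -> list[DbHit]:
    """Keep hits whose percent identity is >= *min_identity*."""
    if not (0.0 <= min_identity <= 100.0):
        raise ValueError("min_identity must lie in [0,100]")
    return [h for h in hits if h.percent_identity >= min_identity]


def _pair_score(a: Optional[str], b: Optional[str], taxonomy: Taxonomy) -> int:
    if not a or not b:
        return 0
    if a == b:
        return PAIR_SAME_SPECIES

    def rank_of(label: str, rank: str) -> Optional[str]:
        value = taxonomy.rank(label, rank)
        if value is None and rank == "genus":
            # unknown label: the genus is still derivable from its first token
            log.debug("species %r absent from taxonomy; using label genus", label)
            return label.split()[0]
        return value

    if rank_of(a, "genus") == rank_of(b, "genus") and rank_of(a, "genus") is not None:
        return PAIR_SAME_GENUS
    order_a, order_b = rank_of(a, "order"), rank_of(b, "order")
    if order_a is not None and order_a == order_b:
        return PAIR_SAME_ORDER
    phyl_a, phyl_b = rank_of(a, "phylum"), rank_of(b, "phylum")
    if phyl_a is not None and phyl_a == phyl_b:
        return PAIR_SAME_PHYLUM
    return 0


def id_score(
    tree_species: Optional[str],
    db1_species: Optional[str],
    db2_species: Optional[str],
    taxonomy: Taxonomy,
    query_id: str = "",
) -> IdScore:
    """0-18 concordance of the three identifications (sum of three pairs)."""
    pairs = (
        _pair_score(tree_species, db1_species, taxonomy),
        _pair_score(tree_species, db2_species, taxonomy),
        _pair_score(db1_species, db2_species, taxonomy),
    )
    return IdScore(
        query_id=query_id,
        tree_species=tree_species,
        db1_species=db1_species,
        db2_species=db2_species,
        pairwise=pairs,
        score=sum(pairs),
    )
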