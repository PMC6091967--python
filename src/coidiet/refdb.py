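"""Reference database: alignment + taxonomy + tree, the terminal
branch-length outlier threshold, and alignment of query reads into the
fixed reference coordinate system.

The reference alignment's columns are frozen: query sequences are
aligned against a per-column profile of the reference rows, never the
other way round, so the reference tree and alignment coordinates stay
valid for placement. Insertions in the query relative to the reference
are discarded (counted and logged).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError
from .seqio import SequenceRecord, read_fasta, read_table, write_fasta, write_table
from .tree import PhyloTree, read_newick, write_newick

log = logging.getLogger(__name__)

__all__ = [
    "TaxonRecord",
    "Taxonomy",
    "ReferenceDB",
    "OutlierThreshold",
    "load_reference",
    "terminal_branch_lengths",
    "quantile_threshold",
    "flag_long_branches",
    "align_query_to_reference",
]

RANKS = ("genus", "family", "order", "phylum")

# "Genus sp." with nothing after it is not species-level; "Genus sp. TAG" is.
_UNTAGGED_SP = re.compile(r"^\S+\s+sp\.$")


@dataclass(frozen=True)
class TaxonRecord:
    species: str
    genus: str
    family: str
    order: str
    phylum: str


class Taxonomy:
    """Species label -> (genus, family, order, phylum)."""

    def __init__(self, records: Sequence[TaxonRecord]):
        self._by_species: dict[str, TaxonRecord] = {}
        for rec in records:
            if rec.species in self._by_species:
                raise ValidationError(f"duplicate taxonomy entry for {rec.species!r}")
            first_token = rec.species.split()[0]
            if rec.genus != first_token:
                raise ValidationError(
                    f"{rec.species!r}: genus {rec.genus!r} is not the first "
                    f"token of the species label"
                )
            self._by_species[rec.species] = rec

    @classmethod
    def from_table(cls, path) -> "Taxonomy":
        rows = read_table(
            path,
            schema={
                "species": str,
                "genus": str,
                "family": str,
                "order": str,
                "phylum": str,
            },
        )
        return cls([TaxonRecord(**{k: r[k] for k in ("species",) + RANKS}) for r in rows])

    def __contains__(self, species: str) -> bool:
        return species in self._by_species

    def __len__(self) -> int:
        return len(self._by_species)

    def get(self, species: str) -> Optional[TaxonRecord]:
        return self._by_species.get(species)

    def rank(self, species: str, rank: str) -> Optional[str]:
        rec = self._by_species.get(species)
        return getattr(rec, rank) if rec else None

    def species(self) -> list[str]:
        return list(self._by_species)

    def records(self) -> list[TaxonRecord]:
        return list(self._by_species.values())


@dataclass
class ReferenceDB:
    """Validated reference alignment, tree and taxonomy."""

    alignment: dict[str, str]
    tree: PhyloTree
    taxonomy: Taxonomy
    n_columns: int

    def __post_init__(self) -> None:
        leaf_set = set(self.tree.leaf_labels())
        aln_set = set(self.alignment)
        if leaf_set != aln_set:
            only_tree = sorted(leaf_set - aln_set)
            only_aln = sorted(aln_set - leaf_set)
            raise ValidationError(
                f"tree/alignment leaf-set mismatch: only in tree {only_tree}, "
                f"only in alignment {only_aln}"
            )
        if len(leaf_set) < 4:
            raise ValidationError("reference needs at least 4 leaves")
        for label, row in self.alignment.items():
            if len(row) != self.n_columns:
                raise ValidationError(
                    f"alignment row {label!r} has {len(row)} columns, "
                    f"expected {self.n_columns}"
                )

    # -- persistence (the on-disk 'refdb directory' used by the CLI) -------
    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(
            [SequenceRecord(id=k, bases=v) for k, v in self.alignment.items()],
            out / "alignment.fasta",
        )
        (out / "tree.nwk").write_text(write_newick(self.tree) + "\n")
        write_table(
            [rec.__dict__ for rec in self.taxonomy.records()],
            out / "taxonomy.tsv",
            columns=["species", "genus", "family", "order", "phylum"],
        )

    @classmethod
    def load(cls, ref_dir) -> "ReferenceDB":
        ref = Path(ref_dir)
        return load_reference(
            ref / "alignment.fasta", ref / "taxonomy.tsv", ref / "tree.nwk"
        )


@dataclass(frozen=True)
class OutlierThreshold:
    q: float
    value: float
    n_branches: int

    def __post_init__(self) -> None:
        if not (0.0 < self.q < 1.0):
            raise ValueError("quantile level must lie in (0,1)")
        if self.value < 0:
            raise ValueError("threshold value must be >= 0")


def is_species_level(label: str) -> bool:
    """True unless the label is an untagged 'Genus sp.' placeholder."""
    return not _UNTAGGED_SP.match(label.strip())


def load_reference(alignment_fasta, taxonomy_tsv, tree_newick) -> ReferenceDB:
    """Load and reconcile the three reference inputs.

    Leaves without a taxonomy record, and untagged 'Genus sp.' labels,
    are dropped from the alignment and pruned from the tree (logged). A
    leaf-set mismatch that survives reconciliation is an error naming
    the offenders.
    """
    records = read_fasta(alignment_fasta, allow_gaps=True)
    taxonomy = Taxonomy.from_table(taxonomy_tsv)
    tree = read_newick(Path(tree_newick).read_text())

    keep: dict[str, str] = {}
    dropped: list[str] = []
    for rec in records:
        if rec.id in taxonomy and is_species_level(rec.id):
            keep[rec.id] = rec.bases
        else:
            dropped.append(rec.id)
    if dropped:
        log.info(
            "dropped %d reference rows (no taxonomy or not species-level): %s",
            len(dropped), ", ".join(sorted(dropped)),
        )
    tree.prune_to(set(keep) & set(tree.leaf_labels()))

    lengths = {len(v) for v in keep.values()}
    if len(lengths) != 1:
        raise ValidationError(f"alignment rows have unequal lengths: {sorted(lengths)}")
    return ReferenceDB(
        alignment=keep, tree=tree, taxonomy=taxonomy, n_columns=lengths.pop()
    )


def terminal_branch_lengths(tree: PhyloTree) -> list[float]:
    """Branch length of every leaf's incident edge (one value per leaf)."""
    return [leaf.length if leaf.length is not None else 0.0 for leaf in tree.leaves()]


def quantile_threshold(
    lengths: Sequence[float], q: float, method: str = "linear"
) -> OutlierThreshold:
    """Empirical quantile of the terminal branch-length distribution.

    Default estimator is linear interpolation between order statistics
    (numpy's 'linear', i.e. the type-7 estimator); other numpy methods
    may be selected.
    """
    if len(lengths) == 0:
        raise ValueError("cannot take a quantile of an empty length list")
    if not (0.0 < q < 1.0):
        raise ValueError("q must lie in (0, 1)")
    value = float(np.quantile(np.asarray(lengths, dtype=float), q, method=method))
    return OutlierThreshold(q=q, value=value, n_branches=len(lengths))


def flag_long_branches(tree: PhyloTree, threshold: float) -> list[str]:
    """Leaves on terminal branches longer than *threshold*, longest first.

    A curation aid: candidates for manual pruning are reported, never
    removed automatically.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    hits = [
        (leaf.length or 0.0, leaf.name)
        for leaf in tree.leaves()
        if (leaf.length or 0.0) > threshold
    ]
    return [name for _, name in sorted(hits, key=lambda t: (-t[0], t[1]))]


# ---------------------------------------------------------------------------
# fixed-profile query alignment
# ---------------------------------------------------------------------------

_PROFILE_BASES = "ACGT"
_GAP_SKIP_COST = 0.9     # charged per reference column left unmatched (scaled by occupancy)
_INSERTION_COST = 1.5    # charged per query base discarded
# Floors for alignability. Divergent-but-homologous sequences (decomposers,
# eDNA) must still be aligned and placed so the pendant-length filter can
# reject them; only uninformative (mostly-N) or anti-profile input is refused.
_MIN_INFORMATIVE_FRAC = 0.5
_SCORE_FLOOR = -0.6      # min average per-informative-base score


def _build_profile(refdb: ReferenceDB) -> np.ndarray:
    """(n_columns, 5) array: per-column frequency of A,C,G,T and gap."""
    rows = list(refdb.alignment.values())
    counts = np.zeros((refdb.n_columns, 5))
    code = {b: i for i, b in enumerate(_PROFILE_BASES)}
    for row in rows:
        for j, c in enumerate(row):
            if c in code:
                counts[j, code[c]] += 1
            elif c == "-":
                counts[j, 4] += 1
            # N contributes to no base
    return counts / max(len(rows), 1)


def align_query_to_reference(
    query_bases: str, refdb: ReferenceDB, return_score: bool = False
):
    """Align a query read against the frozen reference columns.

    Global dynamic programming over (reference column, query position).
    Matching a base to a column scores ``2*f - 1`` where ``f`` is the
    column frequency of that base (N scores 0); skipping a column emits
    '-' and costs in proportion to the column's occupancy; consuming a
    query base without a column (an insertion relative to the reference)
    discards that base. Returns a string of exactly ``refdb.n_columns``
    characters over {A,C,G,T,N,-}, or ``None`` when the query is
    unalignable (mostly N, or scoring below even a random nucleotide
    string would). Divergent homologs deliberately pass the floor: they
    must reach placement so the pendant-length filter can judge them.
    """
    if len(query_bases) < 20:
        raise ValueError("query shorter than 20 bp")
    n_informative = sum(1 for c in query_bases.upper() if c in "ACGT")
    if n_informative < _MIN_INFORMATIVE_FRAC * len(query_bases):
        log.info("query unalignable: %d/%d informative bases",
                 n_informative, len(query_bases))
        return (None, float("-inf")) if return_score else None
    profile = getattr(refdb, "_profile_cache", None)
    if profile is None:
        profile = _build_profile(refdb)
        refdb._profile_cache = profile  # type: ignore[attr-defined]

    q = query_bases.upper()
    ncol, nq = refdb.n_columns, len(q)
    code = {b: i for i, b in enumerate(_PROFILE_BASES)}

    # match[i, j]: score of aligning query base j to reference column i
    match = np.zeros((ncol, nq))
    for j, c in enumerate(q):
        if c in code:
            match[:, j] = 2.0 * profile[:, code[c]] - 1.0
        else:  # N (or mapped-to-N): uninformative
            match[:, j] = 0.0
    skip_cost = _GAP_SKIP_COST * (1.0 - profile[:, 4])  # cheap to skip gappy columns

    NEG = -1e30
    score = np.full((ncol + 1, nq + 1), NEG)
    move = np.zeros((ncol + 1, nq + 1), dtype=np.uint8)  # 1=diag, 2=skip col, 3=ins
    score[0, 0] = 0.0
    for i in range(1, ncol + 1):
        score[i, 0] = score[i - 1, 0] - skip_cost[i - 1]
        move[i, 0] = 2
    for j in range(1, nq + 1):
        score[0, j] = score[0, j - 1] - _INSERTION_COST
        move[0, j] = 3
    for i in range(1, ncol + 1):
        diag = score[i - 1, :-1] + match[i - 1, :]
        up = score[i - 1, 1:] - skip_cost[i - 1]
        for j in range(1, nq + 1):
            best, mv = diag[j - 1], 1
            if up[j - 1] > best:
                best, mv = up[j - 1], 2
            left = score[i, j - 1] - _INSERTION_COST
            if left > best:
                best, mv = left, 3
            score[i, j] = best
            move[i, j] = mv

    total = float(score[ncol, nq])
    if total < _SCORE_FLOOR * n_informative:
        log.info("query unalignable (score %.1f over %d bases)", total, nq)
        return (None, total) if return_score else None

    out = ["-"] * ncol
    i, j, n_inserted = ncol, nq, 0
    while i > 0 or j > 0:
        mv = move[i, j]
        if mv == 1:
            out[i - 1] = q[j - 1] if q[j - 1] in "ACGTN" else "N"
            i, j = i - 1, j - 1
        elif mv == 2:
            i -= 1
        else:
            n_inserted += 1
            j -= 1
    if n_inserted:
        log.debug("discarded %d inserted query bases", n_inserted)
    aligned = "".join(out)
    return (aligned, total) if return_score else aligned
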