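"""Read preprocessing: primer trimming, length filtering, greedy
abundance-sorted clustering, small-cluster removal, and pooled de novo
chimera (bimera) detection.

Divergence between two sequences is the Hamming distance over their
common prefix plus the absolute length difference; minibarcode amplicons
are near-fixed-length, so an ungapped comparison with a length penalty
stands in for alignment-aware distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .config import IUPAC, PipelineConfig
from .seqio import SequenceRecord

log = logging.getLogger(__name__)

__all__ = [
    "ReadCluster",
    "trim_and_filter",
    "greedy_cluster",
    "filter_small_clusters",
    "detect_chimeras",
    "sequence_divergence",
]

_BASE_CODE = {c: i for i, c in enumerate("ACGTN-")}
_PAD = 255


@dataclass
class ReadCluster:
    """A cluster of near-identical reads from one sample.

    ``representative`` is the founding (most abundant) read's sequence;
    ``n_reads`` is the abundance used downstream as a prey-quantity
    surrogate.
    """

    cluster_id: str
    sample_id: str
    representative: str
    member_ids: list[str] = field(default_factory=list)
    chimera_flag: bool = False

    @property
    def n_reads(self) -> int:
        return len(self.member_ids)


def _match_with_ambiguity(primer: str, prefix: str) -> int:
    """Mismatches between a primer (IUPAC codes allowed) and a read prefix."""
    mismatches = 0
    for p, b in zip(primer, prefix):
        if b not in IUPAC.get(p, p):
            mismatches += 1
    return mismatches


def trim_and_filter(
    records: Sequence[SequenceRecord],
    config: PipelineConfig,
    stats: Optional[dict] = None,
) -> list[SequenceRecord]:
    """Clip the forward primer and drop short or primer-less reads.

    The primer must match at the 5' end with at most one mismatch; reads
    without a recognizable primer are dropped, as are reads shorter than
    ``config.min_trimmed_len`` after clipping. Input order is preserved.
    """
    primer = config.primer_fwd.upper()
    if not primer:
        raise ValueError("primer_fwd must be non-empty")
    counters = {"input": 0, "no_primer": 0, "too_short": 0, "kept": 0}
    out: list[SequenceRecord] = []
    for rec in records:
        counters["input"] += 1
        if len(rec.bases) < len(primer):
            counters["no_primer"] += 1
            continue
        if _match_with_ambiguity(primer, rec.bases[: len(primer)]) > 1:
            counters["no_primer"] += 1
            continue
        trimmed = rec.bases[len(primer):]
        if len(trimmed) < config.min_trimmed_len:
            counters["too_short"] += 1
            continue
        quals = rec.qualities[len(primer):] if rec.qualities is not None else None
        out.append(
            SequenceRecord(
                id=rec.id, bases=trimmed, sample_id=rec.sample_id, qualities=quals
            )
        )
        counters["kept"] += 1
    if stats is not None:
        stats.update(counters)
    return out


def _encode_padded(seqs: Sequence[str], width: int) -> np.ndarray:
    arr = np.full((len(seqs), width), _PAD, dtype=np.uint8)
    for i, s in enumerate(seqs):
        arr[i, : len(s)] = [_BASE_CODE.get(c, 4) for c in s]
    return arr


def sequence_divergence(a: str, b: str) -> int:
    """Hamming distance over the common prefix plus the length difference."""
    m = min(len(a), len(b))
    mism = sum(1 for x, y in zip(a[:m], b[:m]) if x != y)
    return mism + abs(len(a) - len(b))


def greedy_cluster(
    records: Sequence[SequenceRecord],
    config: PipelineConfig,
    sample_id: Optional[str] = None,
) -> list[ReadCluster]:
    """Single-pass greedy clustering of trimmed reads from one sample.

    Unique sequences are visited in order of (duplicate multiplicity
    descending, first occurrence); each joins the earliest-founded cluster
    whose representative is within ``config.max_cluster_div`` of it, else
    founds a new cluster. Clusters come back sorted by ``n_reads``
    descending (founding order breaks ties). Deterministic.
    """
    if not records:
        return []
    if sample_id is None:
        sample_id = records[0].sample_id

    groups: dict[str, list[str]] = {}
    first_idx: dict[str, int] = {}
    for i, rec in enumerate(records):
        groups.setdefault(rec.bases, []).append(rec.id)
        first_idx.setdefault(rec.bases, i)
    uniques = sorted(groups, key=lambda s: (-len(groups[s]), first_idx[s]))

    width = max(len(s) for s in uniques)
    encoded = _encode_padded(uniques, width)

    clusters: list[ReadCluster] = []
    rep_rows: list[np.ndarray] = []
    for row, seq in zip(encoded, uniques):
        if rep_rows:
            dists = np.count_nonzero(np.stack(rep_rows) != row, axis=1)
            hits = np.nonzero(dists <= config.max_cluster_div)[0]
        else:
            hits = []
        if len(hits):
            clusters[hits[0]].member_ids.extend(groups[seq])
        else:
            clusters.append(
                ReadCluster(
                    cluster_id=f"{sample_id}_c{len(clusters)}",
                    sample_id=sample_id,
                    representative=seq,
                    member_ids=list(groups[seq]),
                )
            )
            rep_rows.append(row)
    return sorted(clusters, key=lambda c: -c.n_reads)


def filter_small_clusters(
    clusters: Sequence[ReadCluster], config: PipelineConfig
) -> list[ReadCluster]:
    """Keep clusters with at least ``config.min_cluster_reads`` reads."""
    return [c for c in clusters if c.n_reads >= config.min_cluster_reads]


def detect_chimeras(
    clusters_all_samples: Sequence[ReadCluster], config: PipelineConfig
) -> list[ReadCluster]:
    """Flag bimeras on the pooled cluster set (all samples jointly).

    Candidates are examined in ascending abundance. For a candidate C,
    every cluster P (other than C) with ``n_reads >= skew * C.n_reads``
    is a potential parent. C is flagged iff some ordered parent pair
    (P1, P2) and breakpoint k — both segments at least
    ``chimera_min_segment`` bp — give a two-parent model that (a)
    undercuts the best single-parent divergence by at least
    ``chimera_min_advantage`` mismatches and (b) lies within
    ``chimera_max_model_div`` of C. A real bimera differs from its
    spliced parent model only by sequencing error; without (b),
    breakpoint optimization between unrelated abundant clusters flags
    divergent non-chimeric candidates. Flags are set on the input
    cluster objects; the (pooled) input list is returned, so per-sample
    partitioning can be restored by the caller.
    """
    clusters = list(clusters_all_samples)
    if not clusters:
        return []
    width = max(len(c.representative) for c in clusters)
    rows = _encode_padded([c.representative for c in clusters], width)
    order = sorted(range(len(clusters)), key=lambda i: clusters[i].n_reads)

    for ci in order:
        cand = clusters[ci]
        parent_idx = [
            j
            for j in range(len(clusters))
            if j != ci
            and clusters[j].n_reads >= config.chimera_abundance_skew * cand.n_reads
        ]
        if len(parent_idx) < 2:
            continue
        crow = rows[ci]
        clen = len(cand.representative)
        lo, hi = config.chimera_min_segment, clen - config.chimera_min_segment
        if lo > hi:
            continue
        # mismatch prefix sums of each parent against the candidate
        diff = rows[parent_idx] != crow  # (P, width)
        prefix = np.concatenate(
            [np.zeros((len(parent_idx), 1), dtype=int), np.cumsum(diff, axis=1)], axis=1
        )
        totals = prefix[:, -1]
        best_single = int(totals.min())
        flagged = False
        for a in range(len(parent_idx)):
            if flagged:
                break
            for b in range(len(parent_idx)):
                if a == b:
                    continue
                # model = P_a[:k] + P_b[k:]; divergence = prefix_a[k] + (total_b - prefix_b[k])
                ks = np.arange(lo, hi + 1)
                model_div = prefix[a, ks] + (totals[b] - prefix[b, ks])
                best_model = int(model_div.min())
                if (
                    best_model <= best_single - config.chimera_min_advantage
                    and best_model <= config.chimera_max_model_div
                ):
                    flagged = True
                    break
        cand.chimera_flag = flagged
    n_flagged = sum(c.chimera_flag for c in clusters)
    if n_flagged:
        log.info("chimera detection flagged %d of %d clusters", n_flagged, len(clusters))
    return clusters
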