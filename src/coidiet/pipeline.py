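"""End-to-end convenience driver: FASTQ read sets -> identifications.

Chains the per-module operations in the documented order — trim/length
filter, per-sample greedy clustering, small-cluster removal, pooled
chimera detection, fixed-profile alignment, placement, pendant-length
classification — and returns per-cluster identification results plus
per-sample summaries. The individual modules stay usable on their own;
this wrapper exists for the CLI and for end-to-end validation against
simulated ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .config import PipelineConfig
from .diversity import OtuTable, SampleSummary, build_otu_table, percent_target, shannon
from .identify import IdentificationResult, classify_placement
from .placement import PlacementEngine, Placement, default_model
from .preprocess import (
    ReadCluster,
    detect_chimeras,
    filter_small_clusters,
    greedy_cluster,
    trim_and_filter,
)
from .refdb import ReferenceDB, align_query_to_reference, quantile_threshold, terminal_branch_lengths
from .seqio import SequenceRecord

log = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    identifications: list[IdentificationResult]
    clusters: list[ReadCluster]
    summaries: list[SampleSummary]
    otu_table: OtuTable
    threshold_value: float
    per_sample_stats: dict[str, dict] = field(default_factory=dict)


def run_pipeline(
    reads_by_sample: dict[str, Sequence[SequenceRecord]],
    refdb: ReferenceDB,
    config: Optional[PipelineConfig] = None,
) -> PipelineResult:
    config = config or PipelineConfig()

    clusters_pooled: list[ReadCluster] = []
    stats: dict[str, dict] = {}
    for sample_id, reads in reads_by_sample.items():
        st: dict = {"reads_total": len(reads)}
        trimmed = trim_and_filter(reads, config, stats=st)
        clusters = greedy_cluster(trimmed, config, sample_id=sample_id)
        st["clusters"] = len(clusters)
        clusters = filter_small_clusters(clusters, config)
        st["clusters_kept"] = len(clusters)
        clusters_pooled.extend(clusters)
        stats[sample_id] = st

    detect_chimeras(clusters_pooled, config)
    survivors = [c for c in clusters_pooled if not c.chimera_flag]
    for sample_id in stats:
        stats[sample_id]["chimeras"] = sum(
            1 for c in clusters_pooled if c.sample_id == sample_id and c.chimera_flag
        )

    threshold = quantile_threshold(
        terminal_branch_lengths(refdb.tree), config.quantile_q
    )
    engine = PlacementEngine(refdb, model=default_model(config), config=config)

    identifications: list[IdentificationResult] = []
    for cluster in survivors:
        aligned = align_query_to_reference(cluster.representative, refdb)
        placements: list[Placement] = (
            engine.place(cluster.cluster_id, aligned) if aligned is not None else []
        )
        identifications.append(
            classify_placement(
                placements,
                threshold,
                refdb,
                n_reads=cluster.n_reads,
                sample_id=cluster.sample_id,
                query_id=cluster.cluster_id,
                lwr_report_cutoff=config.lwr_report_cutoff,
            )
        )

    otu_table = build_otu_table(identifications, taxonomy=refdb.taxonomy)
    summaries: list[SampleSummary] = []
    for sample_id, st in stats.items():
        sample_ids = [r for r in identifications if r.sample_id == sample_id]
        pct = percent_target(st["reads_total"], sample_ids)
        row = (
            otu_table.counts.loc[sample_id]
            if sample_id in otu_table.counts.index
            else None
        )
        richness = int((row > 0).sum()) if row is not None else 0
        h = (
            shannon(row[row > 0], config.shannon_log_base)
            if row is not None and row.sum() > 0
            else None
        )
        summaries.append(
            SampleSummary(
                sample_id=sample_id,
                fresh=False,
                reads_total=st["reads_total"],
                pct_target=pct,
                otu_richness=richness,
                shannon=h,
            )
        )
    return PipelineResult(
        identifications=identifications,
        clusters=clusters_pooled,
        summaries=summaries,
        otu_table=otu_table,
        threshold_value=threshold.value,
        per_sample_stats=stats,
    )
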