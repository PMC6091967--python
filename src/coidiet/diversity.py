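"""OTU tables and diet diversity statistics.

Read counts of identified clusters act as an abundance surrogate: the
per-sample summary reports total reads, the percentage of reads in
identified target clusters, OTU richness and the Shannon index; group
comparisons (fresh vs. old samples) report per-group means, medians and
a two-sided Mann-Whitney rank-sum P-value; beta diversity between OTU
presence sets uses the Jaccard index.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .identify import IdentificationResult
from .refdb import Taxonomy

log = logging.getLogger(__name__)

__all__ = [
    "OtuTable",
    "SampleSummary",
    "build_otu_table",
    "percent_target",
    "shannon",
    "jaccard",
    "group_compare",
    "composition_table",
    "default_group",
]

_LOG_BASE = {"e": math.e, "2": 2.0, "10": 10.0}


@dataclass
class OtuTable:
    """Sample x OTU read-count matrix with an OTU -> group mapping."""

    counts: pd.DataFrame  # index: samples, columns: OTU labels, int reads
    group_of_otu: dict[str, str] = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otus(self) -> list[str]:
        return list(self.counts.columns)

    def presence(self, sample: str) -> set[str]:
        row = self.counts.loc[sample]
        return set(row.index[row > 0])


@dataclass
class SampleSummary:
    sample_id: str
    fresh: bool
    reads_total: int
    pct_target: Optional[float]
    otu_richness: int
    shannon: Optional[float]


def default_group(taxonomy: Taxonomy, species: str) -> str:
    """Higher group of an OTU: its order, with Chironomidae split out of
    Diptera (the conventional grouping for freshwater diet tables)."""
    rec = taxonomy.get(species)
    if rec is None:
        return "other"
    if rec.family == "Chironomidae":
        return "Chironomidae"
    if rec.order == "Diptera":
        return "Diptera excl. Chironomidae"
    return rec.order


def build_otu_table(
    identifications: Sequence[IdentificationResult],
    taxonomy: Optional[Taxonomy] = None,
) -> OtuTable:
    """Aggregate identified clusters into sample x OTU read counts.

    Outlier and unalignable clusters contribute nothing; a sample whose
    clusters are all outliers still appears as an all-zero row.
    """
    samples = sorted({r.sample_id for r in identifications})
    cells: dict[tuple[str, str], int] = {}
    for r in identifications:
        if r.status != "identified":
            continue
        key = (r.sample_id, r.otu_label)
        cells[key] = cells.get(key, 0) + r.n_reads
    otus = sorted({otu for _, otu in cells})
    counts = pd.DataFrame(0, index=samples, columns=otus, dtype=int)
    for (s, o), n in cells.items():
        counts.loc[s, o] = n
    groups = {}
    if taxonomy is not None:
        groups = {o: default_group(taxonomy, o) for o in otus}
    return OtuTable(counts=counts, group_of_otu=groups)


def percent_target(
    sample_reads_total: int, identifications: Sequence[IdentificationResult]
) -> Optional[float]:
    """Percent of a sample's total reads that sit in identified clusters.

    The denominator is the total reads assigned to the sample before any
    filtering; returns None when it is zero (undefined).
    """
    identified = sum(r.n_reads for r in identifications if r.status == "identified")
    if sample_reads_total == 0:
        return None
    if sample_reads_total < identified:
        raise ValueError("total reads smaller than identified reads")
    return 100.0 * identified / sample_reads_total


def shannon(counts: Iterable[float], log_base: str = "e") -> float:
    """Shannon index H' = -sum p_i log p_i over OTUs with p_i > 0."""
    arr = np.asarray(list(counts), dtype=float)
    if arr.size == 0 or arr.sum() <= 0:
        raise ValueError("Shannon index needs a positive total count")
    if np.any(arr < 0):
        raise ValueError("negative counts")
    return float(sps.entropy(arr, base=_LOG_BASE[log_base]))


def jaccard(otus_a: set, otus_b: set) -> Optional[float]:
    """J = |A n B| / |A u B|; None when both sets are empty (undefined)."""
    union = otus_a | otus_b
    if not union:
        return None
    return len(otus_a & otus_b) / len(union)


_METRICS = ["reads_total", "pct_target", "otu_richness", "shannon"]


def _box_stats(values: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo = values[values >= q1 - 1.5 * iqr].min()
    hi = values[values <= q3 + 1.5 * iqr].max()
    return {"q1": q1, "median": med, "q3": q3, "whisker_lo": lo, "whisker_hi": hi}


def group_compare(
    summaries: Sequence[SampleSummary],
    group_field: str = "fresh",
    metrics: Sequence[str] = tuple(_METRICS),
) -> pd.DataFrame:
    """Compare sample summary metrics between two groups.

    One row per (metric, group) with mean/median/box-plot statistics,
    plus the two-sided Mann-Whitney rank-sum P-value (normal
    approximation with tie correction) attached to every row of the
    metric. Groups with fewer than two samples are skipped with a
    warning.
    """
    df = pd.DataFrame([s.__dict__ for s in summaries])
    rows = []
    for metric in metrics:
        sub = df[[group_field, metric]].dropna()
        groups = {g: v[metric].to_numpy(dtype=float) for g, v in sub.groupby(group_field)}
        usable = {g: v for g, v in groups.items() if len(v) >= 2}
        skipped = set(groups) - set(usable)
        if skipped:
            log.warning("metric %s: skipping groups with <2 samples: %s", metric, skipped)
        pvalue = np.nan
        if len(usable) == 2:
            a, b = usable.values()
            if np.ptp(np.concatenate([a, b])) == 0:
                pvalue = 1.0
            else:
                pvalue = float(
                    sps.mannwhitneyu(
                        a, b, alternative="two-sided", method="asymptotic",
                        use_continuity=False,
                    ).pvalue
                )
        for g, vals in usable.items():
            row = {
                "metric": metric,
                "group": g,
                "n": len(vals),
                "mean": float(vals.mean()),
                "p_value": pvalue,
            }
            row.update(_box_stats(vals))
            rows.append(row)
    return pd.DataFrame(rows)


def composition_table(otu_table: OtuTable, taxonomy: Taxonomy) -> pd.DataFrame:
    """Per sample and group: number of OTUs detected and percent of the
    sample's identified reads (the diet composition table layout).

    OTUs without a group mapping fall into "other" (logged).
    """
    groups = {}
    for otu in otu_table.otus:
        g = otu_table.group_of_otu.get(otu) or default_group(taxonomy, otu)
        if g == "other":
            log.warning("OTU %r has no group mapping; assigned 'other'", otu)
        groups[otu] = g
    all_groups = sorted(set(groups.values()))
    rows = []
    for sample in otu_table.samples:
        counts = otu_table.counts.loc[sample]
        total = counts.sum()
        for g in all_groups:
            members = [o for o in otu_table.otus if groups[o] == g]
            n_otus = int((counts[members] > 0).sum()) if members else 0
            reads = int(counts[members].sum()) if members else 0
            pct = 100.0 * reads / total if total > 0 else 0.0
            rows.append(
                {"sample_id": sample, "group": g, "n_otus": n_otus,
                 "reads": reads, "pct_reads": pct}
            )
    return pd.DataFrame(rows)
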