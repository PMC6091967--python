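"""Pipeline configuration.

The defaults encode the pipeline's operating rules: reads shorter than
124 bp after primer trimming are discarded, reads within 3 mismatches of
a cluster representative join that cluster, clusters of 10 reads or
fewer are dropped, and the identification threshold is the 99.9% quantile
of the reference tree's terminal branch lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# 26-bp COI minibarcode forward primer (Uni-MinibarF1); R = A/G.
DEFAULT_PRIMER = "TCCACTAATCACAARGATATTGGTAC"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass
class PipelineConfig:
    """Tunable knobs for preprocessing, placement and reporting.

    Attributes
    ----------
    primer_fwd:
        Forward primer clipped from the 5' end of every read (up to one
        mismatch tolerated; IUPAC ambiguity codes allowed in the primer).
    min_trimmed_len:
        Minimum read length, in bp, after primer removal.
    max_cluster_div:
        Maximum divergence (mismatches + length difference) between a read
        and its cluster representative.
    min_cluster_reads:
        Smallest cluster size kept; the default 11 discards clusters of
        10 reads or fewer.
    chimera_abundance_skew:
        A chimera candidate's parents must be at least this many times
        more abundant than the candidate.
    chimera_min_segment:
        Both parental segments of a chimeric model must span at least
        this many bp.
    chimera_min_advantage:
        Mismatch advantage (two-parent model vs. best single parent)
        required to call a bimera.
    chimera_max_model_div:
        Maximum divergence allowed between a candidate and its best
        two-parent model: a true bimera differs from the spliced parent
        model only by sequencing error, so this is capped at the
        clustering divergence.
    quantile_q:
        Quantile of the reference terminal branch-length distribution used
        as the pendant-length identification threshold.
    shannon_log_base:
        Log base for the Shannon index: "e", "2" or "10".
    seed:
        Seed for every stochastic component (simulation only; the
        analysis pipeline itself is deterministic).
    """

    primer_fwd: str = DEFAULT_PRIMER
    min_trimmed_len: int = 124
    max_cluster_div: int = 3
    min_cluster_reads: int = 11
    chimera_abundance_skew: float = 2.0
    chimera_min_segment: int = 20
    chimera_min_advantage: int = 3
    chimera_max_model_div: int = 3
    quantile_q: float = 0.999
    shannon_log_base: str = "e"
    seed: int = 0
    optimize_distal: bool = False
    model: str = "jc69"
    lwr_report_cutoff: float = 0.999

    def __post_init__(self) -> None:
        if self.min_trimmed_len < 1:
            raise ValueError("min_trimmed_len must be >= 1")
        if self.max_cluster_div < 0:
            raise ValueError("max_cluster_div must be >= 0")
        if self.min_cluster_reads < 1:
            raise ValueError("min_cluster_reads must be >= 1")
        if not (0.0 < self.quantile_q < 1.0):
            raise ValueError("quantile_q must lie in (0, 1)")
        if self.shannon_log_base not in {"e", "2", "10"}:
            raise ValueError("shannon_log_base must be one of 'e', '2', '10'")
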