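"""Trimming, clustering and chimera detection rules."""

import random

import pytest

from coidiet.config import PipelineConfig
from coidiet.preprocess import (
    ReadCluster,
    detect_chimeras,
    filter_small_clusters,
    greedy_cluster,
    sequence_divergence,
    trim_and_filter,
)
from coidiet.seqio import SequenceRecord

PRIMER = "ACGTACGTACGTACGTACGTACGTAC"  # 26 bp, unambiguous
CFG = PipelineConfig(primer_fwd=PRIMER)


def _read(i, bases, sample="s1"):
    return SequenceRecord(id=f"r{i}", bases=bases, sample_id=sample)


def _rand_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


# -- trim_and_filter --------------------------------------------------------

def test_trim_keeps_exact_boundary_length():
    insert = "A" * 124
    out = trim_and_filter([_read(0, PRIMER + insert)], CFG)
    assert len(out) == 1 and out[0].bases == insert


def test_trim_drops_123bp_insert():
    out = trim_and_filter([_read(0, PRIMER + "A" * 123)], CFG)
    assert out == []


def test_trim_drops_primerless_read_and_counts_it():
    stats = {}
    good = PRIMER + "C" * 130
    bad = "T" * 156  # no primer match
    out = trim_and_filter([_read(0, good), _read(1, bad)], CFG, stats=stats)
    assert [r.id for r in out] == ["r0"]
    assert stats["no_primer"] == 1 and stats["kept"] == 1


def test_trim_tolerates_one_primer_mismatch():
    mutated = "T" + PRIMER[1:]
    out = trim_and_filter([_read(0, mutated + "G" * 130)], CFG)
    assert len(out) == 1 and out[0].bases == "G" * 130


def test_trim_ambiguity_code_in_primer():
    cfg = PipelineConfig(primer_fwd="ARGT" + "ACGT" * 5)  # R matches A or G
    insert = "C" * 124
    assert len(trim_and_filter([_read(0, "AAGT" + "ACGT" * 5 + insert)], cfg)) == 1
    assert len(trim_and_filter([_read(1, "AGGT" + "ACGT" * 5 + insert)], cfg)) == 1


# -- greedy_cluster ---------------------------------------------------------

def test_identical_reads_form_one_cluster():
    reads = [_read(i, "ACGT" * 32) for i in range(20)]
    clusters = greedy_cluster(reads, CFG)
    assert len(clusters) == 1
    assert clusters[0].n_reads == 20


def test_four_mismatches_split_clusters():
    a = "A" * 130
    b = "T" * 4 + "A" * 126  # divergence 4 > 3
    clusters = greedy_cluster([_read(0, a), _read(1, b)], CFG)
    assert len(clusters) == 2


def test_three_mismatches_join_cluster():
    a = "A" * 130
    b = "T" * 3 + "A" * 127
    clusters = greedy_cluster([_read(0, a), _read(0.5, a), _read(1, b)], CFG)
    assert len(clusters) == 1
    assert clusters[0].representative == a


def test_empty_input():
    assert greedy_cluster([], CFG) == []


def _brute_force_greedy(seqs_with_ids, max_div):
    """Independent restatement of the clustering rule with plain loops."""
    from collections import Counter, OrderedDict

    mult = Counter(s for s, _ in seqs_with_ids)
    first = {}
    for idx, (s, _) in enumerate(seqs_with_ids):
        first.setdefault(s, idx)
    uniq = sorted(mult, key=lambda s: (-mult[s], first[s]))
    clusters = []  # list of (representative, [unique seqs])
    for s in uniq:
        for rep, members in clusters:
            if sequence_divergence(s, rep) <= max_div:
                members.append(s)
                break
        else:
            clusters.append((s, [s]))
    assignment = {}
    for rep, members in clusters:
        for m in members:
            assignment[m] = rep
    return assignment


def test_clustering_matches_brute_force_oracle():
    rng = random.Random(42)
    templates = [_rand_seq(rng, 130) for _ in range(3)]
    reads = []
    for i in range(30):
        t = list(templates[i % 3])
        if rng.random() < 0.7:  # up to one mutation
            pos = rng.randrange(130)
            t[pos] = rng.choice([b for b in "ACGT" if b != t[pos]])
        reads.append(_read(i, "".join(t)))
    clusters = greedy_cluster(reads, CFG)
    got = {}
    for c in clusters:
        for rid in c.member_ids:
            read = next(r for r in reads if r.id == rid)
            got[read.bases] = c.representative
    expected = _brute_force_greedy([(r.bases, r.id) for r in reads], CFG.max_cluster_div)
    assert got == expected


def test_read_conservation_and_determinism():
    rng = random.Random(7)
    reads = [_read(i, _rand_seq(rng, 128)) for i in range(100)]
    c1 = greedy_cluster(reads, CFG)
    c2 = greedy_cluster(reads, CFG)
    assert sum(c.n_reads for c in c1) == 100
    assert [(c.representative, sorted(c.member_ids)) for c in c1] == [
        (c.representative, sorted(c.member_ids)) for c in c2
    ]


def test_members_within_divergence_of_representative():
    rng = random.Random(8)
    base = _rand_seq(rng, 130)
    reads = []
    for i in range(50):
        t = list(base)
        for _ in range(rng.randrange(6)):
            pos = rng.randrange(130)
            t[pos] = rng.choice([b for b in "ACGT" if b != t[pos]])
        reads.append(_read(i, "".join(t)))
    for c in greedy_cluster(reads, CFG):
        for rid in c.member_ids:
            bases = next(r.bases for r in reads if r.id == rid)
            assert sequence_divergence(bases, c.representative) <= CFG.max_cluster_div


# -- filter_small_clusters --------------------------------------------------

@pytest.mark.parametrize("n_reads,kept", [(10, False), (11, True), (1, False)])
def test_small_cluster_threshold(n_reads, kept):
    c = ReadCluster(
        cluster_id="c0", sample_id="s", representative="A" * 130,
        member_ids=[f"r{i}" for i in range(n_reads)],
    )
    assert bool(filter_small_clusters([c], CFG)) is kept


def test_filter_small_empty_input():
    assert filter_small_clusters([], CFG) == []


# -- detect_chimeras --------------------------------------------------------

def _cluster(cid, rep, n, sample="s1"):
    return ReadCluster(
        cluster_id=cid, sample_id=sample, representative=rep,
        member_ids=[f"{cid}_m{i}" for i in range(n)],
    )


def test_planted_bimera_flagged():
    rng = random.Random(1)
    p1, p2 = _rand_seq(rng, 130), _rand_seq(rng, 130)
    chim = p1[:65] + p2[65:]
    clusters = [
        _cluster("p1", p1, 250), _cluster("p2", p2, 250), _cluster("c", chim, 25)
    ]
    detect_chimeras(clusters, CFG)
    flags = {c.cluster_id: c.chimera_flag for c in clusters}
    assert flags == {"p1": False, "p2": False, "c": True}


def test_cluster_identical_to_parent_never_flagged():
    rng = random.Random(2)
    p1, p2 = _rand_seq(rng, 130), _rand_seq(rng, 130)
    clusters = [
        _cluster("p1", p1, 250), _cluster("p2", p2, 250), _cluster("c", p1, 25)
    ]
    detect_chimeras(clusters, CFG)
    assert not any(c.chimera_flag for c in clusters)


def _exhaustive_bimera_oracle(clusters, cfg):
    """Exhaustive restatement of the bimera rule: all ordered parent
    pairs x breakpoints, with plain string slicing."""
    flags = {}
    for cand in clusters:
        parents = [
            p for p in clusters
            if p is not cand and p.n_reads >= cfg.chimera_abundance_skew * cand.n_reads
        ]
        flagged = False
        if len(parents) >= 2:
            best_single = min(
                sequence_divergence(cand.representative, p.representative)
                for p in parents
            )
            L = len(cand.representative)
            for pa in parents:
                for pb in parents:
                    if pa is pb:
                        continue
                    for k in range(cfg.chimera_min_segment, L - cfg.chimera_min_segment + 1):
                        model = pa.representative[:k] + pb.representative[k:]
                        d = sequence_divergence(cand.representative, model)
                        if (
                            d <= best_single - cfg.chimera_min_advantage
                            and d <= cfg.chimera_max_model_div
                        ):
                            flagged = True
                            break
                    if flagged:
                        break
                if flagged:
                    break
        flags[cand.cluster_id] = flagged
    return flags


def test_chimera_flags_match_exhaustive_oracle():
    rng = random.Random(9)
    templates = [_rand_seq(rng, 130) for _ in range(8)]
    clusters = []
    for i, t in enumerate(templates):
        clusters.append(_cluster(f"t{i}", t, rng.randrange(150, 400)))
    for i in range(37):  # noise clusters: mutated copies of templates
        t = list(rng.choice(templates))
        for _ in range(rng.randrange(10)):
            pos = rng.randrange(130)
            t[pos] = rng.choice([b for b in "ACGT" if b != t[pos]])
        clusters.append(_cluster(f"n{i}", "".join(t), rng.randrange(11, 60)))
    for i in range(5):  # planted bimeras from abundant parents
        a, b = rng.sample(range(8), 2)
        k = rng.randrange(30, 100)
        chim = templates[a][:k] + templates[b][k:]
        clusters.append(_cluster(f"x{i}", chim, rng.randrange(11, 40)))
    assert len(clusters) == 50
    detect_chimeras(clusters, CFG)
    got = {c.cluster_id: c.chimera_flag for c in clusters}
    assert got == _exhaustive_bimera_oracle(clusters, CFG)
    assert all(got[f"x{i}"] for i in range(5))


def test_chimera_pooling_is_sample_order_independent():
    rng = random.Random(3)
    p1, p2 = _rand_seq(rng, 130), _rand_seq(rng, 130)
    chim = p1[:60] + p2[60:]
    def build():
        return [
            _cluster("a", p1, 300, sample="s1"),
            _cluster("b", p2, 280, sample="s2"),
            _cluster("c", chim, 20, sample="s3"),
        ]
    one = build()
    detect_chimeras(one, CFG)
    two = build()[::-1]
    detect_chimeras(two, CFG)
    f1 = {c.cluster_id: c.chimera_flag for c in one}
    f2 = {c.cluster_id: c.chimera_flag for c in two}
    assert f1 == f2 == {"a": False, "b": False, "c": True}
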