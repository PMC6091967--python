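"""Synthetic data with ground truth for exercising every pipeline stage.

The generator emulates the study's inputs at desk scale: a reference
database (Yule tree, JC69-evolved minibarcode sequences, clade-derived
taxonomy), and per-sample read sets containing target reads (reference
species plus per-base sequencing error), contaminant reads (evolved
from a distant outgroup, stressing the pendant-length filter the way
decomposer/eDNA sequences do), and chimeric reads spliced from two
templates. Every read is covered by a truth record.

All simulators are deterministic given their seed; stochastic helpers
take an explicit numpy Generator.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import dendropy
import numpy as np

from .config import DEFAULT_PRIMER
from .placement import SubstitutionModel
from .refdb import ReferenceDB, TaxonRecord, Taxonomy
from .seqio import SequenceRecord, read_table
from .tree import PhyloTree, TreeNode, read_newick

__all__ = [
    "SimTruth",
    "simulate_reference_db",
    "evolve_sequence",
    "simulate_sample",
    "table1_fixture",
]

_BASES = "ACGT"

# default scale: expected root-to-tip height ~ ln(n)/birth_rate in
# substitutions/site, giving congener-level divergence between sisters
DEFAULT_BIRTH_RATE = 10.0
CONTAMINANT_DIVERGENCE = 1.5  # subst/site from the reference root


@dataclass
class SimTruth:
    """Ground truth for a simulation run."""

    read_origin: dict[str, tuple] = field(default_factory=dict)
    # sample -> species -> number of target reads
    composition: dict[str, dict[str, int]] = field(default_factory=dict)
    root_sequence: Optional[str] = None
    leaf_sequences: dict[str, str] = field(default_factory=dict)
    outgroup_sequences: list[str] = field(default_factory=list)


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(_BASES), size=length))


def evolve_sequence(
    parent_bases: str,
    branch_length: float,
    model: Optional[SubstitutionModel] = None,
    rng: Optional[np.random.Generator] = None,
) -> str:
    """Evolve a sequence along a branch by per-site substitution.

    Under JC69 a site leaves its current state with probability
    (3/4)(1 - exp(-4t/3)) and then picks one of the other three bases
    uniformly. Branch length 0 returns an identical copy.
    """
    if branch_length < 0:
        raise ValueError("branch length must be >= 0")
    if rng is None:
        rng = np.random.default_rng()
    if branch_length == 0:
        return parent_bases
    model = model or SubstitutionModel.jc69()
    P = model.transition_matrix(branch_length)
    codes = np.frombuffer(parent_bases.encode(), dtype=np.uint8)
    idx = np.empty(len(parent_bases), dtype=np.int64)
    for i, b in enumerate(_BASES):
        idx[codes == ord(b)] = i
    u = rng.random(len(idx))
    cum = np.cumsum(P, axis=1)
    child_idx = (u[:, None] > cum[idx]).sum(axis=1)
    return "".join(_BASES[i] for i in child_idx)


def _yule_tree(n_species: int, birth_rate: float, seed: int) -> PhyloTree:
    rng = random.Random(seed)
    t = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_species,
        rng=rng,
    )
    # the generator stops at the n-th speciation, leaving the newest sister
    # tips with zero-length edges; extend every tip by the waiting time to
    # the next (discarded) speciation so terminal branches stay positive
    stem = rng.expovariate(n_species * birth_rate)
    for leaf in t.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + stem
    t.seed_node.edge.length = None
    newick = t.as_string(schema="newick", suppress_rooting=True).strip()
    return read_newick(newick)


def _clades_at(tree: PhyloTree, k: int) -> list[TreeNode]:
    """Split the tree at its k-1 shallowest internal nodes, returning the
    roots of the resulting k clades (deepest k clades)."""
    depths = {}
    for node in tree.preorder():
        depths[node] = (0.0 if node.parent is None else depths[node.parent]) + (
            node.length or 0.0
        )
    frontier = [tree.root]
    while len(frontier) < k:
        internals = [n for n in frontier if not n.is_leaf]
        if not internals:
            break
        shallowest = min(internals, key=lambda n: depths[n])
        frontier.remove(shallowest)
        frontier.extend(shallowest.children)
    return frontier


def _leaves_under(node: TreeNode) -> list[TreeNode]:
    out, stack = [], [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n)
        else:
            stack.extend(n.children)
    return out


def simulate_reference_db(
    n_species: int = 50,
    seq_len: int = 130,
    birth_rate: float = DEFAULT_BIRTH_RATE,
    seed: int = 0,
    n_orders: Optional[int] = None,
) -> tuple[ReferenceDB, SimTruth]:
    """A synthetic reference: Yule tree, JC69 sequences, clade taxonomy.

    Orders are the deepest ``n_orders`` clades (default ~ n/12, at least
    2); genera are shallow clades of up to 3 leaves within each order;
    families group pairs of genera. Deterministic given the seed.
    """
    if n_species < 4:
        raise ValueError("need at least 4 species")
    if seq_len < 60:
        raise ValueError("need at least 60 sites")
    tree = _yule_tree(n_species, birth_rate, seed)
    rng = np.random.default_rng(seed)
    model = SubstitutionModel.jc69()

    root_seq = _random_sequence(seq_len, rng)
    seqs: dict[TreeNode, str] = {tree.root: root_seq}
    for node in tree.preorder():
        if node.parent is not None:
            seqs[node] = evolve_sequence(seqs[node.parent], node.length or 0.0, model, rng)

    # a curated species-level reference must be diagnosable: if two tips
    # end up with identical minibarcodes (likely for the closest sisters
    # at this locus length), nudge one site so every species is distinct
    seen: dict[str, TreeNode] = {}
    for leaf in tree.leaves():
        while seqs[leaf] in seen and seen[seqs[leaf]] is not leaf:
            pos = int(rng.integers(seq_len))
            old = seqs[leaf][pos]
            new = _BASES[int(rng.integers(4))]
            if new != old:
                seqs[leaf] = seqs[leaf][:pos] + new + seqs[leaf][pos + 1:]
        seen[seqs[leaf]] = leaf

    if n_orders is None:
        n_orders = max(2, n_species // 12)
    order_clades = _clades_at(tree, n_orders)
    records: list[TaxonRecord] = []
    alignment: dict[str, str] = {}
    genus_counter = 0
    for oi, clade in enumerate(order_clades):
        order_name = f"Order{oi + 1}"
        # genera: greedy split of the clade into subtrees of <= 3 leaves
        genera: list[list[TreeNode]] = []
        stack = [clade]
        while stack:
            n = stack.pop()
            lv = _leaves_under(n)
            if len(lv) <= 3 or n.is_leaf:
                genera.append(lv)
            else:
                stack.extend(n.children)
        genera.sort(key=lambda lv: min(leaf.name or "" for leaf in lv))
        for gi, leaf_group in enumerate(genera):
            genus_counter += 1
            genus = f"Genus{genus_counter:03d}"
            family = f"Family{(genus_counter + 1) // 2:03d}"
            for si, leaf in enumerate(sorted(leaf_group, key=lambda l: l.name or "")):
                species = f"{genus} species{si + 1}"
                leaf.name = species
                records.append(
                    TaxonRecord(
                        species=species, genus=genus, family=family,
                        order=order_name, phylum="Arthropoda",
                    )
                )
    for leaf in tree.leaves():
        alignment[leaf.name] = seqs[leaf]
    truth = SimTruth(
        root_sequence=root_seq,
        leaf_sequences=dict(alignment),
    )
    refdb = ReferenceDB(
        alignment=alignment, tree=tree, taxonomy=Taxonomy(records), n_columns=seq_len
    )
    return refdb, truth


def _mutate(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = list(seq)
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for i in hits:
        choices = [b for b in _BASES if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def simulate_sample(
    refdb: ReferenceDB,
    composition: dict[str, float],
    n_reads: int = 1000,
    error_rate: float = 0.005,
    contam_frac: float = 0.10,
    chimera_frac: float = 0.05,
    seed: int = 0,
    sample_id: str = "sample1",
    primer: str = DEFAULT_PRIMER,
    ref_truth: Optional[SimTruth] = None,
) -> tuple[list[SequenceRecord], SimTruth]:
    """One fecal sample's reads: targets, contaminants and chimeras.

    Target reads are drawn from *composition* (species -> weight) with a
    per-base substitution error; contaminants come from outgroup
    sequences at ``CONTAMINANT_DIVERGENCE`` subst/site from the
    reference root; chimeras splice two reference templates at a random
    interior breakpoint. The primer is prepended so primer trimming
    applies. Exactly ``n_reads`` reads are emitted and covered by truth.
    """
    unknown = [sp for sp in composition if sp not in refdb.alignment]
    if unknown:
        raise ValueError(f"composition references unknown species: {unknown}")
    if not (0.0 <= contam_frac + chimera_frac <= 1.0):
        raise ValueError("contaminant and chimera fractions must sum to <= 1")
    rng = np.random.default_rng(seed)
    model = SubstitutionModel.jc69()

    primer_concrete = "".join(
        c if c in _BASES else "ACGT"[rng.integers(4)] for c in primer.upper()
    )
    templates = {sp: refdb.alignment[sp].replace("-", "") for sp in composition}

    n_contam = int(round(contam_frac * n_reads))
    n_chim = int(round(chimera_frac * n_reads))
    n_target = n_reads - n_contam - n_chim

    weights = np.array([composition[sp] for sp in composition], dtype=float)
    weights /= weights.sum()
    species = list(composition)
    target_counts = rng.multinomial(n_target, weights)

    root_seq = ref_truth.root_sequence if ref_truth else None
    if root_seq is None:
        root_seq = next(iter(refdb.alignment.values())).replace("-", "")
    outgroups = [
        evolve_sequence(root_seq, CONTAMINANT_DIVERGENCE, model, rng) for _ in range(2)
    ]

    chim_templates = []
    if n_chim > 0:
        seg_min = 20
        pool = species if len(species) >= 2 else list(refdb.alignment)
        for _ in range(max(1, n_chim // 25)):
            p1, p2 = rng.choice(pool, size=2, replace=False)
            s1, s2 = templates.get(p1) or refdb.alignment[p1].replace("-", ""), \
                templates.get(p2) or refdb.alignment[p2].replace("-", "")
            L = min(len(s1), len(s2))
            k = int(rng.integers(seg_min, L - seg_min))
            chim_templates.append((s1[:k] + s2[k:], p1, p2, k))

    truth = SimTruth(
        composition={sample_id: {sp: int(c) for sp, c in zip(species, target_counts)}},
        root_sequence=root_seq,
        outgroup_sequences=list(outgroups),
    )
    reads: list[SequenceRecord] = []

    def emit(insert: str, origin: tuple) -> None:
        rid = f"{sample_id}_r{len(reads):06d}"
        bases = primer_concrete + _mutate(insert, error_rate, rng)
        reads.append(
            SequenceRecord(
                id=rid, bases=bases, sample_id=sample_id,
                qualities=[40] * len(bases),
            )
        )
        truth.read_origin[rid] = origin

    for sp, count in zip(species, target_counts):
        for _ in range(count):
            emit(templates[sp], ("target", sp))
    for i in range(n_contam):
        og = i % len(outgroups)
        emit(outgroups[og], ("contaminant", f"outgroup{og}"))
    for i in range(n_chim):
        tmpl, p1, p2, k = chim_templates[i % len(chim_templates)]
        emit(tmpl, ("chimera", (p1, p2, k)))

    assert len(reads) == n_reads
    return reads, truth


_TABLE1_SCHEMA = {
    "sample": str,
    "fresh": lambda v: v == "yes",
    "date": str,
    "river": str,
    "system": str,
    "region": str,
    "reads": int,
    "pct_target": float,
    "otus": int,
    "shannon": float,
}


def table1_fixture() -> list[dict]:
    """The published 41-sample summary table, as typed records."""
    ref = resources.files("coidiet.data").joinpath("table1.tsv")
    with resources.as_file(ref) as path:
        return read_table(path, schema=_TABLE1_SCHEMA)
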