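"""Maximum-likelihood placement of aligned queries on the fixed
reference tree (EPA-style).

For every edge of the reference tree the query is attached by a new
node splitting the edge (at the midpoint by default; optionally the
attachment position is optimized) and the pendant branch length is
optimized by bounded 1-D likelihood maximization. Per-edge
log-likelihoods are normalized into like-weight ratios. The machinery
is the standard pruning (inside) / outside decomposition: conditional
likelihoods toward the leaves (D) and away from the attachment edge (A)
are precomputed once per reference, so each query costs one 4-vector
product per edge per likelihood evaluation.

Branch lengths are expected substitutions per site throughout. Gaps and
ambiguity codes are treated as missing data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .config import PipelineConfig
from .errors import ValidationError
from .refdb import ReferenceDB
from .seqio import JplaceDocument, PlacementEntry, QueryPlacement
from .tree import PhyloTree, TreeNode

log = logging.getLogger(__name__)

__all__ = [
    "SubstitutionModel",
    "Placement",
    "edge_numbering",
    "compute_loglik",
    "place_query",
    "build_jplace",
    "PlacementEngine",
]

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}
PENDANT_MAX = 5.0  # subst/site; beyond saturation for any 4-state model
_PENDANT_XATOL = 1e-6


# ---------------------------------------------------------------------------
# substitution models
# ---------------------------------------------------------------------------

@dataclass
class SubstitutionModel:
    """JC69 or GTR, scaled so branch lengths are expected subst/site."""

    kind: str = "jc69"
    exchangeabilities: Optional[np.ndarray] = None  # 6 values: AC,AG,AT,CG,CT,GT
    freqs: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    _eig: Optional[tuple] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if not np.isclose(self.freqs.sum(), 1.0):
            raise ValueError("base frequencies must sum to 1")
        if self.kind == "gtr":
            if self.exchangeabilities is None:
                raise ValueError("GTR requires 6 exchangeabilities")
            self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
            if np.any(self.exchangeabilities <= 0):
                raise ValueError("exchangeabilities must be > 0")
        elif self.kind != "jc69":
            raise ValueError(f"unknown model kind {self.kind!r}")

    @classmethod
    def jc69(cls) -> "SubstitutionModel":
        return cls(kind="jc69")

    @classmethod
    def gtr(cls, exchangeabilities, freqs) -> "SubstitutionModel":
        return cls(kind="gtr", exchangeabilities=exchangeabilities, freqs=freqs)

    def _eigen(self):
        if self._eig is None:
            r = self.exchangeabilities
            pi = self.freqs
            R = np.zeros((4, 4))
            pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
            for val, (i, j) in zip(r, pairs):
                R[i, j] = R[j, i] = val
            Q = R * pi[None, :]
            np.fill_diagonal(Q, 0.0)
            np.fill_diagonal(Q, -Q.sum(axis=1))
            # scale to one expected substitution per unit branch length
            mu = -(pi * np.diag(Q)).sum()
            Q /= mu
            sq = np.sqrt(pi)
            S = (Q * sq[:, None]) / sq[None, :]
            w, U = np.linalg.eigh((S + S.T) / 2.0)
            self._eig = (w, U, sq)
        return self._eig

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t): rows = ancestral state, columns = descendant state."""
        if t < 0:
            raise ValueError("branch length must be >= 0")
        if self.kind == "jc69":
            e = np.exp(-4.0 * t / 3.0)
            same = 0.25 + 0.75 * e
            diff = 0.25 - 0.25 * e
            P = np.full((4, 4), diff)
            np.fill_diagonal(P, same)
            return P
        w, U, sq = self._eigen()
        E = U @ np.diag(np.exp(w * t)) @ U.T
        return (E / sq[:, None]) * sq[None, :]


def default_model(config: Optional[PipelineConfig] = None) -> SubstitutionModel:
    if config is not None and config.model == "gtr":
        # empirical-frequency GTR with unit exchangeabilities unless the
        # caller supplies a fitted model explicitly
        return SubstitutionModel.gtr(np.ones(6), np.full(4, 0.25))
    return SubstitutionModel.jc69()


# ---------------------------------------------------------------------------
# edge numbering and basic likelihood
# ---------------------------------------------------------------------------

def edge_numbering(tree: PhyloTree) -> PhyloTree:
    """Assign deterministic 0-based postorder edge numbers in place."""
    num = 0
    for node in tree.postorder():
        if node.parent is not None:
            node.edge_num = num
            num += 1
    return tree


def encode_sequence(seq: str) -> np.ndarray:
    """(L, 4) conditional-likelihood rows; gaps/N/ambiguity -> all-ones."""
    arr = np.ones((len(seq), 4))
    for i, c in enumerate(seq.upper()):
        j = _CODE.get(c)
        if j is not None:
            arr[i] = 0.0
            arr[i, j] = 1.0
    return arr


def _down_partials(
    tree: PhyloTree, alignment: dict[str, str], model: SubstitutionModel
) -> tuple[dict, dict]:
    """Felsenstein pruning with per-site rescaling.

    Returns (D, logscale): per node an (L,4) conditional likelihood of the
    subtree below it, and the per-site log of the factored-out scalers.
    """
    D: dict[TreeNode, np.ndarray] = {}
    S: dict[TreeNode, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            D[node] = encode_sequence(alignment[node.name])
            S[node] = np.zeros(D[node].shape[0])
        else:
            part = None
            scale = None
            for child in node.children:
                P = model.transition_matrix(child.length or 0.0)
                contrib = D[child] @ P.T
                part = contrib if part is None else part * contrib
                scale = S[child] if scale is None else scale + S[child]
            mx = part.max(axis=1)
            mx = np.where(mx > 0, mx, 1.0)
            D[node] = part / mx[:, None]
            S[node] = scale + np.log(mx)
    return D, S


def compute_loglik(
    tree: PhyloTree, alignment: dict[str, str], model: SubstitutionModel
) -> float:
    """Total log-likelihood of the alignment on the tree (pruning).

    Missing data (gaps, N) are marginalized. Column counts must agree and
    alignment keys must equal the leaf set.
    """
    labels = set(tree.leaf_labels())
    if labels != set(alignment):
        raise ValidationError("alignment keys do not match tree leaves")
    lengths = {len(v) for v in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("alignment rows have unequal lengths")
    if lengths.pop() == 0:
        raise ValueError("zero-length alignment")
    D, S = _down_partials(tree, alignment, model)
    root = tree.root
    site_l = D[root] @ model.freqs
    return float(np.sum(np.log(site_l) + S[root]))


# ---------------------------------------------------------------------------
# placement engine
# ---------------------------------------------------------------------------

@dataclass
class Placement:
    query_id: str
    edge_num: int
    log_likelihood: float
    like_weight_ratio: float
    pendant_length: float
    distal_length: float
    edge_length: float = 0.0


class PlacementEngine:
    """Per-reference precomputation shared by all queries.

    For each edge (u, v) (identified with its child node v) and a split
    of the edge length into a distal part d_v (attachment -> v) and the
    remainder d_u (attachment -> u), the per-site likelihood of the tree
    with the query q attached by a pendant branch t_p is

        L_s = sum_x pi_x [P(d_v) D_v]_sx [P(d_u) A_v]_sx [P(t_p) q]_sx

    where D_v is the inside (subtree) conditional and A_v the outside
    conditional of the edge; time-reversibility lets the root be moved to
    the attachment point.
    """

    def __init__(
        self,
        refdb: ReferenceDB,
        model: Optional[SubstitutionModel] = None,
        config: Optional[PipelineConfig] = None,
    ):
        self.refdb = refdb
        self.config = config or PipelineConfig()
        self.model = model or default_model(self.config)
        self.tree = refdb.tree
        edge_numbering(self.tree)
        self.n_sites = refdb.n_columns

        D, DS = _down_partials(self.tree, refdb.alignment, self.model)
        self._D, self._DS = D, DS

        # outside conditionals, indexed by the edge's child node
        A: dict[TreeNode, np.ndarray] = {}
        AS: dict[TreeNode, np.ndarray] = {}
        for node in self.tree.preorder():
            for child in node.children:
                sib_part = None
                sib_scale = np.zeros(self.n_sites)
                for sib in node.children:
                    if sib is child:
                        continue
                    P = self.model.transition_matrix(sib.length or 0.0)
                    contrib = D[sib] @ P.T
                    sib_part = contrib if sib_part is None else sib_part * contrib
                    sib_scale = sib_scale + DS[sib]
                if node.parent is None:
                    above_part = np.ones((self.n_sites, 4))
                    above_scale = np.zeros(self.n_sites)
                else:
                    P = self.model.transition_matrix(node.length or 0.0)
                    above_part = A[node] @ P.T  # sum over parent states
                    above_scale = AS[node]
                part = above_part if sib_part is None else above_part * sib_part
                scale = above_scale + sib_scale
                mx = part.max(axis=1)
                mx = np.where(mx > 0, mx, 1.0)
                A[child] = part / mx[:, None]
                AS[child] = scale + np.log(mx)
        self._A, self._AS = A, AS

        self.edge_nodes: list[TreeNode] = sorted(
            self.tree.edges(), key=lambda n: n.edge_num
        )
        # midpoint surroundings, precomputed once
        self._W: dict[int, np.ndarray] = {}
        self._WS: dict[int, np.ndarray] = {}
        for v in self.edge_nodes:
            W, WS = self._surroundings(v, (v.length or 0.0) / 2.0)
            self._W[v.edge_num] = W
            self._WS[v.edge_num] = WS

    def _surroundings(self, v: TreeNode, distal: float):
        """pi-weighted product of both edge-side conditionals at the
        attachment point sitting *distal* above node v."""
        t = v.length or 0.0
        distal = min(max(distal, 0.0), t)
        Pv = self.model.transition_matrix(distal)
        Pu = self.model.transition_matrix(t - distal)
        W = (self._D[v] @ Pv.T) * (self._A[v] @ Pu.T) * self.model.freqs[None, :]
        return W, self._DS[v] + self._AS[v]

    def _loglik_given(self, W: np.ndarray, WS: np.ndarray, q: np.ndarray, pendant: float) -> float:
        if self.model.kind == "jc69":
            e = np.exp(-4.0 * pendant / 3.0)
            b = 0.25 - 0.25 * e
            qs = q.sum(axis=1, keepdims=True)
            Pq = b * qs + e * q
        else:
            Pq = q @ self.model.transition_matrix(pendant).T
        site = (W * Pq).sum(axis=1)
        # a hard state conflict (zero-length branches) gives site likelihood 0;
        # floor it so the log stays finite and the edge simply scores very low
        return float(np.sum(np.log(np.maximum(site, 1e-300)) + WS))

    def place(self, query_id: str, aligned_query: str) -> list[Placement]:
        if len(aligned_query) != self.n_sites:
            raise ValidationError(
                f"query {query_id!r}: {len(aligned_query)} columns, "
                f"reference has {self.n_sites}"
            )
        q = encode_sequence(aligned_query)
        results = []
        for v in self.edge_nodes:
            t = v.length or 0.0
            if self.config.optimize_distal and t > 0:
                ll, pendant, distal = self._optimize_2d(v, q)
            else:
                W, WS = self._W[v.edge_num], self._WS[v.edge_num]
                ll, pendant = self._optimize_pendant(W, WS, q)
                distal = t / 2.0
            results.append((ll, v.edge_num, pendant, distal, t))

        lls = np.array([r[0] for r in results])
        lwr = np.exp(lls - lls.max())
        lwr /= lwr.sum()
        placements = [
            Placement(
                query_id=query_id,
                edge_num=edge,
                log_likelihood=ll,
                like_weight_ratio=float(w),
                pendant_length=pendant,
                distal_length=distal,
                edge_length=t,
            )
            for (ll, edge, pendant, distal, t), w in zip(results, lwr)
        ]
        placements.sort(key=lambda p: (-p.log_likelihood, p.edge_num))
        return placements

    def _optimize_pendant(self, W, WS, q) -> tuple[float, float]:
        res = minimize_scalar(
            lambda t: -self._loglik_given(W, WS, q, t),
            bounds=(0.0, PENDANT_MAX),
            method="bounded",
            options={"xatol": _PENDANT_XATOL},
        )
        best_t, best_ll = float(res.x), -float(res.fun)
        ll0 = self._loglik_given(W, WS, q, 0.0)
        if ll0 >= best_ll:
            return ll0, 0.0
        return best_ll, best_t

    def _optimize_2d(self, v: TreeNode, q) -> tuple[float, float, float]:
        t = v.length or 0.0

        def neg_best_ll_at(distal: float) -> float:
            W, WS = self._surroundings(v, distal)
            ll, _ = self._optimize_pendant(W, WS, q)
            return -ll

        res = minimize_scalar(
            neg_best_ll_at, bounds=(0.0, t), method="bounded",
            options={"xatol": max(t * 1e-4, 1e-8)},
        )
        candidates = [float(res.x), 0.0, t, t / 2.0]
        best = None
        for d in candidates:
            W, WS = self._surroundings(v, d)
            ll, pendant = self._optimize_pendant(W, WS, q)
            if best is None or ll > best[0]:
                best = (ll, pendant, d)
        return best


def place_query(
    aligned_query: str,
    refdb: ReferenceDB,
    model: Optional[SubstitutionModel] = None,
    config: Optional[PipelineConfig] = None,
    query_id: str = "query",
) -> list[Placement]:
    """Place one aligned query on every edge of the reference tree.

    Returns placements sorted by log-likelihood descending (ties broken
    by smallest edge number); empty list for an unalignable query
    (``aligned_query`` is None).
    """
    if aligned_query is None:
        return []
    engine = _engine_for(refdb, model, config)
    return engine.place(query_id, aligned_query)


def _engine_for(refdb, model, config) -> PlacementEngine:
    cache = getattr(refdb, "_engine_cache", None)
    key = (
        id(model) if model is not None else None,
        (config.model, config.optimize_distal) if config is not None else None,
    )
    if cache is not None and cache[0] == key:
        return cache[1]
    engine = PlacementEngine(refdb, model=model, config=config)
    refdb._engine_cache = (key, engine)  # type: ignore[attr-defined]
    return engine


def build_jplace(
    placements_by_query: dict[str, list[Placement]],
    refdb: ReferenceDB,
    config: Optional[PipelineConfig] = None,
) -> JplaceDocument:
    """Assemble a jplace v3 document.

    Per query, entries are reported in LWR-descending order until the
    accumulated LWR reaches the reporting cutoff (default 0.999).
    """
    config = config or PipelineConfig()
    edge_numbering(refdb.tree)
    qplacements = []
    for query_id, placements in placements_by_query.items():
        if not placements:
            continue
        ordered = sorted(placements, key=lambda p: (-p.like_weight_ratio, p.edge_num))
        entries: list[PlacementEntry] = []
        acc = 0.0
        for p in ordered:
            entries.append(
                PlacementEntry(
                    edge_num=p.edge_num,
                    likelihood=p.log_likelihood,
                    like_weight_ratio=min(p.like_weight_ratio, 1.0),
                    distal_length=p.distal_length,
                    pendant_length=p.pendant_length,
                )
            )
            acc += p.like_weight_ratio
            if acc >= config.lwr_report_cutoff:
                break
        qplacements.append(
            QueryPlacement(name=query_id, multiplicity=1.0, entries=entries)
        )
    doc = JplaceDocument(
        tree=refdb.tree,
        placements=qplacements,
        version=3,
        metadata={"invocation": "coidiet placement"},
    )
    doc.validate()
    return doc
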