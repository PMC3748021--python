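"""Semi-supervised label propagation over image-similarity graphs.

Images are nodes; a subset carries hardened EEG-based labels (1 = target,
0 = distractor).  Per feature space, every node connects to its K nearest
labeled and K nearest unlabeled neighbors (Euclidean distance); arcs carry
Gaussian-kernel weights with a median-heuristic bandwidth.  Per-space
graphs merge with equal contribution (arithmetic-mean weights, absent arc
= 0).  Labels spread by minimizing the weighted quadratic disagreement
sum_ij w_ij (f_i - f_j)^2 with the labeled nodes clamped -- the harmonic
(Gaussian-field) solution, computed by a direct sparse linear solve.  By
the maximum principle, all propagated values lie in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse import csgraph
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

__all__ = [
    "LabeledGraph",
    "PropagationResult",
    "build_graph",
    "merge_graphs",
    "balance_labels",
    "propagate",
]


@dataclass
class LabeledGraph:
    """Weighted symmetric image-similarity graph with a labeled node subset.

    ``weights`` is a symmetric sparse matrix aligned with ``node_ids``
    (zero diagonal, entries in (0, 1]).  ``labels`` maps a labeled node id
    to its hard label in {0, 1}.  ``space`` records the originating feature
    space, or ``"joint"`` after merging.
    """

    node_ids: np.ndarray
    weights: sparse.csr_matrix
    labels: dict[int, int]
    space: str = "joint"

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids)
        n = len(self.node_ids)
        if self.weights.shape != (n, n):
            raise ValueError("weight matrix does not match node count")
        unknown = set(self.labels) - set(self.node_ids.tolist())
        if unknown:
            raise ValueError(f"labeled ids not in graph: {sorted(unknown)[:5]}")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def index_of(self, ids: np.ndarray) -> np.ndarray:
        order = np.argsort(self.node_ids)
        pos = np.searchsorted(self.node_ids, ids, sorter=order)
        return order[pos]


@dataclass
class PropagationResult:
    """Soft labels per node (clamped nodes keep their hard values exactly)."""

    node_ids: np.ndarray
    values: np.ndarray           # in [0, 1], aligned with node_ids
    clamped: np.ndarray          # bool mask
    unreachable: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def as_dict(self) -> dict[int, float]:
        return dict(zip(self.node_ids.tolist(), self.values.tolist()))


def build_graph(features: np.ndarray, node_ids: np.ndarray,
                labeled_ids: np.ndarray, hard_labels: np.ndarray,
                k: int = 5, space: str = "space") -> LabeledGraph:
    """Build a K-nearest-neighbor similarity graph for one feature space.

    Every node gets directed arcs to its ``k`` nearest labeled and ``k``
    nearest unlabeled neighbors; the graph is then symmetrized by union
    (keeping the larger weight, which is identical for both directions of a
    pair).  Weights are ``exp(-d^2 / sigma^2)`` with ``sigma`` the median of
    all selected neighbor distances.
    """
    features = np.asarray(features, dtype=np.float64)
    node_ids = np.asarray(node_ids)
    if len(np.unique(node_ids)) != len(node_ids):
        raise ValueError("duplicate node ids")
    n = len(node_ids)
    if features.shape[0] != n:
        raise ValueError("feature rows must align with node_ids")
    id_to_idx = {int(i): k_ for k_, i in enumerate(node_ids)}
    labeled_idx = np.array([id_to_idx[int(i)] for i in labeled_ids], dtype=int)
    if len(np.unique(labeled_idx)) != len(labeled_idx):
        raise ValueError("duplicate labeled ids")
    labeled_mask = np.zeros(n, dtype=bool)
    labeled_mask[labeled_idx] = True
    unlabeled_idx = np.flatnonzero(~labeled_mask)
    if len(labeled_idx) < k:
        raise ValueError(
            f"only {len(labeled_idx)} labeled nodes for K={k}; lower K"
        )
    if len(unlabeled_idx) < k + 1:
        raise ValueError(
            f"only {len(unlabeled_idx)} unlabeled nodes for K={k}; lower K"
        )

    rows, cols, dists = [], [], []
    # arcs from every node to its k nearest labeled / unlabeled neighbors
    for cand_idx in (labeled_idx, unlabeled_idx):
        dist = cdist(features[cand_idx], features)  # candidates x all nodes
        # a node never counts as its own neighbor
        in_cand = np.full(n, -1, dtype=int)
        in_cand[cand_idx] = np.arange(len(cand_idx))
        has_self = np.flatnonzero(in_cand >= 0)
        dist[in_cand[has_self], has_self] = np.inf
        kk = min(k, len(cand_idx))
        order = np.argpartition(dist, kth=kk - 1, axis=0)[:kk]
        col_idx = np.broadcast_to(np.arange(n), order.shape)
        rows.append(col_idx.ravel())
        cols.append(cand_idx[order.ravel()])
        dists.append(dist[order.ravel(), col_idx.ravel()])

    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    dists = np.concatenate(dists)
    keep = np.isfinite(dists) & (rows != cols)
    rows, cols, dists = rows[keep], cols[keep], dists[keep]

    sigma = float(np.median(dists))
    if sigma <= 0:
        positive = dists[dists > 0]
        sigma = float(np.median(positive)) if positive.size else 1.0
    w = np.exp(-(dists / sigma) ** 2)

    W = sparse.coo_matrix((w, (rows, cols)), shape=(n, n)).tocsr()
    W = W.maximum(W.T)          # union symmetrization (weights are symmetric)
    W.setdiag(0.0)
    W.eliminate_zeros()

    labels = {int(i): int(l) for i, l in zip(labeled_ids, hard_labels)}
    return LabeledGraph(node_ids=node_ids, weights=W, labels=labels, space=space)


def merge_graphs(graphs: list[LabeledGraph]) -> LabeledGraph:
    """Merge per-feature-space graphs with equal contribution.

    The joint arc set is the union; a joint weight is the arithmetic mean
    of the per-space weights, counting an absent arc as 0.
    """
    if not graphs:
        raise ValueError("no graphs to merge")
    first = graphs[0]
    for g in graphs[1:]:
        if not np.array_equal(g.node_ids, first.node_ids):
            raise ValueError("graphs have different node sets")
        if g.labels != first.labels:
            raise ValueError("graphs have different labeled sets")
    W = sum(g.weights for g in graphs) / len(graphs)
    return LabeledGraph(node_ids=first.node_ids.copy(), weights=W.tocsr(),
                        labels=dict(first.labels), space="joint")


def balance_labels(labels: dict[int, int], rng: np.random.Generator
                   ) -> dict[int, int]:
    """Undersample the majority class to equal class counts.

    The minority class is kept intact; majority-class entries are removed
    uniformly at random.  Raises when a class is absent (propagation from a
    one-class labeled set would be vacuous).
    """
    ids = np.array(sorted(labels))
    vals = np.array([labels[int(i)] for i in ids])
    n1 = int((vals == 1).sum())
    n0 = int((vals == 0).sum())
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present to balance labels")
    if n0 == n1:
        return dict(labels)
    major = 0 if n0 > n1 else 1
    keep_n = min(n0, n1)
    major_ids = ids[vals == major]
    kept = rng.choice(major_ids, size=keep_n, replace=False)
    kept_set = set(kept.tolist()) | set(ids[vals != major].tolist())
    return {int(i): int(labels[int(i)]) for i in ids if int(i) in kept_set}


def propagate(graph: LabeledGraph, labels: dict[int, int] | None = None
              ) -> PropagationResult:
    """Clamped harmonic propagation of hard labels to all unlabeled nodes.

    Minimizes ``sum_ij w_ij (f_i - f_j)^2`` over the unlabeled values with
    labeled values fixed; the solution satisfies ``f_i = weighted mean of
    neighbors`` at every unlabeled node and is obtained by one direct
    sparse solve of the graph-Laplacian system.  Unlabeled nodes in
    components containing no labeled node cannot be determined; they are
    reported in ``unreachable`` and assigned the uninformative value 0.5.
    """
    if labels is None:
        labels = graph.labels
    n = graph.n_nodes
    id_to_idx = {int(i): k for k, i in enumerate(graph.node_ids)}
    lab_idx = np.array(sorted(id_to_idx[int(i)] for i in labels), dtype=int)
    f = np.full(n, np.nan)
    for i, v in labels.items():
        f[id_to_idx[int(i)]] = float(v)
    clamped = np.zeros(n, dtype=bool)
    clamped[lab_idx] = True
    unl_idx = np.flatnonzero(~clamped)

    W = graph.weights.tocsr()
    # nodes whose component holds no labeled node are undetermined
    n_comp, comp = csgraph.connected_components(W, directed=False)
    reachable_comps = set(comp[lab_idx].tolist())
    unreachable = unl_idx[~np.isin(comp[unl_idx], list(reachable_comps))]
    solve_idx = unl_idx[np.isin(comp[unl_idx], list(reachable_comps))]
    if unreachable.size:
        logger.warning(
            "%d unlabeled nodes unreachable from any labeled node; "
            "assigned 0.5", unreachable.size,
        )
        f[unreachable] = 0.5

    if solve_idx.size:
        deg = np.asarray(W.sum(axis=1)).ravel()
        L = sparse.diags(deg) - W
        L_uu = L[np.ix_(solve_idx, solve_idx)].tocsc()
        W_ul = W[np.ix_(solve_idx, lab_idx)]
        rhs = W_ul @ f[lab_idx]
        sol = sparse.linalg.spsolve(L_uu, rhs)
        if not np.all(np.isfinite(sol)):
            raise RuntimeError(
                "singular harmonic system after connectivity pruning"
            )
        f[solve_idx] = np.clip(sol, 0.0, 1.0)

    assert not np.any(np.isnan(f))
    return PropagationResult(node_ids=graph.node_ids.copy(), values=f,
                             clamped=clamped, unreachable=graph.node_ids[unreachable])
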