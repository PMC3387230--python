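"""Graph-based gene ranking on directed, reference-annotated networks.

Every edge of the interaction network carries a literature reference count.
For each ordered node pair (A, B) an all-pairs shortest-path pass (a
Floyd–Warshall variant with unit edge weights) records

* ``N[A][B]`` — the number of nodes on a shortest directed path A→B,
  endpoints included (a direct edge gives N = 2), and
* ``R[A][B]`` — the total reference count along that path; among equally
  short paths, the one with the maximal reference total is chosen.

Two power-law scores combine these: a reference score ``rs = w_r * r**alpha``
(sub-linear, increasing — more literature evidence means more relatedness)
and a node score ``ns = w_n * n**(-beta)`` (super-linear decay — more
intermediate nodes means much less relatedness).  The directed pair score is
``rs + ns``; the undirected pair score is the maximum over both directions;
a protein's final score is the sum of its pair scores against every other
node.  Unreachable directions contribute 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

#: Marker for unreachable ordered pairs in the N and R matrices.
UNREACHABLE = np.inf


@dataclass(frozen=True)
class ScoreParams:
    """Constants of the power-law scoring function.

    alpha in (0, 1] keeps the reference score concave; beta > 0 sets the
    node-score decay.  Defaults (0.5, 2.0) make path length dominate
    reference count, the intended ordering of influences.  A warning is
    raised (not an error) when that dominance is violated.
    """

    alpha: float = 0.5
    beta: float = 2.0
    w_r: float = 1.0
    w_n: float = 1.0
    count_endpoints: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.w_r < 0 or self.w_n < 0:
            raise ValueError("weights must be nonnegative")
        if self.beta <= self.alpha:
            import warnings

            warnings.warn(
                "beta <= alpha: node-count influence no longer dominates "
                "reference-count influence",
                stacklevel=2,
            )


@dataclass
class PathMatrices:
    """All-pairs shortest-path summaries of a directed network.

    ``nodes`` fixes row/column order; ``n_counts[i, j]`` is the node count of
    a shortest path i→j (UNREACHABLE if none), ``ref_totals[i, j]`` the
    maximal reference total among shortest paths.  Diagonals are N = 1,
    R = 0.
    """

    nodes: list[str]
    n_counts: np.ndarray
    ref_totals: np.ndarray

    def index(self, node: str) -> int:
        try:
            return self.nodes.index(node)
        except ValueError:
            raise KeyError(f"node {node!r} not in network") from None


def floyd_warshall_unit(net: nx.DiGraph) -> PathMatrices:
    """All-pairs shortest paths with unit edge weights, tracking node counts
    and along-path reference totals.

    Dynamic program over intermediate vertices (Floyd–Warshall) on the
    lexicographic objective (minimize hop count, then maximize reference
    total).  Both objectives are additive along paths, so optimal subpaths
    compose and the relaxation is exact.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    nodes = sorted(net.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)

    hops = np.full((n, n), np.inf)
    refs = np.full((n, n), np.inf)
    np.fill_diagonal(hops, 0.0)
    np.fill_diagonal(refs, 0.0)
    for u, v, attrs in net.edges(data=True):
        rc = attrs.get("ref_count", 1)
        if rc < 1:
            raise ValueError(f"edge {u}->{v} has ref_count {rc} < 1")
        hops[idx[u], idx[v]] = 1.0
        refs[idx[u], idx[v]] = float(rc)

    for k in range(n):
        via_hops = hops[:, k, None] + hops[None, k, :]
        via_refs = refs[:, k, None] + refs[None, k, :]
        shorter = via_hops < hops
        equal_better = (via_hops == hops) & np.isfinite(via_hops) & (via_refs > refs)
        take = shorter | equal_better
        hops = np.where(take, via_hops, hops)
        refs = np.where(take, via_refs, refs)

    n_counts = np.where(np.isfinite(hops), hops + 1.0, UNREACHABLE)
    np.fill_diagonal(n_counts, 1.0)
    ref_totals = np.where(np.isfinite(hops), refs, UNREACHABLE)
    np.fill_diagonal(ref_totals, 0.0)
    return PathMatrices(nodes=nodes, n_counts=n_counts, ref_totals=ref_totals)


def pair_score_directed(
    n: float, r: float, params: ScoreParams | None = None
) -> float:
    """Power-law score of a directed path summary (node count n, reference
    total r); UNREACHABLE input scores 0."""
    params = params or ScoreParams()
    if not np.isfinite(n) or not np.isfinite(r):
        return 0.0
    if n < 2:
        raise ValueError("a reachable distinct pair has n >= 2")
    if r < 1:
        raise ValueError("a reachable distinct pair has r >= 1")
    n_eff = n - 2 if not params.count_endpoints else n
    if n_eff <= 0:
        # intermediate-only counting of a direct edge: no node penalty term
        return params.w_r * r**params.alpha + params.w_n
    return params.w_r * r**params.alpha + params.w_n * n_eff ** (-params.beta)


def _directed_score_matrix(paths: PathMatrices, params: ScoreParams) -> np.ndarray:
    """Vectorized pair_score_directed over the whole N/R matrices."""
    N, R = paths.n_counts, paths.ref_totals
    finite = np.isfinite(N)
    np.fill_diagonal(finite, False)
    if params.count_endpoints:
        n_eff = N
    else:
        n_eff = N - 2
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        ns = np.where(
            finite & (n_eff > 0), np.where(finite, n_eff, 1.0) ** (-params.beta), 0.0
        )
        ns = np.where(finite & (n_eff <= 0), 1.0, ns)
        rs = np.where(finite, np.where(finite, R, 1.0) ** params.alpha, 0.0)
    return np.where(finite, params.w_r * rs + params.w_n * ns, 0.0)


def pair_score_final(
    net: nx.DiGraph,
    a: str,
    b: str,
    params: ScoreParams | None = None,
    paths: PathMatrices | None = None,
) -> float:
    """Undirected pair score: max of the A→B and B→A directed scores;
    0 when the nodes are mutually unreachable."""
    params = params or ScoreParams()
    if a == b:
        raise ValueError("pair score requires two distinct nodes")
    paths = paths or floyd_warshall_unit(net)
    i, j = paths.index(a), paths.index(b)
    s_ab = pair_score_directed(paths.n_counts[i, j], paths.ref_totals[i, j], params)
    s_ba = pair_score_directed(paths.n_counts[j, i], paths.ref_totals[j, i], params)
    return max(s_ab, s_ba)


def protein_score(
    net: nx.DiGraph,
    a: str,
    params: ScoreParams | None = None,
    paths: PathMatrices | None = None,
) -> float:
    """Final score of one protein: the sum of its undirected pair scores
    against every other node in the network."""
    params = params or ScoreParams()
    paths = paths or floyd_warshall_unit(net)
    i = paths.index(a)
    directed = _directed_score_matrix(paths, params)
    both = np.maximum(directed[i, :], directed[:, i])
    both[i] = 0.0
    return float(both.sum())


def rank_network(
    net: nx.DiGraph,
    params: ScoreParams | None = None,
    annotations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Score and rank every node of the network.

    Returns a DataFrame with ``gene``, ``score`` and ``n_edges``
    (in-degree + out-degree) columns, sorted by descending score with
    lexicographic tie-breaking; ``annotations`` (indexed by gene symbol,
    e.g. per-dataset p-values) are left-joined when given.  Output is
    invariant to node insertion order.
    """
    params = params or ScoreParams()
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    paths = floyd_warshall_unit(net)
    directed = _directed_score_matrix(paths, params)
    pairwise = np.maximum(directed, directed.T)
    np.fill_diagonal(pairwise, 0.0)
    scores = pairwise.sum(axis=1)
    table = pd.DataFrame(
        {
            "gene": paths.nodes,
            "score": scores,
            "n_edges": [net.in_degree(v) + net.out_degree(v) for v in paths.nodes],
        }
    )
    if annotations is not None:
        table = table.merge(
            annotations, how="left", left_on="gene", right_index=True
        )
    table = table.sort_values(
        ["score", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return table
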