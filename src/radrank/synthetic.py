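"""Seeded generators for synthetic expression data and interaction networks.

The expression generator emulates a two-condition microarray design on the
log2 scale: Gaussian log-intensities, a configurable number of
differentially expressed probes shifted in the second group.  Defaults
mirror an 8-versus-8 before/after irradiation design.  The network
generator produces directed Erdős–Rényi or preferential-attachment graphs
whose edges carry geometric reference counts (support >= 1), matching what
curated interaction databases export.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .formats_io import LOG2, ExpressionMatrix, add_interaction, new_network


@dataclass(frozen=True)
class ExprSimSpec:
    """Two-group expression simulation parameters (log2 scale).

    ``effect_size`` is the mean log2 shift of the ``n_de`` spiked probes in
    group 2; ``mu`` and ``sigma`` set the shared Gaussian baseline.
    """

    n_probes: int = 1000
    n_per_group: int = 8
    n_de: int = 0
    effect_size: float = 1.0
    mu: float = 8.0
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if not 0 <= self.n_de <= self.n_probes:
            raise ValueError("n_de must lie in [0, n_probes]")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


@dataclass(frozen=True)
class NetSimSpec:
    """Random directed network parameters.

    ``model='erdos_renyi'`` draws each ordered pair independently with
    ``edge_prob``; ``model='preferential'`` grows a scale-free-like digraph
    with ``attachment`` out-edges per new node.  Edge reference counts are
    Geometric(ref_p) with support >= 1.
    """

    n_nodes: int = 10
    edge_prob: float = 0.3
    model: str = "erdos_renyi"  # erdos_renyi | preferential
    attachment: int = 2
    ref_p: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        if not 0 <= self.edge_prob <= 1:
            raise ValueError("edge_prob must lie in [0, 1]")
        if not 0 < self.ref_p < 1:
            raise ValueError("ref_p must lie in (0, 1)")
        if self.model not in ("erdos_renyi", "preferential"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.attachment < 1:
            raise ValueError("attachment must be >= 1")


def gen_expression(spec: ExprSimSpec) -> tuple[ExpressionMatrix, np.ndarray]:
    """Simulate a two-group log2 expression matrix.

    Returns the matrix (scale log2, groups labelled ``pre``/``post``) and a
    boolean truth vector marking the differentially expressed probes (the
    first ``n_de`` rows).
    """
    rng = np.random.default_rng(spec.seed)
    n_samples = 2 * spec.n_per_group
    X = rng.normal(spec.mu, spec.sigma, size=(spec.n_probes, n_samples))
    truth = np.zeros(spec.n_probes, dtype=bool)
    truth[: spec.n_de] = True
    X[truth, spec.n_per_group:] += spec.effect_size
    probes = [f"probe_{i:05d}" for i in range(spec.n_probes)]
    samples = [f"pre_{i+1}" for i in range(spec.n_per_group)] + [
        f"post_{i+1}" for i in range(spec.n_per_group)
    ]
    labels = pd.Series(
        ["pre"] * spec.n_per_group + ["post"] * spec.n_per_group, index=samples
    )
    matrix = ExpressionMatrix(
        data=pd.DataFrame(X, index=probes, columns=samples),
        scale=LOG2,
        labels=labels,
    )
    return matrix, truth


def gen_network(spec: NetSimSpec) -> nx.DiGraph:
    """Simulate a directed interaction network with reference-counted edges."""
    rng = np.random.default_rng(spec.seed)
    names = [f"G{i:03d}" for i in range(spec.n_nodes)]
    net = new_network()
    net.add_nodes_from(names)
    pairs: list[tuple[str, str]] = []
    if spec.model == "erdos_renyi":
        for i in range(spec.n_nodes):
            for j in range(spec.n_nodes):
                if i != j and rng.random() < spec.edge_prob:
                    pairs.append((names[i], names[j]))
    else:  # preferential attachment: new nodes point at degree-biased targets
        degrees = np.ones(spec.n_nodes)
        for i in range(1, spec.n_nodes):
            k = min(spec.attachment, i)
            weights = degrees[:i] / degrees[:i].sum()
            targets = rng.choice(i, size=k, replace=False, p=weights)
            for j in targets:
                pairs.append((names[i], names[int(j)]))
                degrees[i] += 1
                degrees[int(j)] += 1
    for u, v in pairs:
        ref = int(rng.geometric(spec.ref_p))
        add_interaction(net, u, v, ref_count=ref)
    return net
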