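"""Community structure and plotting geometry for the estimated networks.

Walk-trap clustering groups nodes whose short random walks (t steps, on
absolute edge weights) look alike, merging communities agglomeratively and
cutting the dendrogram at the partition with maximum Newman weighted
modularity.  Layouts use the Fruchterman-Reingold force simulation; for
visual comparability across the six role x time networks a single "average
layout" is computed from the element-wise mean of the absolute weight
matrices and reused unchanged for every network.  Node sizes encode the
percent change of the mean subscale score relative to the first assessment.

Edge signs play no role in walks or layout (magnitudes only); they matter
only for rendering, where positive partial associations are drawn green,
negative red, and low-bootstrap-support edges gray.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import igraph as ig
import networkx as nx
import numpy as np

from .data_model import NetworkModel


@dataclass
class ClusterAssignment:
    """Walk-trap output: the chosen partition plus the merge history."""

    membership: dict[str, int]
    merges: list[tuple[int, int]]
    modularity_by_level: list[float]
    chosen_level: int

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))


@dataclass
class LayoutCoordinates:
    """Node coordinates in the unit square."""

    coords: dict[str, tuple[float, float]]
    seed: int
    iterations: int

    def __post_init__(self) -> None:
        for node, (x, y) in self.coords.items():
            if not (np.isfinite(x) and np.isfinite(y)):
                raise ValueError(f"non-finite coordinate for {node}")
            if not (-1e-9 <= x <= 1 + 1e-9 and -1e-9 <= y <= 1 + 1e-9):
                raise ValueError(f"coordinate for {node} outside [0, 1]^2")


def modularity(net: NetworkModel, partition: Mapping[str, int]) -> float:
    """Newman weighted modularity of a partition, on absolute weights.

    Q = sum_c (e_c / m - (d_c / 2m)^2) where m is the total absolute edge
    weight, e_c the within-community weight and d_c the community's weighted
    degree sum.  Returns 0 for an edgeless network.
    """
    W = net.abs_weights()
    m = W[np.triu_indices(net.p, 1)].sum()
    if m == 0:
        return 0.0
    labels = net.node_labels
    comm = np.array([partition[l] for l in labels])
    deg = W.sum(axis=1)
    Q = 0.0
    for c in np.unique(comm):
        mask = comm == c
        e_c = W[np.ix_(mask, mask)].sum() / 2.0
        d_c = deg[mask].sum()
        Q += e_c / m - (d_c / (2 * m)) ** 2
    return float(Q)


def _memberships_by_level(p: int, merges: Sequence[tuple[int, int]]) -> list[np.ndarray]:
    """Partitions along the dendrogram, level 0 = all singletons.

    igraph merge convention: initial communities are 0..p-1; merge k fuses
    the two listed communities into new community p + k.
    """
    parent = list(range(p + len(merges)))
    levels = []

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def snapshot() -> np.ndarray:
        roots = [find(v) for v in range(p)]
        relabel = {r: i for i, r in enumerate(dict.fromkeys(roots))}
        return np.array([relabel[r] for r in roots])

    levels.append(snapshot())
    for k, (a, b) in enumerate(merges):
        new = p + k
        parent[find(a)] = new
        parent[find(b)] = new
        levels.append(snapshot())
    return levels


def walktrap_cluster(net: NetworkModel, t: int = 4) -> ClusterAssignment:
    """Walk-trap community detection cut at maximum modularity.

    Runs the agglomerative random-walk algorithm (walk length ``t``) on the
    absolute weights, then scores every dendrogram level with
    :func:`modularity` and keeps the best.  An edgeless network yields all
    singletons; isolated nodes always end up in singleton communities.
    """
    if t < 1:
        raise ValueError("walk length t must be >= 1")
    p = net.p
    edges = net.edge_list()
    if not edges:
        return ClusterAssignment(
            membership={l: i for i, l in enumerate(net.node_labels)},
            merges=[],
            modularity_by_level=[0.0],
            chosen_level=0,
        )
    g = ig.Graph(
        n=p, edges=[(i, j) for i, j, _ in edges], edge_attrs={"weight": [abs(w) for *_, w in edges]}
    )
    dendro = g.community_walktrap(weights="weight", steps=t)
    merges = [(int(a), int(b)) for a, b in dendro.merges]
    levels = _memberships_by_level(p, merges)
    mods = [
        modularity(net, dict(zip(net.node_labels, mem.tolist()))) for mem in levels
    ]
    chosen = int(np.argmax(mods))
    mem = levels[chosen]
    return ClusterAssignment(
        membership=dict(zip(net.node_labels, mem.tolist())),
        merges=merges,
        modularity_by_level=[float(q) for q in mods],
        chosen_level=chosen,
    )


def _rescale_unit_square(pos: dict[str, np.ndarray]) -> dict[str, tuple[float, float]]:
    """Min-max rescale coordinates to [0, 1]^2; degenerate axes map to 0.5."""
    pts = np.array([pos[k] for k in pos])
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    span = hi - lo
    out = {}
    for k in pos:
        xy = []
        for d in range(2):
            if span[d] <= 0:
                xy.append(0.5)
            else:
                xy.append(float((pos[k][d] - lo[d]) / span[d]))
        out[k] = (xy[0], xy[1])
    return out


def fr_layout(net: NetworkModel, seed: int = 0, iterations: int = 500) -> LayoutCoordinates:
    """Fruchterman-Reingold layout on absolute weights, rescaled to [0, 1]^2.

    Deterministic given the seed.  A single node lands at (0.5, 0.5).
    """
    if net.p < 1:
        raise ValueError("layout requires at least one node")
    G = net.to_graph(use_abs=True)
    pos = nx.spring_layout(G, weight="weight", iterations=iterations, seed=seed)
    return LayoutCoordinates(
        coords=_rescale_unit_square(pos), seed=seed, iterations=iterations
    )


def average_layout(
    nets: Sequence[NetworkModel], seed: int = 0, iterations: int = 500
) -> LayoutCoordinates:
    """One layout for several networks over the same nodes.

    Computes the FR layout of the element-wise mean of the absolute weight
    matrices and reuses it unchanged for every network, so that node
    positions are comparable across strata and only the edges differ.
    """
    if not nets:
        raise ValueError("need at least one network")
    labels = nets[0].node_labels
    for net in nets[1:]:
        if net.node_labels != labels:
            raise ValueError("average_layout requires identical node sets")
    W = np.mean([net.abs_weights() for net in nets], axis=0)
    mean_net = NetworkModel(
        node_labels=list(labels),
        weights=W,
        node_types=list(nets[0].node_types),
    )
    return fr_layout(mean_net, seed=seed, iterations=iterations)


@dataclass
class NodeSizeScale:
    """Relative node sizes: 1.0 = unchanged mean score vs the baseline."""

    sizes: dict[str, float]

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.sizes.values()):
            raise ValueError("node sizes must be strictly positive")


def node_size_scale(
    means_tk: Mapping[str, float],
    means_t1: Mapping[str, float],
    floor: float = 0.2,
) -> NodeSizeScale:
    """Node sizes proportional to percent change of the mean score from T1.

    size = 1 + (mean_Tk - mean_T1) / mean_T1, floored at ``floor`` so that a
    collapsed score still renders visibly.  A zero baseline mean is an error
    naming the node.
    """
    sizes = {}
    for node, m1 in means_t1.items():
        if m1 == 0:
            raise ValueError(f"zero T1 mean for node {node}; size undefined")
        sizes[node] = max(floor, 1.0 + (means_tk[node] - m1) / m1)
    return NodeSizeScale(sizes)
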