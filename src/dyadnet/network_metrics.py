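"""Centrality indices and their bootstrap stability.

Strength is the weighted generalization of degree: the sum of absolute edge
weights at a node.  Betweenness counts (fractionally, over tied geodesics)
the weighted shortest paths passing through a node, with edge length taken
as the inverse absolute weight -- the usual transform for association
networks, where a strong edge is a short distance.  Because the strata here
are small samples, both indices are accompanied by a nonparametric
case-resampling bootstrap that re-estimates the whole network per replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .data_model import NetworkModel, Stratum
from .mgm import MGMConfig, estimate_stratum_network

METRICS = ("strength", "betweenness")


def strength(net: NetworkModel) -> pd.Series:
    """Per-node strength: row sums of |W|.  Isolated nodes score 0."""
    vals = np.abs(net.weights).sum(axis=1)
    return pd.Series(vals, index=net.node_labels, name="strength")


def degree(net: NetworkModel) -> pd.Series:
    """Unweighted degree (number of connections), emitted alongside strength."""
    vals = (net.weights != 0).sum(axis=1)
    return pd.Series(vals, index=net.node_labels, name="degree")


def betweenness(net: NetworkModel) -> pd.DataFrame:
    """Weighted betweenness, raw and normalized.

    Edge length = 1 / |w|; geodesics by Dijkstra with Brandes fractional
    counting of ties; unreachable pairs contribute nothing.  The normalized
    column divides by (p - 1)(p - 2) / 2, the number of ordered-unordered
    pairs excluding the node.
    """
    G = nx.Graph()
    G.add_nodes_from(net.node_labels)
    for i, j, w in net.edge_list():
        G.add_edge(net.node_labels[i], net.node_labels[j], distance=1.0 / abs(w))
    raw = nx.betweenness_centrality(G, weight="distance", normalized=False)
    p = net.p
    denom = (p - 1) * (p - 2) / 2.0 if p > 2 else 1.0
    df = pd.DataFrame(
        {
            "betweenness": [raw[l] for l in net.node_labels],
            "normalized_betweenness": [raw[l] / denom for l in net.node_labels],
        },
        index=net.node_labels,
    )
    return df


def centrality_table(net: NetworkModel) -> pd.DataFrame:
    """Strength, degree, and (raw + normalized) betweenness per node."""
    out = pd.concat([strength(net), degree(net), betweenness(net)], axis=1)
    out.index.name = "node"
    return out


@dataclass
class BootstrapSummary:
    """Bootstrap distribution summaries for every node x metric.

    ``table`` columns: point (original-sample estimate), boot_mean, ci_lo,
    ci_hi (percentile 2.5/97.5, widened if needed so the interval always
    brackets the bootstrap mean -- heavy-tailed betweenness distributions
    can otherwise put the mean past the upper percentile at small B),
    rank_stability (share of replicates in which the node keeps its
    original rank for that metric).  ``edge_support`` holds per-edge
    bootstrap inclusion proportions, used downstream to mark low-support
    ("not significant", gray) edges.
    """

    table: pd.DataFrame  # MultiIndex (metric, node)
    edge_support: np.ndarray
    B: int
    n_failed: int
    seed: int

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        bad = (self.table["ci_lo"] > self.table["boot_mean"] + 1e-12) | (
            self.table["boot_mean"] > self.table["ci_hi"] + 1e-12
        )
        if bad.any():
            raise ValueError("bootstrap CI must bracket the bootstrap mean")


def _metric_matrix(net: NetworkModel) -> np.ndarray:
    """(2, p) array of strength and raw betweenness values."""
    s = strength(net).to_numpy()
    b = betweenness(net)["betweenness"].to_numpy()
    return np.vstack([s, b])


def bootstrap_centrality(
    stratum: Stratum,
    config: MGMConfig | None = None,
    B: int = 1000,
    seed: int = 0,
) -> BootstrapSummary:
    """Case-resampling bootstrap of strength and betweenness.

    Each replicate resamples stratum rows with replacement, re-estimates the
    network (CV folds reseeded per replicate) and recomputes both indices.
    Replicates whose estimation fails are skipped and counted.  Deterministic
    given ``seed``.
    """
    config = config or MGMConfig()
    rng = np.random.default_rng(seed)
    net0, _ = estimate_stratum_network(stratum, config)
    point = _metric_matrix(net0)
    p = net0.p
    ranks0 = np.argsort(np.argsort(-point, axis=1), axis=1)  # 0 = most central
    reps = []
    support = np.zeros((p, p))
    n_failed = 0
    n = stratum.n
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        sub = Stratum(
            parent_role=stratum.parent_role,
            time_point=stratum.time_point,
            data=stratum.data[idx],
            dyad_ids=[stratum.dyad_ids[i] for i in idx],
            columns=stratum.columns,
        )
        rep_config = MGMConfig(
            **{**config.__dict__, "seed": int(rng.integers(0, 2**31 - 1))}
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # constant resampled columns
                net_b, _ = estimate_stratum_network(sub, rep_config)
        except Exception:
            n_failed += 1
            continue
        reps.append(_metric_matrix(net_b))
        support += net_b.weights != 0
    if not reps:
        raise RuntimeError("every bootstrap replicate failed")
    R = np.stack(reps)  # (B_ok, 2, p)
    support /= len(reps)
    ranks = np.argsort(np.argsort(-R, axis=2), axis=2)
    rank_stab = (ranks == ranks0[None]).mean(axis=0)
    rows = []
    for m, metric in enumerate(METRICS):
        for k, node in enumerate(net0.node_labels):
            vals = R[:, m, k]
            mean = float(vals.mean())
            rows.append(
                {
                    "metric": metric,
                    "node": node,
                    "point": float(point[m, k]),
                    "boot_mean": mean,
                    "ci_lo": min(float(np.percentile(vals, 2.5)), mean),
                    "ci_hi": max(float(np.percentile(vals, 97.5)), mean),
                    "rank_stability": float(rank_stab[m, k]),
                }
            )
    table = pd.DataFrame(rows).set_index(["metric", "node"])
    return BootstrapSummary(
        table=table, edge_support=support, B=B, n_failed=n_failed, seed=seed
    )
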