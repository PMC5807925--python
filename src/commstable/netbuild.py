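"""Ensemble network construction by p-value intersection, plus diagnostics.

An edge enters the ensemble network only if all contributing methods agree on
its direction and report p below the threshold.  Because any single p cutoff
is arbitrary, a sweep over thresholds (0.05, then 0.01 down to 1e-8 in powers
of ten) is scored by fit to a scale-free degree distribution — the
biologically motivated criterion (R^2 > 0.8, slope near -2) used to pick the
final network.  Negative edges are stripped before community detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .correlations import EdgeTable

#: 0.05, then 0.01 down to 1e-8 in powers of ten (9 thresholds)
DEFAULT_THRESHOLDS = (0.05,) + tuple(10.0 ** -k for k in range(2, 9))


@dataclass
class Network:
    """Undirected signed simple graph over OTUs; isolated nodes are excluded.

    Edges carry a ``sign`` attribute in {+1, -1}.  A node exists only by
    having at least one edge.
    """

    graph: nx.Graph
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = self.graph
        if any(g.has_edge(n, n) for n in g):
            raise ValueError("self-loops are not allowed")
        isolated = [n for n in g if g.degree(n) == 0]
        g.remove_nodes_from(isolated)
        for u, v, d in g.edges(data=True):
            d.setdefault("sign", 1)
            if d["sign"] not in (+1, -1):
                raise ValueError(f"edge ({u}, {v}) has invalid sign {d['sign']}")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def signed_edges(self) -> list[tuple[str, str, int]]:
        return [(u, v, d["sign"]) for u, v, d in self.graph.edges(data=True)]

    def to_edge_tsv(self, path: str | Path) -> None:
        rows = [(min(u, v), max(u, v), s) for u, v, s in self.signed_edges()]
        pd.DataFrame(rows, columns=["otu_a", "otu_b", "sign"]).to_csv(
            path, sep="\t", index=False)

    @classmethod
    def from_edge_tsv(cls, path: str | Path, **provenance) -> "Network":
        df = pd.read_csv(path, sep="\t")
        g = nx.Graph()
        for _, row in df.iterrows():
            g.add_edge(row["otu_a"], row["otu_b"], sign=int(row["sign"]))
        return cls(g, provenance)

    def to_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, str(path))


@dataclass(frozen=True)
class ScaleFreeFit:
    r_squared: float
    slope: float
    n_breaks: int
    threshold: float | None = None

    @property
    def is_degenerate(self) -> bool:
        return math.isnan(self.r_squared)


@dataclass(frozen=True)
class NetworkSummary:
    n_nodes: int
    n_edges: int
    mean_degree: float
    graph_density: float
    mean_path_length: float
    mean_clustering_coefficient: float


def intersect_edge_tables(tables: list[EdgeTable] | dict[str, EdgeTable],
                          p_threshold: float) -> Network:
    """Edges present in every table with matching direction and p < threshold.

    The threshold is strict ("below a given threshold"); direction 0
    sentinels never match.
    """
    if isinstance(tables, dict):
        tables = list(tables.values())
    if len(tables) < 2:
        raise ValueError("need at least two edge tables to intersect")
    merged = None
    for t in tables:
        df = t.edges.loc[
            (t.edges["p"] < p_threshold) & (t.edges["direction"] != 0),
            ["otu_a", "otu_b", "direction"],
        ]
        if merged is None:
            merged = df
        else:
            merged = merged.merge(df, on=["otu_a", "otu_b", "direction"])
        if merged.empty:
            break
    g = nx.Graph()
    if merged is not None:
        for row in merged.itertuples(index=False):
            g.add_edge(row.otu_a, row.otu_b, sign=int(row.direction))
    return Network(g, {"p_threshold": p_threshold,
                       "methods": [t.method for t in tables]})


def scale_free_fit(net: Network, n_breaks: int = 10,
                   threshold: float | None = None) -> ScaleFreeFit:
    """Goodness of fit of the degree distribution to a power law.

    Degrees are binned into ``n_breaks`` equal-width bins; within each
    non-empty bin the mean degree and the fraction of nodes are computed, and
    log10 of the fraction is regressed on log10 of the mean degree.  A single
    occupied bin (e.g. a k-regular graph) yields the degenerate sentinel
    (NaN r_squared and slope).
    """
    degrees = np.array([d for _, d in net.graph.degree()], dtype=float)
    if degrees.size == 0:
        return ScaleFreeFit(float("nan"), float("nan"), n_breaks, threshold)
    kmin, kmax = degrees.min(), degrees.max()
    if kmin == kmax:
        return ScaleFreeFit(float("nan"), float("nan"), n_breaks, threshold)
    edges = np.linspace(kmin, kmax, n_breaks + 1)
    which = np.clip(np.digitize(degrees, edges[1:-1], right=False), 0,
                    n_breaks - 1)
    k_mean, p_k = [], []
    for b in range(n_breaks):
        mask = which == b
        if mask.any():
            k_mean.append(degrees[mask].mean())
            p_k.append(mask.mean())
    if len(k_mean) < 2:
        return ScaleFreeFit(float("nan"), float("nan"), n_breaks, threshold)
    res = stats.linregress(np.log10(k_mean), np.log10(p_k))
    return ScaleFreeFit(float(res.rvalue ** 2), float(res.slope), n_breaks,
                        threshold)


def network_summary(net: Network) -> NetworkSummary:
    """Descriptive statistics of a network.

    Mean path length averages shortest-path lengths over connected node pairs
    only; the mean clustering coefficient averages local clustering over all
    nodes (nodes of degree < 2 contribute 0).
    """
    g = net.graph
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        raise ValueError("empty network")
    density = e / (n * (n - 1) / 2) if n > 1 else 0.0
    total, pairs = 0, 0
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            total += sum(dists.values())
        pairs += len(comp) * (len(comp) - 1)
    mpl = total / pairs if pairs else float("nan")
    return NetworkSummary(
        n_nodes=n, n_edges=e, mean_degree=2 * e / n, graph_density=density,
        mean_path_length=mpl,
        mean_clustering_coefficient=nx.average_clustering(g),
    )


def strip_negative_edges(net: Network) -> tuple[Network, float]:
    """Remove negative edges (and any node left isolated); returns the
    unsigned network and the fraction of edges removed."""
    g = nx.Graph()
    kept = 0
    for u, v, s in net.signed_edges():
        if s > 0:
            g.add_edge(u, v, sign=1)
            kept += 1
    total = net.n_edges
    frac_removed = 0.0 if total == 0 else 1.0 - kept / total
    return Network(g, dict(net.provenance, negative_edges_removed=frac_removed)), frac_removed


def threshold_sweep(tables: list[EdgeTable] | dict[str, EdgeTable],
                    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
                    n_breaks: int = 10) -> pd.DataFrame:
    """Intersect at each threshold; returns one row per threshold with the
    network, its scale-free fit and summary.  Thresholds must be sorted
    descending; edge counts are checked to be monotone non-increasing."""
    thresholds = tuple(thresholds)
    if list(thresholds) != sorted(thresholds, reverse=True):
        raise ValueError("thresholds must be sorted descending")
    rows = []
    prev_edges = None
    for thr in thresholds:
        net = intersect_edge_tables(tables, thr)
        if prev_edges is not None and net.n_edges > prev_edges:
            raise AssertionError("edge count increased under a stricter threshold")
        prev_edges = net.n_edges
        if net.n_nodes:
            fit = scale_free_fit(net, n_breaks=n_breaks, threshold=thr)
            summ = network_summary(net)
        else:
            fit = ScaleFreeFit(float("nan"), float("nan"), n_breaks, thr)
            summ = NetworkSummary(0, 0, 0.0, 0.0, float("nan"), 0.0)
        rows.append({
            "threshold": thr, "network": net, "fit": fit, "summary": summ,
            "n_nodes": summ.n_nodes, "n_edges": summ.n_edges,
            "mean_degree": summ.mean_degree, "r_squared": fit.r_squared,
            "slope": fit.slope,
        })
    return pd.DataFrame(rows)
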