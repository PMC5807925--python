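"""Cross-network comparison of community structure.

Two partitions are compared on the OTUs shared by both networks using the
variation of information, VI = H(A) + H(B) - 2 I(A; B) (natural logs),
normalised by ln(number of shared nodes) so 1 - nVI is a similarity in
[0, 1] with 1 meaning identical segmentation.  Chance similarity is assessed
by shuffling OTU labels within each partition (preserving community sizes)
and recomparing.  Individual communities are matched across datasets by the
Jaccard index of their OTU sets; groups of communities mutually linked across
all datasets form named "community-types".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .communities import Partition

#: fixed colour vocabulary for community-type labels (assignment order:
#: descending mean Jaccard of the linked communities)
COLOR_NAMES = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
)


@dataclass(frozen=True)
class PartitionComparison:
    shared_nodes: int
    one_minus_nvi: float
    null_mean: float
    null_sd: float
    null_max: float
    n_permutations: int


@dataclass(frozen=True)
class CommunityMatch:
    dataset_a: str
    community_a: int
    dataset_b: str
    community_b: int
    jaccard: float


@dataclass(frozen=True)
class CommunityType:
    label: str
    members: dict[str, int]  # dataset -> community id
    mean_jaccard: float


def _vi_from_labels(a: np.ndarray, b: np.ndarray) -> float:
    """VI from two label arrays over the same nodes, natural logs."""
    n = a.size
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    contingency = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(contingency, (ai, bi), 1.0)
    pij = contingency / n
    pa = pij.sum(axis=1)
    pb = pij.sum(axis=0)
    ha = -np.sum(pa * np.log(pa, where=pa > 0, out=np.zeros_like(pa)))
    hb = -np.sum(pb * np.log(pb, where=pb > 0, out=np.zeros_like(pb)))
    nz = pij > 0
    mi = np.sum(pij[nz] * np.log(pij[nz] / np.outer(pa, pb)[nz]))
    vi = max(ha + hb - 2.0 * mi, 0.0)
    return float(0.0 if vi < 1e-12 else vi)


def normalized_vi(a: Partition, b: Partition) -> tuple[float, float]:
    """(VI, 1 - VI/ln N) over the nodes shared by the two partitions."""
    shared = sorted(set(a.assignment) & set(b.assignment), key=str)
    n = len(shared)
    if n == 0:
        raise ValueError("partitions share no nodes")
    la = np.array([a.assignment[x] for x in shared])
    lb = np.array([b.assignment[x] for x in shared])
    if n == 1:
        return 0.0, 1.0
    vi = _vi_from_labels(la, lb)
    nvi = vi / np.log(n)
    return vi, float(1.0 - min(nvi, 1.0))


def vi_permutation_null(a: Partition, b: Partition,
                        n_permutations: int = 1000,
                        seed: int = 0) -> PartitionComparison:
    """Observed similarity plus its label-shuffle null.

    Each permutation shuffles which node carries which community label within
    each partition's own node universe (community sizes preserved), then the
    similarity is recomputed over the shared nodes.
    """
    shared = sorted(set(a.assignment) & set(b.assignment), key=str)
    if not shared:
        raise ValueError("partitions share no nodes")
    _, observed = normalized_vi(a, b)
    rng = np.random.default_rng(seed)
    nodes_a = sorted(a.assignment, key=str)
    nodes_b = sorted(b.assignment, key=str)
    labels_a = np.array([a.assignment[x] for x in nodes_a])
    labels_b = np.array([b.assignment[x] for x in nodes_b])
    pos_a = {x: k for k, x in enumerate(nodes_a)}
    pos_b = {x: k for k, x in enumerate(nodes_b)}
    idx_a = np.array([pos_a[x] for x in shared])
    idx_b = np.array([pos_b[x] for x in shared])
    n = len(shared)
    logn = np.log(n) if n > 1 else 1.0
    sims = np.empty(n_permutations)
    for k in range(n_permutations):
        la = rng.permutation(labels_a)[idx_a]
        lb = rng.permutation(labels_b)[idx_b]
        vi = _vi_from_labels(la, lb) if n > 1 else 0.0
        sims[k] = 1.0 - min(vi / logn, 1.0)
    return PartitionComparison(
        shared_nodes=n, one_minus_nvi=observed,
        null_mean=float(sims.mean()),
        null_sd=float(sims.std(ddof=1)) if n_permutations > 1 else 0.0,
        null_max=float(sims.max()), n_permutations=n_permutations)


def jaccard(a: set, b: set) -> float:
    """|a & b| / |a | b|."""
    if not a and not b:
        raise ValueError("Jaccard undefined for two empty sets")
    return len(a & b) / len(a | b)


def map_communities(partitions: dict[str, Partition], threshold: float = 0.25
                    ) -> tuple[list[CommunityMatch], list[CommunityType]]:
    """Match communities across datasets by Jaccard and name linked groups.

    All cross-dataset community pairs are scored; matches require Jaccard
    strictly above ``threshold``.  A community-type is emitted for every
    connected group of matches containing exactly one community from every
    dataset; a community matched to more than one community of the same other
    dataset voids type formation for its group (with a warning).  Types are
    labelled with colour names in order of descending mean Jaccard.
    """
    if len(partitions) < 2:
        raise ValueError("need at least two partitions to map")
    datasets = list(partitions)
    matches: list[CommunityMatch] = []
    for i, da in enumerate(datasets):
        for db in datasets[i + 1:]:
            ca = partitions[da].communities()
            cb = partitions[db].communities()
            for ia, sa in ca.items():
                for ib, sb in cb.items():
                    j = jaccard(sa, sb)
                    if j > threshold:
                        matches.append(CommunityMatch(da, ia, db, ib, j))

    # connected components over (dataset, community) nodes
    adjacency: dict[tuple[str, int], set] = {}
    weight: dict[frozenset, float] = {}
    for m in matches:
        u, v = (m.dataset_a, m.community_a), (m.dataset_b, m.community_b)
        adjacency.setdefault(u, set()).add(v)
        adjacency.setdefault(v, set()).add(u)
        weight[frozenset((u, v))] = m.jaccard

    seen: set = set()
    candidates = []
    for start in adjacency:
        if start in seen:
            continue
        comp = {start}
        stack = [start]
        while stack:
            node = stack.pop()
            for nbr in adjacency[node]:
                if nbr not in comp:
                    comp.add(nbr)
                    stack.append(nbr)
        seen |= comp
        by_dataset: dict[str, list[int]] = {}
        for ds, cid in comp:
            by_dataset.setdefault(ds, []).append(cid)
        multi = {ds: ids for ds, ids in by_dataset.items() if len(ids) > 1}
        if multi:
            warnings.warn(
                f"multiple mapping in {sorted(multi)}; no community-type "
                f"formed for this group", RuntimeWarning, stacklevel=2)
            continue
        if set(by_dataset) != set(datasets):
            continue
        pair_scores = [weight[frozenset((u, v))]
                       for u in comp for v in comp
                       if u < v and frozenset((u, v)) in weight]
        candidates.append((float(np.mean(pair_scores)),
                           {ds: ids[0] for ds, ids in by_dataset.items()}))

    candidates.sort(key=lambda c: (-c[0], sorted(c[1].items()).__repr__()))
    types = [CommunityType(COLOR_NAMES[k % len(COLOR_NAMES)]
                           + ("" if k < len(COLOR_NAMES)
                              else f"_{k // len(COLOR_NAMES)}"),
                           members, score)
             for k, (score, members) in enumerate(candidates)]
    return matches, types


def comparison_frame(comparisons: dict[tuple[str, str], PartitionComparison]
                     ) -> pd.DataFrame:
    rows = [{"dataset_a": a, "dataset_b": b, "shared_nodes": c.shared_nodes,
             "similarity": c.one_minus_nvi, "null_mean": c.null_mean,
             "null_sd": c.null_sd, "null_max": c.null_max}
            for (a, b), c in comparisons.items()]
    return pd.DataFrame(rows)
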