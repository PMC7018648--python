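"""Weighted ingredient co-occurrence network: build, normalize, threshold.

Construction: one node per ingredient (optionally restricted to ingredients
appearing in at least ``min_recipes`` recipes) and, for every unordered pair
of included ingredients, an integer count weight W_ij equal to the number of
recipes whose ingredient set contains both.

Normalization maps count weights linearly onto [eps, 1 - eps]:

    W_ij_new = ((1 - 2*eps) * W_ij + (2*eps - 1) * W_min) / (W_max - W_min) + eps

so the smallest weight becomes exactly eps and the largest exactly 1 - eps,
while the rank order of weights is preserved.  eps > 0 exists so that a
threshold of 0 never cuts the weakest links.  When every weight is equal the
transformation is undefined; all weights are then set to 0.5, the midpoint
of the target interval, which preserves thresholding semantics.

Thresholding at t keeps an edge iff its normalized weight is strictly
greater than t and forgets the weights (unit-weight, unweighted network).
Isolated nodes are retained: they matter for the fragmentation profile and
for consensus bookkeeping downstream.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .corpus import RecipeCorpus
from .errors import ValidationError

#: Threshold schedule used in the manuscript-scale reproduction runs.
REFERENCE_THRESHOLDS = (0.0, 0.01, 0.15, 0.29, 0.43, 0.571)


@dataclass(frozen=True)
class NormalizationParams:
    """Parameters of the linear weight normalization (eps in (0, 0.5))."""

    epsilon: float = 0.01

    def __post_init__(self):
        if not 0.0 < self.epsilon < 0.5:
            raise ValidationError("epsilon must be in (0, 0.5)")


@dataclass
class WeightedNetwork:
    """Undirected ingredient network with integer count weights.

    ``edges`` maps node-index pairs (i < j) to count weights; after
    :func:`normalize_weights`, ``normalized`` maps the same pairs to weights
    in [eps, 1 - eps].
    """

    nodes: List[str]
    edges: Dict[Tuple[int, int], int]
    normalized: Optional[Dict[Tuple[int, int], float]] = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def w_min(self) -> int:
        return min(self.edges.values())

    @property
    def w_max(self) -> int:
        return max(self.edges.values())

    def count_weight(self, u: str, v: str) -> int:
        i, j = self.nodes.index(u), self.nodes.index(v)
        return self.edges.get((min(i, j), max(i, j)), 0)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (i, j), w in self.edges.items():
            attrs = {"count_weight": w}
            if self.normalized is not None:
                attrs["normalized_weight"] = self.normalized[(i, j)]
            g.add_edge(self.nodes[i], self.nodes[j], **attrs)
        return g


@dataclass
class UnweightedNetwork:
    """Thresholded, unit-weight network (isolated nodes retained)."""

    nodes: List[str]
    edges: List[Tuple[int, int]]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def m(self) -> int:
        return len(self.edges)

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes))
        for i, j in self.edges:
            a[i, j] = a[j, i] = 1.0
        return a

    def degrees(self) -> np.ndarray:
        k = np.zeros(self.n_nodes)
        for i, j in self.edges:
            k[i] += 1
            k[j] += 1
        return k

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(
            (self.nodes[i], self.nodes[j]) for i, j in self.edges
        )
        return g


@dataclass(frozen=True)
class ThresholdSchedule:
    """Strictly increasing thresholds in [0, 1)."""

    thresholds: Tuple[float, ...]

    def __post_init__(self):
        ts = self.thresholds
        if not ts:
            raise ValidationError("schedule must contain at least one value")
        if any(not 0.0 <= t < 1.0 for t in ts):
            raise ValidationError("thresholds must lie in [0, 1)")
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValidationError("thresholds must be strictly increasing")

    def __iter__(self):
        return iter(self.thresholds)

    def __len__(self):
        return len(self.thresholds)


@dataclass
class FragmentationProfile:
    """(threshold, number of nonisolated nodes) pairs, non-increasing."""

    points: List[Tuple[float, int]] = field(default_factory=list)


def build_network(corpus: RecipeCorpus, min_recipes: int = 2) -> WeightedNetwork:
    """Build the co-occurrence network from a corpus.

    Nodes are ingredients occurring in at least ``min_recipes`` recipes
    (default 2, matching the convention of dropping one-off ingredients);
    W_ij counts the recipes containing both i and j.
    """
    if len(corpus) == 0:
        raise ValidationError("corpus is empty")
    if min_recipes < 1:
        raise ValidationError("min_recipes must be >= 1")
    occur: Dict[str, int] = {}
    for r in corpus:
        for tok in r.ingredients:
            occur[tok] = occur.get(tok, 0) + 1
    nodes = sorted(t for t, c in occur.items() if c >= min_recipes)
    index = {t: i for i, t in enumerate(nodes)}
    edges: Dict[Tuple[int, int], int] = {}
    for r in corpus:
        members = sorted(index[t] for t in r.ingredients if t in index)
        for i, j in itertools.combinations(members, 2):
            edges[(i, j)] = edges.get((i, j), 0) + 1
    return WeightedNetwork(nodes=nodes, edges=edges)


def normalize_weights(
    net: WeightedNetwork, params: NormalizationParams = NormalizationParams()
) -> WeightedNetwork:
    """Map count weights linearly onto [eps, 1 - eps] (order-preserving)."""
    if net.n_edges == 0:
        raise ValidationError("cannot normalize an edgeless network")
    eps = params.epsilon
    w_min, w_max = net.w_min, net.w_max
    if w_max == w_min:
        normalized = {e: 0.5 for e in net.edges}
    else:
        span = w_max - w_min
        # algebraically identical to
        # ((1-2e)W + (2e-1)W_min)/(W_max-W_min) + e, arranged so the
        # extremes land exactly on eps and 1 - eps in floating point
        normalized = {
            e: eps + (1 - 2 * eps) * ((w - w_min) / span)
            for e, w in net.edges.items()
        }
    return WeightedNetwork(
        nodes=list(net.nodes), edges=dict(net.edges), normalized=normalized
    )


def apply_threshold(net: WeightedNetwork, t: float) -> UnweightedNetwork:
    """Keep edges with normalized weight strictly greater than t."""
    if net.normalized is None:
        raise ValidationError("network must be normalized before thresholding")
    if not 0.0 <= t < 1.0:
        raise ValidationError(f"threshold {t} outside [0, 1)")
    edges = [e for e, w in net.normalized.items() if w > t]
    return UnweightedNetwork(nodes=list(net.nodes), edges=sorted(edges))


def fragmentation_profile(
    net: WeightedNetwork, candidates: Optional[Sequence[float]] = None
) -> FragmentationProfile:
    """Count nonisolated nodes at each candidate threshold.

    Default candidates: 0 plus every distinct normalized weight below the
    maximum (thresholding exactly at a weight cuts it, so these are the
    points where the edge set can change).
    """
    if net.normalized is None:
        raise ValidationError("network must be normalized first")
    if candidates is None:
        weights = sorted(set(net.normalized.values()))
        candidates = sorted({0.0} | {w for w in weights if w < 1.0})
    points = []
    for t in sorted(candidates):
        sub = apply_threshold(net, t)
        nonisolated = len({i for e in sub.edges for i in e})
        points.append((t, nonisolated))
    return FragmentationProfile(points=points)


def select_thresholds(
    profile: FragmentationProfile, stop_min_nodes: int = 10
) -> ThresholdSchedule:
    """Pick 0 plus every candidate where the nonisolated count drops.

    Candidates at which fewer than ``stop_min_nodes`` nodes would remain
    nonisolated are excluded (the sweep stops before the network dissolves).
    """
    if not profile.points:
        raise ValidationError("empty fragmentation profile")
    chosen = [0.0]
    prev = profile.points[0][1]
    for t, n in profile.points[1:]:
        if n < stop_min_nodes:
            break
        if n < prev and t > 0.0:
            chosen.append(t)
        prev = n
    return ThresholdSchedule(thresholds=tuple(chosen))


def write_edge_list(net: WeightedNetwork, path) -> None:
    """Edge list TSV: source, target, count_weight, normalized_weight."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tcount_weight\tnormalized_weight\n")
        for (i, j), w in sorted(net.edges.items()):
            norm = (
                f"{net.normalized[(i, j)]:.10g}"
                if net.normalized is not None
                else ""
            )
            fh.write(f"{net.nodes[i]}\t{net.nodes[j]}\t{w}\t{norm}\n")


def write_graphml(net: WeightedNetwork, path) -> None:
    import networkx as nx

    nx.write_graphml(net.to_networkx(), path)


def write_profile(profile: FragmentationProfile, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("threshold\tn_nonisolated\n")
        for t, n in profile.points:
            fh.write(f"{t:.10g}\t{n}\n")
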