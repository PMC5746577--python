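"""Mapper over the feature point cloud.

Filter: Euclidean distance to the k-th nearest neighbour (k = 2, i.e. the
nearest *other* point).  Cover: MI uniform intervals over the filter range
with MO percent pairwise overlap, endpoints closed.  Local clustering:
Ward agglomeration cut at the largest qualifying gap in the merge heights
(outlier above mean + gap_sd * sd of earlier merges and a relative jump of
at least gap_ratio).  Nodes are the
local clusters; edges join nodes in adjacent intervals that share members,
weighted by the overlap size.  The resulting network is decomposed into
connected components, a high-degree core, and arms for functional-group
annotation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator
from sklearn.neighbors import NearestNeighbors

from .preprocess import PointCloud

__all__ = [
    "CoverInterval",
    "MapperNode",
    "TopologicalChart",
    "ChartDecomposition",
    "MapperChart",
    "knn_filter",
    "build_cover",
    "cluster_preimage",
    "build_chart",
    "decompose_chart",
    "annotate_groups",
    "planted_three_arm_cloud",
]


@dataclass(frozen=True)
class CoverInterval:
    low: float
    high: float
    index: int

    def contains(self, v: np.ndarray) -> np.ndarray:
        return (v >= self.low) & (v <= self.high)


@dataclass
class MapperNode:
    id: int
    members: tuple[str, ...]
    interval: int
    mean_filter: float


@dataclass
class TopologicalChart:
    nodes: list[MapperNode]
    edges: list[tuple[int, int, int]]  # (node u, node v, shared-member count)
    parameters: dict
    groups: dict[int, str] = field(default_factory=dict)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for node in self.nodes:
            g.add_node(node.id, members=";".join(node.members),
                       size=len(node.members), interval=node.interval,
                       mean_filter=node.mean_filter,
                       group=self.groups.get(node.id, ""))
        for u, v, w in self.edges:
            g.add_edge(u, v, weight=w)
        return g

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    def to_dict(self) -> dict:
        return {
            "parameters": self.parameters,
            "nodes": [{"id": n.id, "members": list(n.members),
                       "interval": n.interval,
                       "mean_filter": n.mean_filter,
                       "group": self.groups.get(n.id, "")}
                      for n in self.nodes],
            "edges": [{"source": u, "target": v, "weight": w}
                      for u, v, w in self.edges],
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TopologicalChart":
        with open(path) as fh:
            d = json.load(fh)
        nodes = [MapperNode(n["id"], tuple(n["members"]), n["interval"],
                            n["mean_filter"]) for n in d["nodes"]]
        groups = {n["id"]: n["group"] for n in d["nodes"] if n.get("group")}
        edges = [(e["source"], e["target"], e["weight"])
                 for e in d["edges"]]
        return cls(nodes, edges, d.get("parameters", {}), groups)

    def member_node_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for n in self.nodes:
            for m in n.members:
                counts[m] = counts.get(m, 0) + 1
        return counts


def knn_filter(X: np.ndarray, k: int = 2) -> np.ndarray:
    """Distance of each point to its k-th nearest neighbour, the point itself
    counting as the first; k = 2 gives the distance to the nearest other
    point."""
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    if len(X) < k:
        raise ValueError(f"need at least {k} points for k = {k}")
    nn = NearestNeighbors(n_neighbors=k).fit(X)
    dist, _ = nn.kneighbors(X)
    return dist[:, k - 1]


def build_cover(filter_values, n_intervals: int, overlap_pct: float
                ) -> list[CoverInterval]:
    """Uniform overlapping cover of [min, max]: interval length
    L = R / (1 + (MI-1)(1 - MO/100)), stride L(1 - MO/100)."""
    if n_intervals < 1:
        raise ValueError("need at least one interval")
    if not (0.0 <= overlap_pct < 100.0):
        raise ValueError("overlap percentage must lie in [0, 100)")
    fv = np.asarray(filter_values, float)
    lo, hi = float(np.min(fv)), float(np.max(fv))
    if hi <= lo:
        return [CoverInterval(lo, lo, 0)]
    frac = 1.0 - overlap_pct / 100.0
    length = (hi - lo) / (1.0 + (n_intervals - 1) * frac)
    stride = length * frac
    intervals = [CoverInterval(lo + i * stride, lo + i * stride + length, i)
                 for i in range(n_intervals)]
    # clamp the last upper edge to the exact range maximum so the extremal
    # point is never lost to floating-point round-off
    last = intervals[-1]
    intervals[-1] = CoverInterval(last.low, hi, last.index)
    return intervals


def _gap_cut(heights: np.ndarray, gap_sd: float,
             min_ratio: float = 3.0) -> float | None:
    """Height threshold at the largest qualifying gap of the dendrogram.

    A merge qualifies as a gap when it is both a statistical outlier
    (exceeds mean + gap_sd * sd of all previous merge heights) and a genuine
    jump (exceeds min_ratio times the largest previous height).  Among
    qualifying merges the one with the largest relative jump is the cut;
    None when no merge qualifies (the preimage stays one cluster).  The
    ratio guard matters because Ward heights on an evenly spaced chain grow
    geometrically on their own (merging equal segments scales heights by
    about sqrt 2), which would otherwise shatter elongated preimages.
    """
    best_i, best_ratio = None, 0.0
    for i in range(2, len(heights)):
        prev = heights[:i]
        pmax = prev.max()
        if pmax <= 0:
            continue
        ratio = heights[i] / pmax
        if (heights[i] > prev.mean() + gap_sd * prev.std()
                and ratio > min_ratio and ratio > best_ratio):
            best_i, best_ratio = i, ratio
    if best_i is None:
        return None
    return float((heights[best_i - 1] + heights[best_i]) / 2.0)


def cluster_preimage(points: np.ndarray, gap_sd: float = 2.0,
                     gap_ratio: float = 3.0) -> list[np.ndarray]:
    """Ward clustering of one cover preimage, cut at the largest qualifying
    height gap; returns index arrays (into ``points``), ordered by smallest
    member."""
    pts = np.asarray(points, float)
    if pts.ndim == 1:
        pts = pts[:, None]
    n = len(pts)
    if n == 0:
        return []
    if n == 1:
        return [np.array([0])]
    Z = linkage(pts, method="ward")
    cut = _gap_cut(Z[:, 2], gap_sd, gap_ratio)
    if cut is None:
        labels = np.ones(n, dtype=int)
    else:
        labels = fcluster(Z, t=cut, criterion="distance")
    clusters = [np.nonzero(labels == lab)[0]
                for lab in np.unique(labels)]
    clusters.sort(key=lambda idx: int(idx[0]))
    return clusters


def planted_three_arm_cloud(seed: int = 0, jitter: float = 0.01,
                            n_dense: int = 8, n_sparse: int = 14
                            ) -> tuple[np.ndarray, list[str]]:
    """Synthetic Y-shaped point cloud for structural validation.

    One dense chain (arm A, low nearest-neighbour distances) runs into a
    junction from which two progressively sparser chains (arms B, C) radiate
    at 120 degrees.  Under a k-NN-distance filter with a three-interval 50%
    cover this charts as a central core node with three arms; refining the
    cover preserves which arm each point belongs to.  Returns the points and
    per-point arm labels ('A'/'B'/'C', junction labelled 'A').
    """
    rng = np.random.default_rng(seed)
    pts: list[list[float]] = []
    spacing_a = 0.30 + 0.04 * np.arange(n_dense)
    ys = np.cumsum(spacing_a[::-1])[::-1]
    for y in ys:
        pts.append([0.0, float(y)])
    pts.append([0.0, 0.0])  # junction
    labels = ["A"] * (n_dense + 1)
    for arm, theta in zip("BC", np.deg2rad([210.0, 330.0])):
        u = np.array([np.cos(theta), np.sin(theta)])
        spacing = 0.55 + 0.05 * np.arange(n_sparse)
        for r in np.cumsum(spacing):
            pts.append(list(r * u))
            labels.append(arm)
    X = np.asarray(pts) + jitter * rng.standard_normal((len(pts), 2))
    return X, labels


class MapperChart(BaseEstimator):
    """Mapper estimator: ``fit(cloud)`` builds the topological chart.

    Parameters
    ----------
    k : filter neighbour rank (2 = nearest other point).
    n_intervals, overlap_pct : cover resolution MI and overlap MO.
    gap_sd : Ward dendrogram first-gap sensitivity (merge counts as a gap
        when its height exceeds mean + gap_sd * sd of earlier merges).
    allow_singletons : keep single-point local clusters as nodes.

    Attributes (after fit)
    ----------------------
    filter_values_, cover_, chart_, graph_
    """

    def __init__(self, k: int = 2, n_intervals: int = 3,
                 overlap_pct: float = 50.0, gap_sd: float = 2.0,
                 gap_ratio: float = 3.0, allow_singletons: bool = True):
        self.k = k
        self.n_intervals = n_intervals
        self.overlap_pct = overlap_pct
        self.gap_sd = gap_sd
        self.gap_ratio = gap_ratio
        self.allow_singletons = allow_singletons

    def fit(self, cloud: PointCloud | np.ndarray, y=None):
        if isinstance(cloud, PointCloud):
            X, names = cloud.X, list(cloud.feature_names)
        else:
            X = np.asarray(cloud, float)
            names = [f"p{i}" for i in range(len(X))]
        fv = knn_filter(X, self.k)
        cover = build_cover(fv, self.n_intervals, self.overlap_pct)
        nodes: list[MapperNode] = []
        node_members: list[set[int]] = []
        node_intervals: list[int] = []
        for interval in cover:
            mask = np.nonzero(interval.contains(fv))[0]
            if len(mask) == 0:
                continue
            for idx in cluster_preimage(X[mask], self.gap_sd,
                                        self.gap_ratio):
                members = mask[idx]
                if len(members) == 1 and not self.allow_singletons:
                    continue
                nid = len(nodes)
                nodes.append(MapperNode(
                    nid, tuple(names[i] for i in sorted(members)),
                    interval.index, float(np.mean(fv[members]))))
                node_members.append(set(int(i) for i in members))
                node_intervals.append(interval.index)
        edges: list[tuple[int, int, int]] = []
        for u in range(len(nodes)):
            for v in range(u + 1, len(nodes)):
                if abs(node_intervals[u] - node_intervals[v]) != 1:
                    continue
                shared = node_members[u] & node_members[v]
                if shared:
                    edges.append((u, v, len(shared)))
        self.filter_values_ = fv
        self.cover_ = cover
        self.chart_ = TopologicalChart(
            nodes, edges,
            {"k": self.k, "n_intervals": self.n_intervals,
             "overlap_pct": self.overlap_pct, "gap_sd": self.gap_sd,
             "gap_ratio": self.gap_ratio})
        self.graph_ = self.chart_.to_networkx()
        return self


def build_chart(cloud: PointCloud | np.ndarray, k: int = 2,
                n_intervals: int = 3, overlap_pct: float = 50.0,
                gap_sd: float = 2.0, gap_ratio: float = 3.0,
                allow_singletons: bool = True) -> TopologicalChart:
    return MapperChart(k=k, n_intervals=n_intervals,
                       overlap_pct=overlap_pct, gap_sd=gap_sd,
                       gap_ratio=gap_ratio,
                       allow_singletons=allow_singletons).fit(cloud).chart_


# ---------------------------------------------------------------------------
# structural decomposition

@dataclass
class ChartDecomposition:
    """Connected components (largest first), per-component core node ids
    (degree >= 3) and arms (maximal degree-<=2 chains)."""

    components: list[list[int]]
    cores: list[list[int]]
    arms: list[list[list[int]]]  # arms[c] = list of node-id chains

    @property
    def n_components(self) -> int:
        return len(self.components)

    def arm_count(self, component: int = 0) -> int:
        return len(self.arms[component])


def decompose_chart(chart: TopologicalChart) -> ChartDecomposition:
    g = chart.to_networkx()
    comps = sorted(nx.connected_components(g),
                   key=lambda c: (-len(c), min(c)))
    components, cores, arms = [], [], []
    for comp in comps:
        comp_nodes = sorted(comp)
        sub = g.subgraph(comp_nodes)
        core = sorted(n for n in comp_nodes if sub.degree(n) >= 3)
        rest = sub.subgraph([n for n in comp_nodes if n not in core])
        comp_arms = []
        for chain in nx.connected_components(rest):
            chain = sorted(chain)
            if core:
                comp_arms.append(chain)  # hangs off the core
            elif len(chain) >= 2:
                comp_arms.append(chain)  # a core-less path is one arm
        components.append(comp_nodes)
        cores.append(core)
        arms.append(sorted(comp_arms))
    return ChartDecomposition(components, cores, arms)


def annotate_groups(chart: TopologicalChart,
                    labels: dict[int, str] | None = None
                    ) -> TopologicalChart:
    """Attach functional-group labels to nodes.

    With no explicit mapping, labels derive from the decomposition: each arm
    of each component becomes ``c<i>_arm<j>``, core nodes ``c<i>_core`` and
    arm-less isolated nodes ``c<i>``.
    """
    if labels is not None:
        chart.groups = dict(labels)
        return chart
    deco = decompose_chart(chart)
    groups: dict[int, str] = {}
    for ci, comp in enumerate(deco.components):
        for n in deco.cores[ci]:
            groups[n] = f"c{ci}_core"
        for ai, arm in enumerate(deco.arms[ci]):
            for n in arm:
                groups[n] = f"c{ci}_arm{ai}"
        for n in comp:
            groups.setdefault(n, f"c{ci}")
    chart.groups = groups
    return chart
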