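"""TDA Mapper over the rule-index point cloud.

Each mined rule is a point in 3-D index space (support, confidence,
lift).  Mapper summarises that cloud as a graph in four steps: compute a
pairwise distance matrix, map each point to a scalar filter (lens)
value, cover the filter range with overlapping intervals, cluster the
points of each interval's preimage, and finally connect clusters from
different intervals that share points (the nerve of the cover).  The
resulting graph exposes the cloud's shape — connected regions, branches,
loops — at a resolution set by the number of intervals and their
overlap.

Choices made here, all configurable:

* indices are z-scored per column before distances by default, since
  support/confidence are percent-scale while lift is a ratio;
* Euclidean metric;
* filter = eccentricity (mean distance to all points, self included) by
  default; a coordinate projection or the first principal direction are
  alternatives;
* clustering = single linkage with the histogram-gap heuristic standard
  in the Mapper literature: the dendrogram is cut at the first empty bin
  of a histogram of merge distances (no empty bin means one cluster).

Interval membership is half-open [lo, hi) with the last interval closed
at its right end, so that with zero overlap the cover is an exact
partition of the filter range and the nerve has no edges.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .errors import ConfigError
from .mining import AssociationRule

logger = logging.getLogger(__name__)

INDEX_NAMES = ("support", "confidence", "lift")


@dataclass(frozen=True)
class RuleIndexMatrix:
    """Rules x 3 matrix of (support, confidence, lift) values."""

    rule_ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)  # float, shape (n_rules, 3)
    standardized: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != len(INDEX_NAMES):
            raise ValueError("values must be an (n_rules, 3) matrix")
        if self.values.shape[0] != len(self.rule_ids):
            raise ValueError("rule_ids and values row count disagree")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("index values must be finite")

    @property
    def n(self) -> int:
        return len(self.rule_ids)

    def points(self) -> np.ndarray:
        """The coordinates used for geometry: standardized if present."""
        return self.values if self.standardized is None else self.standardized


def rule_index_matrix(rules: Sequence[AssociationRule]) -> RuleIndexMatrix:
    """Build the index matrix from mined rules; ids are ``"X->Y"``."""
    if not rules:
        raise ValueError("no rules to build an index matrix from")
    ids = tuple(f"{r.x_code}->{r.y_code}" for r in rules)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate rule identifiers")
    values = np.array(
        [[r.support, r.confidence, r.lift] for r in rules], dtype=float
    )
    return RuleIndexMatrix(rule_ids=ids, values=values)


@dataclass(frozen=True)
class DistanceMatrix:
    values: np.ndarray = field(repr=False)  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0) or np.any(v < 0):
            raise ValueError("distances must be nonnegative with zero diagonal")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class Interval:
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"degenerate interval [{self.lo}, {self.hi}]")


@dataclass(frozen=True)
class Cover:
    """Overlapping interval cover of the filter range."""

    intervals: tuple[Interval, ...]
    overlap: float
    n_intervals: int

    def assign(self, fvals: np.ndarray) -> list[np.ndarray]:
        """Point indices in each interval's preimage.

        Membership is lo <= v < hi except the last interval, which is
        closed on the right so the maximum is always covered.
        """
        fvals = np.asarray(fvals, dtype=float)
        out = []
        last = len(self.intervals) - 1
        for i, iv in enumerate(self.intervals):
            if i == last:
                mask = (fvals >= iv.lo) & (fvals <= iv.hi)
            else:
                mask = (fvals >= iv.lo) & (fvals < iv.hi)
            out.append(np.flatnonzero(mask))
        return out


@dataclass(frozen=True)
class MapperNode:
    node_id: str
    interval_index: int
    member_rule_ids: frozenset[str]
    size: int
    mean_support: float
    mean_confidence: float
    mean_lift: float


@dataclass(frozen=True)
class MapperGraph:
    """Nerve of the clustered cover: clusters as nodes, shared members as edges."""

    nodes: tuple[MapperNode, ...]
    edges: tuple[tuple[str, str, int], ...]  # (node_id, node_id, shared_count)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for nd in self.nodes:
            g.add_node(
                nd.node_id,
                size=nd.size,
                interval_index=nd.interval_index,
                mean_support=nd.mean_support,
                mean_confidence=nd.mean_confidence,
                mean_lift=nd.mean_lift,
                members=",".join(sorted(nd.member_rule_ids)),
            )
        for u, v, w in self.edges:
            g.add_edge(u, v, shared_count=w)
        return g

    def connected_components(self) -> list[list[str]]:
        """Components as node-id lists, largest first.

        Ordering: by total member count descending, then by the smallest
        member rule id — a deterministic stand-in for presentation-style
        group labels (A, B, C, ...).
        """
        g = self.to_networkx()
        by_id = {nd.node_id: nd for nd in self.nodes}

        def key(comp: set[str]) -> tuple:
            members = set().union(*(by_id[n].member_rule_ids for n in comp))
            return (-len(members), min(members))

        comps = sorted(nx.connected_components(g), key=key)
        return [sorted(c) for c in comps]

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), str(path))

    def write_dot(self, path: str | Path) -> None:
        # hand-rolled writer: pydot/graphviz bindings are not required
        lines = ["graph mapper {"]
        for nd in self.nodes:
            lines.append(
                f'  "{nd.node_id}" [size={nd.size} interval={nd.interval_index} '
                f"mean_support={nd.mean_support:.6g} "
                f"mean_confidence={nd.mean_confidence:.6g} "
                f"mean_lift={nd.mean_lift:.6g}];"
            )
        for u, v, w in self.edges:
            lines.append(f'  "{u}" -- "{v}" [shared_count={w}];')
        lines.append("}")
        Path(path).write_text("\n".join(lines) + "\n")

    def write_memberships_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            fh.write("node_id,rule_id\n")
            for nd in self.nodes:
                for rid in sorted(nd.member_rule_ids):
                    fh.write(f"{nd.node_id},{rid}\n")


@dataclass(frozen=True)
class MapperConfig:
    """Mapper hyperparameters.

    ``filter_kind`` is one of ``"eccentricity"``, ``"coordinate"`` (with
    ``coordinate_index`` selecting the column of the index matrix), or
    ``"max_variance_projection"`` (projection onto the first principal
    direction).
    """

    n_intervals: int = 5
    overlap: float = 0.5
    filter_kind: str = "eccentricity"
    coordinate_index: int = 0
    num_bins: int = 10
    standardize: bool = True
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        if self.n_intervals < 1:
            raise ConfigError("n_intervals must be >= 1")
        if not (0.0 <= self.overlap < 1.0):
            raise ConfigError("overlap must lie in [0, 1)")
        if self.filter_kind not in (
            "eccentricity",
            "coordinate",
            "max_variance_projection",
        ):
            raise ConfigError(f"unknown filter kind {self.filter_kind!r}")
        if self.metric != "euclidean":
            raise ConfigError("only the euclidean metric is supported")
        if self.num_bins < 2:
            raise ConfigError("num_bins must be >= 2")


def standardize(matrix: RuleIndexMatrix) -> RuleIndexMatrix:
    """Column-wise z-scores (sample SD, ddof=1).

    A constant column is mapped to zeros with a warning: it carries no
    geometry but must not poison the distances with NaN.
    """
    if matrix.n < 2:
        raise ValueError("standardization needs at least 2 rules")
    mean = matrix.values.mean(axis=0)
    sd = matrix.values.std(axis=0, ddof=1)
    z = np.zeros_like(matrix.values)
    for j in range(matrix.values.shape[1]):
        if sd[j] == 0.0:
            warnings.warn(
                f"index column {INDEX_NAMES[j]!r} is constant; standardized to zeros",
                stacklevel=2,
            )
        else:
            z[:, j] = (matrix.values[:, j] - mean[j]) / sd[j]
    return replace(matrix, standardized=z)


def distance_matrix(matrix: RuleIndexMatrix, metric: str = "euclidean") -> DistanceMatrix:
    """Pairwise distances between rules in index space."""
    pts = matrix.points()
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 points for a distance matrix")
    return DistanceMatrix(squareform(pdist(pts, metric=metric)))


def filter_values(
    dist: DistanceMatrix,
    kind: str = "eccentricity",
    *,
    matrix: RuleIndexMatrix | None = None,
    coordinate_index: int = 0,
) -> np.ndarray:
    """One scalar lens value per point.

    ``eccentricity`` is the mean of each point's distance row (self
    included); ``coordinate`` returns one column of the (standardized)
    index matrix; ``max_variance_projection`` projects the points onto
    the direction of maximal variance.  The latter two require
    ``matrix``.
    """
    if kind == "eccentricity":
        return dist.values.mean(axis=1)
    if matrix is None:
        raise ValueError(f"filter kind {kind!r} requires the index matrix")
    pts = matrix.points()
    if kind == "coordinate":
        if not 0 <= coordinate_index < pts.shape[1]:
            raise IndexError(
                f"coordinate index {coordinate_index} out of range for "
                f"{pts.shape[1]} columns"
            )
        return pts[:, coordinate_index].copy()
    if kind == "max_variance_projection":
        centered = pts - pts.mean(axis=0)
        # right singular vector of the largest singular value
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        direction = vt[0]
        # deterministic sign: largest-magnitude component positive
        if direction[np.argmax(np.abs(direction))] < 0:
            direction = -direction
        return centered @ direction
    raise ValueError(f"unknown filter kind {kind!r}")


def build_cover(fvals: np.ndarray, n_intervals: int, overlap: float) -> Cover:
    """Overlapping interval cover of [min(fvals), max(fvals)].

    With range R, interval length is L = R / (n - (n-1)*overlap) and
    interval i starts at min + i*L*(1-overlap); consecutive intervals
    then overlap by exactly the fraction ``overlap`` of L.  Constant
    filter values yield a single unit-width interval centred on the
    value.
    """
    if n_intervals < 1:
        raise ConfigError("n_intervals must be >= 1")
    if not (0.0 <= overlap < 1.0):
        raise ConfigError("overlap must lie in [0, 1)")
    fvals = np.asarray(fvals, dtype=float)
    if fvals.size == 0:
        raise ValueError("no filter values")
    lo, hi = float(fvals.min()), float(fvals.max())
    if lo == hi:
        return Cover(
            intervals=(Interval(lo - 0.5, hi + 0.5),), overlap=overlap, n_intervals=1
        )
    r = hi - lo
    length = r / (n_intervals - (n_intervals - 1) * overlap)
    step = length * (1.0 - overlap)
    intervals = []
    for i in range(n_intervals):
        start = lo + i * step
        end = start + length
        if i == n_intervals - 1:
            end = max(end, hi)  # guard float round-off at the top end
        intervals.append(Interval(start, end))
    return Cover(intervals=tuple(intervals), overlap=overlap, n_intervals=n_intervals)


def cluster_preimage(
    member_ids: Sequence[int], dist: DistanceMatrix, num_bins: int = 10
) -> list[list[int]]:
    """Single-linkage clusters of one interval's preimage.

    The merge heights of the dendrogram are histogrammed over
    [0, max height] with ``num_bins`` bins, and the cut threshold is the
    first empty bin that lies *above* the first occupied one (an actual
    gap in the merge-height distribution).  No such gap — including the
    degenerate case of all merges at one height — means one cluster.
    Returns clusters as lists of the original point indices.
    """
    members = list(member_ids)
    if not members:
        raise ValueError("empty preimage")
    if len(members) == 1:
        return [members]
    sub = dist.values[np.ix_(members, members)]
    z = linkage(squareform(sub, checks=False), method="single")
    merges = z[:, 2]
    d_hi = float(merges.max())
    if d_hi == 0.0:  # all points coincide
        return [members]
    counts, edges = np.histogram(merges, bins=num_bins, range=(0.0, d_hi))
    occupied = np.flatnonzero(counts > 0)
    empty_above = np.flatnonzero((counts == 0) & (np.arange(num_bins) > occupied[0]))
    if empty_above.size == 0:
        return [members]
    threshold = float(edges[empty_above[0]])
    labels = fcluster(z, t=threshold, criterion="distance")
    clusters: dict[int, list[int]] = {}
    for m, lab in zip(members, labels):
        clusters.setdefault(int(lab), []).append(m)
    return [sorted(c) for c in sorted(clusters.values(), key=lambda c: c[0])]


def build_nerve(
    clusters_by_interval: Sequence[Sequence[Sequence[int]]],
    matrix: RuleIndexMatrix,
) -> MapperGraph:
    """Nerve graph of the clustered cover.

    One node per cluster, annotated with its size and the mean of each
    raw index over its members; an edge joins every pair of clusters
    from *different* intervals whose member sets intersect, weighted by
    the intersection size.
    """
    nodes: list[MapperNode] = []
    member_sets: dict[str, set[int]] = {}
    for i, clusters in enumerate(clusters_by_interval):
        for k, cluster in enumerate(clusters):
            idx = sorted(int(m) for m in cluster)
            if not idx:
                continue
            node_id = f"i{i}c{k}"
            vals = matrix.values[idx]
            nodes.append(
                MapperNode(
                    node_id=node_id,
                    interval_index=i,
                    member_rule_ids=frozenset(matrix.rule_ids[m] for m in idx),
                    size=len(idx),
                    mean_support=float(vals[:, 0].mean()),
                    mean_confidence=float(vals[:, 1].mean()),
                    mean_lift=float(vals[:, 2].mean()),
                )
            )
            member_sets[node_id] = set(idx)
    edges: list[tuple[str, str, int]] = []
    for u in range(len(nodes)):
        for v in range(u + 1, len(nodes)):
            if nodes[u].interval_index == nodes[v].interval_index:
                continue
            shared = member_sets[nodes[u].node_id] & member_sets[nodes[v].node_id]
            if shared:
                edges.append((nodes[u].node_id, nodes[v].node_id, len(shared)))
    return MapperGraph(nodes=tuple(nodes), edges=tuple(edges))


def run_mapper(matrix: RuleIndexMatrix, config: MapperConfig | None = None) -> MapperGraph:
    """Full Mapper chain: standardize, distances, lens, cover, cluster, nerve.

    Deterministic: no stage involves randomness, so identical inputs and
    config always give the identical graph.
    """
    config = config or MapperConfig()
    if matrix.n < 2:
        raise ValueError("Mapper needs at least 2 rules")
    m = standardize(matrix) if config.standardize else matrix
    dist = distance_matrix(m, metric=config.metric)
    fvals = filter_values(
        dist,
        config.filter_kind,
        matrix=m,
        coordinate_index=config.coordinate_index,
    )
    cover = build_cover(fvals, config.n_intervals, config.overlap)
    clusters_by_interval = []
    for members in cover.assign(fvals):
        if members.size == 0:
            clusters_by_interval.append([])
        else:
            clusters_by_interval.append(
                cluster_preimage(members.tolist(), dist, config.num_bins)
            )
    return build_nerve(clusters_by_interval, m)


def plot_graph(
    graph: MapperGraph, out_prefix: str | Path, seed: int = 0
) -> list[Path]:
    """Optional static plots: one spring layout per index coloring.

    Requires matplotlib; returns the written paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    g = graph.to_networkx()
    pos = nx.spring_layout(g, seed=seed)
    written = []
    for attr in ("mean_support", "mean_confidence", "mean_lift"):
        fig, ax = plt.subplots(figsize=(7, 6))
        colors = [g.nodes[n][attr] for n in g.nodes]
        sizes = [60 + 20 * g.nodes[n]["size"] for n in g.nodes]
        nx.draw_networkx(
            g, pos=pos, ax=ax, node_color=colors, node_size=sizes,
            cmap="viridis", with_labels=False,
        )
        ax.set_title(attr)
        path = Path(f"{out_prefix}_{attr}.png")
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
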