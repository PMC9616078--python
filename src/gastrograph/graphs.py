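"""Slide graphs: discriminative patch selection and the Chebyshev edge rule.

A whole slide is modelled as a graph whose nodes are the most abnormal
patches and whose edges connect patches with similar bottleneck features.
Per patch, the abnormality grade is the mean of its probability map; the
top-n patches by grade become nodes (interference from pure-negative
regions is discarded).  An undirected edge joins nodes m and n exactly when
the Chebyshev (L-infinity) distance between their feature vectors is
*strictly* below a threshold gamma:

    E_mn = 1  if  max_k |x_m[k] - x_n[k]| < gamma   else  0

so gamma = 0 gives an edgeless graph and gamma = +inf a complete one.
gamma may be fixed or chosen per slide as a percentile of the pairwise node
distances ("auto" mode).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "GraphConfig",
    "GraphNode",
    "SlideGraph",
    "abnormality_grade",
    "select_discriminative_nodes",
    "chebyshev_distance",
    "build_graph",
]


@dataclass(frozen=True)
class GraphConfig:
    """Graph construction parameters.

    gamma:
        Edge threshold; a float >= 0 (``numpy.inf`` allowed) or ``"auto"``
        to use the `auto_percentile`-th percentile of this slide's pairwise
        node distances.
    """

    n_nodes: int = 64
    gamma: float | str = "auto"
    auto_percentile: float = 20.0
    add_self_loops: bool = True

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        if isinstance(self.gamma, str):
            if self.gamma != "auto":
                raise ValueError("gamma must be a number >= 0 or 'auto'")
            if not 0 <= self.auto_percentile <= 100:
                raise ValueError("auto_percentile must lie in [0, 100]")
        elif self.gamma < 0:
            raise ValueError("gamma must be >= 0")


@dataclass(frozen=True)
class GraphNode:
    """One selected discriminative patch."""

    patch_index: int          # index into the slide's surviving-patch list
    row: int
    col: int
    grade: float
    feature: np.ndarray = field(repr=False)


@dataclass
class SlideGraph:
    """Selected nodes plus the symmetric binary adjacency matrix."""

    slide_id: str
    nodes: list[GraphNode]
    adjacency: np.ndarray
    gamma: float
    label: str | None = None

    @property
    def features(self) -> np.ndarray:
        return np.stack([nd.feature for nd in self.nodes])

    @property
    def grades(self) -> np.ndarray:
        return np.array([nd.grade for nd in self.nodes])


def abnormality_grade(prob_map: np.ndarray) -> float:
    """Abnormality grade of a patch: mean of its probability map."""
    pm = np.asarray(prob_map, dtype=np.float64)
    if pm.size == 0:
        raise ValueError("empty probability map")
    if pm.min() < 0 or pm.max() > 1:
        raise ValueError("probability map values must lie in [0, 1]")
    return float(pm.mean())


def select_discriminative_nodes(grades, n: int,
                                order_keys: list[tuple[int, int]] | None = None) -> list[int]:
    """Indices of the n highest-grade patches.

    Ties are broken by row-major patch order (`order_keys` = (row, col) per
    patch when the natural index order is not already row-major).  The
    result is sorted by descending grade, then row-major, and contains all
    patches when fewer than n exist.
    """
    grades = np.asarray(grades, dtype=np.float64)
    if grades.size == 0:
        raise ValueError("no patches to select from")
    keys = order_keys if order_keys is not None else [(0, i) for i in range(grades.size)]
    order = sorted(range(grades.size), key=lambda i: (-grades[i], keys[i]))
    return order[:n]


def chebyshev_distance(x_m: np.ndarray, x_n: np.ndarray) -> float:
    """L-infinity distance: max over coordinates of the absolute difference."""
    a = np.asarray(x_m, dtype=np.float64)
    b = np.asarray(x_n, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"feature length mismatch: {a.shape} vs {b.shape}")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("features must be finite")
    return float(np.max(np.abs(a - b))) if a.size else 0.0


def resolve_gamma(features: np.ndarray, cfg: GraphConfig) -> float:
    """Concrete gamma for one slide (percentile of pairwise distances in
    auto mode; the configured constant otherwise)."""
    if not isinstance(cfg.gamma, str):
        return float(cfg.gamma)
    n = features.shape[0]
    if n < 2:
        return 0.0
    dist = cdist(features, features, metric="chebyshev")
    pair = dist[np.triu_indices(n, k=1)]
    return float(np.percentile(pair, cfg.auto_percentile))


def build_graph(nodes: list[GraphNode], cfg: GraphConfig = GraphConfig(), *,
                slide_id: str = "", label: str | None = None) -> SlideGraph:
    """Assemble the slide graph from already-selected nodes.

    Applies the strict-inequality Chebyshev edge rule at the resolved gamma;
    the adjacency is symmetric by construction with diagonal 1 exactly when
    self-loops are enabled.
    """
    if not nodes:
        raise ValueError("a graph needs at least one node")
    feats = np.stack([nd.feature for nd in nodes]).astype(np.float64)
    gamma = resolve_gamma(feats, cfg)
    dist = cdist(feats, feats, metric="chebyshev")
    adj = (dist < gamma).astype(np.uint8)
    np.fill_diagonal(adj, 1 if cfg.add_self_loops else 0)
    return SlideGraph(slide_id, list(nodes), adj, gamma, label=label)


def graph_from_patch_outputs(prob_maps, features, patches, cfg: GraphConfig = GraphConfig(),
                             *, slide_id: str = "", label: str | None = None) -> SlideGraph:
    """Grade patches, keep the top n as nodes, and build the graph.

    `prob_maps`, `features` and `patches` are aligned sequences of the
    surviving patches of one slide (row-major).
    """
    grades = [abnormality_grade(pm) for pm in prob_maps]
    keys = [(pt.row, pt.col) for pt in patches]
    chosen = select_discriminative_nodes(grades, cfg.n_nodes, order_keys=keys)
    nodes = [GraphNode(i, patches[i].row, patches[i].col, grades[i],
                       np.asarray(features[i], dtype=np.float32)) for i in chosen]
    return build_graph(nodes, cfg, slide_id=slide_id, label=label)
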