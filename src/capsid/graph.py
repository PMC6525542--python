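"""Capsomer neighbor graphs and symmetry-environment classification.

Adjacency is recovered from 3-D capsomer centers by a distance cutoff at
``cutoff_factor`` times the median nearest-neighbor distance (default 1.4,
sitting between the first lattice shell at ~1.0 spacings and the second at
~sqrt(3) spacings).  Each capsomer is then classified by its coordination
environment:

- ``fivefold``        degree 5 (pentamer);
- ``pseudothreefold`` degree 6 with at least one fivefold neighbor;
- ``threefold``       degree 6 with only sixfold neighbors;
- ``edge``            any other degree (lattice boundary or noise artifact).

For a closed fullerene shell the discrete Gauss-Bonnet relation forces the
disclination sum over all capsomers, sum(6 - coordination), to equal 12 —
i.e. exactly twelve pentamers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist, squareform

from .synth import CapsomerSet

__all__ = [
    "LatticeGraph",
    "ClosureReport",
    "build_graph",
    "classify_capsomers",
    "closure_report",
]

logger = logging.getLogger(__name__)

CLASS_FIVEFOLD = "fivefold"
CLASS_PSEUDO = "pseudothreefold"
CLASS_THREE = "threefold"
CLASS_EDGE = "edge"


@dataclass
class LatticeGraph:
    """Capsomer adjacency graph with positions, degrees and class labels.

    Wraps a :class:`networkx.Graph` whose nodes are capsomer indices with a
    ``pos`` attribute (nm) and, after :func:`classify_capsomers`, a
    ``class_label`` attribute.
    """

    graph: nx.Graph
    particle_id: str = ""
    classified: bool = False
    adjacency_mode: str = "cutoff"

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def positions(self) -> np.ndarray:
        return np.array([self.graph.nodes[i]["pos"] for i in sorted(self.graph)])

    @property
    def center(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    def degree(self, node: int) -> int:
        return self.graph.degree[node]

    def label(self, node: int) -> str:
        return self.graph.nodes[node]["class_label"]

    def nodes_with_label(self, label: str) -> list:
        return [n for n, d in self.graph.nodes(data=True)
                if d.get("class_label") == label]

    @property
    def class_counts(self) -> dict:
        if not self.classified:
            raise ValueError("graph is not classified yet")
        counts = {CLASS_FIVEFOLD: 0, CLASS_PSEUDO: 0, CLASS_THREE: 0,
                  CLASS_EDGE: 0}
        for _, d in self.graph.nodes(data=True):
            counts[d["class_label"]] += 1
        return counts


@dataclass
class ClosureReport:
    """Fullerene closure verdict for one particle."""

    complete: bool
    n_pentamers: int
    n_hexamers: int
    disclination_sum: int


def build_graph(
    cs: CapsomerSet,
    cutoff_factor: float = 1.4,
    *,
    method: str = "cutoff",
) -> LatticeGraph:
    """Build the capsomer adjacency graph.

    ``method='cutoff'`` (default) links capsomers closer than
    ``cutoff_factor`` x the median nearest-neighbor distance.
    ``method='hull'`` uses convex-hull (spherical Delaunay) edges instead —
    robust for heavily distorted sets where the cutoff graph fractures;
    it assumes a roughly convex shell.  ``method='auto'`` builds the cutoff
    graph and, if it fails fullerene closure while the hull graph passes,
    switches to the hull graph with a logged warning (the chosen mode is
    recorded in ``LatticeGraph.adjacency_mode``).
    """
    if method == "auto":
        lg = build_graph(cs, cutoff_factor, method="cutoff")
        if closure_report(classify_capsomers(lg)).complete:
            return lg
        lg_hull = build_graph(cs, cutoff_factor, method="hull")
        if closure_report(classify_capsomers(lg_hull)).complete:
            logger.warning(
                "particle %s: cutoff graph fails closure; falling back to "
                "spherical-Delaunay adjacency", cs.particle_id,
            )
            return lg_hull
        return lg
    pos = cs.positions
    n = pos.shape[0]
    if n < 2:
        raise ValueError("need at least 2 capsomers to build a graph")
    if not cutoff_factor > 0:
        raise ValueError("cutoff_factor must be positive")
    centered = pos - pos.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(pos).max())) < 2:
        raise ValueError("degenerate geometry: capsomers are collinear or coincident")

    g = nx.Graph()
    for i in range(n):
        g.add_node(i, pos=pos[i])

    if method == "cutoff":
        d = squareform(pdist(pos))
        np.fill_diagonal(d, np.inf)
        nearest = d.min(axis=1)
        cutoff = cutoff_factor * float(np.median(nearest))
        ii, jj = np.nonzero(np.triu(d <= cutoff, k=1))
        g.add_edges_from(zip(ii.tolist(), jj.tolist()))
    elif method == "hull":
        # Spherical Delaunay: triangulate the radial directions, then drop
        # implausibly long edges (e.g. spanning the opening of a partial
        # shell) at 1.8 x the median nearest-neighbor distance.
        norms = np.linalg.norm(centered, axis=1)
        if norms.min() <= 0:
            raise ValueError("capsomer at the particle centroid")
        dirs = centered / norms[:, None]
        hull = ConvexHull(dirs)
        d = squareform(pdist(pos))
        np.fill_diagonal(d, np.inf)
        prune = 1.8 * float(np.median(d.min(axis=1)))
        for simplex in hull.simplices:
            a, b, c = (int(x) for x in simplex)
            for u, v in ((a, b), (b, c), (a, c)):
                if d[u, v] <= prune:
                    g.add_edge(u, v)
    else:
        raise ValueError("method must be 'cutoff' or 'hull'")

    return LatticeGraph(graph=g, particle_id=cs.particle_id,
                        adjacency_mode=method)


def classify_capsomers(lg: LatticeGraph) -> LatticeGraph:
    """Label each capsomer by its coordination environment (in place).

    Degree-5 capsomers are pentamers (fivefold); degree-6 capsomers are
    hexamers, split into pseudothreefold (adjacent to a pentamer) and true
    threefold (surrounded by hexamers).  Any other degree — boundary
    capsomers of incomplete shells, or 7+-coordinated noise artifacts — is
    labelled ``edge`` and excluded from downstream class statistics.
    """
    g = lg.graph
    for node in g:
        deg = g.degree[node]
        if deg == 5:
            g.nodes[node]["class_label"] = CLASS_FIVEFOLD
        elif deg != 6:
            g.nodes[node]["class_label"] = CLASS_EDGE
    for node in g:
        if g.degree[node] != 6:
            continue
        has_five = any(g.degree[m] == 5 for m in g[node])
        g.nodes[node]["class_label"] = CLASS_PSEUDO if has_five else CLASS_THREE
    lg.classified = True
    return lg


def closure_report(lg: LatticeGraph) -> ClosureReport:
    """Fullerene closure check: complete iff every coordination is 5 or 6
    and the disclination sum, sum(6 - degree), is exactly 12."""
    if not lg.classified:
        raise ValueError("classify_capsomers must run before closure_report")
    g = lg.graph
    degrees = [g.degree[n] for n in g]
    disclination = int(sum(6 - d for d in degrees))
    n_pent = sum(1 for d in degrees if d == 5)
    n_hex = sum(1 for d in degrees if d == 6)
    complete = all(d in (5, 6) for d in degrees) and disclination == 12
    return ClosureReport(
        complete=complete,
        n_pentamers=n_pent,
        n_hexamers=n_hex,
        disclination_sum=disclination,
    )
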