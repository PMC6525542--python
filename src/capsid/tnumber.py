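"""Triangulation-number determination by lattice walks.

The Caspar-Klug index of a pentamer pair is read off by walking the hexamer
lattice: the shortest route between two pentamers consists of h steps along
one lattice direction, a 60-degree turn, and k steps along the new
direction, giving T = h^2 + hk + k^2.  Implementation-wise, an integer
two-axis frame is transported outward from one pentamer by breadth-first
traversal over hexamers; each hexamer's six neighbors, taken in cyclic
order about the outward normal, realise the six unit steps of the local
frame, and the frame is carried edge-to-edge so the coordinate of the
target pentamer can be read off directly.

Because a pentagonal disclination removes a 60-degree wedge, frame
transport is path-dependent around pentamers; walks are therefore
restricted to hexamer-only corridors and, among the corridors found, the
minimal-T result is returned.  (h, k) and (k, h) describe mirror-image
lattices with equal T; results are canonicalised to h >= k >= 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.spatial import ConvexHull

from .graph import (
    CLASS_FIVEFOLD,
    ClosureReport,
    LatticeGraph,
    classify_capsomers,
    closure_report,
)

__all__ = [
    "TReport",
    "LatticeCensus",
    "local_t",
    "particle_t",
    "lattice_census",
    "asu_decomposition",
    "canonical_hk",
]

# Axial unit steps in counter-clockwise order (60 degrees apart).
_STEPS = ((1, 0), (0, 1), (-1, 1), (-1, 0), (0, -1), (1, -1))

VERDICT_ICOSAHEDRAL = "icosahedral"
VERDICT_MIXED = "mixed"
VERDICT_INCOMPLETE = "incomplete"


@dataclass
class PairT:
    """Local (h, k, T) for one pentamer pair; h >= k >= 0 canonical.

    ``chirality`` records the hand of the walk before canonicalisation:
    +1 if the raw step vector is a pure rotation of (h, k), -1 if it is the
    mirror image, 0 for achiral vectors (k = 0 or h = k).
    """

    pent_i: int
    pent_j: int
    h: Optional[int]
    k: Optional[int]
    T: Optional[int]
    chirality: int = 0

    @property
    def resolved(self) -> bool:
        return self.T is not None


@dataclass
class TReport:
    """Per-particle triangulation-number verdict."""

    pairs: List[PairT]
    global_T_from_count: Optional[int]
    verdict: str
    T_values: List[int] = field(default_factory=list)

    @property
    def T(self) -> Optional[int]:
        """The icosahedral T-number, or None for mixed/incomplete."""
        if self.verdict == VERDICT_ICOSAHEDRAL:
            return self.T_values[0]
        return None


@dataclass
class LatticeCensus:
    """Closed-form composition of a T-number capsid."""

    T: int
    n_subunits: int
    n_capsomers: int
    n_pentamers: int
    n_hexamers: int


def canonical_hk(h: int, k: int) -> Tuple[int, int]:
    """Canonical representative of an axial vector under the hexagonal
    point group (6 rotations x mirror): the one with h >= k >= 0."""
    best = None
    a, b = h, k
    for _ in range(6):
        a, b = -b, a + b          # rotate +60 degrees
        for (p, q) in ((a, b), (b, a)):   # mirror swaps the axes
            if p >= q >= 0 and (best is None or (p, q) < best):
                best = (p, q)
    if best is None:  # pragma: no cover - every orbit has a canonical member
        raise RuntimeError("canonicalization failed")
    return best


def _cyclic_neighbors(lg: LatticeGraph) -> dict:
    """Neighbors of every node sorted counter-clockwise about the outward
    normal (position relative to the particle centroid)."""
    g = lg.graph
    center = lg.center
    order = {}
    for node in g:
        p = g.nodes[node]["pos"]
        normal = p - center
        nn = np.linalg.norm(normal)
        if nn == 0:
            raise ValueError("capsomer at particle centroid")
        normal = normal / nn
        # Tangent basis with consistent handedness.
        ref = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(ref, normal)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        t1 = np.cross(normal, ref)
        t1 /= np.linalg.norm(t1)
        t2 = np.cross(normal, t1)
        angs = []
        for m in g[node]:
            d = g.nodes[m]["pos"] - p
            angs.append((np.arctan2(np.dot(d, t2), np.dot(d, t1)), m))
        angs.sort()
        order[node] = [m for _, m in angs]
    return order


def local_t(
    lg: LatticeGraph,
    pent_i: int,
    pent_j: int,
    *,
    _order: Optional[dict] = None,
) -> Optional[Tuple[int, int, int]]:
    """Walk the hexamer lattice from ``pent_i`` to ``pent_j``.

    Returns canonical ``(h, k, T)`` with ``h >= k >= 0`` and
    ``T = h^2 + hk + k^2``, or ``None`` when no hexamer-only corridor
    connects the pair (an unresolvable pair, e.g. blocked by adjacent
    pentamers).
    """
    raw = _walk_raw(lg, pent_i, pent_j, _order=_order)
    if raw is None:
        return None
    h, k = canonical_hk(*raw)
    return h, k, h * h + h * k + k * k


def _walk_raw(
    lg: LatticeGraph,
    pent_i: int,
    pent_j: int,
    *,
    _order: Optional[dict] = None,
) -> Optional[Tuple[int, int]]:
    """Minimal-T raw (uncanonicalised) axial vector between two pentamers."""
    g = lg.graph
    if not lg.classified:
        raise ValueError("graph must be classified before walking")
    for p in (pent_i, pent_j):
        if g.nodes[p].get("class_label") != CLASS_FIVEFOLD:
            raise ValueError(f"node {p} is not a fivefold capsomer")
    if pent_i == pent_j:
        raise ValueError("pentamer pair must be distinct")

    candidates = []
    if g.has_edge(pent_i, pent_j):
        candidates.append((1, 0))

    order = _order if _order is not None else _cyclic_neighbors(lg)

    def is_hex(node: int) -> bool:
        return g.degree[node] == 6

    # Seed: put pent_i at the origin and its first hexamer neighbor at
    # (1, 0).  All seeds are related by 60-degree frame rotations (the
    # pentagon's missing wedge), which leave T unchanged.
    seed = next((m for m in order[pent_i] if is_hex(m)), None)
    if seed is not None:
        coord = {seed: (1, 0)}
        # Frame at a node: rotation offset rho such that the neighbor in
        # cyclic slot s lies along axial step (rho + s) mod 6.
        s_back = order[seed].index(pent_i)
        rho = {seed: (3 - s_back) % 6}
        queue = [seed]
        head = 0
        while head < len(queue):
            u = queue[head]
            head += 1
            cu = coord[u]
            ru = rho[u]
            for s, v in enumerate(order[u]):
                d = (ru + s) % 6
                cv = (cu[0] + _STEPS[d][0], cu[1] + _STEPS[d][1])
                if v == pent_j:
                    candidates.append(cv)
                    continue
                if not is_hex(v) or v in coord:
                    continue
                coord[v] = cv
                sb = order[v].index(u)
                rho[v] = ((d + 3) - sb) % 6
                queue.append(v)

    if not candidates:
        return None
    return min(candidates, key=lambda c: c[0] ** 2 + c[0] * c[1] + c[1] ** 2)


def _chirality(raw: Tuple[int, int], h: int, k: int) -> int:
    """Hand of a raw axial vector relative to its canonical (h, k)."""
    if k == 0 or h == k:
        return 0
    a, b = raw
    for _ in range(6):
        a, b = -b, a + b
        if (a, b) == (h, k):
            return 1
    return -1


def _pentamer_pairs(lg: LatticeGraph, pentamers: List[int], complete: bool):
    """Neighboring pentamer pairs: convex-hull edges of the pentamer
    direction vectors for closed shells, mutually nearest pentamers for
    incomplete ones."""
    pos = np.array([lg.graph.nodes[p]["pos"] for p in pentamers])
    if complete and len(pentamers) >= 4:
        center = lg.center
        dirs = pos - center
        dirs /= np.linalg.norm(dirs, axis=1)[:, None]
        hull = ConvexHull(dirs)
        pairs = set()
        for simplex in hull.simplices:
            a, b, c = (int(x) for x in simplex)
            for u, v in ((a, b), (b, c), (a, c)):
                pairs.add((pentamers[min(u, v)], pentamers[max(u, v)]))
        return sorted(pairs)
    # Mutually nearest pairing for damaged lattices.
    pairs = set()
    if len(pentamers) >= 2:
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        nearest = d.argmin(axis=1)
        for i, j in enumerate(nearest):
            if nearest[j] == i:
                a, b = pentamers[min(i, j)], pentamers[max(i, j)]
                pairs.add((a, b))
    return sorted(pairs)


def particle_t(lg: LatticeGraph) -> TReport:
    """Full per-particle T-number analysis.

    Walks every neighboring pentamer pair and renders the verdict:
    ``icosahedral`` when the shell is closed, every pair resolves to the
    same T, and that T matches the capsomer count via N = 10T + 2;
    ``mixed`` for closed shells with heterogeneous local T; ``incomplete``
    for open shells (local T listed where resolvable, no global T).
    """
    if not lg.classified:
        classify_capsomers(lg)
    closure = closure_report(lg)
    pentamers = sorted(lg.nodes_with_label(CLASS_FIVEFOLD))

    n = len(lg)
    global_T = (n - 2) // 10 if closure.complete and (n - 2) % 10 == 0 else None

    if len(pentamers) < 2:
        return TReport(pairs=[], global_T_from_count=global_T,
                       verdict=VERDICT_INCOMPLETE)

    order = _cyclic_neighbors(lg)
    pairs = []
    for (a, b) in _pentamer_pairs(lg, pentamers, closure.complete):
        raw = _walk_raw(lg, a, b, _order=order)
        if raw is None:
            pairs.append(PairT(a, b, None, None, None))
        else:
            h, k = canonical_hk(*raw)
            pairs.append(PairT(a, b, h, k, h * h + h * k + k * k,
                               chirality=_chirality(raw, h, k)))

    t_vals = sorted({p.T for p in pairs if p.resolved})
    if not closure.complete:
        verdict = VERDICT_INCOMPLETE
    elif (len(t_vals) == 1 and all(p.resolved for p in pairs)
          and (global_T is None or global_T == t_vals[0])):
        verdict = VERDICT_ICOSAHEDRAL
    else:
        verdict = VERDICT_MIXED
    return TReport(pairs=pairs, global_T_from_count=global_T,
                   verdict=verdict, T_values=t_vals)


def lattice_census(T: int) -> LatticeCensus:
    """Closed-form composition of a T-capsid: 60T subunits in 10T + 2
    capsomers (12 pentamers + 10(T - 1) hexamers)."""
    T = int(T)
    if T < 1:
        raise ValueError("T must be a positive integer")
    return LatticeCensus(
        T=T,
        n_subunits=60 * T,
        n_capsomers=10 * T + 2,
        n_pentamers=12,
        n_hexamers=10 * T - 10,
    )


def asu_decomposition(lg: LatticeGraph) -> dict:
    """Quasi-equivalent subunit multiplicities per icosahedral asymmetric
    unit: subunits contributed by each capsomer class divided by 60.

    For T = 9 this gives one fivefold, six pseudothreefold and two
    threefold copies per asymmetric unit.  Requires an icosahedral
    particle; the multiplicities always sum to T.
    """
    report = particle_t(lg)
    if report.verdict != VERDICT_ICOSAHEDRAL:
        raise ValueError(
            f"asu_decomposition requires an icosahedral particle "
            f"(verdict: {report.verdict})"
        )
    counts = lg.class_counts
    mult = {
        "fivefold": 5 * counts[CLASS_FIVEFOLD] / 60,
        "pseudothreefold": 6 * counts["pseudothreefold"] / 60,
        "threefold": 6 * counts["threefold"] / 60,
    }
    out = {}
    for key, val in mult.items():
        ival = int(round(val))
        if abs(val - ival) > 1e-9:
            raise ValueError("class counts are not commensurate with 60-fold symmetry")
        out[key] = ival
    return out
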