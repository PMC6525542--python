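"""Synthetic capsomer lattices and density maps.

Generators for ideal Caspar-Klug icosahedral shells, prolate (tubular)
fullerene shells with mixed local T-numbers, noisy/incomplete variants of
either, and voxelised density maps emulating immature (thick inner shell)
and mature (condensed core) particle morphologies.

A capsid with triangulation number T = h^2 + hk + k^2 carries 10T + 2
capsomers: 12 pentamers at the icosahedral fivefold axes and 10(T - 1)
hexamers.  Capsomer centers are the vertices of the (h, k) geodesic
subdivision of the icosahedron, either projected onto the circumscribed
sphere (default, matching quasi-spherical particles) or left on the facets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "CapsomerSet",
    "DensityMap",
    "generate_icosahedral",
    "generate_prolate",
    "perturb",
    "render_density",
]

_SQRT3_2 = math.sqrt(3.0) / 2.0


@dataclass
class CapsomerSet:
    """3-D capsomer centers for one particle.

    Attributes
    ----------
    particle_id : str
        Identifier used in tables and reports.
    positions : (N, 3) float array
        Capsomer centers in nm.
    radius_nominal : float or None
        Generation radius in nm; ``None`` for file-loaded sets.
    source : str
        Provenance: generation parameters or originating file path.
    seed : int or None
        RNG seed if stochastic operations produced this set.
    """

    particle_id: str
    positions: np.ndarray
    radius_nominal: Optional[float] = None
    source: str = ""
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be an (N, 3) array")
        if pos.shape[0] < 1:
            raise ValueError("a CapsomerSet needs at least one capsomer")
        if not np.all(np.isfinite(pos)):
            raise ValueError("capsomer coordinates must be finite")
        if pos.shape[0] > 1:
            from scipy.spatial.distance import pdist

            if pdist(pos).min() <= 0.0:
                raise ValueError("coincident capsomer centers")
        self.positions = pos

    def __len__(self) -> int:
        return self.positions.shape[0]

    @property
    def center(self) -> np.ndarray:
        return self.positions.mean(axis=0)


@dataclass
class DensityMap:
    """A scalar voxel grid.

    ``values[i, j, k]`` is the density at the voxel whose *center* sits at
    ``origin + voxel_size * (i, j, k)`` nm; axes (i, j, k) map to (x, y, z).
    """

    values: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("values must be a non-empty 3-D grid")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def voxel_centers_axes(self):
        """Per-axis physical coordinates (nm) of voxel centers."""
        return tuple(
            self.origin[a] + self.voxel_size * np.arange(self.values.shape[a])
            for a in range(3)
        )


# ---------------------------------------------------------------------------
# Icosahedral (h, k) lattices


def _icosahedron(radius: float = 1.0):
    """Vertices and outward-CCW faces of a regular icosahedron."""
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    base = [
        (-1, phi, 0), (1, phi, 0), (-1, -phi, 0), (1, -phi, 0),
        (0, -1, phi), (0, 1, phi), (0, -1, -phi), (0, 1, -phi),
        (phi, 0, -1), (phi, 0, 1), (-phi, 0, -1), (-phi, 0, 1),
    ]
    verts = np.array(base, dtype=float)
    verts *= radius / np.linalg.norm(verts[0])
    from scipy.spatial import ConvexHull

    hull = ConvexHull(verts)
    faces = []
    for simplex in hull.simplices:
        a, b, c = verts[simplex]
        n = np.cross(b - a, c - a)
        if np.dot(n, (a + b + c) / 3.0) < 0:
            simplex = simplex[[0, 2, 1]]
        faces.append(tuple(int(i) for i in simplex))
    return verts, faces


def _ck_triangle_points(h: int, k: int):
    """Lattice points of the (h, k) Caspar-Klug triangle, as barycentric
    coordinates with respect to its three corners.

    The triangle has corners at lattice points (0,0), (h,k) and the +60
    degree rotation of (h,k), i.e. (-k, h+k), in the triangular lattice with
    basis a1=(1,0), a2=(1/2, sqrt(3)/2).
    """
    a1 = np.array([1.0, 0.0])
    a2 = np.array([0.5, _SQRT3_2])
    c1 = h * a1 + k * a2
    c2 = -k * a1 + (h + k) * a2
    # Invert [c1 c2] once; barycentric coords of p are the solution of
    # p = l1*c1 + l2*c2, l0 = 1 - l1 - l2.
    mat = np.linalg.inv(np.column_stack([c1, c2]))
    pts = []
    eps = 1e-9
    lo, hi = -(h + k), 2 * (h + k)
    for i in range(lo, hi + 1):
        for j in range(lo, hi + 1):
            p = i * a1 + j * a2
            l1, l2 = mat @ p
            l0 = 1.0 - l1 - l2
            if l0 >= -eps and l1 >= -eps and l2 >= -eps:
                pts.append((l0, l1, l2))
    return np.array(pts)


def _dedupe(points: np.ndarray, tol: float) -> np.ndarray:
    """Merge points closer than tol (single-linkage via grid rounding)."""
    keys = np.round(points / tol).astype(np.int64)
    seen = {}
    out = []
    for key, p in zip(map(tuple, keys), points):
        found = None
        for dx in (0, -1, 1):
            for dy in (0, -1, 1):
                for dz in (0, -1, 1):
                    cand = (key[0] + dx, key[1] + dy, key[2] + dz)
                    if cand in seen:
                        found = seen[cand]
                        break
                if found is not None:
                    break
            if found is not None:
                break
        if found is None:
            seen[key] = len(out)
            out.append(p)
    return np.array(out)


def generate_icosahedral(
    h: int,
    k: int,
    radius_nm: float,
    *,
    projection: str = "sphere",
    particle_id: Optional[str] = None,
) -> CapsomerSet:
    """Ideal icosahedral (h, k) capsomer lattice.

    Capsomer centers are the vertices of the (h, k) geodesic subdivision of
    the icosahedron: 12 fivefold vertices plus 10(T - 1) sixfold vertices,
    T = h^2 + hk + k^2.  ``projection='sphere'`` (default) projects every
    center radially onto the sphere of the requested radius;
    ``projection='facet'`` keeps the facetted icosahedral geometry with the
    icosahedron circumradius equal to ``radius_nm``.

    Note (h, k) and (k, h) produce mirror-image (enantiomeric) lattices.
    """
    h, k = int(h), int(k)
    if h < 0 or k < 0 or h + k < 1:
        raise ValueError("require h >= 0, k >= 0 and h + k >= 1")
    if not radius_nm > 0:
        raise ValueError("radius_nm must be positive")
    if projection not in ("sphere", "facet"):
        raise ValueError("projection must be 'sphere' or 'facet'")

    verts, faces = _icosahedron(radius_nm)
    bary = _ck_triangle_points(h, k)
    pts = []
    for (ia, ib, ic) in faces:
        corners = verts[[ia, ib, ic]]          # (3, 3)
        pts.append(bary @ corners)
    pts = np.vstack(pts)
    T = h * h + h * k + k * k
    # Spacing-scaled merge tolerance: lattice spacing ~ edge / sqrt(T).
    edge = np.linalg.norm(verts[faces[0][0]] - verts[faces[0][1]])
    pts = _dedupe(pts, tol=0.2 * edge / math.sqrt(T))
    if projection == "sphere":
        pts = pts * (radius_nm / np.linalg.norm(pts, axis=1))[:, None]
    expected = 10 * T + 2
    if pts.shape[0] != expected:
        raise RuntimeError(
            f"lattice construction produced {pts.shape[0]} capsomers, "
            f"expected {expected} for T={T}"
        )
    pid = particle_id or f"icos_h{h}k{k}"
    return CapsomerSet(
        particle_id=pid,
        positions=pts,
        radius_nominal=float(radius_nm),
        source=f"generate_icosahedral(h={h}, k={k}, radius_nm={radius_nm}, "
               f"projection={projection})",
    )


# ---------------------------------------------------------------------------
# Prolate (elongated icosahedron) lattices


def _rotation_onto(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix taking direction a onto direction b (Rodrigues)."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    s = np.linalg.norm(v)
    c = float(np.dot(a, b))
    if s < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([
        [0.0, -v[2], v[1]],
        [v[2], 0.0, -v[0]],
        [-v[1], v[0], 0.0],
    ])
    return np.eye(3) + vx + vx @ vx * ((1.0 - c) / s**2)


def _rotz(angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def generate_prolate(
    h_cap: int,
    q_rings: int,
    radius_nm: float,
    *,
    particle_id: Optional[str] = None,
) -> CapsomerSet:
    """Closed prolate fullerene lattice: two (h_cap, 0) icosahedral caps
    about a fivefold axis joined by ``q_rings`` extra rings of hexamers.

    This is the phage-style elongated icosahedron.  Each inserted ring holds
    5*h_cap hexamers, so the capsomer count is 10*h_cap^2 + 2 +
    5*h_cap*q_rings; the shell stays closed with exactly 12 pentamers.
    Local T equals h_cap^2 within each cap and exceeds it across the tube
    when q_rings > 0.  ``radius_nm`` sets the tube (and cap) radius.
    """
    h = int(h_cap)
    q = int(q_rings)
    if h < 1:
        raise ValueError("h_cap must be a positive integer")
    if q < 0:
        raise ValueError("q_rings must be non-negative")
    if not radius_nm > 0:
        raise ValueError("radius_nm must be positive")

    # Top cap: the polar half of the sphere-projected (h, 0) lattice, with
    # the pole rotated onto +z and one upper-pentamer vertex at azimuth 0.
    full = generate_icosahedral(h, 0, radius_nm).positions
    # Pick a vertex as pole: vertices are the 12 points of the (1,0) shell,
    # identifiable as the points of the underlying icosahedron.
    ico = _icosahedron(radius_nm)[0]
    pole = ico[int(np.argmax(ico[:, 2]))]
    full = full @ _rotation_onto(pole, np.array([0.0, 0.0, radius_nm])).T
    ico = ico @ _rotation_onto(pole, np.array([0.0, 0.0, radius_nm])).T
    z_ring = radius_nm / math.sqrt(5.0)          # upper pentagon vertex plane
    ring_vert = ico[np.argsort(ico[:, 2])[-2]]   # one upper-ring vertex
    phi_v = math.atan2(ring_vert[1], ring_vert[0])
    rotz = _rotz(-phi_v)
    full = full @ rotz.T

    cap = full[full[:, 2] >= z_ring - 1e-6 * radius_nm]
    r_seam = math.sqrt(radius_nm**2 - z_ring**2)  # horizontal seam radius
    n_ring = 5 * h                                # capsomers per tube ring
    delta = 2.0 * math.pi / n_ring                # tube azimuthal step
    s_ring = r_seam * delta                       # tube lattice spacing
    dz = s_ring * _SQRT3_2                        # tube ring pitch

    n_rows = h + q                      # rows between the two pentamer rings
    pts = [cap]
    for t in range(1, n_rows):
        theta = delta * (np.arange(n_ring) + 0.5 * t)
        ring = np.column_stack([
            r_seam * np.cos(theta),
            r_seam * np.sin(theta),
            np.full(n_ring, z_ring - t * dz),
        ])
        pts.append(ring)
    # Bottom cap: rotate the top cap by pi about x (proper rotation), then
    # about z to phase-match row n_rows, and translate down the axis.
    bot = cap @ np.diag([1.0, -1.0, -1.0])
    bot = bot @ _rotz(delta * 0.5 * n_rows).T
    bot[:, 2] += 2.0 * z_ring - n_rows * dz
    pts.append(bot)
    pts = np.vstack(pts)
    spacing = s_ring
    pts = _dedupe(pts, tol=0.2 * spacing)

    # Center on the origin.
    pts[:, 2] -= z_ring - 0.5 * n_rows * dz

    expected = 10 * h * h + 2 + n_ring * q
    if pts.shape[0] != expected:
        raise RuntimeError(
            f"prolate construction produced {pts.shape[0]} capsomers, "
            f"expected {expected}"
        )
    pid = particle_id or f"prolate_h{h}q{q}"
    return CapsomerSet(
        particle_id=pid,
        positions=pts,
        radius_nominal=float(radius_nm),
        source=f"generate_prolate(h_cap={h}, q_rings={q}, radius_nm={radius_nm})",
    )


# ---------------------------------------------------------------------------
# Perturbation


def perturb(
    cs: CapsomerSet,
    sigma_nm: float,
    drop_fraction: float,
    seed: int,
) -> CapsomerSet:
    """Noisy / incomplete copy of a capsomer set.

    A uniformly random subset of ``round(drop_fraction * N)`` capsomers is
    removed, then every survivor is displaced by isotropic Gaussian noise of
    standard deviation ``sigma_nm`` per axis.  Deterministic for fixed seed.
    """
    if sigma_nm < 0:
        raise ValueError("sigma_nm must be non-negative")
    if not 0.0 <= drop_fraction < 1.0:
        raise ValueError("drop_fraction must be in [0, 1)")
    n = len(cs)
    n_drop = int(round(drop_fraction * n))
    if n - n_drop < 1:
        raise ValueError("drop_fraction would leave no capsomers")
    rng = np.random.default_rng(seed)
    keep = np.ones(n, dtype=bool)
    if n_drop:
        keep[rng.choice(n, size=n_drop, replace=False)] = False
    pos = cs.positions[keep].copy()
    if sigma_nm > 0:
        pos += rng.normal(0.0, sigma_nm, size=pos.shape)
    return CapsomerSet(
        particle_id=cs.particle_id,
        positions=pos,
        radius_nominal=cs.radius_nominal,
        source=f"perturb({cs.source}, sigma_nm={sigma_nm}, "
               f"drop_fraction={drop_fraction}, seed={seed})",
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Density rendering

_INTERIORS = ("none", "thick_shell", "condensed_core")


def render_density(
    cs: CapsomerSet,
    voxel_nm: float,
    blob_sigma_nm: float,
    interior: str = "none",
) -> DensityMap:
    """Render a capsomer set as a sum of unit-amplitude Gaussian blobs.

    The box is auto-sized to contain all capsomers plus three blob sigmas of
    padding.  ``interior`` adds a synthetic lumen emulating the two particle
    morphologies seen in thin-section EM of retroelement particles:

    - ``thick_shell``: a broad shell of density directly beneath the
      capsomer layer (immature-like: thick ring, empty center);
    - ``condensed_core``: a compact Gaussian ball at the particle center
      (mature-like: thin ring with condensed interior).
    """
    if not voxel_nm > 0:
        raise ValueError("voxel_nm must be positive")
    if not blob_sigma_nm > 0:
        raise ValueError("blob_sigma_nm must be positive")
    if interior not in _INTERIORS:
        raise ValueError(f"interior must be one of {_INTERIORS}")

    pos = cs.positions
    pad = 3.0 * blob_sigma_nm
    lo = pos.min(axis=0) - pad
    hi = pos.max(axis=0) + pad
    extent = hi - lo
    diameter = float(extent.max())
    if diameter / voxel_nm < 8:
        raise ValueError(
            "voxel too coarse: fewer than 8 voxels across the particle"
        )
    shape = tuple(int(math.ceil(e / voxel_nm)) + 1 for e in extent)
    values = np.zeros(shape)
    origin = lo

    half = max(1, int(math.ceil(4.0 * blob_sigma_nm / voxel_nm)))
    inv2s2 = 1.0 / (2.0 * blob_sigma_nm**2)
    for p in pos:
        idx = np.floor((p - origin) / voxel_nm).astype(int)
        sl, axes = [], []
        for a in range(3):
            a0 = max(0, idx[a] - half)
            a1 = min(shape[a], idx[a] + half + 2)
            sl.append(slice(a0, a1))
            axes.append(origin[a] + voxel_nm * np.arange(a0, a1) - p[a])
        dx, dy, dz = axes
        r2 = (dx[:, None, None] ** 2 + dy[None, :, None] ** 2
              + dz[None, None, :] ** 2)
        values[tuple(sl)] += np.exp(-r2 * inv2s2)

    if interior != "none":
        center = cs.center
        shell_r = float(np.linalg.norm(pos - center, axis=1).mean())
        ax = [origin[a] + voxel_nm * np.arange(shape[a]) - center[a]
              for a in range(3)]
        r = np.sqrt(ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2
                    + ax[2][None, None, :] ** 2)
        # Interior amplitudes are fractions of the capsomer layer's
        # rotationally averaged density, so the capsid shell remains the
        # radial-profile peak for both morphologies (as in section images
        # of real particles, where the radius is read off the shell peak).
        band = np.abs(r - shell_r) < max(2.0 * voxel_nm, 0.1 * shell_r)
        shell_mean = float(values[band].mean()) if band.any() else 1.0
        if interior == "thick_shell":
            # Broad band hugging the underside of the capsomer layer.
            band_c, band_w = 0.75 * shell_r, 0.12 * shell_r
            values += (0.75 * shell_mean
                       * np.exp(-0.5 * ((r - band_c) / band_w) ** 2))
        else:  # condensed_core
            core_sigma = 0.25 * shell_r
            values += (0.8 * shell_mean
                       * np.exp(-0.5 * (r / core_sigma) ** 2))

    return DensityMap(values=values, voxel_size=float(voxel_nm), origin=origin)
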