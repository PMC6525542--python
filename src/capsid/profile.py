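"""Radial profiles, morphology typing, symmetry spectra, averaging and FSC.

Desk-scale analogues of the standard EM analyses of shell-like particles:
rotationally averaged radial density profiles (shell peak = capsid radius),
two-way morphology typing (thick ring / empty lumen vs thin ring /
condensed core), cyclic-symmetry scoring of capsomer subvolumes,
translational align-and-average of particle volumes, Fourier shell
correlation between half-maps, and the linear shrinkage correction applied
to lengths measured in resin-embedded material.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import ndimage

from .synth import DensityMap

__all__ = [
    "RadialProfile",
    "SymmetrySpectrum",
    "FSCCurve",
    "MorphologyResult",
    "NoParticleError",
    "AmbiguousParticleError",
    "radial_profile",
    "estimate_center",
    "classify_morphology",
    "cyclic_symmetry_spectrum",
    "align_average",
    "fsc",
    "shrinkage_correct",
]

LABEL_THICK = "type1_thick_ring"
LABEL_THIN = "type2_thin_ring"


class NoParticleError(ValueError):
    """The map contains no shell-like particle (e.g. it is flat)."""


class AmbiguousParticleError(ValueError):
    """More than one particle candidate; a single center is undefined."""


@dataclass
class RadialProfile:
    """Rotationally averaged density vs distance from the particle center."""

    bin_centers: np.ndarray     # nm
    mean_density: np.ndarray    # arbitrary units

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.mean_density = np.asarray(self.mean_density, dtype=float)
        if self.bin_centers.shape != self.mean_density.shape:
            raise ValueError("bin_centers and mean_density must match")
        if np.any(np.diff(self.bin_centers) <= 0):
            raise ValueError("bins must be strictly increasing")

    @property
    def peak_radius(self) -> float:
        return float(self.bin_centers[int(np.argmax(self.mean_density))])


@dataclass
class SymmetrySpectrum:
    """Rotational self-correlation score per cyclic order n."""

    orders: np.ndarray
    scores: np.ndarray
    ambiguous: bool = False

    @property
    def best_order(self) -> int:
        mask = self.orders >= 2
        return int(self.orders[mask][int(np.argmax(self.scores[mask]))])


@dataclass
class FSCCurve:
    """Fourier shell correlation vs spatial frequency (1/nm)."""

    frequencies: np.ndarray
    correlations: np.ndarray

    def crossing(self, threshold: float) -> Optional[float]:
        """Frequency (1/nm) of the first downward crossing of ``threshold``,
        linearly interpolated; None if the curve never falls below it."""
        c = self.correlations
        f = self.frequencies
        below = np.nonzero(c < threshold)[0]
        below = below[below > 0]
        if below.size == 0:
            return None
        i = int(below[0])
        c0, c1 = c[i - 1], c[i]
        if c0 == c1:
            return float(f[i])
        frac = (c0 - threshold) / (c0 - c1)
        return float(f[i - 1] + frac * (f[i] - f[i - 1]))

    def resolution(self, threshold: float) -> Optional[float]:
        """Resolution in nm at the given FSC threshold (1/crossing)."""
        freq = self.crossing(threshold)
        return None if freq is None or freq == 0 else 1.0 / freq


@dataclass
class MorphologyResult:
    labels: List[str]
    statistic: np.ndarray            # interior-to-peak density ratio
    threshold: Optional[float]
    degenerate: bool
    group_means: dict                # label -> RadialProfile


def _radius_grid(dmap: DensityMap, center: np.ndarray) -> np.ndarray:
    ax = [axis - center[a] for a, axis in enumerate(dmap.voxel_centers_axes())]
    return np.sqrt(ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2
                   + ax[2][None, None, :] ** 2)


def radial_profile(dmap: DensityMap, center: Sequence[float]) -> RadialProfile:
    """Mean density in spherical shells about ``center`` (nm), one bin per
    voxel width."""
    center = np.asarray(center, dtype=float).reshape(3)
    lo = dmap.origin
    hi = dmap.origin + dmap.voxel_size * (np.array(dmap.shape) - 1)
    if np.any(center < lo) or np.any(center > hi):
        raise ValueError("center lies outside the map box")
    r = _radius_grid(dmap, center)
    idx = np.floor(r / dmap.voxel_size).astype(int).ravel()
    vals = dmap.values.ravel()
    nbins = idx.max() + 1
    sums = np.bincount(idx, weights=vals, minlength=nbins)
    counts = np.bincount(idx, minlength=nbins)
    mean = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    centers = (np.arange(nbins) + 0.5) * dmap.voxel_size
    return RadialProfile(bin_centers=centers, mean_density=mean)


def _profile_sharpness(dmap: DensityMap, center: np.ndarray) -> float:
    """Peak height over peak width of the radial profile — the quantity the
    center search maximises."""
    prof = radial_profile(dmap, center)
    m = prof.mean_density
    peak = float(m.max())
    if peak <= 0:
        return 0.0
    width = max(1, int(np.sum(m > 0.5 * peak)))
    return peak / width


def estimate_center(dmap: DensityMap) -> np.ndarray:
    """Locate the center of a single shell-like particle.

    Center-of-mass initialisation on the thresholded map, followed by a
    voxel-step hill climb maximising radial-profile sharpness.  Raises
    :class:`NoParticleError` on a flat map and
    :class:`AmbiguousParticleError` when two comparable particles share the
    box (never a silent midpoint).
    """
    vals = dmap.values
    vmax, vmin = float(vals.max()), float(vals.min())
    if not np.isfinite(vmax) or vmax - vmin <= 1e-12 * max(1.0, abs(vmax)):
        raise NoParticleError("map is flat: no particle found")

    # Smooth before segmenting so a shell of discrete capsomer blobs reads
    # as one connected particle; escalate the smoothing scale until the
    # component picture stabilises.  Distinct particles survive even heavy
    # smoothing as separate comparable components.
    com_vox = None
    sigmas = (2.0, 4.0, max(6.0, min(vals.shape) / 8.0))
    for i_s, sigma in enumerate(sigmas):
        smooth = ndimage.gaussian_filter(vals - vmin, sigma=sigma)
        mask = smooth >= 0.3 * smooth.max()
        labels, n_comp = ndimage.label(mask)
        if n_comp == 0:
            raise NoParticleError("no density above threshold")
        masses = ndimage.sum_labels(smooth, labels,
                                    index=np.arange(1, n_comp + 1))
        order = np.argsort(masses)[::-1]
        ambiguous = False
        if n_comp > 1 and masses[order[1]] >= 0.5 * masses[order[0]]:
            c0 = np.array(ndimage.center_of_mass(smooth, labels,
                                                 int(order[0]) + 1))
            c1 = np.array(ndimage.center_of_mass(smooth, labels,
                                                 int(order[1]) + 1))
            ambiguous = np.linalg.norm(c0 - c1) > 0.2 * min(vals.shape)
        if not ambiguous:
            com_vox = np.array(
                ndimage.center_of_mass(smooth, labels, int(order[0]) + 1)
            )
            break
        if i_s == len(sigmas) - 1:
            raise AmbiguousParticleError(
                "two comparable particles in one box; crop before centering"
            )
    center = dmap.origin + com_vox * dmap.voxel_size

    best = _profile_sharpness(dmap, center)
    step = dmap.voxel_size
    moves = step * np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
    )
    for _ in range(50):
        improved = False
        for mv in moves:
            cand = center + mv
            try:
                score = _profile_sharpness(dmap, cand)
            except ValueError:
                continue
            if score > best:
                best, center, improved = score, cand, True
        if not improved:
            break
    return center


def classify_morphology(
    profiles: Sequence[RadialProfile],
    *,
    interior_fraction: float = 0.6,
) -> MorphologyResult:
    """Two-way morphology typing of radial profiles.

    The split statistic is the ratio of mean density inside
    ``interior_fraction`` x peak radius to the peak density — low for
    thick-ring particles that are empty inside, high for thin-ring
    particles with a condensed core.  The threshold is data-driven (largest
    gap in the sorted statistic).  A near-degenerate split (all profiles
    alike) yields a single label and a warning.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    base = profiles[0].bin_centers
    for p in profiles[1:]:
        if len(p.bin_centers) != len(base) or not np.allclose(p.bin_centers, base):
            raise ValueError("profiles must share a common binning")

    bin_w = float(np.median(np.diff(base))) if len(base) > 1 else 1.0
    stat = np.empty(len(profiles))
    for i, p in enumerate(profiles):
        # Shell radius from a lightly smoothed profile, skipping the first
        # couple of bins whose tiny voxel counts make the mean unreliable
        # on noisy maps.
        m = ndimage.uniform_filter1d(p.mean_density, size=3, mode="nearest")
        skip = min(2, len(m) - 1)
        peak_idx = skip + int(np.argmax(m[skip:]))
        peak_r = float(p.bin_centers[peak_idx])
        peak = float(m[peak_idx])
        inner = p.bin_centers < interior_fraction * peak_r
        if peak <= 0 or not inner.any():
            stat[i] = 0.0
        else:
            stat[i] = float(np.mean(m[inner])) / peak

    # Otsu-style split: threshold maximising the between-class variance of
    # the interior-ratio statistic.
    svals = np.sort(stat)
    spread = float(svals[-1] - svals[0])
    best_split, best_between = None, -np.inf
    for i in range(1, len(svals)):
        lo, hi = svals[:i], svals[i:]
        w0, w1 = len(lo) / len(svals), len(hi) / len(svals)
        between = w0 * w1 * (hi.mean() - lo.mean()) ** 2
        if between > best_between:
            best_between, best_split = between, i
    lo, hi = svals[:best_split], svals[best_split:]
    separation = float(hi.mean() - lo.mean())
    within = float(lo.std() + hi.std())
    degenerate = spread < 1e-6 or separation < max(within, 0.02)
    if degenerate:
        warnings.warn(
            "morphology split is degenerate: profiles form a single group",
            stacklevel=2,
        )
        threshold = None
        labels = [LABEL_THICK] * len(profiles)
    else:
        threshold = float((svals[best_split - 1] + svals[best_split]) / 2.0)
        labels = [LABEL_THIN if s > threshold else LABEL_THICK for s in stat]

    group_means = {}
    for label in sorted(set(labels)):
        members = [p.mean_density for p, l in zip(profiles, labels) if l == label]
        group_means[label] = RadialProfile(
            bin_centers=base.copy(),
            mean_density=np.mean(members, axis=0),
        )
    return MorphologyResult(
        labels=labels,
        statistic=stat,
        threshold=threshold,
        degenerate=degenerate,
        group_means=group_means,
    )


def cyclic_symmetry_spectrum(
    dmap: DensityMap,
    axis: Sequence[float] = (0.0, 0.0, 1.0),
    n_max: int = 12,
    *,
    center: Optional[Sequence[float]] = None,
) -> SymmetrySpectrum:
    """Score cyclic symmetry orders of a subvolume about an axis through
    ``center`` (nm; default: the box center).

    The map is resampled on a cylindrical grid (1-degree azimuthal step)
    about the axis; score(n) is the Pearson correlation between the grid
    and itself rotated by 360/n degrees.  ``best_order`` is the argmax over
    n >= 2; a flat spectrum (e.g. a rotationally uniform torus) is flagged
    ``ambiguous``.
    """
    if n_max < 2:
        raise ValueError("n_max must be at least 2")
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("axis must be a non-zero vector")
    axis = axis / norm

    shape = np.array(dmap.shape)
    if center is None:
        center = dmap.origin + dmap.voxel_size * (shape - 1) / 2.0
    else:
        center = np.asarray(center, dtype=float).reshape(3)
    # Orthonormal frame (t1, t2, axis).
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, axis)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    t1 = np.cross(axis, ref)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(axis, t1)

    half_extent = dmap.voxel_size * (shape - 1) / 2.0
    rmax = float(half_extent.min())
    nr = max(4, int(rmax / dmap.voxel_size))
    radii = (np.arange(nr) + 0.5) * (rmax / nr)
    zmax = rmax
    nz = nr
    zs = (np.arange(nz) + 0.5) * (2.0 * zmax / nz) - zmax

    def cylinder_samples(phase_deg: float) -> np.ndarray:
        theta = np.deg2rad(np.arange(360) + phase_deg)
        # points[r, z, theta, 3]
        circ = (np.cos(theta)[:, None] * t1[None, :]
                + np.sin(theta)[:, None] * t2[None, :])    # (360, 3)
        pts = (radii[:, None, None, None] * circ[None, None, :, :]
               + zs[None, :, None, None] * axis[None, None, None, :])
        pts = pts + center
        vox = (pts - dmap.origin) / dmap.voxel_size
        return ndimage.map_coordinates(
            dmap.values, vox.reshape(-1, 3).T, order=1, mode="constant"
        ).reshape(nr, nz, 360)

    base = cylinder_samples(0.0)
    b = base.ravel()
    bstd = b.std()
    orders = np.arange(1, n_max + 1)
    scores = np.empty(orders.size)
    for i, n in enumerate(orders):
        rot = cylinder_samples(360.0 / n).ravel()
        if bstd == 0 or rot.std() == 0:
            scores[i] = 1.0 if np.allclose(b, rot) else 0.0
        else:
            scores[i] = float(np.corrcoef(b, rot)[0, 1])
    scores = np.clip(scores, -1.0, 1.0)
    ambiguous = bool(scores[1:].max() - scores[1:].min() < 0.05)
    return SymmetrySpectrum(orders=orders, scores=scores, ambiguous=ambiguous)


def align_average(
    maps: Sequence[DensityMap],
    reference: Union[DensityMap, str] = "first",
) -> DensityMap:
    """Translationally align maps to a reference and average them.

    Shifts are integer-voxel and circular, found at the peak of the FFT
    cross-correlation.  All maps must share grid dimensions and voxel size.
    """
    maps = list(maps)
    if not maps:
        raise ValueError("no maps to average")
    ref = maps[0] if reference == "first" else reference
    shape = ref.shape
    for m in maps:
        if m.shape != shape or not math.isclose(m.voxel_size, ref.voxel_size):
            raise ValueError("all maps must share grid dimensions and voxel size")
    if len(maps) == 1:
        return DensityMap(values=maps[0].values.copy(),
                          voxel_size=maps[0].voxel_size,
                          origin=maps[0].origin.copy())

    f_ref = np.fft.fftn(ref.values)
    acc = np.zeros(shape)
    for m in maps:
        cc = np.fft.ifftn(f_ref * np.conj(np.fft.fftn(m.values))).real
        shift = np.array(np.unravel_index(int(np.argmax(cc)), shape))
        acc += np.roll(m.values, shift, axis=(0, 1, 2))
    return DensityMap(values=acc / len(maps), voxel_size=ref.voxel_size,
                      origin=ref.origin.copy())


def fsc(map_a: DensityMap, map_b: DensityMap) -> FSCCurve:
    """Fourier shell correlation between two maps on identical grids.

    Shells are one frequency voxel wide; the per-shell statistic is the
    normalised cross-correlation of the Fourier coefficients.  Use
    :meth:`FSCCurve.crossing` / ``resolution`` for the 0.5 and 0.143
    threshold conventions.
    """
    if map_a.shape != map_b.shape or not math.isclose(
        map_a.voxel_size, map_b.voxel_size
    ):
        raise ValueError("maps must share grid dimensions and voxel size")
    fa = np.fft.fftn(map_a.values)
    fb = np.fft.fftn(map_b.values)
    shape = map_a.shape
    # Integer shell index from the unscaled frequency grid.
    grids = np.meshgrid(
        *[np.fft.fftfreq(n) * n for n in shape], indexing="ij"
    )
    r = np.sqrt(sum(g**2 for g in grids))
    shell = np.rint(r).astype(int).ravel()
    n_shells = min(shape) // 2 + 1
    keep = shell < n_shells
    shell = shell[keep]
    a = fa.ravel()[keep]
    b = fb.ravel()[keep]
    cross = np.bincount(shell, weights=(a * np.conj(b)).real, minlength=n_shells)
    pa = np.bincount(shell, weights=np.abs(a) ** 2, minlength=n_shells)
    pb = np.bincount(shell, weights=np.abs(b) ** 2, minlength=n_shells)
    denom = np.sqrt(pa * pb)
    corr = np.where(denom > 0, cross / np.maximum(denom, 1e-300), 1.0)
    freqs = np.arange(n_shells) / (min(shape) * map_a.voxel_size)
    return FSCCurve(frequencies=freqs, correlations=corr)


def shrinkage_correct(length_nm: float, factor: float) -> float:
    """Correct a length measured in embedded/imaged material for sample
    shrinkage: returns ``length_nm * factor``."""
    if not factor > 0:
        raise ValueError("shrinkage factor must be positive")
    return length_nm * factor
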