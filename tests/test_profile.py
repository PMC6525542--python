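"""Radial profiles, centering, morphology, symmetry spectra, FSC."""

import math
import warnings

import numpy as np
import pytest

from capsid import (
    AmbiguousParticleError,
    CapsomerSet,
    DensityMap,
    NoParticleError,
    align_average,
    classify_morphology,
    cyclic_symmetry_spectrum,
    estimate_center,
    fsc,
    radial_profile,
    render_density,
    shrinkage_correct,
)
from capsid.profile import LABEL_THICK, LABEL_THIN, RadialProfile


def synthetic_shell(radius=21.0, voxel=1.0, box=64, width=1.5):
    """Ideal thin spherical shell of given radius centered in the box."""
    ax = (np.arange(box) - (box - 1) / 2.0) * voxel
    r = np.sqrt(ax[:, None, None] ** 2 + ax[None, :, None] ** 2
                + ax[None, None, :] ** 2)
    vals = np.exp(-0.5 * ((r - radius) / width) ** 2)
    return DensityMap(values=vals, voxel_size=voxel,
                      origin=np.full(3, ax[0]))


class TestRadialProfile:
    def test_ideal_shell_peak_at_its_radius(self):
        m = synthetic_shell(radius=21.0)
        prof = radial_profile(m, estimate_center(m))
        assert abs(prof.peak_radius - 21.0) <= 1.0

    def test_rendered_t9_peaks_at_generation_radius(self, t9_map):
        prof = radial_profile(t9_map, estimate_center(t9_map))
        assert abs(prof.peak_radius - 24.0) <= 1.0

    def test_zero_map_gives_zero_profile(self):
        m = DensityMap(np.zeros((16, 16, 16)), 1.0)
        prof = radial_profile(m, np.full(3, 7.5))
        assert np.all(prof.mean_density == 0.0)

    def test_rotation_invariance(self, t9_map):
        c = estimate_center(t9_map)
        prof_a = radial_profile(t9_map, c)
        rot = DensityMap(np.rot90(t9_map.values, axes=(0, 1)).copy(),
                         t9_map.voxel_size, t9_map.origin)
        # np.rot90 maps voxel (a, b) -> (N_b - 1 - b, a); move the center
        # into the rotated frame the same way.
        shape = np.array(t9_map.shape)
        cv = (c - t9_map.origin) / t9_map.voxel_size
        cv_rot = np.array([shape[1] - 1 - cv[1], cv[0], cv[2]])
        prof_b = radial_profile(rot, rot.origin + cv_rot * rot.voxel_size)
        n = min(len(prof_a.mean_density), len(prof_b.mean_density))
        assert np.allclose(prof_a.mean_density[:n], prof_b.mean_density[:n],
                           atol=1e-10)

    def test_center_outside_box_rejected(self, t9_map):
        with pytest.raises(ValueError):
            radial_profile(t9_map, t9_map.origin - 10.0)


class TestEstimateCenter:
    def test_centered_shell(self):
        m = synthetic_shell()
        box_center = m.origin + m.voxel_size * (np.array(m.shape) - 1) / 2.0
        assert np.linalg.norm(estimate_center(m) - box_center) <= m.voxel_size

    def test_recovers_known_shift(self):
        m = synthetic_shell(box=72)
        shifted = DensityMap(np.roll(m.values, (3, -2, 1), axis=(0, 1, 2)),
                             m.voxel_size, m.origin)
        c0 = estimate_center(m)
        c1 = estimate_center(shifted)
        assert np.linalg.norm((c1 - c0) - np.array([3.0, -2.0, 1.0])) \
            <= math.sqrt(3) * m.voxel_size

    def test_flat_map_rejected(self):
        with pytest.raises(NoParticleError):
            estimate_center(DensityMap(np.zeros((12, 12, 12)), 1.0))

    def test_two_shells_flagged_ambiguous(self):
        # Two identical shells side by side in one box.
        ax = np.arange(96.0)
        r1 = np.sqrt((ax[:, None, None] - 24) ** 2 + (ax[None, :, None] - 48) ** 2
                     + (ax[None, None, :24 * 2] - 24) ** 2)
        r2 = np.sqrt((ax[:, None, None] - 72) ** 2 + (ax[None, :, None] - 48) ** 2
                     + (ax[None, None, :48] - 24) ** 2)
        vals = (np.exp(-0.5 * ((r1 - 10) / 1.5) ** 2)
                + np.exp(-0.5 * ((r2 - 10) / 1.5) ** 2))
        with pytest.raises(AmbiguousParticleError):
            estimate_center(DensityMap(vals, 1.0))


class TestMorphology:
    def test_clean_separation(self, morphology_maps):
        profs, truth = [], []
        for i in range(20):
            kind = "thick_shell" if i % 2 else "condensed_core"
            m = morphology_maps[kind]
            profs.append(radial_profile(m, estimate_center(m)))
            truth.append(kind)
        res = classify_morphology(profs)
        assert not res.degenerate
        for label, kind in zip(res.labels, truth):
            assert label == (LABEL_THICK if kind == "thick_shell"
                             else LABEL_THIN)

    def test_group_mean_peaks_match_for_equal_radius(self, morphology_maps):
        # Same generation radius: both group means peak at the same radius.
        profs = []
        for kind in ("thick_shell", "condensed_core"):
            m = morphology_maps[kind]
            c = estimate_center(m)
            for _ in range(3):
                profs.append(radial_profile(m, c))
        res = classify_morphology(profs)
        peaks = [p.peak_radius for p in res.group_means.values()]
        assert len(peaks) == 2
        assert abs(peaks[0] - peaks[1]) <= 2.0 * 2.0  # within one bin each

    def test_duplicated_profiles_degenerate(self, morphology_maps):
        m = morphology_maps["thick_shell"]
        p = radial_profile(m, estimate_center(m))
        dup = RadialProfile(p.bin_centers.copy(), p.mean_density.copy())
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            res = classify_morphology([p, dup, dup])
        assert res.degenerate
        assert len(set(res.labels)) == 1
        assert any("degenerate" in str(w.message) for w in rec)


class TestSymmetrySpectrum:
    def test_c5_ring_of_blobs(self):
        ang = np.linspace(0, 2 * np.pi, 5, endpoint=False)
        ring = CapsomerSet("c5", np.column_stack(
            [8 * np.cos(ang), 8 * np.sin(ang), np.zeros(5)]))
        m = render_density(ring, 1.0, 1.2)
        sp = cyclic_symmetry_spectrum(m, (0, 0, 1), center=(0, 0, 0))
        assert sp.best_order == 5
        assert sp.scores[4] > 0.9
        assert not sp.ambiguous

    def test_three_blob_pairs_read_as_c3(self):
        # Six blobs arranged as three dimers: trimeric, not hexameric.
        pos = []
        for j in range(3):
            a = 2 * np.pi * j / 3
            for da in (-0.18, 0.18):
                pos.append([8 * np.cos(a + da), 8 * np.sin(a + da), 0.0])
        m = render_density(CapsomerSet("c3", np.array(pos)), 1.0, 1.2)
        sp = cyclic_symmetry_spectrum(m, (0, 0, 1), center=(0, 0, 0))
        assert sp.best_order == 3
        assert sp.scores[2] > 0.9

    def test_uniform_torus_is_ambiguous(self):
        g = np.indices((33, 33, 33)).astype(float) - 16.0
        rho = np.sqrt(g[0] ** 2 + g[1] ** 2)
        vals = np.exp(-0.5 * ((np.sqrt((rho - 8) ** 2 + g[2] ** 2)) / 1.5) ** 2)
        sp = cyclic_symmetry_spectrum(DensityMap(vals, 1.0), (0, 0, 1))
        assert sp.ambiguous
        assert np.all(sp.scores > 0.99)

    def test_exact_invariance_scores_one(self):
        # A C4-symmetric object scores exactly 1 at n = 4 (and 2).
        g = np.indices((41, 41, 41)).astype(float) - 20.0
        vals = np.exp(-0.5 * ((np.abs(g[0]) - 8) ** 2 + (np.abs(g[1]) - 8) ** 2
                              + g[2] ** 2) / 4.0)
        sp = cyclic_symmetry_spectrum(DensityMap(vals, 1.0), (0, 0, 1))
        assert sp.scores[3] > 0.999
        assert sp.best_order in (2, 4)

    def test_rejects_small_n_max(self, t9_map):
        with pytest.raises(ValueError):
            cyclic_symmetry_spectrum(t9_map, (0, 0, 1), n_max=1)


class TestAlignAverage:
    def test_known_integer_shifts_realign_exactly(self, morphology_maps):
        base = morphology_maps["thick_shell"]
        shifted = [
            DensityMap(np.roll(base.values, s, axis=(0, 1, 2)),
                       base.voxel_size, base.origin)
            for s in [(0, 0, 0), (2, -1, 3), (-4, 2, 1)]
        ]
        avg = align_average(shifted, base)
        assert np.allclose(avg.values, base.values, atol=1e-10)

    def test_averaging_beats_single_noisy_copy(self, morphology_maps):
        base = morphology_maps["thick_shell"]
        rng = np.random.default_rng(0)
        sigma = base.values.std() / math.sqrt(0.5)  # SNR 0.5
        noisy = [
            DensityMap(base.values + rng.normal(0, sigma, base.values.shape),
                       base.voxel_size, base.origin)
            for _ in range(50)
        ]
        avg = align_average(noisy, base)

        def corr(m):
            return np.corrcoef(m.values.ravel(), base.values.ravel())[0, 1]

        assert corr(avg) > max(corr(m) for m in noisy)

    def test_single_map_returned_unchanged(self, t9_map):
        out = align_average([t9_map])
        assert np.array_equal(out.values, t9_map.values)

    def test_mismatched_grids_rejected(self, t9_map):
        other = DensityMap(np.zeros((8, 8, 8)), t9_map.voxel_size)
        with pytest.raises(ValueError):
            align_average([t9_map, other])


class TestFSC:
    def test_self_correlation_is_one_everywhere(self, t9_map):
        curve = fsc(t9_map, t9_map)
        assert np.allclose(curve.correlations, 1.0)

    def test_independent_noise_decorrelates(self):
        rng = np.random.default_rng(1)
        a = DensityMap(rng.normal(size=(48, 48, 48)), 1.0)
        b = DensityMap(rng.normal(size=(48, 48, 48)), 1.0)
        curve = fsc(a, b)
        # Skip the DC shell; high shells contain many voxels -> small |FSC|.
        assert np.all(np.abs(curve.correlations[5:]) < 0.2)

    def test_symmetric_and_bounded(self, morphology_maps):
        rng = np.random.default_rng(2)
        base = morphology_maps["thick_shell"]
        a = DensityMap(base.values + rng.normal(0, 0.1, base.values.shape),
                       base.voxel_size)
        b = DensityMap(base.values + rng.normal(0, 0.1, base.values.shape),
                       base.voxel_size)
        ab, ba = fsc(a, b), fsc(b, a)
        assert np.allclose(ab.correlations, ba.correlations)
        assert np.all(np.abs(ab.correlations) <= 1.0 + 1e-12)

    def test_matches_snr_expectation(self):
        # Shared white signal + independent white noise:
        # E[FSC] = SNR / (1 + SNR) in every shell.
        rng = np.random.default_rng(3)
        n = 48
        signal = rng.normal(size=(n, n, n))
        snr = 0.8
        sigma = 1.0 / math.sqrt(snr)
        a = DensityMap(signal + rng.normal(0, sigma, signal.shape), 1.0)
        b = DensityMap(signal + rng.normal(0, sigma, signal.shape), 1.0)
        curve = fsc(a, b)
        expected = snr / (1.0 + snr)
        # Average over well-populated shells to beat sampling noise.
        assert abs(curve.correlations[8:].mean() - expected) < 0.03

    def test_threshold_crossings_interpolated(self):
        curve_f = np.arange(11) / 10.0
        from capsid.profile import FSCCurve

        c = FSCCurve(frequencies=curve_f,
                     correlations=np.linspace(1.0, 0.0, 11))
        assert math.isclose(c.crossing(0.55), 0.45, rel_tol=1e-6)
        assert c.crossing(-0.5) is None


class TestShrinkage:
    @pytest.mark.parametrize("length,factor,expected", [
        (21.0, 25.0 / 21.0, 25.0),
        (40.0, 47.0 / 40.0, 47.0),
        (13.7, 1.0, 13.7),
    ])
    def test_linear_correction(self, length, factor, expected):
        assert math.isclose(shrinkage_correct(length, factor), expected)
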