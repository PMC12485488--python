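"""Helical indexing: radial profile, cylindrical unwrapping, lattice peaks."""

import numpy as np
import pytest

from helical_validate import (
    DensityMap,
    HelicalParams,
    IndexingError,
    amyloid_model,
    autocorrelate,
    cylindrical_projection,
    default_model,
    detect_csym,
    estimate_radius,
    find_lattice_peaks,
    index_helical_params,
    make_helical_map,
    radial_profile,
    wrap_twist,
)
from helical_validate.indexing import RadialProfile


class TestRadialProfile:
    def test_uniform_map_flat_profile(self):
        m = DensityMap(np.ones((16, 16, 16)), 1.0)
        prof = radial_profile(m)
        assert np.allclose(prof.mean_density, 1.0)
        assert prof.radii[0] == 0.0
        assert np.all(np.diff(prof.radii) > 0)

    def test_zero_map_zero_profile(self):
        prof = radial_profile(DensityMap(np.zeros((16, 16, 16)), 1.0))
        assert np.all(prof.mean_density == 0)

    def test_tube_profile_peaks_at_tube_radius(self):
        from helical_validate import PseudoAtom, PseudoAtomModel

        model = PseudoAtomModel(
            atoms=(PseudoAtom(radius=20.0, azimuth=0.0, height=0.0, sigma=2.5),),
            box_size=64,
            voxel_size=2.0,
        )
        m = make_helical_map(model, HelicalParams(33.0, 4.0, 1))
        prof = radial_profile(m)
        r_max = prof.radii[int(np.argmax(prof.mean_density))]
        assert r_max == pytest.approx(20.0, abs=2.0)


class TestEstimateRadius:
    def test_sharp_shell(self):
        radii = np.arange(16.0)
        dens = np.zeros(16)
        dens[10] = 5.0
        assert estimate_radius(RadialProfile(radii, dens)) == pytest.approx(10.0)

    def test_two_equal_shells_average(self):
        radii = np.arange(40.0)
        dens = np.zeros(40)
        dens[10] = dens[30] = 1.0
        assert estimate_radius(RadialProfile(radii, dens)) == pytest.approx(20.0)

    def test_scale_invariance(self, helix_c1):
        prof = radial_profile(helix_c1)
        scaled = RadialProfile(prof.radii, prof.mean_density * 7.3)
        assert estimate_radius(scaled) == pytest.approx(estimate_radius(prof))

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            estimate_radius(RadialProfile(np.arange(8.0), np.zeros(8)))


class TestCylindricalProjection:
    def test_rotationally_invariant_map_constant_in_azimuth(self):
        # analytic cylinder shell: density depends on radius only
        n = 32
        y, x = np.meshgrid(np.arange(n) - n / 2, np.arange(n) - n / 2, indexing="ij")
        r = np.hypot(y, x)
        slab = np.exp(-((r - 8.0) ** 2) / 8.0)
        m = DensityMap(np.broadcast_to(slab, (n, n, n)).copy(), 1.0)
        proj = cylindrical_projection(m, (6.0, 10.0), angular_step=2.0, axial_step=1.0)
        spread = proj.image.max(axis=0) - proj.image.min(axis=0)
        assert np.all(spread < 0.02 * proj.image.max())

    def test_step_controls_sampling_density(self, helix_c1):
        p1 = cylindrical_projection(helix_c1, (10.0, 20.0), angular_step=1.0)
        p2 = cylindrical_projection(helix_c1, (10.0, 20.0), angular_step=2.0)
        assert p1.image.shape[0] == 2 * p2.image.shape[0]
        assert p1.image.shape[1] == p2.image.shape[1]

    def test_band_outside_grid_rejected(self, helix_c1):
        with pytest.raises(ValueError, match="radius band"):
            cylindrical_projection(helix_c1, (10.0, 1000.0))


class TestAutocorrelate:
    def test_origin_value_is_one(self, helix_c1):
        proj = cylindrical_projection(helix_c1, (10.0, 20.0))
        surf = autocorrelate(proj)
        i0 = len(surf.dphi) // 2
        j0 = len(surf.dz) // 2
        assert surf.values[i0, j0] == pytest.approx(1.0, abs=1e-9)

    def test_point_inversion_symmetry(self, helix_c1):
        proj = cylindrical_projection(helix_c1, (10.0, 20.0))
        v = autocorrelate(proj).values
        # v(-dphi, -dz) == v(dphi, dz); grid is odd in dz, even in dphi
        flipped = v[::-1, ::-1]
        core = v[1:, :]
        np.testing.assert_allclose(core, flipped[:-1, :], atol=1e-9)

    def test_peaks_at_generating_lag(self, helix_c1, params_c1):
        proj = cylindrical_projection(helix_c1, (10.0, 20.0))
        surf = autocorrelate(proj)
        peaks = find_lattice_peaks(surf)
        best = min(
            peaks,
            key=lambda p: abs(p.dphi - params_c1.twist) + abs(p.dz - params_c1.rise),
        )
        assert abs(best.dphi - params_c1.twist) <= 1.0
        assert abs(best.dz - params_c1.rise) <= 1.0


class TestFindLatticePeaks:
    def test_peak_set_closed_under_inversion(self, helix_c1):
        proj = cylindrical_projection(helix_c1, (10.0, 20.0))
        peaks = find_lattice_peaks(autocorrelate(proj))
        assert peaks, "expected lattice peaks on a clean helix"
        tagged = {(round(p.dphi, 3), round(p.dz, 3)) for p in peaks}
        for p in peaks:
            assert (round(wrap_twist(-p.dphi), 3), round(-p.dz, 3)) in tagged

    def test_pure_noise_yields_no_stable_peaks(self):
        rng = np.random.default_rng(3)
        m = DensityMap(rng.standard_normal((64, 64, 64)), 2.0)
        with pytest.raises((IndexingError, ValueError)):
            index_helical_params(m, with_csym=False)


class TestIndexHelicalParams:
    @pytest.mark.parametrize(
        "twist, rise, csym",
        [(57.0, 12.0, 1), (57.0, 12.0, 3), (130.78, 9.68, 1), (-75.13, 11.54, 1)],
    )
    def test_recovery_within_one_step(self, twist, rise, csym):
        p = HelicalParams(twist, rise, csym)
        m = make_helical_map(default_model(), p)
        res = index_helical_params(m)
        assert abs(wrap_twist(res.params.twist - twist)) <= 1.0
        assert abs(res.params.rise - rise) <= 1.0
        assert res.params.csym == csym
        # result invariants
        assert res.params.rise == pytest.approx(abs(res.peak[1]))
        assert res.params.twist == pytest.approx(wrap_twist(res.peak[0]))
        assert -1.0 <= res.peak_score <= 1.0 + 1e-9

    def test_amyloid_preset_recovers_small_twist(self):
        p = HelicalParams(-1.2, 4.8, 1)
        m = make_helical_map(amyloid_model(), p)
        res = index_helical_params(m, angular_step=0.5, axial_step=0.2)
        assert abs(res.params.twist - p.twist) <= 0.5
        assert abs(res.params.rise - p.rise) <= 0.2

    def test_full_symmetry_chosen_over_multiple(self):
        # map whose lattice contains both (65.42, 5.07) and its n=22
        # multiple near (-0.76, 111.54): the point nearest the equator wins
        p_full = HelicalParams(65.42, 5.07, 1)
        m = make_helical_map(default_model(), p_full)
        res = index_helical_params(m, with_csym=False)
        assert abs(res.params.twist - 65.42) <= 1.0
        assert abs(res.params.rise - 5.07) <= 1.0

    def test_mirrored_map_flips_twist_sign(self, helix_c1, params_c1):
        mirrored = helix_c1.with_data(np.ascontiguousarray(helix_c1.data[::-1]))
        res = index_helical_params(helix_c1, with_csym=False)
        res_m = index_helical_params(mirrored, with_csym=False)
        assert abs(res_m.params.rise - res.params.rise) <= 1.0
        assert abs(wrap_twist(res_m.params.twist + res.params.twist)) <= 1.0

    def test_deterministic(self, helix_c1):
        a = index_helical_params(helix_c1, with_csym=False)
        b = index_helical_params(helix_c1, with_csym=False)
        assert a.params == b.params and a.peak == b.peak


class TestDetectCsym:
    @pytest.mark.parametrize("csym", [1, 2, 3, 4, 6])
    def test_recovers_generator_order(self, csym):
        m = make_helical_map(default_model(), HelicalParams(57.0, 12.0, csym))
        assert detect_csym(m) == csym

    def test_intensity_scale_invariance(self, helix_c3):
        scaled = helix_c3.with_data(helix_c3.data * 100.0)
        assert detect_csym(scaled) == detect_csym(helix_c3)
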