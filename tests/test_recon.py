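"""Elastogram reconstruction chain: unwrap, align, harmonic, curl, invert."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from elastomap.phantom import homogeneous_phantom
from elastomap.recon import (
    align_slice_offsets,
    compose_elastogram,
    compute_curl,
    extract_first_harmonic,
    invert_helmholtz,
    reconstruct_elastogram,
    unwrap_phase_stack,
)
from elastomap.wavesim import (
    ComplexWaveField,
    WaveAcquisition,
    encode_wave_phases,
    plane_wave_field,
    shear_wavenumber,
)


def _acq_from_phases(phases, scale=1.0, spacing=(0.3, 0.3, 0.3), wrap=True):
    return WaveAcquisition(phase_images=phases, scale=scale, frequency=900.0,
                           spacing_mm=spacing, wrap_applied=wrap)


class TestUnwrap:
    def test_smooth_ramp_restored_up_to_slicewise_constant(self):
        x = np.linspace(0.0, 6.0, 32)
        ramp = np.broadcast_to(x[:, None], (32, 32)).copy()
        phases = np.zeros((32, 32, 3, 3, 4))
        phases += np.angle(np.exp(1j * ramp))[:, :, None, None, None]
        out = unwrap_phase_stack(_acq_from_phases(np.angle(np.exp(1j * phases))))
        for k in range(3):
            diff = out[:, :, k, 0, 0] - ramp
            assert np.allclose(diff, diff[0, 0], atol=1e-9)
            assert diff[0, 0] / (2 * np.pi) == pytest.approx(round(diff[0, 0] / (2 * np.pi)), abs=1e-9)

    def test_in_range_input_is_unchanged(self):
        rng = np.random.default_rng(0)
        phases = rng.uniform(-2.0, 2.0, (8, 8, 3, 3, 4)) * 0.4  # well inside (-pi, pi]
        smooth = phases * 0  # constant zero is trivially smooth
        out = unwrap_phase_stack(_acq_from_phases(smooth))
        assert np.allclose(out, smooth, atol=1e-12)

    def test_noisy_wrapped_plane_wave_mostly_restored(self):
        ph = homogeneous_phantom(5000.0, 0.0)
        f = plane_wave_field(ph, (2 / 5**0.5, 0, 1 / 5**0.5), (0, 1, 0))
        scale = 3.5 / np.abs(f.displacement).max()
        acq = encode_wave_phases(f, scale=scale, noise_sd_rad=0.1, wrap=True, seed=1)
        truth = scale * np.real(
            f.displacement[..., :, None] * np.exp(1j * acq.phase_offsets)
        )
        out = unwrap_phase_stack(acq)
        # compare after removing the per-slice 2-pi constant
        n_ok = 0
        n_tot = 0
        for d in range(3):
            for n in range(4):
                for k in range(9):
                    diff = out[:, :, k, d, n] - truth[:, :, k, d, n]
                    const = 2 * np.pi * np.round(np.median(diff) / (2 * np.pi))
                    err = np.abs(diff - const)
                    n_ok += (err < np.pi / 2).sum()
                    n_tot += err.size
        assert n_ok / n_tot > 0.99


class TestAlign:
    def test_injected_slice_offsets_removed_exactly(self):
        rng = np.random.default_rng(2)
        vol = rng.uniform(-0.5, 0.5, (6, 6, 3))
        shifted = vol + np.array([0.0, 2 * np.pi, 4 * np.pi])
        out = align_slice_offsets(shifted)
        assert np.allclose(out, vol, atol=1e-12)

    def test_consistent_stack_unchanged(self):
        rng = np.random.default_rng(3)
        vol = rng.uniform(-1.0, 1.0, (6, 6, 4))
        assert np.allclose(align_slice_offsets(vol), vol, atol=1e-12)

    @given(st.lists(st.integers(min_value=-3, max_value=3), min_size=4, max_size=4))
    @settings(deadline=None, max_examples=25)
    def test_arbitrary_integer_turn_offsets_removed(self, turns):
        rng = np.random.default_rng(7)
        vol = rng.uniform(-0.5, 0.5, (5, 5, 4))
        shifted = vol + 2 * np.pi * np.array(turns, float)
        out = align_slice_offsets(shifted)
        assert np.allclose(out - out[:, :, :1] + vol[:, :, :1], vol, atol=1e-9)

    def test_through_slice_wavenumber_recovered(self):
        ph = homogeneous_phantom(5000.0, 0.0)
        n = np.array([2.0, 0.0, 1.0]) / np.sqrt(5)
        f = plane_wave_field(ph, n, (0, 1, 0))
        scale = 3.5 / np.abs(f.displacement).max()
        acq = encode_wave_phases(f, scale=scale, wrap=True)
        aligned = align_slice_offsets(unwrap_phase_stack(acq))
        rec = extract_first_harmonic(aligned, scale, 900.0, acq.spacing_mm)
        u = rec.displacement[..., 1]
        kz = -np.median(np.angle(u[:, :, 1:] / u[:, :, :-1])) / 0.3e-3
        k_true = shear_wavenumber(5000 + 0j, 1000.0, 900.0).real * n[2]
        assert kz == pytest.approx(k_true, rel=0.05)


class TestFirstHarmonic:
    def test_unit_cosine(self):
        s = np.zeros((1, 1, 1, 3, 4))
        s[0, 0, 0, 0] = [1.0, 0.0, -1.0, 0.0]
        h = extract_first_harmonic(s, 1.0, 900.0, (0.3, 0.3, 0.3))
        assert h.displacement[0, 0, 0, 0] == pytest.approx(1.0 + 0.0j, abs=1e-14)

    def test_dc_rejected(self):
        s = np.full((1, 1, 1, 3, 4), 7.3)
        h = extract_first_harmonic(s, 1.0, 900.0, (0.3, 0.3, 0.3))
        assert np.allclose(h.displacement, 0.0, atol=1e-13)

    def test_amplitude_and_phase_recovered(self):
        theta = np.array([0, np.pi / 2, np.pi, 3 * np.pi / 2])
        s = np.zeros((1, 1, 1, 3, 4))
        s[0, 0, 0, 1] = 3.0 * np.cos(theta + np.pi / 3)
        h = extract_first_harmonic(s, 1.0, 900.0, (0.3, 0.3, 0.3))
        val = h.displacement[0, 0, 0, 1]
        assert abs(val) == pytest.approx(3.0, rel=1e-12)
        assert np.angle(val) == pytest.approx(np.pi / 3, abs=1e-12)

    def test_missing_wave_phase_rejected(self):
        with pytest.raises(ValueError, match="4 wave phases"):
            extract_first_harmonic(np.zeros((2, 2, 2, 3, 3)), 1.0, 900.0, (0.3,) * 3)


class TestCurl:
    def test_gradient_field_has_negligible_curl(self):
        # U = grad(sin(ax) * cos(by) * z) sampled analytically
        nx, ny, nz = 24, 24, 7
        h = 0.3e-3
        x, y, z = np.meshgrid(*(np.arange(m) * h for m in (nx, ny, nz)), indexing="ij")
        a, b = 300.0, 200.0
        u = np.stack([
            a * np.cos(a * x) * np.cos(b * y) * z,
            -b * np.sin(a * x) * np.sin(b * y) * z,
            np.sin(a * x) * np.cos(b * y),
        ], axis=-1).astype(complex)
        f = ComplexWaveField(u, 900.0, (0.3, 0.3, 0.3))
        q = compute_curl(f)
        scale = np.abs(u).max() / h
        assert np.abs(q.q[q.validity]).max() < 1e-3 * scale

    def test_plane_wave_curl_matches_analytic(self):
        # >= 18 voxels/wavelength keeps the central-difference sinc factor
        # within 2 percent of unity
        ph = homogeneous_phantom(5000.0, 0.0, spacing_mm=(0.13, 0.13, 0.13))
        f = plane_wave_field(ph, (1, 0, 0), (0, 1, 0))
        k = shear_wavenumber(5000 + 0j, 1000.0, 900.0)
        q = compute_curl(f)
        expected = -1j * k * f.displacement[..., 1]  # q_z = d(u_y)/dx
        ratio = q.q[..., 2][q.validity] / expected[q.validity]
        assert np.abs(ratio - 1).max() < 0.02

    def test_compressional_contamination_leaves_curl_unchanged(self):
        from elastomap.wavesim import add_compressional_component

        ph = homogeneous_phantom(5000.0, 0.0)
        f = plane_wave_field(ph, (1, 0, 0), (0, 1, 0))
        fc = add_compressional_component(f, amplitude=np.abs(f.displacement).max())
        q1 = compute_curl(f)
        q2 = compute_curl(fc)
        ref = np.abs(q1.q[q1.validity]).max()
        assert np.abs((q2.q - q1.q)[q1.validity]).max() < 0.02 * ref

    def test_too_few_slices_rejected(self):
        u = np.zeros((8, 8, 2, 3), complex)
        with pytest.raises(ValueError, match="3 voxels"):
            compute_curl(ComplexWaveField(u, 900.0, (0.3, 0.3, 0.3)))


class TestInversion:
    def test_elastic_plane_wave_recovered_within_5_percent(self):
        ph = homogeneous_phantom(5000.0, 0.0)
        n = np.array([2.0, 1.0, 1.0]) / np.sqrt(6)
        p = np.array([1.0, -2.0, 0.0]) / np.sqrt(5)
        f = plane_wave_field(ph, n, p)
        acq = encode_wave_phases(f, scale=2.0 / np.abs(f.displacement).max())
        e = reconstruct_elastogram(acq)
        assert np.median(e.g_magnitude[e.validity]) == pytest.approx(5000.0, rel=0.05)

    def test_viscoelastic_phase_angle_recovered(self):
        ph = homogeneous_phantom(5000.0, 2000.0)
        n = np.array([2.0, 1.0, 1.0]) / np.sqrt(6)
        p = np.array([1.0, -2.0, 0.0]) / np.sqrt(5)
        f = plane_wave_field(ph, n, p)
        acq = encode_wave_phases(f, scale=2.0 / np.abs(f.displacement).max())
        e = reconstruct_elastogram(acq)
        y_truth = (2 / np.pi) * np.arctan(0.4)
        assert abs(np.median(e.y[e.validity]) - y_truth) < 0.05

    def test_frequency_scaling_is_exact(self):
        ph = homogeneous_phantom(5000.0, 1000.0, grid_shape=(24, 24, 7))
        f = plane_wave_field(ph, (1, 0, 0), (0, 0, 1))
        q = compute_curl(f)
        e1 = invert_helmholtz(q, frequency=900.0)
        e2 = invert_helmholtz(q, frequency=1800.0)
        v = e1.validity & e2.validity
        assert np.allclose(e2.gd_raw[v], 4 * e1.gd_raw[v], rtol=1e-12)
        assert np.allclose(e2.gl_raw[v], 4 * e1.gl_raw[v], rtol=1e-12)

    def test_scale_invariance_end_to_end(self):
        ph = homogeneous_phantom(5000.0, 2000.0)
        f = plane_wave_field(ph, (1, 0, 0), (0, 0, 1))
        base = 1.2 / np.abs(f.displacement).max()
        maps = []
        for c in (1.0, 2.5):
            acq = encode_wave_phases(f, scale=c * base, wrap=True)
            e = reconstruct_elastogram(acq)
            maps.append(e)
        v = maps[0].validity & maps[1].validity
        assert np.allclose(maps[0].g_magnitude[v], maps[1].g_magnitude[v], rtol=1e-9)

    def test_recovery_error_decreases_with_resolution(self):
        errs = []
        for vox_per_wl in (4, 6, 8, 12):
            lam_mm = np.sqrt(5.0) / 900.0 * 1e3
            sp = lam_mm / vox_per_wl
            ph = homogeneous_phantom(5000.0, 0.0, grid_shape=(48, 16, 7),
                                     spacing_mm=(sp, sp, sp))
            f = plane_wave_field(ph, (1, 0, 0), (0, 0, 1))
            acq = encode_wave_phases(f, scale=2.0 / np.abs(f.displacement).max())
            e = reconstruct_elastogram(acq)
            errs.append(abs(np.median(e.g_magnitude[e.validity]) / 5000.0 - 1))
        assert all(a > b for a, b in zip(errs, errs[1:]))

    def test_all_voxels_excluded_raises(self):
        q_zero = compute_curl(ComplexWaveField(
            np.zeros((8, 8, 5, 3), complex), 900.0, (0.3, 0.3, 0.3)))
        with pytest.raises(ValueError, match="excluded"):
            invert_helmholtz(q_zero)


class TestCompose:
    def test_three_four_five(self):
        g, y = compose_elastogram(3000.0, 4000.0)
        assert float(g) == pytest.approx(5000.0, abs=1e-10)

    def test_purely_elastic_and_viscous_limits(self):
        _, y0 = compose_elastogram(5000.0, 0.0)
        _, y1 = compose_elastogram(0.0, 5000.0)
        assert float(y0) == 0.0
        assert float(y1) == 1.0

    def test_equal_moduli_give_half(self):
        _, y = compose_elastogram(2000.0, 2000.0)
        assert float(y) == pytest.approx(0.5, abs=1e-14)

    def test_zero_modulus_is_masked(self):
        g, y = compose_elastogram(0.0, 0.0)
        assert float(g) == 0.0
        assert np.isnan(float(y))

    @given(st.floats(0.0, 1e5), st.floats(0.0, 1e5))
    @settings(deadline=None, max_examples=100)
    def test_identities_hold_for_any_moduli(self, gd, gl):
        g, y = compose_elastogram(gd, gl)
        assert float(g) == pytest.approx(np.hypot(gd, gl), rel=1e-12, abs=1e-12)
        if gd > 0 or gl > 0:
            assert 0.0 <= float(y) <= 1.0
            assert max(gd, gl) - 1e-9 <= float(g) <= gd + gl + 1e-9
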