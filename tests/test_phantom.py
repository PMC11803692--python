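"""Phantom and raw-signal generator contracts."""

import numpy as np
import pytest

from elastomap.phantom import (
    Band,
    Ellipsoid,
    REGION_IDS,
    RegionParams,
    build_property_phantom,
    homogeneous_phantom,
    magnitude_noise,
    synthesize_dwi,
    synthesize_echo_train,
    synthesize_histology,
)


class TestPropertyPhantom:
    def test_homogeneous_fill_is_exact(self):
        ph = homogeneous_phantom(5000.0, 2000.0)
        assert ph.grid_shape == (64, 64, 9)
        assert ph.spacing_mm == (0.3, 0.3, 0.3)
        assert np.all(ph.storage_modulus == 5000.0)
        assert np.all(ph.loss_modulus == 2000.0)
        assert np.all(ph.labels == REGION_IDS["brain"])

    def test_callosal_band_carries_its_own_stiffness(self):
        regions = {
            "brain": RegionParams(5000.0, 0.0),
            "corpus_callosum": RegionParams(4440.0, 0.0),
        }
        shapes = {"corpus_callosum": Band(9.6, 12.0, -0.05, 0.9, (3.0, 16.2), (0.0, 2.7))}
        ph = build_property_phantom(regions, shapes)
        cc = ph.region_mask("corpus_callosum")
        assert cc.any() and (~cc).any()
        assert np.all(ph.storage_modulus[cc] == 4440.0)
        assert np.all(ph.storage_modulus[ph.region_mask("brain")] == 5000.0)

    def test_tumor_ellipsoid_volume_matches_request(self):
        target = 16.88  # mm^3
        regions = {
            "brain": RegionParams(5000.0),
            "tumor_core": RegionParams(4240.0),
        }
        shapes = {"tumor_core": Ellipsoid.from_volume((9.6, 9.6, 1.35), target)}
        ph = build_property_phantom(regions, shapes)
        vol = ph.region_volume_mm3("tumor_core")
        assert abs(vol - target) <= ph.voxel_volume_mm3

    def test_overlap_resolves_by_priority(self):
        regions = {
            "brain": RegionParams(5000.0),
            "corpus_callosum": RegionParams(4440.0),
            "tumor_core": RegionParams(3900.0),
        }
        shapes = {
            "corpus_callosum": Band(9.6, 9.6, 0.0, 1.5, (0.0, 19.2), (0.0, 2.7)),
            "tumor_core": Ellipsoid((9.6, 9.6, 1.35), (2.0, 2.0, 1.0)),
        }
        ph = build_property_phantom(regions, shapes)
        tumor = ph.region_mask("tumor_core")
        assert tumor.any()
        assert np.all(ph.storage_modulus[tumor] == 3900.0)

    def test_negative_modulus_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            RegionParams(-100.0)

    def test_tensors_symmetric_positive_semidefinite(self):
        ph = homogeneous_phantom(5000.0)
        t6 = ph.tensors.reshape(-1, 6)[0]
        d = np.array([
            [t6[0], t6[3], t6[4]],
            [t6[3], t6[1], t6[5]],
            [t6[4], t6[5], t6[2]],
        ])
        assert np.all(np.linalg.eigvalsh(d) >= 0)


class TestEchoTrain:
    def test_closed_form_decay(self):
        ph = homogeneous_phantom(5000.0, t2_ms=40.0, grid_shape=(3, 3, 3))
        tr = synthesize_echo_train(ph, te_list=[40.0, 80.0], s0=1000.0, noise_sd=0.0)
        assert tr.signal[0, 0, 0, 0] == pytest.approx(1000.0 / np.e, rel=1e-12)

    def test_log_signal_linear_in_te(self):
        ph = homogeneous_phantom(5000.0, t2_ms=40.0, grid_shape=(2, 2, 2))
        tr = synthesize_echo_train(ph, noise_sd=0.0)
        logs = np.log(tr.signal[0, 0, 0])
        slopes = np.diff(logs) / np.diff(tr.te_list)
        assert np.allclose(slopes, -1.0 / 40.0, atol=1e-12)

    def test_pure_noise_plateau_mean_is_rayleigh(self):
        rng = np.random.default_rng(0)
        mags = magnitude_noise(np.zeros(200_000), 10.0, rng)
        assert mags.mean() == pytest.approx(10.0 * np.sqrt(np.pi / 2), rel=0.01)

    def test_zero_t2_voxels_flagged_and_zeroed(self):
        ph = homogeneous_phantom(5000.0, t2_ms=40.0, grid_shape=(2, 2, 1))
        ph.t2[0, 0, 0] = 0.0
        tr = synthesize_echo_train(ph, noise_sd=0.0)
        assert tr.zero_t2_mask[0, 0, 0]
        assert np.all(tr.signal[0, 0, 0] == 0.0)

    def test_determinism(self):
        ph = homogeneous_phantom(5000.0, grid_shape=(4, 4, 2))
        a = synthesize_echo_train(ph, noise_sd=5.0, seed=3).signal
        b = synthesize_echo_train(ph, noise_sd=5.0, seed=3).signal
        assert np.array_equal(a, b)


class TestDWI:
    def test_isotropic_attenuation(self):
        ph = build_property_phantom(
            {"brain": RegionParams(5000.0, d_eigs=(6e-4, 6e-4, 6e-4))},
            shapes={}, grid_shape=(2, 2, 2),
        )
        dwi = synthesize_dwi(ph, noise_sd=0.0, s0=1000.0)
        ratio = dwi.signal[0, 0, 0, 1:] / dwi.signal[0, 0, 0, 0]
        assert np.allclose(ratio, np.exp(-0.9), atol=1e-12)

    def test_eigendirection_attenuation(self):
        ph = build_property_phantom(
            {"brain": RegionParams(5000.0, d_eigs=(1.7e-3, 2e-4, 2e-4),
                                   fiber_axis=(1, 0, 0))},
            shapes={}, grid_shape=(2, 2, 1),
        )
        dwi = synthesize_dwi(ph, directions=np.array([[1.0, 0.0, 0.0]]),
                             noise_sd=0.0, s0=1.0)
        assert dwi.signal[0, 0, 0, 1] == pytest.approx(np.exp(-2.55), rel=1e-12)

    def test_negative_bvalue_rejected(self):
        ph = homogeneous_phantom(5000.0, grid_shape=(2, 2, 1))
        with pytest.raises(ValueError, match="non-negative"):
            synthesize_dwi(ph, bvalue=-1.0)

    def test_non_unit_directions_rejected(self):
        ph = homogeneous_phantom(5000.0, grid_shape=(2, 2, 1))
        with pytest.raises(ValueError, match="unit-norm"):
            synthesize_dwi(ph, directions=np.array([[2.0, 0.0, 0.0]]))


class TestHistology:
    def test_zero_fraction_means_no_stained_pixels(self):
        img = synthesize_histology(stained_fraction=0.0, seed=0)
        assert img.truth_stained_fraction == 0.0
        assert not img.truth_stain_mask.any()

    def test_truth_bookkeeping(self):
        img = synthesize_histology(stained_fraction=0.1, seed=0)
        n = img.pixels.shape[0] * img.pixels.shape[1]
        assert img.truth_stain_mask.sum() == round(0.1 * n)
        assert img.truth_stained_fraction == pytest.approx(0.1, abs=1e-4)

    def test_nucleus_count_is_poisson_with_requested_mean(self):
        # mean over many seeds approaches density * area / 100
        counts = [
            len(synthesize_histology(width=96, height=96, stained_fraction=0.0,
                                     cell_density_per_100um2=30.0,
                                     seed=s).truth_nucleus_centers)
            for s in range(100)
        ]
        area_um2 = 96 * 96 * 0.25**2
        expected = 30.0 * area_um2 / 100.0
        counts = np.asarray(counts)
        assert counts.mean() == pytest.approx(expected, rel=0.1)
        # Poisson: variance comparable to the mean
        assert 0.5 * expected < counts.var() < 2.0 * expected

    def test_infeasible_density_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            synthesize_histology(width=32, height=32,
                                 cell_density_per_100um2=5000.0, seed=0)

    def test_inseparable_palettes_rejected(self):
        with pytest.raises(ValueError, match="separable"):
            synthesize_histology(
                stained_palette={"mean": (100, 100, 100), "sd": (5, 5, 5)},
                background_palette={"mean": (110, 100, 100), "sd": (5, 5, 5)},
            )

    def test_determinism(self):
        a = synthesize_histology(stained_fraction=0.05,
                                 cell_density_per_100um2=10.0, seed=9)
        b = synthesize_histology(stained_fraction=0.05,
                                 cell_density_per_100um2=10.0, seed=9)
        assert np.array_equal(a.pixels, b.pixels)
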