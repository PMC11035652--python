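"""FRAP fitting, Debye form factors, scattering peaks, and phase maps,
validated end to end on synthetic fixtures with known ground truth."""

import numpy as np
import pytest

from condnet.frap import FRAPFit, fit_frap, frap_model
from condnet.imaging import classify_phase_map, index_of_dispersion
from condnet.scattering import (ScatteringProfile, detect_peaks, form_factor)
from condnet.synth import (make_droplet_image, make_frap_curves,
                           make_scattering_profile)


class TestFRAP:
    def test_noiseless_self_consistency(self):
        t, y, truth = make_frap_curves(I0=0.5, I_inf=1.0, t_half=50.0,
                                       n_replicates=1, noise_sd=0.0)
        fit = fit_frap(t, y)
        assert fit.I0[0] == pytest.approx(0.5, abs=1e-8)
        assert fit.I_inf[0] == pytest.approx(1.0, abs=1e-8)
        assert fit.t_half == pytest.approx(50.0, abs=1e-6)

    def test_half_time_property(self):
        # the model passes through the midpoint at t = t_half
        assert frap_model(50.0, 0.4, 1.2, 50.0) == pytest.approx(
            (0.4 + 1.2) / 2)

    def test_grouped_fit_recovers_within_2se(self):
        """12 replicates at 2% noise: shared t_half within 2 SE of truth."""
        t, y, truth = make_frap_curves(n_replicates=12, noise_sd=0.02, seed=3)
        fit = fit_frap(t, y)
        assert abs(fit.t_half - truth["t_half"]) < 2 * fit.t_half_se
        assert fit.n_replicates == 12

    def test_monte_carlo_calibration(self):
        """Across many noise seeds, the truth lies within 2 SE most of
        the time (the standard error is well calibrated)."""
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            t, y, truth = make_frap_curves(n_replicates=12, noise_sd=0.02,
                                           seed=seed)
            fit = fit_frap(t, y)
            hits += abs(fit.t_half - truth["t_half"]) < 2 * fit.t_half_se
        assert hits >= int(0.9 * n_seeds)

    def test_scale_equivariance(self):
        t, y, _ = make_frap_curves(n_replicates=3, noise_sd=0.01, seed=1)
        f1 = fit_frap(t, y)
        f2 = fit_frap(t, 7.0 * y)
        assert f2.t_half == pytest.approx(f1.t_half, rel=1e-6)
        assert np.allclose(f2.I0, 7.0 * f1.I0, rtol=1e-6)
        assert np.allclose(f2.I_inf, 7.0 * f1.I_inf, rtol=1e-6)

    def test_reference_normalization(self):
        t, y, truth = make_frap_curves(n_replicates=2, noise_sd=0.0)
        bleach = np.exp(-t / 900.0)
        fit = fit_frap(t, y * bleach, reference=bleach)
        assert fit.t_half == pytest.approx(truth["t_half"], rel=1e-6)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="6"):
            fit_frap([0, 1, 2], [[1, 2, 3]])
        with pytest.raises(ValueError):
            fit_frap([-1, 0, 1, 2, 3, 4], [[1] * 6])


class TestFormFactor:
    def test_single_point_unity(self):
        q = np.linspace(0.01, 1.0, 30)
        p = form_factor(np.zeros((1, 3)), q)
        assert np.allclose(p.intensity, 1.0)

    def test_low_q_normalization(self, rng):
        coords = rng.random((40, 3)) * 10
        p = form_factor(coords, np.array([1e-6]))
        assert p.intensity[0] == pytest.approx(1.0, abs=1e-6)

    def test_two_point_closed_form(self):
        d = 4.2
        q = np.linspace(0.05, 2.0, 60)
        p = form_factor(np.array([[0, 0, 0], [0, 0, d]]), q)
        expected = 0.5 * (1 + np.sin(q * d) / (q * d))
        assert np.allclose(p.intensity, expected, rtol=1e-12)

    def test_rigid_body_invariance(self, rng):
        """P(q) is invariant under rotation + translation of the body."""
        from scipy.spatial.transform import Rotation

        coords = rng.random((30, 3)) * 8
        q = np.linspace(0.05, 1.5, 40)
        p1 = form_factor(coords, q)
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0])
        p2 = form_factor(rot.apply(coords) + np.array([5.0, -3.0, 11.0]), q)
        assert np.allclose(p1.intensity, p2.intensity, rtol=1e-10)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            form_factor(np.zeros((1, 3)), np.array([0.0, 0.1]))
        with pytest.raises(ValueError):
            form_factor(np.zeros((0, 3)), np.array([0.1]))


class TestDetectPeaks:
    def test_pure_power_law_empty(self):
        prof, _ = make_scattering_profile(peak_lengths=(), noise=0.0)
        assert len(detect_peaks(prof)) == 0

    def test_noisy_power_law_empty(self):
        prof, _ = make_scattering_profile(peak_lengths=(), noise=0.01, seed=4)
        assert len(detect_peaks(prof)) == 0

    @pytest.mark.parametrize("method", ["derivative", "multi_gauss"])
    def test_two_peak_recovery(self, method):
        """Gaussians at the condensate correlation lengths (55 and 77 Å)
        on a q^-2 background: both recovered within 2%."""
        prof, truth = make_scattering_profile(peak_lengths=(55.0, 77.0),
                                              noise=0.01, seed=2)
        peaks = detect_peaks(prof, method=method)
        assert len(peaks) == 2
        for d_true in truth["peak_lengths"]:
            err = np.abs(peaks.d - d_true).min() / d_true
            assert err < 0.02

    def test_methods_cross_validate_single_peak(self):
        prof, truth = make_scattering_profile(peak_lengths=(60.0,), noise=0.0)
        a = detect_peaks(prof, method="derivative")
        b = detect_peaks(prof, method="multi_gauss")
        assert len(a) == len(b) == 1
        grid_spacing = np.diff(np.log(prof.q)).max()
        assert abs(np.log(a.q[0]) - np.log(b.q[0])) < grid_spacing

    def test_length_map_inverts_generator(self):
        """d = 2pi/q is the exact inverse of the generator's q = 2pi/d."""
        prof, truth = make_scattering_profile(peak_lengths=(64.0,), noise=0.0)
        peaks = detect_peaks(prof)
        assert peaks.d[0] == pytest.approx(2 * np.pi / peaks.q[0])
        assert peaks.q[0] == pytest.approx(truth["peak_q"][0], rel=5e-3)

    def test_profile_validation(self):
        with pytest.raises(ValueError, match="increasing"):
            ScatteringProfile(q=np.array([0.2, 0.1]), intensity=np.ones(2))
        with pytest.raises(ValueError, match="20"):
            detect_peaks(ScatteringProfile(q=np.linspace(0.1, 1, 10),
                                           intensity=np.ones(10)))


class TestIndexOfDispersion:
    def test_constant_image(self):
        assert index_of_dispersion(np.full((32, 32), 7.0)) == 0.0

    def test_binary_half_half(self):
        img = np.zeros((10, 10))
        img[:5] = 8.0
        assert index_of_dispersion(img) == pytest.approx(8.0 / 2)

    def test_poisson_near_unity(self, rng):
        img = rng.poisson(100.0, size=(256, 256)).astype(float)
        assert abs(index_of_dispersion(img) - 1.0) < 3.0 / 256

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            index_of_dispersion(np.zeros((4, 4)))

    def test_tiff_and_npy_loading(self, rng, tmp_path):
        from condnet.imaging import load_image
        import tifffile

        img = rng.poisson(30.0, (16, 16)).astype(np.uint16)
        p = tmp_path / "well.tif"
        tifffile.imwrite(p, img)
        assert np.array_equal(load_image(p), img.astype(float))
        pn = tmp_path / "well.npy"
        np.save(pn, img)
        assert np.array_equal(load_image(pn), img.astype(float))


class TestPhaseMap:
    def test_identical_wells_all_positive_by_tie(self, rng):
        img = rng.poisson(50.0, (32, 32)).astype(float)
        wells = {k: [img.copy()] for k in ("a", "b", "c")}
        pm = classify_phase_map(wells)
        assert pm.table.positive.all()

    def test_threshold_arithmetic(self):
        # IoD 100 vs 5: threshold 10, so only the 100-well is positive
        big = np.zeros(200)
        big[:100] = 200.0       # IoD = var/mean = 100
        small = np.zeros(200)
        small[:100] = 10.0      # IoD = 5
        pm = classify_phase_map({"hot": [big], "cold1": [small],
                                 "cold2": [small]})
        assert pm.positive_wells() == ["hot"]
        assert pm.threshold == pytest.approx(10.0)

    def test_droplet_wells_positive(self, rng):
        droplet_wells = {
            f"d{k}": [make_droplet_image(seed=10 * k + i) for i in range(5)]
            for k in range(2)
        }
        uniform_wells = {
            f"u{k}": [rng.poisson(40.0, (128, 128)).astype(float)
                      for _ in range(5)]
            for k in range(2)
        }
        pm = classify_phase_map({**droplet_wells, **uniform_wells})
        tbl = pm.table.set_index("well")
        assert tbl.loc[["d0", "d1"], "positive"].all()
        assert not tbl.loc[["u0", "u1"], "positive"].any()

    def test_single_well_degenerate_flag(self, rng):
        pm = classify_phase_map({"only": [rng.poisson(10.0, (8, 8)) + 0.0]})
        assert pm.degenerate
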