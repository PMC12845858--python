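"""Physical-unit PSF kernels, the phantom generator, and image formation."""

import math

import numpy as np
import pytest

from psexcite import (
    ExcitationConfig,
    OpticalSystem,
    Phantom,
    RadialProfile,
    VesselSpec,
    build_psf_kernel,
    count_resolved_peaks,
    generate_phantom,
    kernel_fwhm,
    line_profile,
    parallel_pair_phantom,
    simulate_image,
)


class TestOpticalSystem:
    def test_waist_convention(self, optics):
        assert optics.waist_nm == pytest.approx(532 / (math.pi * 1.4), rel=1e-12)
        assert optics.gaussian_fwhm_nm == pytest.approx(142.4, abs=0.1)

    def test_invalid_na_rejected(self):
        with pytest.raises(ValueError):
            OpticalSystem(numerical_aperture=1.7)


class TestKernels:
    def test_gaussian_kernel_fwhm(self, optics, gaussian_kernel):
        measured = kernel_fwhm(gaussian_kernel)
        assert measured == pytest.approx(optics.gaussian_fwhm_nm, abs=gaussian_kernel.pixel_size)
        assert measured == pytest.approx(142.0, abs=3.0)

    def test_phase_shifted_kernel_fwhm(self, optics, phase_shifted_kernel):
        from psexcite import measure_psf
        analytic = measure_psf(ExcitationConfig(gamma=1.16, waist=optics.waist_nm)).fwhm
        measured = kernel_fwhm(phase_shifted_kernel)
        assert measured == pytest.approx(analytic, abs=phase_shifted_kernel.pixel_size)
        assert measured == pytest.approx(100.0, abs=3.0)

    def test_kernel_ring_to_center_ratio(self, phase_shifted_kernel):
        c = phase_shifted_kernel.center_index
        row = phase_shifted_kernel.values[c]
        # ring peak beyond the zero crossing vs center, within 2% of e^{-2.16}/1.16
        zc_px = int(math.sqrt(1.16 / 2) * 532 / (math.pi * 1.4) / phase_shifted_kernel.pixel_size)
        ring = row[c + zc_px + 1:].max()
        assert ring / row[c] == pytest.approx(math.exp(-2.16) / 1.16, rel=0.02)

    def test_kernels_are_normalized_and_shaped(self, gaussian_kernel, phase_shifted_kernel):
        for k in (gaussian_kernel, phase_shifted_kernel):
            assert k.values.sum() == pytest.approx(1.0, rel=1e-12)
            assert k.values.shape[0] % 2 == 1
        cg = gaussian_kernel.center_index
        assert gaussian_kernel.values[cg, cg] == gaussian_kernel.values.max()
        cp = phase_shifted_kernel.center_index
        assert phase_shifted_kernel.values[cp, cp] == phase_shifted_kernel.values.max()

    def test_undersampled_pixel_rejected(self, optics):
        with pytest.raises(ValueError, match="w0/5"):
            build_psf_kernel(optics, "gaussian", pixel_size_nm=30.0)


class TestPhantom:
    def test_seed_determinism(self):
        a = generate_phantom(seed=7, field_nm=2560.0)
        b = generate_phantom(seed=7, field_nm=2560.0)
        assert np.array_equal(a.image, b.image)
        c = generate_phantom(seed=8, field_nm=2560.0)
        assert not np.array_equal(a.image, c.image)

    def test_empty_spec_gives_blank_image(self):
        p = generate_phantom(VesselSpec.empty(), field_nm=1280.0)
        assert np.all(p.image == 0.0)
        assert p.junction_line is None

    def test_width_below_two_pixels_rejected(self):
        with pytest.raises(ValueError, match="2 pixels"):
            generate_phantom(VesselSpec(junction_branch_width_nm=15.0), pixel_size_nm=10.0)

    def test_calibrated_junction_separation(self, phantom):
        """Peak-to-peak distance across the rasterized branches = 120 nm +- 1 px."""
        start, end = phantom.junction_line
        prof = line_profile(phantom.image, start, end, phantom.pixel_size, n=481)
        from scipy.signal import find_peaks
        idx, _ = find_peaks(prof.values, prominence=0.5)
        assert len(idx) == 2
        centers = prof.radii[idx]
        assert centers[1] - centers[0] == pytest.approx(
            phantom.vessel_spec.junction_separation_nm, abs=phantom.pixel_size
        )

    def test_image_values_bounded(self, phantom):
        assert phantom.image.min() >= 0.0
        assert phantom.image.max() == pytest.approx(1.0)


class TestSimulateImage:
    @staticmethod
    def _phantom_from(image, pixel_size=10.0):
        return Phantom(image=image, pixel_size=pixel_size, seed=0,
                       vessel_spec=VesselSpec.empty())

    def test_delta_phantom_reproduces_kernel(self, gaussian_kernel):
        n = 201
        img = np.zeros((n, n))
        img[n // 2, n // 2] = 1.0
        out = simulate_image(self._phantom_from(img), gaussian_kernel).image
        k = gaussian_kernel.values
        half = k.shape[0] // 2
        sl = slice(n // 2 - half, n // 2 + half + 1)
        np.testing.assert_allclose(out[sl, sl], k, atol=1e-12)

    def test_uniform_phantom_stays_uniform(self, gaussian_kernel):
        out = simulate_image(self._phantom_from(np.full((201, 201), 0.7)),
                             gaussian_kernel).image
        np.testing.assert_allclose(out, 0.7, atol=1e-9)

    def test_interior_signal_conservation(self, gaussian_kernel):
        # content kept a full kernel extent away from the field edge: the
        # unit-sum kernel then redistributes but does not lose signal
        rng = np.random.default_rng(11)
        n = 301
        k = gaussian_kernel.values.shape[0]
        img = np.zeros((n, n))
        img[k:n - k, k:n - k] = rng.random((n - 2 * k, n - 2 * k))
        out = simulate_image(self._phantom_from(img), gaussian_kernel).image
        assert out.sum() == pytest.approx(img.sum(), rel=1e-6)

    def test_linearity(self, gaussian_kernel):
        rng = np.random.default_rng(3)
        n = 101
        p1, p2 = rng.random((n, n)), rng.random((n, n))
        a, b = 2.0, 0.5
        combo = simulate_image(self._phantom_from(a * p1 + b * p2), gaussian_kernel).image
        s1 = simulate_image(self._phantom_from(p1), gaussian_kernel).image
        s2 = simulate_image(self._phantom_from(p2), gaussian_kernel).image
        np.testing.assert_allclose(combo, a * s1 + b * s2, atol=1e-9)

    def test_pixel_size_mismatch_rejected(self, phantom, optics):
        k = build_psf_kernel(optics, "gaussian", pixel_size_nm=20.0)
        with pytest.raises(ValueError, match="mismatch"):
            simulate_image(phantom, k)


class TestLineProfileAndPeaks:
    def test_single_vessel_has_one_peak(self):
        ph = parallel_pair_phantom(separation_nm=0.0, width_nm=80.0)
        start, end = ph.junction_line
        prof = line_profile(ph.image, start, end, ph.pixel_size)
        assert count_resolved_peaks(prof) == 1

    def test_degenerate_segment_rejected(self, phantom):
        with pytest.raises(ValueError, match="degenerate"):
            line_profile(phantom.image, (100.0, 100.0), (100.0, 100.0), phantom.pixel_size)

    def test_endpoint_outside_rejected(self, phantom):
        with pytest.raises(ValueError, match="outside"):
            line_profile(phantom.image, (0.0, 0.0), (1e6, 0.0), phantom.pixel_size)

    def test_monotone_profile_has_no_interior_peaks(self):
        prof = RadialProfile(radii=np.linspace(0, 10, 50), values=np.linspace(1, 0, 50))
        assert count_resolved_peaks(prof) == 0

    def test_peak_normalization(self, phantom):
        start, end = phantom.junction_line
        prof = line_profile(phantom.image, start, end, phantom.pixel_size)
        assert prof.values.max() == pytest.approx(1.0)


class TestJunctionResolvability:
    def test_truth_resolved_gaussian_merged_phase_shifted_resolved(self, phantom, simulated_pair):
        img_gauss, img_ps = simulated_pair
        start, end = phantom.junction_line
        profs = {
            label: line_profile(im, start, end, phantom.pixel_size)
            for label, im in (("truth", phantom.image), ("gaussian", img_gauss.image),
                              ("ps", img_ps.image))
        }
        assert count_resolved_peaks(profs["truth"]) == 2
        assert count_resolved_peaks(profs["gaussian"]) == 1
        assert count_resolved_peaks(profs["ps"]) == 2


class TestTwoPointResolutionSweep:
    def test_thresholds_track_kernel_widths(self, optics):
        """Minimum resolvable separation: ~kernel FWHM for each mode, PS < Gaussian."""
        cfg = ExcitationConfig(gamma=1.16, waist=optics.waist_nm)
        kernels = {
            "gaussian": build_psf_kernel(optics, "gaussian", pixel_size_nm=5.0),
            "phase_shifted": build_psf_kernel(optics, "phase_shifted", cfg, pixel_size_nm=5.0),
        }
        thresholds = {}
        for label, kernel in kernels.items():
            thresholds[label] = None
            for sep in range(80, 170, 10):
                ph = parallel_pair_phantom(separation_nm=float(sep), pixel_size_nm=5.0)
                out = simulate_image(ph, kernel)
                start, end = ph.junction_line
                prof = line_profile(out.image, start, end, ph.pixel_size, n=400)
                if count_resolved_peaks(prof) == 2:
                    thresholds[label] = sep
                    break
        assert thresholds["phase_shifted"] is not None
        assert thresholds["gaussian"] is not None
        assert thresholds["phase_shifted"] < thresholds["gaussian"]
        assert abs(thresholds["gaussian"] - 142) <= 20
        assert abs(thresholds["phase_shifted"] - 100) <= 20
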