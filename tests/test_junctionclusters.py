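"""Line-profile extraction, baseline normalisation, peak calling, overlap,
correlation and Gaussian cluster sizing, checked against brute-force
oracles and generative ground truth."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from condensquant import junctionclusters as jc
from condensquant import synthgen
from condensquant.junctionclusters import FWHM_PER_SIGMA, LineProfile


def profile_from_values(values, pixel_size_nm=100.0):
    values = np.asarray(values, dtype=float)
    return LineProfile(np.arange(len(values), dtype=float), values, pixel_size_nm)


def normalized_from_values(values, pixel_size_nm=100.0):
    return jc.normalize_profile(profile_from_values(values, pixel_size_nm))


class TestExtractLineProfile:
    def test_uniform_image_gives_constant_profile(self):
        img = np.full((30, 30), 7.0)
        poly = np.array([[5.0, 5.0], [25.0, 20.0]])
        prof = jc.extract_line_profile(img, poly, width_px=4)
        assert np.allclose(prof.intensity, 7.0)

    def test_vertical_line_averages_spanned_columns(self):
        # columns hold values 1, 2, 3, ...: a vertical 4-px-wide line centred
        # between columns 10 and 11 averages columns 9..12 -> mean 11.5
        img = np.tile(np.arange(1.0, 31.0), (30, 1))
        poly = np.array([[2.0, 10.5], [27.0, 10.5]])
        prof = jc.extract_line_profile(img, poly, width_px=4)
        assert np.allclose(prof.intensity, np.mean([10.0, 11.0, 12.0, 13.0]))

    def test_width_one_on_grid_row_is_identity(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 10, (20, 40))
        poly = np.array([[7.0, 0.0], [7.0, 39.0]])
        prof = jc.extract_line_profile(img, poly, width_px=1)
        np.testing.assert_allclose(prof.intensity, img[7, : len(prof.intensity)])

    def test_too_short_polyline_rejected(self):
        with pytest.raises(ValueError, match="2"):
            jc.extract_line_profile(np.ones((10, 10)), np.array([[1.0, 1.0]]))

    def test_length_um_follows_pixel_size(self):
        prof = profile_from_values(np.arange(51.0), pixel_size_nm=100.0)
        assert prof.length_um == pytest.approx(5.0)


class TestNormalizeProfile:
    def test_constant_profile_baseline_and_unit_values(self):
        nprof = normalized_from_values(np.full(50, 5.0))
        assert nprof.baseline == 5.0
        assert np.allclose(nprof.normalized, 1.0)

    def test_length_39_rejected(self):
        with pytest.raises(ValueError, match="20th-40th"):
            normalized_from_values(np.ones(39))

    def test_rank_window_is_inclusive_1_based(self):
        # 21 values (ranks 20..40) of a strictly increasing sequence
        values = np.arange(1.0, 101.0)
        nprof = normalized_from_values(values)
        assert nprof.baseline == pytest.approx(np.mean(np.arange(20.0, 41.0)))

    def test_baseline_recovery_with_sparse_clusters(self):
        truth = synthgen.ProfileTruth(
            length_px=300, pixel_size_nm=100.0,
            cluster_centers_px=[60.0, 150.0, 240.0],
            cluster_fwhms_nm=[300.0, 300.0, 300.0],
            cluster_amplitudes=[200.0, 150.0, 250.0],
            baseline=100.0, noise_sd=0.0, seed=0,
        )
        real = synthgen.gen_junction_profile(truth)
        nprof = normalized_from_values(real.channel1)
        assert abs(nprof.baseline - 100.0) / 100.0 < 0.02

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            normalized_from_values(np.zeros(50))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(scale=st.floats(0.01, 1000.0), seed=st.integers(0, 1000))
    def test_scale_equivariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        values = rng.uniform(1.0, 10.0, 60)
        a = normalized_from_values(values)
        b = normalized_from_values(values * scale)
        np.testing.assert_allclose(a.normalized, b.normalized, rtol=1e-10)


class TestDetectPeaks:
    def test_monotonic_ramp_has_no_peaks(self):
        nprof = normalized_from_values(np.linspace(1.0, 10.0, 60))
        assert len(jc.detect_peaks(nprof, 0.5)) == 0

    def test_flat_profile_has_no_peaks(self):
        nprof = normalized_from_values(np.full(50, 3.0))
        assert len(jc.detect_peaks(nprof, 0.5)) == 0

    def test_single_gaussian_found_at_truth_center(self, single_cluster_profile):
        real = single_cluster_profile
        nprof = normalized_from_values(real.channel1)
        peaks = jc.detect_peaks(nprof, 0.5)
        assert len(peaks) == 1
        # brute-force oracle: the global maximum sample
        assert abs(peaks.indices[0] - np.argmax(real.channel1)) <= 1
        assert abs(peaks.indices[0] - 100) <= 1

    def test_prominence_threshold_separates_two_gaussians(self):
        x = np.arange(200.0)
        small = 0.3 * np.exp(-((x - 60) ** 2) / (2 * 3.0**2))
        big = 0.9 * np.exp(-((x - 140) ** 2) / (2 * 3.0**2))
        nprof = normalized_from_values(1.0 + small + big)
        peaks = jc.detect_peaks(nprof, 0.5)
        assert len(peaks) == 1 and abs(peaks.indices[0] - 140) <= 1
        both = jc.detect_peaks(nprof, 0.25)
        assert len(both) == 2

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 500))
    def test_count_non_increasing_in_amplitude_setting(self, seed):
        truth = synthgen.random_profile_truth(seed, n_clusters=4, noise_sd=20.0)
        real = synthgen.gen_junction_profile(truth)
        nprof = normalized_from_values(real.channel1)
        counts = [len(jc.detect_peaks(nprof, f)) for f in (0.1, 0.25, 0.5, 0.75, 0.9)]
        assert counts == sorted(counts, reverse=True)

    def test_all_clusters_found_when_above_threshold(self):
        truth = synthgen.random_profile_truth(
            11, n_clusters=5, amplitude_range=(300.0, 400.0), baseline=100.0,
            noise_sd=0.0, length_px=300, min_separation_px=40,
        )
        real = synthgen.gen_junction_profile(truth)
        nprof = normalized_from_values(real.channel1)
        peaks = jc.detect_peaks(nprof, 0.5)
        assert len(peaks) == 5
        matched = np.abs(
            peaks.indices[:, None] - truth.cluster_centers_px[None, :]
        ).min(axis=1)
        assert np.all(matched <= 1)


class TestPeakDensity:
    def test_examples(self):
        five = jc.PeakSet(np.arange(5), np.ones(5), 0.5)
        none = jc.PeakSet(np.array([], dtype=int), np.array([]), 0.5)
        assert jc.peak_density(five, 10.0) == 0.5
        assert jc.peak_density(none, 10.0) == 0.0

    def test_zero_length_rejected(self):
        none = jc.PeakSet(np.array([], dtype=int), np.array([]), 0.5)
        with pytest.raises(ValueError):
            jc.peak_density(none, 0.0)

    def test_generative_count_recovered(self):
        truth = synthgen.random_profile_truth(
            5, n_clusters=4, amplitude_range=(300.0, 400.0), noise_sd=0.0,
            length_px=250, min_separation_px=40,
        )
        real = synthgen.gen_junction_profile(truth)
        nprof = normalized_from_values(real.channel1, truth.pixel_size_nm)
        peaks = jc.detect_peaks(nprof, 0.5)
        assert jc.peak_density(peaks, nprof.length_um) == pytest.approx(
            4 / nprof.length_um
        )


def peak_set(indices):
    indices = np.asarray(indices, dtype=int)
    return jc.PeakSet(indices, np.ones(len(indices)), 0.5)


class TestOverlapFraction:
    def test_identical_sets_give_one(self):
        p = peak_set([10, 40, 90])
        assert jc.overlap_fraction(p, p) == 1.0

    def test_offset_beyond_window_gives_zero(self):
        assert jc.overlap_fraction(peak_set([10]), peak_set([14]), 3) == 0.0

    def test_offset_exactly_window_is_inclusive(self):
        assert jc.overlap_fraction(peak_set([10]), peak_set([13]), 3) == 1.0

    def test_zero_reference_peaks_not_applicable(self):
        assert jc.overlap_fraction(peak_set([]), peak_set([5])) is None

    def test_one_to_many_matching(self):
        # one partner peak satisfies two reference peaks
        assert jc.overlap_fraction(peak_set([10, 13]), peak_set([11]), 3) == 1.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            ref = np.unique(rng.integers(0, 100, 6))
            par = np.unique(rng.integers(0, 100, 6))
            got = jc.overlap_fraction(peak_set(ref), peak_set(par), 3)
            expect = np.mean([any(abs(r - p) <= 3 for p in par) for r in ref])
            assert got == pytest.approx(expect)

    def test_cooccurrence_probability_recovered(self):
        # mean overlap over many seeded two-channel profiles estimates p
        for p_true in (0.0, 1.0):
            fracs = []
            for seed in range(60):
                truth = synthgen.random_profile_truth(
                    seed + int(p_true) * 1000, n_clusters=4, co_occurrence_p=p_true,
                    amplitude_range=(300.0, 400.0), noise_sd=0.0, jitter_sd_px=1.0,
                    length_px=250, min_separation_px=40,
                )
                real = synthgen.gen_junction_profile(truth)
                n1 = normalized_from_values(real.channel1)
                n2 = normalized_from_values(real.channel2)
                frac = jc.overlap_fraction(
                    jc.detect_peaks(n1, 0.5), jc.detect_peaks(n2, 0.5), 3
                )
                if frac is not None:
                    fracs.append(frac)
            assert abs(np.mean(fracs) - p_true) < 0.05


class TestProfileCorrelation:
    def test_identical_profiles_give_one(self):
        rng = np.random.default_rng(0)
        n = normalized_from_values(rng.uniform(1, 5, 60))
        assert jc.profile_correlation(n, n) == pytest.approx(1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        raw = rng.uniform(1, 5, 60)
        a = normalized_from_values(raw)
        b = normalized_from_values(3.0 * raw + 2.0)
        assert jc.profile_correlation(a, b) == pytest.approx(1.0)

    def test_independent_noise_uncorrelated(self):
        rng = np.random.default_rng(42)
        a = normalized_from_values(rng.uniform(1, 5, 500))
        b = normalized_from_values(rng.uniform(1, 5, 500))
        assert jc.profile_correlation(a, b) < 0.05

    def test_constant_profile_not_applicable(self):
        rng = np.random.default_rng(3)
        a = normalized_from_values(np.full(50, 4.0))
        b = normalized_from_values(rng.uniform(1, 5, 50))
        assert jc.profile_correlation(a, b) is None


class TestClusterFwhm:
    def test_closed_form_sigma_100nm(self):
        # sigma 100 nm at 50 nm/px -> FWHM 2*sqrt(2 ln 2)*100 = 235.48 nm
        x = np.arange(200.0)
        y = 1.0 + 2.0 * np.exp(-((x - 100) ** 2) / (2 * 2.0**2))
        nprof = normalized_from_values(y, pixel_size_nm=50.0)
        shape = jc.cluster_fwhm(nprof, 100, fit_window_px=10)
        assert shape.converged
        assert shape.fwhm_nm == pytest.approx(FWHM_PER_SIGMA * 100.0, rel=1e-6)
        assert shape.fwhm_nm == pytest.approx(235.48, abs=0.01)
        assert shape.fwhm_nm == pytest.approx(FWHM_PER_SIGMA * shape.sigma_nm)

    @pytest.mark.parametrize("fwhm_nm,length", [(250.0, 200), (600.0, 400)])
    def test_analytic_fwhm_recovered_within_one_percent(self, fwhm_nm, length):
        truth = synthgen.ProfileTruth(
            length_px=length, pixel_size_nm=50.0,
            cluster_centers_px=[length / 2.0], cluster_fwhms_nm=[fwhm_nm],
            cluster_amplitudes=[2.0], baseline=1.0, noise_sd=0.0, seed=0,
        )
        real = synthgen.gen_junction_profile(truth)
        nprof = normalized_from_values(real.channel1, 50.0)
        peaks = jc.detect_peaks(nprof, 0.5)
        shape = jc.cluster_fwhm(nprof, int(peaks.indices[0]), fit_window_px=15)
        assert abs(shape.fwhm_nm - fwhm_nm) / fwhm_nm < 0.01

    def test_exact_on_noiseless_gaussians_sigma_ge_1p5px(self):
        for sigma_px in (1.5, 2.5, 4.0):
            x = np.arange(200.0)
            y = 1.0 + 2.0 * np.exp(-((x - 100) ** 2) / (2 * sigma_px**2))
            nprof = normalized_from_values(y, pixel_size_nm=100.0)
            shape = jc.cluster_fwhm(nprof, 100, fit_window_px=12)
            expect = FWHM_PER_SIGMA * sigma_px * 100.0
            assert abs(shape.fwhm_nm - expect) / expect < 0.005

    def test_noisy_ensemble_mean_within_three_percent(self):
        rng = np.random.default_rng(0)
        sigma_px = 3.0
        expect = FWHM_PER_SIGMA * sigma_px * 100.0
        x = np.arange(200.0)
        clean = 1.0 + 2.0 * np.exp(-((x - 100) ** 2) / (2 * sigma_px**2))
        fwhms = []
        for _ in range(100):
            noisy = clean + rng.normal(0, 0.05 * 2.0, clean.shape)
            nprof = normalized_from_values(np.clip(noisy, 0.01, None))
            shape = jc.cluster_fwhm(nprof, int(np.argmax(noisy)), fit_window_px=12)
            if shape.converged:
                fwhms.append(shape.fwhm_nm)
        assert abs(np.mean(fwhms) - expect) / expect < 0.03

    def test_window_must_contain_peak_with_enough_samples(self):
        nprof = normalized_from_values(np.random.default_rng(0).uniform(1, 2, 50))
        with pytest.raises(ValueError, match="window"):
            jc.cluster_fwhm(nprof, 49, fit_window_px=1)
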