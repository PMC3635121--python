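"""Profile processing: strip, background, registration, integration, scaling."""
import numpy as np
import pytest

from blastovar import (
    IntegratedProfile,
    Profile,
    extract_strip,
    fit_quadratic_spline,
    generate_cohort,
    half_max_boundaries,
    integrate,
    register,
    remove_background,
    scale_to_reference,
    smooth_gaussian,
)
from blastovar.exceptions import (
    DegenerateScalingError,
    EmptyProfileError,
    InvalidArgumentError,
    MissingChannelError,
)

from conftest import gaussian_profile, make_record, noise_free


class TestExtractStrip:
    def test_all_nuclei_on_midline_retained(self):
        rec = make_record(np.arange(30.0), np.full(30, 50.0), {"eve": np.arange(30.0)})
        prof = extract_strip(rec, "eve", 0.10)
        assert prof.n == 30

    def test_band_membership(self):
        rec = make_record(
            [10.0, 20.0, 30.0], [10.0, 50.0, 90.0], {"eve": [1.0, 2.0, 3.0]}
        )
        prof = extract_strip(rec, "eve", 0.10)
        assert prof.n == 1
        assert prof.intensity[0] == 2.0

    def test_uniform_dv_density_retention(self):
        """A 10% strip keeps ~10% of uniformly placed nuclei (binomial bounds)."""
        rng = np.random.default_rng(0)
        n = 1000
        rec = make_record(np.sort(rng.uniform(0, 100, n)), rng.uniform(0, 100, n),
                          {"eve": np.zeros(n)})
        prof = extract_strip(rec, "eve", 0.10)
        half = 1.96 * np.sqrt(n * 0.1 * 0.9)
        assert 100 - half <= prof.n <= 100 + half

    def test_positions_strictly_increasing_with_duplicates(self):
        rec = make_record([5.0, 5.0, 5.0, 7.0], [50.0] * 4, {"eve": [1.0, 2.0, 3.0, 4.0]})
        prof = extract_strip(rec, "eve", 0.10)
        assert np.all(np.diff(prof.x) > 0)

    def test_errors(self):
        rec = make_record([10.0], [50.0], {"eve": [1.0]})
        with pytest.raises(MissingChannelError):
            extract_strip(rec, "hb", 0.10)
        rec2 = make_record([10.0], [5.0], {"eve": [1.0]})
        with pytest.raises(EmptyProfileError):
            extract_strip(rec2, "eve", 0.10)


class TestRemoveBackground:
    def test_constant_baseline_removed(self):
        """Gaussian + constant 10, degree 0: recovers the pure signal off-peak."""
        prof = gaussian_profile(center=50.0, amplitude=100.0, sigma=3.0, baseline=10.0)
        pure = gaussian_profile(center=50.0, amplitude=100.0, sigma=3.0)
        cleaned = remove_background(prof, quantile=0.1, poly_degree=0)
        off_peak = np.abs(prof.x - 50.0) > 10.0
        assert np.max(np.abs(cleaned.intensity[off_peak] - pure.intensity[off_peak])) < 1.0

    def test_all_zero_profile(self):
        prof = Profile("e", "eve", "t1", np.arange(100.0), np.zeros(100))
        cleaned = remove_background(prof)
        np.testing.assert_array_equal(cleaned.intensity, 0.0)

    def test_quadratic_baseline_recovered(self):
        """Signal + 0.002*(x-50)^2 baseline, degree 2: error < 5% of amplitude."""
        x = np.arange(0.0, 100.0, 0.2)
        signal = 100.0 * np.exp(-((x - 50.0) ** 2) / (2 * 9.0))
        baseline = 5.0 + 0.002 * (x - 50.0) ** 2
        prof = Profile("e", "eve", "t1", x, signal + baseline)
        cleaned = remove_background(prof, quantile=0.1, poly_degree=2)
        assert np.max(np.abs(cleaned.intensity - signal)) < 5.0

    def test_offset_invariance(self):
        rng = np.random.default_rng(9)
        prof = gaussian_profile(center=40.0, baseline=0.0)
        noisy = Profile("e", "eve", "t8", prof.x, prof.intensity + rng.normal(3, 1, prof.n))
        shifted = Profile("e", "eve", "t8", noisy.x, noisy.intensity + 25.0)
        a = remove_background(noisy, poly_degree=1)
        b = remove_background(shifted, poly_degree=1)
        np.testing.assert_allclose(a.intensity, b.intensity, atol=1e-6)

    def test_idempotent_within_one_unit(self):
        prof = gaussian_profile(center=50.0, amplitude=150.0, sigma=4.0, baseline=12.0)
        once = remove_background(prof)
        twice = remove_background(once)
        assert np.max(np.abs(twice.intensity - once.intensity)) < 1.0

    def test_invalid_arguments(self):
        prof = gaussian_profile(center=50.0)
        with pytest.raises(InvalidArgumentError):
            remove_background(prof, quantile=0.7)
        with pytest.raises(InvalidArgumentError):
            remove_background(prof, poly_degree=3)


class TestRegister:
    def _identical_cohort(self, m=6):
        return [
            gaussian_profile(center=50.0, embryo_id=f"e{i}") for i in range(m)
        ]

    def test_identical_profiles_give_identity_maps(self):
        profiles, maps = register(self._identical_cohort())
        for m in maps:
            assert abs(m.a - 1.0) < 1e-3
            assert abs(m.b) < 1e-2

    def test_translated_profile_recovers_inverse_offset(self):
        cohort = self._identical_cohort(50)
        cohort[0] = gaussian_profile(center=52.0, embryo_id="e0")
        _, maps = register(cohort)
        assert maps[0].b == pytest.approx(-2.0, abs=0.1)

    def test_registration_reduces_positional_scatter(self, wt_preset, eve_config):
        """On a jittered cohort, post-registration peak SD drops below raw SD."""
        recs, _ = generate_cohort(wt_preset, {"t8": 25}, seed=31)
        raw = [remove_background(extract_strip(r, "eve")) for r in recs]

        def stripe3_peak_sd(profiles):
            peaks = []
            for p in profiles:
                spl = fit_quadratic_spline(p)
                grid = np.arange(43.0, 51.0, 0.01)
                peaks.append(grid[np.argmax(spl(grid))])
            return np.std(peaks, ddof=1)

        registered, _ = register(raw)
        assert stripe3_peak_sd(registered) < stripe3_peak_sd(raw)

    def test_affine_map_preserves_rank_order(self):
        cohort = self._identical_cohort(4)
        registered, maps = register(cohort)
        for p, m in zip(registered, maps):
            assert m.a > 0
            assert np.all(np.diff(p.x) > 0)

    def test_needs_two_profiles(self):
        with pytest.raises(InvalidArgumentError):
            register(self._identical_cohort(1))


class TestIntegrate:
    def test_constant_profile(self):
        x = np.arange(100.0) + 0.5
        prof = Profile("e", "eve", "t1", x, np.full(100, 42.0), "wildtype")
        ip = integrate([prof])
        np.testing.assert_allclose(ip.values, 42.0)

    def test_mean_of_two(self):
        x = np.arange(100.0) + 0.5
        a = Profile("a", "eve", "t1", x, np.full(100, 10.0), "wildtype")
        b = Profile("b", "eve", "t1", x, np.full(100, 30.0), "wildtype")
        np.testing.assert_allclose(integrate([a, b]).values, 20.0)

    def test_matches_group_by_bin_oracle(self):
        """Binwise equality with an independently coded group-by-then-mean."""
        rng = np.random.default_rng(2)
        profiles = []
        for i in range(5):
            x = np.sort(rng.uniform(0, 100, 300))
            x = x[np.concatenate([[True], np.diff(x) > 0])]
            profiles.append(
                Profile(f"e{i}", "eve", "t1", x, rng.uniform(0, 255, x.size), "wildtype")
            )
        ip = integrate(profiles)
        allx = np.concatenate([p.x for p in profiles])
        ally = np.concatenate([p.intensity for p in profiles])
        for b in range(100):
            mask = (allx >= b) & (allx < b + 1)
            if mask.any():
                assert ip.values[b] == pytest.approx(ally[mask].mean(), abs=1e-9)

    def test_empty_bins_interpolated(self):
        prof = Profile("e", "eve", "t1", np.array([10.5, 12.5]), np.array([10.0, 30.0]), "wt")
        ip = integrate([prof])
        assert ip.values[11] == pytest.approx(20.0)

    def test_jitter_free_cohort_reproduces_single_embryo(self, wt_preset, eve_config):
        """Averaging a noise-only cohort converges on the deterministic profile."""
        import dataclasses

        from blastovar.synthetic import BackgroundSpec

        quiet = noise_free(wt_preset)
        noisy = dataclasses.replace(
            quiet, background=BackgroundSpec(8.0, 0.001, noise_sd=3.0)
        )
        n = 30
        recs, _ = generate_cohort(noisy, {"t8": n}, seed=4)
        ref_rec, _ = generate_cohort(quiet, {"t8": 1}, seed=0)
        cohort_ip = integrate([extract_strip(r, "eve") for r in recs])
        ref_ip = integrate([extract_strip(ref_rec[0], "eve")])
        err = cohort_ip.values - ref_ip.values
        assert np.abs(err).mean() < 3.0 / np.sqrt(n) * 3  # 3x the SE of the bin mean


class TestSmoothGaussian:
    def _ip(self, values):
        return IntegratedProfile("wt", "eve", "t1", np.asarray(values, float), 1)

    def test_sigma_zero_is_identity(self):
        ip = self._ip(np.random.default_rng(0).uniform(0, 255, 100))
        np.testing.assert_array_equal(smooth_gaussian(ip, 0.0).values, ip.values)

    def test_delta_smooths_symmetrically(self):
        values = np.zeros(100)
        values[40] = 100.0
        sm = smooth_gaussian(self._ip(values), 1.0).values
        np.testing.assert_allclose(sm[41:51], sm[39:29:-1], atol=1e-12)

    def test_matches_dense_convolution_oracle(self):
        """Equality with an explicit reflected-kernel matrix convolution."""
        rng = np.random.default_rng(7)
        values = rng.uniform(0, 255, 100)
        sigma = 2.0
        radius = int(4 * sigma + 0.5)
        k = np.exp(-np.arange(-radius, radius + 1) ** 2 / (2 * sigma**2))
        k /= k.sum()
        padded = np.concatenate([values[radius - 1 :: -1], values, values[: -radius - 1 : -1]])
        oracle = np.convolve(padded, k, mode="valid")
        sm = smooth_gaussian(self._ip(values), sigma).values
        np.testing.assert_allclose(sm, oracle, atol=1e-9)

    def test_total_sum_preserved(self):
        values = np.random.default_rng(1).uniform(0, 255, 100)
        sm = smooth_gaussian(self._ip(values), 1.0).values
        assert abs(sm.sum() - values.sum()) / values.sum() < 0.005


class TestScaleToReference:
    def _ip(self, values, genotype="tll"):
        return IntegratedProfile(genotype, "eve", "t8", np.asarray(values, float), 1)

    def test_exact_proportionality(self):
        ref = self._ip(np.linspace(0, 200, 100), "wildtype")
        target = self._ip(ref.values * 0.5)
        scaled, factor = scale_to_reference(target, ref)
        assert factor == pytest.approx(2.0, abs=1e-9)
        np.testing.assert_allclose(scaled.values, ref.values, atol=1e-9)

    def test_identity(self):
        ref = self._ip(np.linspace(0, 200, 100), "wildtype")
        _, factor = scale_to_reference(self._ip(ref.values), ref)
        assert factor == pytest.approx(1.0)

    def test_noisy_proportional_pair(self):
        rng = np.random.default_rng(3)
        base = 100.0 * np.exp(-((np.arange(100.0) - 50) ** 2) / 200.0)
        ref = self._ip(base * 1.7 * (1 + rng.normal(0, 0.05, 100)), "wildtype")
        target = self._ip(base * (1 + rng.normal(0, 0.05, 100)))
        _, factor = scale_to_reference(target, ref)
        assert factor == pytest.approx(1.7, abs=0.1)

    def test_degenerate_target(self):
        ref = self._ip(np.linspace(0, 200, 100), "wildtype")
        with pytest.raises(DegenerateScalingError):
            scale_to_reference(self._ip(np.zeros(100)), ref)

    def test_scaling_leaves_boundary_positions_unchanged(self):
        """Positional features are invariant under positive intensity scaling."""
        prof = gaussian_profile(center=60.0, amplitude=120.0, sigma=3.0)
        scaled = Profile("e", "eve", "t8", prof.x, prof.intensity * 3.7)
        for p in (prof, scaled):
            spl = fit_quadratic_spline(p, smoothing=0.0)
            peak_grid = np.arange(55.0, 65.0, 0.01)
            peak = peak_grid[np.argmax(spl(peak_grid))]
            ant, post, _ = half_max_boundaries(spl, peak, float(spl(peak)), (40.0, 80.0))
            if p is prof:
                first = (ant, post)
        assert abs(first[0] - ant) < 1e-6
        assert abs(first[1] - post) < 1e-6
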