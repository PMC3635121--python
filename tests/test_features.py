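"""Spline fitting, peak/boundary extraction, shifts, stripe-7 classification."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from blastovar import (
    Profile,
    classify_stripe7,
    compute_shift,
    domain_width,
    extract_domain_features,
    find_domain_peaks,
    fit_quadratic_spline,
    half_max_boundaries,
    total_expression_extent,
    windows_from_preset,
)
from blastovar.containers import DomainFeatures
from blastovar.exceptions import (
    DegenerateFitError,
    InsufficientPeaksError,
    InvalidArgumentError,
    UnclassifiableError,
)
from blastovar.features import NO_CROSSING

from conftest import gaussian_profile

HALF_W = math.sqrt(2.0 * math.log(2.0))


def _multi_gaussian(x, components):
    y = np.zeros_like(x)
    for amp, center, sigma in components:
        y = y + amp * np.exp(-((x - center) ** 2) / (2 * sigma**2))
    return y


class TestSplineFit:
    def test_reproduces_quadratic_exactly(self):
        x = np.arange(0.0, 100.0, 1.0)
        y = (x - 50.0) ** 2
        spl = fit_quadratic_spline((x, y), smoothing=0.0)
        mid = x[:-1] + 0.5
        np.testing.assert_allclose(spl(mid), (mid - 50.0) ** 2, atol=1e-8)

    def test_constant_profile(self):
        x = np.arange(0.0, 100.0, 1.0)
        spl = fit_quadratic_spline((x, np.full(100, 7.0)))
        np.testing.assert_allclose(spl(np.linspace(0, 99, 500)), 7.0, atol=1e-9)

    def test_noisy_gaussian_recovered(self):
        """Default smoothing keeps the fit within 2 units RMS of the truth."""
        rng = np.random.default_rng(0)
        x = np.arange(0.0, 100.0 + 1e-9, 0.25)
        truth = 100.0 * np.exp(-((x - 50.0) ** 2) / (2 * 16.0))
        spl = fit_quadratic_spline((x, truth + rng.normal(0, 5, x.size)))
        rms = np.sqrt(np.mean((spl(x) - truth) ** 2))
        assert rms < 2.0

    def test_too_few_samples(self):
        with pytest.raises(DegenerateFitError):
            fit_quadratic_spline((np.arange(4.0), np.arange(4.0)))

    def test_fixed_knot_path(self):
        x = np.arange(0.0, 100.0, 0.5)
        y = _multi_gaussian(x, [(100.0, 50.0, 4.0)])
        spl = fit_quadratic_spline((x, y), knot_spacing=1.0)
        assert np.max(np.abs(spl(x) - y)) < 0.5


class TestFindDomainPeaks:
    def test_two_gaussians(self):
        x = np.arange(0.0, 100.0, 0.1)
        y = _multi_gaussian(x, [(100.0, 40.0, 3.0), (80.0, 60.0, 3.0)])
        spl = fit_quadratic_spline((x, y), smoothing=0.0)
        calls = find_domain_peaks(spl, [("a", 30.0, 50.0), ("b", 50.0, 70.0)])
        assert calls[0].position == pytest.approx(40.0, abs=0.01)
        assert calls[1].position == pytest.approx(60.0, abs=0.01)

    def test_flat_zero_profile_all_absent(self):
        x = np.arange(0.0, 100.0, 0.5)
        spl = fit_quadratic_spline((x, np.zeros_like(x)))
        calls = find_domain_peaks(spl, [("a", 10.0, 40.0), ("b", 60.0, 90.0)])
        assert not any(c.present for c in calls)

    def test_matches_dense_grid_argmax_oracle(self):
        """Refined peaks agree with brute-force argmax on a 1e-3 grid."""
        rng = np.random.default_rng(5)
        for _ in range(50):
            center = rng.uniform(30.0, 70.0)
            sigma = rng.uniform(1.5, 6.0)
            x = np.arange(0.0, 100.0, 0.25)
            y = _multi_gaussian(x, [(rng.uniform(50, 200), center, sigma)])
            spl = fit_quadratic_spline((x, y), smoothing=0.0)
            dense = np.arange(20.0, 80.0, 0.001)
            oracle = dense[np.argmax(spl(dense))]
            call = find_domain_peaks(spl, [("d", 20.0, 80.0)])[0]
            assert call.present
            assert call.position == pytest.approx(oracle, abs=0.02)

    def test_sub_threshold_peak_reported_absent(self):
        x = np.arange(0.0, 100.0, 0.2)
        y = _multi_gaussian(x, [(100.0, 30.0, 3.0), (5.0, 70.0, 3.0)])
        spl = fit_quadratic_spline((x, y), smoothing=0.0)
        calls = find_domain_peaks(spl, [("big", 20.0, 40.0), ("small", 60.0, 80.0)],
                                  min_rel_amplitude=0.1)
        assert calls[0].present and not calls[1].present


class TestHalfMaxBoundaries:
    def test_gaussian_closed_form(self):
        prof = gaussian_profile(center=50.0, amplitude=100.0, sigma=4.0)
        spl = fit_quadratic_spline(prof, smoothing=0.0)
        ant, post, reasons = half_max_boundaries(spl, 50.0, 100.0, (30.0, 70.0))
        assert ant == pytest.approx(50.0 - 4.0 * HALF_W, abs=0.01)
        assert post == pytest.approx(50.0 + 4.0 * HALF_W, abs=0.01)
        assert not reasons

    def test_triangle_linear_flanks(self):
        x = np.arange(0.0, 100.0, 0.1)
        y = np.clip(100.0 * (1.0 - np.abs(x - 50.0) / 10.0), 0.0, None)
        spl = fit_quadratic_spline((x, y), smoothing=0.0)
        ant, post, _ = half_max_boundaries(spl, 50.0, 100.0, (35.0, 65.0))
        assert ant == pytest.approx(45.0, abs=0.05)
        assert post == pytest.approx(55.0, abs=0.05)

    def test_fused_domains_censored(self):
        """A valley that stays above half maximum censors the inner boundary."""
        x = np.arange(0.0, 100.0, 0.1)
        y = _multi_gaussian(x, [(100.0, 48.0, 5.0), (100.0, 58.0, 5.0)])
        spl = fit_quadratic_spline((x, y), smoothing=0.0)
        ant, post, reasons = half_max_boundaries(spl, 48.0, float(spl(48.0)), (30.0, 53.0))
        assert ant is not None
        assert post is None
        assert reasons["posterior"] == NO_CROSSING

    def test_invalid_peak_intensity(self):
        prof = gaussian_profile(center=50.0)
        spl = fit_quadratic_spline(prof, smoothing=0.0)
        with pytest.raises(InvalidArgumentError):
            half_max_boundaries(spl, 50.0, 0.0, (30.0, 70.0))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        sigma=st.floats(1.0, 6.0),
        center=st.floats(30.0, 70.0),
        amplitude=st.floats(20.0, 250.0),
    )
    def test_closed_form_property(self, sigma, center, amplitude):
        """Boundaries sit at center +- sigma*sqrt(2 ln 2) for any Gaussian."""
        prof = gaussian_profile(center=center, amplitude=amplitude, sigma=sigma)
        spl = fit_quadratic_spline(prof, smoothing=0.0)
        ant, post, _ = half_max_boundaries(
            spl, center, amplitude, (center - 5 * sigma, center + 5 * sigma)
        )
        assert ant == pytest.approx(center - sigma * HALF_W, abs=0.05)
        assert post == pytest.approx(center + sigma * HALF_W, abs=0.05)
        assert ant < center < post


class TestWidthShiftExtent:
    def test_width_subtraction_and_censoring(self):
        f = DomainFeatures("eve", "d", 50.0, 100.0, anterior=45.0, posterior=60.0)
        assert domain_width(f) == 15.0
        f2 = DomainFeatures("eve", "d", 50.0, 100.0, anterior=45.0, posterior=None)
        assert domain_width(f2) is None

    def test_gaussian_width_closed_form(self):
        prof = gaussian_profile(center=50.0, amplitude=100.0, sigma=4.0)
        spl = fit_quadratic_spline(prof, smoothing=0.0)
        ant, post, _ = half_max_boundaries(spl, 50.0, 100.0, (30.0, 70.0))
        assert post - ant == pytest.approx(2 * 4.0 * HALF_W, abs=0.01)

    def test_extent(self):
        assert total_expression_extent([30.0, 40.0, 77.0]) == pytest.approx(47.0)
        with pytest.raises(InsufficientPeaksError):
            total_expression_extent([42.0])

    def test_shift_sign_and_validation(self):
        early = DomainFeatures("eve", "s6", 88.0, 1.0, time_class="t3")
        late = DomainFeatures("eve", "s6", 83.66, 1.0, time_class="t8")
        assert compute_shift(early, late) == pytest.approx(4.34)
        same = DomainFeatures("eve", "s6", 88.0, 1.0, time_class="t3")
        assert compute_shift(same, DomainFeatures("eve", "s6", 88.0, 1.0, time_class="t8")) == 0.0
        with pytest.raises(InvalidArgumentError):
            compute_shift(late, early)  # wrong temporal order
        with pytest.raises(InvalidArgumentError):
            compute_shift(early, DomainFeatures("eve", "s7", 80.0, 1.0, time_class="t8"))


class TestClassifyStripe7:
    WINDOWS = [("eve_stripe_6", 60.0, 80.0), ("eve_stripe_7", 80.0, 97.0)]

    def _spline(self, amp7, center7=90.0):
        x = np.arange(0.0, 100.0, 0.1)
        comps = [(180.0, 70.0, 2.0)]
        if amp7 > 0:
            comps.append((amp7, center7, 2.0))
        return fit_quadratic_spline((x, _multi_gaussian(x, comps)), smoothing=0.0)

    def test_no_posterior_peak_is_six(self):
        cls = classify_stripe7(self._spline(0.0), self.WINDOWS)
        assert cls.pattern == "six"

    def test_strong_separated_peak_is_full(self):
        cls = classify_stripe7(self._spline(150.0), self.WINDOWS)
        assert cls.pattern == "full_seven"
        assert cls.valley_depth < 0.5

    def test_reduced_amplitude_is_partial(self):
        cls = classify_stripe7(self._spline(55.0), self.WINDOWS)
        assert cls.pattern == "partial_seven"

    def test_fused_stripe_is_partial(self):
        """A strong stripe 7 merged with stripe 6 (no inter-stripe dip) stays partial."""
        cls = classify_stripe7(self._spline(170.0, center7=74.0),
                               [("eve_stripe_6", 60.0, 72.0), ("eve_stripe_7", 72.0, 97.0)])
        assert cls.pattern == "partial_seven"
        assert cls.valley_depth == 1.0  # fused: no interior minimum between peaks

    def test_stripe6_absent_unclassifiable(self):
        x = np.arange(0.0, 100.0, 0.1)
        spl = fit_quadratic_spline((x, np.zeros_like(x)))
        with pytest.raises(UnclassifiableError):
            classify_stripe7(spl, self.WINDOWS)


class TestWindowsAndFeatures:
    def test_windows_ordered_and_disjoint(self, wt_preset):
        for tc in ("t1", "t4", "t8"):
            for gene, wins in windows_from_preset(wt_preset, tc).items():
                for (l1, lo1, hi1), (l2, lo2, hi2) in zip(wins, wins[1:]):
                    assert hi1 <= lo2 + 1e-9
                for _, lo, hi in wins:
                    assert 0.0 <= lo < hi <= 100.0

    def test_uncensored_features_are_ordered(self, wt_preset):
        """anterior < peak < posterior holds for every extracted domain."""
        x = np.arange(0.0, 100.0, 0.1)
        y = _multi_gaussian(
            x, [(d.amplitude, d.center_at("t8"), d.sigma) for d in wt_preset.domains_of("eve")]
        )
        spl = fit_quadratic_spline((x, y), smoothing=0.0)
        wins = windows_from_preset(wt_preset, "t8")["eve"]
        feats = extract_domain_features(spl, wins, "eve")
        assert len(feats) == 7
        for f in feats:
            if f.anterior is not None and f.posterior is not None:
                assert f.anterior < f.peak < f.posterior
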