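"""Power model, architecture spectra, causal-count inference, projections."""

import numpy as np
import pytest
from scipy.stats import chi2, gamma, ncx2

from liabarch.liability import design_from_prevalence
from liabarch.polygenicity import (ArchitectureSpectrum, PowerSettings,
                                   infer_num_causal, liability_to_observed_variance,
                                   make_spectrum, prob_zero_discoveries,
                                   project_discoveries, required_variance,
                                   spectrum_histogram, variant_power)

SETTINGS = PowerSettings(n=6387, p=1258 / 6387, K=0.005, alpha=5e-8)
INFER = PowerSettings(n=6387, p=1258 / 6387, K=0.005, alpha=1.9e-6)


class TestVariantPower:
    def test_printed_anchors(self):
        # 80% power at 0.46% of liability variance, 50% at 0.35%
        assert variant_power(0.0046, SETTINGS) == pytest.approx(0.80, abs=0.02)
        assert variant_power(0.0035, SETTINGS) == pytest.approx(0.50, abs=0.02)

    def test_matches_noncentral_chisquare(self):
        # the two-Phi closed form IS the noncentral chi2(1) tail
        c = chi2.isf(SETTINGS.alpha, 1)
        for vL in (1e-4, 1e-3, 0.0046, 0.02):
            ncp = SETTINGS.n * liability_to_observed_variance(vL, SETTINGS.design)
            assert variant_power(vL, SETTINGS) == pytest.approx(
                ncx2.sf(c, 1, ncp), abs=1e-10)

    def test_null_limit_is_alpha(self):
        s = PowerSettings(n=6387, p=0.2, K=0.005, alpha=1e-3)
        assert variant_power(1e-12, s) == pytest.approx(s.alpha, rel=1e-3)

    def test_strictly_increasing_in_v_and_n(self):
        vs = np.linspace(1e-4, 0.02, 40)
        pw = variant_power(vs, SETTINGS)
        assert np.all(np.diff(pw) > 0)
        ns = [2000, 6387, 20000, 100000]
        pw_n = [variant_power(0.003, PowerSettings(n=n, p=0.2, K=0.005, alpha=5e-8))
                for n in ns]
        assert np.all(np.diff(pw_n) > 0)

    def test_inversion(self):
        # required_variance recovers the printed 0.46% / 0.35% anchors
        assert 100 * required_variance(0.80, SETTINGS) == pytest.approx(0.46, abs=0.01)
        assert 100 * required_variance(0.50, SETTINGS) == pytest.approx(0.35, abs=0.01)
        v = required_variance(0.9, SETTINGS)
        assert variant_power(v, SETTINGS) == pytest.approx(0.9, abs=1e-9)


class TestSpectrum:
    def test_equal_split(self):
        spec = make_spectrum(0.26, 870, "equal")
        assert np.allclose(spec.v, 0.26 / 870)
        assert spec.v.sum() == pytest.approx(0.26, abs=1e-10)

    def test_uniform_two_variants(self):
        # mid-quantiles 0.25 and 0.75, rescaled to the total, descending
        spec = make_spectrum(0.2, 2, "uniform")
        assert spec.v == pytest.approx([0.15, 0.05], abs=1e-12)

    def test_gamma_quantile_ratio(self):
        m = 1000
        spec = make_spectrum(0.3, m, "chi2")
        assert spec.v.sum() == pytest.approx(0.3, abs=1e-10)
        expected = gamma.ppf((m - 0.5) / m, 0.5) / gamma.ppf(0.5 / m, 0.5)
        assert spec.v.max() / spec.v.min() == pytest.approx(expected, rel=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            make_spectrum(0.26, 0, "equal")
        with pytest.raises(ValueError):
            make_spectrum(1.2, 10, "equal")
        with pytest.raises(ValueError):
            make_spectrum(0.26, 10, "gaussian")


class TestZeroDiscoveries:
    def test_single_variant_complement(self):
        spec = make_spectrum(0.0046, 1, "equal")
        p0 = prob_zero_discoveries(spec, SETTINGS)
        assert p0 == pytest.approx(1.0 - variant_power(0.0046, SETTINGS), abs=1e-12)

    def test_matches_brute_force_product(self):
        spec = make_spectrum(0.26, 870, "equal")
        pw = variant_power(spec.v, INFER)
        assert prob_zero_discoveries(spec, INFER) == pytest.approx(
            np.prod(1.0 - pw), rel=1e-9)
        # the defining property of the point estimate: probability ~ 0.5
        assert prob_zero_discoveries(spec, INFER) == pytest.approx(0.5, abs=0.02)

    def test_powerless_limit(self):
        weak = PowerSettings(n=10, p=0.2, K=0.005, alpha=5e-8)
        assert prob_zero_discoveries(make_spectrum(0.01, 500, "chi2"), weak) > 0.9999


class TestCausalCountInference:
    # frozen from our own grid search; the printed counts are 870/420 (equal),
    # 1230/600 (uniform), 2160/1060 (exponential), 3390/1650 (chi2)
    @pytest.mark.parametrize("family,point,lower", [
        ("equal", 860, 420),
        ("uniform", 1220, 600),
        ("exponential", 2170, 1070),
        ("chi2", 3450, 1700),
    ])
    def test_point_and_lower_bound(self, family, point, lower):
        assert infer_num_causal(0.26, family, INFER, 0.5) == point
        assert infer_num_causal(0.26, family, INFER, 0.05) == lower

    def test_lower_bound_below_point(self):
        for family in ("equal", "uniform", "exponential", "chi2"):
            lo = infer_num_causal(0.26, family, INFER, 0.05)
            hi = infer_num_causal(0.26, family, INFER, 0.5)
            assert lo < hi

    def test_unreachable_target(self):
        with pytest.raises(RuntimeError):
            infer_num_causal(0.26, "equal", INFER, 0.999999, grid_cap=1000)


class TestProjections:
    def test_table_projection(self):
        # equal spectrum of 870 at n = 50 000: ~147 discoveries, ~4.4% variance
        spec = make_spectrum(0.26, 870, "equal")
        s = PowerSettings(n=50_000, p=1258 / 6387, K=0.005, alpha=5e-8)
        count, var = project_discoveries(spec, s)
        assert count == pytest.approx(141.6, abs=0.5)
        assert 100 * var == pytest.approx(4.23, abs=0.05)

    def test_no_sample_no_power(self):
        spec = make_spectrum(0.26, 870, "equal")
        s = PowerSettings(n=2, p=1258 / 6387, K=0.005, alpha=5e-8)
        count, var = project_discoveries(spec, s)
        assert count < 1e-4 and var < 1e-6

    def test_monte_carlo_bernoulli_sum(self):
        spec = make_spectrum(0.26, 200, "exponential")
        s = PowerSettings(n=30_000, p=0.2, K=0.005, alpha=5e-8)
        count, _ = project_discoveries(spec, s)
        pw = variant_power(spec.v, s)
        rng = np.random.default_rng(42)
        reps = 10_000
        draws = rng.random((reps, spec.m)) < pw
        mc = draws.sum(axis=1)
        se = mc.std(ddof=1) / np.sqrt(reps)
        assert abs(mc.mean() - count) < 3 * se + 1e-9


class TestHistogram:
    def test_equal_spectrum_single_bin(self):
        spec = make_spectrum(0.26, 870, "equal")
        v = 0.26 / 870
        counts, shares = spectrum_histogram(spec, [0, v * 0.9, v * 1.1, 1])
        assert list(counts) == [0, 870, 0]
        assert shares.sum() == pytest.approx(1.0, abs=1e-10)

    def test_shares_conserved(self):
        spec = make_spectrum(0.3, 500, "chi2")
        _, shares = spectrum_histogram(spec, np.linspace(0, 0.1, 50))
        assert shares.sum() == pytest.approx(1.0, abs=1e-10)

    def test_small_effect_majority(self):
        # at the gamma-family point estimate most heritability sits with
        # variants explaining < 0.04% of liability each
        m = infer_num_causal(0.26, "chi2", INFER, 0.5)
        spec = make_spectrum(0.26, m, "chi2")
        _, shares = spectrum_histogram(spec, [0.0, 0.0004, 1.0])
        assert shares[0] > 0.5

    def test_bad_edges(self):
        spec = make_spectrum(0.26, 10, "equal")
        with pytest.raises(ValueError):
            spectrum_histogram(spec, [0.1, 0.1, 0.2])
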