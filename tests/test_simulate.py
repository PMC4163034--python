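"""Synthetic genotype/phenotype generators."""

import numpy as np
import pytest
from scipy.stats import chisquare, norm

from liabarch.liability import design_from_prevalence
from liabarch.simulate import (ascertain_case_control, inject_genotype_errors,
                               simulate_ascertained_cohort, simulate_correlated_traits,
                               simulate_genotypes, simulate_liability_trait)


class TestGenotypes:
    def test_fixed_frequency_moment(self):
        G = simulate_genotypes(1000, 200, (0.5, 0.5), seed=0)
        assert np.all(np.abs(G.dosages.mean(axis=0) - 1.0) < 0.1)

    def test_deterministic_under_seed(self):
        a = simulate_genotypes(200, 50, seed=7)
        b = simulate_genotypes(200, 50, seed=7)
        assert np.array_equal(a.dosages, b.dosages)
        assert np.array_equal(a.allele_freq, b.allele_freq)
        c = simulate_genotypes(200, 50, seed=8)
        assert not np.array_equal(a.dosages, c.dosages)

    def test_hardy_weinberg_proportions(self):
        G = simulate_genotypes(2000, 100, (0.1, 0.4), seed=3)
        ok = 0
        for j in range(100):
            f = G.allele_freq[j]
            counts = np.bincount(G.dosages[:, j], minlength=3)
            expected = 2000 * np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2])
            if chisquare(counts, expected).pvalue > 0.001:
                ok += 1
        assert ok >= 95

    def test_mean_tracks_frequency(self):
        G = simulate_genotypes(5000, 50, (0.05, 0.45), seed=1)
        assert np.allclose(G.dosages.mean(axis=0), 2 * G.allele_freq, atol=0.05)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            simulate_genotypes(0, 10)
        with pytest.raises(ValueError):
            simulate_genotypes(10, 10, (0.0, 0.5))


class TestLiabilityTrait:
    def test_null_trait_is_pure_noise(self):
        G = simulate_genotypes(3000, 50, seed=2)
        model, liab = simulate_liability_trait(G, 20, 0.0, seed=2)
        assert np.all(model.beta == 0)
        assert liab.var() == pytest.approx(1.0, abs=0.08)

    def test_equal_family_exact_split(self):
        G = simulate_genotypes(200, 300, seed=4)
        model, _ = simulate_liability_trait(G, 100, 0.26, "equal", seed=4)
        assert np.allclose(model.beta**2, 0.0026)

    def test_variance_bookkeeping_chi2_family(self):
        # unit liability variance holds across seeds for a skewed spectrum
        variances = []
        for s in range(20):
            G = simulate_genotypes(1500, 600, seed=100 + s)
            model, liab = simulate_liability_trait(G, 500, 0.3, "chi2", seed=100 + s)
            assert np.sum(model.beta**2) == pytest.approx(0.3, abs=1e-12)
            variances.append(liab.var())
        assert np.mean(variances) == pytest.approx(1.0, abs=0.05)

    def test_h2_validation(self):
        G = simulate_genotypes(50, 20, seed=0)
        with pytest.raises(ValueError):
            simulate_liability_trait(G, 10, 1.0)
        with pytest.raises(ValueError):
            simulate_liability_trait(G, 30, 0.5)


class TestAscertainment:
    def test_symmetric_threshold_truncation(self):
        rng = np.random.default_rng(0)
        liab = rng.standard_normal(20_000)
        d = design_from_prevalence(0.5, 0.5)
        idx, y = ascertain_case_control(liab, d, 2000, 2000, seed=0)
        assert liab[idx[y == 1]].mean() == pytest.approx(0.798, abs=0.05)
        assert y.mean() == 0.5

    def test_rare_disease_truncated_moments(self):
        # cases sit at the mean of the upper 0.5% tail; controls just below 0
        G, y, model, liab = simulate_ascertained_cohort(
            n_case=400, n_ctrl=400, K=0.005, m=50, n_causal=20, h2=0.3, seed=5)
        d = design_from_prevalence(0.005, 0.5)
        assert liab[y == 1].mean() == pytest.approx(d.i, abs=0.08)
        assert liab[y == 0].mean() == pytest.approx(-d.z / (1 - d.K), abs=0.05)
        assert np.all(liab[y == 1] > d.T)
        assert np.all(liab[y == 0] <= d.T)

    def test_infeasible_request_raises(self):
        liab = np.full(100, -1.0)
        d = design_from_prevalence(0.2, 0.5)
        with pytest.raises(RuntimeError):
            ascertain_case_control(liab, d, 5, 5, seed=0)
        with pytest.raises(RuntimeError):
            simulate_ascertained_cohort(n_case=50, n_ctrl=50, K=1e-5, m=20,
                                        n_causal=5, h2=0.2, seed=0,
                                        batch_size=200, max_batches=2)

    def test_cohort_split_and_determinism(self):
        a = simulate_ascertained_cohort(n_case=50, n_ctrl=100, K=0.05, m=30,
                                        n_causal=10, h2=0.2, seed=9,
                                        control_cohorts=("ctrlA", "ctrlB"))
        b = simulate_ascertained_cohort(n_case=50, n_ctrl=100, K=0.05, m=30,
                                        n_causal=10, h2=0.2, seed=9,
                                        control_cohorts=("ctrlA", "ctrlB"))
        assert np.array_equal(a[0].dosages, b[0].dosages)
        labels = a[0].cohort_label
        assert (labels == "case").sum() == 50
        assert (labels == "ctrlA").sum() == 50
        assert (labels == "ctrlB").sum() == 50


class TestGenotypeErrors:
    def test_zero_rate_is_noop(self):
        G = simulate_genotypes(100, 40, seed=1, cohort_label="ctrlB")
        out = inject_genotype_errors(G, 0.0, "ctrlB", seed=1)
        assert np.array_equal(out.dosages, G.dosages)

    def test_only_named_cohort_touched(self):
        G, y, *_ = simulate_ascertained_cohort(
            n_case=50, n_ctrl=100, K=0.05, m=200, n_causal=20, h2=0.2, seed=3,
            control_cohorts=("ctrlA", "ctrlB"))
        out = inject_genotype_errors(G, 0.5, "ctrlB", seed=3, freq_shift=0.2)
        untouched = G.cohort_label != "ctrlB"
        assert np.array_equal(out.dosages[untouched], G.dosages[untouched])
        assert not np.array_equal(out.dosages[~untouched], G.dosages[~untouched])

    def test_full_replacement_regenerates_hwe(self):
        G = simulate_genotypes(3000, 50, (0.3, 0.3), seed=6, cohort_label="ctrlB")
        out = inject_genotype_errors(G, 1.0, "ctrlB", seed=6, freq_shift=0.0)
        assert np.allclose(out.dosages.mean(axis=0), 0.6, atol=0.06)
        assert not np.array_equal(out.dosages, G.dosages)

    def test_unknown_cohort(self):
        G = simulate_genotypes(10, 5, seed=0)
        with pytest.raises(KeyError):
            inject_genotype_errors(G, 0.1, "ctrlB")

    def test_errors_inflate_control_scan(self):
        # a pseudo case-control scan of clean cohort A vs errored cohort B
        # shows genomic inflation relative to the error-free scan
        from liabarch.reml import association_scan

        G, y, *_ = simulate_ascertained_cohort(
            n_case=10, n_ctrl=1000, K=0.05, m=2000, n_causal=50, h2=0.2, seed=11,
            control_cohorts=("ctrlA", "ctrlB"))
        ctrl = G.cohort_label != "case"
        b = (G.cohort_label[ctrl] == "ctrlB").astype(float)
        clean = association_scan(G.subset(rows=np.flatnonzero(ctrl)), b)
        Ge = inject_genotype_errors(G, 0.05, "ctrlB", seed=11, freq_shift=0.2)
        errored = association_scan(Ge.subset(rows=np.flatnonzero(ctrl)), b)
        assert clean.lambda_gc < 1.15
        assert errored.lambda_gc > clean.lambda_gc + 0.1


class TestCorrelatedTraits:
    def test_perfect_correlation_identical_effects(self):
        G = simulate_genotypes(200, 400, seed=8)
        m1, m2, l1, l2 = simulate_correlated_traits(G, 150, 0.4, 0.4, 1.0, seed=8)
        assert np.allclose(m1.beta, m2.beta)
        Z = G.standardized()[:, m1.causal_idx]
        assert np.allclose(Z @ m1.beta, Z @ m2.beta)

    def test_independent_effects(self):
        G = simulate_genotypes(50, 1200, seed=9)
        m1, m2, *_ = simulate_correlated_traits(G, 1000, 0.4, 0.4, 0.0, seed=9)
        r = np.corrcoef(m1.beta, m2.beta)[0, 1]
        assert abs(r) < 2 / np.sqrt(1000) + 0.02

    def test_intermediate_correlation(self):
        G = simulate_genotypes(50, 1200, seed=10)
        m1, m2, *_ = simulate_correlated_traits(G, 1000, 0.5, 0.3, 0.45, seed=10)
        r = np.corrcoef(m1.beta, m2.beta)[0, 1]
        assert r == pytest.approx(0.45, abs=0.06)
        assert np.sum(m1.beta**2) == pytest.approx(0.5, abs=1e-10)
        assert np.sum(m2.beta**2) == pytest.approx(0.3, abs=1e-10)

    def test_rho_out_of_range(self):
        G = simulate_genotypes(20, 30, seed=0)
        with pytest.raises(ValueError):
            simulate_correlated_traits(G, 10, 0.3, 0.3, 1.5, seed=0)
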