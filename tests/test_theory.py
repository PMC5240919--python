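import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from metapower import (
    Architecture,
    CGRStructure,
    ConfigurationError,
    DesignValidationError,
    StudyPanel,
    attenuation,
    clustered_design,
    detection_report,
    equal_design,
    meta_z_variance,
    pgs_r2,
    power_per_causal_snp,
    power_report,
)
from conftest import random_design


def brute_force_sigma2(panel, cgr, arch):
    """Independent oracle: explicit covariance of the per-study Z vector.

    Var(Z_c) = 1 + N_c h2_c / M, Cov(Z_c, Z_d) = sqrt(N_c N_d) rho_cd
    sqrt(h2_c h2_d) / M, combined with weights w_c = sqrt(N_c / N_T).
    """
    n, h2, m = panel.sizes, panel.heritabilities, arch.m_causal
    c = panel.n_studies
    cov = np.empty((c, c))
    for i in range(c):
        for j in range(c):
            if i == j:
                cov[i, j] = 1.0 + n[i] * h2[i] / m
            else:
                cov[i, j] = (
                    math.sqrt(n[i] * n[j]) * cgr.among[i, j] * math.sqrt(h2[i] * h2[j]) / m
                )
    w = np.sqrt(n / panel.n_total)
    return float(w @ cov @ w)


class TestMetaZVariance:
    def test_matches_bruteforce_covariance_oracle(self, rng):
        for _ in range(30):
            panel, cgr, arch = random_design(rng)
            s2 = meta_z_variance(panel, cgr, arch)
            assert s2 == pytest.approx(brute_force_sigma2(panel, cgr, arch), rel=1e-12)
            assert s2 >= 1.0

    def test_single_study_closed_form(self):
        panel = StudyPanel([250_000], [0.5])
        cgr = CGRStructure.constant(1, 1.0, 0.5, 0.5)
        arch = Architecture(100_000, 1_000)
        assert meta_z_variance(panel, cgr, arch) == pytest.approx(
            1 + 250_000 * 0.5 / 1_000, rel=1e-15
        )

    def test_no_heritability_gives_null_variance(self):
        panel = StudyPanel([10_000], [0.0])
        cgr = CGRStructure.constant(1, 1.0, 0.0, 0.0)
        assert meta_z_variance(panel, cgr, Architecture(1000, 100)) == 1.0

    def test_two_equal_studies_closed_form(self):
        # sigma^2 = 1 + (h2/M) N (1 + rho) for two equal studies
        n, h2, rho, m = 5_000.0, 0.4, 0.3, 500
        panel = StudyPanel([n, n], [h2, h2])
        cgr = CGRStructure.constant(2, rho, 0.5, 0.5)
        arch = Architecture(10_000, m)
        assert meta_z_variance(panel, cgr, arch) == pytest.approx(
            1 + (h2 / m) * n * (1 + rho), rel=1e-14
        )

    def test_two_cluster_design_value(self):
        # 100 studies of 2,500 in two clusters, within-CGR 1, across-CGR 0:
        # brute-force evaluation of the 100x100 covariance gives 63.5 exactly
        panel, cgr = clustered_design(250_000, 2, 50, 0.5, 1.0, 0.0, 0.5, 0.5)
        arch = Architecture(100_000, 1_000)
        s2 = meta_z_variance(panel, cgr, arch)
        assert s2 == pytest.approx(brute_force_sigma2(panel, cgr, arch), rel=1e-12)
        assert s2 == pytest.approx(63.5, abs=1e-9)

    def test_dimension_mismatch_raises(self, small_design):
        panel, _, arch = small_design
        with pytest.raises(ConfigurationError):
            meta_z_variance(panel, CGRStructure.constant(2, 0.5, 0.5, 0.5), arch)


class TestPowerPerCausalSnp:
    @pytest.mark.parametrize("alpha", [0.05, 5e-4, 5e-8])
    def test_null_variance_returns_alpha(self, alpha):
        assert power_per_causal_snp(1.0, alpha) == pytest.approx(alpha, rel=1e-12)

    def test_matches_monte_carlo_rejection_rate(self, rng):
        sigma2, alpha = 20.0, 5e-4
        t = Architecture(10, 1, alpha).threshold
        draws = rng.normal(0.0, math.sqrt(sigma2), size=1_000_000)
        emp = np.mean(np.abs(draws) > t)
        beta = power_per_causal_snp(sigma2, alpha)
        se = math.sqrt(beta * (1 - beta) / len(draws))
        assert abs(emp - beta) < 3 * se + 1e-12

    def test_monotone_in_variance(self):
        betas = [power_per_causal_snp(s2, 5e-8) for s2 in (1.0, 2.0, 10.0, 100.0)]
        assert all(b2 > b1 for b1, b2 in zip(betas, betas[1:]))

    def test_extreme_tail_does_not_underflow(self):
        # alpha around 1e-290 exercises the log-space tail; beta stays
        # positive and at least alpha
        beta = power_per_causal_snp(1.0, 1e-290)
        assert 0.0 < beta < 1e-280
        beta2 = power_per_causal_snp(1.5, 1e-290)
        assert beta2 > beta

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 2.0])
    def test_invalid_alpha_rejected(self, bad):
        with pytest.raises(DesignValidationError):
            power_per_causal_snp(2.0, bad)


class TestDetectionReport:
    @given(
        beta=st.floats(0.0, 1.0),
        m=st.integers(1, 10**6),
        extra=st.integers(0, 10**6),
    )
    def test_count_identities(self, beta, m, extra):
        arch = Architecture(m + extra, m, 5e-8)
        rep = detection_report(beta, arch)
        assert rep.expected_true_pos + rep.expected_false_neg == pytest.approx(
            m, rel=1e-9
        )
        assert rep.expected_false_pos + rep.expected_true_neg == pytest.approx(
            arch.s_total - m, rel=1e-9, abs=1e-9
        )
        assert rep.expected_hits == pytest.approx(
            rep.expected_true_pos + rep.expected_false_pos, rel=1e-12, abs=1e-300
        )
        assert 0.0 <= rep.p_any_true_pos <= 1.0
        assert rep.p_any_hit >= rep.p_any_true_pos - 1e-12

    def test_zero_power_degenerate_case(self):
        arch = Architecture(1000, 100, 5e-4)
        rep = detection_report(0.0, arch)
        assert rep.expected_hits == pytest.approx(5e-4 * 900)
        assert rep.expected_true_pos == 0.0
        assert rep.p_any_true_pos == 0.0

    def test_all_snps_causal(self):
        arch = Architecture(50, 50, 5e-8)
        rep = detection_report(0.5, arch)
        assert rep.expected_false_pos == 0.0
        assert rep.p_any_hit == pytest.approx(1 - 0.5**50, rel=1e-12)

    def test_vanishing_power_survives_large_m(self):
        # M = 1e6 with beta ~ 1e-300: log-space accumulation keeps the
        # any-true-positive probability at its first-order value beta*M
        arch = Architecture(2_000_000, 1_000_000, 5e-8)
        beta = 1e-300
        rep = detection_report(beta, arch)
        assert rep.p_any_true_pos == pytest.approx(beta * arch.m_causal, rel=1e-6)


class TestPGSR2:
    def test_single_study_closed_form(self):
        # R2 = rho^2 h2^2 / (S/N + h2) for one study with equal h2
        n, h2, rho, s = 250_000, 0.5, 0.5, 100_000
        panel, cgr = equal_design(n, 1, h2, 1.0, rho, h2)
        rep = pgs_r2(panel, cgr, Architecture(s, 1_000))
        assert rep.r2 == pytest.approx(rho**2 * h2**2 / (s / n + h2), rel=1e-14)
        assert rep.r2 == pytest.approx(rep.pgs_pheno_cov**2 / rep.pgs_variance, rel=1e-12)

    def test_zero_holdout_correlation_gives_zero(self, small_design):
        panel, _, arch = small_design
        cgr = CGRStructure.constant(3, 0.6, 0.0, 0.45)
        assert pgs_r2(panel, cgr, arch).r2 == 0.0

    def test_large_sample_limit_is_rho2_h2(self):
        h2, rho = 0.5, 0.6
        panel, cgr = equal_design(1e13, 10, h2, 1.0, rho, h2)
        r2 = pgs_r2(panel, cgr, Architecture(100_000, 1_000)).r2
        assert r2 == pytest.approx(rho**2 * h2, rel=1e-5)

    def test_quadratic_in_cgr_for_single_study(self):
        for rho in (0.1, 0.25, 0.5, 0.9):
            panel, cgr = equal_design(50_000, 1, 0.4, 1.0, rho, 0.4)
            _, cgr1 = equal_design(50_000, 1, 0.4, 1.0, 1.0, 0.4)
            arch = Architecture(100_000, 1_000)
            ratio = pgs_r2(panel, cgr, arch).r2 / pgs_r2(panel, cgr1, arch).r2
            assert ratio == pytest.approx(rho**2, rel=1e-12)

    def test_bounded_by_holdout_ceiling(self, rng):
        for _ in range(30):
            panel, cgr, arch = random_design(rng)
            r2 = pgs_r2(panel, cgr, arch).r2
            assert 0.0 <= r2 <= 1.0
            ceiling = cgr.holdout_h2 * float(np.max(cgr.to_holdout)) ** 2
            assert r2 <= ceiling + 1e-12


class TestMonotonicity:
    def test_power_nondecreasing_in_size_h2_cgr(self):
        arch = Architecture(100_000, 1_000)

        def beta(n, h2, rho):
            panel, cgr = equal_design(n, 5, h2, rho, rho, h2)
            return power_report(panel, cgr, arch).beta

        for grid, f in [
            ([1e4, 1e5, 1e6], lambda v: beta(v, 0.4, 0.5)),
            ([0.1, 0.3, 0.6], lambda v: beta(1e5, v, 0.5)),
            ([0.0, 0.4, 0.8, 1.0], lambda v: beta(1e5, 0.4, v)),
        ]:
            values = [f(v) for v in grid]
            assert all(b2 >= b1 for b1, b2 in zip(values, values[1:]))

    def test_r2_nondecreasing_in_studies_at_fixed_total(self):
        # splitting a fixed total across more studies helps prediction when
        # the CGR is imperfect: idiosyncratic study effects average out
        arch = Architecture(100_000, 1_000)
        r2s = [
            pgs_r2(*equal_design(250_000, c, 0.5, 0.5, 0.5, 0.5), arch).r2
            for c in (1, 2, 10, 100)
        ]
        assert all(b >= a for a, b in zip(r2s, r2s[1:]))

    def test_zero_cgr_cluster_power_equals_single_set(self):
        # two equally-powered disjoint sets with zero between-set CGR: the
        # joint meta-analysis has exactly the power of either set alone
        arch = Architecture(100_000, 1_000)
        joint = clustered_design(250_000, 2, 50, 0.5, 1.0, 0.0, 0.5, 0.5)
        single = equal_design(125_000, 50, 0.5, 1.0, 0.5, 0.5)
        beta_joint = power_report(*joint, arch).beta
        beta_single = power_report(*single, arch).beta
        assert beta_joint == pytest.approx(beta_single, rel=1e-12)


class TestAttenuation:
    def test_all_ones_benchmark_is_identity(self):
        panel, cgr = equal_design(100_000, 10, 0.5, 1.0, 1.0, 0.5)
        rep = attenuation(panel, cgr, Architecture(100_000, 1_000))
        assert rep.hits_loss == 0.0 and rep.r2_loss == 0.0
        assert rep.hits_defined and rep.r2_defined

    def test_losses_are_relative(self, wood_config):
        panel, cgr, arch = wood_config.to_design()
        rep = attenuation(panel, cgr, arch)
        assert rep.hits_loss == pytest.approx(
            1 - rep.hits_given / rep.hits_benchmark, rel=1e-12
        )
        assert 0.0 < rep.hits_loss < 1.0
        assert 0.0 < rep.r2_loss < 1.0

    def test_undefined_benchmark_flagged_not_silent(self):
        # zero hold-out heritability: the benchmark R2 is exactly zero and
        # the ratio is undefined; must be flagged rather than NaN-silent
        panel = StudyPanel([1000], [0.5])
        cgr = CGRStructure.constant(1, 1.0, 0.5, 0.0)
        rep = attenuation(panel, cgr, Architecture(1000, 100))
        assert not rep.r2_defined
        assert math.isnan(rep.r2_loss)
        assert rep.hits_defined  # expected hits never fall below alpha*(S-M)
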