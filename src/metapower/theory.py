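"""Closed-form power and polygenic-score accuracy for multi-study meta-analyses.

Model
-----
Phenotypes and genotypes are standardized within study. Causal-SNP effects are
random across studies: at each of the ``M`` causal blocks the vector of
standardized effects over studies (and the hold-out sample) is mean-zero
jointly Gaussian, with per-study variance ``h2_c / M`` (the equal-R2
assumption) and cross-study correlation given by the CGR matrix.

Under a sample-size-weighted fixed-effects meta-analysis of per-study Z
statistics, ``Z_meta = sum_c sqrt(N_c / N_T) Z_c``, the marginal distribution
of ``Z_meta`` at a causal SNP is exactly normal with mean zero and variance

    sigma^2 = 1 + (1 / (M N_T)) sum_{c,d} N_c N_d rho_cd sqrt(h2_c h2_d),

where ``rho_cc = 1``. Power per causal SNP is the two-sided tail mass
``beta = 2 Phi(-t / sigma)`` at ``t = Phi^-1(1 - alpha/2)``.

The polygenic score uses effect-size meta-analysis weights ``N_c / N_T`` over
all ``S`` blocks (no SNP selection); its theoretical hold-out R2 is

    R2 = [sum_c (N_c/N_T) rho_ch sqrt(h2_c h2_h)]^2
         / (S/N_T + (1/N_T^2) sum_{c,d} N_c N_d rho_cd sqrt(h2_c h2_d)).

Attenuation compares expected hits and R2 against the same design with every
cross-study correlation set to one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import log_ndtr, ndtri

from .design import (
    Architecture,
    CGRStructure,
    ConfigurationError,
    DesignValidationError,
    StudyPanel,
)

__all__ = [
    "PowerReport",
    "PGSReport",
    "AttenuationReport",
    "meta_z_variance",
    "power_per_causal_snp",
    "detection_report",
    "power_report",
    "pgs_r2",
    "attenuation",
]

_LOG2 = math.log(2.0)


@dataclass(frozen=True)
class PowerReport:
    """Power per causal SNP and the implied expected discovery counts."""

    z_variance: float
    beta: float
    expected_hits: float
    expected_true_pos: float
    expected_false_pos: float
    expected_false_neg: float
    expected_true_neg: float
    p_any_true_pos: float
    p_any_hit: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass(frozen=True)
class PGSReport:
    """Theoretical hold-out polygenic-score accuracy."""

    r2: float
    pgs_variance: float
    pgs_pheno_cov: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass(frozen=True)
class AttenuationReport:
    """Relative loss in expected hits and PGS R2 versus the CGR=1 benchmark.

    A loss is ``1 - value(given CGR) / value(CGR = 1)``.  When the benchmark
    value itself is numerically zero the ratio is undefined; the corresponding
    ``*_defined`` flag is False and the loss is reported as NaN explicitly.
    """

    hits_loss: float
    r2_loss: float
    hits_defined: bool
    r2_defined: bool
    hits_given: float
    hits_benchmark: float
    r2_given: float
    r2_benchmark: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _check_dims(panel: StudyPanel, cgr: CGRStructure) -> None:
    if panel.n_studies != cgr.n_studies:
        raise ConfigurationError(
            f"panel has {panel.n_studies} studies but CGR structure has {cgr.n_studies}"
        )


def _genetic_quadratic_form(panel: StudyPanel, cgr: CGRStructure) -> float:
    # sum_{c,d} N_c N_d rho_cd sqrt(h2_c h2_d) = a' R a with a_c = N_c sqrt(h2_c)
    a = panel.sizes * np.sqrt(panel.heritabilities)
    return float(a @ cgr.among @ a)


def meta_z_variance(
    panel: StudyPanel, cgr: CGRStructure, arch: Architecture
) -> float:
    """Variance of the meta-analysis Z statistic at a causal SNP.

    Equals ``1 + N h2 / M`` for a single study and
    ``1 + (h2/M) N (1 + rho)`` for two equal studies.
    """
    _check_dims(panel, cgr)
    q = _genetic_quadratic_form(panel, cgr)
    return 1.0 + q / (arch.m_causal * panel.n_total)


def power_per_causal_snp(sigma2: float, alpha: float) -> float:
    """Two-sided rejection probability ``beta = 2 Phi(-t/sigma)``.

    Computed through the log normal tail so that powers down to ~1e-300
    (deep sub-significance designs) do not underflow prematurely.
    ``sigma2 = 1`` returns exactly ``alpha``.
    """
    if not 0.0 < alpha < 1.0:
        raise DesignValidationError("alpha must lie in (0, 1)")
    if sigma2 < 1.0 - 1e-12:
        raise DesignValidationError("sigma2 must be >= 1 under the random-effects model")
    t = float(-ndtri(alpha / 2.0))
    sigma = math.sqrt(max(sigma2, 1.0))
    return float(math.exp(_LOG2 + log_ndtr(-t / sigma)))


def detection_report(
    beta: float, arch: Architecture, z_variance: float = float("nan")
) -> PowerReport:
    """Expected hit counts and any-hit probabilities for power ``beta``.

    ``(1-beta)^M`` and ``(1-alpha)^(S-M)`` are accumulated in log space so
    that architectures with millions of blocks and vanishing power remain
    finite and exact to double precision.
    """
    if not 0.0 <= beta <= 1.0:
        raise DesignValidationError("beta must lie in [0, 1]")
    m, s, a = arch.m_causal, arch.s_total, arch.alpha
    e_tp = beta * m
    e_fp = a * (s - m)
    if beta >= 1.0:
        log_none_tp = -math.inf
    else:
        log_none_tp = m * math.log1p(-beta)
    log_none_fp = (s - m) * math.log1p(-a)
    return PowerReport(
        z_variance=z_variance,
        beta=beta,
        expected_hits=e_tp + e_fp,
        expected_true_pos=e_tp,
        expected_false_pos=e_fp,
        expected_false_neg=(1.0 - beta) * m,
        expected_true_neg=(1.0 - a) * (s - m),
        p_any_true_pos=float(-math.expm1(log_none_tp)) if np.isfinite(log_none_tp) else 1.0,
        p_any_hit=float(-math.expm1(log_none_tp + log_none_fp))
        if np.isfinite(log_none_tp)
        else 1.0,
    )


def power_report(
    panel: StudyPanel, cgr: CGRStructure, arch: Architecture
) -> PowerReport:
    """Convenience chain: Z variance -> power -> detection counts."""
    s2 = meta_z_variance(panel, cgr, arch)
    beta = power_per_causal_snp(s2, arch.alpha)
    return detection_report(beta, arch, z_variance=s2)


def pgs_r2(panel: StudyPanel, cgr: CGRStructure, arch: Architecture) -> PGSReport:
    """Theoretical hold-out R2 of the all-SNP polygenic score.

    For one discovery study with ``h2_c = h2_h = h2`` and CGR ``rho`` this
    reduces to ``rho^2 h2^2 / (S/N + h2)``; as ``N_T -> inf`` at fixed
    hold-out CGR ``rho`` and equal h2 it approaches the ceiling ``rho^2 h2``.
    """
    _check_dims(panel, cgr)
    n_t = panel.n_total
    w = panel.sizes / n_t
    cov = float(
        np.sum(
            w
            * cgr.to_holdout
            * np.sqrt(panel.heritabilities * cgr.holdout_h2)
        )
    )
    var = arch.s_total / n_t + _genetic_quadratic_form(panel, cgr) / n_t**2
    return PGSReport(r2=cov * cov / var, pgs_variance=var, pgs_pheno_cov=cov)


#: Benchmark expected values below this are treated as zero for attenuation.
_ATTENUATION_FLOOR = 1e-300


def attenuation(
    panel: StudyPanel, cgr: CGRStructure, arch: Architecture
) -> AttenuationReport:
    """Relative loss in expected hits and PGS R2 due to imperfect CGR.

    Recomputes both quantities with every off-diagonal correlation (including
    the hold-out row) set to one and returns ``1 - given / benchmark``.
    Returns exact zeros when the given CGR is already all ones.
    """
    _check_dims(panel, cgr)
    hits = power_report(panel, cgr, arch).expected_hits
    r2 = pgs_r2(panel, cgr, arch).r2
    if cgr.is_all_ones():
        return AttenuationReport(0.0, 0.0, True, True, hits, hits, r2, r2)
    bench = cgr.all_ones()
    hits1 = power_report(panel, bench, arch).expected_hits
    r21 = pgs_r2(panel, bench, arch).r2
    hits_ok = hits1 > _ATTENUATION_FLOOR
    r2_ok = r21 > _ATTENUATION_FLOOR
    return AttenuationReport(
        hits_loss=1.0 - hits / hits1 if hits_ok else float("nan"),
        r2_loss=1.0 - r2 / r21 if r2_ok else float("nan"),
        hits_defined=hits_ok,
        r2_defined=r2_ok,
        hits_given=hits,
        hits_benchmark=hits1,
        r2_given=r2,
        r2_benchmark=r21,
    )
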