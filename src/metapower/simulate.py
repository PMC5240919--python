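"""Generative validation of the closed forms: a seeded multi-study GWAS world.

Each replicate draws, from scratch, (i) per-SNP allele frequencies, (ii)
causal effects that are jointly Gaussian across the discovery studies and the
hold-out sample with the target cross-study correlation structure, (iii)
0/1/2 genotypes at ``S`` independent blocks and additive phenotypes in every
study, then runs a per-study GWAS (simple regression on standardized
genotypes), a sample-size-weighted fixed-effects meta-analysis, and an
all-SNP polygenic score in the hold-out sample. Empirical power (fraction of
causal SNPs passing the two-sided threshold) and hold-out PGS R2 are compared
with the closed-form predictions.

Assumption-violation switches:

* ``maf_effect_coupling`` -- exponent ``s`` tying raw (allele-count) effect
  variance to ``[2f(1-f)]^s``.  On standardized genotypes the per-SNP effect
  variance is then proportional to ``[2f(1-f)]^(s+1)``: ``s = -1`` is the
  equal-R2 assumption of the theory, ``s = 0`` (equal raw-effect variance)
  violates it.
* ``maf`` with ``per_study=True`` -- allele frequencies redrawn independently
  per study, so studies disagree about which variants are common.
* ``overlap_fraction q < 1`` -- only a fraction ``q`` of each study's ``M``
  causal loci is shared across studies (one common set plus per-study private
  sets); shared-locus effects correlate ``effect_corr`` across studies. The
  implied genome-wide CGR is ``q * effect_corr`` for every pair.
* ``strict_equal_r2`` -- effects of fixed magnitude ``sqrt(h2/M)`` with
  random signs, sign-coupled across studies to hit the target correlation.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .design import (
    Architecture,
    CGRStructure,
    DesignValidationError,
    StudyPanel,
)
from .theory import meta_z_variance, pgs_r2, power_per_causal_snp

__all__ = [
    "MafSpec",
    "SimScenario",
    "SimResult",
    "draw_effects",
    "simulate_study",
    "run_gwas_and_meta",
    "holdout_pgs_r2",
    "run_scenario",
    "validate_grid",
    "baseline_validation_grid",
    "overlap_validation_grid",
]


@dataclass(frozen=True)
class MafSpec:
    """Allele-frequency model: a fixed value or Uniform(low, high) per SNP.

    With ``per_study=True`` frequencies are redrawn independently for every
    study (and the hold-out sample); otherwise all samples share one draw.
    """

    kind: str = "uniform"
    value: float = 0.5
    low: float = 0.05
    high: float = 0.5
    per_study: bool = False

    def __post_init__(self):
        if self.kind not in ("fixed", "uniform"):
            raise DesignValidationError(f"unknown MAF model {self.kind!r}")
        lo, hi = (self.value, self.value) if self.kind == "fixed" else (self.low, self.high)
        if not (0.0 < lo <= hi < 1.0):
            raise DesignValidationError("allele frequencies must lie strictly in (0, 1)")

    def draw(self, rng: np.random.Generator, n_groups: int, n_snps: int) -> np.ndarray:
        """Frequencies for ``n_groups`` samples (studies + hold-out) at ``n_snps`` loci."""
        if self.kind == "fixed":
            return np.full((n_groups, n_snps), self.value)
        if self.per_study:
            return rng.uniform(self.low, self.high, size=(n_groups, n_snps))
        shared = rng.uniform(self.low, self.high, size=n_snps)
        return np.broadcast_to(shared, (n_groups, n_snps)).copy()


@dataclass(frozen=True)
class SimScenario:
    """One generative setting: design, architecture, and violation switches."""

    panel: StudyPanel
    cgr: CGRStructure
    arch: Architecture
    maf: MafSpec = field(default_factory=MafSpec)
    maf_effect_coupling: float = -1.0
    overlap_fraction: float = 1.0
    effect_corr: float | None = None
    n_holdout: int = 2000
    n_replicates: int = 60
    seed: int = 0
    standardize: str = "sample"
    strict_equal_r2: bool = False
    label: str = ""

    def __post_init__(self):
        sizes = self.panel.sizes
        if np.any(sizes != np.round(sizes)):
            raise DesignValidationError("simulator requires integer study sizes")
        if np.any(sizes < 30) or self.n_holdout < 30:
            raise DesignValidationError("simulated samples need n >= 30")
        if self.standardize not in ("sample", "population"):
            raise DesignValidationError("standardize must be 'sample' or 'population'")
        if not 0.0 < self.overlap_fraction <= 1.0:
            raise DesignValidationError("overlap fraction q must lie in (0, 1]")
        m = self.arch.m_causal
        q = self.overlap_fraction
        if q < 1.0:
            if self.effect_corr is None:
                raise DesignValidationError(
                    "overlap scenarios require an effect correlation rho_e"
                )
            if round(q * m) < 1:
                raise DesignValidationError("q*M must be at least one shared locus")
            n_groups = self.panel.n_studies + 1
            n_shared = int(round(q * m))
            if n_shared + n_groups * (m - n_shared) > self.arch.s_total:
                raise DesignValidationError(
                    "S too small for the union of shared and private causal sets"
                )
        if self.n_replicates < 1:
            raise DesignValidationError("need at least one replicate")

    @property
    def implied_cgr(self) -> float | None:
        """Genome-wide CGR implied by an overlap scenario: ``q * rho_e``."""
        if self.overlap_fraction >= 1.0:
            return None
        return self.overlap_fraction * float(self.effect_corr)

    def theory_cgr(self) -> CGRStructure:
        """CGR structure the closed forms should be evaluated at."""
        if self.overlap_fraction >= 1.0:
            return self.cgr
        rho = self.implied_cgr
        return CGRStructure.constant(
            self.panel.n_studies, rho, rho, self.cgr.holdout_h2
        )

    def theory(self) -> tuple[float, float]:
        """Matched closed-form (power, R2) for this scenario."""
        cgr = self.theory_cgr()
        s2 = meta_z_variance(self.panel, cgr, self.arch)
        beta = power_per_causal_snp(s2, self.arch.alpha)
        return beta, pgs_r2(self.panel, cgr, self.arch).r2


@dataclass(frozen=True)
class SimResult:
    """Empirical vs theoretical power and R2 for one scenario."""

    label: str
    empirical_power: float
    power_se: float
    empirical_r2: float
    r2_se: float
    theory_power: float
    theory_r2: float
    n_replicates: int
    n_excluded_snps: int = 0

    def __post_init__(self):
        for v in (self.empirical_power, self.empirical_r2):
            if not 0.0 <= v <= 1.0:
                raise DesignValidationError("rates and R2 must lie in [0, 1]")
        if self.power_se < 0 or self.r2_se < 0:
            raise DesignValidationError("standard errors must be nonnegative")

    def as_dict(self) -> dict:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# effect drawing


def _correlated_normals(
    corr: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """(G, n) standard normals with cross-row correlation ``corr``.

    Factored by eigendecomposition so exactly singular targets (e.g. all
    correlations one) yield exactly identical rows.
    """
    eigval, eigvec = np.linalg.eigh(corr)
    if eigval.min() < -1e-8:
        raise DesignValidationError(
            "effect correlation structure is not positive semidefinite: "
            f"smallest eigenvalue {eigval.min():.3e}"
        )
    factor = eigvec * np.sqrt(np.clip(eigval, 0.0, None))
    return factor @ rng.standard_normal((len(corr), n))


def _causal_sets(
    scenario: SimScenario, rng: np.random.Generator
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Shared causal indices and per-group private indices (disjoint)."""
    s, m = scenario.arch.s_total, scenario.arch.m_causal
    n_groups = scenario.panel.n_studies + 1
    if scenario.overlap_fraction >= 1.0:
        shared = rng.choice(s, size=m, replace=False)
        return shared, [np.empty(0, dtype=int)] * n_groups
    n_shared = int(round(scenario.overlap_fraction * m))
    n_private = m - n_shared
    picks = rng.choice(s, size=n_shared + n_groups * n_private, replace=False)
    shared = picks[:n_shared]
    private = [
        picks[n_shared + g * n_private : n_shared + (g + 1) * n_private]
        for g in range(n_groups)
    ]
    return shared, private


def draw_effects(
    scenario: SimScenario,
    freqs: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Standardized-genotype effect vectors, one row per study plus hold-out.

    Returns a ``(C+1, S)`` array, zero at non-causal indices.  Per-group
    causal-effect variances sum to that group's h2; cross-group correlations
    follow the scenario's CGR structure (or the overlap construction).
    """
    c = scenario.panel.n_studies
    s = scenario.arch.s_total
    m = scenario.arch.m_causal
    h2 = np.append(scenario.panel.heritabilities, scenario.cgr.holdout_h2)
    effects = np.zeros((c + 1, s))
    shared, private = _causal_sets(scenario, rng)

    if scenario.overlap_fraction >= 1.0:
        corr = scenario.cgr.bordered()
        if scenario.strict_equal_r2:
            # fixed-magnitude effects; sign-coupling via a Gaussian copula whose
            # latent correlation sin(pi*rho/2) yields sign correlation rho
            latent = np.sin(np.pi * corr / 2.0)
            np.fill_diagonal(latent, 1.0)
            u = np.sign(_correlated_normals(latent, m, rng))
            effects[:, shared] = u * np.sqrt(h2 / m)[:, None]
        else:
            u = _correlated_normals(corr, m, rng)
            w = (2.0 * freqs[:, shared] * (1.0 - freqs[:, shared])) ** (
                scenario.maf_effect_coupling + 1.0
            )
            var = h2[:, None] * w / w.sum(axis=1, keepdims=True)
            effects[:, shared] = np.sqrt(var) * u
        return effects

    # overlap construction: equal-R2 variances h2/M at every causal locus
    rho_e = float(scenario.effect_corr)
    corr_sh = np.full((c + 1, c + 1), rho_e)
    np.fill_diagonal(corr_sh, 1.0)
    u_sh = _correlated_normals(corr_sh, len(shared), rng)
    scale = np.sqrt(h2 / m)
    effects[:, shared] = scale[:, None] * u_sh
    for g in range(c + 1):
        effects[g, private[g]] = scale[g] * rng.standard_normal(len(private[g]))
    return effects


# ---------------------------------------------------------------------------
# data generation and GWAS


@dataclass(frozen=True, eq=False)
class StudyData:
    """Standardized genotypes and phenotype for one simulated sample."""

    genotypes: np.ndarray  # (n, S), standardized, zeroed where invalid
    phenotype: np.ndarray  # (n,), standardized
    valid: np.ndarray  # (S,) bool, False for monomorphic SNPs

    @property
    def n(self) -> int:
        return len(self.phenotype)


def simulate_study(
    effects: np.ndarray,
    n: int,
    freqs: np.ndarray,
    h2: float,
    rng: np.random.Generator,
    standardize: str = "sample",
) -> StudyData:
    """Genotypes and additive phenotype for one sample of size ``n``.

    Genotypes are allele counts 0/1/2 (two Bernoulli(f) draws per individual),
    standardized by within-sample moments (GWAS practice) or by population
    moments.  The phenotype adds Gaussian noise of variance ``1 - h2`` to the
    genetic component and is then standardized.  Monomorphic SNPs are flagged
    invalid and excluded from that study's GWAS.
    """
    s = len(freqs)
    # genotypes kept in float32 throughout: the per-SNP statistics are sample
    # correlations of O(1) quantities, where single precision is ~1e-6 --
    # orders of magnitude below the Monte-Carlo noise of any feasible run
    f32 = freqs.astype(np.float32)
    g = (rng.random((n, s), dtype=np.float32) < f32).astype(np.float32)
    g += rng.random((n, s), dtype=np.float32) < f32
    if standardize == "population":
        sd = np.sqrt(2.0 * f32 * (1.0 - f32))
        valid = g.std(axis=0) > 0  # undefined Z at zero realized variance
        gstd = g
        gstd -= 2.0 * f32
        gstd /= sd
        gstd[:, ~valid] = 0.0
    else:
        mu = g.mean(axis=0)
        sd = g.std(axis=0)
        valid = sd > 0
        gstd = g
        gstd -= mu
        gstd /= np.where(valid, sd, np.float32(1.0))
        gstd[:, ~valid] = 0.0
    genetic = (gstd @ effects.astype(np.float32)).astype(np.float64)
    y = genetic + math.sqrt(max(1.0 - h2, 0.0)) * rng.standard_normal(n)
    y = (y - y.mean()) / y.std()
    return StudyData(genotypes=gstd, phenotype=y, valid=valid)


@dataclass(frozen=True, eq=False)
class MetaResult:
    """Per-SNP meta-analysis Z statistics and effect estimates."""

    z: np.ndarray  # (S,), NaN where no study contributed
    coef: np.ndarray  # (S,), sample-size-weighted mean correlation
    n_contributing: np.ndarray  # (S,) int


def _study_gwas(data: StudyData) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP (correlation, Z) from simple regression on standardized data."""
    n = data.n
    coef = (data.genotypes.T @ data.phenotype.astype(np.float32)).astype(np.float64) / n
    z = math.sqrt(n) * coef
    return coef, z


def run_gwas_and_meta(
    studies: Sequence[StudyData], panel: StudyPanel
) -> MetaResult:
    """Sample-size-weighted fixed-effects meta-analysis across studies.

    Z weights are ``sqrt(N_c / N_T)``, effect weights ``N_c / N_T``.  A SNP
    excluded (monomorphic) in some studies is meta-analyzed over the rest
    with weights renormalized; excluded everywhere, its statistics are NaN.
    """
    if len(studies) < 1:
        raise DesignValidationError("need at least one study")
    if len(studies) != panel.n_studies:
        raise DesignValidationError("study data does not match panel")
    s = studies[0].genotypes.shape[1]
    sizes = panel.sizes
    num_z = np.zeros(s)
    num_coef = np.zeros(s)
    denom_n = np.zeros(s)
    contributing = np.zeros(s, dtype=int)
    for data, n_c in zip(studies, sizes):
        coef, z = _study_gwas(data)
        v = data.valid
        num_z[v] += math.sqrt(n_c) * z[v]
        num_coef[v] += n_c * coef[v]
        denom_n[v] += n_c
        contributing[v] += 1
    any_c = denom_n > 0
    z_meta = np.full(s, np.nan)
    coef_meta = np.full(s, np.nan)
    z_meta[any_c] = num_z[any_c] / np.sqrt(denom_n[any_c])
    coef_meta[any_c] = num_coef[any_c] / denom_n[any_c]
    return MetaResult(z=z_meta, coef=coef_meta, n_contributing=contributing)


def holdout_pgs_r2(meta: MetaResult, holdout: StudyData) -> float:
    """Squared correlation between the all-SNP PGS and the hold-out phenotype.

    SNPs with no meta-analysis estimate (or monomorphic in the hold-out
    sample) contribute zero weight.
    """
    w = np.where(np.isnan(meta.coef), 0.0, meta.coef)
    score = (holdout.genotypes @ w.astype(np.float32)).astype(np.float64)
    sd = score.std()
    if sd == 0:
        raise DesignValidationError("degenerate polygenic score (zero variance)")
    r = float(np.mean((score - score.mean()) / sd * holdout.phenotype))
    return r * r


# ---------------------------------------------------------------------------
# scenario driver


def _replicate(
    scenario: SimScenario, rep_seed: np.random.SeedSequence
) -> tuple[float, float, int]:
    """One replicate: (causal rejection rate, hold-out R2, #excluded SNPs)."""
    c = scenario.panel.n_studies
    streams = rep_seed.spawn(c + 3)  # maf, effects, per-study, holdout
    rng_maf = np.random.default_rng(streams[0])
    rng_eff = np.random.default_rng(streams[1])
    freqs = scenario.maf.draw(rng_maf, c + 1, scenario.arch.s_total)
    effects = draw_effects(scenario, freqs, rng_eff)
    # power is assessed over loci causal in at least one discovery study
    causal_union = np.flatnonzero(np.abs(effects[:c]).sum(axis=0) > 0)

    studies = []
    excluded = 0
    for g in range(c):
        rng_g = np.random.default_rng(streams[2 + g])
        data = simulate_study(
            effects[g],
            int(scenario.panel.sizes[g]),
            freqs[g],
            float(scenario.panel.heritabilities[g]),
            rng_g,
            scenario.standardize,
        )
        excluded += int((~data.valid).sum())
        studies.append(data)
    meta = run_gwas_and_meta(studies, scenario.panel)

    # empirical power per associated SNP = true positives / M, with M the
    # per-study causal count: under partial causal overlap the union of
    # causal loci is larger than M, but the closed form predicts beta*M true
    # positives for a design whose genome-wide CGR matches the overlap's
    t = scenario.arch.threshold
    z_causal = meta.z[causal_union]
    z_causal = z_causal[~np.isnan(z_causal)]
    power = float(np.sum(np.abs(z_causal) > t) / scenario.arch.m_causal)

    rng_h = np.random.default_rng(streams[2 + c])
    holdout = simulate_study(
        effects[c],
        scenario.n_holdout,
        freqs[c],
        scenario.cgr.holdout_h2,
        rng_h,
        scenario.standardize,
    )
    r2 = holdout_pgs_r2(meta, holdout)
    return power, r2, excluded


def _scenario_seed(scenario: SimScenario) -> np.random.SeedSequence:
    # label-keyed entropy: adding scenarios to a grid never perturbs others
    key = zlib.crc32(scenario.label.encode() or b"metapower")
    return np.random.SeedSequence([scenario.seed, key])


def run_scenario(scenario: SimScenario) -> SimResult:
    """Run all replicates of one scenario; deterministic in (label, seed)."""
    rep_seeds = _scenario_seed(scenario).spawn(scenario.n_replicates)
    powers, r2s = np.empty(scenario.n_replicates), np.empty(scenario.n_replicates)
    excluded = 0
    for i, rs in enumerate(rep_seeds):
        powers[i], r2s[i], exc = _replicate(scenario, rs)
        excluded += exc
    beta_th, r2_th = scenario.theory()
    n = scenario.n_replicates
    return SimResult(
        label=scenario.label,
        empirical_power=float(powers.mean()),
        power_se=float(powers.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0,
        empirical_r2=float(r2s.mean()),
        r2_se=float(r2s.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0,
        theory_power=beta_th,
        theory_r2=r2_th,
        n_replicates=n,
        n_excluded_snps=excluded,
    )


def validate_grid(
    scenarios: Iterable[SimScenario],
) -> tuple[pd.DataFrame, dict]:
    """Empirical-vs-theory table and aggregate RMSE (percentage points).

    The aggregate RMSE is the root of the mean squared difference between
    empirical and closed-form values across scenarios, times 100.
    """
    results = [run_scenario(sc) for sc in scenarios]
    if len(results) < 1:
        raise DesignValidationError("validation grid is empty")
    frame = pd.DataFrame([r.as_dict() for r in results])
    frame["power_delta"] = frame.empirical_power - frame.theory_power
    frame["r2_delta"] = frame.empirical_r2 - frame.theory_r2
    summary = {
        "n_scenarios": len(frame),
        "rmse_power_pp": float(np.sqrt(np.mean(frame.power_delta**2)) * 100.0),
        "rmse_r2_pp": float(np.sqrt(np.mean(frame.r2_delta**2)) * 100.0),
        "max_abs_power_delta_pp": float(frame.power_delta.abs().max() * 100.0),
        "max_abs_r2_delta_pp": float(frame.r2_delta.abs().max() * 100.0),
    }
    return frame, summary


# ---------------------------------------------------------------------------
# default scenario grids

#: Relaxed threshold for validation runs: genome-wide alpha needs enormous
#: samples before power leaves zero, and the closed form is a statement about
#: the Z variance that holds at any alpha.
VALIDATION_ALPHA = 5e-4


def baseline_validation_grid(
    seed: int,
    n_replicates: int = 60,
    n_per_study: int = 2000,
    n_holdout: int = 2000,
) -> list[SimScenario]:
    """Assumption-violating baseline grid: MAF-coupled raw effects (s = 0)
    with study-specific Uniform(0.05, 0.5) allele frequencies, spanning S,
    C, h2 and CGR."""
    scenarios = []
    maf = MafSpec(kind="uniform", low=0.05, high=0.5, per_study=True)
    for s_total in (1000, 2000):
        for c in (2, 5):
            for h2 in (0.2, 0.5):
                for rho in (0.3, 0.7, 1.0):
                    panel = StudyPanel([n_per_study] * c, [h2] * c)
                    cgr = CGRStructure.constant(c, rho, rho, h2)
                    arch = Architecture(s_total, s_total // 10, VALIDATION_ALPHA)
                    label = f"base_S{s_total}_C{c}_h{h2}_r{rho}"
                    scenarios.append(
                        SimScenario(
                            panel=panel,
                            cgr=cgr,
                            arch=arch,
                            maf=maf,
                            maf_effect_coupling=0.0,
                            n_holdout=n_holdout,
                            n_replicates=n_replicates,
                            seed=seed,
                            label=label,
                        )
                    )
    return scenarios


def overlap_validation_grid(
    seed: int,
    n_replicates: int = 60,
    n_per_study: int = 2000,
    n_holdout: int = 2000,
) -> list[SimScenario]:
    """Causal-overlap grid: CGR shaped by partially shared causal loci
    (fraction q) and the effect correlation rho_e at the shared loci."""
    scenarios = []
    maf = MafSpec(kind="uniform", low=0.05, high=0.5, per_study=False)
    for h2 in (0.2, 0.5):
        for q in (0.5, 0.8):
            for rho_e in (0.6, 1.0):
                c = 2
                panel = StudyPanel([n_per_study] * c, [h2] * c)
                # cgr field is a placeholder: theory uses the implied q*rho_e
                cgr = CGRStructure.constant(c, q * rho_e, q * rho_e, h2)
                arch = Architecture(1000, 100, VALIDATION_ALPHA)
                label = f"ovl_h{h2}_q{q}_re{rho_e}"
                scenarios.append(
                    SimScenario(
                        panel=panel,
                        cgr=cgr,
                        arch=arch,
                        maf=maf,
                        overlap_fraction=q,
                        effect_corr=rho_e,
                        n_holdout=n_holdout,
                        n_replicates=n_replicates,
                        seed=seed,
                        label=label,
                    )
                )
    return scenarios
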