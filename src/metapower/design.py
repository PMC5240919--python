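"""Study-design containers for multi-study GWAS power and prediction analyses.

A meta-analysis design is described by three objects:

* :class:`StudyPanel` -- the ``C`` discovery studies, each with a sample size
  ``N_c`` and a SNP heritability ``h2_c``.
* :class:`CGRStructure` -- the cross-study genetic correlations (CGR): the
  ``C x C`` correlation matrix of causal-SNP effects among the discovery
  studies, the length-``C`` vector of correlations between each study and the
  hold-out (prediction) sample, and the hold-out SNP heritability.
* :class:`Architecture` -- the genetic architecture abstraction: ``S``
  independent haplotype blocks (each tagged by one SNP), of which ``M`` are
  causal, and the genome-wide significance level ``alpha``.

Constructors :func:`equal_design` and :func:`clustered_design` build the
constant-correlation and two-cluster designs used throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import ndtri

__all__ = [
    "ConfigurationError",
    "DesignValidationError",
    "StudyPanel",
    "CGRStructure",
    "Architecture",
    "equal_design",
    "clustered_design",
]

#: Tolerance on the smallest eigenvalue of the bordered correlation matrix.
PSD_TOL = 1e-8


class ConfigurationError(ValueError):
    """Inconsistent combination of design inputs (e.g. dimension mismatch)."""


class DesignValidationError(ValueError):
    """A single design input is invalid (range, symmetry, PSD violation)."""


def _as_readonly(a: np.ndarray) -> np.ndarray:
    a = np.array(a, dtype=float)
    a.flags.writeable = False
    return a


@dataclass(frozen=True, eq=False)
class StudyPanel:
    """The discovery studies: per-study sample sizes and SNP heritabilities.

    Sizes may be fractional: constant designs split a total sample size
    ``N_T`` into ``C`` equal parts ``N_T / C`` without rounding, which is the
    arithmetic required to reproduce published equal-design results exactly.
    The simulator, which instantiates individuals, requires integer sizes.
    """

    sizes: np.ndarray
    heritabilities: np.ndarray

    def __init__(self, sizes: Sequence[float], heritabilities: Sequence[float]):
        sizes = np.atleast_1d(np.asarray(sizes, dtype=float))
        h2 = np.atleast_1d(np.asarray(heritabilities, dtype=float))
        if sizes.ndim != 1 or h2.ndim != 1:
            raise DesignValidationError("sizes and heritabilities must be 1-D")
        if len(sizes) != len(h2):
            raise ConfigurationError(
                f"{len(sizes)} study sizes but {len(h2)} heritabilities"
            )
        if len(sizes) < 1:
            raise DesignValidationError("at least one study is required")
        if not np.all(np.isfinite(sizes)) or np.any(sizes < 1):
            raise DesignValidationError("every study size N_c must be >= 1")
        if np.any(h2 < 0) or np.any(h2 > 1):
            raise DesignValidationError("every h2_c must lie in [0, 1]")
        object.__setattr__(self, "sizes", _as_readonly(sizes))
        object.__setattr__(self, "heritabilities", _as_readonly(h2))

    @property
    def n_studies(self) -> int:
        return len(self.sizes)

    @property
    def n_total(self) -> float:
        return float(self.sizes.sum())


@dataclass(frozen=True, eq=False)
class CGRStructure:
    """Cross-study genetic correlations, including the hold-out sample.

    ``among`` is the ``C x C`` correlation matrix of causal-SNP effects between
    discovery studies (unit diagonal); ``to_holdout`` holds the correlation of
    each study's effects with the hold-out sample's; ``holdout_h2`` is the
    SNP heritability in the hold-out sample.  The bordered ``(C+1) x (C+1)``
    matrix must be positive semidefinite: effects across studies and hold-out
    are jointly Gaussian in the underlying random-effects model.
    """

    among: np.ndarray
    to_holdout: np.ndarray
    holdout_h2: float

    def __init__(
        self,
        among: Sequence[Sequence[float]] | np.ndarray,
        to_holdout: Sequence[float] | np.ndarray,
        holdout_h2: float,
    ):
        among = np.atleast_2d(np.asarray(among, dtype=float))
        to_holdout = np.atleast_1d(np.asarray(to_holdout, dtype=float))
        c = among.shape[0]
        if among.shape != (c, c):
            raise DesignValidationError("among-study CGR matrix must be square")
        if to_holdout.shape != (c,):
            raise ConfigurationError(
                f"hold-out CGR vector has length {len(to_holdout)}, expected {c}"
            )
        if not np.allclose(among, among.T, atol=1e-12):
            raise DesignValidationError("among-study CGR matrix must be symmetric")
        if not np.allclose(np.diag(among), 1.0, atol=1e-12):
            raise DesignValidationError("among-study CGR matrix must have unit diagonal")
        full = np.block(
            [[among, to_holdout[:, None]], [to_holdout[None, :], np.ones((1, 1))]]
        )
        if np.any(np.abs(full) > 1 + 1e-12):
            raise DesignValidationError("correlations must lie in [-1, 1]")
        min_eig = float(np.linalg.eigvalsh(full).min())
        if min_eig < -PSD_TOL:
            raise DesignValidationError(
                "bordered (C+1)x(C+1) CGR matrix is not positive semidefinite: "
                f"smallest eigenvalue {min_eig:.3e}"
            )
        if not 0.0 <= holdout_h2 <= 1.0:
            raise DesignValidationError("hold-out h2 must lie in [0, 1]")
        object.__setattr__(self, "among", _as_readonly(among))
        object.__setattr__(self, "to_holdout", _as_readonly(to_holdout))
        object.__setattr__(self, "holdout_h2", float(holdout_h2))

    @property
    def n_studies(self) -> int:
        return self.among.shape[0]

    def bordered(self) -> np.ndarray:
        """Full ``(C+1) x (C+1)`` correlation matrix, hold-out row last."""
        c = self.n_studies
        full = np.empty((c + 1, c + 1))
        full[:c, :c] = self.among
        full[:c, c] = full[c, :c] = self.to_holdout
        full[c, c] = 1.0
        return full

    @classmethod
    def constant(
        cls,
        n_studies: int,
        rho_among: float,
        rho_holdout: float,
        holdout_h2: float,
    ) -> "CGRStructure":
        """Constant-correlation structure: one CGR among studies, one to hold-out."""
        among = np.full((n_studies, n_studies), float(rho_among))
        np.fill_diagonal(among, 1.0)
        return cls(among, np.full(n_studies, float(rho_holdout)), holdout_h2)

    @classmethod
    def from_bordered(cls, full: np.ndarray) -> "CGRStructure":
        """Split a bordered ``(C+1) x (C+1)`` matrix (hold-out row last).

        The hold-out heritability is not part of the correlation matrix and
        must be attached by the caller; this returns a structure with
        ``holdout_h2`` unset (zero) for composition by configuration code.
        """
        full = np.asarray(full, dtype=float)
        c = full.shape[0] - 1
        if c < 1:
            raise DesignValidationError("bordered matrix must be at least 2 x 2")
        return cls(full[:c, :c], full[:c, c], 0.0)

    def with_holdout_h2(self, holdout_h2: float) -> "CGRStructure":
        return CGRStructure(self.among, self.to_holdout, holdout_h2)

    def all_ones(self) -> "CGRStructure":
        """Perfect-correlation benchmark with the same dimensions and h2."""
        return CGRStructure.constant(self.n_studies, 1.0, 1.0, self.holdout_h2)

    def is_all_ones(self) -> bool:
        return bool(
            np.all(self.among == 1.0) and np.all(self.to_holdout == 1.0)
        )


@dataclass(frozen=True)
class Architecture:
    """Genetic architecture: S independent blocks, M causal, significance alpha."""

    s_total: int
    m_causal: int
    alpha: float = 5e-8

    def __post_init__(self):
        if int(self.s_total) != self.s_total or self.s_total < 1:
            raise DesignValidationError("S must be a positive integer")
        if int(self.m_causal) != self.m_causal or self.m_causal < 1:
            raise DesignValidationError("M must be a positive integer")
        if self.m_causal > self.s_total:
            raise DesignValidationError(
                f"M = {self.m_causal} causal SNPs cannot exceed S = {self.s_total}"
            )
        if not 0.0 < self.alpha < 1.0:
            raise DesignValidationError("alpha must lie in (0, 1)")
        object.__setattr__(self, "s_total", int(self.s_total))
        object.__setattr__(self, "m_causal", int(self.m_causal))

    @property
    def threshold(self) -> float:
        """Two-sided |Z| threshold ``t = Phi^-1(1 - alpha/2)``."""
        t = float(-ndtri(self.alpha / 2.0))
        if not np.isfinite(t) or t <= 0:
            raise DesignValidationError(f"degenerate threshold for alpha={self.alpha}")
        return t


def equal_design(
    n_total: float,
    n_studies: int,
    h2: float,
    cgr_among: float,
    cgr_holdout: float,
    h2_holdout: float,
) -> tuple[StudyPanel, CGRStructure]:
    """Equal-size, equal-h2, constant-CGR design.

    Splits ``n_total`` into ``n_studies`` equal parts, keeping fractional
    per-study sizes unrounded (rounding shifts equal-design results at the
    second decimal).
    """
    if n_studies < 1:
        raise DesignValidationError("need at least one study")
    if n_total < n_studies:
        raise DesignValidationError(
            f"total sample size {n_total} is smaller than the number of studies {n_studies}"
        )
    panel = StudyPanel(
        np.full(n_studies, n_total / n_studies), np.full(n_studies, h2)
    )
    cgr = CGRStructure.constant(n_studies, cgr_among, cgr_holdout, h2_holdout)
    return panel, cgr


def clustered_design(
    n_total: float,
    n_clusters: int,
    studies_per_cluster: int,
    h2: float,
    rho_within: float,
    rho_between: float,
    cgr_holdout: float,
    h2_holdout: float,
) -> tuple[StudyPanel, CGRStructure]:
    """Block-correlation design: clusters of studies with perfect-or-high CGR
    within each cluster and a (possibly lower) CGR between clusters.

    Models, e.g., a meta-analysis pooling one set of European-ancestry cohorts
    with one set of Asian-ancestry cohorts.
    """
    if n_clusters < 1 or studies_per_cluster < 1:
        raise DesignValidationError("cluster counts must be positive")
    c = n_clusters * studies_per_cluster
    if n_total < c:
        raise DesignValidationError("total sample size smaller than number of studies")
    panel = StudyPanel(np.full(c, n_total / c), np.full(c, h2))
    among = np.full((c, c), float(rho_between))
    for k in range(n_clusters):
        sl = slice(k * studies_per_cluster, (k + 1) * studies_per_cluster)
        among[sl, sl] = rho_within
    np.fill_diagonal(among, 1.0)
    cgr = CGRStructure(among, np.full(c, float(cgr_holdout)), h2_holdout)
    return panel, cgr
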