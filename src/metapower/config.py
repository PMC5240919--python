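"""Calculator configurations: the two input modes of the power calculator.

``ScalarConfig`` mirrors the simple interface: an average sample size per
study (or total), one average h2, and exactly two CGR values -- one among the
discovery studies and one between each study and the hold-out sample.
``MatrixConfig`` mirrors the general interface: per-study sizes and
heritabilities plus a full bordered ``(C+1) x (C+1)`` correlation matrix.
Both reduce to the same ``(StudyPanel, CGRStructure, Architecture)`` triple,
and a matrix configuration built from constant correlations reproduces the
scalar one exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .design import (
    Architecture,
    CGRStructure,
    ConfigurationError,
    StudyPanel,
    equal_design,
)
from .theory import attenuation, pgs_r2, power_report

__all__ = ["ScalarConfig", "MatrixConfig", "config_from_dict", "run_calculator"]


@dataclass(frozen=True)
class ScalarConfig:
    """Constant-correlation equal design specified by scalars."""

    n_total: float
    n_studies: int
    h2: float
    cgr: float
    cgr_holdout: float
    h2_holdout: float
    s_total: int
    m_causal: int
    alpha: float = 5e-8

    def to_design(self) -> tuple[StudyPanel, CGRStructure, Architecture]:
        panel, cgr = equal_design(
            self.n_total,
            self.n_studies,
            self.h2,
            self.cgr,
            self.cgr_holdout,
            self.h2_holdout,
        )
        return panel, cgr, Architecture(self.s_total, self.m_causal, self.alpha)

    def as_dict(self) -> dict:
        return {"mode": "scalar", **asdict(self)}


@dataclass(frozen=True, eq=False)
class MatrixConfig:
    """General design: per-study sizes/h2 and a full bordered CGR matrix."""

    sizes: np.ndarray
    heritabilities: np.ndarray
    cgr_matrix: np.ndarray  # (C+1) x (C+1), hold-out row last
    h2_holdout: float
    s_total: int
    m_causal: int
    alpha: float = 5e-8

    def __post_init__(self):
        object.__setattr__(self, "sizes", np.asarray(self.sizes, dtype=float))
        object.__setattr__(
            self, "heritabilities", np.asarray(self.heritabilities, dtype=float)
        )
        object.__setattr__(self, "cgr_matrix", np.asarray(self.cgr_matrix, dtype=float))
        c = len(self.sizes)
        if len(self.heritabilities) != c:
            raise ConfigurationError("sizes and heritabilities must have equal length")
        if self.cgr_matrix.shape != (c + 1, c + 1):
            raise ConfigurationError(
                f"CGR matrix must be (C+1) x (C+1) = {(c + 1, c + 1)}, "
                f"got {self.cgr_matrix.shape}"
            )

    def to_design(self) -> tuple[StudyPanel, CGRStructure, Architecture]:
        panel = StudyPanel(self.sizes, self.heritabilities)
        cgr = CGRStructure.from_bordered(self.cgr_matrix).with_holdout_h2(
            self.h2_holdout
        )
        return panel, cgr, Architecture(self.s_total, self.m_causal, self.alpha)

    def as_dict(self) -> dict:
        return {
            "mode": "matrix",
            "sizes": self.sizes.tolist(),
            "heritabilities": self.heritabilities.tolist(),
            "cgr_matrix": self.cgr_matrix.tolist(),
            "h2_holdout": self.h2_holdout,
            "s_total": self.s_total,
            "m_causal": self.m_causal,
            "alpha": self.alpha,
        }


def config_from_dict(d: dict) -> ScalarConfig | MatrixConfig:
    """Build a configuration from a plain dict (e.g. parsed JSON).

    The mode is taken from the ``mode`` key, or inferred: a ``cgr_matrix``
    key selects matrix mode.
    """
    d = dict(d)
    mode = d.pop("mode", "matrix" if "cgr_matrix" in d else "scalar")
    try:
        if mode == "scalar":
            return ScalarConfig(**d)
        if mode == "matrix":
            return MatrixConfig(
                sizes=np.asarray(d["sizes"], dtype=float),
                heritabilities=np.asarray(d["heritabilities"], dtype=float),
                cgr_matrix=np.asarray(d["cgr_matrix"], dtype=float),
                h2_holdout=float(d["h2_holdout"]),
                s_total=int(d["s_total"]),
                m_causal=int(d["m_causal"]),
                alpha=float(d.get("alpha", 5e-8)),
            )
    except KeyError as exc:
        raise ConfigurationError(f"missing configuration field: {exc}") from exc
    except TypeError as exc:
        raise ConfigurationError(str(exc)) from exc
    raise ConfigurationError(f"unknown configuration mode {mode!r}")


def load_config(path: str | Path) -> ScalarConfig | MatrixConfig:
    return config_from_dict(json.loads(Path(path).read_text()))


def run_calculator(config: ScalarConfig | MatrixConfig) -> dict:
    """Full report bundle for one configuration.

    Returns a JSON-serializable dict with the Z variance, power per causal
    SNP, all expected counts and any-hit probabilities, the hold-out PGS R2,
    and attenuation versus the perfect-correlation benchmark.
    """
    panel, cgr, arch = config.to_design()
    power = power_report(panel, cgr, arch)
    pgs = pgs_r2(panel, cgr, arch)
    att = attenuation(panel, cgr, arch)
    return {
        "config": config.as_dict(),
        "power": power.as_dict(),
        "pgs": pgs.as_dict(),
        "attenuation": att.as_dict(),
    }
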