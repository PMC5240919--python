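"""Two-dimensional design grids of power and PGS R2, in tidy long format.

These tables back the contour-plot views of the theory: power per causal SNP
and hold-out PGS R2 as two design factors vary with the rest held fixed.
The ``two_set`` grid type sweeps the between-cluster CGR of a two-cluster
design (clusters internally perfectly correlated), the setting used to reason
about, e.g., cross-ancestry meta-analyses.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import pandas as pd

from .config import ScalarConfig
from .design import Architecture, clustered_design
from .theory import pgs_r2, power_report

__all__ = ["GRID_AXES", "TWO_SET_AXES", "run_grid"]

#: Axes a standard grid may sweep (fields of :class:`ScalarConfig`).
GRID_AXES = (
    "n_total",
    "n_studies",
    "h2",
    "cgr",
    "cgr_holdout",
    "h2_holdout",
)

#: Axes of the two-cluster grid.
TWO_SET_AXES = ("n_total", "rho_between")


def _standard_point(base: ScalarConfig, updates: dict) -> tuple[float, float]:
    # cgr sweeps move the hold-out correlation along unless pinned separately
    if "cgr" in updates and "cgr_holdout" not in updates:
        updates = {**updates, "cgr_holdout": updates["cgr"]}
    if "h2" in updates and "h2_holdout" not in updates:
        updates = {**updates, "h2_holdout": updates["h2"]}
    if "n_studies" in updates:
        updates = {**updates, "n_studies": int(updates["n_studies"])}
    cfg = replace(base, **updates)
    panel, cgr, arch = cfg.to_design()
    return power_report(panel, cgr, arch).beta, pgs_r2(panel, cgr, arch).r2


def _two_set_point(
    base: ScalarConfig, studies_per_cluster: int, updates: dict
) -> tuple[float, float]:
    known = {"n_total", "rho_between"}
    extra = set(updates) - known
    if extra:
        raise ValueError(
            f"unknown two-set axis {sorted(extra)}; valid axes: {sorted(known)}"
        )
    n_total = updates.get("n_total", base.n_total)
    rho_b = updates.get("rho_between", base.cgr)
    panel, cgr = clustered_design(
        n_total,
        2,
        studies_per_cluster,
        base.h2,
        1.0,
        rho_b,
        base.cgr_holdout,
        base.h2_holdout,
    )
    arch = Architecture(base.s_total, base.m_causal, base.alpha)
    return power_report(panel, cgr, arch).beta, pgs_r2(panel, cgr, arch).r2


def run_grid(
    base: ScalarConfig,
    axis1: tuple[str, Sequence[float]],
    axis2: tuple[str, Sequence[float]],
    grid_type: str = "standard",
    studies_per_cluster: int = 50,
) -> pd.DataFrame:
    """Evaluate power and R2 on the cross product of two axes.

    Returns a tidy frame with columns ``(axis1, value1, axis2, value2, beta,
    r2)`` suitable for contour plotting.  In a standard grid a ``cgr`` (or
    ``h2``) sweep carries the hold-out correlation (heritability) along with
    it, matching the one-CGR, one-h2 scalar interface; pin ``cgr_holdout`` /
    ``h2_holdout`` in ``base`` via a second axis to decouple them.
    """
    name1, vals1 = axis1
    name2, vals2 = axis2
    valid = TWO_SET_AXES if grid_type == "two_set" else GRID_AXES
    for name in (name1, name2):
        if name not in valid:
            raise ValueError(
                f"unknown axis {name!r} for grid type {grid_type!r}; "
                f"valid axes: {list(valid)}"
            )
    if grid_type not in ("standard", "two_set"):
        raise ValueError(f"unknown grid type {grid_type!r}")
    rows = []
    for v1 in vals1:
        for v2 in vals2:
            updates = {name1: v1, name2: v2}
            if grid_type == "two_set":
                beta, r2 = _two_set_point(base, studies_per_cluster, updates)
            else:
                beta, r2 = _standard_point(base, updates)
            rows.append(
                {
                    "axis1": name1,
                    "value1": v1,
                    "axis2": name2,
                    "value2": v2,
                    "beta": beta,
                    "r2": r2,
                }
            )
    return pd.DataFrame(rows)
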