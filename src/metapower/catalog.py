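"""Catalog of published study designs with their printed expected values.

Each entry names a design (a large-scale GWAS effort re-expressed as an
equal-size, constant-CGR meta-analysis, or a theoretical figure setting),
computes expected hits, hold-out PGS R2 and attenuation through the closed
forms, and compares against the values printed in the source publication at
the precision printed there.

Comparison tolerances: 2-decimal hit counts at |diff| <= 0.005, 1-decimal
percentages at 0.05 points, 0-decimal percentages at 0.5 points, and
"around"-qualified in-text values at 0.5 points.

Known discrepancies are flagged rather than hidden: the published hits
columns for the smaller designs are not reproducible from the printed
inputs (the printed 0.00 for the smallest height design is below the
alpha*(S-M) false-positive floor of the stated count formula, and designs
sharing printed h2/CGR imply mutually inconsistent Z variances), and the
large designs agree to within the rounding of the 3-digit printed inputs
(<= 0.05% relative) but not to the 0.005 absolute printed precision. All R2
and R2-attenuation cells reproduce.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .config import ScalarConfig
from .design import Architecture, clustered_design
from .theory import attenuation, pgs_r2, power_report

__all__ = ["ExpectedValue", "NamedDesign", "CATALOG", "run_all"]

# tolerance classes
TOL_HITS_2DEC = 0.005
TOL_PCT_1DEC = 0.05
TOL_PCT_0DEC = 0.5
TOL_AROUND = 0.5


@dataclass(frozen=True)
class ExpectedValue:
    """One printed value: which quantity, its printed value and tolerance."""

    quantity: str  # e.g. "hits", "hits_cgr1", "r2_pct", "beta_pct", ...
    printed: float
    tol: float
    citation: str
    known_discrepant: bool = False
    note: str = ""


@dataclass(frozen=True)
class NamedDesign:
    """A labeled design plus every printed value attached to it."""

    label: str
    config: ScalarConfig
    expected: tuple[ExpectedValue, ...]
    two_set: bool = False  # two-cluster design: config.cgr = between-cluster CGR

    def compute(self) -> dict:
        """All comparable quantities for this design."""
        if self.two_set:
            panel, cgr = clustered_design(
                self.config.n_total,
                2,
                self.config.n_studies // 2,
                self.config.h2,
                1.0,
                self.config.cgr,
                self.config.cgr_holdout,
                self.config.h2_holdout,
            )
            arch = Architecture(
                self.config.s_total, self.config.m_causal, self.config.alpha
            )
        else:
            panel, cgr, arch = self.config.to_design()
        power = power_report(panel, cgr, arch)
        pgs = pgs_r2(panel, cgr, arch)
        att = attenuation(panel, cgr, arch)
        return {
            "hits": power.expected_hits,
            "hits_cgr1": att.hits_benchmark,
            "true_pos": power.expected_true_pos,
            "beta_pct": power.beta * 100.0,
            "r2_pct": pgs.r2 * 100.0,
            "r2_cgr1_pct": att.r2_benchmark * 100.0,
            "att_hits_pct": att.hits_loss * 100.0 if att.hits_defined else float("nan"),
            "att_r2_pct": att.r2_loss * 100.0 if att.r2_defined else float("nan"),
        }


def _gwas_row(
    label: str,
    n: float,
    c: int,
    h2: float,
    rho: float,
    hits_lt: float,
    hits_eq: float,
    att_hits: float | None,
    r2_lt: float,
    r2_eq: float,
    att_r2: float,
    hits_reproducible: bool,
    citation: str,
    hits_note: str = "",
) -> NamedDesign:
    cfg = ScalarConfig(
        n_total=n,
        n_studies=c,
        h2=h2,
        cgr=rho,
        cgr_holdout=rho,
        h2_holdout=h2,
        s_total=250_000,
        m_causal=20_000,
    )
    exp = [
        ExpectedValue(
            "hits", hits_lt, TOL_HITS_2DEC, citation,
            known_discrepant=not hits_reproducible, note=hits_note,
        ),
        ExpectedValue(
            "hits_cgr1", hits_eq, TOL_HITS_2DEC, citation,
            known_discrepant=not hits_reproducible, note=hits_note,
        ),
        ExpectedValue("r2_pct", r2_lt, TOL_PCT_1DEC, citation),
        ExpectedValue("r2_cgr1_pct", r2_eq, TOL_PCT_1DEC, citation),
        ExpectedValue("att_r2_pct", att_r2, TOL_PCT_0DEC, citation),
    ]
    if att_hits is not None:
        exp.append(
            ExpectedValue(
                "att_hits_pct", att_hits, TOL_PCT_0DEC, citation,
                known_discrepant=not hits_reproducible, note=hits_note,
            )
        )
    return NamedDesign(label=label, config=cfg, expected=tuple(exp))


_SMALL_ROW_NOTE = (
    "printed hits not reproducible from printed inputs: values imply a "
    "Z variance inconsistent with same-trait rows sharing h2 and CGR"
)
_LARGE_ROW_NOTE = (
    "agrees within the sensitivity of the 3-digit printed h2/CGR inputs "
    "(<=1% relative, <=0.02% for the well-powered rows) but not to 0.005 absolute"
)

# Predicted-vs-observed table for large-scale GWAS efforts (theory columns):
# equal-size designs, S = 250k blocks, M = 20k causal, alpha = 5e-8.
_TABLE_ROWS = [
    _gwas_row("height_wood_2014", 253_288, 79, 0.449, 0.965,
              647.26, 700.24, 8.0, 13.2, 14.0, 6.0, False,
              "published theory table, height row 1", _LARGE_ROW_NOTE),
    _gwas_row("height_allen_2010", 183_727, 61, 0.449, 0.965,
              292.03, 320.77, 9.0, 10.5, 11.1, 6.0, False,
              "published theory table, height row 2", _LARGE_ROW_NOTE),
    _gwas_row("height_weedon_2008", 13_665, 5, 0.449, 0.965,
              0.00, 0.00, None, 1.0, 1.1, 7.0, False,
              "published theory table, height row 3",
              "printed 0.00 lies below the alpha*(S-M)=0.0115 false-positive floor"),
    _gwas_row("bmi_locke_2015", 339_224, 125, 0.219, 0.917,
              188.52, 241.07, 22.0, 4.3, 5.0, 14.0, False,
              "published theory table, BMI row 1", _LARGE_ROW_NOTE),
    _gwas_row("bmi_speliotes_2010", 123_865, 46, 0.219, 0.917,
              5.48, 7.64, 28.0, 1.8, 2.1, 15.0, False,
              "published theory table, BMI row 2", _LARGE_ROW_NOTE),
    _gwas_row("bmi_willer_2008", 32_387, 15, 0.219, 0.917,
              0.01, 0.02, 65.0, 0.5, 0.6, 16.0, False,
              "published theory table, BMI row 3", _SMALL_ROW_NOTE),
    _gwas_row("eduyears_okbay_2016_pooled", 405_072, 65, 0.182, 0.783,
              115.28, 235.90, 51.0, 2.7, 4.1, 36.0, False,
              "published theory table, EduYears row 1", _LARGE_ROW_NOTE),
    _gwas_row("eduyears_okbay_2016_discovery", 293_723, 64, 0.182, 0.783,
              39.30, 88.93, 56.0, 2.0, 3.2, 36.0, False,
              "published theory table, EduYears row 2", _LARGE_ROW_NOTE),
    _gwas_row("eduyears_rietveld_2013", 101_069, 42, 0.182, 0.783,
              0.63, 1.64, 62.0, 0.8, 1.2, 38.0, False,
              "published theory table, EduYears row 3", _SMALL_ROW_NOTE),
    _gwas_row("health_harris_2016", 111_749, 1, 0.157, 0.468,
              1.35, 1.35, 0.0, 0.2, 1.0, 78.0, False,
              "published theory table, self-rated health row",
              "documented discrepancy: reconstruction gives ~1.39 or 1.40 vs printed 1.35"),
]

# Harris attenuation-of-hits is exactly 0 for C=1 (among-study CGR is trivial)
# and does reproduce; undo the blanket flag for that single cell.
_hr = _TABLE_ROWS[-1]
_TABLE_ROWS[-1] = NamedDesign(
    label=_hr.label,
    config=_hr.config,
    expected=tuple(
        ExpectedValue(e.quantity, e.printed, e.tol, e.citation, False, "")
        if e.quantity == "att_hits_pct"
        else e
        for e in _hr.expected
    ),
)


def _fig_design(
    label: str,
    n_total: float,
    c: int,
    h2: float,
    rho: float,
    expected: list[ExpectedValue],
    *,
    h2_holdout: float | None = None,
    s_total: int = 100_000,
    m_causal: int = 1_000,
    two_set: bool = False,
) -> NamedDesign:
    cfg = ScalarConfig(
        n_total=n_total,
        n_studies=c,
        h2=h2,
        cgr=rho,
        cgr_holdout=rho,
        h2_holdout=h2 if h2_holdout is None else h2_holdout,
        s_total=s_total,
        m_causal=m_causal,
    )
    return NamedDesign(label=label, config=cfg, expected=tuple(expected), two_set=two_set)


# In-text contour-figure values: 50-study (or varying-C) designs, 100k blocks,
# 1k causal, alpha = 5e-8.
_FIGURE_DESIGNS = [
    _fig_design("fig_sample_size_cgr1", 1e7, 50, 0.5, 1.0, [
        ExpectedValue("beta_pct", 94.0, TOL_PCT_0DEC, "in-text, sample-size figure"),
        ExpectedValue("r2_pct", 49.0, TOL_PCT_0DEC, "in-text, sample-size figure"),
    ]),
    _fig_design("fig_sample_size_cgr02", 1e7, 50, 0.5, 0.2, [
        ExpectedValue("beta_pct", 87.0, TOL_PCT_0DEC, "in-text, sample-size figure"),
        ExpectedValue("r2_pct", 8.5, TOL_PCT_1DEC, "in-text, sample-size figure"),
    ]),
    _fig_design("fig_h2_cgr_a", 250_000, 50, 0.25, 0.5, [
        ExpectedValue("beta_pct", 34.0, TOL_AROUND, "in-text, h2-vs-CGR figure ('around 34%')"),
        ExpectedValue("r2_pct", 3.0, TOL_PCT_1DEC, "in-text, h2-vs-CGR figure"),
    ]),
    _fig_design("fig_h2_cgr_b", 250_000, 50, 0.5, 0.25, [
        ExpectedValue("beta_pct", 35.0, TOL_AROUND, "in-text, h2-vs-CGR figure"),
        ExpectedValue("r2_pct", 2.9, TOL_PCT_1DEC, "in-text, h2-vs-CGR figure"),
    ]),
    _fig_design("fig_nstudies_c1", 250_000, 1, 0.5, 0.5, [
        ExpectedValue("beta_pct", 63.0, TOL_PCT_0DEC, "in-text, number-of-studies figure"),
        ExpectedValue("r2_pct", 6.9, TOL_PCT_1DEC, "in-text, number-of-studies figure"),
    ]),
    _fig_design("fig_nstudies_c2", 250_000, 2, 0.5, 0.5, [
        ExpectedValue("beta_pct", 58.0, TOL_PCT_0DEC, "in-text, number-of-studies figure"),
        ExpectedValue("r2_pct", 8.1, TOL_PCT_1DEC, "in-text, number-of-studies figure"),
    ]),
    _fig_design("fig_nstudies_c10", 250_000, 10, 0.5, 0.5, [
        ExpectedValue("beta_pct", 51.0, TOL_PCT_0DEC, "in-text, number-of-studies figure"),
        ExpectedValue("r2_pct", 9.3, TOL_PCT_1DEC, "in-text, number-of-studies figure"),
    ]),
    _fig_design("fig_nstudies_c100", 250_000, 100, 0.5, 0.5, [
        ExpectedValue("beta_pct", 50.0, TOL_PCT_0DEC, "in-text, number-of-studies figure"),
        ExpectedValue("r2_pct", 9.6, TOL_PCT_1DEC, "in-text, number-of-studies figure"),
    ]),
    _fig_design("fig_holdout_h2_low", 250_000, 50, 0.5, 0.8, [
        ExpectedValue("r2_pct", 10.0, TOL_PCT_0DEC, "in-text, hold-out-h2 figure"),
    ], h2_holdout=0.25),
    _fig_design("fig_holdout_h2_high", 250_000, 50, 0.25, 0.8, [
        ExpectedValue("r2_pct", 13.0, TOL_PCT_0DEC, "in-text, hold-out-h2 figure"),
    ], h2_holdout=0.5),
    _fig_design("fig_two_set_rho0", 250_000, 100, 0.5, 0.0, [
        ExpectedValue("beta_pct", 49.0, TOL_PCT_0DEC, "in-text, two-set figure"),
    ], two_set=True),
    _fig_design("fig_two_set_rho05", 250_000, 100, 0.5, 0.5, [
        ExpectedValue("beta_pct", 58.0, TOL_PCT_0DEC, "in-text, two-set figure"),
    ], two_set=True),
]

CATALOG: tuple[NamedDesign, ...] = tuple(_TABLE_ROWS + _FIGURE_DESIGNS)


def run_all(catalog: tuple[NamedDesign, ...] = CATALOG) -> pd.DataFrame:
    """Compute every catalog design and compare with its printed values.

    Returns one row per printed value with columns label, quantity, printed,
    computed, tol, matches, known_discrepant, note, citation.  Failures are
    reported, never raised.
    """
    rows = []
    for design in catalog:
        computed = design.compute()
        for exp in design.expected:
            value = computed[exp.quantity]
            matches = bool(abs(value - exp.printed) <= exp.tol)
            rows.append(
                {
                    "label": design.label,
                    "quantity": exp.quantity,
                    "printed": exp.printed,
                    "computed": value,
                    "tol": exp.tol,
                    "matches": matches,
                    "known_discrepant": exp.known_discrepant,
                    "note": exp.note,
                    "citation": exp.citation,
                }
            )
    return pd.DataFrame(rows)
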