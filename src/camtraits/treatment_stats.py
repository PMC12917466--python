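"""Non-phylogenetic statistics: treatment effects and cross-species regressions.

Covers the percent-change effect matrix (treatment vs control, reversal
vs treatment, per taxon), Welch t-tests of those contrasts, and ordinary
least-squares regressions of species-mean nocturnal acidification against
log minimum conductance, degree of succulence and leaf thickness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from camtraits.design import CONTROL_OF
from camtraits.errors import InsufficientDataError


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    slope_t: float
    intercept_t: float
    slope_p: float
    intercept_p: float
    r: float
    r_squared: float
    n: int
    x_transform: str  # "none" | "log"


def sampling_coverage(n_sampled: int, n_total: int) -> float:
    """Percent of the study group's species diversity sampled (0–100)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return 100.0 * n_sampled / n_total


def percent_change(mean_treatment: float, mean_reference: float) -> float:
    """Percent change of a treatment mean relative to a reference mean.

    100 · (treatment − reference) / |reference|; undefined (ValueError)
    for a zero reference.
    """
    if mean_reference == 0:
        raise ValueError("percent change undefined for zero reference mean")
    return 100.0 * (mean_treatment - mean_reference) / abs(mean_reference)


def treatment_effect_test(
    values_a,
    values_b,
    paired: bool = False,
) -> tuple[float, float, float]:
    """Two-sided t-test of two replicate sets; Welch by default.

    Returns ``(t, p, df)``.  With ``paired=True`` a paired t-test on the
    common individuals is used instead.  Fewer than two values per side
    raises :class:`InsufficientDataError` — single-replicate taxa get a
    flag, not a test.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if paired:
        if a.size != b.size or a.size < 2:
            raise InsufficientDataError("paired test needs ≥ 2 pairs")
        res = stats.ttest_rel(a, b)
        df = float(a.size - 1)
    else:
        if a.size < 2 or b.size < 2:
            raise InsufficientDataError("need ≥ 2 values per side")
        if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
            # identical constant samples: no evidence of a difference
            return 0.0, 1.0, float(a.size + b.size - 2)
        res = stats.ttest_ind(a, b, equal_var=False)
        df = float(res.df)
    return float(res.statistic), float(res.pvalue), df


def comparison_plan(design_table: pd.DataFrame) -> list[dict]:
    """Enumerate the taxon-level contrasts implied by the factorial design.

    ``design_table`` needs columns ``taxon``, ``group``, ``phase`` (one
    row per available cell).  For every treated group: the treatment
    phase is compared against the matching control group's treatment
    phase, and the reversal phase against the same group's treatment
    phase.  Control groups generate no comparisons.  A missing reference
    cell yields a comparison flagged ``missing`` rather than a dropped
    row.
    """
    cells = {
        (r.taxon, r.group, r.phase) for r in design_table.itertuples(index=False)
    }
    taxa = sorted({t for t, _, _ in cells})
    plan: list[dict] = []
    for taxon in taxa:
        for group, control in CONTROL_OF.items():
            for phase, ref in (
                ("treatment", (control, "treatment")),
                ("reversal", (group, "treatment")),
            ):
                if (taxon, group, phase) not in cells:
                    continue
                ref_group, ref_phase = ref
                plan.append(
                    {
                        "taxon": taxon,
                        "group": group,
                        "phase": phase,
                        "reference_group": ref_group,
                        "reference_phase": ref_phase,
                        "missing_reference": (taxon, ref_group, ref_phase) not in cells,
                    }
                )
    return plan


def build_effect_matrix(delta_h_long: pd.DataFrame) -> pd.DataFrame:
    """Percent-change effect matrix with significance flags, one row per contrast.

    Input is the long ΔH⁺ table from
    :func:`camtraits.titration.build_delta_h_table`.  Each row carries
    the percent change of mean ΔH⁺ for the contrast, Welch t statistic
    and two-sided p where both sides have ≥ 2 replicates, and a flag:
    ``significant`` (p < 0.05), ``ns``, ``n1`` (single replicate on a
    side — the effect is reported without a test), ``missing`` (no
    reference data) or ``undefined`` (zero reference mean).
    """
    plan = comparison_plan(delta_h_long[["taxon", "group", "phase"]].drop_duplicates())
    grouped = delta_h_long.groupby(["taxon", "group", "phase"])["delta_h_umol_g"]
    values = {k: np.asarray(v) for k, v in grouped}
    rows = []
    for c in plan:
        key = (c["taxon"], c["group"], c["phase"])
        ref_key = (c["taxon"], c["reference_group"], c["reference_phase"])
        row = dict(c)
        row.update(
            {"percent_change": np.nan, "t": np.nan, "p": np.nan,
             "n": len(values.get(key, ())), "n_reference": len(values.get(ref_key, ()))}
        )
        if c["missing_reference"] or ref_key not in values:
            row["flag"] = "missing"
        else:
            a, b = values[key], values[ref_key]
            ref_mean = float(np.mean(b))
            if ref_mean == 0:
                row["flag"] = "undefined"
            else:
                row["percent_change"] = percent_change(float(np.mean(a)), ref_mean)
                if len(a) < 2 or len(b) < 2:
                    row["flag"] = "n1"
                else:
                    t, p, _ = treatment_effect_test(a, b)
                    row.update({"t": t, "p": p})
                    row["flag"] = "significant" if p < 0.05 else "ns"
        rows.append(row)
    return pd.DataFrame(rows)


def ols_regression(x, y, x_transform: str = "none") -> RegressionFit:
    """Ordinary least squares of y on x with optional natural-log transform of x.

    Classical (non-robust) standard errors; two-sided t tests; requires
    n ≥ 3.  ``x_transform="log"`` demands strictly positive x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InsufficientDataError("regression needs ≥ 3 aligned observations")
    if x_transform == "log":
        if np.any(x <= 0):
            raise ValueError("log transform requires strictly positive x")
        x = np.log(x)
    elif x_transform != "none":
        raise ValueError(f"unknown x_transform {x_transform!r}")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    slope, intercept = float(model.params[1]), float(model.params[0])
    r = float(np.corrcoef(x, y)[0, 1])
    return RegressionFit(
        slope=slope,
        intercept=intercept,
        slope_se=float(model.bse[1]),
        intercept_se=float(model.bse[0]),
        slope_t=float(model.tvalues[1]),
        intercept_t=float(model.tvalues[0]),
        slope_p=float(model.pvalues[1]),
        intercept_p=float(model.pvalues[0]),
        r=r,
        r_squared=float(model.rsquared),
        n=int(x.size),
        x_transform=x_transform,
    )
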