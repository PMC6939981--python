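"""Validation statistics: Pearson r, ICC(2,1), t-test, ANOVA, agreement report.

The agreement report mirrors the sensitivity-analysis layout used when a
tilt-correction method is validated against images of known tilt: means
(sd) of actual and measured tilt, their difference and absolute
difference, the fraction of errors under 5 degrees, direction accuracy,
Pearson correlation and a two-sample t-test between the actual and
measured means, with subgrouping by sex and by excluding tilts that are
multiples of 5 degrees (i.e. the calibration orientations themselves).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

DIRECTION_THRESHOLD_DEG = 2.0  # near-zero tilts carry no meaningful direction
AGREEMENT_BOUND_DEG = 5.0


def pearson_r(x, y, return_p: bool = False):
    """Product-moment correlation; constant input is an explicit error."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("correlation undefined for constant input")
    res = sps.pearsonr(x, y)
    return (float(res.statistic), float(res.pvalue)) if return_p else float(res.statistic)


def icc_2_1(ratings) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    ``ratings`` is an (n subjects x k raters) matrix with no missing cells.
    From the two-way ANOVA mean squares (rows MSR, columns MSC, error MSE):

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    """
    m = np.asarray(ratings, float)
    if m.ndim != 2:
        raise ValueError("ratings must be a 2-D (subjects x raters) matrix")
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 raters")
    if np.isnan(m).any():
        raise ValueError("missing cells are not supported")
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0.0:
        return 1.0  # all ratings identical: perfect agreement
    return float((msr - mse) / denom)


def t_test_two_sample(a, b, pooled: bool = True) -> tuple[float, float]:
    """Two-sided two-sample t-test (Student by default, Welch optional)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
        if a[0] == b[0]:
            return 0.0, 1.0  # identical constants: no evidence of difference
        raise ValueError("degenerate test: zero variance with unequal means")
    res = sps.ttest_ind(a, b, equal_var=pooled)
    return float(res.statistic), float(res.pvalue)


def one_way_anova(groups: Sequence) -> tuple[float, float]:
    """Single-factor ANOVA F and upper-tail p across >= 2 groups."""
    gs = [np.asarray(g, float) for g in groups]
    if len(gs) < 2 or any(len(g) < 2 for g in gs):
        raise ValueError("need >= 2 groups with >= 2 values each")
    if all(np.ptp(g) == 0.0 for g in gs):
        raise ValueError("degenerate ANOVA: all groups have zero variance")
    res = sps.f_oneway(*gs)
    return float(res.statistic), float(res.pvalue)


@dataclass
class ValidationReport:
    """One subgroup row of the actual-vs-measured agreement analysis."""

    label: str
    n: int
    mean_actual: float
    sd_actual: float
    mean_measured: float
    sd_measured: float
    mean_diff: float
    sd_diff: float
    abs_mean_diff: float
    sd_abs_diff: float
    pct_within_5deg: float
    direction_accuracy_pct: float
    direction_threshold_deg: float
    n_direction: int
    pearson_r: float
    t_p_value: float

    def __post_init__(self) -> None:
        for pct in (self.pct_within_5deg, self.direction_accuracy_pct):
            if math.isfinite(pct) and not 0.0 <= pct <= 100.0:
                raise ValueError("percentages must lie in [0, 100]")
        if math.isfinite(self.pearson_r) and abs(self.pearson_r) > 1.0 + 1e-12:
            raise ValueError("|pearson_r| must be <= 1")

    def as_dict(self) -> dict:
        return asdict(self)


def validation_report(
    actual,
    measured,
    label: str = "all",
    direction_threshold_deg: float = DIRECTION_THRESHOLD_DEG,
    agreement_bound_deg: float = AGREEMENT_BOUND_DEG,
) -> ValidationReport:
    """Full agreement statistics between true and estimated tilt (degrees).

    ``mean_diff`` is measured - actual; ``pct_within_5deg`` counts strict
    |difference| < 5 deg; direction accuracy is evaluated only where
    |actual| >= the threshold (default 2 deg) and is NaN when no case
    qualifies.  Standard deviations use ddof = 1.
    """
    a = np.asarray(actual, float)
    m = np.asarray(measured, float)
    if a.shape != m.shape or a.ndim != 1:
        raise ValueError("actual and measured must be 1-D arrays of equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 paired observations")
    diff = m - a
    adiff = np.abs(diff)
    sel = np.abs(a) >= direction_threshold_deg
    if sel.any():
        direction = float(np.mean(np.sign(m[sel]) == np.sign(a[sel])) * 100.0)
    else:
        direction = math.nan
    try:
        r = pearson_r(a, m)
    except ValueError:
        r = math.nan
    _, p = t_test_two_sample(a, m)
    return ValidationReport(
        label=label,
        n=int(len(a)),
        mean_actual=float(a.mean()),
        sd_actual=float(a.std(ddof=1)),
        mean_measured=float(m.mean()),
        sd_measured=float(m.std(ddof=1)),
        mean_diff=float(diff.mean()),
        sd_diff=float(diff.std(ddof=1)),
        abs_mean_diff=float(adiff.mean()),
        sd_abs_diff=float(adiff.std(ddof=1)),
        pct_within_5deg=float(np.mean(adiff < agreement_bound_deg) * 100.0),
        direction_accuracy_pct=direction,
        direction_threshold_deg=float(direction_threshold_deg),
        n_direction=int(sel.sum()),
        pearson_r=r,
        t_p_value=float(p),
    )


def _is_multiple_of_5(x: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    return np.abs(x - 5.0 * np.round(x / 5.0)) <= tol


def validation_table(
    rows: pd.DataFrame,
    direction_threshold_deg: float = DIRECTION_THRESHOLD_DEG,
) -> pd.DataFrame:
    """Subgroup agreement table from per-image validation rows.

    ``rows`` needs columns true_tilt_deg, estimated_tilt_deg and sex.
    Subgroups: all, per sex, non-multiples-of-5 (overall and per sex);
    subgroups with fewer than 2 rows are omitted.
    """
    required = {"true_tilt_deg", "estimated_tilt_deg", "sex"}
    if not required.issubset(rows.columns):
        raise ValueError(f"rows must have columns {sorted(required)}")
    tilt = rows["true_tilt_deg"].to_numpy(float)
    masks: list[tuple[str, np.ndarray]] = [("all", np.ones(len(rows), bool))]
    for sex in ("male", "female"):
        masks.append((sex, (rows["sex"] == sex).to_numpy()))
    non5 = ~_is_multiple_of_5(tilt)
    masks.append(("non_multiples_of_5", non5))
    for sex in ("male", "female"):
        masks.append((f"{sex}_non_multiples_of_5", non5 & (rows["sex"] == sex).to_numpy()))
    reports = []
    for label, mask in masks:
        if mask.sum() < 2:
            continue
        reports.append(
            validation_report(
                tilt[mask],
                rows["estimated_tilt_deg"].to_numpy(float)[mask],
                label=label,
                direction_threshold_deg=direction_threshold_deg,
            ).as_dict()
        )
    return pd.DataFrame(reports)


def write_report(table: pd.DataFrame, path: str | Path) -> None:
    """Serialize a subgroup report as TSV or JSON depending on suffix."""
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(table.to_dict(orient="records"), indent=1))
    else:
        table.to_csv(path, sep="\t", index=False)
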