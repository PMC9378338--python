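"""Reliability statistics for the measurement suite.

Implements the statistical toolkit used to validate topographic trunk
measurements: ICC(2,1) — two-way random effects, absolute agreement, single
measurement (McGraw & Wong) — with F-based 95% confidence intervals, RMS
(quadratic-mean) error, a Spearman screen of measurement consistency
against BMI with Bonferroni-Holm correction, and paired comparison of ICC
sets.

Study tables are long-format DataFrames with columns
``subject, rater, placement, trial, parameter, value``: placement 0 is the
first stand (its two trials are the test-retest pair), placement 1 the
re-placed stand (remove-replace pair = first trial of each placement).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05


@dataclass
class IccResult:
    """ICC(2,1) point estimate with 95% CI and the two-way mean squares."""

    icc: float
    ci_low: float
    ci_high: float
    ms_rows: float
    ms_cols: float
    ms_error: float
    n: int
    k: int


def icc_2_1(table: np.ndarray, alpha: float = ALPHA) -> IccResult:
    """ICC(2,1): absolute agreement of single ratings, two-way random model.

    ``table`` is n subjects x k raters, complete.  The estimate is

        (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

    with the standard F-quantile confidence bounds.  Negative estimates are
    reported as computed (not clamped).
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2:
        raise ValueError("rating table must be 2-D (subjects x raters)")
    n, k = x.shape
    if n < 3 or k < 2:
        raise ValueError("need n >= 3 subjects and k >= 2 raters")
    if np.any(~np.isfinite(x)):
        raise ValueError("rating table has missing cells")
    grand = x.mean()
    row_m = x.mean(axis=1)
    col_m = x.mean(axis=0)
    ss_rows = k * np.sum((row_m - grand) ** 2)
    ss_cols = n * np.sum((col_m - grand) ** 2)
    ss_tot = np.sum((x - grand) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if abs(denom) < 1e-300 or ss_tot < 1e-300:
        raise ValueError("zero total variance: ICC undefined")
    icc = (msr - mse) / denom

    # F-based CI (McGraw & Wong): Satterthwaite df for the column+error mix
    a = (k * icc) / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + (k * icc * (n - 1)) / (n * (1 - icc)) if icc < 1 else np.inf
    if np.isfinite(a) and (a * msc + b * mse) > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1)))
    else:
        v = (n - 1) * (k - 1)
    f_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
    lo = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - n - k) * mse) + n * msr)
    hi = n * (f_u * msr - mse) / (
        k * msc + (k * n - n - k) * mse + n * f_u * msr)
    lo, hi = min(lo, icc), max(hi, icc)
    return IccResult(icc=float(icc), ci_low=float(lo), ci_high=float(hi),
                     ms_rows=float(msr), ms_cols=float(msc), ms_error=float(mse),
                     n=n, k=k)


def rms_error(values, reference) -> float:
    """Quadratic mean of (value - reference) differences; same units as input."""
    values = np.asarray(values, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if values.size == 0:
        raise ValueError("rms_error needs at least one value")
    if values.shape != reference.shape:
        raise ValueError("values and reference must have equal length")
    d = values - reference
    return float(np.sqrt(np.mean(d ** 2)))


def holm_reject(pvals, alpha: float = ALPHA) -> np.ndarray:
    """Bonferroni-Holm step-down rejections at family level alpha."""
    from statsmodels.stats.multitest import multipletests

    reject, *_ = multipletests(np.asarray(pvals, dtype=float), alpha=alpha,
                               method="holm")
    return reject


INTRINSIC_KEYS = ("spine_length", "back_area", "xsa", "xsv")


def is_intrinsic(parameter: str) -> bool:
    return any(key in parameter for key in INTRINSIC_KEYS)


def consistency_vs_bmi(measurements: pd.DataFrame, bmi: dict,
                       alpha: float = ALPHA) -> pd.DataFrame:
    """Spearman screen: does inter-rater consistency depend on body type?

    Consistency per subject and parameter is |(rA - rB)/mean| for intrinsic
    measures and |rA - rB| for pose-dependent ones, computed from each
    rater's first scan.  Returns a per-parameter frame with columns
    ``rho, p, holm_reject`` (Holm at family level ``alpha``).
    """
    first = measurements[(measurements["placement"] == 0) &
                         (measurements["trial"] == 0)]
    rows = []
    for param, grp in first.groupby("parameter", sort=True):
        wide = grp.pivot_table(index="subject", columns="rater", values="value")
        if wide.shape[1] < 2:
            raise ValueError(f"parameter {param}: need two raters")
        wide = wide.dropna()
        if len(wide) < 4:
            raise ValueError(f"parameter {param}: fewer than 4 subjects")
        ra, rb = wide.iloc[:, 0].to_numpy(), wide.iloc[:, 1].to_numpy()
        if is_intrinsic(param):
            mean = 0.5 * (ra + rb)
            cons = np.abs((ra - rb) / np.where(np.abs(mean) > 1e-12, mean, np.nan))
        else:
            cons = np.abs(ra - rb)
        bmis = np.array([bmi[s] for s in wide.index])
        ok = np.isfinite(cons)
        rho, p = sps.spearmanr(bmis[ok], cons[ok])
        rows.append((param, float(rho), float(p)))
    out = pd.DataFrame(rows, columns=["parameter", "rho", "p"]).set_index("parameter")
    out["holm_reject"] = holm_reject(out["p"].to_numpy(), alpha=alpha)
    return out


def compare_icc_sets(iccs_a, iccs_b, paired: bool = True):
    """Paired two-tailed t test between two sets of ICCs; returns (t, df, p).

    Degenerate inputs follow a documented convention: zero variance of the
    differences yields (0, n-1, 1.0) when the mean difference is also zero,
    and (+-inf, n-1, 0.0) otherwise.
    """
    a = np.asarray(iccs_a, dtype=float)
    b = np.asarray(iccs_b, dtype=float)
    if not paired:
        t, p = sps.ttest_ind(a, b)
        return float(t), len(a) + len(b) - 2, float(p)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired comparison needs equal-length sets, n >= 2")
    d = a - b
    df = len(d) - 1
    if np.std(d, ddof=1) < 1e-15:
        if abs(d.mean()) < 1e-15:
            return 0.0, df, 1.0
        return float(np.sign(d.mean()) * np.inf), df, 0.0
    t, p = sps.ttest_rel(a, b)
    return float(t), df, float(p)


# ---------------------------------------------------------------------------
# study-level report
# ---------------------------------------------------------------------------

def _rating_matrix(df: pd.DataFrame, selectors: list) -> np.ndarray | None:
    """Subjects x conditions matrix; each selector is a {column: value} dict."""
    mats = []
    for sel in selectors:
        mask = np.ones(len(df), dtype=bool)
        for col, val in sel.items():
            mask &= (df[col] == val).to_numpy()
        mats.append(df[mask].set_index("subject")["value"])
    wide = pd.concat(mats, axis=1, join="inner")
    if wide.isna().any().any() or len(wide) < 3:
        return None
    return wide.to_numpy()


def reliability_report(study: pd.DataFrame) -> pd.DataFrame:
    """Per-parameter reliability table from a long-format study.

    For every parameter: intra-rater test-retest and remove-replace ICCs
    per rater, the inter-rater ICC with 95% CI, and the grand mean/SD over
    all scans.  Incomplete designs are skipped per parameter with a log
    entry.  Scan-pair policy: test-retest = the two trials of placement 0;
    remove-replace = first trial of each placement; inter-rater = each
    rater's first scan.
    """
    from .geometry import logger

    required = {"subject", "rater", "placement", "trial", "parameter", "value"}
    missing = required - set(study.columns)
    if missing:
        raise ValueError(f"study table missing columns: {sorted(missing)}")
    raters = sorted(study["rater"].unique())
    rows = []
    for param, grp in study.groupby("parameter", sort=True):
        rec = {"parameter": param,
               "grand_mean": float(grp["value"].mean()),
               "grand_sd": float(grp["value"].std(ddof=1))}

        def icc_or_nan(matrix, label):
            if matrix is None:
                logger.warning("reliability_report: %s %s has incomplete "
                               "design cells", param, label)
                return np.nan
            try:
                return icc_2_1(matrix).icc
            except ValueError as exc:
                logger.warning("reliability_report: %s %s skipped (%s)",
                               param, label, exc)
                return np.nan

        for rater in raters:
            sub = grp[grp["rater"] == rater]
            tr = _rating_matrix(sub, [{"placement": 0, "trial": 0},
                                      {"placement": 0, "trial": 1}])
            rr = _rating_matrix(sub, [{"placement": 0, "trial": 0},
                                      {"placement": 1, "trial": 0}])
            rec[f"icc_intra_{rater}_test_retest"] = icc_or_nan(
                tr, f"intra-{rater} test-retest")
            rec[f"icc_intra_{rater}_remove_replace"] = icc_or_nan(
                rr, f"intra-{rater} remove-replace")
        inter = _rating_matrix(
            grp, [{"rater": rater, "placement": 0, "trial": 0}
                  for rater in raters])
        rec["icc_inter"] = np.nan
        rec["icc_inter_ci_low"] = np.nan
        rec["icc_inter_ci_high"] = np.nan
        if inter is not None:
            try:
                res = icc_2_1(inter)
                rec["icc_inter"] = res.icc
                rec["icc_inter_ci_low"] = res.ci_low
                rec["icc_inter_ci_high"] = res.ci_high
            except ValueError as exc:
                logger.warning("reliability_report: %s inter-rater skipped "
                               "(%s)", param, exc)
        rows.append(rec)
    return pd.DataFrame(rows).set_index("parameter")
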