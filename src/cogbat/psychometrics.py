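"""Validation statistics: paired comparisons, convergent correlations with a
normality-adaptive coefficient, and test-retest ICC.

The paired comparison is the two-condition within-subject ANOVA (its F is
exactly the square of the paired t).  Convergent correlations use Pearson's
r when both variables pass Shapiro-Wilk normality at the chosen alpha and
Kendall's tau otherwise.  Test-retest reliability is the single-rater,
absolute-agreement intraclass correlation from the two-way repeated-measures
decomposition, ICC = (MSR - MSE) / (MSR + (k-1)MSE + (k/n)(MSC - MSE)).
Effect-size bands follow the conventional cut points (0.1/0.3/0.5 for
correlations; 0.5/0.75/0.90 for ICC, inclusive lower edges).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SchemaError


@dataclass
class PairedComparison:
    metric: str
    mean_a: float
    mean_b: float
    f_statistic: float
    p_value: float
    n: int
    degenerate: bool = False


@dataclass
class CorrelationResult:
    pair: tuple
    coefficient_type: str  # "pearson" | "kendall_tau"
    estimate: float
    p_value: float
    n: int
    band: str


@dataclass
class IccResult:
    metric: str
    icc: float
    p_value: float
    n: int
    band: str
    undefined: bool = False


def correlation_band(r: float) -> str:
    a = abs(r)
    if a >= 0.5:
        return "large"
    if a >= 0.3:
        return "medium"
    if a >= 0.1:
        return "small"
    return "none"


def icc_band(icc: float) -> str:
    if icc >= 0.90:
        return "excellent"
    if icc >= 0.75:
        return "good"
    if icc >= 0.5:
        return "moderate"
    return "poor"


def paired_f(a, b, metric: str = "") -> PairedComparison:
    """Two-condition repeated-measures ANOVA; F equals the paired t squared."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise SchemaError("paired vectors must have equal length")
    n = len(a)
    if n < 3:
        raise SchemaError("paired comparison needs n >= 3")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return PairedComparison(metric, float(a.mean()), float(b.mean()),
                                    0.0, 1.0, n)
        return PairedComparison(metric, float(a.mean()), float(b.mean()),
                                float("inf"), 0.0, n, degenerate=True)
    t = d.mean() / (sd / np.sqrt(n))
    f = float(t * t)
    p = float(stats.f.sf(f, 1, n - 1))
    return PairedComparison(metric, float(a.mean()), float(b.mean()), f, p, n)


def convergent_correlation(
    a, b, normality_alpha: float = 0.05, pair: tuple = ("a", "b"),
    force: Optional[str] = None,
) -> CorrelationResult:
    """Correlation with the coefficient chosen by a normality gate.

    Shapiro-Wilk runs on both vectors; if either rejects normality at
    ``normality_alpha`` the coefficient is Kendall's tau, otherwise
    Pearson's r.  ``force`` overrides the gate ("pearson"/"kendall_tau").
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) != len(b) or len(a) < 5:
        raise SchemaError("correlation needs paired vectors with n >= 5")
    if a.std(ddof=1) == 0 or b.std(ddof=1) == 0:
        raise ZeroDivisionError("correlation undefined for zero-variance input")
    if force is None:
        normal = (stats.shapiro(a).pvalue >= normality_alpha
                  and stats.shapiro(b).pvalue >= normality_alpha)
        kind = "pearson" if normal else "kendall_tau"
    else:
        kind = force
    if kind == "pearson":
        r, p = stats.pearsonr(a, b)
    elif kind == "kendall_tau":
        r, p = stats.kendalltau(a, b)
    else:
        raise ValueError(f"unknown coefficient {kind!r}")
    return CorrelationResult(pair, kind, float(r), float(p), len(a),
                             correlation_band(float(r)))


def icc_absolute_agreement(occ1, occ2, metric: str = "") -> IccResult:
    """Single-rater absolute-agreement ICC from two measurement occasions.

    Computed from the two-way ANOVA mean squares with k = 2 occasions:
    (MSR - MSE) / (MSR + (k-1)MSE + (k/n)(MSC - MSE)).  The p-value comes
    from F = MSR/MSE on (n-1, (n-1)(k-1)) df.  Zero between-subject variance
    leaves the coefficient undefined and flagged.
    """
    y = np.column_stack([np.asarray(occ1, float), np.asarray(occ2, float)])
    n, k = y.shape
    if n < 5:
        raise SchemaError("ICC needs n >= 5 subjects")
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if msr == 0 and mse == 0:
        return IccResult(metric, float("nan"), float("nan"), n, "poor",
                         undefined=True)
    if denom == 0:
        icc = 1.0 if mse == 0 else float("nan")
        return IccResult(metric, icc, 0.0 if icc == 1.0 else float("nan"),
                         n, icc_band(icc) if np.isfinite(icc) else "poor",
                         undefined=not np.isfinite(icc))
    icc = float((msr - mse) / denom)
    if mse == 0:
        p = 0.0
    else:
        p = float(stats.f.sf(msr / mse, n - 1, (n - 1) * (k - 1)))
    return IccResult(metric, icc, p, n, icc_band(icc))


# --------------------------------------------------------------- report ---
REQUIRED_COLUMNS = ("participant", "task", "version", "occasion")


class ValidationReport:
    """Cohort-level validation output: paired comparisons, convergent
    correlations, and retest ICCs, as DataFrames plus a text rendering."""

    def __init__(self, paired: pd.DataFrame, correlations: pd.DataFrame,
                 icc: pd.DataFrame, n_tests: int):
        self.paired = paired
        self.correlations = correlations
        self.icc = icc
        self.n_tests = n_tests

    def to_text(self) -> str:
        parts = ["Cohort validation report", "=" * 60]
        for name, df in (("Paired gamified-vs-standard comparisons", self.paired),
                         ("Convergent correlations", self.correlations),
                         ("Test-retest ICC (absolute agreement)", self.icc)):
            parts.append(f"\n{name}:")
            parts.append(df.to_string(index=False) if len(df) else "  (no data)")
        parts.append(f"\nstatistical tests run: {self.n_tests} "
                     "(no multiple-comparison correction applied)")
        return "\n".join(parts) + "\n"

    def save(self, outdir) -> None:
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.paired.to_csv(out / "paired_comparisons.csv", index=False)
        self.correlations.to_csv(out / "correlations.csv", index=False)
        self.icc.to_csv(out / "icc.csv", index=False)
        (out / "report.txt").write_text(self.to_text())


def _metric_columns(cohort: pd.DataFrame) -> list:
    return [
        c for c in cohort.columns
        if c not in REQUIRED_COLUMNS
        and pd.api.types.is_numeric_dtype(cohort[c])
    ]


def validation_report(cohort: pd.DataFrame,
                      normality_alpha: float = 0.05) -> ValidationReport:
    """Build the full validation report from a scored, QC-filtered cohort.

    The cohort table needs participant/task/version/occasion columns plus
    one numeric column per metric.  Paired comparisons and correlations run
    per metric between the two version tags at the first occasion; ICCs run
    per metric between occasions within the gamified version.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in cohort.columns]
    if missing:
        raise SchemaError(f"cohort table missing columns: {missing}")
    if len(cohort) == 0:
        raise SchemaError("cohort table is empty")
    metrics = _metric_columns(cohort)
    n_tests = 0
    paired_rows, corr_rows, icc_rows = [], [], []

    test = cohort[cohort["occasion"] == "test"]
    versions = sorted(test["version"].unique())
    for task in sorted(cohort["task"].unique()):
        sub = test[test["task"] == task]
        if len(versions) == 2:
            wide = sub.pivot_table(index="participant", columns="version",
                                   values=metrics, aggfunc="first").dropna()
            for m in metrics:
                if (m, versions[0]) not in wide.columns:
                    continue
                a = wide[(m, versions[0])].to_numpy()
                b = wide[(m, versions[1])].to_numpy()
                if len(a) < 5 or np.std(a, ddof=1) == 0 or np.std(b, ddof=1) == 0:
                    continue
                pc = paired_f(a, b, metric=m)
                paired_rows.append({
                    "task": task, "metric": m,
                    f"mean_{versions[0]}": pc.mean_a,
                    f"mean_{versions[1]}": pc.mean_b,
                    "F": pc.f_statistic, "p": pc.p_value, "n": pc.n,
                })
                cr = convergent_correlation(a, b, normality_alpha,
                                            pair=(m, m))
                corr_rows.append({
                    "task": task, "metric": m, "type": cr.coefficient_type,
                    "estimate": cr.estimate, "p": cr.p_value, "n": cr.n,
                    "band": cr.band,
                })
                n_tests += 2

        # retest: gamified version across occasions
        gam = cohort[(cohort["task"] == task)
                     & (cohort["version"] == cohort["version"].iloc[0])]
        if set(gam["occasion"]) >= {"test", "retest"}:
            wide = gam.pivot_table(index="participant", columns="occasion",
                                   values=metrics, aggfunc="first").dropna()
            for m in metrics:
                if (m, "test") not in wide.columns:
                    continue
                o1 = wide[(m, "test")].to_numpy()
                o2 = wide[(m, "retest")].to_numpy()
                if len(o1) < 5:
                    continue
                ir = icc_absolute_agreement(o1, o2, metric=m)
                icc_rows.append({
                    "task": task, "metric": m, "icc": ir.icc, "p": ir.p_value,
                    "n": ir.n, "band": ir.band,
                })
                n_tests += 1

    return ValidationReport(
        paired=pd.DataFrame(paired_rows),
        correlations=pd.DataFrame(corr_rows),
        icc=pd.DataFrame(icc_rows),
        n_tests=n_tests,
    )
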