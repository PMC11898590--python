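"""Method-agreement statistics: intraclass correlation (two-way model,
absolute agreement, single measurement), Bland-Altman analysis with limits of
agreement and their confidence intervals, minimal detectable change, and
table-level MDC aggregation.

Conventions:

* ICC follows the McGraw & Wong ICC(A,1) definition computed from the two-way
  ANOVA decomposition, with the F-distribution confidence interval.
* Agreement categories: poor (<= 0.50), moderate (<= 0.75), good (<= 0.90),
  excellent (> 0.90); bands are closed on the right.
* Limits of agreement use the fixed 1.96 multiplier; their confidence
  intervals use the classic approximation se(LoA) = sd * sqrt(3/n) with a
  t(n-1) quantile.  MDC is half the LoA range, i.e. 1.96 * sd of the
  differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

ICC_CATEGORIES = ("poor", "moderate", "good", "excellent")


@dataclass
class PairedMeasurements:
    """Same-unit measurements of one quantity by two methods on n subjects."""

    subjects: np.ndarray
    a: np.ndarray
    b: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.subjects = np.asarray(self.subjects)
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        n = self.subjects.size
        if self.a.shape != (n,) or self.b.shape != (n,):
            raise ValueError("a and b must hold one value per subject")
        if np.isnan(self.a).any() or np.isnan(self.b).any():
            raise ValueError("missing pairs are not allowed")

    @property
    def n(self) -> int:
        return self.subjects.size

    @property
    def differences(self) -> np.ndarray:
        return self.a - self.b

    @property
    def means(self) -> np.ndarray:
        return 0.5 * (self.a + self.b)


def classify_icc(value: float) -> str:
    """Categorical interpretation of an ICC value (bands closed on the right)."""
    if not np.isfinite(value):
        raise ValueError("ICC value must be finite")
    if value <= 0.50:
        return "poor"
    if value <= 0.75:
        return "moderate"
    if value <= 0.90:
        return "good"
    return "excellent"


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    category: str
    degenerate: bool = False

    def __post_init__(self) -> None:
        eps = 1e-9
        if not self.degenerate and not (self.ci_low - eps <= self.icc <= self.ci_high + eps):
            raise ValueError("CI must bracket the ICC value")


def _two_way_anova(values: np.ndarray) -> tuple[float, float, float]:
    """Mean squares (rows, columns, error) of an n x k two-way layout."""
    n, k = values.shape
    grand = values.mean()
    row_means = values.mean(axis=1)
    col_means = values.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((values - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_absolute_single(pairs: PairedMeasurements, alpha: float = 0.05) -> ICCResult:
    """ICC(A,1): two-way model, absolute agreement, single measurement.

    From the two-way ANOVA decomposition with n subjects and k = 2 methods:

        icc = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    with the McGraw & Wong F-based confidence interval.  Zero between-subject
    variance makes the coefficient degenerate; the result is flagged and the
    CI collapses to the point value.
    """
    if pairs.n < 3:
        raise ValueError("at least 3 subjects are required")
    values = np.column_stack([pairs.a, pairs.b])
    if not np.isfinite(values).all():
        raise ValueError("values must be finite")
    n, k = values.shape
    msr, msc, mse = _two_way_anova(values)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0 or np.isclose(msr, 0.0) and np.isclose(mse, 0.0) and np.isclose(msc, 0.0):
        return ICCResult(icc=0.0, ci_low=0.0, ci_high=0.0, category="poor",
                         degenerate=True)
    icc = (msr - mse) / denom

    if mse == 0.0:
        return ICCResult(icc=float(icc), ci_low=float(icc), ci_high=float(icc),
                         category=classify_icc(icc), degenerate=True)
    # Satterthwaite df for the absolute-agreement interval
    a_ = (k * icc) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    b_ = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    v_num = (a_ * msc + b_ * mse) ** 2
    v_den = (a_ * msc) ** 2 / (k - 1) + (b_ * mse) ** 2 / ((n - 1) * (k - 1))
    v = v_num / v_den if np.isfinite(v_num) and v_den > 0 else (n - 1) * (k - 1)
    f_l = stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
    f_u = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
    lower = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    return ICCResult(icc=float(icc), ci_low=float(lower), ci_high=float(upper),
                     category=classify_icc(icc))


@dataclass
class AssumptionReport:
    normality_stat: float
    normality_p: float
    normality_ok: bool
    slope: float
    slope_t: float
    slope_p: float
    homoscedastic_ok: bool
    constant_differences: bool = False


def check_assumptions(differences: np.ndarray, means: np.ndarray,
                      alpha: float = 0.05) -> AssumptionReport:
    """Normality (Shapiro-Wilk) and homoscedasticity checks for BA analysis.

    Homoscedasticity is assessed by regressing |difference| on the pair means
    and t-testing the slope: a slope indistinguishable from zero means the
    measurement error does not scale with magnitude.
    """
    d = np.asarray(differences, dtype=float)
    m = np.asarray(means, dtype=float)
    if d.size < 3:
        raise ValueError("at least 3 pairs are required")
    if np.allclose(d, d[0]):
        return AssumptionReport(np.nan, np.nan, True, 0.0, 0.0, 1.0, True,
                                constant_differences=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        w, p_norm = stats.shapiro(d)
    if np.allclose(m, m[0]):
        slope, t_stat, p_slope = 0.0, 0.0, 1.0
    else:
        reg = stats.linregress(m, np.abs(d))
        slope = float(reg.slope)
        se = reg.stderr if reg.stderr > 0 else np.inf
        t_stat = slope / se
        p_slope = float(reg.pvalue)
    return AssumptionReport(
        normality_stat=float(w), normality_p=float(p_norm),
        normality_ok=bool(p_norm >= alpha),
        slope=slope, slope_t=float(t_stat), slope_p=p_slope,
        homoscedastic_ok=bool(p_slope >= alpha),
    )


@dataclass
class BAResult:
    bias: float
    sd: float
    loa_low: float
    loa_high: float
    bias_ci: tuple[float, float]
    loa_low_ci: tuple[float, float]
    loa_high_ci: tuple[float, float]
    assumptions: AssumptionReport | None = None

    @property
    def loa_range(self) -> float:
        return self.loa_high - self.loa_low

    @property
    def mdc(self) -> float:
        return self.loa_range / 2.0


def mdc_from_loa(loa_range: float) -> float:
    """Minimal detectable change: one-half of the LoA range."""
    if loa_range < 0:
        raise ValueError("LoA range must be non-negative")
    return loa_range / 2.0


def bland_altman(pairs: PairedMeasurements, loa_multiplier: float = 1.96,
                 alpha: float = 0.05) -> BAResult:
    """Bland-Altman agreement analysis of two methods.

    Differences are ``a - b``; bias is their mean, limits of agreement
    bias +- 1.96 sd, the bias CI uses the t distribution and the LoA CIs the
    sd * sqrt(3/n) standard-error approximation.
    """
    if pairs.n < 3:
        raise ValueError("at least 3 pairs are required")
    d = pairs.differences
    n = pairs.n
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_low = bias - loa_multiplier * sd
    loa_high = bias + loa_multiplier * sd
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, n - 1)
    se_bias = sd / np.sqrt(n)
    se_loa = sd * np.sqrt(3.0 / n)
    assumptions = check_assumptions(d, pairs.means, alpha=alpha)
    return BAResult(
        bias=bias, sd=sd, loa_low=float(loa_low), loa_high=float(loa_high),
        bias_ci=(bias - t_crit * se_bias, bias + t_crit * se_bias),
        loa_low_ci=(loa_low - t_crit * se_loa, loa_low + t_crit * se_loa),
        loa_high_ci=(loa_high - t_crit * se_loa, loa_high + t_crit * se_loa),
        assumptions=assumptions,
    )


def ba_plot_data(pairs: PairedMeasurements, result: BAResult | None = None) -> pd.DataFrame:
    """Scatter + line data for a Bland-Altman plot, as a plain table."""
    result = result or bland_altman(pairs)
    df = pd.DataFrame({"mean": pairs.means, "difference": pairs.differences})
    for name, val in (("bias", result.bias), ("loa_low", result.loa_low),
                      ("loa_high", result.loa_high)):
        df[name] = val
    return df


def aggregate_mdc(
    table: pd.DataFrame,
    value_col: str = "mdc",
    reference_mode: str = "NMC",
) -> dict:
    """Per-mode mean MDC reduction relative to the no-correction reference.

    ``table`` must hold long-format rows with columns ``comparison``,
    ``region``, ``mode`` and the MDC value.  For every (comparison, region)
    key with a reference-mode row, reduction = MDC(reference) - MDC(mode);
    keys lacking a reference counterpart are skipped with a warning.  Returns
    ``{"reductions": long DataFrame, "mean_reduction": per-mode Series,
    "max_mdc": per-mode Series}`` (means rounded to 2 decimals in the report
    column, full precision retained).
    """
    required = {"comparison", "region", "mode", value_col}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    ref = table[table["mode"] == reference_mode].set_index(["comparison", "region"])
    rows = []
    for _, r in table[table["mode"] != reference_mode].iterrows():
        key = (r["comparison"], r["region"])
        if key not in ref.index:
            warnings.warn(f"no {reference_mode} counterpart for {key}; skipped",
                          stacklevel=2)
            continue
        rows.append({"comparison": r["comparison"], "region": r["region"],
                     "mode": r["mode"],
                     "reduction": float(ref.loc[key, value_col]) - float(r[value_col])})
    reductions = pd.DataFrame(rows, columns=["comparison", "region", "mode", "reduction"])
    mean_reduction = reductions.groupby("mode")["reduction"].mean()
    max_mdc = table[table["mode"] != reference_mode].groupby("mode")[value_col].max()
    return {"reductions": reductions, "mean_reduction": mean_reduction,
            "mean_reduction_2dp": mean_reduction.round(2), "max_mdc": max_mdc}
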