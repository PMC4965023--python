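"""Statistical battery for cohort tables: group comparisons, regional
contrasts, three-plane associations, inter-observer reliability and the
sample-size calculation.

Conventions: two-sided tests, significance level 0.05, Welch t by default
(pooled available), Bonferroni adjustment for post-hoc pairs, ICC(2,1)
(two-way random effects, absolute agreement, single measures) for
reliability.  Normality is screened with Kolmogorov-Smirnov tests and
reported, but never switches a test to a non-parametric variant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "AssociationResult",
    "ReliabilityResult",
    "two_sample_t",
    "anova_bonferroni",
    "paired_t",
    "pearson_with_regression",
    "icc_2_1",
    "sample_size_two_means",
    "ks_normality",
    "run_paper_battery",
]


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    df: float
    p_value: float
    group_means: tuple[float, ...]
    group_sds: tuple[float, ...]
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    adjustment: str = "none"
    pairwise: tuple = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value out of range: {self.p_value}")

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "group_means": list(self.group_means),
            "group_sds": list(self.group_sds),
            "adjustment": self.adjustment,
        }
        if not math.isnan(self.ci_low):
            d["ci"] = [self.ci_low, self.ci_high]
        if self.pairwise:
            d["pairwise"] = [dict(p) for p in self.pairwise]
        return d


@dataclass(frozen=True)
class AssociationResult:
    pearson_r: float
    p_value: float
    slope: float
    intercept: float
    slope_ci_low: float
    slope_ci_high: float
    n: int

    def __post_init__(self) -> None:
        if abs(self.pearson_r) > 1 + 1e-12:
            raise ValueError(f"|r| > 1: {self.pearson_r}")
        if not (math.isfinite(self.slope) and math.isfinite(self.intercept)):
            raise ValueError("non-finite regression coefficients")

    def to_dict(self) -> dict:
        return {
            "pearson_r": self.pearson_r,
            "p_value": self.p_value,
            "slope": self.slope,
            "intercept": self.intercept,
            "slope_ci": [self.slope_ci_low, self.slope_ci_high],
            "n": self.n,
        }


@dataclass(frozen=True)
class ReliabilityResult:
    icc: float
    ci_low: float
    ci_high: float
    model: str = "ICC(2,1) absolute agreement"

    def __post_init__(self) -> None:
        if self.icc > 1 + 1e-12:
            raise ValueError(f"ICC > 1: {self.icc}")

    def to_dict(self) -> dict:
        return {"icc": self.icc, "ci": [self.ci_low, self.ci_high], "model": self.model}


def _mean_sd(x: np.ndarray) -> tuple[float, float]:
    return float(np.mean(x)), float(np.std(x, ddof=1)) if len(x) > 1 else float("nan")


def two_sample_t(group_a, group_b, pooled: bool = False) -> TestResult:
    """Two-sided independent-samples t-test (Welch by default)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need n >= 2 per group")
    if np.std(a) == 0 and np.std(b) == 0:
        raise ValueError("degenerate: zero variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=pooled)
    ma, sa = _mean_sd(a)
    mb, sb = _mean_sd(b)
    ci = res.confidence_interval(0.95)
    return TestResult(
        name="pooled t" if pooled else "Welch t",
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        group_means=(ma, mb),
        group_sds=(sa, sb),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
    )


def anova_bonferroni(groups: dict[str, np.ndarray] | list[np.ndarray]) -> TestResult:
    """One-way ANOVA with Bonferroni-adjusted pairwise post-hoc t-tests.

    The family size is always ``k (k - 1) / 2``; adjusted p-values are
    ``min(1, p * m)`` and never fall below the raw p-value.
    """
    if isinstance(groups, dict):
        names = list(groups)
        arrays = [np.asarray(groups[n], dtype=float) for n in names]
    else:
        arrays = [np.asarray(g, dtype=float) for g in groups]
        names = [f"group{i}" for i in range(len(arrays))]
    if len(arrays) < 3:
        raise ValueError("one-way ANOVA battery expects k >= 3 groups")
    if any(len(g) < 2 for g in arrays):
        raise ValueError("every group needs n >= 2")
    f, p = stats.f_oneway(*arrays)
    m = len(arrays) * (len(arrays) - 1) // 2
    pairs = []
    for (i, gi), (j, gj) in combinations(enumerate(arrays), 2):
        r = stats.ttest_ind(gi, gj, equal_var=False)
        pairs.append(
            (
                ("pair", f"{names[i]} vs {names[j]}"),
                ("p_raw", float(r.pvalue)),
                ("p_adjusted", float(min(1.0, r.pvalue * m))),
            )
        )
    k = len(arrays)
    n_total = sum(len(g) for g in arrays)
    return TestResult(
        name="one-way ANOVA",
        statistic=float(f),
        df=float(k - 1),
        p_value=float(p),
        group_means=tuple(float(np.mean(g)) for g in arrays),
        group_sds=tuple(float(np.std(g, ddof=1)) for g in arrays),
        adjustment="bonferroni",
        pairwise=tuple(pairs),
    )


def paired_t(values_a, values_b) -> TestResult:
    """Two-sided paired-samples t-test."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired vectors must have equal length")
    if len(a) < 2:
        raise ValueError("need n >= 2 pairs")
    if np.all(a == b):
        raise ValueError("degenerate: all paired differences are zero")
    res = stats.ttest_rel(a, b)
    ma, sa = _mean_sd(a)
    mb, sb = _mean_sd(b)
    return TestResult(
        name="paired t",
        statistic=float(res.statistic),
        df=float(len(a) - 1),
        p_value=float(res.pvalue),
        group_means=(ma, mb),
        group_sds=(sa, sb),
    )


def pearson_with_regression(x, y) -> AssociationResult:
    """Pearson r plus the least-squares line and a 95% CI on the slope."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if len(xv) != len(yv) or len(xv) < 3:
        raise ValueError("need n >= 3 paired observations")
    if np.std(xv) == 0:
        raise ValueError("zero variance in x")
    r, p = stats.pearsonr(xv, yv)
    reg = stats.linregress(xv, yv)
    tcrit = stats.t.ppf(0.975, len(xv) - 2)
    return AssociationResult(
        pearson_r=float(r),
        p_value=float(p),
        slope=float(reg.slope),
        intercept=float(reg.intercept),
        slope_ci_low=float(reg.slope - tcrit * reg.stderr),
        slope_ci_high=float(reg.slope + tcrit * reg.stderr),
        n=len(xv),
    )


def icc_2_1(matrix) -> ReliabilityResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    Computed from the two-way ANOVA mean squares (rows = subjects, columns =
    raters) with the Shrout-Fleiss F-based 95% confidence interval.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 5 or x.shape[1] < 2:
        raise ValueError("need a subjects x raters matrix with >= 5 subjects and >= 2 raters")
    if np.allclose(x, x.flat[0]):
        raise ValueError("degenerate: constant measurement matrix")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)  # between subjects
    msc = ss_cols / (k - 1)  # between raters
    mse = ss_err / ((n - 1) * (k - 1))  # residual
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    if mse <= 0 or icc >= 1:  # perfect agreement: the F-based CI degenerates
        return ReliabilityResult(icc=float(icc), ci_low=float(icc), ci_high=float(icc))

    # Shrout & Fleiss approximate CI for ICC(2,1)
    a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
    v = (a * msc + b * mse) ** 2 / ((a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1)))
    if not np.isfinite(v) or v <= 0:
        return ReliabilityResult(icc=float(icc), ci_low=float("nan"), ci_high=float("nan"))
    f_low = stats.f.ppf(0.975, n - 1, v)
    f_up = stats.f.ppf(0.975, v, n - 1)
    ci_low = (n * (msr - f_low * mse)) / (f_low * (k * msc + (k * n - k - n) * mse) + n * msr)
    ci_high = (n * (f_up * msr - mse)) / (k * msc + (k * n - k - n) * mse + n * f_up * msr)
    return ReliabilityResult(icc=float(icc), ci_low=float(ci_low), ci_high=float(ci_high))


def sample_size_two_means(mu1: float, mu2: float, sigma: float, power: float = 0.80, alpha: float = 0.05) -> int:
    """Per-group n for a two-sided two-sample comparison of means
    (normal approximation): ``n = 2 sigma^2 (z_{1-alpha/2} + z_power)^2 / (mu1 - mu2)^2``,
    rounded up."""
    if mu1 == mu2:
        raise ValueError("mu1 must differ from mu2")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if not (0 < power < 1) or not (0 < alpha < 1):
        raise ValueError("power and alpha must lie in (0, 1)")
    z_alpha = stats.norm.ppf(1 - alpha / 2)
    z_power = stats.norm.ppf(power)
    n = 2 * sigma**2 * (z_alpha + z_power) ** 2 / (mu1 - mu2) ** 2
    return int(math.ceil(n))


def ks_normality(values) -> dict:
    """Kolmogorov-Smirnov normality screen against the fitted normal (report
    only; the battery stays parametric regardless)."""
    x = np.asarray(values, dtype=float)
    if len(x) < 3 or np.std(x) == 0:
        return {"n": int(len(x)), "statistic": float("nan"), "p_value": float("nan")}
    d, p = stats.kstest((x - x.mean()) / x.std(ddof=1), "norm")
    return {"n": int(len(x)), "statistic": float(d), "p_value": float(p)}


# ---------------------------------------------------------------------------
# full battery


def _col(table: pd.DataFrame, region: str, column: str, group: str | None = None) -> np.ndarray:
    sel = table["region"] == region
    if group is not None:
        sel &= table["group"] == group
    return table.loc[sel, column].to_numpy(dtype=float)


def run_paper_battery(table: pd.DataFrame) -> dict:
    """Run the full comparison battery on a cohort table and return a
    JSON-serialisable report.

    Sections: scoliosis-vs-control per spinal segment, curve-pattern ANOVA,
    apical-vs-junctional paired contrasts, standing-Cobb associations with
    slope-per-10-degrees summaries, and normality screening.  Missing
    regions or groups produce warnings and a partial report.
    """
    report: dict = {"warnings": [], "normality": {}}
    has_ais = (table["group"] == "ais").any()
    has_control = (table["group"] == "control").any()

    pairs = [
        ("thoracic", "main_thoracic", "thoracic_T4T12"),
        ("lumbar", "thoracolumbar", "lumbar_L1L5"),
    ]
    if has_ais and has_control:
        section = {}
        for label, ais_region, ctl_region in pairs:
            for metric in ("delta_ap_percent", "axial_rotation_deg"):
                a = _col(table, ais_region, metric, "ais")
                c = _col(table, ctl_region, metric, "control")
                if len(a) >= 2 and len(c) >= 2:
                    section[f"{label}_{metric}"] = two_sample_t(a, c).to_dict()
                else:
                    report["warnings"].append(f"ais-vs-control {label} {metric}: insufficient data")
        report["ais_vs_control"] = section
    else:
        report["warnings"].append("ais-vs-control comparisons skipped: one group absent")

    if has_ais:
        ais = table[table["group"] == "ais"]
        patterns = [p for p in ais["curve_pattern"].unique() if p != "none"]
        if len(patterns) >= 3:
            section = {}
            for region, metric in (
                ("main_thoracic", "cobb_deg"),
                ("main_thoracic", "axial_rotation_deg"),
                ("main_thoracic", "delta_ap_percent"),
                ("thoracolumbar", "cobb_deg"),
                ("thoracolumbar", "axial_rotation_deg"),
                ("thoracolumbar", "delta_ap_percent"),
            ):
                sub = ais[ais["region"] == region]
                groups = {p: sub.loc[sub["curve_pattern"] == p, metric].to_numpy(dtype=float) for p in sorted(patterns)}
                if all(len(g) >= 2 for g in groups.values()):
                    section[f"{region}_{metric}"] = anova_bonferroni(groups).to_dict()
            report["curve_pattern_anova"] = section
        else:
            report["warnings"].append("curve-pattern ANOVA skipped: fewer than 3 patterns present")

        # apical vs junctional, paired within subject
        section = {}
        wide = ais.pivot_table(index="subject_id", columns="region", values="delta_ap_percent")
        for apical, junctional in (
            ("apical_thoracic", "proximal_junctional"),
            ("apical_thoracic", "distal_junctional"),
            ("apical_lumbar", "distal_junctional"),
        ):
            if apical in wide.columns and junctional in wide.columns:
                sub = wide[[apical, junctional]].dropna()
                if len(sub) >= 2:
                    section[f"{apical}_vs_{junctional}"] = paired_t(sub[apical], sub[junctional]).to_dict()
            else:
                report["warnings"].append(f"paired contrast {apical} vs {junctional}: region missing")
        report["apical_vs_junctional"] = section

        # couplings against the standing radiograph Cobb (thoracic curves)
        thor = ais[ais["region"] == "main_thoracic"].dropna(subset=["standing_cobb_deg"])
        if len(thor) >= 3:
            section = {}
            x = thor["standing_cobb_deg"].to_numpy(dtype=float)
            for key, metric in (
                ("ct_cobb", "cobb_deg"),
                ("axial_rotation", "axial_rotation_deg"),
                ("delta_ap", "delta_ap_percent"),
            ):
                assoc = pearson_with_regression(x, thor[metric].to_numpy(dtype=float))
                d = assoc.to_dict()
                d["per_10_deg_cobb"] = assoc.slope * 10.0
                section[key] = d
            rot = thor["axial_rotation_deg"].to_numpy(dtype=float)
            dap = thor["delta_ap_percent"].to_numpy(dtype=float)
            section["rotation_vs_delta_ap"] = pearson_with_regression(rot, dap).to_dict()
            report["standing_cobb_couplings"] = section
        else:
            report["warnings"].append("standing-Cobb couplings skipped: no standing Cobb values")

    for region in sorted(table["region"].unique()):
        for group in sorted(table["group"].unique()):
            vals = _col(table, region, "delta_ap_percent", group)
            if len(vals) >= 3:
                report["normality"][f"{group}_{region}_delta_ap"] = ks_normality(vals)

    return report
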