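"""Cohort-level statistics.

Covers the analysis side of the pipeline: diabetic macular edema (DME)
classification from central subfield thickness, covariate-adjusted linear
models of logMAR visual acuity on per-layer metrics with Bonferroni
control, group comparisons of acuity across disruption-severity
categories, and statistical power for detecting a partial correlation in
a multivariable linear model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .errors import (
    CategoryError,
    CollinearityError,
    InsufficientDataError,
    ValidationError,
)

__all__ = [
    "SEXES",
    "RACES",
    "SubjectRecord",
    "RegressionResult",
    "GroupComparison",
    "PowerResult",
    "classify_dme",
    "fit_va_model",
    "sensitivity_refit",
    "bonferroni_threshold",
    "report_threshold",
    "disruption_category",
    "compare_groups",
    "power_partial_correlation",
]

SEXES = ("male", "female")
RACES = ("White", "African American", "Hispanic or Latino", "Asian")
DM_TYPES = (1, 2)

#: Sex-specific central-subfield-thickness thresholds (um) defining DME.
DME_CST_THRESHOLD_UM = {"male": 320.0, "female": 304.0}

#: Covariates adjusted for in every acuity model.
COVARIATES = ("age", "sex", "race", "dm_type", "dm_duration", "hba1c")


@dataclass
class SubjectRecord:
    """One study eye: covariates, best-corrected acuity, and layer metrics.

    ``metrics`` maps metric names (``NFL_T`` ... ``OSL_R``, ``CST``,
    ``NFL_d`` ...) to values; ``None`` marks a metric that could not be
    computed (insufficient assigned subfield pixels).
    """

    id: str
    age: float
    sex: str
    race: str
    dm_type: int
    dm_duration: float
    hba1c: float
    va_logmar: float
    anti_vegf: bool = False
    metrics: dict[str, float | None] = field(default_factory=dict)

    def __post_init__(self):
        if self.sex not in SEXES:
            raise CategoryError(f"sex {self.sex!r} not in {SEXES}")
        if self.race not in RACES:
            raise CategoryError(f"race {self.race!r} not in {RACES}")
        if int(self.dm_type) not in DM_TYPES:
            raise CategoryError(f"dm_type {self.dm_type!r} not in {DM_TYPES}")
        self.dm_type = int(self.dm_type)
        if not np.isfinite(self.va_logmar):
            raise ValidationError("va_logmar must be finite")
        if not self.hba1c > 0:
            raise ValidationError("hba1c must be > 0")

    @property
    def dme(self) -> bool | None:
        """DME status derived from CST and sex; None when CST is missing."""
        cst = self.metrics.get("CST")
        if cst is None:
            return None
        return classify_dme(cst, self.sex)


@dataclass
class RegressionResult:
    """A scaled metric coefficient from one covariate-adjusted acuity model.

    The coefficient is expressed as logMAR change per 10 um of thickness
    (``*_T``, ``CST``), per 0.1 of reflectance ratio (``*_R``), or per
    percentage point of disruption area (``*_d``).
    """

    metric: str
    coefficient: float
    ci95: tuple[float, float]
    p_value: float
    n: int
    n_excluded: int
    significant_after_bonferroni: bool
    threshold: float

    def __post_init__(self):
        lo, hi = self.ci95
        if not lo <= self.coefficient <= hi:
            raise ValidationError("coefficient must lie inside its 95% CI")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError("p-value outside [0, 1]")


@dataclass
class GroupComparison:
    """One-way comparison of acuity across groups (ANOVA + Kruskal-Wallis)."""

    anova_f: float
    anova_p: float
    kruskal_h: float
    kruskal_p: float
    group_mean_sd: list[tuple[float, float, int]]  # (mean, sd, n) per group


@dataclass
class PowerResult:
    """Power to detect a partial correlation in a k-variable linear model."""

    r_partial: float
    n: int
    n_predictors: int
    alpha: float
    power: float
    method: str = "fisher-z"

    def __post_init__(self):
        if not 0.0 <= self.power <= 1.0:
            raise ValidationError("power outside [0, 1]")


# ---------------------------------------------------------------------------
# classification and thresholds
# ---------------------------------------------------------------------------


def classify_dme(cst: float, sex: str) -> bool:
    """DME iff CST strictly exceeds the sex-specific threshold.

    Thresholds: 320 um for males, 304 um for females (strict inequality, so
    a CST exactly at the threshold is no-DME).
    """
    if sex not in DME_CST_THRESHOLD_UM:
        raise CategoryError(f"sex {sex!r} not in {SEXES}")
    if not cst > 0:
        raise ValidationError(f"CST must be > 0, got {cst}")
    return cst > DME_CST_THRESHOLD_UM[sex]


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold alpha / m."""
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    if m < 1:
        raise ValidationError(f"m must be >= 1, got {m}")
    return alpha / m


def report_threshold(alpha: float, m: int) -> float:
    """The per-test threshold rounded to 3 decimals, as reported in text."""
    return round(bonferroni_threshold(alpha, m), 3)


def disruption_category(percent: float) -> str:
    """Severity bin of a percent-area disruption metric.

    ``zero`` (exactly 0%), ``lt10`` (0% < x < 10%) or ``ge10`` (>= 10%,
    boundary inclusive).
    """
    if not 0.0 <= percent <= 100.0:
        raise ValidationError(f"percent {percent} outside [0, 100]")
    if percent == 0.0:
        return "zero"
    return "lt10" if percent < 10.0 else "ge10"


# ---------------------------------------------------------------------------
# regression
# ---------------------------------------------------------------------------


def metric_scale(metric: str) -> float:
    """Unit rescaling for reported coefficients: 10 um for thickness, 0.1
    for reflectance ratios, 1 percentage point for disruption areas."""
    if metric.endswith("_T") or metric == "CST":
        return 10.0
    if metric.endswith("_R"):
        return 0.1
    return 1.0


def design_matrix(records: list[SubjectRecord], metric: str) -> tuple[pd.DataFrame, np.ndarray, int]:
    """Design matrix (with intercept), response, and listwise-exclusion count.

    Columns: the metric, age, a female indicator, race dummies with White as
    the reference level, a type-2 indicator, diabetes duration and HbA1c.
    Records missing the metric are excluded (and counted).
    """
    rows, y = [], []
    n_excluded = 0
    for r in records:
        v = r.metrics.get(metric)
        if v is None or not np.isfinite(v):
            n_excluded += 1
            continue
        row = {
            "const": 1.0,
            metric: float(v),
            "age": r.age,
            "sex_female": 1.0 if r.sex == "female" else 0.0,
            "dm_type2": 1.0 if r.dm_type == 2 else 0.0,
            "dm_duration": r.dm_duration,
            "hba1c": r.hba1c,
        }
        for race in RACES[1:]:
            row[f"race_{race.replace(' ', '_')}"] = 1.0 if r.race == race else 0.0
        rows.append(row)
        y.append(r.va_logmar)
    X = pd.DataFrame(rows)
    return X, np.asarray(y, dtype=np.float64), n_excluded


def fit_va_model(
    records: list[SubjectRecord],
    metric: str,
    alpha: float = 0.05,
    m_comparisons: int = 6,
    drop_degenerate: bool = False,
) -> RegressionResult:
    """Covariate-adjusted OLS of logMAR acuity on one layer metric.

    Fits ``va_logmar ~ metric + age + sex + race + dm_type + dm_duration +
    hba1c`` by QR-based ordinary least squares, reports the metric
    coefficient rescaled to its conventional units (per 10 um / per 0.1
    ratio / per % point) with a t-based two-sided p-value and 95% CI on
    ``n - p`` degrees of freedom, and flags significance at the Bonferroni
    threshold ``alpha / m_comparisons``.

    ``drop_degenerate=True`` silently drops constant (zero-variance)
    columns instead of raising :class:`CollinearityError` — useful when
    fitting many simulated cohorts where a rare category may be absent.
    """
    X, y, n_excluded = design_matrix(records, metric)
    n = len(y)
    if n == 0 or n < X.shape[1] + 2:
        raise InsufficientDataError(
            f"need at least {X.shape[1] + 2 if n else 'several'} complete records, got {n}"
        )

    degenerate = [
        c for c in X.columns if c != "const" and float(np.ptp(X[c].to_numpy())) == 0.0
    ]
    if degenerate:
        if drop_degenerate:
            X = X.drop(columns=degenerate)
        else:
            raise CollinearityError(
                f"constant design columns: {degenerate}", columns=degenerate
            )
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise CollinearityError(
            "design matrix is rank-deficient (collinear columns)",
            columns=list(X.columns),
        )

    model = sm.OLS(y, X)  # statsmodels solves via pinv/QR, not normal equations
    res = model.fit()
    scale = metric_scale(metric)
    coef = float(res.params[metric]) * scale
    ci = res.conf_int(alpha=0.05)
    lo, hi = float(ci.loc[metric, 0]) * scale, float(ci.loc[metric, 1]) * scale
    p = float(res.pvalues[metric])
    thr = bonferroni_threshold(alpha, m_comparisons)
    return RegressionResult(
        metric=metric,
        coefficient=coef,
        ci95=(lo, hi),
        p_value=p,
        n=n,
        n_excluded=n_excluded,
        significant_after_bonferroni=p < thr,
        threshold=thr,
    )


def sensitivity_refit(
    records: list[SubjectRecord],
    metric: str,
    cutoff: float | None = None,
    **fit_kwargs,
) -> tuple[RegressionResult, dict]:
    """Refit without influential points (Cook's distance > cutoff).

    ``cutoff`` defaults to the conventional 4/n. Returns the refit result
    and a report with the original result and the excluded record count.
    """
    full = fit_va_model(records, metric, **fit_kwargs)
    X, y, _ = design_matrix(records, metric)
    res = sm.OLS(y, X).fit()
    cooks = res.get_influence().cooks_distance[0]
    n = len(y)
    cut = cutoff if cutoff is not None else 4.0 / n
    keep_local = cooks <= cut
    # map back to the record list (records with the metric present, in order)
    kept_records, i = [], 0
    for r in records:
        v = r.metrics.get(metric)
        if v is None or not np.isfinite(v):
            continue
        if keep_local[i]:
            kept_records.append(r)
        i += 1
    refit = fit_va_model(kept_records, metric, **fit_kwargs)
    report = {
        "cutoff": cut,
        "n_influential": int((~keep_local).sum()),
        "original": full,
    }
    return refit, report


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------


def compare_groups(groups: list[np.ndarray]) -> GroupComparison:
    """One-way ANOVA and Kruskal-Wallis across >= 2 groups of acuities.

    Kruskal-Wallis uses midranks with tie correction and a chi-square
    reference with k-1 df. Degenerate case: when every observation is
    identical across all groups, both statistics are 0 with p = 1.
    """
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    arrs = [np.asarray(g, dtype=np.float64) for g in groups]
    for g in arrs:
        if g.size == 0:
            raise ValidationError("groups must be nonempty")
    stats_per_group = [
        (float(g.mean()), float(g.std(ddof=1)) if g.size > 1 else 0.0, int(g.size))
        for g in arrs
    ]
    allv = np.concatenate(arrs)
    if np.ptp(allv) == 0.0:
        return GroupComparison(0.0, 1.0, 0.0, 1.0, stats_per_group)
    f, pf = sps.f_oneway(*arrs)
    h, ph = sps.kruskal(*arrs)
    return GroupComparison(float(f), float(pf), float(h), float(ph), stats_per_group)


# ---------------------------------------------------------------------------
# power
# ---------------------------------------------------------------------------


def power_partial_correlation(
    r: float,
    n: int,
    k: int = 7,
    alpha: float = 0.05,
    method: str = "fisher-z",
    n_sims: int = 5000,
    seed: int | None = None,
) -> PowerResult:
    """Power to detect a partial correlation ``r`` of one predictor in a
    linear model with ``k`` total variables (the tested predictor plus
    ``k - 1`` controlled covariates) at two-sided level ``alpha``.

    ``method="fisher-z"``: normal approximation
    ``power = Phi(z_r * sqrt(n - (k-1) - 3) - z_{1-a/2})
            + Phi(-z_r * sqrt(n - (k-1) - 3) - z_{1-a/2})``
    with ``z_r = atanh(|r|)``; the second tail makes power equal alpha at
    r = 0 under the two-sided convention. This is an approximation,
    typically within a few percentage points of the exact noncentral-t
    power.

    ``method="simulation"``: draws ``n_sims`` datasets with the requested
    partial correlation (the tested predictor orthogonal to the covariates
    in population), fits OLS with intercept, and counts two-sided
    t-rejections of the tested coefficient at ``alpha``.
    """
    if not abs(r) < 1:
        raise ValidationError(f"|r| must be < 1, got {r}")
    if k < 1:
        raise ValidationError("k must be >= 1")
    if n <= k + 3:
        raise ValidationError(f"n={n} too small for k={k} (need n > k + 3)")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")

    if method == "fisher-z":
        zr = np.arctanh(abs(r))
        se_df = n - (k - 1) - 3
        zcrit = sps.norm.ppf(1 - alpha / 2)
        lam = zr * np.sqrt(se_df)
        power = float(sps.norm.cdf(lam - zcrit) + sps.norm.cdf(-lam - zcrit))
    elif method == "simulation":
        rng = np.random.default_rng(seed)
        df = n - (k + 1)
        tcrit = sps.t.ppf(1 - alpha / 2, df)
        rej = 0
        for _ in range(n_sims):
            X = np.empty((n, k + 1))
            X[:, 0] = 1.0
            X[:, 1:] = rng.standard_normal((n, k))
            y = r * X[:, 1] + np.sqrt(1 - r * r) * rng.standard_normal(n)
            beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            s2 = resid @ resid / df
            xtx_inv = np.linalg.inv(X.T @ X)
            se = np.sqrt(s2 * xtx_inv[1, 1])
            if abs(beta[1] / se) > tcrit:
                rej += 1
        power = rej / n_sims
    else:
        raise ValidationError(f"unknown method {method!r}")
    return PowerResult(
        r_partial=r, n=n, n_predictors=k, alpha=alpha, power=power, method=method
    )
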