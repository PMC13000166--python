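"""Statistical core: group tests, effect sizes, correlation classification,
covariate-adjusted linear models and allometric scaling fits.

Two modelling families are exposed for organ-weight analysis:

* an ordinary linear model ``Y = α + βX + ε`` fitted by OLS, with the group
  indicator as an additional covariate when comparing groups (covariate
  adjustment instead of ratio normalization);
* the allometric power law ``Y = a·X^b``, fitted as the log–log regression
  ``ln Y = ln a + b·ln X``.  The exponent b is read against isometry
  (b = 1, organ growing in fixed proportion to body size) with the Wald
  statistic t = (b̂ − 1)/SE(b̂) on n − 2 degrees of freedom; b < 1 is
  negative allometry (the organ grows more slowly than the body).

Group tests are Student's pooled-variance two-sample t (Welch available
behind a flag), reported together with Cohen's d computed from the pooled
sample SD so that significance in large cohorts can be weighed against a
standardized effect size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .errors import DegenerateTestError, DesignMatrixError


# ----------------------------------------------------------------------
# group tests and effect sizes
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class GroupTestResult:
    """Two-sample comparison: t statistic, p-value and Cohen's d.

    ``direction`` is the sign of (mean_a − mean_b); the first-listed
    sample is group A, so the sign convention follows the caller's
    argument order.
    """

    mean_a: float
    mean_b: float
    t_stat: float
    df: float
    p_value: float
    cohens_d: float
    direction: int


def _pooled_sd(sd_a: float, n_a: int, sd_b: float, n_b: int) -> float:
    return math.sqrt(
        ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2)
    )


def cohens_d_summary(
    mean_a: float,
    sd_a: float,
    n_a: int,
    mean_b: float,
    sd_b: float,
    n_b: int,
    hedges: bool = False,
) -> float:
    """Cohen's d from summary statistics: (mean_a − mean_b) / pooled SD.

    The pooled SD uses sample (n−1) weights.  The classic (uncorrected)
    form is the default; ``hedges=True`` applies the small-sample
    correction factor 1 − 3/(4(n_a+n_b) − 9).
    """
    if n_a < 2 or n_b < 2:
        raise DegenerateTestError("need n >= 2 per group for a pooled SD")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be nonnegative")
    sp = _pooled_sd(sd_a, n_a, sd_b, n_b)
    if sp == 0:
        raise DegenerateTestError("zero pooled standard deviation")
    d = (mean_a - mean_b) / sp
    if hedges:
        d *= 1.0 - 3.0 / (4.0 * (n_a + n_b) - 9.0)
    return d


def student_t_test(
    sample_a, sample_b, welch: bool = False
) -> GroupTestResult:
    """Two-tailed two-sample t-test with Cohen's d.

    Default is Student's pooled-variance test with df = n_a + n_b − 2;
    ``welch=True`` switches to the Welch unequal-variance form (Cohen's d
    stays the pooled-SD definition either way).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    n_a, n_b = a.size, b.size
    if n_a < 2 or n_b < 2:
        raise DegenerateTestError("need at least 2 observations per group")
    sd_a = float(np.std(a, ddof=1))
    sd_b = float(np.std(b, ddof=1))
    # values equal up to rounding noise leave a pooled SD of machine
    # epsilon, not zero; both are degenerate for a t-test
    scale = max(float(np.max(np.abs(a))), float(np.max(np.abs(b))), 1.0)
    if _pooled_sd(sd_a, n_a, sd_b, n_b) <= 1e-12 * scale:
        raise DegenerateTestError(
            "zero pooled variance: values identical up to rounding"
        )
    res = st.ttest_ind(a, b, equal_var=not welch)
    mean_a, mean_b = float(np.mean(a)), float(np.mean(b))
    d = cohens_d_summary(mean_a, sd_a, n_a, mean_b, sd_b, n_b)
    diff = mean_a - mean_b
    return GroupTestResult(
        mean_a=mean_a,
        mean_b=mean_b,
        t_stat=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        cohens_d=d,
        direction=0 if diff == 0 else int(math.copysign(1, diff)),
    )


# ----------------------------------------------------------------------
# correlation
# ----------------------------------------------------------------------

STRENGTH_BINS = (
    (0.10, "negligible"),
    (0.40, "weak"),
    (0.70, "moderate"),
    (0.90, "strong"),
    (1.00 + 1e-12, "very strong"),
)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    strength: str


def classify_strength(abs_r: float) -> str:
    """Qualitative label for |r|.

    Half-open bins [0, 0.10) negligible, [0.10, 0.40) weak, [0.40, 0.70)
    moderate, [0.70, 0.90) strong, [0.90, 1.00] very strong; the lower
    edge of each bin belongs to the stronger label.
    """
    if not (0.0 <= abs_r <= 1.0):
        raise ValueError(f"|r| must be in [0, 1], got {abs_r}")
    for upper, label in STRENGTH_BINS:
        if abs_r < upper:
            return label
    return "very strong"  # pragma: no cover


def pearson_correlation(x, y) -> CorrelationResult:
    """Pearson product–moment correlation with strength classification."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired (equal length)")
    if x.size < 3:
        raise DegenerateTestError("need n >= 3 for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateTestError("zero variance in one of the variables")
    r = float(st.pearsonr(x, y).statistic)
    r = max(-1.0, min(1.0, r))
    return CorrelationResult(r=r, n=int(x.size), strength=classify_strength(abs(r)))


# ----------------------------------------------------------------------
# linear and allometric models
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class CoefficientEstimate:
    name: str
    estimate: float
    se: float
    ci_lower: float
    ci_upper: float
    p_value: float


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit summary: per-coefficient estimates with 95% CIs, R² and
    the exact adjusted R² = 1 − (1 − R²)(n − 1)/(n − k − 1)."""

    coefficients: dict[str, CoefficientEstimate]
    n: int
    k: int  # number of predictors, intercept excluded
    r2: float
    adj_r2: float
    residual_sd: float

    def __getitem__(self, name: str) -> CoefficientEstimate:
        return self.coefficients[name]


def adjusted_r2(r2: float, n: int, k: int) -> float:
    """1 − (1 − R²)(n − 1)/(n − k − 1) for k predictors."""
    if n - k - 1 <= 0:
        raise ValueError("adjusted R² undefined: n <= k + 1")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)


def fit_linear_model(
    response, predictors: pd.DataFrame, ci_level: float = 0.95
) -> RegressionResult:
    """OLS fit of ``response ~ intercept + predictors``.

    ``predictors`` is a DataFrame whose columns become named slope
    coefficients (a 0/1 group indicator column yields the adjusted group
    effect).  SEs use the residual variance with df = n − k − 1; CIs are
    t-quantile based at ``ci_level``.
    """
    y = np.asarray(response, dtype=float)
    X = pd.DataFrame(predictors).astype(float).reset_index(drop=True)
    n, k = len(y), X.shape[1]
    if len(X) != n:
        raise ValueError("response and predictors differ in length")
    if n <= k + 1:
        raise DesignMatrixError(f"need n > k + 1 (n={n}, k={k})")
    design = sm.add_constant(X, prepend=True, has_constant="add")
    design = design.rename(columns={"const": "Intercept"})
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise DesignMatrixError(
            "rank-deficient design; collinear columns among "
            f"{list(design.columns)}"
        )
    res = sm.OLS(y, design).fit()
    ci = res.conf_int(alpha=1 - ci_level)
    coefs = {}
    for name in design.columns:
        coefs[name] = CoefficientEstimate(
            name=name,
            estimate=float(res.params[name]),
            se=float(res.bse[name]),
            ci_lower=float(ci.loc[name, 0]),
            ci_upper=float(ci.loc[name, 1]),
            p_value=float(res.pvalues[name]),
        )
    return RegressionResult(
        coefficients=coefs,
        n=n,
        k=k,
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        residual_sd=float(np.sqrt(res.mse_resid)) if n > k + 1 else math.nan,
    )


@dataclass(frozen=True)
class AllometricFit:
    """Power-law fit Y = a·X^b via OLS on the natural-log scale.

    ``isometry_t = (b − 1)/se_b`` tests H0: b = 1 (two-sided, df = n − 2).
    """

    a: float
    b: float
    se_b: float
    n: int
    isometry_t: float
    isometry_p: float
    regression: RegressionResult = field(repr=False)
    log_base: str = "natural"


def fit_allometric(x, y) -> AllometricFit:
    """Fit the allometric model by log–log OLS.

    All values must be strictly positive; offending row indices are listed
    in the error rather than silently dropped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired (equal length)")
    bad = np.flatnonzero((x <= 0) | (y <= 0) | ~np.isfinite(x) | ~np.isfinite(y))
    if bad.size:
        raise ValueError(
            f"allometric fit needs strictly positive values; offending rows "
            f"(0-based): {bad[:20].tolist()}"
        )
    if x.size < 3:
        raise DesignMatrixError("need n >= 3 for the allometric fit")
    reg = fit_linear_model(np.log(y), pd.DataFrame({"log_x": np.log(x)}))
    b = reg["log_x"].estimate
    se_b = reg["log_x"].se
    n = reg.n
    # Interpolatory (noise-free) data leave only rounding error in the
    # residuals, so the raw SE is machine noise and the Wald ratio is
    # meaningless; such fits are reported as numerically exact (SE 0).
    if reg.r2 >= 1.0 - 1e-12:
        se_b = 0.0
    if se_b == 0:
        exact_isometric = abs(b - 1.0) <= 1e-8
        iso_t = 0.0 if exact_isometric else math.copysign(math.inf, b - 1.0)
        iso_p = 1.0 if exact_isometric else 0.0
    else:
        iso_t = (b - 1.0) / se_b
        iso_p = float(2.0 * st.t.sf(abs(iso_t), df=n - 2))
    return AllometricFit(
        a=math.exp(reg["Intercept"].estimate),
        b=b,
        se_b=se_b,
        n=n,
        isometry_t=iso_t,
        isometry_p=iso_p,
        regression=reg,
    )
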