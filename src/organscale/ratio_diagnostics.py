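"""Ratio indices with guardrails: proportionality diagnosis before use.

Dividing an organ measure by a body-size measure (e.g. HW/BW in mg/g) is
only a valid normalization when the two are strictly proportional — a
linear relationship whose regression line passes through the origin, so
that the ratio estimates a single constant.  This module computes ratios,
diagnoses proportionality (origin-compatible intercept plus at least a
moderate linear correlation) and refuses ratio-based group tests by
default when the diagnosis fails; callers may force the test and receive
the diagnosis alongside it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateTestError
from .scaling_models import (
    GroupTestResult,
    classify_strength,
    fit_linear_model,
    pearson_correlation,
    student_t_test,
)

#: |r| below this is considered too weak a linear relationship for a ratio;
#: the boundary of the "moderate" correlation class.
DEFAULT_LINEARITY_FLOOR = 0.40


def compute_ratio(numerator, denominator, scale: float = 1.0) -> np.ndarray:
    """Element-wise paired ratio numerator/denominator × scale.

    Pairing and order are preserved; a zero denominator raises with the
    offending (0-based) row index.
    """
    num = np.asarray(numerator, dtype=float)
    den = np.asarray(denominator, dtype=float)
    if num.shape != den.shape:
        raise ValueError("numerator and denominator must be paired")
    zero = np.flatnonzero(den == 0)
    if zero.size:
        raise ZeroDivisionError(
            f"zero denominator at rows (0-based): {zero[:20].tolist()}"
        )
    return num / den * scale


@dataclass(frozen=True)
class ProportionalityDiagnosis:
    """Outcome of the proportionality check for a candidate ratio.

    ``origin_compatible`` records whether the intercept CI of y ~ x
    contains 0; the verdict is ``ratio_permissible`` iff that holds AND
    |r| reaches the linearity floor.
    """

    intercept_estimate: float
    intercept_ci_lower: float
    intercept_ci_upper: float
    slope_estimate: float
    r: float
    origin_compatible: bool
    verdict: str  # "ratio_permissible" | "ratio_not_recommended"
    rationale: str
    alpha: float
    linearity_floor: float

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept_estimate,
            "ci": [self.intercept_ci_lower, self.intercept_ci_upper],
            "slope": self.slope_estimate,
            "r": self.r,
            "r_strength": classify_strength(min(abs(self.r), 1.0)),
            "origin_compatible": self.origin_compatible,
            "verdict": self.verdict,
            "rationale": self.rationale,
            "alpha": self.alpha,
            "linearity_floor": self.linearity_floor,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def proportionality_check(
    x,
    y,
    alpha: float = 0.05,
    linearity_floor: float = DEFAULT_LINEARITY_FLOOR,
) -> ProportionalityDiagnosis:
    """Diagnose whether y/x is a defensible normalization of y by x.

    Fits y ~ x by OLS; the ratio is permissible only when the
    (1 − alpha) CI of the intercept contains 0 (origin compatibility) and
    the Pearson correlation is at least ``linearity_floor`` in magnitude
    (the relationship is actually linear enough to normalize against).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    corr = pearson_correlation(x, y)
    reg = fit_linear_model(y, pd.DataFrame({"x": x}), ci_level=1 - alpha)
    ic = reg["Intercept"]
    origin_ok = ic.ci_lower <= 0.0 <= ic.ci_upper
    linear_ok = abs(corr.r) >= linearity_floor
    if origin_ok and linear_ok:
        verdict = "ratio_permissible"
        rationale = (
            f"intercept CI [{ic.ci_lower:.4g}, {ic.ci_upper:.4g}] contains 0 "
            f"and |r| = {abs(corr.r):.3f} >= {linearity_floor}"
        )
    else:
        verdict = "ratio_not_recommended"
        reasons = []
        if not origin_ok:
            reasons.append(
                f"regression line does not pass through the origin "
                f"(intercept {ic.estimate:.4g}, CI [{ic.ci_lower:.4g}, "
                f"{ic.ci_upper:.4g}] excludes 0)"
            )
        if not linear_ok:
            reasons.append(
                f"|r| = {abs(corr.r):.3f} below the linearity floor "
                f"{linearity_floor} ({classify_strength(min(abs(corr.r), 1.0))})"
            )
        rationale = "; ".join(reasons)
    return ProportionalityDiagnosis(
        intercept_estimate=ic.estimate,
        intercept_ci_lower=ic.ci_lower,
        intercept_ci_upper=ic.ci_upper,
        slope_estimate=reg["x"].estimate,
        r=corr.r,
        origin_compatible=origin_ok,
        verdict=verdict,
        rationale=rationale,
        alpha=alpha,
        linearity_floor=linearity_floor,
    )


@dataclass(frozen=True)
class RatioTestOutcome:
    """Result of a guarded ratio-based group comparison.

    When the diagnosis is adverse and ``force`` was not set, ``refused``
    is True and no test (hence no p-value) is attached; the full
    diagnosis always is.
    """

    diagnosis: ProportionalityDiagnosis
    test: GroupTestResult | None
    refused: bool
    message: str


def ratio_group_test(
    numerator,
    denominator,
    groups: Sequence,
    force: bool = False,
    alpha: float = 0.05,
    linearity_floor: float = DEFAULT_LINEARITY_FLOOR,
    scale: float = 1.0,
) -> RatioTestOutcome:
    """Group comparison of per-subject ratios, guarded by the diagnosis.

    ``groups`` holds exactly two distinct labels; group A is the smaller
    label under sorting.  The proportionality check runs first on the
    pooled (denominator, numerator) pairs: an adverse verdict refuses the
    test unless ``force=True``, in which case the t-test is returned with
    the adverse diagnosis attached.
    """
    num = np.asarray(numerator, dtype=float)
    den = np.asarray(denominator, dtype=float)
    groups = np.asarray(groups)
    if not (num.size == den.size == groups.size):
        raise ValueError("numerator, denominator and groups must be paired")
    labels = sorted(pd.unique(groups).tolist())
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    diagnosis = proportionality_check(
        den, num, alpha=alpha, linearity_floor=linearity_floor
    )
    if diagnosis.verdict == "ratio_not_recommended" and not force:
        return RatioTestOutcome(
            diagnosis=diagnosis,
            test=None,
            refused=True,
            message=(
                "ratio-based comparison refused: " + diagnosis.rationale
                + " (pass force=True to run it anyway)"
            ),
        )
    ratios = compute_ratio(num, den, scale=scale)
    mask_a = groups == labels[0]
    test = student_t_test(ratios[mask_a], ratios[~mask_a])
    message = (
        "ratio-based comparison run despite adverse diagnosis: "
        + diagnosis.rationale
        if diagnosis.verdict == "ratio_not_recommended"
        else "proportionality diagnosis favourable"
    )
    return RatioTestOutcome(
        diagnosis=diagnosis, test=test, refused=False, message=message
    )
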