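"""Two-group simulation cases probing when ratio indices mislead.

Two generic parameters P1 (a body-size-like quantity) and P2 (an
organ-weight-like quantity) are simulated for two independent groups of
``n_per_group`` subjects each.  P1 is always Normal(μ_g, σ) with a lower
mean in Group 2.  Three canonical cases differ only in how P2 arises:

* **1A** — linear but *non-proportional*: P2 = 30 + 1.5·P1 + ε (non-zero
  intercept).  The per-subject ratio then mixes the intercept with the
  denominator and its group ordering can *reverse* relative to raw P2.
* **1B** — strictly proportional: P2 = 1.5·P1 + ε.  The ratio estimates
  the proportionality constant and behaves.
* **1C** — independent: P2 ~ Normal(80, 5) with no P1 connection.  The
  ratio inherits the P1 group shift through its denominator, producing
  spurious "organ" differences (denominator leakage).

``analyze_case`` runs the three two-tailed Student t-tests (raw P1, raw
P2, per-subject ratio) plus the covariate-adjusted regression
P2 ~ P1 + group, and ``replicate`` turns that into Monte-Carlo rejection
and reversal rates.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml

from .errors import DegenerateTestError, SpecError
from .scaling_models import (
    GroupTestResult,
    RegressionResult,
    fit_linear_model,
    student_t_test,
)

RatioOrientation = Literal["p2_over_p1", "p1_over_p2"]

#: significance threshold used throughout unless overridden
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class ScenarioSpec:
    """Generative description of a two-group simulation case.

    For ``p2_rule="affine"``, P2 = intercept + slope·P1 + ε with
    ε ~ Normal(0, noise_sd); for ``"independent"``, P2 ~ Normal(p2_mean,
    p2_sd).  All Normal(m, s) parameters are mean and *standard
    deviation*.
    """

    case_label: str = "custom"  # "1A" | "1B" | "1C" | "custom"
    n_per_group: int = 10
    p1_mean_g1: float = 35.0
    p1_mean_g2: float = 30.0
    p1_sd: float = 3.0
    p2_rule: str = "affine"  # "affine" | "independent"
    intercept: float = 30.0
    slope: float = 1.5
    noise_sd: float = 3.0
    p2_mean: float = 80.0
    p2_sd: float = 5.0

    def __post_init__(self):
        if self.n_per_group < 2:
            raise SpecError("n_per_group must be >= 2")
        for name in ("p1_sd", "noise_sd", "p2_sd"):
            if getattr(self, name) < 0:
                raise SpecError(f"{name} must be >= 0")
        if self.p2_rule not in ("affine", "independent"):
            raise SpecError(f"unknown p2_rule {self.p2_rule!r}")
        if self.case_label not in ("1A", "1B", "1C", "custom"):
            raise SpecError(f"unknown case_label {self.case_label!r}")
        if self.case_label == "1A" and not (
            self.p2_rule == "affine" and self.intercept != 0
        ):
            raise SpecError("case 1A requires the affine rule with a non-zero intercept")
        if self.case_label == "1B" and not (
            self.p2_rule == "affine" and self.intercept == 0
        ):
            raise SpecError("case 1B requires the affine rule with zero intercept")
        if self.case_label == "1C" and self.p2_rule != "independent":
            raise SpecError("case 1C requires the independent rule")


def builtin_case(label: str) -> ScenarioSpec:
    """The canonical parameterizations of cases 1A, 1B and 1C.

    P1 ~ Normal(35, sd 3) in Group 1 and Normal(30, sd 3) in Group 2,
    n = 10 per group; 1A: P2 = 30 + 1.5·P1 + ε (ε sd 3); 1B: the same
    with zero intercept; 1C: P2 ~ Normal(80, sd 5) independently.
    """
    if label == "1A":
        return ScenarioSpec(case_label="1A", p2_rule="affine", intercept=30.0)
    if label == "1B":
        return ScenarioSpec(case_label="1B", p2_rule="affine", intercept=0.0)
    if label == "1C":
        return ScenarioSpec(case_label="1C", p2_rule="independent")
    raise SpecError(f"unknown case label {label!r}; expected 1A, 1B or 1C")


@dataclass(frozen=True)
class SimulatedDataset:
    """Per-subject rows (group ∈ {1, 2}, p1, p2) plus generating context."""

    df: pd.DataFrame = field(repr=False)
    spec: ScenarioSpec
    seed: int

    def group_values(self, column: str, group: int) -> np.ndarray:
        return self.df.loc[self.df["group"] == group, column].to_numpy()


def generate(spec: ScenarioSpec, seed: int) -> SimulatedDataset:
    """Draw one dataset from a scenario; deterministic in (spec, seed)."""
    rng = np.random.default_rng(seed)
    n = spec.n_per_group
    p1 = np.concatenate(
        [
            rng.normal(spec.p1_mean_g1, spec.p1_sd, size=n),
            rng.normal(spec.p1_mean_g2, spec.p1_sd, size=n),
        ]
    )
    if spec.p2_rule == "affine":
        eps = rng.normal(0.0, spec.noise_sd, size=2 * n)
        p2 = spec.intercept + spec.slope * p1 + eps
    else:
        p2 = rng.normal(spec.p2_mean, spec.p2_sd, size=2 * n)
    df = pd.DataFrame(
        {"group": np.repeat([1, 2], n), "p1": p1, "p2": p2}
    )
    return SimulatedDataset(df=df, spec=spec, seed=seed)


def generate_shared_noise(
    spec_a: ScenarioSpec, spec_b: ScenarioSpec, seed: int
) -> tuple[SimulatedDataset, SimulatedDataset]:
    """One realization of (P1, ε) pushed through two affine P2 rules.

    Both datasets share identical P1 and ε draws and differ only through
    intercept/slope, which isolates the algebraic effect of the intercept:
    fitted regressions differ only in their intercept estimate.
    """
    for s in (spec_a, spec_b):
        if s.p2_rule != "affine":
            raise SpecError("shared-noise generation requires affine p2 rules")
    same = (
        spec_a.n_per_group == spec_b.n_per_group
        and spec_a.p1_mean_g1 == spec_b.p1_mean_g1
        and spec_a.p1_mean_g2 == spec_b.p1_mean_g2
        and spec_a.p1_sd == spec_b.p1_sd
        and spec_a.noise_sd == spec_b.noise_sd
    )
    if not same:
        raise SpecError(
            "shared-noise specs must agree in n and in the P1 and ε distributions"
        )
    rng = np.random.default_rng(seed)
    n = spec_a.n_per_group
    p1 = np.concatenate(
        [
            rng.normal(spec_a.p1_mean_g1, spec_a.p1_sd, size=n),
            rng.normal(spec_a.p1_mean_g2, spec_a.p1_sd, size=n),
        ]
    )
    eps = rng.normal(0.0, spec_a.noise_sd, size=2 * n)
    group = np.repeat([1, 2], n)

    def build(spec):
        p2 = spec.intercept + spec.slope * p1 + eps
        df = pd.DataFrame({"group": group, "p1": p1, "p2": p2})
        return SimulatedDataset(df=df, spec=spec, seed=seed)

    return build(spec_a), build(spec_b)


@dataclass(frozen=True)
class CaseAnalysis:
    """Bundle of group tests plus covariate-adjusted regression.

    ``test_ratio`` is ``None`` when the ratio test is degenerate (zero
    within-group variance); ``ratio_error`` then carries the reason.
    ``reversal_flag`` is True when the group ordering of the mean ratio
    opposes the group ordering of mean P2 (Group 1 minus Group 2 signs
    disagree).
    """

    test_p1: GroupTestResult
    test_p2: GroupTestResult
    test_ratio: GroupTestResult | None
    ratio_error: str | None
    regression: RegressionResult
    ratio_orientation: RatioOrientation
    ratio_mean_g1: float
    ratio_mean_g2: float
    reversal_flag: bool


def analyze_case(
    data: SimulatedDataset,
    ratio_orientation: RatioOrientation = "p2_over_p1",
) -> CaseAnalysis:
    """Full per-dataset analysis: raw tests, ratio test, adjusted model.

    The regression is P2 ~ P1 + group with the group indicator coded
    0 for Group 1 (reference) and 1 for Group 2.  A degenerate ratio test
    is reported explicitly via ``ratio_error``, never as silent NaNs.
    """
    df = data.df
    g1 = df["group"] == 1
    p1_1, p1_2 = df.loc[g1, "p1"].to_numpy(), df.loc[~g1, "p1"].to_numpy()
    p2_1, p2_2 = df.loc[g1, "p2"].to_numpy(), df.loc[~g1, "p2"].to_numpy()
    if min(p1_1.size, p1_2.size) < 2:
        raise DegenerateTestError("need >= 2 subjects per group")

    if ratio_orientation == "p2_over_p1":
        num_1, den_1, num_2, den_2 = p2_1, p1_1, p2_2, p1_2
    elif ratio_orientation == "p1_over_p2":
        num_1, den_1, num_2, den_2 = p1_1, p2_1, p1_2, p2_2
    else:
        raise ValueError(f"unknown ratio orientation {ratio_orientation!r}")
    if (den_1 == 0).any() or (den_2 == 0).any():
        raise DegenerateTestError("zero denominator in ratio computation")
    ratio_1, ratio_2 = num_1 / den_1, num_2 / den_2

    test_p1 = student_t_test(p1_1, p1_2)
    test_p2 = student_t_test(p2_1, p2_2)
    try:
        test_ratio, ratio_error = student_t_test(ratio_1, ratio_2), None
    except DegenerateTestError as exc:
        test_ratio, ratio_error = None, str(exc)

    regression = fit_linear_model(
        df["p2"],
        pd.DataFrame({"p1": df["p1"], "group": (df["group"] == 2).astype(float)}),
    )

    rmean_1, rmean_2 = float(np.mean(ratio_1)), float(np.mean(ratio_2))
    ratio_dir = math.copysign(1, rmean_1 - rmean_2) if rmean_1 != rmean_2 else 0
    p2_dir = test_p2.direction
    return CaseAnalysis(
        test_p1=test_p1,
        test_p2=test_p2,
        test_ratio=test_ratio,
        ratio_error=ratio_error,
        regression=regression,
        ratio_orientation=ratio_orientation,
        ratio_mean_g1=rmean_1,
        ratio_mean_g2=rmean_2,
        reversal_flag=bool(ratio_dir != 0 and p2_dir != 0 and ratio_dir != p2_dir),
    )


@dataclass(frozen=True)
class ReplicationSummary:
    """Monte-Carlo aggregate over independent replicates of one scenario.

    Rejection rates count two-sided p ≤ alpha among non-degenerate
    replicates; ``n_ratio_degenerate`` counts exclusions of the ratio
    test.  ``mc_se(rate)`` gives the binomial Monte-Carlo standard error
    sqrt(rate·(1 − rate)/n_reps).
    """

    spec: ScenarioSpec
    n_reps: int
    alpha: float
    ratio_orientation: RatioOrientation
    rejection_rate_p1: float
    rejection_rate_p2: float
    rejection_rate_ratio: float
    reversal_rate: float
    n_ratio_degenerate: int
    mean_p2_diff: float
    mean_ratio_diff: float

    def mc_se(self, rate: float) -> float:
        return math.sqrt(rate * (1.0 - rate) / self.n_reps)


def replicate(
    spec: ScenarioSpec,
    n_reps: int,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
    ratio_orientation: RatioOrientation = "p2_over_p1",
    collect: bool = False,
) -> ReplicationSummary | tuple[ReplicationSummary, pd.DataFrame]:
    """Repeat generate → analyze ``n_reps`` times and aggregate.

    Per-replicate seeds are derived from ``seed`` through a SeedSequence
    so replicates are independent yet the whole study is reproducible.
    With ``collect=True`` also returns a tidy per-replicate DataFrame.
    """
    if n_reps < 1:
        raise SpecError("n_reps must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_reps, dtype=np.uint32)
    rej_p1 = rej_p2 = rej_ratio = reversals = degenerate = 0
    p2_diffs, ratio_diffs = [], []
    rows = []
    for rep, s in enumerate(child_seeds):
        analysis = analyze_case(generate(spec, int(s)), ratio_orientation)
        rej_p1 += analysis.test_p1.p_value <= alpha
        rej_p2 += analysis.test_p2.p_value <= alpha
        if analysis.test_ratio is None:
            degenerate += 1
        else:
            rej_ratio += analysis.test_ratio.p_value <= alpha
        reversals += analysis.reversal_flag
        p2_diffs.append(analysis.test_p2.mean_a - analysis.test_p2.mean_b)
        ratio_diffs.append(analysis.ratio_mean_g1 - analysis.ratio_mean_g2)
        if collect:
            for name, t in (
                ("p1", analysis.test_p1),
                ("p2", analysis.test_p2),
                ("ratio", analysis.test_ratio),
            ):
                rows.append(
                    dict(
                        replicate=rep,
                        test=name,
                        t_stat=math.nan if t is None else t.t_stat,
                        p_value=math.nan if t is None else t.p_value,
                        cohens_d=math.nan if t is None else t.cohens_d,
                        reversal=analysis.reversal_flag,
                    )
                )
    n_ratio_ok = n_reps - degenerate
    summary = ReplicationSummary(
        spec=spec,
        n_reps=n_reps,
        alpha=alpha,
        ratio_orientation=ratio_orientation,
        rejection_rate_p1=rej_p1 / n_reps,
        rejection_rate_p2=rej_p2 / n_reps,
        rejection_rate_ratio=rej_ratio / n_ratio_ok if n_ratio_ok else math.nan,
        reversal_rate=reversals / n_reps,
        n_ratio_degenerate=degenerate,
        mean_p2_diff=float(np.mean(p2_diffs)),
        mean_ratio_diff=float(np.mean(ratio_diffs)),
    )
    if collect:
        return summary, pd.DataFrame(rows)
    return summary


def scenario_to_dict(spec: ScenarioSpec) -> dict:
    return asdict(spec)


def scenario_from_dict(d: dict) -> ScenarioSpec:
    return ScenarioSpec(**d)


def write_scenario(spec: ScenarioSpec, path: str | Path) -> None:
    """Serialize a scenario to YAML (or JSON when the suffix is .json)."""
    path = Path(path)
    d = scenario_to_dict(spec)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def read_scenario(path: str | Path) -> ScenarioSpec:
    path = Path(path)
    text = path.read_text()
    d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return scenario_from_dict(d)


def regression_summary_frame(
    analyses: dict[str, CaseAnalysis]
) -> pd.DataFrame:
    """Tidy regression report, one row per case × coefficient.

    Columns mirror the standard two-group report: case, coefficient,
    estimate, ci_lower, ci_upper, p_value, n, r2, adj_r2.
    """
    rows = []
    for case, analysis in analyses.items():
        reg = analysis.regression
        for name, coef in reg.coefficients.items():
            rows.append(
                dict(
                    case=case,
                    coefficient=name,
                    estimate=coef.estimate,
                    ci_lower=coef.ci_lower,
                    ci_upper=coef.ci_upper,
                    p_value=coef.p_value,
                    n=reg.n,
                    r2=reg.r2,
                    adj_r2=reg.adj_r2,
                )
            )
    return pd.DataFrame(rows)
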