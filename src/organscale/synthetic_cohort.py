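"""Synthetic mouse-like cohorts with a realistic organ/body-size structure.

Real heart-weight phenotyping data show approximately normal marginals for
heart weight (HW, mg), body weight (BW, g) and tibia length (TL, mm) within
each sex × age stratum, with only negligible-to-weak HW–BW and HW–TL
correlations.  The generator reproduces exactly that structure so every
downstream stage (descriptives, group tests, regression, allometry, ratio
diagnostics) can be exercised without external data.

Two coupling modes are available per stratum:

* ``gaussian_copula`` — (BW, TL, HW) drawn from a trivariate normal with
  the stratum's marginal means/SDs and target pairwise correlations; this
  is the default because real cohorts are reported via marginals and
  correlations only.
* ``allometric`` — BW and TL drawn as a bivariate normal, then
  HW = a·BW^b·exp(ε) with ε ~ Normal(0, log_noise_sd); this encodes the
  power-law model explicitly and is used for exponent-recovery tests.

The joint trivariate-normal form is this package's modelling choice, not
an empirical fact; see docs/methods.md.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .cohort_io import ALL_COLUMNS, AgeGroup, CohortTable, Sex
from .errors import SpecError

#: TL–BW correlation is not reported for the real cohorts; a weak default
#: consistent with the negligible-to-weak correlation landscape.
DEFAULT_R_TL_BW = 0.30

_MAX_REDRAW_ROUNDS = 100  # cap on reject-and-redraw rounds for positivity


@dataclass
class StratumGenSpec:
    """Generative description of one sex × age stratum."""

    sex: Sex
    age_group: AgeGroup
    n: int
    bw_mean: float  # g
    bw_sd: float
    tl_mean: float  # mm
    tl_sd: float
    hw_mean: float  # mg
    hw_sd: float
    r_hw_bw: float = 0.0
    r_hw_tl: float = 0.0
    r_tl_bw: float = DEFAULT_R_TL_BW
    coupling: str = "gaussian_copula"  # or "allometric"
    allometric_a: float | None = None
    allometric_b: float | None = None
    log_noise_sd: float | None = None

    def __post_init__(self):
        self.sex = Sex(self.sex)
        self.age_group = AgeGroup(self.age_group)
        if self.n < 0:
            raise SpecError("n must be >= 0")
        for name in ("bw_sd", "tl_sd", "hw_sd"):
            if getattr(self, name) < 0:
                raise SpecError(f"{name} must be >= 0")
        for name in ("r_hw_bw", "r_hw_tl", "r_tl_bw"):
            r = getattr(self, name)
            if not -1.0 <= r <= 1.0:
                raise SpecError(f"{name} must be in [-1, 1], got {r}")
        if self.coupling not in ("gaussian_copula", "allometric"):
            raise SpecError(f"unknown coupling {self.coupling!r}")
        if self.coupling == "allometric":
            if (
                self.allometric_a is None
                or self.allometric_b is None
                or self.log_noise_sd is None
            ):
                raise SpecError(
                    "allometric coupling needs allometric_a, allometric_b "
                    "and log_noise_sd"
                )
            if self.allometric_a <= 0 or self.log_noise_sd < 0:
                raise SpecError("allometric_a must be > 0 and log_noise_sd >= 0")
        else:
            # the implied (BW, TL, HW) correlation matrix must be PSD
            eigvals = np.linalg.eigvalsh(self.correlation_matrix())
            if eigvals.min() < -1e-10:
                raise SpecError(
                    "correlation targets do not form a positive semi-definite "
                    f"matrix (min eigenvalue {eigvals.min():.3g})"
                )

    def correlation_matrix(self) -> np.ndarray:
        """3×3 correlation matrix in (BW, TL, HW) order."""
        return np.array(
            [
                [1.0, self.r_tl_bw, self.r_hw_bw],
                [self.r_tl_bw, 1.0, self.r_hw_tl],
                [self.r_hw_bw, self.r_hw_tl, 1.0],
            ]
        )


# Reference marginals per stratum: (BW mean, sd), (HW mean, sd), (TL mean, sd),
# HW–BW and HW–TL correlation targets, and the heart-weight stratum size.
_DEFAULTS: dict[tuple[AgeGroup, Sex], dict] = {
    (AgeGroup.EA, Sex.FEMALE): dict(
        n=11016, bw_mean=23.7, bw_sd=2.6, hw_mean=115.9, hw_sd=19.2,
        tl_mean=18.3, tl_sd=0.6, r_hw_bw=0.21, r_hw_tl=0.058,
    ),
    (AgeGroup.EA, Sex.MALE): dict(
        n=10830, bw_mean=29.4, bw_sd=3.5, hw_mean=139.5, hw_sd=26.4,
        tl_mean=18.4, tl_sd=0.5, r_hw_bw=0.21, r_hw_tl=0.014,
    ),
    (AgeGroup.LA, Sex.FEMALE): dict(
        n=1782, bw_mean=37.2, bw_sd=6.9, hw_mean=139.5, hw_sd=17.7,
        tl_mean=18.7, tl_sd=0.4, r_hw_bw=0.26, r_hw_tl=0.055,
    ),
    (AgeGroup.LA, Sex.MALE): dict(
        n=1699, bw_mean=44.4, bw_sd=7.1, hw_mean=169.8, hw_sd=26.0,
        tl_mean=18.8, tl_sd=0.4, r_hw_bw=-0.069, r_hw_tl=-0.12,
    ),
}


def default_spec(n: int | None = None) -> dict[tuple[AgeGroup, Sex], StratumGenSpec]:
    """The four reference strata (sex × {EA, LA}) with published marginals
    and correlation targets, gaussian_copula coupling.

    ``n`` overrides the per-stratum sample size (default: the real
    heart-weight stratum sizes, totalling 25,327).
    """
    specs = {}
    for (age, sex), params in _DEFAULTS.items():
        params = dict(params)
        if n is not None:
            params["n"] = n
        specs[(age, sex)] = StratumGenSpec(sex=sex, age_group=age, **params)
    return specs


def _draw_positive(rng: np.random.Generator, draw, n: int) -> np.ndarray:
    """Sample n rows via ``draw``, rejecting and redrawing rows with any
    non-positive coordinate.  With realistic parameters rejections are
    astronomically rare; a hard cap guards degenerate specs."""
    out = draw(n)
    bad = np.flatnonzero((out <= 0).any(axis=1))
    rounds = 0
    while bad.size:
        rounds += 1
        if rounds > _MAX_REDRAW_ROUNDS:
            raise SpecError(
                "could not draw strictly positive measurements; spec places "
                "substantial mass below zero"
            )
        out[bad] = draw(bad.size)
        bad = bad[np.flatnonzero((out[bad] <= 0).any(axis=1))]
    return out


def _generate_stratum(spec: StratumGenSpec, rng: np.random.Generator) -> pd.DataFrame:
    n = spec.n
    if spec.coupling == "gaussian_copula":
        mean = np.array([spec.bw_mean, spec.tl_mean, spec.hw_mean])
        sds = np.array([spec.bw_sd, spec.tl_sd, spec.hw_sd])
        cov = spec.correlation_matrix() * np.outer(sds, sds)

        def draw(m):
            return rng.multivariate_normal(mean, cov, size=m, method="svd")

        bw, tl, hw = _draw_positive(rng, draw, n).T
    else:
        mean = np.array([spec.bw_mean, spec.tl_mean])
        sds = np.array([spec.bw_sd, spec.tl_sd])
        corr = np.array([[1.0, spec.r_tl_bw], [spec.r_tl_bw, 1.0]])
        cov = corr * np.outer(sds, sds)

        def draw(m):
            return rng.multivariate_normal(mean, cov, size=m, method="svd")

        bw, tl = _draw_positive(rng, draw, n).T
        eps = rng.normal(0.0, spec.log_noise_sd, size=n)
        hw = spec.allometric_a * bw**spec.allometric_b * np.exp(eps)

    return pd.DataFrame(
        {
            "animal_id": [
                f"{spec.age_group.value}-{spec.sex.value[0].upper()}-{i:06d}"
                for i in range(n)
            ],
            "sex": spec.sex.value,
            "age_group": spec.age_group.value,
            "heart_weight_mg": hw,
            "body_weight_g": bw,
            "tibia_length_mm": tl,
            "centre": "synthetic",
        }
    )


def generate_cohort(
    specs: Iterable[StratumGenSpec] | Mapping[tuple, StratumGenSpec],
    seed: int,
) -> CohortTable:
    """Generate a cohort from stratum specs; deterministic in (specs, seed).

    One generator is seeded per call and consumed stratum by stratum in the
    given order, so identical inputs yield identical tables within this
    implementation (no cross-library bit-reproducibility is promised).
    """
    if isinstance(specs, Mapping):
        specs = list(specs.values())
    else:
        specs = list(specs)
    rng = np.random.default_rng(seed)
    frames = [_generate_stratum(s, rng) for s in specs]
    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.DataFrame(columns=list(ALL_COLUMNS))
    return CohortTable(df, provenance=f"synthetic(seed={seed})")


# ----------------------------------------------------------------------
# spec serialization
# ----------------------------------------------------------------------

def specs_to_dict(specs) -> list[dict]:
    if isinstance(specs, Mapping):
        specs = list(specs.values())
    out = []
    for s in specs:
        d = asdict(s)
        d["sex"] = s.sex.value
        d["age_group"] = s.age_group.value
        out.append(d)
    return out


def specs_from_dict(items: Iterable[dict]) -> list[StratumGenSpec]:
    return [StratumGenSpec(**d) for d in items]


def write_specs(specs, path: str | Path) -> None:
    """Serialize specs to YAML (or JSON when the suffix is .json)."""
    path = Path(path)
    data = specs_to_dict(specs)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def read_specs(path: str | Path) -> list[StratumGenSpec]:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return specs_from_dict(data)
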