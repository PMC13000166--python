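"""Cohort data model, CSV I/O, stratification and descriptive summaries.

The central container is :class:`CohortTable`, a thin validated wrapper
around a :class:`pandas.DataFrame` holding one row per animal with sex,
age group (early adult ``EA`` / late adult ``LA``), heart weight [mg],
body weight [g] and optional tibia length [mm].  Stratification by
(sex, age group) partitions a cohort into the four strata used throughout
organ-weight phenotyping, and :func:`summarize_stratum` produces the
descriptive layer: mean ± sample SD plus the median with the 95% reference
range (2.5th and 97.5th percentiles).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .errors import CohortValidationError, SchemaError


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"


class AgeGroup(str, enum.Enum):
    EA = "EA"  # early adult, median 16 weeks
    LA = "LA"  # late adult, median 60 weeks


#: canonical column order of the cohort CSV dialect
MANDATORY_COLUMNS = (
    "animal_id",
    "sex",
    "age_group",
    "heart_weight_mg",
    "body_weight_g",
)
OPTIONAL_COLUMNS = ("tibia_length_mm", "centre")
ALL_COLUMNS = MANDATORY_COLUMNS + OPTIONAL_COLUMNS

# the reader optionally maps long-form age tokens onto the canonical codes
_AGE_ALIASES = {
    "ea": "EA",
    "la": "LA",
    "early adult": "EA",
    "early-adult": "EA",
    "late adult": "LA",
    "late-adult": "LA",
}
_SEX_TOKENS = {s.value for s in Sex}
_AGE_TOKENS = {a.value for a in AgeGroup}


@dataclass(frozen=True)
class CohortRecord:
    """A single animal: identifiers, stratum labels and measurements."""

    animal_id: str
    sex: Sex
    age_group: AgeGroup
    heart_weight: float  # mg
    body_weight: float  # g
    tibia_length: float | None = None  # mm; absent when not measured
    centre: str | None = None


class CohortTable:
    """Ordered, validated collection of :class:`CohortRecord`.

    Internally backed by a DataFrame with the canonical columns; missing
    tibia length and centre are ``NaN``/``None``.  Construction validates
    positivity of weights, enum tokens and uniqueness of ``animal_id``.
    """

    def __init__(self, df: pd.DataFrame, provenance: str = ""):
        df = df.copy().reset_index(drop=True)
        for col in MANDATORY_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"missing mandatory column: {col!r}")
        for col in OPTIONAL_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan if col == "tibia_length_mm" else None
        df = df[list(ALL_COLUMNS)]

        df["animal_id"] = df["animal_id"].astype(str)
        if df["animal_id"].duplicated().any():
            dup = df.loc[df["animal_id"].duplicated(), "animal_id"].iloc[0]
            raise CohortValidationError(f"duplicate animal_id {dup!r}")

        bad_sex = ~df["sex"].isin(_SEX_TOKENS)
        if bad_sex.any():
            i = int(np.flatnonzero(bad_sex)[0])
            raise CohortValidationError(
                f"unknown sex token {df['sex'].iloc[i]!r}; "
                f"permitted: {sorted(_SEX_TOKENS)}",
                row=i + 1,
            )
        bad_age = ~df["age_group"].isin(_AGE_TOKENS)
        if bad_age.any():
            i = int(np.flatnonzero(bad_age)[0])
            raise CohortValidationError(
                f"unknown age_group token {df['age_group'].iloc[i]!r}; "
                f"permitted: {sorted(_AGE_TOKENS)}",
                row=i + 1,
            )

        for col in ("heart_weight_mg", "body_weight_g", "tibia_length_mm"):
            vals = pd.to_numeric(df[col], errors="coerce")
            raw_missing = df[col].isna()
            unparsable = vals.isna() & ~raw_missing
            if col != "tibia_length_mm" and raw_missing.any():
                i = int(np.flatnonzero(raw_missing)[0])
                raise CohortValidationError(f"missing {col}", row=i + 1)
            if unparsable.any():
                i = int(np.flatnonzero(unparsable)[0])
                raise CohortValidationError(
                    f"non-numeric {col}: {df[col].iloc[i]!r}", row=i + 1
                )
            nonpos = vals <= 0  # NaN compares False, so absent TL passes
            if nonpos.any():
                i = int(np.flatnonzero(nonpos)[0])
                raise CohortValidationError(
                    f"non-positive {col}: {vals.iloc[i]}", row=i + 1
                )
            df[col] = vals.astype(float)

        self._df = df
        self.provenance = provenance

    # ------------------------------------------------------------------
    @classmethod
    def from_records(
        cls, records: Iterable[CohortRecord], provenance: str = ""
    ) -> "CohortTable":
        rows = [
            {
                "animal_id": r.animal_id,
                "sex": Sex(r.sex).value,
                "age_group": AgeGroup(r.age_group).value,
                "heart_weight_mg": r.heart_weight,
                "body_weight_g": r.body_weight,
                "tibia_length_mm": np.nan if r.tibia_length is None else r.tibia_length,
                "centre": r.centre,
            }
            for r in records
        ]
        df = pd.DataFrame(rows, columns=list(ALL_COLUMNS))
        return cls(df, provenance=provenance)

    @property
    def df(self) -> pd.DataFrame:
        """The underlying DataFrame (do not mutate)."""
        return self._df

    def to_dataframe(self) -> pd.DataFrame:
        return self._df.copy()

    def __len__(self) -> int:
        return len(self._df)

    def __iter__(self) -> Iterator[CohortRecord]:
        return iter(self.records())

    def records(self) -> list[CohortRecord]:
        out = []
        for row in self._df.itertuples(index=False):
            tl = row.tibia_length_mm
            centre = row.centre
            out.append(
                CohortRecord(
                    animal_id=row.animal_id,
                    sex=Sex(row.sex),
                    age_group=AgeGroup(row.age_group),
                    heart_weight=float(row.heart_weight_mg),
                    body_weight=float(row.body_weight_g),
                    tibia_length=None if pd.isna(tl) else float(tl),
                    centre=None if centre in (None, "") or pd.isna(centre) else str(centre),
                )
            )
        return out


@dataclass(frozen=True)
class StratumSummary:
    """Descriptive summary of one parameter within one stratum.

    ``sd`` is the sample (n−1 denominator) standard deviation and is
    ``None`` (undefined) when n = 1.  ``p2_5``/``p97_5`` bound the 95%
    reference range.
    """

    n: int
    mean: float
    sd: float | None
    median: float
    p2_5: float
    p97_5: float


def read_cohort_csv(
    path: str | Path, map_age_aliases: bool = True, provenance: str | None = None
) -> CohortTable:
    """Read the standard cohort CSV into a validated :class:`CohortTable`.

    The dialect is comma-separated UTF-8 with a header row naming at least
    the mandatory columns; empty cells in ``tibia_length_mm``/``centre``
    mean "absent".  Lines starting with ``#`` (provenance comments) are
    ignored.  Row order is preserved.
    """
    path = Path(path)
    raw = pd.read_csv(
        path, dtype=str, comment="#", keep_default_na=False, skip_blank_lines=True
    )
    raw.columns = [c.strip() for c in raw.columns]
    for col in MANDATORY_COLUMNS:
        if col not in raw.columns:
            raise SchemaError(f"missing mandatory column: {col!r} in {path.name}")

    df = pd.DataFrame()
    df["animal_id"] = raw["animal_id"].str.strip()
    df["sex"] = raw["sex"].str.strip().str.lower()
    age = raw["age_group"].str.strip()
    if map_age_aliases:
        age = age.map(lambda t: _AGE_ALIASES.get(t.lower(), t))
    df["age_group"] = age
    for col in ("heart_weight_mg", "body_weight_g"):
        df[col] = raw[col].str.strip().replace("", np.nan)
    if "tibia_length_mm" in raw.columns:
        df["tibia_length_mm"] = raw["tibia_length_mm"].str.strip().replace("", np.nan)
    if "centre" in raw.columns:
        centre = raw["centre"].str.strip()
        df["centre"] = centre.where(centre != "", None)
    return CohortTable(df, provenance=provenance if provenance is not None else str(path))


def write_cohort_csv(table: CohortTable, path: str | Path) -> None:
    """Write a cohort in the standard dialect (empty string = missing)."""
    df = table.df.copy()
    df["centre"] = df["centre"].fillna("")
    df.to_csv(path, index=False, na_rep="")


def stratify(table: CohortTable) -> dict[tuple[Sex, AgeGroup], CohortTable]:
    """Partition a cohort by (sex, age group).

    Always returns all four strata; a stratum with no animals maps to an
    empty table.  The union of the outputs is exactly the input.
    """
    out: dict[tuple[Sex, AgeGroup], CohortTable] = {}
    df = table.df
    for sex in Sex:
        for age in AgeGroup:
            mask = (df["sex"] == sex.value) & (df["age_group"] == age.value)
            out[(sex, age)] = CohortTable(
                df.loc[mask], provenance=f"{table.provenance}[{sex.value},{age.value}]"
            )
    return out


def summarize_stratum(
    values: Iterable[float], percentile_method: str = "linear"
) -> StratumSummary:
    """Descriptive summary: mean, sample SD, median and 95% reference range.

    Percentiles use linear interpolation between closest ranks by default
    (configurable via ``percentile_method``, passed to numpy).  Missing
    values (NaN) are dropped before summarising; ``n`` counts what remains.
    """
    x = np.asarray(list(values), dtype=float)
    x = x[~np.isnan(x)]
    n = x.size
    if n == 0:
        raise CohortValidationError("cannot summarize an empty collection")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1)) if n >= 2 else None
    median = float(np.median(x))
    p2_5, p97_5 = (
        float(v) for v in np.percentile(x, [2.5, 97.5], method=percentile_method)
    )
    return StratumSummary(n=n, mean=mean, sd=sd, median=median, p2_5=p2_5, p97_5=p97_5)


#: parameter label -> cohort column
PARAMETER_COLUMNS = {
    "heart_weight_mg": "heart_weight_mg",
    "body_weight_g": "body_weight_g",
    "tibia_length_mm": "tibia_length_mm",
}


def summarize_cohort(table: CohortTable) -> pd.DataFrame:
    """Stratum × parameter summary table.

    One row per (age_group, sex, parameter) with columns
    ``age_group,sex,parameter,mean,sd,median,p2_5,p97_5,n``.  Strata with
    no data for a parameter are flagged with n = 0 and NaN statistics
    rather than dropped.
    """
    rows = []
    strata = stratify(table)
    for age in AgeGroup:
        for sex in Sex:
            sub = strata[(sex, age)].df
            for param, col in PARAMETER_COLUMNS.items():
                vals = sub[col].dropna()
                if len(vals) == 0:
                    rows.append(
                        dict(
                            age_group=age.value, sex=sex.value, parameter=param,
                            mean=math.nan, sd=math.nan, median=math.nan,
                            p2_5=math.nan, p97_5=math.nan, n=0,
                        )
                    )
                    continue
                s = summarize_stratum(vals)
                rows.append(
                    dict(
                        age_group=age.value, sex=sex.value, parameter=param,
                        mean=s.mean, sd=math.nan if s.sd is None else s.sd,
                        median=s.median, p2_5=s.p2_5, p97_5=s.p97_5, n=s.n,
                    )
                )
    return pd.DataFrame(rows)
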