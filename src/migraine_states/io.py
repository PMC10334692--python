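"""Readers, writers and validation for GBD-Results-Tool-style extracts.

Two kinds of input feed the pipeline:

* long-format CSV extracts of active-migraine prevalence and incidence with
  95% uncertainty intervals, keyed by (measure, location, sex, year, age
  group) in the layout of the GBD Results Tool;
* a small table of lifetime migraine prevalence by 10-year age group and sex
  with 95% confidence limits (four groups spanning ages 25-64).

Age-group labels are mapped to continuous age midpoints, treating each group
as the half-open year span [lower, upper + 1), so "10 to 14" -> 12.5 and the
open-ended "95 plus" -> 97.5.  All values are stored as proportions (for
prevalence) or rates per person-year (for incidence); percent appears only
at reporting boundaries.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

MEASURES = ("prevalence", "incidence")
LOCATIONS = ("Germany", "Global")
SEXES = ("male", "female")

#: Ordered GBD age-group labels, youngest first.
AGE_LABELS: tuple[str, ...] = ("<1 year", "1 to 4") + tuple(
    f"{lo} to {lo + 4}" for lo in range(5, 95, 5)
) + ("95 plus",)

#: Lifetime-prevalence age groups and their midpoints.
LIFETIME_GROUPS: dict[str, float] = {
    "25-34": 29.5,
    "35-44": 39.5,
    "45-54": 49.5,
    "55-64": 59.5,
}

#: Fixed column order for normalized GBD CSV output.
GBD_COLUMNS = (
    "measure", "location", "sex", "year",
    "age_label", "age_mid", "value", "lower", "upper",
)

KEY_COLUMNS = ("measure", "location", "sex", "year", "age_mid")


class SchemaError(ValueError):
    """A required column is missing from an input file."""


class ValidationError(ValueError):
    """Input rows violate the container invariants."""


class ParseError(ValueError):
    """A label or field could not be interpreted."""


def age_midpoint(age_label: str) -> float:
    """Midpoint in years of a GBD age-group label.

    Groups are read as half-open integer-year spans, so "5 to 9" covers
    [5, 10) with midpoint 7.5; "<1 year" is [0, 1) with midpoint 0.5 and
    "95 plus" is assigned 97.5.
    """
    label = age_label.strip()
    if label == "<1 year":
        return 0.5
    if label == "95 plus":
        return 97.5
    parts = label.split(" to ")
    if len(parts) == 2:
        try:
            lo, hi = int(parts[0]), int(parts[1])
        except ValueError:
            raise ParseError(f"unrecognized age label: {age_label!r}") from None
        if label in AGE_LABELS:
            return (lo + hi + 1) / 2.0
    raise ParseError(f"unrecognized age label: {age_label!r}")


def lifetime_midpoint(age_group: str) -> float:
    """Midpoint of a lifetime-prevalence age group such as "25-34"."""
    key = age_group.strip().replace("–", "-").replace(" to ", "-")
    if key not in LIFETIME_GROUPS:
        raise ParseError(f"unrecognized lifetime age group: {age_group!r}")
    return LIFETIME_GROUPS[key]


@dataclass
class GbdTable:
    """Tidy long-format prevalence/incidence records with uncertainty limits.

    ``frame`` holds one row per (measure, location, sex, year, age_mid) with
    columns :data:`GBD_COLUMNS`.  ``rejects`` carries rows that failed row
    invariants during reading together with the reason, so that
    ``len(input) == len(frame) + len(rejects)``.
    """

    frame: pd.DataFrame
    meta: dict = field(default_factory=dict)
    rejects: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = [c for c in GBD_COLUMNS if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"missing columns: {missing}")
        self.frame = self.frame.loc[:, list(GBD_COLUMNS)].reset_index(drop=True)
        dup = self.frame.duplicated(subset=list(KEY_COLUMNS), keep=False)
        if dup.any():
            keys = self.frame.loc[dup, list(KEY_COLUMNS)].drop_duplicates()
            raise ValidationError(
                "duplicate keys:\n" + keys.to_string(index=False)
            )
        order = self.frame.sort_values(list(KEY_COLUMNS)).index
        self.frame = self.frame.loc[order].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def slice(self, measure: str, sex: str, location: str) -> pd.DataFrame:
        """Rows for one (measure, sex, location), sorted by year then age."""
        f = self.frame
        out = f[(f["measure"] == measure) & (f["sex"] == sex)
                & (f["location"] == location)]
        return out.sort_values(["year", "age_mid"]).reset_index(drop=True)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False, columns=list(GBD_COLUMNS))

    def perturbed(self, values: Sequence[float]) -> "GbdTable":
        """Copy of the table with ``value`` replaced (used by resampling)."""
        frame = self.frame.copy()
        frame["value"] = list(values)
        return GbdTable(frame, meta=dict(self.meta))


def _row_problems(df: pd.DataFrame) -> pd.Series:
    """Reason string per row, empty where the row satisfies all invariants."""
    reason = pd.Series("", index=df.index, dtype=object)
    bad_order = ~((df["lower"] <= df["value"]) & (df["value"] <= df["upper"]))
    reason[bad_order] += "value outside [lower, upper];"
    neg = df["lower"] < 0
    reason[neg] += "negative lower limit;"
    prev = df["measure"] == "prevalence"
    out01 = prev & ~df["value"].between(0.0, 1.0)
    reason[out01] += "prevalence outside [0, 1];"
    neg_inc = (df["measure"] == "incidence") & (df["value"] < 0)
    reason[neg_inc] += "negative incidence;"
    nonnum = ~(df[["value", "lower", "upper"]].apply(
        lambda c: pd.to_numeric(c, errors="coerce")).notna().all(axis=1))
    reason[nonnum] = "non-numeric value/lower/upper;"
    return reason


def read_gbd_csv(
    path: str | Path | _io.IOBase,
    schema: Mapping[str, str] | None = None,
    on_invalid: str = "raise",
    year_range: tuple[int, int] = (1990, 2019),
) -> GbdTable:
    """Read a GBD-Results-Tool-style CSV into a validated :class:`GbdTable`.

    Parameters
    ----------
    path:
        CSV file with a header row.  Required columns (after renaming):
        measure, location, sex, year, age_label, value, lower, upper.
    schema:
        Optional map from file column names to the canonical names, so raw
        Results Tool exports ("age", "val", ...) can be read without editing
        the file, e.g. ``{"age": "age_label", "val": "value"}``.
    on_invalid:
        "raise" (default) raises :class:`ValidationError` on any row failing
        the record invariants; "reject" drops those rows into
        ``table.rejects`` with a reason column instead.
    """
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns=dict(schema))
    required = ["measure", "location", "sex", "year", "age_label",
                "value", "lower", "upper"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    df = df.loc[:, required].copy()
    df["age_mid"] = df["age_label"].map(age_midpoint)
    df["year"] = df["year"].astype(int)

    lo, hi = year_range
    reason = _row_problems(df)
    bad_year = ~df["year"].between(lo, hi)
    reason[bad_year] += f"year outside [{lo}, {hi}];"
    bad = reason != ""
    if bad.any():
        if on_invalid == "raise":
            report = df.loc[bad].assign(reason=reason[bad])
            raise ValidationError(
                f"{int(bad.sum())} invalid rows:\n"
                + report.head(20).to_string(index=False)
            )
        rejects = df.loc[bad].assign(reason=reason[bad]).reset_index(drop=True)
    else:
        rejects = df.iloc[0:0].assign(reason=pd.Series(dtype=object))
    accepted = df.loc[~bad]
    table = GbdTable(
        accepted,
        meta={"source": str(path), "year_range": year_range},
        rejects=rejects,
    )
    return table


@dataclass(frozen=True)
class LifetimePoint:
    """Lifetime migraine prevalence for one sex and age group with 95% CI."""

    sex: str
    age_group: str
    age_mid: float
    q0: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ParseError(f"unknown sex: {self.sex!r}")
        if not (0.0 <= self.lower <= self.q0 <= self.upper <= 1.0):
            raise ValidationError(
                f"lifetime CI ordering violated for {self.sex}/{self.age_group}: "
                f"lower={self.lower}, q0={self.q0}, upper={self.upper}"
            )


def read_lifetime_table(path: str | Path | _io.IOBase) -> list[LifetimePoint]:
    """Read a lifetime-prevalence table CSV into :class:`LifetimePoint` rows.

    Expects columns sex, age_group, estimate, lower, upper (proportions);
    midpoints are attached per :data:`LIFETIME_GROUPS`.
    """
    df = pd.read_csv(path)
    required = ["sex", "age_group", "estimate", "lower", "upper"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    points = []
    for row in df.itertuples(index=False):
        points.append(LifetimePoint(
            sex=str(row.sex),
            age_group=str(row.age_group),
            age_mid=lifetime_midpoint(str(row.age_group)),
            q0=float(row.estimate),
            lower=float(row.lower),
            upper=float(row.upper),
        ))
    return points


def write_lifetime_table(points: Iterable[LifetimePoint],
                         path: str | Path) -> None:
    rows = [{"sex": p.sex, "age_group": p.age_group, "estimate": p.q0,
             "lower": p.lower, "upper": p.upper} for p in points]
    pd.DataFrame(rows).to_csv(path, index=False)
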