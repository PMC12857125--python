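"""Social-category system, strata, record filtering and outcome preparation.

The analysis cross-classifies individuals by sex, race/ethnicity, age group
and educational attainment.  Each cell of the cross-classification is an
*intersectional stratum* and becomes a level-2 unit of the multilevel model.
This module defines the category axes, enumerates the strata, assigns records
to strata, applies the study's exclusion rules, and prepares the consumption
outcome (cap and log transform).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: CSV schema for individual records; missing values are empty fields.
RECORD_COLUMNS = [
    "sex",
    "race_ethnicity",
    "age_group",
    "education",
    "survey_year",
    "drinker",
    "gpd",
]

#: Default cap (grams of pure alcohol per day, ~14 standard drinks).
GPD_CAP = 200.0

#: Grams of pure alcohol in one US standard drink.
GRAMS_PER_STANDARD_DRINK = 14.0


@dataclass(frozen=True)
class CategoryAxis:
    """One social-category axis: an ordered set of levels with a reference.

    Parameters
    ----------
    name
        Field identifier, one of ``sex``, ``race_ethnicity``, ``age_group``,
        ``education``.
    levels
        Ordered, unique category labels.  The order fixes the stratum
        enumeration and the design-matrix column order.
    reference_level
        The level absorbed into the intercept of main-effects models.
    short_codes
        Optional map from level to the short code used in canonical stratum
        labels (e.g. ``Men -> M``).  Defaults to the level itself.
    """

    name: str
    levels: tuple[str, ...]
    reference_level: str
    short_codes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.levels) == 0:
            raise ValueError(f"axis {self.name!r} has no levels")
        if len(set(self.levels)) != len(self.levels):
            raise ValueError(f"axis {self.name!r} has duplicate levels")
        if self.reference_level not in self.levels:
            raise ValueError(
                f"reference level {self.reference_level!r} not a level of "
                f"axis {self.name!r}"
            )

    def short(self, level: str) -> str:
        return self.short_codes.get(level, level)


@dataclass(frozen=True)
class Stratum:
    """A single intersectional stratum (one cell of the cross-classification).

    ``index`` is the 1-based stratum subscript *j* used by the model;
    ``labels`` holds one level per axis, in axis order; ``canonical_label``
    is the human-readable row label, e.g. ``"M, 21-24, White, high"``.
    """

    index: int
    labels: tuple[str, ...]
    canonical_label: str


@dataclass(frozen=True)
class StrataDesign:
    """The full crossed design: axes plus the deterministic stratum list."""

    axes: tuple[CategoryAxis, ...]
    strata: tuple[Stratum, ...]

    @property
    def n_strata(self) -> int:
        return len(self.strata)

    @property
    def axis_names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.axes)

    def stratum_for(self, labels: Sequence[str]) -> Stratum:
        """Look up the stratum for one tuple of levels (axis order)."""
        key = tuple(labels)
        try:
            return self._lookup[key]
        except KeyError:
            raise KeyError(f"label combination {key!r} is not in the design")

    @property
    def _lookup(self) -> dict[tuple[str, ...], Stratum]:
        # cached on first use; frozen dataclass so stash via __dict__
        cache = self.__dict__.get("_lookup_cache")
        if cache is None:
            cache = {s.labels: s for s in self.strata}
            self.__dict__["_lookup_cache"] = cache
        return cache

    def to_dict(self) -> dict:
        return {
            "axes": [
                {
                    "name": a.name,
                    "levels": list(a.levels),
                    "reference_level": a.reference_level,
                    "short_codes": dict(a.short_codes),
                }
                for a in self.axes
            ]
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "StrataDesign":
        axes = [
            CategoryAxis(
                name=a["name"],
                levels=tuple(a["levels"]),
                reference_level=a["reference_level"],
                short_codes=dict(a.get("short_codes", {})),
            )
            for a in d["axes"]
        ]
        return build_strata_design(axes)


#: Display order of axes in canonical labels (Tables-style: sex, age, race,
#: education) — independent of the enumeration order.
_CANONICAL_ORDER = ("sex", "age_group", "race_ethnicity", "education")


def _canonical_label(axes: Sequence[CategoryAxis], labels: Sequence[str]) -> str:
    by_name = {a.name: a.short(lv) for a, lv in zip(axes, labels)}
    order = [n for n in _CANONICAL_ORDER if n in by_name]
    order += [a.name for a in axes if a.name not in order]
    return ", ".join(by_name[n] for n in order)


def build_strata_design(axes: Iterable[CategoryAxis]) -> StrataDesign:
    """Enumerate all strata of the crossed design.

    The enumeration is lexicographic over axis order then level order, so the
    stratum indices are deterministic.  The stratum count equals the product
    of the axis level counts.
    """
    axes = tuple(axes)
    if not axes:
        raise ValueError("at least one axis is required")
    combos = [()]
    for axis in axes:
        combos = [c + (lv,) for c in combos for lv in axis.levels]
    strata = tuple(
        Stratum(index=i + 1, labels=c, canonical_label=_canonical_label(axes, c))
        for i, c in enumerate(combos)
    )
    return StrataDesign(axes=axes, strata=strata)


def default_design() -> StrataDesign:
    """The study's 2 x 6 x 3 x 3 = 108-stratum design.

    Reference categories: Men, White, 21-24, high school or less.  All race
    groups except Hispanic are non-Hispanic (e.g. Black = non-Hispanic Black).
    """
    axes = [
        CategoryAxis("sex", ("Men", "Women"), "Men", {"Men": "M", "Women": "F"}),
        CategoryAxis(
            "race_ethnicity",
            ("White", "Black", "Asian", "Mixed-race", "AI/AN", "Hispanic"),
            "White",
        ),
        CategoryAxis("age_group", ("21-24", "25-59", "60+"), "21-24"),
        CategoryAxis(
            "education",
            ("High school or less", "Some college", "4+ years college"),
            "High school or less",
            {
                "High school or less": "low",
                "Some college": "medium",
                "4+ years college": "high",
            },
        ),
    ]
    return build_strata_design(axes)


def assign_stratum(record: Mapping[str, str], design: StrataDesign) -> int:
    """Return the 1-based stratum index for one fully-categorised record."""
    labels = []
    for axis in design.axes:
        value = record.get(axis.name)
        if value is None or (isinstance(value, float) and np.isnan(value)):
            raise KeyError(f"record is missing axis {axis.name!r}")
        labels.append(value)
    return design.stratum_for(labels).index


def assign_strata(records: pd.DataFrame, design: StrataDesign) -> pd.Series:
    """Vectorised stratum assignment; raises on out-of-design labels."""
    key = list(design.axis_names)
    lookup = {s.labels: s.index for s in design.strata}
    tuples = list(map(tuple, records[key].itertuples(index=False, name=None)))
    try:
        idx = [lookup[t] for t in tuples]
    except KeyError as e:
        raise KeyError(f"label combination {e.args[0]!r} is not in the design")
    return pd.Series(idx, index=records.index, name="stratum", dtype=int)


# ---------------------------------------------------------------------------
# Exclusion rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExclusionRule:
    """A named record filter: ``predicate(df)`` marks rows to remove.

    When rules overlap, each removed record is tallied under the first
    matching rule in declared order; the kept set itself is order-invariant.
    """

    name: str
    predicate: Callable[[pd.DataFrame], pd.Series]


def min_age_rule(min_age: int = 21, name: str = "under_age") -> ExclusionRule:
    """Exclude respondents under the legal drinking age (uses ``age_years``)."""

    def pred(df: pd.DataFrame) -> pd.Series:
        if "age_years" not in df.columns:
            return pd.Series(False, index=df.index)
        age = pd.to_numeric(df["age_years"], errors="coerce")
        return age.notna() & (age < min_age)

    return ExclusionRule(name, pred)


def disallowed_category_rule(
    column: str, values: Sequence[str], name: str | None = None
) -> ExclusionRule:
    """Exclude records whose ``column`` is one of ``values`` (e.g. 'other' race)."""
    values = set(values)

    def pred(df: pd.DataFrame) -> pd.Series:
        return df[column].isin(values)

    return ExclusionRule(name or f"disallowed_{column}", pred)


def missing_field_rule(column: str, name: str | None = None) -> ExclusionRule:
    def pred(df: pd.DataFrame) -> pd.Series:
        col = df[column] if column in df.columns else pd.Series(np.nan, index=df.index)
        missing = col.isna()
        if col.dtype == object:
            missing = missing | (col == "")
        return missing

    return ExclusionRule(name or f"missing_{column}", pred)


def year_range_rule(
    first_year: int, last_year: int, name: str = "outside_year_range"
) -> ExclusionRule:
    """Keep only records with ``first_year <= survey_year <= last_year``.

    Used for the restricted-period robustness analysis (e.g. 2010-2018).
    """

    def pred(df: pd.DataFrame) -> pd.Series:
        yr = pd.to_numeric(df["survey_year"], errors="coerce")
        return yr.isna() | (yr < first_year) | (yr > last_year)

    return ExclusionRule(name, pred)


def nondrinker_rule(name: str = "non_drinker") -> ExclusionRule:
    def pred(df: pd.DataFrame) -> pd.Series:
        return pd.to_numeric(df["drinker"], errors="coerce") == 0

    return ExclusionRule(name, pred)


def inconsistent_consumption_rule(
    name: str = "inconsistent_consumption",
    predicate: Callable[[pd.DataFrame], pd.Series] | None = None,
) -> ExclusionRule:
    """Flag drinkers with unusable consumption data.

    The survey's own consistency criterion is not published; the default
    stand-in flags records reporting drinker status 1 with gpd missing or 0.
    A caller may supply any replacement predicate.
    """
    if predicate is None:

        def predicate(df: pd.DataFrame) -> pd.Series:  # type: ignore[misc]
            drinker = pd.to_numeric(df["drinker"], errors="coerce")
            gpd = pd.to_numeric(df.get("gpd"), errors="coerce")
            return (drinker == 1) & (gpd.isna() | (gpd <= 0))

    return ExclusionRule(name, predicate)


def drinker_subset_rules() -> list[ExclusionRule]:
    """Rules producing the current-drinker analytic sample with valid gpd."""
    return [
        nondrinker_rule(),
        missing_field_rule("drinker", name="missing_drinker_status"),
        inconsistent_consumption_rule(),
    ]


def apply_exclusions(
    records: pd.DataFrame, rules: Sequence[ExclusionRule]
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Partition ``records`` into kept rows and a per-rule removal tally.

    Each removed row is attributed to the first rule (in declared order)
    whose predicate matches it; the kept set does not depend on rule order.
    """
    tally: dict[str, int] = {r.name: 0 for r in rules}
    removed = pd.Series(False, index=records.index)
    for rule in rules:
        hit = rule.predicate(records).astype(bool) & ~removed
        tally[rule.name] = int(hit.sum())
        removed |= hit
    kept = records.loc[~removed].copy()
    return kept, tally


# ---------------------------------------------------------------------------
# Outcome preparation
# ---------------------------------------------------------------------------

def cap_consumption(gpd, cap: float = GPD_CAP):
    """Cap daily consumption at ``cap`` grams (idempotent; rejects negatives)."""
    arr = np.asarray(gpd, dtype=float)
    if np.any(arr[~np.isnan(arr)] < 0):
        raise ValueError("gpd must be non-negative")
    out = np.minimum(arr, cap)
    return float(out) if np.isscalar(gpd) else out


def log_transform_outcome(gpd):
    """Natural log of positive consumption (drinkers only)."""
    arr = np.asarray(gpd, dtype=float)
    if np.any(arr[~np.isnan(arr)] <= 0):
        raise ValueError("log transform requires gpd > 0")
    out = np.log(arr)
    return float(out) if np.isscalar(gpd) else out


def age_to_group(age_years) -> np.ndarray:
    """Map integer ages to the study's closed bins 21-24, 25-59, 60+.

    Ages at or above 85 are treated as 85 (survey top-code).  Ages below 21
    map to NaN and should be removed by the minimum-age rule.
    """
    age = np.minimum(np.asarray(age_years, dtype=float), 85.0)
    out = np.full(age.shape, None, dtype=object)
    out[(age >= 21) & (age <= 24)] = "21-24"
    out[(age >= 25) & (age <= 59)] = "25-59"
    out[age >= 60] = "60+"
    return out


def read_records(path) -> pd.DataFrame:
    """Read an individual-record CSV (empty fields are missing values)."""
    df = pd.read_csv(path, dtype={c: object for c in
                                  ("sex", "race_ethnicity", "age_group", "education")})
    for col in ("survey_year", "drinker", "gpd", "age_years"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def write_records(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)
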