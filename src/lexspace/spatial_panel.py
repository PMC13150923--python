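"""Derived district-year quantities: resource densities, the summary resource
index, crime rates, case proportions, crime-category grouping, and per-district
temporal correlations between resources and mental-illness crime.

Two outcome scales are carried side by side: the *crime rate* (mental-illness
crimes per 10,000 residents, the whole population at risk) and the *case
proportion* (mental-illness crimes per 100 criminal cases, the offender
population at risk).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_formats import CRIME_CATEGORIES, RESOURCE_COLUMNS

#: fixed surjective grouping of the ten crime-type labels onto four categories
CRIME_TYPE_TO_CATEGORY = {
    "larceny": "larceny",
    "narcotics": "narcotics",
    "homicide": "violent",
    "attempted_homicide": "violent",
    "sexual_offense": "violent",
    "causing_injury": "violent",
    "robbery": "violent",
    "obstructing_officer": "normal",
    "public_safety": "normal",
    "fraudulence": "normal",
}

CRIME_TYPES = tuple(CRIME_TYPE_TO_CATEGORY)

#: default weights of the summary resource index:
#: beds + 2*(psychologists+social workers) + 3*doctors + 4*psychiatry departments
DEFAULT_INDEX_WEIGHTS = (1.0, 2.0, 3.0, 4.0)

_STAFF_COLUMNS = ("clin_psych_clinic", "couns_psych_clinic", "soc_worker_clinic",
                  "clin_psych_hosp", "couns_psych_hosp", "soc_worker_hosp")
_BED_COLUMNS = ("beds_acute", "beds_chronic", "beds_intensive")
_DEPARTMENT_COLUMNS = ("psychiatry_clinic", "psychiatry_hosp")

#: base year for the centered year term (first panel year of the study frame)
BASE_YEAR = 2012

#: per-capita density scale (events or staff per this many persons)
DENSITY_SCALE = 10_000.0


def group_crime_category(crime_type: str) -> str:
    """Map one of the ten crime-type labels onto its analytical category."""
    try:
        return CRIME_TYPE_TO_CATEGORY[crime_type]
    except KeyError:
        raise ValueError(
            f"unknown crime type {crime_type!r}; accepted labels: {sorted(CRIME_TYPES)}"
        ) from None


def resource_index(beds, psych_sw, doctors, departments,
                   weights=DEFAULT_INDEX_WEIGHTS):
    """Summary index of district mental-health capacity.

    ``index = beds + 2*(psychologists + social workers) + 3*doctors
    + 4*psychiatry departments`` with the default weights.
    Accepts scalars or aligned arrays; all inputs must be non-negative.
    """
    args = [np.asarray(a, dtype=float) for a in (beds, psych_sw, doctors, departments)]
    for name, a in zip(("beds", "psych_sw", "doctors", "departments"), args):
        if np.any(a < 0):
            raise ValueError(f"resource_index: negative {name} input")
    w = np.asarray(weights, dtype=float)
    out = w[0] * args[0] + w[1] * args[1] + w[2] * args[2] + w[3] * args[3]
    return float(out) if out.ndim == 0 else out


def derive_panel(panel: pd.DataFrame, index_weights=DEFAULT_INDEX_WEIGHTS,
                 base_year: int = BASE_YEAR) -> pd.DataFrame:
    """Augment a district-year panel with densities, rates and the index.

    Adds, per row: resource aggregates (``beds_total``, ``psych_sw_total``,
    ``departments_total``), ``resource_index``, per-10,000-person densities
    (``<col>_per10k`` for each resource column plus the aggregates),
    ``crime_rate_<cat>`` (mh crimes per 10,000 persons),
    ``case_proportion_<cat>`` (mh crimes per 100 cases of that category,
    NaN + flag when the category has zero cases), the ``all``-category
    versions summed over categories, and ``year_centered`` (year − base_year).

    Rows with zero population get NaN rates and ``rate_undefined=True``.
    """
    df = panel.copy()
    df["beds_total"] = sum(df[c] for c in _BED_COLUMNS)
    df["psych_sw_total"] = sum(df[c] for c in _STAFF_COLUMNS)
    df["departments_total"] = sum(df[c] for c in _DEPARTMENT_COLUMNS)
    df["resource_index"] = resource_index(
        df["beds_total"], df["psych_sw_total"], df["psychiatry_doctor"],
        df["departments_total"], weights=index_weights)

    pop = df["population"].to_numpy(dtype=float)
    bad_pop = pop <= 0
    df["rate_undefined"] = bad_pop
    safe_pop = np.where(bad_pop, np.nan, pop)

    for c in RESOURCE_COLUMNS:
        df[f"{c}_per10k"] = DENSITY_SCALE * df[c] / safe_pop
    df["psych_sw_per10k"] = DENSITY_SCALE * df["psych_sw_total"] / safe_pop
    df["beds_per10k"] = DENSITY_SCALE * df["beds_total"] / safe_pop
    df["psychiatry_per10k"] = DENSITY_SCALE * df["departments_total"] / safe_pop
    df["resource_index_per10k"] = DENSITY_SCALE * df["resource_index"] / safe_pop

    df["mh_all"] = sum(df[f"mh_{c}"] for c in CRIME_CATEGORIES)
    df["crime_all"] = sum(df[f"crime_{c}"] for c in CRIME_CATEGORIES)
    for c in CRIME_CATEGORIES + ("all",):
        df[f"crime_rate_{c}"] = DENSITY_SCALE * df[f"mh_{c}"] / safe_pop
        denom = df[f"crime_{c}"].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            prop = 100.0 * df[f"mh_{c}"].to_numpy(dtype=float) / denom
        df[f"case_proportion_{c}"] = np.where(denom > 0, prop, np.nan)
        df[f"case_proportion_{c}_undefined"] = denom <= 0

    df["year_centered"] = df["year"] - base_year
    return df


def district_correlations(derived: pd.DataFrame, category: str,
                          crime_series: str = "count") -> pd.DataFrame:
    """Per-district Pearson r between the resource index and mh crime.

    ``crime_series`` selects the crime side: ``"count"`` (default, the number
    of mental-illness crimes in the category) or ``"rate"``. Districts where
    either yearly series has zero variance get ``r = NaN`` — mirroring the
    exclusion of districts with little to no variation over the study period.
    Requires at least 3 years per district.
    """
    if category not in CRIME_CATEGORIES + ("all",):
        raise ValueError(f"unknown category {category!r}")
    ycol = f"mh_{category}" if crime_series == "count" else f"crime_rate_{category}"
    rows = []
    for did, g in derived.groupby("district_id", sort=True):
        g = g.sort_values("year")
        if len(g) < 3:
            raise ValueError(f"district {did}: need >= 3 years, got {len(g)}")
        x = g["resource_index"].to_numpy(dtype=float)
        y = g[ycol].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0 or np.any(~np.isfinite(y)):
            r = np.nan
        else:
            r = float(np.corrcoef(x, y)[0, 1])
        rows.append({"district_id": did, "r": r, "n_years": len(g)})
    return pd.DataFrame(rows)
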