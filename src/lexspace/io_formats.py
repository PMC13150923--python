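"""Readers and writers for the pipeline's file formats.

Three external formats are supported:

* judgment corpora as JSON arrays or JSON-lines streams of seven-field
  objects (``JID``, ``JYEAR``, ``JCASE``, ``JNO``, ``JDATE``, ``JTITLE``,
  ``JFULL``), mirroring the Judicial Yuan Open Data schema;
* district geometry as GeoJSON FeatureCollections carrying a top-level
  ``crs_epsg`` property declaring a *projected* (metric) CRS;
* district-year panels of mental-health resources, socioeconomic covariates
  and crime counts as CSV with a fixed documented header.

Validation is total: every input record lands either in the accepted set or
in a reject list with a reason; nothing is silently dropped.
"""

from __future__ import annotations

import csv
import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from shapely.geometry import mapping, shape
from shapely.validation import make_valid

log = logging.getLogger(__name__)

REQUIRED_JUDGMENT_FIELDS = ("JID", "JYEAR", "JCASE", "JNO", "JDATE", "JTITLE", "JFULL")

#: the four analytical crime categories used throughout the pipeline
CRIME_CATEGORIES = ("larceny", "narcotics", "violent", "normal")

#: resource-count columns of the district-year panel
RESOURCE_COLUMNS = (
    "beds_acute",
    "beds_chronic",
    "beds_intensive",
    "clin_psych_clinic",
    "couns_psych_clinic",
    "soc_worker_clinic",
    "clin_psych_hosp",
    "couns_psych_hosp",
    "soc_worker_hosp",
    "psychiatry_clinic",
    "psychiatry_hosp",
    "psychiatry_doctor",
)

PANEL_COLUMNS = (
    ("district_id", "year", "population")
    + RESOURCE_COLUMNS
    + ("low_income_households", "college_share")
    + tuple(f"crime_{c}" for c in CRIME_CATEGORIES)
    + tuple(f"mh_{c}" for c in CRIME_CATEGORIES)
    + ("total_cases",)
)

GAZETTEER_COLUMNS = ("short_name", "full_name", "county", "district_id", "lon", "lat")

#: EPSG codes that are geographic (lon/lat) and therefore rejected for districts
_GEOGRAPHIC_EPSG = {4326, 4269, 4283, 4171, 3824}


class FormatError(ValueError):
    """Malformed file content (bad JSON, wrong structure, bad header)."""


class PanelValidationError(ValueError):
    """Panel rows violating a hard invariant (e.g. mh count > total count)."""


@dataclass(frozen=True)
class Judgment:
    """One raw court record as published on the open-data platform."""

    jid: str
    jyear: int
    jcase: str
    jno: str
    jdate: dt.date
    jtitle: str
    jfull: str


@dataclass(frozen=True)
class Reject:
    """An input record that failed validation, with the reason."""

    jid: str | None
    reason: str
    index: int = -1


def _parse_date(value) -> dt.date:
    s = str(value).strip()
    if len(s) == 8 and s.isdigit():  # YYYYMMDD as used inside JIDs
        return dt.date(int(s[:4]), int(s[4:6]), int(s[6:8]))
    return dt.date.fromisoformat(s)


def _validate_judgment(obj: dict, index: int, seen: set[str],
                       year_window: tuple[int, int] | None) -> Judgment | Reject:
    if not isinstance(obj, dict):
        return Reject(None, "record is not a JSON object", index)
    for f in REQUIRED_JUDGMENT_FIELDS:
        if f not in obj or obj[f] is None or obj[f] == "":
            return Reject(str(obj.get("JID")) if obj.get("JID") else None,
                          f"missing required field {f}", index)
    jid = str(obj["JID"])
    if jid in seen:
        return Reject(jid, "duplicate JID", index)
    try:
        jyear = int(obj["JYEAR"])
    except (TypeError, ValueError):
        return Reject(jid, "JYEAR is not an integer", index)
    if year_window is not None and not (year_window[0] <= jyear <= year_window[1]):
        return Reject(jid, f"JYEAR {jyear} outside study window {year_window}", index)
    try:
        jdate = _parse_date(obj["JDATE"])
    except (TypeError, ValueError):
        return Reject(jid, "JDATE is not a parseable date", index)
    jfull = str(obj["JFULL"])
    if len(jfull) < 1:
        return Reject(jid, "JFULL is empty", index)
    seen.add(jid)
    return Judgment(jid=jid, jyear=jyear, jcase=str(obj["JCASE"]), jno=str(obj["JNO"]),
                    jdate=jdate, jtitle=str(obj["JTITLE"]), jfull=jfull)


def read_judgments(path, year_window: tuple[int, int] | None = None
                   ) -> tuple[list[Judgment], list[Reject]]:
    """Read a judgment corpus from a JSON array or a JSON-lines stream.

    The layout is auto-detected from the first non-whitespace byte: ``[``
    means one JSON array, anything else means one object per line.

    Returns ``(judgments, rejects)``; ``len(judgments) + len(rejects)``
    equals the number of input records.
    """
    text = Path(path).read_text(encoding="utf-8")
    stripped = text.lstrip()
    records: list = []
    if stripped.startswith("["):
        try:
            records = json.loads(text)
        except json.JSONDecodeError as e:
            raise FormatError(f"malformed JSON in {path} at byte offset {e.pos}: {e.msg}") from e
        if not isinstance(records, list):
            raise FormatError(f"{path}: top-level JSON value is not an array")
    else:
        offset = 0
        for lineno, line in enumerate(text.splitlines(), start=1):
            if line.strip():
                try:
                    records.append(json.loads(line))
                except json.JSONDecodeError as e:
                    raise FormatError(
                        f"malformed JSON in {path} on line {lineno} "
                        f"(byte offset {offset + e.pos}): {e.msg}") from e
            offset += len(line.encode("utf-8")) + 1

    judgments: list[Judgment] = []
    rejects: list[Reject] = []
    seen: set[str] = set()
    for i, obj in enumerate(records):
        out = _validate_judgment(obj, i, seen, year_window)
        if isinstance(out, Judgment):
            judgments.append(out)
        else:
            rejects.append(out)
    return judgments, rejects


def write_judgments(judgments: Iterable[Judgment], path, fmt: str = "jsonl") -> None:
    """Write judgments as JSON-lines (default) or one JSON array."""
    objs = [
        {"JID": j.jid, "JYEAR": j.jyear, "JCASE": j.jcase, "JNO": j.jno,
         "JDATE": j.jdate.isoformat(), "JTITLE": j.jtitle, "JFULL": j.jfull}
        for j in judgments
    ]
    p = Path(path)
    if fmt == "array":
        p.write_text(json.dumps(objs, ensure_ascii=False, indent=1), encoding="utf-8")
    elif fmt == "jsonl":
        with p.open("w", encoding="utf-8") as fh:
            for o in objs:
                fh.write(json.dumps(o, ensure_ascii=False) + "\n")
    else:
        raise ValueError(f"unknown judgment format {fmt!r} (use 'jsonl' or 'array')")


# ---------------------------------------------------------------------------
# district geometry


def read_districts(path, repair: bool = True) -> pd.DataFrame:
    """Read district polygons from GeoJSON into a table with centroids.

    The FeatureCollection must carry a top-level ``crs_epsg`` property naming
    a projected (metric) CRS; geographic (lon/lat) input is rejected with an
    instruction to reproject, because all downstream distances are planar.

    Returns a DataFrame with columns ``district_id``, ``geometry`` (shapely),
    ``cx``, ``cy`` and ``df.attrs['crs_epsg']`` set.
    """
    gj = json.loads(Path(path).read_text(encoding="utf-8"))
    if gj.get("type") != "FeatureCollection":
        raise FormatError(f"{path}: expected a GeoJSON FeatureCollection")
    epsg = gj.get("crs_epsg")
    if epsg is None:
        raise FormatError(
            f"{path}: no crs_epsg declared; district geometry must be supplied in a "
            "projected metric CRS (reproject, e.g. to TWD97/TM2, and set crs_epsg)")
    epsg = int(epsg)
    if epsg in _GEOGRAPHIC_EPSG:
        raise FormatError(
            f"{path}: crs_epsg {epsg} is a geographic (lon/lat) CRS; reproject the "
            "polygons to a metric projection before use")
    rows = []
    seen: set[str] = set()
    for i, feat in enumerate(gj.get("features", [])):
        props = feat.get("properties") or {}
        did = props.get("district_id")
        if did is None:
            raise FormatError(f"{path}: feature {i} lacks a district_id property")
        did = str(did)
        if did in seen:
            raise FormatError(f"{path}: duplicate district_id {did!r}")
        seen.add(did)
        geom = shape(feat["geometry"])
        if not geom.is_valid:
            if repair:
                geom = make_valid(geom)
                log.warning("repaired invalid geometry for district %s", did)
            else:
                raise FormatError(f"{path}: invalid geometry for district {did!r}")
        c = geom.centroid
        rows.append({"district_id": did, "geometry": geom, "cx": c.x, "cy": c.y,
                     **{k: v for k, v in props.items() if k != "district_id"}})
    df = pd.DataFrame(rows)
    df.attrs["crs_epsg"] = epsg
    return df


def write_districts(districts: pd.DataFrame, path, crs_epsg: int | None = None,
                    properties: Sequence[str] = ()) -> None:
    """Write a district table back to GeoJSON with the ``crs_epsg`` extension."""
    epsg = crs_epsg if crs_epsg is not None else districts.attrs.get("crs_epsg")
    if epsg is None:
        raise ValueError("crs_epsg must be given (metric projection required)")
    feats = []
    for _, row in districts.iterrows():
        props = {"district_id": row["district_id"]}
        for k in properties:
            v = row[k]
            props[k] = None if pd.isna(v) else v
        feats.append({"type": "Feature", "properties": props,
                      "geometry": mapping(row["geometry"])})
    gj = {"type": "FeatureCollection", "crs_epsg": int(epsg), "features": feats}
    Path(path).write_text(json.dumps(gj), encoding="utf-8")


# ---------------------------------------------------------------------------
# gazetteer


def read_gazetteer(path, districts: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read the police-office gazetteer (CSV).

    Full names must be unique; short names may collide (that ambiguity is the
    point of the disambiguation step). If ``districts`` is given, every
    ``district_id`` must exist there.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in GAZETTEER_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: gazetteer missing columns {missing}")
    dup = df["full_name"][df["full_name"].duplicated()]
    if len(dup):
        raise FormatError(f"{path}: duplicate gazetteer full names: {sorted(set(dup))}")
    df["lon"] = df["lon"].astype(float)
    df["lat"] = df["lat"].astype(float)
    if districts is not None:
        known = set(districts["district_id"])
        bad = sorted(set(df["district_id"]) - known)
        if bad:
            raise FormatError(f"{path}: gazetteer district_ids not in geometry: {bad}")
    return df


def write_gazetteer(gazetteer: pd.DataFrame, path) -> None:
    gazetteer.loc[:, list(GAZETTEER_COLUMNS)].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# district-year panel


def read_panel(path, districts: Sequence[str] | None = None,
               years: Sequence[int] | None = None) -> pd.DataFrame:
    """Read the district-year panel CSV and enforce rectangle completeness.

    Missing (district, year) combinations are filled with zero counts and
    flagged via the boolean ``filled`` column; a category's mental-illness
    count exceeding its total count is a hard validation error listing the
    offending rows.
    """
    df = pd.read_csv(path)
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: panel missing columns {missing}")
    dup = df.duplicated(subset=["district_id", "year"])
    if dup.any():
        raise PanelValidationError(
            f"{path}: duplicate (district_id, year) rows at index {list(df.index[dup])}")
    count_cols = [c for c in PANEL_COLUMNS if c not in
                  ("district_id", "year", "college_share")]
    for c in count_cols:
        df[c] = pd.to_numeric(df[c], errors="raise").fillna(0)
    df["college_share"] = pd.to_numeric(df["college_share"], errors="raise")
    neg = [c for c in count_cols if (df[c] < 0).any()]
    if neg:
        raise PanelValidationError(f"{path}: negative counts in columns {neg}")
    bad_rows = []
    for c in CRIME_CATEGORIES:
        over = df[f"mh_{c}"] > df[f"crime_{c}"]
        if over.any():
            for _, r in df[over].iterrows():
                bad_rows.append((r["district_id"], int(r["year"]), c))
    if bad_rows:
        raise PanelValidationError(
            f"{path}: mh count exceeds total count for (district, year, category): {bad_rows}")

    df["district_id"] = df["district_id"].astype(str)
    df["year"] = df["year"].astype(int)
    all_d = sorted(set(districts) if districts is not None else set(df["district_id"]))
    all_y = sorted(set(years) if years is not None else set(df["year"]))
    full = pd.MultiIndex.from_product([all_d, all_y], names=["district_id", "year"])
    df = df.set_index(["district_id", "year"]).reindex(full)
    filled = df["population"].isna()
    for c in count_cols:
        df[c] = df[c].fillna(0)
    df["college_share"] = df["college_share"].fillna(0.0)
    df["filled"] = filled.to_numpy()
    if filled.any():
        log.warning("panel %s: %d missing district-year cells filled with zeros",
                    path, int(filled.sum()))
    return df.reset_index()


def write_panel(panel: pd.DataFrame, path) -> None:
    panel.loc[:, list(PANEL_COLUMNS)].to_csv(path, index=False)
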