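"""Synthetic inputs with ground-truth sidecars.

Two generators stand in for the data the pipeline was designed around:

* :func:`gen_corpus` emits a judgment corpus assembled from schematic
  Chinese-pattern templates that realize exactly the character patterns the
  extractor matches — Article-19 citation variants, 不服{JID}…。 appeal
  clauses, 事實…。理由 FACT sections, 訴由/案經{office}…。 police-office
  sentences — plus distractors that must *not* match (刑法第190條, 事實
  mentioned after 理由). It also writes a police-office gazetteer with
  planted short-name collisions and a per-judgment truth sidecar.
* :func:`gen_panel` emits a metric-CRS district grid, a district-year panel
  of resources/covariates/crime counts, planted growing space-time clusters
  for the hot-spot analysis, and a smooth spatially/temporally varying
  coefficient surface with its exact regression design for GTWR
  parameter-recovery checks.

Both are deterministic given their spec's seed; the text is schematic rather
than fluent legal prose — extractor correctness depends only on the patterns.
"""

from __future__ import annotations

import datetime as dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import box

from .io_formats import (CRIME_CATEGORIES, RESOURCE_COLUMNS, Judgment,
                         write_gazetteer, write_judgments, write_panel)
from .spatial_panel import CRIME_TYPES

COUNTIES = ("臺北市", "新北市", "桃園市", "臺中市", "臺南市", "高雄市")

_NAME_CH1 = "中大信文北士內南萬永"
_NAME_CH2 = "山安義正湖港華康寧強"

#: schematic offence descriptions, one per crime-type label (no county tokens)
DEEDS = {
    "larceny": "竊取他人財物",
    "narcotics": "持有毒品",
    "homicide": "殺害他人",
    "attempted_homicide": "著手殺人未遂",
    "sexual_offense": "對他人為性侵害行為",
    "causing_injury": "傷害他人身體",
    "robbery": "強盜他人財物",
    "obstructing_officer": "妨害公務執行",
    "public_safety": "駕車危害公共安全",
    "fraudulence": "詐取他人財物",
}

ARTICLE19_PHRASES = (
    "被告行為時因精神障礙，依刑法第19條第2項減輕其刑。",
    "被告行為時因精神障礙，依刑法第十九條第二項減輕其刑。",
    "被告行為時因精神障礙，依刑法第１９條第２項減輕其刑。",
)


@dataclass
class CorpusSpec:
    """Conditions of the synthetic judgment corpus.

    Probabilities mirror the structure of the real pipeline's yields (the
    99% FACT-extraction and two-thirds geocoding rates are emulated by
    ``p_fact_present`` and the office-pattern mix; they are configurable, not
    asserted equal to the real ones).
    """

    n_judgments: int = 1000
    year_range: tuple[int, int] = (2012, 2021)
    p_article19: float = 0.3
    p_appeal: float = 0.3
    max_chain_length: int = 3
    n_offices: int = 30
    p_short_name_collision: float = 0.2
    p_fact_present: float = 0.99
    office_pattern_probs: dict = field(default_factory=lambda: {
        "訴由": 0.3, "案經": 0.5, "none": 0.2})
    p_office_short: float = 0.5
    p_county_cue: float = 0.5
    court_mix: dict = field(default_factory=lambda: {
        "TPDM": 0.4, "KSDM": 0.2, "TCDM": 0.2, "TPHM": 0.2})
    appeal_court: str = "TPSM"
    crime_type_probs: dict | None = None
    district_ids: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_judgments < 1:
            raise ValueError("n_judgments must be >= 1")
        for name in ("p_article19", "p_appeal", "p_short_name_collision",
                     "p_fact_present", "p_office_short", "p_county_cue"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class CorpusResult:
    judgments: list
    gazetteer: pd.DataFrame
    truth: list[dict]
    paths: dict = field(default_factory=dict)


def _build_gazetteer(spec: CorpusSpec, rng) -> pd.DataFrame:
    names = [a + b for a in _NAME_CH1 for b in _NAME_CH2]
    n_pairs = int(round(spec.p_short_name_collision * spec.n_offices / 2))
    n_names = spec.n_offices - n_pairs
    if n_names > len(names):
        raise ValueError(f"office name pool exhausted (need {n_names})")
    chosen = [names[i] for i in rng.choice(len(names), size=n_names, replace=False)]
    rows = []
    if spec.district_ids is not None:
        dist_pool = list(spec.district_ids)
        dist_of = lambda i: dist_pool[i % len(dist_pool)]
    else:
        dist_of = lambda i: f"D{i:03d}"
    k = 0
    for name in chosen[:n_pairs]:  # collision pairs: same short name, two counties
        c1, c2 = rng.choice(len(COUNTIES), size=2, replace=False)
        for c in (c1, c2):
            county = COUNTIES[c]
            rows.append({"short_name": f"{name}分局",
                         "full_name": f"{county}政府警察局{name}分局",
                         "county": county, "district_id": dist_of(k),
                         "lon": 120.0 + rng.uniform(0, 2),
                         "lat": 22.0 + rng.uniform(0, 3)})
            k += 1
    for name in chosen[n_pairs:]:
        county = COUNTIES[int(rng.integers(len(COUNTIES)))]
        rows.append({"short_name": f"{name}分局",
                     "full_name": f"{county}政府警察局{name}分局",
                     "county": county, "district_id": dist_of(k),
                     "lon": 120.0 + rng.uniform(0, 2),
                     "lat": 22.0 + rng.uniform(0, 3)})
        k += 1
    return pd.DataFrame(rows)


def _assemble_text(jyear: int, jno: str, crime_type: str, article19: bool,
                   fact_present: bool, parent_jid: str | None,
                   office_sentence: str | None, county_cue: str | None,
                   rng) -> tuple[str, str | None]:
    """Compose a schematic judgment text; returns (text, planted fact span)."""
    parts = [f"地方法院刑事判決第{jno}號。"]
    if parent_jid:
        parts.append(f"被告不服{parent_jid}之判決提起上訴。")
    if county_cue:
        parts.append(f"本件行為地位於{county_cue}轄區。")
    fact_span = None
    if fact_present:
        fact_span = f"一、被告於{jyear}年間{DEEDS[crime_type]}"
        if rng.random() < 0.3:  # internal sentence break inside the FACT span
            fact_span += "。二、案發後經查獲到案"
        parts.append(f"事實{fact_span}。理由")
    else:
        parts.append("理由")
    reason = [f"一、被告所為{DEEDS[crime_type]}之行為，事證明確。"]
    if article19:
        reason.append(ARTICLE19_PHRASES[int(rng.integers(3))])
    elif rng.random() < 0.3:
        reason.append("二、被告另涉刑法第190條之罪嫌，未據起訴。")
    if not fact_present and rng.random() < 0.5:
        reason.append("相關事實部分詳如卷附資料。")  # 事實 after 理由: must not match
    if office_sentence:
        reason.append(office_sentence)
    parts.extend(reason)
    return "".join(parts), fact_span


def gen_corpus(spec: CorpusSpec, out_dir=None) -> CorpusResult:
    """Generate a judgment corpus, gazetteer and per-judgment truth sidecar.

    Deterministic given ``spec.seed``. When ``out_dir`` is given, writes
    ``judgments.jsonl``, ``gazetteer.csv`` and ``corpus_truth.jsonl`` there.
    """
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 11)))
    gaz = _build_gazetteer(spec, rng)
    short_counts = gaz["short_name"].value_counts()

    courts = sorted(spec.court_mix)
    court_p = np.array([spec.court_mix[c] for c in courts], dtype=float)
    court_p = court_p / court_p.sum()
    ctypes = list(CRIME_TYPES)
    if spec.crime_type_probs is None:
        ct_p = np.full(len(ctypes), 1 / len(ctypes))
    else:
        ct_p = np.array([spec.crime_type_probs.get(t, 0.0) for t in ctypes])
        ct_p = ct_p / ct_p.sum()
    patterns = sorted(spec.office_pattern_probs)
    pat_p = np.array([spec.office_pattern_probs[p] for p in patterns], dtype=float)
    pat_p = pat_p / pat_p.sum()
    y0, y1 = spec.year_range

    judgments: list[Judgment] = []
    truth: list[dict] = []
    jno_counter = 0

    while len(judgments) < spec.n_judgments:
        # one case (appeal chain root + possible children)
        article19 = rng.random() < spec.p_article19
        crime_type = ctypes[int(rng.choice(len(ctypes), p=ct_p))]
        office_pattern = patterns[int(rng.choice(len(patterns), p=pat_p))]
        office_row = gaz.iloc[int(rng.integers(len(gaz)))]
        collision = short_counts[office_row["short_name"]] > 1
        use_short = rng.random() < spec.p_office_short
        county_cue = None
        if office_pattern != "none" and use_short and collision:
            if rng.random() < spec.p_county_cue:
                county_cue = office_row["county"]
        if office_pattern == "none":
            office_sentence, mention, expected = None, None, None
        else:
            mention = (office_row["short_name"] if use_short
                       else office_row["full_name"])
            office_sentence = f"{office_pattern}{mention}移送偵辦。"
            if use_short and collision:
                expected = "resolved" if county_cue else "ambiguous"
            else:
                expected = "resolved"

        root_year = int(rng.integers(y0, y1 + 1))
        root_date = dt.date(root_year, 1, 1) + dt.timedelta(
            days=int(rng.integers(0, 360)))
        chain_len = 1
        while (chain_len < spec.max_chain_length
               and rng.random() < spec.p_appeal):
            chain_len += 1
        chain_len = min(chain_len, spec.n_judgments - len(judgments))

        case_id = None
        parent_jid = None
        date = root_date
        for depth in range(chain_len):
            jno_counter += 1
            jno = str(jno_counter)
            if depth == 0:
                court = courts[int(rng.choice(len(courts), p=court_p))]
            else:
                court = spec.appeal_court
                date = min(date + dt.timedelta(days=int(rng.integers(60, 240))),
                           dt.date(y1, 12, 31))
            jyear = date.year
            jid = f"{court},{jyear - 1911},訴,{jno},{date:%Y%m%d},1"
            if case_id is None:
                case_id = jid
            fact_present = rng.random() < spec.p_fact_present
            text, fact_span = _assemble_text(
                jyear, jno, crime_type, article19, fact_present, parent_jid,
                office_sentence, county_cue, rng)
            judgments.append(Judgment(jid=jid, jyear=jyear, jcase="訴", jno=jno,
                                      jdate=date, jtitle=crime_type, jfull=text))
            truth.append({
                "jid": jid, "case_id": case_id, "parent_jid": parent_jid,
                "court": court, "year": jyear, "article19": article19,
                "crime_type": crime_type, "fact_text": fact_span,
                "office_pattern": office_pattern, "office_mention": mention,
                "office_full_name": office_row["full_name"] if mention else None,
                "district_id": office_row["district_id"] if mention else None,
                "county": office_row["county"] if mention else None,
                "collision": bool(collision and mention is not None and use_short),
                "county_cue": county_cue is not None,
                "expected_resolution": expected,
            })
            parent_jid = jid

    result = CorpusResult(judgments=judgments, gazetteer=gaz, truth=truth)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        jpath = out / "judgments.jsonl"
        gpath = out / "gazetteer.csv"
        tpath = out / "corpus_truth.jsonl"
        write_judgments(judgments, jpath)
        write_gazetteer(gaz, gpath)
        with tpath.open("w", encoding="utf-8") as fh:
            for row in truth:
                fh.write(json.dumps(row, ensure_ascii=False) + "\n")
        result.paths = {"judgments": jpath, "gazetteer": gpath, "truth": tpath}
    return result


# ---------------------------------------------------------------------------
# spatial panel generator


@dataclass
class ClusterBlock:
    """A planted growing space-time cluster: a square block of grid cells
    whose mental-illness count intensity is multiplied by ``growth`` for each
    year from ``start_idx`` on."""

    row0: int = 2
    col0: int = 2
    size: int = 3
    start_idx: int = 4
    growth: float = 1.6


@dataclass
class PanelSpec:
    """Conditions of the synthetic spatial panel.

    Defaults reproduce the study frame: 365 districts observed annually
    2012–2021 (3650 space-time bins) on a metric grid. Coefficient surfaces
    for the GTWR ground truth are closed-form planes plus a Gaussian bump
    (parameters recorded in the truth sidecar); the regression outcome is
    ``y = beta0(u,v,t) + beta1(u,v,t) * x1 + Normal(0, noise_sd)`` with
    ``x1`` the psychiatry-doctor density.
    """

    n_districts: int = 365
    years: tuple[int, ...] = tuple(range(2012, 2022))
    cell_size: float = 1000.0        # meters
    crs_epsg: int = 3826             # TWD97 / TM2, a metric projection
    pop_mean: float = 30000.0
    pop_sigma: float = 0.4
    noise_sd: float = 0.5
    beta0_params: tuple[float, float, float] = (1.0, 0.5, 0.0)   # a + b*u + c*v
    beta1_params: tuple[float, float, float, float] = (1.0, 1.0, 1.0, -0.3)
    beta1_bump: tuple[float, float, float, float] = (1.5, 0.3, 0.7, 0.2)
    cluster_blocks: tuple[ClusterBlock, ...] = (ClusterBlock(),)
    cluster_category: str = "violent"
    cluster_base_rate: float = 1.5   # expected mh count per bin off-cluster
    planted_effects: dict = field(default_factory=lambda: {
        "psychiatry_doctor_per10k": 0.3})
    effect_category: str = "larceny"
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_districts < 1:
            raise ValueError("n_districts must be >= 1")


@dataclass
class PanelResult:
    districts: pd.DataFrame
    panel: pd.DataFrame
    truth: dict
    paths: dict = field(default_factory=dict)


#: baseline per-10k-person densities of each resource column
_RESOURCE_BASE = {
    "beds_acute": 6.0, "beds_chronic": 4.0, "beds_intensive": 1.0,
    "clin_psych_clinic": 1.5, "couns_psych_clinic": 1.2, "soc_worker_clinic": 1.0,
    "clin_psych_hosp": 1.5, "couns_psych_hosp": 1.0, "soc_worker_hosp": 1.2,
    "psychiatry_clinic": 0.6, "psychiatry_hosp": 0.4, "psychiatry_doctor": 2.5,
}

#: baseline crime cases per 10k persons by category
_CRIME_BASE = {"larceny": 8.0, "narcotics": 6.0, "violent": 4.0, "normal": 7.0}


def _gauss_bump(u, v, amp, u0, v0, sigma):
    return amp * np.exp(-((u - u0) ** 2 + (v - v0) ** 2) / (2 * sigma**2))


def gen_panel(spec: PanelSpec, out_dir=None) -> PanelResult:
    """Generate districts, a district-year panel and the GTWR/hot-spot truth.

    When ``out_dir`` is given, writes ``districts.geojson``, ``panel.csv``
    and ``panel_truth.json`` there. Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 23)))
    n = spec.n_districts
    ncols = math.ceil(math.sqrt(n))
    nrows = math.ceil(n / ncols)
    years = [int(y) for y in spec.years]
    T = len(years)

    ids, geoms, uu, vv, rows_of, cols_of = [], [], [], [], [], []
    for i in range(n):
        r, c = divmod(i, ncols)
        ids.append(f"D{i + 1:03d}")
        geoms.append(box(c * spec.cell_size, r * spec.cell_size,
                         (c + 1) * spec.cell_size, (r + 1) * spec.cell_size))
        uu.append((c + 0.5) / ncols)
        vv.append((r + 0.5) / max(nrows, 1))
        rows_of.append(r)
        cols_of.append(c)
    districts = pd.DataFrame({
        "district_id": ids, "geometry": geoms,
        "cx": [g.centroid.x for g in geoms], "cy": [g.centroid.y for g in geoms]})
    districts.attrs["crs_epsg"] = spec.crs_epsg
    u = np.array(uu)
    v = np.array(vv)

    # spatial gradients of each resource density field, drawn once per seed
    grads = {c: (rng.uniform(-0.5, 0.5), rng.uniform(-0.5, 0.5),
                 rng.uniform(0.5, 1.5))
             for c in RESOURCE_COLUMNS}

    cluster_members: list[str] = []
    for blk in spec.cluster_blocks:
        for i in range(n):
            if (blk.row0 <= rows_of[i] < blk.row0 + blk.size
                    and blk.col0 <= cols_of[i] < blk.col0 + blk.size):
                cluster_members.append(ids[i])

    pop0 = spec.pop_mean * np.exp(rng.normal(0, spec.pop_sigma, size=n))
    rows = []
    tn = np.linspace(0, 1, T) if T > 1 else np.zeros(1)
    a0, b0, c0 = spec.beta0_params
    a1, b1, c1, d1 = spec.beta1_params
    amp, u0b, v0b, sig = spec.beta1_bump
    beta0_truth, beta1_truth, y_truth, x1_truth = [], [], [], []

    for t_idx, year in enumerate(years):
        pop = np.maximum(np.round(pop0 * (1.01**t_idx)), 100).astype(int)
        rec = {"district_id": ids, "year": year, "population": pop}
        dens = {}
        for col in RESOURCE_COLUMNS:
            gu, gv, scale = grads[col]
            f = _RESOURCE_BASE[col] * scale * (1 + gu * (u - 0.5) + gv * (v - 0.5))
            f = np.maximum(f, 0.05) * (1 + 0.03 * t_idx)
            counts = rng.poisson(f * pop / 1e4)
            rec[col] = counts
            dens[col] = 1e4 * counts / pop
        rec["low_income_households"] = rng.poisson(pop * 0.02 * (0.5 + v))
        rec["college_share"] = np.clip(
            0.2 + 0.3 * u + rng.normal(0, 0.02, size=n), 0.0, 1.0)

        # non-mh case load per category; totals below add the mh cases on
        # top so the planted mh intensities are never truncated
        non_mh = {c: rng.poisson(_CRIME_BASE[c] * pop / 1e4)
                  for c in CRIME_CATEGORIES}
        mh = {}
        for c in CRIME_CATEGORIES:
            if c == spec.cluster_category:
                lam = np.full(n, spec.cluster_base_rate)
                for blk in spec.cluster_blocks:
                    for i in range(n):
                        if (blk.row0 <= rows_of[i] < blk.row0 + blk.size
                                and blk.col0 <= cols_of[i] < blk.col0 + blk.size
                                and t_idx >= blk.start_idx):
                            lam[i] *= blk.growth ** (t_idx - blk.start_idx + 1)
                mh[c] = rng.poisson(lam)
            elif c == spec.effect_category:
                rate = np.full(n, 0.2)
                for term, eff in spec.planted_effects.items():
                    col = term.removesuffix("_per10k")
                    rate = rate + eff * dens[col]
                mh[c] = rng.poisson(np.maximum(rate, 0.02) * pop / 1e4)
            else:
                mh[c] = rng.poisson(0.3 * pop / 1e4)
        for c in CRIME_CATEGORIES:
            rec[f"crime_{c}"] = non_mh[c] + mh[c]
            rec[f"mh_{c}"] = mh[c]
        rec["total_cases"] = sum(non_mh.values()) + sum(mh.values())
        rows.append(pd.DataFrame(rec))

        # GTWR ground truth on this year's slice
        beta0 = a0 + b0 * u + c0 * v
        beta1 = (a1 + b1 * u + c1 * v + d1 * tn[t_idx]
                 + _gauss_bump(u, v, amp, u0b, v0b, sig))
        x1 = dens["psychiatry_doctor"]
        y = beta0 + beta1 * x1 + rng.normal(0, spec.noise_sd, size=n)
        beta0_truth.append(beta0)
        beta1_truth.append(beta1)
        x1_truth.append(x1)
        y_truth.append(y)

    panel = pd.concat(rows, ignore_index=True)
    panel["filled"] = False

    coords = np.column_stack([
        np.tile(districts["cx"].to_numpy(), T),
        np.tile(districts["cy"].to_numpy(), T),
        np.repeat(years, n).astype(float),
    ])
    x1_flat = np.concatenate(x1_truth)
    truth = {
        "district_ids": ids,
        "years": years,
        "beta0": np.concatenate(beta0_truth).tolist(),
        "beta1": np.concatenate(beta1_truth).tolist(),
        "y": np.concatenate(y_truth).tolist(),
        "design_terms": ["intercept", "psychiatry_doctor_per10k"],
        "X": np.column_stack([np.ones(n * T), x1_flat]).tolist(),
        "coords": coords.tolist(),
        "cluster_members": sorted(set(cluster_members)),
        "cluster_category": spec.cluster_category,
        "planted_effects": dict(spec.planted_effects),
        "effect_category": spec.effect_category,
        "beta_params": {"beta0": list(spec.beta0_params),
                        "beta1": list(spec.beta1_params),
                        "beta1_bump": list(spec.beta1_bump)},
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
    }
    result = PanelResult(districts=districts, panel=panel, truth=truth)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        from .io_formats import write_districts
        dpath = out / "districts.geojson"
        ppath = out / "panel.csv"
        tpath = out / "panel_truth.json"
        write_districts(districts, dpath, crs_epsg=spec.crs_epsg)
        write_panel(panel, ppath)
        tpath.write_text(json.dumps(truth), encoding="utf-8")
        result.paths = {"districts": dpath, "panel": ppath, "truth": tpath}
    return result
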