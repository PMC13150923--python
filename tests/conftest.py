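import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from lexspace.synthetic_data import CorpusSpec, PanelSpec, gen_corpus, gen_panel


def make_grid(nrows: int, ncols: int, cell: float = 1.0) -> pd.DataFrame:
    """A rectangular grid of square districts in a metric plane."""
    rows = []
    for r in range(nrows):
        for c in range(ncols):
            g = box(c * cell, r * cell, (c + 1) * cell, (r + 1) * cell)
            rows.append({"district_id": f"G{r}{c}", "geometry": g,
                         "cx": g.centroid.x, "cy": g.centroid.y})
    df = pd.DataFrame(rows)
    df.attrs["crs_epsg"] = 3826
    return df


@pytest.fixture(scope="session")
def grid3x3():
    return make_grid(3, 3)


@pytest.fixture(scope="session")
def corpus_small():
    """A 300-judgment corpus with default (collision-bearing) conditions."""
    return gen_corpus(CorpusSpec(n_judgments=300, seed=42))


@pytest.fixture(scope="session")
def corpus_collision_free():
    return gen_corpus(CorpusSpec(n_judgments=300, p_short_name_collision=0.0,
                                 seed=7))


@pytest.fixture(scope="session")
def panel_small():
    """7x7 grid x 10 years with the default planted cluster and surfaces."""
    return gen_panel(PanelSpec(n_districts=49, seed=11))


def expected_cases_from_truth(truth, allowed_courts):
    """Independent reconstruction of the expected case table from the
    generator's truth sidecar: group judgments by planted chain, drop members
    at disallowed courts, and take attributes from the surviving member with
    the latest date (largest JNO breaks ties by construction)."""
    by_case = {}
    for row in truth:
        if row["court"] in allowed_courts:
            by_case.setdefault(row["case_id"], []).append(row)
    expected = {}
    for members in by_case.values():
        last = max(members, key=lambda r: (r["jid"].split(",")[4],
                                           int(r["jid"].split(",")[3])))
        first = min(members, key=lambda r: (r["jid"].split(",")[4],
                                            int(r["jid"].split(",")[3])))
        expected[first["jid"]] = {"members": sorted(r["jid"] for r in members),
                                  "retained": last}
    return expected
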