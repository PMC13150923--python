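import itertools

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box
from statsmodels.stats.multitest import multipletests

from lexspace.hotspots import (ALL_CATEGORIES, SpaceTimeCube, build_cube,
                               classify_emerging, emerging_hotspots, fdr_adjust,
                               gi_star, mann_kendall, queen_weights)
from lexspace.synthetic_data import PanelSpec, gen_panel

from conftest import make_grid


# ---------------------------------------------------------------------------
# oracles


def gi_star_oracle(counts, neighbors, k):
    """Loop-based direct evaluation of the Gi* closed form."""
    counts = np.asarray(counts, dtype=float)
    L, T = counts.shape
    n = counts.size
    xbar = counts.mean()
    s = np.sqrt((counts**2).mean() - xbar**2)
    z = np.zeros((L, T))
    for i in range(L):
        for t in range(T):
            total, w = 0.0, 0
            for j in neighbors[i]:
                for tt in range(max(0, t - k), t + 1):
                    total += counts[j, tt]
                    w += 1
            if w >= n:  # neighborhood covers the whole cube: deviation is 0
                z[i, t] = 0.0
            else:
                z[i, t] = (total - xbar * w) / (s * np.sqrt((n * w - w**2) / (n - 1)))
    return z


def bh_oracle(p, alpha):
    """Brute-force step-up rule: largest j with p(j) <= j*alpha/m rejects
    everything up to j in sorted order."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, bool)
    kmax = 0
    for j in range(1, m + 1):
        if p[order[j - 1]] <= j * alpha / m:
            kmax = j
    reject[order[:kmax]] = True
    return reject


def mk_oracle(x):
    x = np.asarray(x, float)
    n = len(x)
    S = sum(np.sign(x[j] - x[i]) for i in range(n) for j in range(i + 1, n))
    ties = [np.sum(x == v) for v in np.unique(x)]
    var = (n * (n - 1) * (2 * n + 5)
           - sum(t * (t - 1) * (2 * t + 5) for t in ties)) / 18
    return int(S), var


def _cube_from_grid(grid, counts, k=1):
    w = queen_weights(grid)
    ids = list(grid["district_id"])
    idx = {d: i for i, d in enumerate(ids)}
    neighbors = [np.array([idx[n] for n in w[d]]) for d in ids]
    return SpaceTimeCube(ids, list(range(counts.shape[1])), counts, neighbors, k)


# ---------------------------------------------------------------------------
# queen weights


def test_queen_weights_3x3_center(grid3x3):
    w = queen_weights(grid3x3)
    assert set(w["G11"]) == {f"G{r}{c}" for r in range(3) for c in range(3)}
    assert set(w["G00"]) == {"G00", "G01", "G10", "G11"}


def test_queen_weights_disjoint_islands_warn():
    df = pd.DataFrame({
        "district_id": ["A", "B"],
        "geometry": [box(0, 0, 1, 1), box(5, 5, 6, 6)]})
    with pytest.warns(UserWarning, match="island"):
        w = queen_weights(df)
    assert w == {"A": ["A"], "B": ["B"]}


def test_queen_weights_random_tessellation_vs_bruteforce():
    """Adjacency from the spatial index equals pairwise boundary-intersection
    brute force on a randomized rectangle partition."""
    rng = np.random.default_rng(3)
    rects = [(0.0, 0.0, 10.0, 10.0)]
    for _ in range(40):  # recursive random splits -> irregular tessellation
        i = int(rng.integers(len(rects)))
        x0, y0, x1, y1 = rects.pop(i)
        if rng.random() < 0.5 and x1 - x0 > 0.5:
            xm = rng.uniform(x0 + 0.1, x1 - 0.1)
            rects += [(x0, y0, xm, y1), (xm, y0, x1, y1)]
        elif y1 - y0 > 0.5:
            ym = rng.uniform(y0 + 0.1, y1 - 0.1)
            rects += [(x0, y0, x1, ym), (x0, ym, x1, y1)]
        else:
            rects.append((x0, y0, x1, y1))
    df = pd.DataFrame({"district_id": [f"R{i}" for i in range(len(rects))],
                       "geometry": [box(*r) for r in rects]})
    w = queen_weights(df)
    for i, gi in enumerate(df["geometry"]):
        oracle = {df["district_id"][j] for j, gj in enumerate(df["geometry"])
                  if i == j or gi.intersects(gj)}
        assert set(w[df["district_id"][i]]) == oracle


# ---------------------------------------------------------------------------
# cube


def test_build_cube_study_frame_bin_count():
    res = gen_panel(PanelSpec(n_districts=365, seed=0))
    cube, rejects = build_cube(pd.DataFrame(columns=["district_id", "year"]),
                               res.districts, range(2012, 2022))
    assert cube.n_bins == 3650 and len(rejects) == 0
    assert (cube.counts == 0).all()


def test_build_cube_marginals_match_planted_totals(panel_small):
    df = panel_small.panel
    events = df.loc[df.index.repeat(df["mh_violent"].astype(int)),
                    ["district_id", "year"]]
    cube, rejects = build_cube(events, panel_small.districts, range(2012, 2022))
    assert len(rejects) == 0
    assert cube.counts.sum() == df["mh_violent"].sum()
    by_year = df.groupby("year")["mh_violent"].sum()
    np.testing.assert_array_equal(cube.counts.sum(axis=0),
                                  by_year.loc[cube.times].to_numpy())


def test_build_cube_routes_out_of_frame_records(grid3x3):
    events = pd.DataFrame({"district_id": ["G00", "XX", "G11"],
                           "year": [2012, 2013, 1999]})
    cube, rejects = build_cube(events, grid3x3, [2012, 2013])
    assert cube.counts.sum() == 1
    assert sorted(rejects["reason"]) == ["district outside frame",
                                         "year outside frame"]


# ---------------------------------------------------------------------------
# Gi*


def test_gi_star_constant_cube_degenerate(grid3x3):
    cube = _cube_from_grid(grid3x3, np.full((9, 4), 7.0))
    out = gi_star(cube)
    assert out.attrs["degenerate"]
    assert (out["gi_z"] == 0).all()


def test_gi_star_matches_closed_form_oracle(grid3x3):
    counts = np.zeros((9, 1))
    counts[4, 0] = 10.0  # single elevated center cell
    cube = _cube_from_grid(grid3x3, counts, k=0)
    out = gi_star(cube)
    z_oracle = gi_star_oracle(counts, cube.neighbors, 0)
    np.testing.assert_allclose(out["gi_z"].to_numpy().reshape(9, 1), z_oracle,
                               rtol=1e-12)


def test_gi_star_elevated_center_pools_high_values():
    grid = make_grid(4, 4)
    counts = np.zeros((16, 1))
    center = list(grid["district_id"]).index("G11")
    counts[center, 0] = 10.0
    cube = _cube_from_grid(grid, counts, k=0)
    out = gi_star(cube).set_index("location")
    z_oracle = gi_star_oracle(counts, cube.neighbors, 0)
    np.testing.assert_allclose(
        out["gi_z"].to_numpy(), z_oracle[:, 0], rtol=1e-12)
    # every neighborhood pooling the elevated cell clusters high
    assert out.loc["G11", "gi_z"] > 0
    assert out["gi_z"].idxmax() in {"G00", "G01", "G10", "G11"}


def test_gi_star_random_cubes_match_oracle(grid3x3):
    rng = np.random.default_rng(5)
    for k in (0, 1, 2):
        counts = rng.poisson(3, size=(9, 5)).astype(float)
        cube = _cube_from_grid(grid3x3, counts, k=k)
        out = gi_star(cube)
        np.testing.assert_allclose(out["gi_z"].to_numpy().reshape(9, 5),
                                   gi_star_oracle(counts, cube.neighbors, k),
                                   rtol=1e-10)


def test_gi_star_monotone_in_own_count(grid3x3):
    rng = np.random.default_rng(9)
    counts = rng.poisson(3, size=(9, 3)).astype(float)
    cube = _cube_from_grid(grid3x3, counts)
    z0 = gi_star(cube)["gi_z"].to_numpy().reshape(9, 3)
    bumped = counts.copy()
    bumped[4, 2] += 1
    z1 = gi_star(_cube_from_grid(grid3x3, bumped))["gi_z"].to_numpy().reshape(9, 3)
    assert z1[4, 2] > z0[4, 2]


# ---------------------------------------------------------------------------
# BH-FDR


def test_fdr_all_ones_no_rejections():
    q, rej = fdr_adjust(np.ones(10), 0.05)
    assert not rej.any() and (q == 1).all()


def test_fdr_example_matches_bruteforce():
    p = np.array([0.01, 0.02, 0.03, 0.9])
    q, rej = fdr_adjust(p, 0.05)
    np.testing.assert_array_equal(rej, bh_oracle(p, 0.05))
    assert (q >= p).all()


def test_fdr_single_p_reduces_to_raw_test():
    _, rej = fdr_adjust([0.04], 0.05)
    assert rej[0]
    _, rej2 = fdr_adjust([0.06], 0.05)
    assert not rej2[0]


def test_fdr_matches_bruteforce_and_statsmodels_on_random_vectors():
    rng = np.random.default_rng(6)
    for _ in range(1000):
        m = int(rng.integers(1, 40))
        p = rng.uniform(size=m) ** rng.uniform(0.5, 3)
        q, rej = fdr_adjust(p, 0.05)
        np.testing.assert_array_equal(rej, bh_oracle(p, 0.05))
    p = rng.uniform(size=500) ** 2
    q, rej = fdr_adjust(p, 0.05)
    sm_rej, sm_q, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
    np.testing.assert_array_equal(rej, sm_rej)
    np.testing.assert_allclose(q, sm_q, rtol=1e-12)


# ---------------------------------------------------------------------------
# Mann-Kendall


def test_mann_kendall_strictly_increasing():
    res = mann_kendall(np.arange(10.0))
    assert res.S == 45  # n(n-1)/2 concordant pairs
    assert res.Z > 0 and res.p < 0.01


def test_mann_kendall_constant_series_degenerate():
    res = mann_kendall(np.ones(6))
    assert res.S == 0 and res.Z == 0 and res.degenerate


def test_mann_kendall_ties_match_bruteforce():
    rng = np.random.default_rng(2)
    for _ in range(200):
        x = rng.integers(0, 4, size=8).astype(float)
        res = mann_kendall(x)
        S, var = mk_oracle(x)
        assert res.S == S
        assert res.var == pytest.approx(var, rel=1e-12)
        if var > 0:
            zexp = (S - np.sign(S)) / np.sqrt(var) if S != 0 else 0.0
            assert res.Z == pytest.approx(zexp, rel=1e-12)


def test_mann_kendall_reversal_negates_S():
    rng = np.random.default_rng(7)
    x = rng.normal(size=12)
    assert mann_kendall(x).S == -mann_kendall(x[::-1]).S


# ---------------------------------------------------------------------------
# emerging classification


def test_classify_all_hot_significant_up_is_intensifying():
    h = np.ones(10, bool)
    c = np.zeros(10, bool)
    assert classify_emerging(h, c, mk_z=3.0, mk_p=0.001) == "intensifying hot spot"


def test_classify_nothing_significant_is_no_pattern():
    z = np.zeros(10, bool)
    assert classify_emerging(z, z, mk_z=0.5, mk_p=0.6) == "no pattern"


def test_classify_hot_only_final_step_is_new():
    h = np.zeros(10, bool)
    h[-1] = True
    c = np.zeros(10, bool)
    assert classify_emerging(h, c, 1.5, 0.2) == "new hot spot"


@pytest.mark.parametrize("flags,trend,expected", [
    # hand-applied rule table on T=5 flag vectors (h=hot, c=cold, .=neither)
    ("...hh", "none", "consecutive hot spot"),
    ("hhhhh", "up", "intensifying hot spot"),
    ("hhhhh", "none", "persistent hot spot"),
    ("hhhhh", "down", "diminishing hot spot"),
    ("h..hh", "none", "sporadic hot spot"),
    ("c.h.h", "none", "oscillating hot spot"),
    ("c..hh", "none", "consecutive hot spot"),  # suffix-run rule fires first
    # >=90% hot but final step not hot: persistent fires when the trend is
    # not significant, historical when it is (first-match order)
    ("hhhhhhhhh.", "none", "persistent hot spot"),
    ("hhhhhhhhh.", "up", "historical hot spot"),
    ("...cc", "none", "consecutive cold spot"),
    ("ccccc", "down", "intensifying cold spot"),
    ("ccccc", "up", "diminishing cold spot"),
    ("h.c.c", "none", "oscillating cold spot"),
    ("....c", "up", "new cold spot"),
    (".....", "up", "no pattern"),
])
def test_classify_rule_table(flags, trend, expected):
    h = np.array([f == "h" for f in flags])
    c = np.array([f == "c" for f in flags])
    z, p = {"up": (2.5, 0.01), "down": (-2.5, 0.01), "none": (0.3, 0.7)}[trend]
    assert classify_emerging(h, c, z, p) == expected


def test_classify_total_over_all_flag_and_trend_states():
    """Exhaustive T=4 enumeration: every {none,hot,cold}^4 x trend state maps
    to exactly one category in the taxonomy."""
    trends = [(2.5, 0.01), (-2.5, 0.01), (0.0, 1.0)]
    for combo in itertools.product("._hc", repeat=4):
        h = np.array([f == "h" for f in combo])
        c = np.array([f == "c" for f in combo])
        for z, p in trends:
            cat = classify_emerging(h, c, z, p)
            assert cat in ALL_CATEGORIES


def test_emerging_hotspots_all_zero_cube(grid3x3):
    cube = _cube_from_grid(grid3x3, np.zeros((9, 10)))
    trends, bins = emerging_hotspots(cube)
    assert len(bins) == 90
    assert (trends["category"] == "no pattern").all()


def test_emerging_hotspots_flags_planted_growing_cluster(panel_small):
    """The planted growing block ends in hot categories; far-field districts
    show no pattern (single-seed smoke; the power sweep lives in the
    acceptance suite)."""
    df = panel_small.panel
    events = df.loc[df.index.repeat(df["mh_violent"].astype(int)),
                    ["district_id", "year"]]
    cube, _ = build_cube(events, panel_small.districts, range(2012, 2022))
    trends, bins = emerging_hotspots(cube)
    assert len(bins) == 490
    members = set(panel_small.truth["cluster_members"])
    by_loc = trends.set_index("location")["category"]
    assert all(by_loc[m].endswith("hot spot") for m in members)
    # far field = districts not queen-adjacent to the block (its contiguity
    # ring legitimately pools the planted counts)
    w = queen_weights(panel_small.districts)
    halo = {n for m in members for n in w[m]}
    far = [d for d in by_loc.index if d not in halo]
    frac_quiet = np.mean([not by_loc[d].endswith("hot spot") for d in far])
    assert frac_quiet > 0.9
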