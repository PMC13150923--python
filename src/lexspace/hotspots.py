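"""Emerging space-time hot-spot analysis.

A complete location × time cube of event counts is scanned with the local
Getis–Ord Gi* statistic over a queen-contiguity spatial neighborhood (self
included) extended backward in time by a window of ``k`` steps. Per-bin
two-sided p-values are Benjamini–Hochberg FDR-adjusted jointly across all
bins; each location's sequence of Gi* z-scores is then tested for monotone
trend with the Mann-Kendall test, and the per-step hot/cold significance
history plus the trend give the location its emerging-pattern category
(new / consecutive / intensifying / persistent / diminishing / sporadic /
oscillating / historical, hot or cold, or "no pattern").

For bin b = (i, t) with neighborhood N(b), global mean X̄ and global scale
S = sqrt(Σx²/n − X̄²) over all n bins,

    Gi*(b) = [Σ_{N(b)} x − X̄·|N(b)|] / (S·sqrt[(n·|N(b)| − |N(b)|²)/(n−1)]).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats
from shapely.strtree import STRtree

log = logging.getLogger(__name__)

HOT_CATEGORIES = ("new", "consecutive", "intensifying", "persistent",
                  "diminishing", "sporadic", "oscillating", "historical")

#: the full category taxonomy (8 hot + 8 cold + no pattern)
ALL_CATEGORIES = tuple(f"{c} hot spot" for c in HOT_CATEGORIES) + \
    tuple(f"{c} cold spot" for c in HOT_CATEGORIES) + ("no pattern",)


@dataclass
class SpaceTimeCube:
    """Complete location × time array of counts with a spatial neighbor set.

    ``neighbors[i]`` lists the indices spatially adjacent to location i,
    *including i itself*; ``temporal_window`` is the number of earlier time
    steps pooled into each bin's neighborhood.
    """

    locations: list[str]
    times: list[int]
    counts: np.ndarray            # (L, T) non-negative
    neighbors: list[np.ndarray]   # per-location neighbor indices incl. self
    temporal_window: int = 1

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.locations), len(self.times)):
            raise ValueError("counts shape must be (n_locations, n_times)")
        if np.any(self.counts < 0):
            raise ValueError("cube counts must be non-negative")
        if self.temporal_window < 0:
            raise ValueError("temporal_window must be >= 0")

    @property
    def n_bins(self) -> int:
        return self.counts.size


def queen_weights(districts: pd.DataFrame) -> dict[str, list[str]]:
    """Queen-contiguity neighbor structure over district polygons.

    Two districts are neighbors iff their polygons share at least one
    boundary point (edge *or* corner). Every district additionally neighbors
    itself, as required by Gi*. Islands (no spatial neighbors) are kept with
    a self-only neighborhood and warned about.
    """
    ids = list(districts["district_id"])
    geoms = list(districts["geometry"])
    tree = STRtree(geoms)
    out: dict[str, list[str]] = {}
    for i, g in enumerate(geoms):
        cand = tree.query(g)
        nbrs = {ids[i]}
        for j in cand:
            j = int(j)
            if j != i and g.intersects(geoms[j]):
                nbrs.add(ids[j])
        if len(nbrs) == 1:
            warnings.warn(f"district {ids[i]} has no spatial neighbors (island); "
                          "kept with a self-only neighborhood", stacklevel=2)
        out[ids[i]] = sorted(nbrs)
    return out


def build_cube(events: pd.DataFrame, districts: pd.DataFrame, years,
               temporal_window: int = 1,
               weights: dict[str, list[str]] | None = None
               ) -> tuple[SpaceTimeCube, pd.DataFrame]:
    """Aggregate per-event (district_id, year) records into a cube.

    ``events`` needs ``district_id`` and ``year`` columns (one row per case);
    records outside the district × year frame are routed to the returned
    rejects table with a reason. The cube is zero-filled, so the bin count is
    exactly ``len(districts) × len(years)``.
    """
    years = sorted(int(y) for y in years)
    ids = sorted(districts["district_id"].astype(str))
    loc_index = {d: i for i, d in enumerate(ids)}
    yr_index = {y: t for t, y in enumerate(years)}
    counts = np.zeros((len(ids), len(years)))
    rej = []
    for _, row in events.iterrows():
        d, y = str(row["district_id"]), int(row["year"])
        if d not in loc_index:
            rej.append({"district_id": d, "year": y, "reason": "district outside frame"})
        elif y not in yr_index:
            rej.append({"district_id": d, "year": y, "reason": "year outside frame"})
        else:
            counts[loc_index[d], yr_index[y]] += 1
    if weights is None:
        weights = queen_weights(districts)
    neighbors = [np.array([loc_index[n] for n in weights[d]], dtype=int) for d in ids]
    cube = SpaceTimeCube(ids, years, counts, neighbors, temporal_window)
    return cube, pd.DataFrame(rej, columns=["district_id", "year", "reason"])


def gi_star(cube: SpaceTimeCube) -> pd.DataFrame:
    """Per-bin Gi* z-scores and two-sided normal p-values.

    Mean and scale are taken over the whole cube (one global reference
    distribution for all 3650 bins in the study frame). A constant cube is
    degenerate: all z are defined as 0 and ``attrs['degenerate']`` is set.
    """
    x = cube.counts
    L, T = x.shape
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 bins")
    xbar = x.mean()
    s = np.sqrt((x**2).mean() - xbar**2)

    rows_idx, cols_idx = [], []
    for i, nbrs in enumerate(cube.neighbors):
        rows_idx.extend([i] * len(nbrs))
        cols_idx.extend(nbrs.tolist())
    A = sparse.csr_matrix((np.ones(len(rows_idx)), (rows_idx, cols_idx)), shape=(L, L))
    deg = np.asarray(A.sum(axis=1)).ravel()          # spatial neighborhood size
    spatial_sum = A @ x                              # (L, T)

    k = cube.temporal_window
    zmat = np.zeros((L, T))
    pmat = np.ones((L, T))
    wlen = np.zeros((L, T))
    csum = np.cumsum(spatial_sum, axis=1)
    degenerate = s == 0
    for t in range(T):
        t0 = max(0, t - k)
        win_sum = csum[:, t] - (csum[:, t0 - 1] if t0 > 0 else 0.0)
        w = deg * (t - t0 + 1)                       # |N(b)|, binary weights
        wlen[:, t] = w
        if not degenerate:
            denom = s * np.sqrt((n * w - w**2) / (n - 1))
            # a neighborhood spanning the whole cube has zero deviation by
            # construction (0/0 in the closed form): define its z as 0
            with np.errstate(invalid="ignore", divide="ignore"):
                z = (win_sum - xbar * w) / denom
            zmat[:, t] = np.where(w >= n, 0.0, z)
    if degenerate:
        log.warning("constant cube: Gi* degenerate, all z set to 0")
    else:
        pmat = 2 * stats.norm.sf(np.abs(zmat))

    out = pd.DataFrame({
        "location": np.repeat(cube.locations, T),
        "time": np.tile(cube.times, L),
        "count": x.ravel(),
        "n_neigh": wlen.ravel(),
        "gi_z": zmat.ravel(),
        "p": pmat.ravel(),
    })
    out.attrs["degenerate"] = bool(degenerate)
    return out


def fdr_adjust(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up adjustment.

    Returns ``(q, reject)`` with q(i) = min_{j >= i} m·p(j)/j on the sorted
    p-values, clipped at 1; reject iff q <= alpha.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0, 1)
    return q, q <= alpha


@dataclass(frozen=True)
class MKResult:
    S: int
    var: float
    Z: float
    p: float
    degenerate: bool = False


def mann_kendall(series) -> MKResult:
    """Mann-Kendall monotone-trend test with tie-corrected variance.

    S = Σ_{i<j} sgn(x_j − x_i);
    Var = [n(n−1)(2n+5) − Σ_g t_g(t_g−1)(2t_g+5)] / 18 over tie groups;
    Z uses the ±1 continuity correction. An all-tied series is degenerate
    with Z defined as 0.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("Mann-Kendall needs a series of length >= 3")
    diff_sign = np.sign(x[None, :] - x[:, None])
    S = int(np.triu(diff_sign, 1).sum())
    _, tie_counts = np.unique(x, return_counts=True)
    tie_term = np.sum(tie_counts * (tie_counts - 1) * (2 * tie_counts + 5))
    var = (n * (n - 1) * (2 * n + 5) - tie_term) / 18.0
    if var <= 0:
        return MKResult(S=S, var=0.0, Z=0.0, p=1.0, degenerate=True)
    if S > 0:
        Z = (S - 1) / np.sqrt(var)
    elif S < 0:
        Z = (S + 1) / np.sqrt(var)
    else:
        Z = 0.0
    p = 2 * stats.norm.sf(abs(Z))
    return MKResult(S=S, var=float(var), Z=float(Z), p=float(p))


def _suffix_run_only(flags: np.ndarray) -> bool:
    """Flags form one uninterrupted run ending at the final step, nothing earlier."""
    idx = np.nonzero(flags)[0]
    return len(idx) > 0 and flags[-1] and len(idx) == len(flags) - idx[0]


def _classify_side(f: np.ndarray, other: np.ndarray, up_sig: bool, down_sig: bool,
                   pct: float) -> str | None:
    frac = f.mean()
    final = bool(f[-1])
    if final and f.sum() == 1:
        return "new"
    if final and frac < pct and _suffix_run_only(f):
        return "consecutive"
    if frac >= pct and final and up_sig:
        return "intensifying"
    if frac >= pct and not up_sig and not down_sig:
        return "persistent"
    if frac >= pct and final and down_sig:
        return "diminishing"
    if final and frac < pct and not other.any():
        return "sporadic"
    if final and other[:-1].any():
        return "oscillating"
    if frac >= pct and not final:
        return "historical"
    return None


def classify_emerging(hot, cold, mk_z: float, mk_p: float, alpha: float = 0.05,
                      pct_threshold: float = 0.9) -> str:
    """Emerging-pattern category from per-step flags and the Gi*-trend.

    ``hot``/``cold`` are per-time-step significance flags; the hot-side rules
    are evaluated first in fixed order (new, consecutive, intensifying,
    persistent, diminishing, sporadic, oscillating, historical), then the
    cold side symmetrically (with the trend direction mirrored); anything
    left is "no pattern". Total over every flag/trend combination.
    """
    h = np.asarray(hot, dtype=bool)
    c = np.asarray(cold, dtype=bool)
    if h.shape != c.shape or h.ndim != 1 or len(h) < 1:
        raise ValueError("hot/cold must be aligned 1-d flag vectors")
    if np.any(h & c):
        raise ValueError("a bin cannot be both hot and cold")
    up = bool(mk_p < alpha and mk_z > 0)
    down = bool(mk_p < alpha and mk_z < 0)
    label = _classify_side(h, c, up, down, pct_threshold)
    if label is not None:
        return f"{label} hot spot"
    label = _classify_side(c, h, down, up, pct_threshold)
    if label is not None:
        return f"{label} cold spot"
    return "no pattern"


def emerging_hotspots(cube: SpaceTimeCube, alpha: float = 0.05,
                      pct_threshold: float = 0.9
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full emerging hot-spot analysis on a cube.

    Composes gi_star → joint BH-FDR over all bins → per-location
    Mann-Kendall on the Gi* z series → category. Returns
    ``(location_trends, bin_stats)``.
    """
    bins = gi_star(cube)
    q, rej = fdr_adjust(bins["p"].to_numpy(), alpha)
    bins["q"] = q
    bins["hot"] = (bins["gi_z"] > 0) & rej
    bins["cold"] = (bins["gi_z"] < 0) & rej

    L, T = cube.counts.shape
    zmat = bins["gi_z"].to_numpy().reshape(L, T)
    hmat = bins["hot"].to_numpy().reshape(L, T)
    cmat = bins["cold"].to_numpy().reshape(L, T)
    rows = []
    for i, loc in enumerate(cube.locations):
        mk = mann_kendall(zmat[i])
        cat = classify_emerging(hmat[i], cmat[i], mk.Z, mk.p, alpha, pct_threshold)
        rows.append({"location": loc, "mk_S": mk.S, "mk_Z": mk.Z, "mk_p": mk.p,
                     "category": cat, "final_gi_z": zmat[i, -1],
                     "n_hot": int(hmat[i].sum()), "n_cold": int(cmat[i].sum())})
    return pd.DataFrame(rows), bins
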