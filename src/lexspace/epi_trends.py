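"""Yearly proportion series of Article-19 cases and the Cochran–Armitage
trend test.

The Cochran–Armitage statistic for k binomial samples (r_i successes of n_i,
year scores s_i) is

    T = sum_i s_i (r_i - n_i * pbar),          pbar = R / N,
    Var(T) = pbar (1 - pbar) [sum_i n_i s_i^2 - (sum_i n_i s_i)^2 / N],
    Z = T / sqrt(Var(T)),

with a two-sided normal p-value. Z is invariant under positive affine
transformations of the scores; the default scores are 0, 1, 2, ….
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class YearlyCounts:
    year: int
    n_mh: int
    n_total: int
    proportion: float


@dataclass(frozen=True)
class TrendResult:
    Z: float
    p: float
    direction: int
    score_vector: tuple[float, ...]
    degenerate: bool = False


def round_half_up(x: float, decimals: int) -> float:
    """Decimal round-half-up (0.225 → 0.23 at 2 decimals), for reporting."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def format_pct(proportion: float, decimals: int = 2) -> float:
    """Proportion as a percentage, rounded half-up for reporting."""
    return round_half_up(100.0 * proportion, decimals)


def yearly_proportions(cases: dict[int, int], totals: dict[int, int]
                       ) -> tuple[list[YearlyCounts], list[int]]:
    """Per-year Article-19 proportions.

    ``cases`` maps year → mental-illness case count, ``totals`` maps year →
    all-judgment count. Years with zero (or missing) totals are excluded and
    returned in the flagged list. Requires ``n_mh <= n_total`` per year.
    """
    out: list[YearlyCounts] = []
    flagged: list[int] = []
    for year in sorted(set(cases) | set(totals)):
        n_mh = int(cases.get(year, 0))
        n_total = int(totals.get(year, 0))
        if n_total <= 0:
            flagged.append(year)
            continue
        if n_mh > n_total:
            raise ValueError(f"year {year}: n_mh {n_mh} exceeds n_total {n_total}")
        out.append(YearlyCounts(year, n_mh, n_total, n_mh / n_total))
    return out, flagged


def cochran_armitage(n_mh, n_total, scores=None) -> TrendResult:
    """Cochran–Armitage test for a linear trend in proportions.

    Degenerate inputs (pooled proportion 0 or 1, or zero score variance)
    yield ``degenerate=True`` with Z undefined (NaN).
    """
    r = np.asarray(n_mh, dtype=float)
    n = np.asarray(n_total, dtype=float)
    if r.shape != n.shape or r.ndim != 1 or len(r) < 2:
        raise ValueError("need aligned 1-d successes/totals with k >= 2 years")
    if np.any(n <= 0):
        raise ValueError("all yearly totals must be positive")
    if np.any(r < 0) or np.any(r > n):
        raise ValueError("successes must satisfy 0 <= r_i <= n_i")
    s = np.arange(len(r), dtype=float) if scores is None else np.asarray(scores, float)
    if s.shape != r.shape:
        raise ValueError("scores must align with the yearly counts")

    N = n.sum()
    R = r.sum()
    pbar = R / N
    T = float(np.sum(s * (r - n * pbar)))
    var = pbar * (1 - pbar) * (np.sum(n * s**2) - np.sum(n * s) ** 2 / N)
    if pbar in (0.0, 1.0) or var <= 0:
        return TrendResult(Z=float("nan"), p=float("nan"), direction=0,
                           score_vector=tuple(s), degenerate=True)
    Z = T / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(Z))
    return TrendResult(Z=float(Z), p=float(p), direction=int(np.sign(Z)),
                       score_vector=tuple(s))


def fold_change(p_from: float, p_to: float) -> float:
    """Ratio of two proportions; report with round_half_up(·, 1)."""
    if p_from <= 0:
        raise ValueError("fold_change undefined: baseline proportion is zero")
    return p_to / p_from
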