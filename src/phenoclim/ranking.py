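"""Ranking observed flowering windows against cyclic alternatives.

For each scored climate cell the observed flowering window is compared
with every other window of the same length: its rank is one plus the
number of alternatives with strictly less time outside the
physiological limits, so rank 1 means no alternative season would have
been more suitable and ties share the better rank. The four per-variable
ranks are combined into a normalized Euclidean distance from the
all-rank-1 corner — the summary statistic for "how far from the best
available season does this population flower".
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .suitability import VARIABLES, DailyFlags, PhysiologyThresholds, _day_mask
from .windows import MonthWindow, candidate_windows

__all__ = [
    "rank_observed",
    "score_candidates",
    "optimal_window",
    "distance_to_optimum",
    "KSComparison",
    "compare_rank_distributions",
    "OptimalShare",
    "optimal_share",
    "SampleSizeEffect",
    "sample_size_effect",
]


def rank_observed(percents, observed_index: int) -> int:
    """Rank of the observed window: 1 + number strictly more suitable."""
    pct = np.asarray(percents, dtype=float)
    if pct.size == 0:
        raise ValueError("need at least one candidate window")
    if not 0 <= observed_index < pct.size:
        raise ValueError("observed_index out of range")
    return int(1 + np.sum(pct < pct[observed_index]))


def score_candidates(
    daily: DailyFlags,
    row: int,
    col: int,
    variable: str,
    window: MonthWindow,
    years=None,
) -> tuple[list[MonthWindow], np.ndarray]:
    """Percent-unsuitable for the observed window and all alternatives.

    Returns the candidate list (observed first) and the matching
    percent vector, computed from precomputed daily flags for one cell.
    """
    flags = daily.flags[variable][:, row, col]
    cands = candidate_windows(window)
    percents = np.empty(len(cands))
    for i, cand in enumerate(cands):
        mask = _day_mask(daily, cand, years)
        percents[i] = 100.0 * flags[mask].sum() / mask.sum()
    return cands, percents


def optimal_window(
    cands: list[MonthWindow], percents
) -> MonthWindow:
    """Candidate with minimal percent unsuitable, earliest start on ties."""
    pct = np.asarray(percents, dtype=float)
    best = min(
        range(len(cands)), key=lambda i: (pct[i], cands[i].start_month)
    )
    return cands[best]


def distance_to_optimum(ranks, max_rank: int = 12) -> float:
    """Normalized Euclidean distance of the four ranks from all-ones.

    ``sqrt(sum((r_i - 1)^2)) / sqrt(k * (max_rank - 1)^2)`` for k rank
    coordinates: 0 when every variable ranks the observed window first,
    1 when every variable ranks it last.
    """
    r = np.asarray(ranks, dtype=float)
    if np.any((r < 1) | (r > max_rank)):
        raise ValueError(f"ranks must lie in 1..{max_rank}")
    return float(
        np.sqrt(np.sum((r - 1.0) ** 2)) / np.sqrt(r.size * (max_rank - 1) ** 2)
    )


@dataclass(frozen=True)
class KSComparison:
    """Pairwise two-sample KS results across the four variables."""

    statistic: pd.DataFrame  # symmetric, NaN diagonal
    p_value: pd.DataFrame
    has_ties: bool  # ranks are discrete; ties make asymptotic p conservative

    def table_layout(self) -> pd.DataFrame:
        """Statistics in the lower triangle, p-values in the upper."""
        out = self.statistic.copy()
        vars_ = list(out.index)
        for i, vi in enumerate(vars_):
            for j, vj in enumerate(vars_):
                if j > i:
                    out.loc[vi, vj] = self.p_value.loc[vi, vj]
                elif j == i:
                    out.loc[vi, vj] = np.nan
        return out


def compare_rank_distributions(ranks_by_variable: dict) -> KSComparison:
    """Two-sided two-sample Kolmogorov-Smirnov tests between variables.

    Takes per-variable rank samples (one rank per scored cell) and
    returns the full symmetric D and p matrices. Ranks are discrete, so
    samples routinely tie; the asymptotic p-values are kept (no tie
    correction) and the presence of ties is reported.
    """
    names = list(ranks_by_variable)
    samples = {k: np.asarray(v, dtype=float) for k, v in ranks_by_variable.items()}
    for k, v in samples.items():
        if v.size < 2:
            raise ValueError(f"variable {k!r} has fewer than 2 ranks")
    d = pd.DataFrame(np.nan, index=names, columns=names)
    p = pd.DataFrame(np.nan, index=names, columns=names)
    ties = any(np.unique(v).size < v.size for v in samples.values())
    for a, b in itertools.combinations(names, 2):
        res = stats.ks_2samp(samples[a], samples[b], method="asymp")
        d.loc[a, b] = d.loc[b, a] = float(res.statistic)
        p.loc[a, b] = p.loc[b, a] = float(res.pvalue)
    return KSComparison(statistic=d, p_value=p, has_ties=ties)


@dataclass(frozen=True)
class OptimalShare:
    """Per-variable share of (cell, flowering-month) combos that are optimal."""

    n_optimal: dict[str, int]
    n_total: int

    def fraction(self, variable: str) -> float:
        return self.n_optimal[variable] / self.n_total if self.n_total else math.nan


def optimal_share(
    monthly_fraction_by_variable: dict[str, np.ndarray],
    cell_windows: dict[int, MonthWindow],
    grid,
    threshold_share: float = 0.70,
) -> OptimalShare:
    """Count flowering-month combinations meeting a suitability share.

    A (cell, month) combination — one scored climate cell crossed with
    one month of its flowering window — counts as optimal for a
    variable when the fraction of suitable days in that calendar month
    across all years is at least ``threshold_share``. The denominator
    (cells x flowering months) is reported explicitly.
    """
    n_opt = {v: 0 for v in monthly_fraction_by_variable}
    n_tot = 0
    for cid, window in sorted(cell_windows.items()):
        row, col = grid.row_col(cid)
        for month in window.months():
            n_tot += 1
            for v, frac in monthly_fraction_by_variable.items():
                if frac[month - 1, row, col] >= threshold_share:
                    n_opt[v] += 1
    return OptimalShare(n_optimal=n_opt, n_total=n_tot)


@dataclass(frozen=True)
class SampleSizeEffect:
    """Spearman association between specimen count and distance."""

    rho: float
    p_value: float
    n: int
    undefined: bool
    method: str  # "exact" or "permutation"


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    return float(stats.spearmanr(x, y).statistic)


def sample_size_effect(
    distances,
    n_specimens,
    n_permutations: int = 10_000,
    seed: int = 0,
    method: str = "auto",
) -> SampleSizeEffect:
    """Does specimen count predict distance to the optimum?

    Spearman rank correlation with a two-sided permutation p-value:
    exhaustive over all n! pairings when n <= 7 (or ``method="exact"``),
    otherwise a seeded Monte Carlo with ``n_permutations`` draws. A
    constant sample in either margin leaves the coefficient undefined
    and is flagged rather than coerced to a number.
    """
    d = np.asarray(distances, dtype=float)
    n = np.asarray(n_specimens, dtype=float)
    if d.size != n.size or d.size < 3:
        raise ValueError("need matched samples of at least 3 cells")
    if np.unique(d).size == 1 or np.unique(n).size == 1:
        return SampleSizeEffect(
            rho=math.nan, p_value=math.nan, n=d.size, undefined=True, method="none"
        )
    rho = _spearman(n, d)
    exact = method == "exact" or (method == "auto" and d.size <= 7)
    if method not in ("auto", "exact", "permutation"):
        raise ValueError(f"unknown method {method!r}")
    if exact:
        perms = itertools.permutations(d)
        hits = total = 0
        for perm in perms:
            total += 1
            if abs(_spearman(n, np.asarray(perm))) >= abs(rho) - 1e-12:
                hits += 1
        return SampleSizeEffect(rho=rho, p_value=hits / total, n=d.size,
                                undefined=False, method="exact")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        if abs(_spearman(n, rng.permutation(d))) >= abs(rho) - 1e-12:
            hits += 1
    return SampleSizeEffect(
        rho=rho,
        p_value=(1 + hits) / (1 + n_permutations),
        n=d.size,
        undefined=False,
        method="permutation",
    )
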