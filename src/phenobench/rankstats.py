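"""Rank-based comparison of prediction methods across traits.

Given a traits × methods table of accuracies (cvR² or test R²), each trait's
row is ranked with rank 1 for the most accurate method (midranks for ties).
The omnibus null hypothesis that all methods perform equivalently is tested
with the Friedman statistic including the standard tie correction,

    χ²_F = [12 Σⱼ (Rⱼ − n(k+1)/2)²] / [n k (k+1)] / C,
    C = 1 − Σ (t³ − t) / [n k (k² − 1)],

with Rⱼ the rank sum of method j over n traits, k methods, and the tie sum
running over tied groups of size t in every row; the p-value comes from the
χ² distribution with k − 1 degrees of freedom. Pairwise differences are
assessed with the Nemenyi post-hoc test: the standardized average-rank gap
z = |R̄ᵢ − R̄ⱼ| / √(k(k+1)/(6n)) is referred to the studentized range
distribution with k groups and infinite degrees of freedom at z√2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class RankComparison:
    ranks: pd.DataFrame  # traits × methods midranks, 1 = best
    average_ranks: pd.Series
    n_traits: int
    n_methods: int
    friedman_chi2: float
    friedman_p: float
    tie_correction: float


def _check_table(T: pd.DataFrame) -> pd.DataFrame:
    if T.isna().any().any():
        raise ValueError("result table must have no missing cells")
    if T.shape[1] < 2 or T.shape[0] < 1:
        raise ValueError("need at least 2 methods and 1 trait")
    return T.astype(float)


def rank_table(T: pd.DataFrame) -> RankComparison:
    """Per-trait midranks (1 = highest accuracy) and the Friedman test."""
    T = _check_table(T)
    n, k = T.shape
    ranks = T.apply(lambda row: pd.Series(stats.rankdata(-row), index=T.columns), axis=1)
    rank_sums = ranks.sum(axis=0)
    # tie correction: Σ(t³ − t) over tied groups in each trait's row
    ties = 0.0
    for _, row in ranks.iterrows():
        for _, cnt in row.value_counts().items():
            ties += cnt**3 - cnt
    C = 1.0 - ties / (n * k * (k * k - 1)) if n >= 1 else 1.0
    chi2 = (12.0 * ((rank_sums - n * (k + 1) / 2.0) ** 2).sum()) / (n * k * (k + 1))
    if C > 0:
        chi2 = chi2 / C
        p = float(stats.chi2.sf(chi2, k - 1))
    else:  # every row fully tied
        chi2, p = 0.0, 1.0
    return RankComparison(
        ranks=ranks,
        average_ranks=rank_sums / n,
        n_traits=n,
        n_methods=k,
        friedman_chi2=float(chi2),
        friedman_p=p,
        tie_correction=float(C),
    )


def friedman_test(rc: RankComparison) -> tuple[float, float]:
    """(χ², p) of the tie-corrected Friedman test (requires n ≥ 2)."""
    if rc.n_traits < 2:
        raise ValueError("Friedman test needs at least 2 traits")
    return rc.friedman_chi2, rc.friedman_p


def nemenyi_posthoc(rc: RankComparison) -> pd.DataFrame:
    """Symmetric matrix of pairwise Nemenyi p-values (unit diagonal)."""
    if rc.n_methods < 3:
        raise ValueError("Nemenyi post-hoc needs at least 3 methods")
    k, n = rc.n_methods, rc.n_traits
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    methods = list(rc.average_ranks.index)
    P = pd.DataFrame(np.ones((k, k)), index=methods, columns=methods)
    for i in range(k):
        for j in range(i + 1, k):
            z = abs(rc.average_ranks.iloc[i] - rc.average_ranks.iloc[j]) / se
            p = float(stats.studentized_range.sf(z * np.sqrt(2.0), k, np.inf))
            P.iloc[i, j] = P.iloc[j, i] = min(p, 1.0)
    return P


def best_method_counts(T: pd.DataFrame) -> pd.DataFrame:
    """Per-method counts of strict per-trait wins, with ties listed apart."""
    T = _check_table(T)
    strict = pd.Series(0, index=T.columns, dtype=int)
    tied = pd.Series(0, index=T.columns, dtype=int)
    for _, row in T.iterrows():
        top = row[row == row.max()].index
        if len(top) == 1:
            strict[top[0]] += 1
        else:
            for m in top:
                tied[m] += 1
    return pd.DataFrame({"strict_wins": strict, "tied_wins": tied})


def advantage_margins(
    T: pd.DataFrame, reference: str, challengers: list[str]
) -> dict:
    """Where and by how much the reference method beats every challenger.

    Margins are (reference − best challenger) in percentage points on the
    traits where the reference wins outright; the symmetric challenger-side
    margins report the challengers' advantage where the reference loses.
    """
    T = _check_table(T)
    if reference not in T.columns:
        raise ValueError(f"unknown reference method {reference!r}")
    best_chal = T[challengers].max(axis=1)
    diff = (T[reference] - best_chal) * 100.0
    wins = diff[diff > 0]
    losses = -diff[diff < 0]
    return {
        "winning_traits": list(wins.index),
        "mean_margin": float(wins.mean()) if len(wins) else 0.0,
        "max_margin": float(wins.max()) if len(wins) else 0.0,
        "challenger_mean_margin": float(losses.mean()) if len(losses) else 0.0,
        "challenger_max_margin": float(losses.max()) if len(losses) else 0.0,
    }


def round_half_even(x: float, decimals: int = 2) -> float:
    """Banker's rounding used for display of average ranks (4.125 → 4.12)."""
    return float(np.round(x, decimals))
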