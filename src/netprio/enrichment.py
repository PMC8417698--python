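"""Over-representation (one-sided Fisher) and rank-based set enrichment.

Fisher enrichment reports the hypergeometric upper-tail p-value, a
Haldane-corrected odds ratio with a log-normal 95% CI, a hypergeometric
z-score, and Benjamini-Hochberg FDR across the tested collection.

The rank-based analysis walks the rating-ordered gene list with a weighted
running sum (GSEA-style), takes the maximum positive deviation as the
enrichment score, normalizes it against gene-label permutations, and extracts
the members ranked at or before the peak ("leading" subset).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .genesets import GeneSetCollection

__all__ = [
    "fisher_enrichment",
    "tsea",
    "leading_prioritization",
]

_Z95 = 1.959963984540054


def _odds_ratio_ci(k: int, n: int, K: int, N: int) -> tuple[float, float, float]:
    """Odds ratio for the 2x2 table with Haldane 0.5 correction on zero cells."""
    a, b, c, d = float(k), float(n - k), float(K - k), float(N - n - K + k)
    if min(a, b, c, d) == 0.0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds = (a * d) / (b * c)
    se = np.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    log_or = np.log(odds)
    return odds, float(np.exp(log_or - _Z95 * se)), float(np.exp(log_or + _Z95 * se))


def fisher_enrichment(
    query: Iterable[str],
    sets: GeneSetCollection,
    universe: Iterable[str],
) -> pd.DataFrame:
    """One-sided (greater) Fisher enrichment of ``query`` in each gene set.

    Sets are intersected with the universe before testing. The returned frame
    has one row per set id (sorted), with columns k, n, K, N, Z, OR, CI_low,
    CI_high, p, FDR.
    """
    query = frozenset(query)
    universe = frozenset(universe)
    offenders = sorted(query - universe)
    if offenders:
        raise ValueError(f"query genes outside the universe: {offenders}")
    n, N = len(query), len(universe)
    rows = []
    for set_id in sorted(sets):
        members = sets[set_id].members & universe
        K = len(members)
        k = len(query & members)
        p = float(hypergeom.sf(k - 1, N, K, n))
        odds, ci_lo, ci_hi = _odds_ratio_ci(k, n, K, N)
        mean = n * K / N
        var = n * (K / N) * (1 - K / N) * (N - n) / (N - 1) if N > 1 else 0.0
        z = (k - mean) / np.sqrt(var) if var > 0 else np.nan
        rows.append(
            {
                "set_id": set_id,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "Z": z,
                "OR": odds,
                "CI_low": ci_lo,
                "CI_high": ci_hi,
                "p": min(p, 1.0),
            }
        )
    result = pd.DataFrame(rows)
    if len(result):
        result["FDR"] = multipletests(result["p"], method="fdr_bh")[1]
    else:
        result["FDR"] = pd.Series(dtype=float)
    return result


def _running_sum(
    hit_mask: np.ndarray, ratings: np.ndarray, weight_exponent: float
) -> np.ndarray:
    """Cumulative GSEA-style walk: weighted increments on hits, -1/(N-K) off."""
    n = hit_mask.size
    n_hits = int(hit_mask.sum())
    steps = np.full(n, -1.0 / (n - n_hits))
    w = np.abs(ratings[hit_mask]) ** weight_exponent
    total = w.sum()
    if total <= 0:
        w = np.full(n_hits, 1.0 / n_hits)
    else:
        w = w / total
    steps[hit_mask] = w
    return np.cumsum(steps)


def tsea(
    priority: pd.DataFrame,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    weight_exponent: float = 1.0,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Rank-based set enrichment over the priority table.

    ES is the maximum of the running sum; NES divides it by the mean ES under
    ``n_perm`` gene-label permutations; the empirical p carries a +1
    pseudocount. Members missing from the priority table are dropped with a
    warning; sets with fewer than 2 ranked members are skipped.
    """
    rng = np.random.default_rng(rng)
    ordered = priority.sort_values("rank", ignore_index=True)
    genes = ordered["gene"].to_numpy()
    ratings = ordered["rating"].to_numpy(dtype=float)
    pos_of = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    rows = []
    for set_id in sorted(sets):
        members = sets[set_id].members
        ranked = [g for g in members if g in pos_of]
        missing = len(members) - len(ranked)
        if missing:
            warnings.warn(
                f"{set_id}: {missing} member(s) absent from priority table",
                stacklevel=2,
            )
        if len(ranked) < 2 or len(ranked) >= n:
            warnings.warn(f"{set_id}: skipped (needs 2 <= members < N)", stacklevel=2)
            continue
        hit = np.zeros(n, dtype=bool)
        hit[[pos_of[g] for g in ranked]] = True
        walk = _running_sum(hit, ratings, weight_exponent)
        es = float(walk.max())
        peak = int(np.argmax(walk))
        k = len(ranked)
        perm_es = np.empty(n_perm)
        for i in range(n_perm):
            mask = np.zeros(n, dtype=bool)
            mask[rng.choice(n, size=k, replace=False)] = True
            perm_es[i] = _running_sum(mask, ratings, weight_exponent).max()
        mean_perm = perm_es.mean()
        nes = es / mean_perm if mean_perm > 0 else np.nan
        p_perm = (1.0 + np.sum(perm_es >= es)) / (1.0 + n_perm)
        leading = [g for g in ranked if pos_of[g] <= peak]
        leading.sort(key=lambda g: pos_of[g])
        rows.append(
            {
                "set_id": set_id,
                "ES": es,
                "NES": nes,
                "p_perm": p_perm,
                "peak_rank": peak + 1,
                "n_members": k,
                "n_leading": len(leading),
                "leading_genes": ",".join(leading),
            }
        )
    result = pd.DataFrame(rows)
    if len(result):
        result["FDR"] = multipletests(result["p_perm"], method="fdr_bh")[1]
    else:
        result["FDR"] = pd.Series(dtype=float)
    return result


def leading_prioritization(
    priority: pd.DataFrame,
    members: Iterable[str] | Sequence[str],
    weight_exponent: float = 1.0,
) -> list[str]:
    """Members ranked at or before the peak of the enrichment running sum."""
    ordered = priority.sort_values("rank", ignore_index=True)
    genes = ordered["gene"].to_numpy()
    ratings = ordered["rating"].to_numpy(dtype=float)
    pos_of = {g: i for i, g in enumerate(genes)}
    ranked = sorted((g for g in set(members) if g in pos_of), key=lambda g: pos_of[g])
    if not ranked:
        return []
    n = len(genes)
    hit = np.zeros(n, dtype=bool)
    hit[[pos_of[g] for g in ranked]] = True
    if hit.all():
        return ranked
    walk = _running_sum(hit, ratings, weight_exponent)
    peak = int(np.argmax(walk))
    return [g for g in ranked if pos_of[g] <= peak]
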