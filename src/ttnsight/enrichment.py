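"""Immunostimulatory signature score and ranked-sample mutation enrichment.

The IS score of a sample is the mean log2(expression+1) of six
immunostimulatory genes (IFNG, IL2, IL12A, IL12B, IL15, TNF).  Samples are
ranked by decreasing IS score and a Kolmogorov–Smirnov-style running sum is
walked down the ranking: each sample carrying a mutation in the gene of
interest contributes +sqrt((N-G)/G), every other sample -sqrt(G/(N-G)),
where N is the cohort size and G the number of mutated samples.  The walk
necessarily returns to zero; its prefix maximum (max ES) measures how
concentrated the mutated samples are at the immunologically hot end of the
ranking, bounded above by sqrt(G(N-G)) when all G occupy the top ranks.
Significance comes from a label-shuffle permutation null:
p = B^-1 sum_b I(maxES_0 <= maxES_b).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .vocab import IS_GENES


def is_score(expression: pd.DataFrame, is_genes=IS_GENES) -> pd.Series:
    """Per-sample mean log2(x+1) over the immunostimulatory genes.

    ``expression`` is a raw (non-negative, unlogged) genes x samples matrix.
    """
    missing = [g for g in is_genes if g not in expression.index]
    if missing:
        raise KeyError(f"expression matrix lacks IS gene(s): {', '.join(missing)}")
    sub = expression.loc[list(is_genes)]
    if (sub.to_numpy() < 0).any():
        raise ValueError("expression must be non-negative raw values")
    return np.log2(sub + 1.0).mean(axis=0).rename("is_score")


def rank_samples(scores: pd.Series) -> list[str]:
    """Sample ids sorted by IS score descending; ties broken by sample id."""
    order = sorted(scores.index, key=lambda s: (-scores[s], s))
    return list(order)


def enrichment_walk(ranked_samples, mutated_set) -> tuple[np.ndarray, float]:
    """Running enrichment sum over a ranking and its prefix maximum.

    Requires 0 < G < N (the statistic is undefined for an empty or
    all-mutated cohort).  Returns ``(walk, max_es)`` where ``walk`` has one
    running value per rank and ``walk[-1] == 0`` identically.
    """
    ranked = list(ranked_samples)
    mutated = set(mutated_set)
    n = len(ranked)
    g = sum(1 for s in ranked if s in mutated)
    if g == 0 or g == n:
        raise ValueError(f"enrichment undefined for G={g} of N={n} mutated samples")
    up = np.sqrt((n - g) / g)
    down = np.sqrt(g / (n - g))
    steps = np.array([up if s in mutated else -down for s in ranked])
    walk = np.cumsum(steps)
    return walk, float(walk.max())


def _perm_max_es(n: int, g: int, b: int, rng: np.random.Generator) -> np.ndarray:
    """Max ES of ``b`` uniformly drawn label placements (G of N mutated)."""
    up = np.sqrt((n - g) / g)
    down = np.sqrt(g / (n - g))
    out = np.empty(b)
    base = np.full(n, -down)
    for i in range(b):
        steps = base.copy()
        steps[rng.choice(n, size=g, replace=False)] = up
        out[i] = np.cumsum(steps).max()
    return out


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed max ES with its permutation null."""

    gene: str
    n: int
    g: int
    max_es: float
    walk: np.ndarray
    perm_max_es: np.ndarray
    perm_p: float
    b: int
    seed: int


def permutation_p(
    ranked_samples, mutated_set, b: int, seed: int, gene: str = ""
) -> EnrichmentResult:
    """Permutation p-value of the observed max ES under label shuffles.

    Each permutation reassigns the G mutated labels uniformly over the N
    samples (ranking fixed) and records its max ES;
    p = B^-1 #{b : maxES_0 <= maxES_b}, reported without smoothing, so an
    observed statistic above every permutation yields p = 0 (< 1/B).
    """
    if b < 1:
        raise ValueError("need at least one permutation")
    walk, max_es = enrichment_walk(ranked_samples, mutated_set)
    n = len(walk)
    g = sum(1 for s in ranked_samples if s in set(mutated_set))
    rng = np.random.default_rng(seed)
    perm = _perm_max_es(n, g, b, rng)
    p = float(np.mean(max_es <= perm))
    return EnrichmentResult(
        gene=gene, n=n, g=g, max_es=max_es, walk=walk, perm_max_es=perm, perm_p=p, b=b, seed=seed
    )


def group_score_test(scores: pd.Series, mutated_set) -> tuple[float, float]:
    """Rank-sum comparison of IS scores between mutated and wild-type groups.

    Returns ``(delta, p)`` with delta the mutated-minus-wildtype median
    difference and p from the two-sided Wilcoxon rank-sum (Mann-Whitney)
    test.  Identical groups return p = 1.
    """
    mutated = set(mutated_set)
    a = scores[scores.index.isin(mutated)].to_numpy(float)
    c = scores[~scores.index.isin(mutated)].to_numpy(float)
    if len(a) == 0 or len(c) == 0:
        raise ValueError("both mutated and wild-type groups must be non-empty")
    delta = float(np.median(a) - np.median(c))
    if len(a) == len(c) and np.array_equal(np.sort(a), np.sort(c)):
        return delta, 1.0
    p = float(stats.mannwhitneyu(a, c, alternative="two-sided").pvalue)
    return delta, p


def mutated_samples(mutations: pd.DataFrame, gene: str) -> set[str]:
    """Samples carrying at least one qualifying mutation in ``gene``."""
    from .tmb import qualifies_for_tmb

    sub = mutations[(mutations["gene"] == gene) & mutations["variant_classification"].map(qualifies_for_tmb)]
    return set(sub["sample_id"])
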