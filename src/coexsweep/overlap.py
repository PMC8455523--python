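"""Permutation tests for gene-set overlaps and the DE-vs-bias report.

Whether sex-biased (disease) genes hit a target list — FDA-approved drug
targets, disease genes — more often than chance is assessed by drawing
size-matched random gene sets from a comparator pool (the non-sex-biased
analyzed genes) and comparing overlap counts.  The headline p-value is
upper-tail with add-one correction, ``(1 + #{null >= observed}) /
(n_perm + 1)``; the raw proportion of null overlaps below the observed
one is also reported as a diagnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["OverlapPermutationResult", "overlap_permutation_test", "de_bias_overlap"]


@dataclass(frozen=True)
class OverlapPermutationResult:
    observed: int
    null_overlaps: np.ndarray
    p_value: float  # upper tail, add-one corrected
    proportion_lower: float  # diagnostic: share of null overlaps < observed
    n_perm: int
    seed: int


def overlap_permutation_test(
    query_set: Iterable[str],
    target_set: Iterable[str],
    permutation_pool: Iterable[str],
    n_perm: int = 10_000,
    seed: int = 0,
) -> OverlapPermutationResult:
    """Is ``|query & target|`` larger than for random same-size draws?

    Each permutation draws ``|query|`` genes uniformly without replacement
    from the pool and records the overlap with the target set.  Query
    genes present in the pool are removed from the pool with a warning
    (the pool is meant to be the complementary comparator).
    """
    query = frozenset(query_set)
    target = frozenset(target_set)
    pool = list(dict.fromkeys(permutation_pool))
    shared = query.intersection(pool)
    if shared:
        logger.warning(
            "%d query gene(s) removed from the permutation pool", len(shared)
        )
        pool = [g for g in pool if g not in query]
    if len(pool) < len(query):
        raise ValueError(
            f"pool ({len(pool)}) smaller than query ({len(query)}); cannot draw"
        )
    observed = len(query & target)
    rng = np.random.default_rng(seed)
    in_target = np.fromiter((g in target for g in pool), dtype=bool, count=len(pool))
    q = len(query)
    nulls = np.empty(n_perm, dtype=int)
    for i in range(n_perm):
        draw = rng.choice(len(pool), size=q, replace=False)
        nulls[i] = int(in_target[draw].sum())
    p_upper = (1 + int((nulls >= observed).sum())) / (n_perm + 1)
    proportion_lower = float((nulls < observed).mean())
    return OverlapPermutationResult(
        observed=observed,
        null_overlaps=nulls,
        p_value=p_upper,
        proportion_lower=proportion_lower,
        n_perm=n_perm,
        seed=seed,
    )


def _pair_report(de: frozenset[str], biased: frozenset[str]) -> dict[str, float]:
    inter = len(de & biased)
    union = len(de | biased)
    return {
        "n_de": len(de),
        "n_biased": len(biased),
        "overlap": inter,
        "jaccard": inter / union if union else 0.0,
        "fraction_of_de": inter / len(de) if de else 0.0,
        "fraction_of_biased": inter / len(biased) if biased else 0.0,
    }


def de_bias_overlap(
    de_up_in_females: Iterable[str],
    de_up_in_males: Iterable[str],
    female_biased: Iterable[str],
    male_biased: Iterable[str],
) -> dict[str, dict[str, float]]:
    """Overlap report between sex-differential expression and co-expression bias.

    Genes higher expressed in females are compared with female-biased
    co-expression genes, and likewise for males: overlap count, Jaccard
    index and the fraction of each side covered.
    """
    return {
        "female": _pair_report(frozenset(de_up_in_females), frozenset(female_biased)),
        "male": _pair_report(frozenset(de_up_in_males), frozenset(male_biased)),
    }
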