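"""Over-representation analysis against GMT gene-set collections and
evidence-score filtering of gene-disease association tables.

The ORA p-value is the exact hypergeometric upper tail
``P(X >= k)`` for an overlap of ``k`` between a query of size ``q`` and a
set of size ``m`` inside a universe of ``N`` testable genes.  Significance
is the raw ``p < 0.05`` rule; a Benjamini-Hochberg column is emitted for
reference but does not drive the flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "AssociationFilterConfig",
    "read_gmt",
    "write_gmt",
    "ora",
    "filter_associations",
    "compare_clusters",
    "significance_codes",
]

_RESULT_COLUMNS = [
    "term",
    "overlap",
    "query_size",
    "set_size",
    "universe_size",
    "p_value",
    "gene_ratio",
    "genes",
    "significant",
    "fdr_bh",
]


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets with an optional declared universe."""

    sets: Mapping[str, frozenset[str]]
    descriptions: Mapping[str, str] = field(default_factory=dict)
    universe: frozenset[str] | None = None

    def __len__(self) -> int:
        return len(self.sets)

    def restricted_to(self, universe: frozenset[str]) -> "GeneSetCollection":
        """Drop set members outside ``universe`` (logged count)."""
        restricted = {}
        dropped = 0
        for name, members in self.sets.items():
            inside = members & universe
            dropped += len(members) - len(inside)
            restricted[name] = inside
        if dropped:
            logger.info("dropped %d set member(s) outside the universe", dropped)
        return GeneSetCollection(
            sets=restricted, descriptions=self.descriptions, universe=universe
        )


@dataclass(frozen=True)
class AssociationFilterConfig:
    """Disease-size and evidence-score thresholds for association tables."""

    min_genes_per_disease: int = 100
    score_quantile: float = 0.90

    def __post_init__(self) -> None:
        if not (0 < self.score_quantile < 1):
            raise ValueError(
                f"score_quantile must lie in (0, 1), got {self.score_quantile}"
            )


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: name TAB description TAB member genes.

    Duplicate members within a set are deduplicated; a line with fewer
    than 3 fields is an error naming the line number.
    """
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"malformed GMT line {lineno}: expected >= 3 tab-separated fields"
            )
        name, description, *members = fields
        sets[name] = frozenset(m for m in members if m)
        descriptions[name] = description
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = []
    for name, members in collection.sets.items():
        description = collection.descriptions.get(name, "")
        lines.append("\t".join([name, description, *sorted(members)]))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def ora(
    query: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Exact hypergeometric over-representation of ``query`` in each set.

    Query genes outside the universe are dropped (logged); set members
    outside the universe do not count toward set size.  Results are sorted
    ascending by p-value; ``significant`` flags raw ``p < alpha``.
    """
    universe_set = frozenset(universe)
    if not universe_set:
        raise ValueError("universe must contain at least one gene")
    query_set = frozenset(query)
    outside = query_set - universe_set
    if outside:
        logger.info("dropped %d query gene(s) outside the universe", len(outside))
        query_set = query_set & universe_set
    if not query_set:
        logger.warning("query empty after intersecting with the universe")
        return pd.DataFrame(columns=_RESULT_COLUMNS)

    restricted = collection.restricted_to(universe_set)
    n_universe = len(universe_set)
    n_query = len(query_set)
    rows = []
    for term, members in restricted.sets.items():
        overlap = query_set & members
        k, m = len(overlap), len(members)
        # upper tail P(X >= k)
        p = float(hypergeom.sf(k - 1, n_universe, m, n_query))
        p = min(p, 1.0)
        rows.append(
            {
                "term": term,
                "overlap": k,
                "query_size": n_query,
                "set_size": m,
                "universe_size": n_universe,
                "p_value": p,
                "gene_ratio": k / n_query,
                "genes": ",".join(sorted(overlap)),
                "significant": p < alpha,
            }
        )
    result = pd.DataFrame(rows, columns=_RESULT_COLUMNS[:-1])
    if len(result):
        result["fdr_bh"] = multipletests(result["p_value"], method="fdr_bh")[1]
        result = result.sort_values("p_value", kind="stable").reset_index(drop=True)
    else:
        result["fdr_bh"] = pd.Series(dtype=float)
    return result


def filter_associations(
    table: pd.DataFrame, config: AssociationFilterConfig | None = None
) -> pd.DataFrame:
    """Two-step filter of a gene-disease association table.

    Step 1 keeps diseases annotated with at least
    ``min_genes_per_disease`` genes; step 2 keeps rows whose evidence
    score is at or above the ``score_quantile`` quantile (linear
    interpolation) of the step-1 table.
    """
    if config is None:
        config = AssociationFilterConfig()
    if table.empty:
        return table.copy()
    counts = table.groupby("disease")["gene"].nunique()
    big = counts.index[counts >= config.min_genes_per_disease]
    step1 = table[table["disease"].isin(big)]
    if step1.empty:
        return step1.copy()
    cutoff = step1["score"].quantile(config.score_quantile, interpolation="linear")
    return step1[step1["score"] >= cutoff].copy()


def compare_clusters(
    queries: Mapping[str, Iterable[str]],
    collection: GeneSetCollection,
    universe: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run :func:`ora` per query set against a shared universe.

    Long-format output keyed (query_set, term), suitable for building
    which-sex-is-enriched heatmaps.
    """
    universe_set = frozenset(universe)
    frames = []
    for name, genes in queries.items():
        result = ora(genes, collection, universe_set, alpha=alpha)
        result.insert(0, "query_set", name)
        frames.append(result)
    if not frames:
        return pd.DataFrame(columns=["query_set", *_RESULT_COLUMNS])
    return pd.concat(frames, ignore_index=True)


def significance_codes(
    long_results: pd.DataFrame, female_set: str, male_set: str
) -> pd.Series:
    """Per-term code: 'female', 'male', 'both' or 'none' significance.

    Mirrors the female/male/both coloring of a per-term significance
    heatmap over two query sets.
    """
    sig = (
        long_results[long_results["query_set"].isin([female_set, male_set])]
        .pivot_table(
            index="term", columns="query_set", values="significant", aggfunc="any"
        )
        .reindex(columns=[female_set, male_set], fill_value=False)
        .fillna(False)
    )

    def code(row: pd.Series) -> str:
        f, m = bool(row[female_set]), bool(row[male_set])
        if f and m:
            return "both"
        if f:
            return "female"
        if m:
            return "male"
        return "none"

    return sig.apply(code, axis=1).rename("code")
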