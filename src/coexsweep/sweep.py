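"""The population gradient sweep: sex-biased co-expression calling.

Connectivity of every gene is recomputed across ``n + 1`` equal-size
populations that shift one sample at a time from all group-A (females) to
all group-B (males).  The ordered trajectory is quintilized — five
contiguous population blocks, per-gene median connectivity in each — and
the bias statistic is the log2 ratio of the extreme quintile medians
(Q5, male-most, over Q1, female-most).  A gene is called in one iteration
when ``|log2fc|`` strictly exceeds 1; the whole procedure is repeated with
fresh random samples, and a gene is sex-biased when called in at least
``min_calls`` of the iterations.  The calibration null runs identical
machinery on random mixed-sex populations instead of a sex gradient.

The same machinery, applied within females over the age dichotomy
< 50 vs >= 50 years, yields the menopause variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .network import AdjacencyConfig, connectivity_from_log_expression

logger = logging.getLogger(__name__)

__all__ = [
    "SweepConfig",
    "GradientPlan",
    "SweepTrajectory",
    "QuintileSummary",
    "BiasCallResult",
    "NullCalibration",
    "build_gradient_plan",
    "build_null_plan",
    "run_sweep",
    "quintilize",
    "log2_shift",
    "call_iteration",
    "summarize_calls",
    "run_consistency",
    "run_null",
    "threshold_pass_counts",
    "menopause_sweep",
]

N_QUINTILES = 5


@dataclass(frozen=True)
class SweepConfig:
    """Parameters of the gradient sweep and the consistency rule.

    population_size defaults to min(n_A, n_B) after filtering (None);
    log2fc_threshold applies strictly (``> 1``), min_calls inclusively
    (``>= 20`` of n_iterations).  connectivity_pseudocount guards the log
    ratio against zero-median connectivity.
    """

    population_size: int | None = None
    n_iterations: int = 100
    log2fc_threshold: float = 1.0
    min_calls: int = 20
    connectivity_pseudocount: float = 1e-6
    seed: int = 0
    adjacency: AdjacencyConfig = field(default_factory=AdjacencyConfig)

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError(f"n_iterations must be >= 1, got {self.n_iterations}")
        if self.min_calls > self.n_iterations:
            raise ValueError(
                f"min_calls ({self.min_calls}) cannot exceed n_iterations"
                f" ({self.n_iterations})"
            )
        if not self.log2fc_threshold > 0:
            raise ValueError(
                f"log2fc_threshold must be > 0, got {self.log2fc_threshold}"
            )
        if self.population_size is not None and self.population_size < 3:
            raise ValueError("population_size must be >= 3")


@dataclass(frozen=True)
class GradientPlan:
    """Ordered list of n+1 equal-size sample populations.

    Step k holds ``n - k`` group-A and ``k`` group-B samples; consecutive
    steps differ by removing one A sample and adding one B sample.
    """

    populations: tuple[tuple[str, ...], ...]

    @property
    def n(self) -> int:
        return len(self.populations) - 1

    def __len__(self) -> int:
        return len(self.populations)


@dataclass(frozen=True)
class SweepTrajectory:
    """Per-gene connectivity across the ordered populations of one sweep."""

    gene_ids: tuple[str, ...]
    values: np.ndarray  # genes x (n + 1), all >= 0


@dataclass(frozen=True)
class QuintileSummary:
    """Per-gene median connectivity in the five contiguous population blocks.

    Q1 is the female-most block, Q5 the male-most.
    """

    gene_ids: tuple[str, ...]
    medians: np.ndarray  # genes x 5


@dataclass(frozen=True)
class BiasCallResult:
    """Consistency-run output: the bias-call table and per-iteration record.

    table columns: gene, mean_log2fc, direction, n_called, is_sex_biased.
    log2fc is the per-iteration record (genes x n_iterations).
    """

    table: pd.DataFrame
    log2fc: pd.DataFrame
    group_labels: tuple[str, str] = ("female", "male")

    @property
    def biased_genes(self) -> list[str]:
        return self.table.loc[self.table["is_sex_biased"], "gene"].tolist()


@dataclass(frozen=True)
class NullCalibration:
    """Distribution of threshold-passing counts under random populations."""

    counts: np.ndarray  # one count per permutation
    lower: float  # 2.5th percentile
    upper: float  # 97.5th percentile
    threshold: float


def build_gradient_plan(
    group_a_ids: list[str],
    group_b_ids: list[str],
    population_size: int,
    rng: np.random.Generator,
) -> GradientPlan:
    """Random gradient plan from all-A to all-B populations of fixed size.

    Step 0 is a uniform subsample of ``population_size`` group-A samples;
    each step removes one remaining A sample and adds one unused B sample
    from a uniform subsample of size ``population_size``, in random order.
    """
    n = population_size
    for label, ids in (("group A", group_a_ids), ("group B", group_b_ids)):
        if len(ids) < n:
            raise ValueError(
                f"{label} has {len(ids)} samples; population_size {n} required"
            )
    a_order = list(rng.choice(group_a_ids, size=n, replace=False))
    b_order = list(rng.choice(group_b_ids, size=n, replace=False))
    removal = rng.permutation(n)
    populations = [tuple(a_order)]
    current = list(a_order)
    for k in range(n):
        current.remove(a_order[removal[k]])
        current.append(b_order[k])
        populations.append(tuple(current))
    return GradientPlan(populations=tuple(populations))


def build_null_plan(
    female_ids: list[str],
    male_ids: list[str],
    population_size: int,
    rng: np.random.Generator,
) -> GradientPlan:
    """Null counterpart of the gradient: random samples, no sex gradient.

    The plan has exactly the gradient's shape — ``n + 1`` populations of
    size ``n``, each step removing one starting member (in uniformly
    random order, never a sample shifted in) and adding one unused sample
    — but every population is sex-balanced: the start holds ``n//2``
    random females and the rest males, and each removed sample is replaced
    by an unused sample of the same sex.  The population-overlap structure
    (populations j and k share ``n - |j - k|`` samples) therefore matches
    the gradient exactly, so under exchangeable samples the two produce
    identically distributed connectivity-shift counts, while the fixed
    composition removes any sex gradient by construction.
    """
    n = population_size
    n_f = n // 2
    n_m = n - n_f
    for label, ids, need in (("female", female_ids, 2 * n_f), ("male", male_ids, 2 * n_m)):
        if len(ids) < need:
            raise ValueError(
                f"{label} pool has {len(ids)} samples; {need} required for a null plan"
            )
    f = list(rng.choice(female_ids, size=2 * n_f, replace=False))
    m = list(rng.choice(male_ids, size=2 * n_m, replace=False))
    start = f[:n_f] + m[:n_m]
    replacements_f = f[n_f:]
    replacements_m = m[n_m:]
    order = rng.permutation(n)
    current = list(start)
    populations = [tuple(current)]
    next_f = next_m = 0
    for idx in order:
        current.remove(start[idx])
        if idx < n_f:
            current.append(replacements_f[next_f])
            next_f += 1
        else:
            current.append(replacements_m[next_m])
            next_m += 1
        populations.append(tuple(current))
    return GradientPlan(populations=tuple(populations))


def run_sweep(
    log_expr: pd.DataFrame, plan: GradientPlan, adjacency: AdjacencyConfig | None = None
) -> SweepTrajectory:
    """Connectivity of every gene in every population of the plan."""
    if adjacency is None:
        adjacency = AdjacencyConfig()
    if min(len(p) for p in plan.populations) < 3:
        raise ValueError("every population must have at least 3 samples")
    col_index = {s: i for i, s in enumerate(log_expr.columns)}
    missing = {s for pop in plan.populations for s in pop if s not in col_index}
    if missing:
        raise ValueError(f"plan samples missing from the matrix: {sorted(missing)[:5]}")
    values = log_expr.to_numpy(dtype=float)
    traj = np.empty((values.shape[0], len(plan)), dtype=float)
    for j, pop in enumerate(plan.populations):
        idx = [col_index[s] for s in pop]
        traj[:, j] = connectivity_from_log_expression(values[:, idx], adjacency)
    return SweepTrajectory(gene_ids=tuple(log_expr.index), values=traj)


def quintile_blocks(n_columns: int) -> np.ndarray:
    """Block index of each sweep column: ``floor(5 * i / n_columns)``."""
    return (N_QUINTILES * np.arange(n_columns)) // n_columns


def quintilize(trajectory: SweepTrajectory) -> QuintileSummary:
    """Median connectivity per gene within five contiguous population blocks."""
    n_cols = trajectory.values.shape[1]
    if n_cols < N_QUINTILES:
        raise ValueError(f"quintilization requires >= 5 populations, got {n_cols}")
    blocks = quintile_blocks(n_cols)
    medians = np.column_stack(
        [
            np.median(trajectory.values[:, blocks == q], axis=1)
            for q in range(N_QUINTILES)
        ]
    )
    return QuintileSummary(gene_ids=trajectory.gene_ids, medians=medians)


def log2_shift(summary: QuintileSummary, epsilon: float = 1e-6) -> np.ndarray:
    """Per-gene ``log2((Q5 + eps) / (Q1 + eps))``.

    Positive values mean the gene is more connected in male-most
    populations (male-biased direction); negative, female-biased.
    """
    q1 = summary.medians[:, 0]
    q5 = summary.medians[:, -1]
    return np.log2(q5 + epsilon) - np.log2(q1 + epsilon)


def call_iteration(
    log2fc: np.ndarray, threshold: float = 1.0
) -> np.ndarray:
    """Per-gene call for one iteration: 'male', 'female' or 'none'.

    Strict inequalities: ``log2fc > threshold`` is male-biased,
    ``log2fc < -threshold`` female-biased, anything else (including the
    exact boundary) no call.
    """
    calls = np.full(log2fc.shape, "none", dtype=object)
    calls[log2fc > threshold] = "male"
    calls[log2fc < -threshold] = "female"
    return calls


def summarize_calls(
    log2fc: pd.DataFrame,
    threshold: float = 1.0,
    min_calls: int = 20,
    group_labels: tuple[str, str] = ("female", "male"),
) -> pd.DataFrame:
    """Collapse a genes x iterations log2fc record into the bias-call table.

    n_called counts iterations whose ``|log2fc|`` strictly exceeds the
    threshold; is_sex_biased requires ``n_called >= min_calls``; direction
    is the majority vote among calling iterations (ties -> 'none', logged).
    """
    values = log2fc.to_numpy(dtype=float)
    toward_b = values > threshold
    toward_a = values < -threshold
    n_b = toward_b.sum(axis=1)
    n_a = toward_a.sum(axis=1)
    n_called = n_a + n_b
    is_biased = n_called >= min_calls

    label_a, label_b = group_labels
    direction = np.full(values.shape[0], "none", dtype=object)
    direction[n_b > n_a] = label_b
    direction[n_a > n_b] = label_a
    ties = (n_a == n_b) & (n_called > 0)
    direction[ties] = "none"
    if ties.any():
        logger.warning(
            "%d gene(s) with tied call directions; direction set to 'none'",
            int(ties.sum()),
        )
    return pd.DataFrame(
        {
            "gene": log2fc.index,
            "mean_log2fc": values.mean(axis=1),
            "direction": direction,
            "n_called": n_called,
            "is_sex_biased": is_biased,
        }
    ).reset_index(drop=True)


def _group_ids(metadata: pd.DataFrame, column: str, value: str) -> list[str]:
    return metadata.loc[metadata[column] == value, "sample_id"].tolist()


def _resolve_population_size(
    config: SweepConfig, n_a: int, n_b: int
) -> int:
    n = config.population_size if config.population_size is not None else min(n_a, n_b)
    if n < 3:
        raise ValueError(f"population_size resolves to {n}; at least 3 required")
    if n > n_a or n > n_b:
        short = "group A" if n_a < n else "group B"
        raise ValueError(
            f"population_size {n} exceeds available samples in {short}"
            f" (A={n_a}, B={n_b})"
        )
    return n


def _iteration_log2fc(
    log_expr: pd.DataFrame,
    plan: GradientPlan,
    config: SweepConfig,
) -> np.ndarray:
    trajectory = run_sweep(log_expr, plan, config.adjacency)
    summary = quintilize(trajectory)
    return log2_shift(summary, config.connectivity_pseudocount)


def _consistency(
    log_expr: pd.DataFrame,
    group_a_ids: list[str],
    group_b_ids: list[str],
    config: SweepConfig,
    group_labels: tuple[str, str],
) -> BiasCallResult:
    n = _resolve_population_size(config, len(group_a_ids), len(group_b_ids))
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_iterations)
    fcs = np.empty((log_expr.shape[0], config.n_iterations))
    for i, child in enumerate(seeds):
        rng = np.random.default_rng(child)
        plan = build_gradient_plan(group_a_ids, group_b_ids, n, rng)
        fcs[:, i] = _iteration_log2fc(log_expr, plan, config)
    log2fc = pd.DataFrame(
        fcs,
        index=log_expr.index,
        columns=[f"iter{i + 1}" for i in range(config.n_iterations)],
    )
    table = summarize_calls(
        log2fc, config.log2fc_threshold, config.min_calls, group_labels
    )
    return BiasCallResult(table=table, log2fc=log2fc, group_labels=group_labels)


def run_consistency(
    log_expr: pd.DataFrame, metadata: pd.DataFrame, config: SweepConfig
) -> BiasCallResult:
    """Full sex-bias determination: n_iterations independent gradient sweeps.

    Each iteration draws a fresh random subsample of each sex and a fresh
    gradient order (child seeds derived from ``config.seed``), computes the
    extreme-quintile log2 fold change per gene, and the calls are collapsed
    by :func:`summarize_calls`.
    """
    females = _group_ids(metadata, "sex", "female")
    males = _group_ids(metadata, "sex", "male")
    return _consistency(log_expr, females, males, config, ("female", "male"))


def run_null(
    log_expr: pd.DataFrame, metadata: pd.DataFrame, config: SweepConfig
) -> NullCalibration:
    """Calibration null: gradient-shaped plans without a sex gradient.

    Each permutation builds a sex-balanced random plan
    (:func:`build_null_plan`) and records how many genes pass
    ``|log2fc| > threshold``.  Returns the count distribution with its
    2.5/97.5 percentile bounds (median-unbiased quantile estimator, which
    is tail-conservative at small permutation counts).
    """
    females = _group_ids(metadata, "sex", "female")
    males = _group_ids(metadata, "sex", "male")
    n = _resolve_population_size(config, len(females), len(males))
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_iterations)
    counts = np.empty(config.n_iterations, dtype=int)
    for i, child in enumerate(seeds):
        rng = np.random.default_rng(child)
        plan = build_null_plan(females, males, n, rng)
        fc = _iteration_log2fc(log_expr, plan, config)
        counts[i] = int((np.abs(fc) > config.log2fc_threshold).sum())
    lower, upper = np.percentile(counts, [2.5, 97.5], method="median_unbiased")
    return NullCalibration(
        counts=counts,
        lower=float(lower),
        upper=float(upper),
        threshold=config.log2fc_threshold,
    )


def threshold_pass_counts(result: BiasCallResult, threshold: float) -> np.ndarray:
    """Per-iteration count of genes with ``|log2fc|`` above the threshold."""
    return (np.abs(result.log2fc.to_numpy()) > threshold).sum(axis=0)


def menopause_sweep(
    log_expr: pd.DataFrame,
    metadata: pd.DataFrame,
    config: SweepConfig,
    sex_biased_genes: list[str] | None = None,
    age_cut: int = 50,
) -> tuple[BiasCallResult, float | None]:
    """The sweep within females over the menopause age dichotomy.

    Group A is females in age decades starting below ``age_cut``, group B
    females at or above it; direction labels are 'premenopause' /
    'postmenopause'.  When ``sex_biased_genes`` is supplied, also returns
    the fraction of those genes that are menopause-affected.
    """
    females = metadata[metadata["sex"] == "female"]
    lower = females["age_decade"].map(lambda d: int(str(d).split("-")[0]))
    pre = females.loc[lower < age_cut, "sample_id"].tolist()
    post = females.loc[lower >= age_cut, "sample_id"].tolist()
    n = config.population_size if config.population_size is not None else min(
        len(pre), len(post)
    )
    for label, ids in (("premenopause", pre), ("postmenopause", post)):
        if len(ids) < max(n, 3):
            raise ValueError(
                f"{label} group has {len(ids)} samples; at least {max(n, 3)} required"
            )
    config_n = replace(config, population_size=n)
    result = _consistency(
        log_expr, pre, post, config_n, ("premenopause", "postmenopause")
    )
    overlap_fraction: float | None = None
    if sex_biased_genes is not None:
        biased = set(sex_biased_genes)
        affected = set(result.biased_genes)
        overlap_fraction = (
            len(biased & affected) / len(biased) if biased else 0.0
        )
    return result, overlap_fraction
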