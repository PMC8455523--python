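"""Synthetic TPM-scale expression with planted sex-dependent co-expression.

The generative model is one latent factor per module and sample: for a
sample whose group matches the module's target, a module gene's latent
log-scale value is ``z = sqrt(rho_on) * f + sqrt(1 - rho_on) * eps`` with
``f`` shared across the module's genes within the sample and ``eps``
gene-specific standard normal; in the other group ``rho_off`` replaces
``rho_on``.  TPM values are ``2**(mu_g + sigma_g * z) - 1`` floored at 0,
so ``log2(TPM + 1)`` recovers the (approximately Gaussian) latent scale
and planted genes clear the default expression/variance filters.

Background genes are independent noise; differential-expression-only (DE)
genes add a sex-specific mean shift with no correlation structure, so
tests can verify that co-expression bias and differential expression are
distinct signals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .enrich import GeneSetCollection

__all__ = [
    "ModuleSpec",
    "SimulationConfig",
    "SyntheticTruth",
    "generate_dataset",
    "generate_gene_sets",
    "generate_association_table",
]

TARGET_GROUPS = ("male", "female", "both", "premenopause_female")

# GTEx-like age-decade composition of adult donors.
DEFAULT_AGE_WEIGHTS: dict[str, float] = {
    "20-29": 0.07,
    "30-39": 0.08,
    "40-49": 0.16,
    "50-59": 0.31,
    "60-69": 0.33,
    "70-79": 0.05,
}


def _decade_lower_bound(decade: str) -> int:
    return int(str(decade).split("-")[0])


@dataclass(frozen=True)
class ModuleSpec:
    """A planted co-expression module.

    rho_on is the within-module latent correlation in the target group,
    rho_off in the complementary group; ``target_group="both"`` keeps the
    module active in all samples, ``"premenopause_female"`` restricts
    rho_on to female samples in age decades below 50-59.
    """

    n_genes: int
    target_group: str
    rho_on: float
    rho_off: float = 0.0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError(f"module n_genes must be >= 2, got {self.n_genes}")
        if self.target_group not in TARGET_GROUPS:
            raise ValueError(
                f"target_group must be one of {TARGET_GROUPS}, got {self.target_group!r}"
            )
        for name in ("rho_on", "rho_off"):
            value = getattr(self, name)
            if not (0 <= value < 1):
                raise ValueError(f"{name} must lie in [0, 1), got {value}")
        if self.rho_on < self.rho_off:
            raise ValueError(
                f"rho_on ({self.rho_on}) must be >= rho_off ({self.rho_off})"
            )


@dataclass(frozen=True)
class SimulationConfig:
    n_females: int = 80
    n_males: int = 80
    n_background_genes: int = 250
    modules: tuple[ModuleSpec, ...] = ()
    n_de_genes: int = 0
    de_log2_shift: float = 1.0
    base_log2_mean: float = 6.0
    gene_log2_sd: float = 1.5
    age_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AGE_WEIGHTS)
    )
    tissue: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_females < 5:
            raise ValueError(f"n_females must be >= 5, got {self.n_females}")
        if self.n_males < 5:
            raise ValueError(f"n_males must be >= 5, got {self.n_males}")
        for name in ("n_background_genes", "n_de_genes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not self.gene_log2_sd > 0:
            raise ValueError(f"gene_log2_sd must be > 0, got {self.gene_log2_sd}")
        if self.age_weights and not all(w >= 0 for w in self.age_weights.values()):
            raise ValueError("age decade weights must be non-negative")
        object.__setattr__(self, "modules", tuple(self.modules))

    @property
    def n_genes(self) -> int:
        return (
            sum(m.n_genes for m in self.modules)
            + self.n_background_genes
            + self.n_de_genes
        )


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of the planted structure, for recovery testing."""

    gene_module: dict[str, str]  # planted gene -> module name
    module_target: dict[str, str]  # module name -> target group
    de_genes: dict[str, str]  # DE-only gene -> sex with higher expression
    background_genes: tuple[str, ...]

    @property
    def all_genes(self) -> list[str]:
        return (
            list(self.gene_module)
            + list(self.de_genes)
            + list(self.background_genes)
        )

    def module_genes(self, module: str) -> list[str]:
        return [g for g, m in self.gene_module.items() if m == module]

    def genes_for_target(self, target_group: str) -> list[str]:
        return [
            g
            for g, m in self.gene_module.items()
            if self.module_target[m] == target_group
        ]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "gene_module": self.gene_module,
                    "module_target": self.module_target,
                    "de_genes": self.de_genes,
                    "background_genes": list(self.background_genes),
                },
                indent=1,
            )
        )


def _module_active_mask(
    spec: ModuleSpec, sexes: np.ndarray, decades: np.ndarray
) -> np.ndarray:
    if spec.target_group == "both":
        return np.ones(sexes.shape, dtype=bool)
    if spec.target_group == "male":
        return sexes == "male"
    if spec.target_group == "female":
        return sexes == "female"
    # premenopause_female: female samples below the 50-59 decade
    lower = np.array([_decade_lower_bound(d) for d in decades])
    return (sexes == "female") & (lower < 50)


def generate_dataset(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate (expression TPM frame, sample metadata, planted truth).

    The expression frame is genes x samples; metadata has columns
    sample_id, sex, age_decade, rin, tissue.  Identical seeds give
    bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n_samples = config.n_females + config.n_males

    sample_ids = [f"F{i + 1:04d}" for i in range(config.n_females)] + [
        f"M{i + 1:04d}" for i in range(config.n_males)
    ]
    sexes = np.array(
        ["female"] * config.n_females + ["male"] * config.n_males, dtype=object
    )
    decades = list(config.age_weights) or ["50-59"]
    weights = np.array([config.age_weights.get(d, 1.0) for d in decades], float)
    weights = weights / weights.sum()
    age_decade = rng.choice(decades, size=n_samples, p=weights)
    rin = np.round(rng.uniform(6.5, 9.5, size=n_samples), 1)
    metadata = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "sex": sexes,
            "age_decade": age_decade,
            "rin": rin,
            "tissue": config.tissue,
        }
    )

    gene_module: dict[str, str] = {}
    module_target: dict[str, str] = {}
    blocks: list[np.ndarray] = []
    gene_ids: list[str] = []

    for m_idx, spec in enumerate(config.modules, start=1):
        module = f"module{m_idx}_{spec.target_group}"
        module_target[module] = spec.target_group
        names = [f"{module}_g{i + 1}" for i in range(spec.n_genes)]
        gene_ids.extend(names)
        gene_module.update({g: module for g in names})
        active = _module_active_mask(spec, sexes, age_decade)
        rho = np.where(active, spec.rho_on, spec.rho_off)
        factor = rng.standard_normal(n_samples)
        eps = rng.standard_normal((spec.n_genes, n_samples))
        z = np.sqrt(rho)[None, :] * factor[None, :] + np.sqrt(1 - rho)[None, :] * eps
        blocks.append(z)

    de_genes: dict[str, str] = {}
    de_shift = np.zeros((config.n_de_genes, n_samples))
    if config.n_de_genes:
        names = [f"de_g{i + 1}" for i in range(config.n_de_genes)]
        gene_ids.extend(names)
        blocks.append(rng.standard_normal((config.n_de_genes, n_samples)))
        is_male = sexes == "male"
        for i, g in enumerate(names):
            up_in = "male" if i % 2 == 0 else "female"
            de_genes[g] = up_in
            shift = np.where(is_male, 1.0, -1.0) * (1 if up_in == "male" else -1)
            de_shift[i] = 0.5 * config.de_log2_shift * shift

    background = tuple(f"bg_g{i + 1}" for i in range(config.n_background_genes))
    if background:
        gene_ids.extend(background)
        blocks.append(rng.standard_normal((config.n_background_genes, n_samples)))

    if not gene_ids:
        raise ValueError("configuration generates zero genes")

    z_all = np.vstack(blocks)
    n_genes = z_all.shape[0]
    # per-gene baseline means jittered around the configured baseline
    mu = config.base_log2_mean + rng.uniform(-1.0, 1.0, size=n_genes)
    log2_vals = mu[:, None] + config.gene_log2_sd * z_all
    # DE-only genes: sex-specific mean shift on the log2 scale
    n_planted = sum(m.n_genes for m in config.modules)
    if config.n_de_genes:
        log2_vals[n_planted : n_planted + config.n_de_genes] += de_shift
    tpm = np.maximum(np.exp2(log2_vals) - 1.0, 0.0)

    expr = pd.DataFrame(tpm, index=gene_ids, columns=sample_ids)
    truth = SyntheticTruth(
        gene_module=gene_module,
        module_target=module_target,
        de_genes=de_genes,
        background_genes=background,
    )
    return expr, metadata, truth


def generate_gene_sets(
    truth: SyntheticTruth, n_decoy_sets: int, seed: int
) -> GeneSetCollection:
    """One gene set per planted module plus uniform random decoy sets."""
    universe = truth.all_genes
    if not universe:
        raise ValueError("truth is empty; nothing to build gene sets from")
    rng = np.random.default_rng(seed)
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for module in truth.module_target:
        sets[module] = frozenset(truth.module_genes(module))
        descriptions[module] = f"planted module targeting {truth.module_target[module]}"
    for i in range(n_decoy_sets):
        size = int(rng.integers(5, min(51, len(universe) + 1)))
        members = rng.choice(universe, size=size, replace=False)
        name = f"decoy{i + 1}"
        sets[name] = frozenset(members)
        descriptions[name] = "random decoy set"
    return GeneSetCollection(
        sets=sets, descriptions=descriptions, universe=frozenset(universe)
    )


def generate_association_table(
    truth: SyntheticTruth,
    n_diseases: int,
    genes_per_disease: tuple[int, int] = (20, 150),
    min_genes_top_disease: int = 100,
    score_beta: tuple[float, float] = (5.0, 2.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Gene-disease association rows with Beta-distributed evidence scores.

    Columns: gene, disease, score.  Scores lie in (0, 1]; the first
    disease is annotated with at least ``min_genes_top_disease`` genes so
    the count filter always has something to retain.
    """
    universe = truth.all_genes
    if not universe:
        raise ValueError("truth is empty; nothing to annotate")
    rng = np.random.default_rng(seed)
    lo, hi = genes_per_disease
    rows: list[tuple[str, str, float]] = []
    for d in range(n_diseases):
        disease = f"disease{d + 1}"
        size = int(rng.integers(lo, hi + 1))
        if d == 0:
            size = max(size, min(min_genes_top_disease, len(universe)))
        size = min(size, len(universe))
        genes = rng.choice(universe, size=size, replace=False)
        scores = rng.beta(*score_beta, size=size)
        scores = np.clip(scores, np.finfo(float).tiny, 1.0)
        rows.extend((g, disease, float(s)) for g, s in zip(genes, scores))
    return pd.DataFrame(rows, columns=["gene", "disease", "score"])
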