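"""Sample, tissue and gene selection rules plus the log transform and PCA QC.

Selection mirrors the study design the pipeline implements: samples need
RNA integrity (RIN) strictly above 6.0, a tissue is analyzed only when both
sexes contribute at least 80 samples, and genes enter the co-expression
analysis when their log2(TPM+1) profile has mean >= 1 and unbiased variance
>= 1 across the retained samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = [
    "FilterConfig",
    "filter_samples",
    "select_tissues",
    "log_transform",
    "select_genes",
    "pca_qc",
]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for sample, tissue and gene selection.

    rin_min applies strictly (RIN must exceed it); min_samples_per_sex is
    inclusive; the gene filters are inclusive on mean and variance of
    log2(TPM + pseudocount).
    """

    rin_min: float = 6.0
    min_samples_per_sex: int = 80
    mean_log2_tpm_min: float = 1.0
    var_log2_min: float = 1.0
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        for name in ("rin_min", "mean_log2_tpm_min", "var_log2_min", "pseudocount"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not self.pseudocount > 0:
            raise ValueError(f"pseudocount must be > 0, got {self.pseudocount}")


def filter_samples(metadata: pd.DataFrame, rin_min: float = 6.0) -> list[str]:
    """Sample IDs with RIN strictly greater than ``rin_min``, order preserved.

    Samples with missing RIN are excluded with a logged warning.
    """
    if "rin" not in metadata.columns:
        raise ValueError("metadata must have a 'rin' column")
    rin = pd.to_numeric(metadata["rin"], errors="coerce")
    n_missing = int(rin.isna().sum())
    if n_missing:
        logger.warning("%d sample(s) with missing RIN excluded", n_missing)
    keep = rin > rin_min
    return metadata.loc[keep.fillna(False), "sample_id"].tolist()


def select_tissues(metadata: pd.DataFrame, min_samples_per_sex: int = 80) -> list[str]:
    """Tissues with at least ``min_samples_per_sex`` samples of each sex."""
    for col in ("tissue", "sex"):
        if col not in metadata.columns:
            raise ValueError(f"metadata must have a {col!r} column")
    counts = metadata.groupby(["tissue", "sex"], observed=True).size().unstack(fill_value=0)
    for sex in ("female", "male"):
        if sex not in counts.columns:
            counts[sex] = 0
    ok = (counts["female"] >= min_samples_per_sex) & (counts["male"] >= min_samples_per_sex)
    retained = counts.index[ok].tolist()
    if not retained:
        logger.warning("no tissue has >= %d samples of both sexes", min_samples_per_sex)
    return retained


def log_transform(expr: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """``log2(TPM + pseudocount)``; shape and labels preserved."""
    values = expr.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("expression values must be non-negative (TPM scale)")
    return pd.DataFrame(
        np.log2(values + pseudocount), index=expr.index, columns=expr.columns
    )


def select_genes(
    expr: pd.DataFrame,
    mean_log2_tpm_min: float = 1.0,
    var_log2_min: float = 1.0,
    pseudocount: float = 1.0,
) -> list[str]:
    """Gene IDs whose log2(TPM+pseudocount) mean and unbiased variance pass.

    A gene is retained iff mean >= ``mean_log2_tpm_min`` and variance
    (ddof=1) >= ``var_log2_min`` over samples.
    """
    if expr.shape[1] < 2:
        raise ValueError("gene variance is undefined with fewer than 2 samples")
    log_values = log_transform(expr, pseudocount).to_numpy()
    means = log_values.mean(axis=1)
    variances = log_values.var(axis=1, ddof=1)
    keep = (means >= mean_log2_tpm_min) & (variances >= var_log2_min)
    return expr.index[keep].tolist()


def pca_qc(
    expr: pd.DataFrame, n_top_genes: int = 1000, pseudocount: float = 1.0
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-sample scores on the first two PCs of the most variable genes.

    Genes are ranked by variance of log2(TPM+pseudocount); the top
    ``n_top_genes`` (capped at the gene count) feed a centered PCA.
    Returns (scores frame with PC1/PC2 columns indexed by sample,
    variance-explained ratios).  QC only — nothing downstream consumes it.
    """
    if expr.shape[1] < 3:
        raise ValueError("PCA QC requires at least 3 samples")
    log_values = log_transform(expr, pseudocount)
    variances = log_values.var(axis=1, ddof=1)
    if n_top_genes > expr.shape[0]:
        logger.info(
            "n_top_genes=%d exceeds gene count %d; using all genes",
            n_top_genes,
            expr.shape[0],
        )
        n_top_genes = expr.shape[0]
    if n_top_genes < 2:
        raise ValueError("fewer than 2 genes available for PCA")
    top = variances.nlargest(n_top_genes).index
    sub = log_values.loc[top].to_numpy().T  # samples x genes
    if np.allclose(sub.var(axis=0), 0):
        raise ValueError("selected genes have zero variance; PCA undefined")
    pca = PCA(n_components=2)
    scores = pca.fit_transform(sub - sub.mean(axis=0))
    frame = pd.DataFrame(scores, index=expr.columns, columns=["PC1", "PC2"])
    return frame, pca.explained_variance_ratio_
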