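"""Soft-threshold co-expression networks and per-gene connectivity.

The quantity tracked through the population sweep is WGCNA-style
whole-network connectivity: Pearson correlation between gene expression
profiles, raised elementwise to a power ``beta`` (soft thresholding),
summed over all partner genes.  With the default unsigned adjacency
``a_ij = |r_ij|**beta`` and zero self-adjacency, connectivity lies in
``[0, G-1]`` for ``G`` genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AdjacencyConfig",
    "correlation_matrix",
    "soft_threshold_adjacency",
    "connectivity",
    "connectivity_from_log_expression",
]


@dataclass(frozen=True)
class AdjacencyConfig:
    """Soft-threshold adjacency parameters.

    beta
        Soft-threshold exponent; default 5.
    signed
        If False (default), unsigned adjacency ``|r|**beta``;
        if True, signed adjacency ``((1 + r) / 2)**beta``.
    correlation
        Correlation estimator; only ``"pearson"`` is supported.
    """

    beta: float = 5.0
    signed: bool = False
    correlation: str = "pearson"

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if self.correlation != "pearson":
            raise ValueError(f"unsupported correlation estimator: {self.correlation!r}")


def _standardize_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center and scale rows to unit variance; zero-variance rows become 0.

    Returns the standardized matrix and a boolean mask of zero-variance rows.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[1]
    centered = values - values.mean(axis=1, keepdims=True)
    sd = centered.std(axis=1, ddof=1)
    degenerate = sd == 0
    sd_safe = np.where(degenerate, 1.0, sd)
    standardized = centered / (sd_safe[:, None] * np.sqrt(n - 1))
    standardized[degenerate] = 0.0
    return standardized, degenerate


def correlation_matrix(log_expr: pd.DataFrame) -> pd.DataFrame:
    """Gene x gene Pearson correlation of a genes x samples log-expression frame.

    Requires at least 3 samples.  Genes with zero variance in the given
    sample subset get correlation 0 to every partner (diagonal stays 1),
    with a logged warning, so downstream adjacency sums remain finite.
    """
    if log_expr.shape[1] < 3:
        raise ValueError(
            f"correlation requires >= 3 samples, got {log_expr.shape[1]}"
        )
    standardized, degenerate = _standardize_rows(log_expr.to_numpy())
    if degenerate.any():
        logger.warning(
            "%d zero-variance gene(s) in sample subset; correlations set to 0",
            int(degenerate.sum()),
        )
    corr = standardized @ standardized.T
    np.clip(corr, -1.0, 1.0, out=corr)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=log_expr.index, columns=log_expr.index)


def soft_threshold_adjacency(
    cor: pd.DataFrame | np.ndarray, config: AdjacencyConfig | None = None
) -> pd.DataFrame | np.ndarray:
    """Raise correlations to the soft-threshold power; zero the diagonal.

    Unsigned: ``a_ij = |r_ij|**beta``.  Signed: ``a_ij = ((1+r_ij)/2)**beta``.
    Self-adjacency is excluded (diagonal set to 0).
    """
    if config is None:
        config = AdjacencyConfig()
    values = cor.to_numpy() if isinstance(cor, pd.DataFrame) else np.asarray(cor, float)
    if config.signed:
        adj = ((1.0 + values) / 2.0) ** config.beta
    else:
        adj = np.abs(values) ** config.beta
    np.fill_diagonal(adj, 0.0)
    if isinstance(cor, pd.DataFrame):
        return pd.DataFrame(adj, index=cor.index, columns=cor.columns)
    return adj


def connectivity(adjacency: pd.DataFrame | np.ndarray) -> pd.Series | np.ndarray:
    """Whole-network connectivity: ``k_i = sum_{j != i} a_ij``.

    The adjacency must be square and symmetric; any diagonal entries are
    excluded from the sum regardless of their value.
    """
    values = (
        adjacency.to_numpy()
        if isinstance(adjacency, pd.DataFrame)
        else np.asarray(adjacency, float)
    )
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {values.shape}")
    if not np.allclose(values, values.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    k = values.sum(axis=1) - np.diagonal(values)
    if isinstance(adjacency, pd.DataFrame):
        return pd.Series(k, index=adjacency.index, name="k")
    return k


def connectivity_from_log_expression(
    values: np.ndarray, config: AdjacencyConfig
) -> np.ndarray:
    """Connectivity straight from a genes x samples log-expression array.

    Fast path used inside the sweep: standardize rows, one matrix product
    for the correlation, soft-threshold, row-sum.  Zero-variance genes
    contribute 0 adjacency (matching :func:`correlation_matrix`).
    """
    standardized, _ = _standardize_rows(values)
    corr = standardized @ standardized.T
    np.clip(corr, -1.0, 1.0, out=corr)
    if config.signed:
        adj = ((1.0 + corr) / 2.0) ** config.beta
    else:
        adj = np.abs(corr) ** config.beta
    np.fill_diagonal(adj, 0.0)
    return adj.sum(axis=1)
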