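"""Testing phase: residuals, absolute-residual gene ranking, replicate averaging.

Given the trained interaction matrix, a test experiment's expression vector
is centered with the training means and the residual

    r = y_centered - B_hat @ y_centered

isolates effects the gene network cannot explain.  Genes are ranked by
decreasing |residual| (rank 1 = strongest candidate target); ties keep
compendium gene order.  The z-score baseline ranks genes by
|y - mean| / sd against the training compendium without any network
adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionCompendium
from .training import InteractionNetwork

__all__ = [
    "ResidualProfile",
    "GeneRanking",
    "compute_residuals",
    "rank_genes",
    "average_rankings",
    "zscore_ranking",
]


@dataclass
class ResidualProfile:
    genes: list[str]
    y_pert: np.ndarray
    residuals: np.ndarray

    def __post_init__(self) -> None:
        p = len(self.genes)
        if len(self.residuals) != p or len(self.y_pert) != p:
            raise ValueError("profile vectors must match the gene list length")
        if not np.all(np.isfinite(self.residuals)):
            raise ValueError("residuals must be finite")


@dataclass
class GeneRanking:
    """1-based ranks (a permutation of 1..p) by decreasing absolute score."""

    genes: list[str]
    rank: np.ndarray
    abs_residual: np.ndarray
    residuals: np.ndarray | None = None

    def __post_init__(self) -> None:
        p = len(self.genes)
        if sorted(self.rank.tolist()) != list(range(1, p + 1)):
            raise ValueError("rank must be a permutation of 1..p")
        if self.residuals is None:
            self.residuals = self.abs_residual.copy()

    def rank_of(self, gene: str) -> int:
        try:
            i = self.genes.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene {gene!r}") from None
        return int(self.rank[i])

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": self.genes, "abs_residual": self.abs_residual, "rank": self.rank}
        ).set_index("gene")


def _check_universe(genes_a: list[str], genes_b: list[str], what: str) -> None:
    if list(genes_a) != list(genes_b):
        missing = sorted(set(genes_a) - set(genes_b))
        surplus = sorted(set(genes_b) - set(genes_a))
        detail = []
        if missing:
            detail.append(f"missing: {missing[:10]}")
        if surplus:
            detail.append(f"unexpected: {surplus[:10]}")
        if not detail:
            detail.append("same genes, different order")
        raise ValueError(f"gene universe mismatch in {what} ({'; '.join(detail)})")


def _as_vector(y_pert, genes: list[str]) -> np.ndarray:
    if isinstance(y_pert, pd.Series):
        _check_universe(genes, [str(g) for g in y_pert.index], "test vector")
        return y_pert.to_numpy(dtype=float)
    arr = np.asarray(y_pert, dtype=float)
    if arr.shape != (len(genes),):
        raise ValueError(f"expected a length-{len(genes)} vector, got shape {arr.shape}")
    return arr


def compute_residuals(net: InteractionNetwork, y_pert) -> ResidualProfile:
    """Residual profile r = y_tilde - B_hat y_tilde, y_tilde centered by training means."""
    y = _as_vector(y_pert, net.genes)
    if not np.all(np.isfinite(y)):
        raise ValueError("test vector contains non-finite values")
    centered = y - net.train_means
    residuals = centered - net.B_hat @ centered
    return ResidualProfile(genes=list(net.genes), y_pert=y, residuals=residuals)


def rank_genes(profile: ResidualProfile) -> GeneRanking:
    """Rank genes by decreasing |residual|; ties keep gene (compendium) order."""
    scores = np.abs(profile.residuals)
    order = np.argsort(-scores, kind="stable")
    p = len(scores)
    rank = np.empty(p, dtype=int)
    rank[order] = np.arange(1, p + 1)
    return GeneRanking(
        genes=list(profile.genes),
        rank=rank,
        abs_residual=scores,
        residuals=profile.residuals.copy(),
    )


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero (display convention)."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def average_rankings(rankings: list[GeneRanking]) -> pd.DataFrame:
    """Average per-gene ranks across replicate experiments.

    Returns a frame indexed by gene with the exact mean rank and the
    half-up-rounded integer used for display.
    """
    if not rankings:
        raise ValueError("at least one ranking is required")
    genes = rankings[0].genes
    for r in rankings[1:]:
        _check_universe(genes, r.genes, "average_rankings")
    ranks = np.vstack([r.rank for r in rankings]).astype(float)
    mean = ranks.mean(axis=0)
    return pd.DataFrame(
        {
            "gene": genes,
            "mean_rank": mean,
            "display_rank": [round_half_up(m) for m in mean],
        }
    ).set_index("gene")


def zscore_ranking(train: ExpressionCompendium, y_pert) -> GeneRanking:
    """Baseline ranking by |z| against the training compendium (no network).

    z = (y - training mean) / training sd per gene; genes with zero training
    sd get score 0 with a warning.  Ranking follows :func:`rank_genes`.
    """
    genes = train.genes
    y = _as_vector(y_pert, genes)
    Y = train.values
    mean = Y.mean(axis=1)
    sd = Y.std(axis=1, ddof=1)
    zero_sd = sd == 0
    if np.any(zero_sd):
        warnings.warn(
            f"{int(zero_sd.sum())} gene(s) have zero training variance; z set to 0",
            stacklevel=2,
        )
    z = np.zeros_like(y)
    ok = ~zero_sd
    z[ok] = (y[ok] - mean[ok]) / sd[ok]
    profile = ResidualProfile(genes=genes, y_pert=y, residuals=z)
    return rank_genes(profile)
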