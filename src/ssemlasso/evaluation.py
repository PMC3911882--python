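"""Evaluation statistics: rank percentiles, gene-set ROC/AUC%, rank changes.

Conventions (fixed so that higher is better throughout):

* rank percentile = 100 * (N - rank) / N, the percentage of genes ranking
  worse than the target; display rounds to the nearest integer (half away
  from zero), keeping one decimal when that would print 100 for a gene not
  ranked first.
* AUC% is the trapezoidal area under the gene-set ROC curve (TPR vs FPR
  over every rank threshold) times 100; 50% is the random-guess level.
* RC = rank_original - rank_modified, so positive means the rank improved
  after modifying the training compendium.  The RC percentile is the
  percentage of the experiment's genome-wide RCs strictly below the
  target's RC, reported only when RC > 0 ('n/a' otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import GeneSet
from .scoring import GeneRanking, round_half_up

__all__ = [
    "RocCurve",
    "RankChangeResult",
    "rank_percentile",
    "format_rank_percentile",
    "gene_set_roc",
    "average_auc",
    "rank_change",
    "rc_percentile",
    "format_rc_percentile",
]


@dataclass
class RocCurve:
    """ROC points over rank thresholds 0..p plus the trapezoidal AUC%."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc_percent: float

    def __post_init__(self) -> None:
        for arr in (self.tpr, self.fpr):
            if np.any(np.diff(arr) < 0) or arr[0] != 0.0 or arr[-1] != 1.0:
                raise ValueError("ROC rates must be non-decreasing from 0 to 1")
        if not 0.0 <= self.auc_percent <= 100.0:
            raise ValueError("auc_percent must lie in [0, 100]")


@dataclass
class RankChangeResult:
    """Per-gene rank change between original and modified compendium runs."""

    gene: str
    rank_original: float
    rank_modified: float
    rc: float
    rc_percentile: float | None

    @classmethod
    def from_ranks(
        cls,
        gene: str,
        rank_original: float,
        rank_modified: float,
        all_rcs: np.ndarray,
    ) -> "RankChangeResult":
        rc = rank_change(rank_original, rank_modified)
        return cls(
            gene=gene,
            rank_original=rank_original,
            rank_modified=rank_modified,
            rc=rc,
            rc_percentile=rc_percentile(rc, all_rcs),
        )


def rank_percentile(rank: float, n_genes: int) -> float:
    """Percentage of genes ranking worse than a gene ranked ``rank`` of ``n_genes``."""
    if not 1 <= rank <= n_genes:
        raise ValueError(f"rank {rank} outside [1, {n_genes}]")
    return 100.0 * (n_genes - rank) / n_genes


def format_rank_percentile(rank: float, n_genes: int) -> float:
    """Display value of the rank percentile.

    Nearest integer (half away from zero), except that a gene not ranked
    first never displays 100: one decimal is kept instead (e.g. rank 20 of
    6681 displays 99.7, not 100).
    """
    pct = rank_percentile(rank, n_genes)
    rounded = round_half_up(pct)
    if rounded >= 100 and rank > 1:
        one_decimal = np.floor(pct * 10.0 + 0.5) / 10.0
        if one_decimal >= 100.0:  # still rounds up; truncate instead
            one_decimal = np.floor(pct * 10.0) / 10.0
        return float(one_decimal)
    return float(rounded)


def gene_set_roc(ranking: GeneRanking, gene_set: GeneSet) -> RocCurve:
    """ROC curve of a gene set against a genome-wide ranking.

    At rank threshold t, TPR is the fraction of set members ranked <= t and
    FPR the fraction of non-members ranked <= t; the AUC% is the trapezoid
    area over (FPR, TPR) times 100.
    """
    genes = ranking.genes
    p = len(genes)
    universe = set(genes)
    stray = sorted(gene_set.members - universe)
    if stray:
        raise ValueError(f"gene set members outside the ranking universe: {stray[:10]}")
    n_pos = len(gene_set.members)
    if n_pos == 0 or n_pos == p:
        raise ValueError("gene set must be a proper nonempty subset of the universe")
    member = np.array([g in gene_set.members for g in genes])
    # positives[t] = number of members with rank <= t, via a rank histogram
    pos_hist = np.bincount(ranking.rank[member], minlength=p + 1)
    neg_hist = np.bincount(ranking.rank[~member], minlength=p + 1)
    tpr = np.cumsum(pos_hist) / n_pos
    fpr = np.cumsum(neg_hist) / (p - n_pos)
    auc = float(np.trapezoid(tpr, fpr)) * 100.0
    return RocCurve(
        thresholds=np.arange(p + 1), tpr=tpr, fpr=fpr, auc_percent=auc
    )


def average_auc(curves: list[RocCurve]) -> float:
    """Arithmetic mean AUC% over replicate ROC curves."""
    if not curves:
        raise ValueError("at least one ROC curve is required")
    return float(np.mean([c.auc_percent for c in curves]))


def rank_change(rank_original: float, rank_modified: float) -> float:
    """RC = original rank minus modified rank; positive = improved."""
    return rank_original - rank_modified


def rc_percentile(rc_target: float, all_rcs: np.ndarray) -> float | None:
    """Percentage of genome-wide RCs strictly below the target's RC.

    Defined only for RC > 0; returns ``None`` (displayed 'n/a') otherwise.
    """
    all_rcs = np.asarray(all_rcs, dtype=float)
    if all_rcs.size == 0:
        raise ValueError("empty RC vector")
    if rc_target <= 0:
        return None
    return 100.0 * float(np.sum(all_rcs < rc_target)) / all_rcs.size


def format_rc_percentile(value: float | None) -> str:
    """Display an RC percentile: nearest integer, or 'n/a' when undefined."""
    if value is None:
        return "n/a"
    return str(round_half_up(value))
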