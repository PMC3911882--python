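"""Training phase: row-by-row sparse regression of the interaction matrix.

With the perturbation term set to zero, each gene's (centered) expression is
regressed on all other genes' expression:

    y_k = sum_{j != k} B_kj y_j + e_k

and the row of B is estimated by the Lasso without intercept,

    min_b  (1/2n) || y_k - X b ||^2  +  lambda ||b||_1

(the 1/2n scaling makes lambda comparable across compendium sizes).  The
penalty is either chosen per row by K-fold cross-validation or fixed.
Fitting is delegated to scikit-learn's coordinate-descent solvers, whose
objective uses exactly this scaling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold

from .io import ExpressionCompendium

__all__ = ["LassoConfig", "InteractionNetwork", "fit_row", "fit_network"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LassoConfig:
    """Penalty selection and solver contract for row-wise Lasso fits.

    Exactly one penalty source is active: K-fold cross-validation
    (``penalty_mode='cv'``, default K = 5, minimizing mean validation MSE)
    or a fixed ``fixed_lambda``.  ``seed`` controls the shuffled fold
    assignment only; given data and seed the fit is deterministic.
    """

    penalty_mode: Literal["cv", "fixed"] = "cv"
    cv_folds: int = 5
    fixed_lambda: float | None = None
    max_iter: int = 50_000
    tol: float = 1e-6
    seed: int = 0
    n_alphas: int = 100

    def __post_init__(self) -> None:
        if self.penalty_mode not in ("cv", "fixed"):
            raise ValueError("penalty_mode must be 'cv' or 'fixed'")
        if self.penalty_mode == "cv":
            if self.cv_folds < 2:
                raise ValueError("cv_folds must be >= 2")
            if self.fixed_lambda is not None:
                raise ValueError("fixed_lambda must be unset in cv mode")
        else:
            if self.fixed_lambda is None or not self.fixed_lambda > 0:
                raise ValueError("fixed mode requires fixed_lambda > 0")


@dataclass
class InteractionNetwork:
    """Estimated sparse interaction matrix plus training means.

    ``B_hat[k, j]`` is the effect of gene j on gene k; the diagonal is
    identically zero.  ``train_means`` are the per-gene means of the
    training compendium, retained to center test vectors.
    """

    genes: list[str]
    B_hat: np.ndarray
    train_means: np.ndarray
    lasso_report: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        p = len(self.genes)
        if self.B_hat.shape != (p, p):
            raise ValueError("B_hat shape does not match gene list")
        if np.any(np.diag(self.B_hat) != 0.0):
            raise ValueError("B_hat diagonal must be exactly zero")
        if not np.all(np.isfinite(self.train_means)):
            raise ValueError("train_means must be finite")

    @property
    def p(self) -> int:
        return len(self.genes)


def fit_row(
    k: int, Y_centered: np.ndarray, config: LassoConfig
) -> tuple[np.ndarray, float, int]:
    """Fit one row of B by intercept-free Lasso.

    Parameters
    ----------
    k:
        Index of the response gene.
    Y_centered:
        p x n matrix with per-gene means already removed.
    config:
        Penalty-selection configuration.

    Returns
    -------
    (coefficients, chosen_lambda, nonzero_count) where ``coefficients`` has
    length p with entry k forced to zero.  A response with zero variance
    yields an all-zero row (with a warning); ``n < cv_folds`` is rejected.
    """
    p, n = Y_centered.shape
    if config.penalty_mode == "cv" and n < config.cv_folds:
        raise ValueError(
            f"n = {n} training samples is fewer than cv_folds = {config.cv_folds}"
        )
    y = Y_centered[k]
    X = np.delete(Y_centered, k, axis=0).T  # n x (p-1)
    row = np.zeros(p)
    if np.allclose(y, 0.0):
        warnings.warn(
            f"response gene index {k} is constant after centering; returning a zero row",
            stacklevel=2,
        )
        return row, float("nan"), 0
    if config.penalty_mode == "fixed":
        model = Lasso(
            alpha=config.fixed_lambda,
            fit_intercept=False,
            max_iter=config.max_iter,
            tol=config.tol,
        )
        model.fit(X, y)
        chosen = float(config.fixed_lambda)
    else:
        folds = KFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
        model = LassoCV(
            cv=folds,
            fit_intercept=False,
            alphas=config.n_alphas,  # size of the automatic alpha grid
            max_iter=config.max_iter,
            tol=config.tol,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # benign convergence chatter on coarse alphas
            model.fit(X, y)
        chosen = float(model.alpha_)
    coefs = model.coef_
    others = [j for j in range(p) if j != k]
    row[others] = coefs
    row[k] = 0.0
    return row, chosen, int(np.count_nonzero(row))


def fit_network(train: ExpressionCompendium, config: LassoConfig) -> InteractionNetwork:
    """Infer the full interaction network from a training compendium.

    Centers every gene by its training mean, then fits each row of B
    independently with :func:`fit_row`.  Row fits do not interact; the
    output is independent of the order in which rows are processed.
    """
    n_min = max(config.cv_folds if config.penalty_mode == "cv" else 0, 3)
    if train.n < n_min:
        raise ValueError(f"need at least {n_min} training samples, got {train.n}")
    Y = train.values
    means = Y.mean(axis=1)
    Yc = Y - means[:, None]
    p = train.p
    B = np.zeros((p, p))
    report_rows = []
    for k, gene in enumerate(train.genes):
        try:
            row, lam, nnz = fit_row(k, Yc, config)
        except Exception as exc:
            raise RuntimeError(f"row fit failed for gene {gene!r}: {exc}") from exc
        B[k] = row
        report_rows.append({"gene": gene, "lambda": lam, "nonzero": nnz})
        logger.info("fit row %d/%d (%s): lambda=%.4g nonzero=%d", k + 1, p, gene, lam, nnz)
    report = pd.DataFrame(report_rows)
    return InteractionNetwork(
        genes=list(train.genes), B_hat=B, train_means=means, lasso_report=report
    )
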