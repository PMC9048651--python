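"""L1-penalized per-gene regression with StARS regularization selection.

The lasso penalty weight is chosen by the Stability Approach to
Regularization Selection: fit the lasso path on many random subsamples,
measure how unstable each predictor's selection is (instability of predictor
j at penalty lambda is 2 theta (1 - theta) for selection frequency theta),
and pick the least regularization whose monotonized mean instability stays
below a target (default 0.05).  Selected supports are refit by OLS so edges
carry the same explained-variance scores as the best-subset engine.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, lasso_path

from .io_model import (ActivityMatrix, AdjacencyNetwork, GeneExpressionMatrix,
                       ScoredEdgeSet)
from .regression_bbsr import bootstrap_indices, ols_refit_scores, standardize_columns

logger = logging.getLogger("grninfer")


@dataclass
class StabilityPath:
    """Per-lambda selection frequencies and instabilities from subsampling."""

    lambdas: np.ndarray          # descending
    theta: np.ndarray            # n_lambda x p selection frequencies
    instability: np.ndarray      # D(lambda) = mean_j 2 theta (1 - theta)
    monotone_instability: np.ndarray  # running max of D from largest lambda


def lambda_max(y: np.ndarray, X: np.ndarray) -> float:
    """Smallest penalty at which the lasso solution is identically zero."""
    n = len(y)
    return float(np.max(np.abs(X.T @ y)) / n) if X.size else 0.0


def solve_l1_least_squares(y: np.ndarray, X: np.ndarray, lam: float
                           ) -> np.ndarray:
    """Minimize (1/2n)||y - X b||^2 + lam ||b||_1 (no intercept)."""
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if lam == 0:
        return np.linalg.lstsq(X, y, rcond=None)[0]
    model = Lasso(alpha=lam, fit_intercept=False, max_iter=100_000, tol=1e-10)
    model.fit(X, y)
    return model.coef_.copy()


def _lambda_grid(lam_max: float, grid_size: int) -> np.ndarray:
    return np.logspace(math.log10(lam_max), math.log10(0.01 * lam_max),
                       grid_size)


def _path_supports(X: np.ndarray, y: np.ndarray, grid: np.ndarray,
                   precompute=None, Xy=None) -> np.ndarray:
    """Boolean support (n_lambda x p) of the lasso path at each grid penalty."""
    alphas, coefs, _ = lasso_path(X, y, alphas=grid,
                                  precompute=precompute if precompute is not None else "auto",
                                  Xy=Xy)
    # lasso_path returns alphas in decreasing order; align to our grid
    order = np.argsort(-alphas)
    grid_order = np.argsort(-grid)
    supports = np.empty((len(grid), coefs.shape[0]), bool)
    supports[grid_order] = (coefs[:, order] != 0).T
    return supports


def stars_select_lambda(y: np.ndarray, X: np.ndarray, grid_size: int = 20,
                        n_subsamples: int = 20,
                        subsample_fraction: float = 0.63,
                        threshold: float = 0.05, seed: int = 0,
                        subsample_indices: list[np.ndarray] | None = None
                        ) -> tuple[float, StabilityPath | None]:
    """Pick the least regularization whose support is stable across subsamples.

    The grid has ``grid_size`` log-spaced penalties from lambda_max down to
    0.01 * lambda_max.  The monotonized instability is the running max of
    D(lambda) from the largest penalty downward; the winner is the smallest
    grid penalty with monotonized instability <= ``threshold`` (lambda_max if
    none qualifies).  A zero-variance response yields an empty model.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    if n < 10:
        raise ValueError("StARS needs at least 10 samples")
    lam_max = lambda_max(y, X)
    if lam_max <= 0 or float(np.std(y)) == 0.0:
        logger.info("stars: degenerate response, returning empty model")
        return math.inf, None
    grid = _lambda_grid(lam_max, grid_size)
    if subsample_indices is None:
        rng = np.random.default_rng(seed)
        m = math.ceil(subsample_fraction * n)
        subsample_indices = [rng.choice(n, size=m, replace=False)
                             for _ in range(n_subsamples)]
    counts = np.zeros((len(grid), p))
    for idx in subsample_indices:
        counts += _path_supports(X[idx], y[idx], grid)
    theta = counts / len(subsample_indices)
    instability = (2 * theta * (1 - theta)).mean(axis=1)
    monotone = np.maximum.accumulate(instability)
    stable = np.flatnonzero(monotone <= threshold)
    lam_star = float(grid[stable[-1]]) if len(stable) else float(grid[0])
    return lam_star, StabilityPath(grid, theta, instability, monotone)


def run_stars_lasso(expr: GeneExpressionMatrix, activities: ActivityMatrix,
                    prior: AdjacencyNetwork | None = None,
                    n_bootstraps: int = 5, seed: int = 42,
                    threshold: float = 0.05, n_subsamples: int = 20,
                    subsample_fraction: float = 0.63, grid_size: int = 20,
                    origin_prefix: str = "task0") -> list[ScoredEdgeSet]:
    """Run StARS-LASSO over bootstraps; one scored edge set per bootstrap.

    The prior does not mask candidates here — it enters only through the TF
    activities — so every TF is a potential predictor for every gene (except
    a TF for its own gene).  Subsample index sets are drawn once per
    bootstrap and shared by all genes, which keeps runs deterministic and
    independent of worker count.
    """
    tf_ids = activities.tf_ids
    results = []
    n = expr.n_samples
    m = math.ceil(subsample_fraction * n)
    for b in range(n_bootstraps):
        idx = bootstrap_indices(expr.sample_ids, seed + b)
        X_b = expr.values[:, idx]
        A_b = activities.values[:, idx]
        Z, valid = standardize_columns(A_b.T)
        sub_rng = np.random.default_rng([seed + b, 7919])
        subsamples = [sub_rng.choice(n, size=m, replace=False)
                      for _ in range(n_subsamples)]
        grams = [Z[s].T @ Z[s] for s in subsamples]

        edges: list[tuple[str, str, float, int]] = []
        for gi, gene in enumerate(expr.gene_ids):
            cols = [j for j in range(len(tf_ids))
                    if valid[j] and tf_ids[j] != gene]
            if not cols:
                continue
            y = X_b[gi] - X_b[gi].mean()
            if float(np.std(y)) == 0.0:
                continue
            full_cols = len(cols) == len(tf_ids)
            Zg = Z if full_cols else Z[:, cols]
            lam_max_g = lambda_max(y, Zg)
            if lam_max_g <= 0:
                continue
            grid = _lambda_grid(lam_max_g, grid_size)
            counts = np.zeros((grid_size, len(cols)))
            for s, gram in zip(subsamples, grams):
                pre = gram if full_cols else None
                counts += _path_supports(Zg[s], y[s], grid, precompute=pre)
            theta = counts / n_subsamples
            monotone = np.maximum.accumulate(
                (2 * theta * (1 - theta)).mean(axis=1))
            stable = np.flatnonzero(monotone <= threshold)
            lam_star = float(grid[stable[-1]]) if len(stable) else float(grid[0])
            coef = solve_l1_least_squares(y, Zg, lam_star)
            support = np.flatnonzero(coef != 0)
            if len(support) == 0:
                continue
            refit_coef, scores = ols_refit_scores(y, Zg[:, support])
            for pos, j in enumerate(support):
                edges.append((tf_ids[cols[j]], gene, float(scores[pos]),
                              int(np.sign(refit_coef[pos]))))
        results.append(ScoredEdgeSet(
            pd.DataFrame(edges, columns=["tf", "target", "score", "sign"]),
            tfs=list(tf_ids), genes=list(expr.gene_ids),
            origin=f"{origin_prefix}:bootstrap{b}"))
    return results
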