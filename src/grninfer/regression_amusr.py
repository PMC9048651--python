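"""Adaptive multi-task sparse regression (AMuSR, "dirty" multi-task model).

For each gene, the regression coefficients across K tasks are decomposed as
W = B + S: a block-sparse component B whose rows (predictors) are shared by
all tasks, penalized by lambda_B * sum_j max_k |B_jk| (an l1/linf norm), and
a task-specific sparse component S penalized entrywise by
lambda_S * sum_jk w_jk |S_jk|, where w_jk < 1 for prior-supported edges makes
the penalty adaptive.  The objective

    sum_k (1/2 n_k) ||y_k - X_k (b_k + s_k)||^2
        + lambda_B sum_j max_k |B_jk| + lambda_S sum_jk w_jk |S_jk|

is minimized by alternating exact block-coordinate updates: entrywise
soft-thresholding for S and a sorted water-filling prox for each row of B.
Penalties are selected on a one-dimensional grid (lambda_S coupled to
lambda_B / sqrt(K)) by extended BIC.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import (ActivityMatrix, AdjacencyNetwork, GeneExpressionMatrix,
                       ScoredEdgeSet)
from .regression_bbsr import (bootstrap_indices, ols_refit_scores,
                              prior_on_namespace, standardize_columns)

logger = logging.getLogger("grninfer")

EPS_RSS = 1e-10


@dataclass
class TaskData:
    """Per-task regression data for one gene: centered y, standardized X."""

    y: np.ndarray
    X: np.ndarray

    @property
    def n(self) -> int:
        return len(self.y)


@dataclass
class MultiTaskGeneFit:
    """Fitted dirty model for one gene across tasks."""

    gene_id: str
    B: np.ndarray            # predictors x tasks, row-structured support
    S: np.ndarray            # predictors x tasks, entrywise sparse
    lambda_b: float
    lambda_s: float
    ebic: float
    converged: bool

    @property
    def W(self) -> np.ndarray:
        return self.B + self.S


def amusr_objective(B: np.ndarray, S: np.ndarray, tasks: list[TaskData],
                    lambda_b: float, lambda_s: float,
                    edge_weights: np.ndarray) -> float:
    """Evaluate the dirty-model objective directly from residuals."""
    W = B + S
    value = 0.0
    for k, t in enumerate(tasks):
        r = t.y - t.X @ W[:, k]
        value += float(r @ r) / (2 * t.n)
    value += lambda_b * float(np.abs(B).max(axis=1).sum())
    value += lambda_s * float((edge_weights * np.abs(S)).sum())
    return value


def _linf_row_prox(a: np.ndarray, curv: np.ndarray, lam: float) -> np.ndarray:
    """Minimize sum_k curv_k/2 (b_k - a_k)^2 + lam * max_k |b_k|.

    The solution clamps each coordinate at a common cap m:
    b_k = sign(a_k) * min(|a_k|, m), with m found by scanning the sorted
    magnitudes (water-filling).
    """
    mag = np.abs(a)
    if float(curv @ mag) <= lam:
        return np.zeros_like(a)
    order = np.argsort(-mag)
    cw = 0.0
    cwa = 0.0
    m = 0.0
    K = len(a)
    for t in range(K):
        j = order[t]
        cw += curv[j]
        cwa += curv[j] * mag[j]
        m = (cwa - lam) / cw
        nxt = mag[order[t + 1]] if t + 1 < K else 0.0
        if m >= nxt - 1e-15:
            break
    m = max(m, 0.0)
    return np.sign(a) * np.minimum(mag, m)


def fit_dirty_model(tasks: list[TaskData], lambda_b: float, lambda_s: float,
                    edge_weights: np.ndarray, tol: float = 1e-4,
                    max_iter: int = 200,
                    B0: np.ndarray | None = None, S0: np.ndarray | None = None
                    ) -> tuple[np.ndarray, np.ndarray, bool]:
    """Alternating exact block minimization of the dirty-model objective.

    Works in covariance space (Gram matrices), so iteration cost is
    independent of sample counts.  Each S entry and each B row is minimized
    exactly, so the objective is monotonically nonincreasing; iteration
    stops when the relative decrease falls below ``tol``.
    Returns (B, S, converged).
    """
    K = len(tasks)
    p = tasks[0].X.shape[1]
    Gs = np.stack([t.X.T @ t.X / t.n for t in tasks])         # K x p x p
    cs = np.stack([t.X.T @ t.y / t.n for t in tasks])         # K x p
    yty = np.array([float(t.y @ t.y) / t.n for t in tasks])   # K
    diag = np.stack([np.diag(Gs[k]) for k in range(K)]).T     # p x K
    safe_diag = np.where(diag > 0, diag, 1.0)

    B = np.zeros((p, K)) if B0 is None else B0.copy()
    S = np.zeros((p, K)) if S0 is None else S0.copy()

    def gram_objective(B, S):
        W = B + S
        fit = 0.0
        for k in range(K):
            w = W[:, k]
            fit += 0.5 * yty[k] - float(w @ cs[k]) + 0.5 * float(w @ Gs[k] @ w)
        return (fit + lambda_b * float(np.abs(B).max(axis=1).sum())
                + lambda_s * float((edge_weights * np.abs(S)).sum()))

    prev = gram_objective(B, S)
    converged = False
    # residual correlations r_k = c_k - G_k w_k, maintained incrementally
    W = B + S
    R = cs - np.einsum("kij,jk->ki", Gs, W)  # K x p
    for _ in range(max_iter):
        # S-step: entrywise soft threshold
        for j in range(p):
            rj = R[:, j] + diag[j] * S[j]          # partial residual corr
            thr = lambda_s * edge_weights[j]
            new = np.sign(rj) * np.maximum(np.abs(rj) - thr, 0.0) / safe_diag[j]
            new = np.where(diag[j] > 0, new, 0.0)
            delta = new - S[j]
            if np.any(delta != 0):
                S[j] = new
                R -= np.einsum("k,kp->kp", delta, Gs[:, j, :])
        # B-step: rowwise l_inf prox
        for j in range(p):
            rj = R[:, j] + diag[j] * B[j]
            a = np.where(diag[j] > 0, rj / safe_diag[j], 0.0)
            new = _linf_row_prox(a, diag[j], lambda_b)
            delta = new - B[j]
            if np.any(delta != 0):
                B[j] = new
                R -= np.einsum("k,kp->kp", delta, Gs[:, j, :])
        cur = gram_objective(B, S)
        if prev - cur <= tol * max(abs(prev), 1e-12):
            converged = True
            prev = cur
            break
        prev = cur
    if not converged:
        logger.debug("amusr: fit did not converge in %d iterations", max_iter)
    return B, S, converged


def make_prior_edge_weights(prior_cols: np.ndarray, rho: float) -> np.ndarray:
    """Adaptive penalty weights: rho for prior-supported (TF, task) pairs, else 1.

    ``prior_cols`` is predictors x tasks, nonzero where the task's prior
    contains the edge.  rho = 1 disables the adaptation.
    """
    if not 0 < rho <= 1:
        raise ValueError("prior_penalty_weight must be in (0, 1]")
    return np.where(prior_cols != 0, rho, 1.0)


def _lambda_b_max(tasks: list[TaskData], edge_weights: np.ndarray) -> float:
    """Smallest lambda_B that zeroes both B and S under the sqrt(K) coupling."""
    K = len(tasks)
    cs = np.stack([t.X.T @ t.y / t.n for t in tasks])  # K x p
    b_bound = float(np.abs(cs).sum(axis=0).max())      # rows of B zero
    s_bound = math.sqrt(K) * float((np.abs(cs).T / edge_weights).max())
    return max(b_bound, s_bound, 1e-12)


def select_lambda_ebic(tasks: list[TaskData], grid_size: int = 20,
                       gamma: float = 1.0,
                       edge_weights: np.ndarray | None = None,
                       tol: float = 1e-4, max_iter: int = 200,
                       gene_id: str = "") -> MultiTaskGeneFit:
    """Fit the dirty model along a one-dimensional penalty grid, pick by EBIC.

    lambda_B runs over ``grid_size`` log-spaced values from lambda_B^max down
    to 0.01 * lambda_B^max with lambda_S = lambda_B / sqrt(K); fits are
    warm-started along the grid.  EBIC_k = n_k ln(RSS_k / n_k)
    + df_k ln(n_k) + 2 gamma df_k ln(p), summed over tasks; ties prefer the
    larger penalty.
    """
    K = len(tasks)
    p = tasks[0].X.shape[1]
    if edge_weights is None:
        edge_weights = np.ones((p, K))
    lam_max = _lambda_b_max(tasks, edge_weights)
    grid = np.logspace(math.log10(lam_max), math.log10(0.01 * lam_max),
                       grid_size)
    log_p = math.log(p)
    best: MultiTaskGeneFit | None = None
    B = S = None
    for lam_b in grid:
        lam_s = lam_b / math.sqrt(K)
        B, S, converged = fit_dirty_model(tasks, lam_b, lam_s, edge_weights,
                                          tol=tol, max_iter=max_iter,
                                          B0=B, S0=S)
        W = B + S
        ebic = 0.0
        for k, t in enumerate(tasks):
            r = t.y - t.X @ W[:, k]
            rss = max(float(r @ r), EPS_RSS)
            df = int(np.count_nonzero(W[:, k]))
            ebic += (t.n * math.log(rss / t.n) + df * math.log(t.n)
                     + 2 * gamma * df * log_p)
        if best is None or ebic < best.ebic:
            best = MultiTaskGeneFit(gene_id, B.copy(), S.copy(),
                                    float(lam_b), float(lam_s), float(ebic),
                                    converged)
    assert best is not None
    return best


def run_amusr(task_exprs: list[GeneExpressionMatrix],
              task_activities: list[ActivityMatrix],
              task_priors: list[AdjacencyNetwork] | None = None,
              n_bootstraps: int = 1, seed: int = 42, gamma: float = 1.0,
              prior_penalty_weight: float = 1.0, grid_size: int = 20,
              task_names: list[str] | None = None) -> list[ScoredEdgeSet]:
    """Multi-task inference; returns one scored edge set per (bootstrap, task).

    All tasks must share the activity TF namespace.  A gene is fit jointly
    over the tasks in which it is measured; tasks missing the gene are
    omitted from that gene's fit.  Per-task edges are the nonzeros of the
    task's coefficient vector, scored by per-task OLS-refit explained
    variance (as in the single-task engines).
    """
    K = len(task_exprs)
    tf_ids = task_activities[0].tf_ids
    for act in task_activities[1:]:
        if act.tf_ids != tf_ids:
            raise ValueError("all tasks must share the TF namespace")
    task_names = task_names or [f"task{k}" for k in range(K)]
    all_genes = sorted(set().union(*[set(e.gene_ids) for e in task_exprs]))
    prior_mats = None
    if task_priors is not None:
        prior_mats = [prior_on_namespace(pr, tf_ids, all_genes)
                      for pr in task_priors]

    results: list[ScoredEdgeSet] = []
    for b in range(n_bootstraps):
        boot_idx = [bootstrap_indices(e.sample_ids, seed + b)
                    for e in task_exprs]
        Zs, valids, Xbs, gene_maps = [], [], [], []
        for k, e in enumerate(task_exprs):
            A_b = task_activities[k].values[:, boot_idx[k]]
            Z, valid = standardize_columns(A_b.T)
            Zs.append(Z)
            valids.append(valid)
            Xbs.append(e.values[:, boot_idx[k]])
            gene_maps.append({g: i for i, g in enumerate(e.gene_ids)})
        per_task_edges: list[list[tuple[str, str, float, int]]] = [
            [] for _ in range(K)]
        for gene in all_genes:
            ks = [k for k in range(K) if gene in gene_maps[k]]
            if not ks:
                continue
            cols = [j for j in range(len(tf_ids))
                    if tf_ids[j] != gene and all(valids[k][j] for k in ks)]
            if not cols:
                continue
            tasks = []
            skip = False
            for k in ks:
                y = Xbs[k][gene_maps[k][gene]]
                y = y - y.mean()
                if float(np.std(y)) == 0.0:
                    skip = True
                    break
                tasks.append(TaskData(y, Zs[k][:, cols]))
            if skip or not tasks:
                continue
            if prior_mats is not None and prior_penalty_weight < 1:
                gidx = all_genes.index(gene)
                pcols = np.stack([prior_mats[k][cols, gidx] for k in ks]).T
                weights = make_prior_edge_weights(pcols, prior_penalty_weight)
            else:
                weights = np.ones((len(cols), len(ks)))
            try:
                fit = select_lambda_ebic(tasks, grid_size=grid_size,
                                         gamma=gamma, edge_weights=weights,
                                         gene_id=gene)
            except Exception as exc:
                logger.warning("amusr: gene %s failed: %s", gene, exc)
                continue
            W = fit.W
            for pos_k, k in enumerate(ks):
                support = np.flatnonzero(W[:, pos_k] != 0)
                if len(support) == 0:
                    continue
                coef, scores = ols_refit_scores(tasks[pos_k].y,
                                                tasks[pos_k].X[:, support])
                for pos, j in enumerate(support):
                    per_task_edges[k].append(
                        (tf_ids[cols[j]], gene, float(scores[pos]),
                         int(np.sign(coef[pos]))))
        for k in range(K):
            results.append(ScoredEdgeSet(
                pd.DataFrame(per_task_edges[k],
                             columns=["tf", "target", "score", "sign"]),
                tfs=list(tf_ids), genes=list(all_genes),
                origin=f"{task_names[k]}:bootstrap{b}"))
    return results
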