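"""Bayesian best-subset regression (BBSR) model selection.

Each gene's (transformed) expression is regressed on a small candidate set of
TF activities.  Candidates are preselected by prior membership and by context
likelihood of relatedness (CLR, a background-corrected mutual-information
z-score); all 2^|candidates| subsets are then enumerated exhaustively and
scored by BIC, optionally with per-predictor penalty weights that favor
prior-supported TFs.  Edges are scored by the explained variance each
selected predictor contributes to the winning model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations

import numpy as np
import pandas as pd

from .io_model import (ActivityMatrix, AdjacencyNetwork, GeneExpressionMatrix,
                       ScoredEdgeSet)

logger = logging.getLogger("grninfer")

EPS_RSS = 1e-10


@dataclass
class GeneModel:
    """Winning regression model for a single gene."""

    gene_id: str
    tf_ids: list[str]
    coefficients: np.ndarray
    scores: np.ndarray  # per-TF explained variance d_j in [0, 1]
    bic: float
    n_obs: int


# ---------------------------------------------------------------------------
# Mutual information / CLR
# ---------------------------------------------------------------------------

def _bin_indices(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width bin index per entry, per row, over each row's observed range."""
    lo = values.min(axis=1, keepdims=True)
    hi = values.max(axis=1, keepdims=True)
    span = np.where(hi > lo, hi - lo, 1.0)
    idx = ((values - lo) / span * n_bins).astype(np.int64)
    return np.clip(idx, 0, n_bins - 1)


def compute_mi_clr(targets: np.ndarray, regressors: np.ndarray,
                   n_bins: int = 10) -> np.ndarray:
    """CLR matrix (regressors x targets) from equal-width-binned mutual information.

    MI uses natural logs; a constant variable has zero MI with everything.
    CLR_ij = sqrt(max(0, z_row)^2 + max(0, z_col)^2) where the z-scores
    standardize MI_ij against row i's and column j's MI distributions.
    """
    targets = np.asarray(targets, float)
    regressors = np.asarray(regressors, float)
    n = targets.shape[1]
    if n < 2 or n_bins < 2:
        raise ValueError("need >= 2 samples and >= 2 bins")
    tb = _bin_indices(targets, n_bins)
    rb = _bin_indices(regressors, n_bins)
    T, G = regressors.shape[0], targets.shape[0]
    mi = np.empty((T, G))
    for i in range(T):
        code_base = rb[i] * n_bins
        for j in range(G):
            joint = np.bincount(code_base + tb[j], minlength=n_bins * n_bins)
            p = joint.reshape(n_bins, n_bins) / n
            pi = p.sum(axis=1, keepdims=True)
            pj = p.sum(axis=0, keepdims=True)
            with np.errstate(divide="ignore", invalid="ignore"):
                term = p * np.log(p / (pi * pj))
            mi[i, j] = max(0.0, float(np.nansum(term)))

    def _z(m: np.ndarray, axis: int) -> np.ndarray:
        mean = m.mean(axis=axis, keepdims=True)
        std = m.std(axis=axis, keepdims=True)
        return np.where(std > 0, (m - mean) / np.where(std > 0, std, 1.0), 0.0)

    zr = np.maximum(_z(mi, axis=1), 0.0)
    zc = np.maximum(_z(mi, axis=0), 0.0)
    return np.sqrt(zr ** 2 + zc ** 2)


def select_candidates(gene_id: str, prior_col: np.ndarray, clr_col: np.ndarray,
                      tf_ids: list[str], nK: int = 10,
                      eligible: np.ndarray | None = None) -> list[int]:
    """Candidate TF indices for one gene: prior TFs first, ranked by CLR.

    Prior-supported TFs are ordered by CLR descending (lexicographic tie on
    TF id) and truncated to ``nK``; if fewer, the highest-CLR non-prior TFs
    fill the remaining slots.  The gene's own TF is never a candidate.
    """
    if eligible is None:
        eligible = np.ones(len(tf_ids), bool)
    order_key = sorted(range(len(tf_ids)),
                       key=lambda i: (-clr_col[i], tf_ids[i]))
    in_prior = [i for i in order_key
                if prior_col[i] != 0 and eligible[i] and tf_ids[i] != gene_id]
    out_prior = [i for i in order_key
                 if prior_col[i] == 0 and eligible[i] and tf_ids[i] != gene_id]
    chosen = in_prior[:nK]
    if len(chosen) < nK:
        chosen += out_prior[:nK - len(chosen)]
    return chosen


# ---------------------------------------------------------------------------
# Exhaustive subset enumeration
# ---------------------------------------------------------------------------

@lru_cache(maxsize=32)
def _subset_index_arrays(p: int) -> dict[int, np.ndarray]:
    """All index subsets of {0..p-1}, grouped by size, in lexicographic order."""
    return {k: np.array(list(combinations(range(p), k)), dtype=np.int64)
            for k in range(1, p + 1)}


def _solve_batch(Gs: np.ndarray, cs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Solve the stacked normal equations; singular subsets get NaN solutions."""
    try:
        b = np.linalg.solve(Gs, cs[..., None])[..., 0]
        ok = np.all(np.isfinite(b), axis=1)
    except np.linalg.LinAlgError:
        m, k = cs.shape
        b = np.full((m, k), np.nan)
        ok = np.zeros(m, bool)
        for i in range(m):
            try:
                b[i] = np.linalg.solve(Gs[i], cs[i])
                ok[i] = np.all(np.isfinite(b[i]))
            except np.linalg.LinAlgError:
                pass
    return b, ok


def best_subset_regression(y: np.ndarray, X: np.ndarray,
                           penalty_weights: np.ndarray | None = None,
                           gene_id: str = "", tf_ids: list[str] | None = None
                           ) -> GeneModel:
    """Exhaustive best-subset OLS with BIC selection.

    ``y`` must be centered and the columns of ``X`` standardized.  Subset m
    scores BIC_m = n ln(max(RSS_m, eps) / n) + ln(n) * sum of the selected
    predictors' penalty weights (weight 1 = ordinary BIC; weights < 1 favor
    inclusion).  Ties prefer fewer predictors, then the lexicographically
    first subset.  Singular subsets are skipped.  Per-predictor scores are
    d_j = max(0, 1 - RSS_full / RSS_without_j).
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    if penalty_weights is None:
        penalty_weights = np.ones(p)
    tf_ids = tf_ids if tf_ids is not None else [f"x{j}" for j in range(p)]

    yty = float(y @ y)
    G = X.T @ X
    c = X.T @ y
    log_n = np.log(n)

    best_bic = n * np.log(max(yty, EPS_RSS) / n)  # empty model
    best_subset: tuple[int, ...] = ()
    best_coef = np.empty(0)
    best_rss = yty

    subsets = _subset_index_arrays(p)
    for k in range(1, p + 1):
        S = subsets[k]
        Gs = G[S[:, :, None], S[:, None, :]]
        cs = c[S]
        b, ok = _solve_batch(Gs, cs)
        if not ok.any():
            continue
        rss = yty - np.einsum("ij,ij->i", b, cs)
        rss = np.maximum(rss, EPS_RSS)
        bic = n * np.log(rss / n) + log_n * penalty_weights[S].sum(axis=1)
        bic = np.where(ok, bic, np.inf)
        i = int(np.argmin(bic))  # argmin returns the lexicographically first
        if bic[i] < best_bic:
            best_bic = float(bic[i])
            best_subset = tuple(int(v) for v in S[i])
            best_coef = b[i].copy()
            best_rss = float(rss[i])

    if not best_subset:
        return GeneModel(gene_id, [], np.empty(0), np.empty(0),
                         float(best_bic), n)

    scores = np.empty(len(best_subset))
    for pos, j in enumerate(best_subset):
        rest = [v for v in best_subset if v != j]
        if rest:
            idx = np.array(rest)
            try:
                b_rest = np.linalg.solve(G[np.ix_(idx, idx)], c[idx])
                rss_minus = max(yty - float(b_rest @ c[idx]), EPS_RSS)
            except np.linalg.LinAlgError:
                rss_minus = EPS_RSS
        else:
            rss_minus = max(yty, EPS_RSS)
        scores[pos] = max(0.0, 1.0 - best_rss / rss_minus)

    return GeneModel(gene_id, [tf_ids[j] for j in best_subset], best_coef,
                     scores, float(best_bic), n)


def ols_refit_scores(y: np.ndarray, X: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """OLS fit of a selected support plus per-predictor explained variance.

    Returns (coefficients, d) with d_j = max(0, 1 - RSS_full / RSS_without_j),
    the same edge score the best-subset engine assigns.
    """
    yty = float(y @ y)
    G = X.T @ X
    c = X.T @ y
    try:
        coef = np.linalg.solve(G, c)
    except np.linalg.LinAlgError:
        coef = np.linalg.lstsq(X, y, rcond=None)[0]
    rss_full = max(yty - float(coef @ c), EPS_RSS)
    k = X.shape[1]
    scores = np.empty(k)
    for j in range(k):
        rest = [v for v in range(k) if v != j]
        if rest:
            idx = np.array(rest)
            try:
                b_rest = np.linalg.solve(G[np.ix_(idx, idx)], c[idx])
                rss_minus = max(yty - float(b_rest @ c[idx]), EPS_RSS)
            except np.linalg.LinAlgError:
                rss_minus = EPS_RSS
        else:
            rss_minus = max(yty, EPS_RSS)
        scores[j] = max(0.0, 1.0 - rss_full / rss_minus)
    return coef, scores


# ---------------------------------------------------------------------------
# Engine entry point
# ---------------------------------------------------------------------------

def prior_on_namespace(prior: AdjacencyNetwork, tf_ids: list[str],
                       gene_ids: list[str]) -> np.ndarray:
    """Re-index a prior's values onto (tf_ids x gene_ids); absent pairs are 0."""
    out = np.zeros((len(tf_ids), len(gene_ids)))
    tf_pos = {t: i for i, t in enumerate(tf_ids)}
    gene_pos = {g: j for j, g in enumerate(gene_ids)}
    tfi, gj = np.nonzero(prior.values)
    for i, j in zip(tfi, gj):
        tf, g = prior.tf_ids[i], prior.gene_ids[j]
        if tf in tf_pos and g in gene_pos:
            out[tf_pos[tf], gene_pos[g]] = prior.values[i, j]
    return out


def _canonical_order(sample_ids: list[str]) -> np.ndarray:
    return np.array(sorted(range(len(sample_ids)), key=lambda i: sample_ids[i]))


def bootstrap_indices(sample_ids: list[str], seed: int) -> np.ndarray:
    """Sample-with-replacement indices, drawn after a canonical sample-id sort.

    Indexing positions in the sorted order makes bootstrap draws invariant to
    the on-disk sample ordering.
    """
    order = _canonical_order(sample_ids)
    rng = np.random.default_rng(seed)
    return order[rng.integers(0, len(order), len(order))]


def standardize_columns(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center/scale columns to unit variance; returns (Z, valid-column mask)."""
    mean = M.mean(axis=0)
    std = M.std(axis=0)
    valid = std > 0
    Z = (M - mean) / np.where(valid, std, 1.0)
    Z[:, ~valid] = 0.0
    return Z, valid


def run_bbsr(expr: GeneExpressionMatrix, activities: ActivityMatrix,
             prior: AdjacencyNetwork, n_bootstraps: int = 5, seed: int = 42,
             nK: int = 10, prior_penalty_weight: float = 1.0,
             n_bins: int = 10, origin_prefix: str = "task0"
             ) -> list[ScoredEdgeSet]:
    """Run BBSR over bootstraps; one scored edge set per bootstrap.

    Bootstrap b uses seed ``seed + b``.  Genes are modeled independently;
    failures for single genes are logged and skipped rather than aborting
    the run.
    """
    tf_ids = activities.tf_ids
    prior_cols = prior_on_namespace(prior, tf_ids, expr.gene_ids)

    results = []
    for b in range(n_bootstraps):
        idx = bootstrap_indices(expr.sample_ids, seed + b)
        X_b = expr.values[:, idx]
        A_b = activities.values[:, idx]
        clr = compute_mi_clr(X_b, A_b, n_bins=n_bins)
        Z, valid = standardize_columns(A_b.T)
        G_all = Z.T @ Z
        edges = _fit_all_genes(X_b, Z, G_all, valid, clr, prior_cols, tf_ids,
                               expr.gene_ids, nK, prior_penalty_weight)
        results.append(ScoredEdgeSet(
            pd.DataFrame(edges, columns=["tf", "target", "score", "sign"]),
            tfs=list(tf_ids), genes=list(expr.gene_ids),
            origin=f"{origin_prefix}:bootstrap{b}"))
    return results


def _fit_all_genes(X_b, Z, G_all, valid, clr, prior_cols, tf_ids, gene_ids,
                   nK, prior_penalty_weight):
    edges: list[tuple[str, str, float, int]] = []
    n = Z.shape[0]
    log_n = np.log(n)
    for gi, gene in enumerate(gene_ids):
        cand = select_candidates(gene, prior_cols[:, gi], clr[:, gi], tf_ids,
                                 nK=nK, eligible=valid)
        if not cand:
            logger.debug("bbsr: no candidates for gene %s", gene)
            continue
        y = X_b[gi] - X_b[gi].mean()
        if not np.any(y != 0):
            continue
        weights = np.array([prior_penalty_weight if prior_cols[j, gi] != 0 else 1.0
                            for j in cand])
        try:
            model = best_subset_regression(
                y, Z[:, cand], penalty_weights=weights, gene_id=gene,
                tf_ids=[tf_ids[j] for j in cand])
        except Exception as exc:  # keep the run alive on per-gene failures
            logger.warning("bbsr: gene %s failed: %s", gene, exc)
            continue
        for tf, coef, score in zip(model.tf_ids, model.coefficients, model.scores):
            edges.append((tf, gene, float(score), int(np.sign(coef))))
    return edges
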