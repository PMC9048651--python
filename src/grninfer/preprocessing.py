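"""Count filtering, transforms, depth normalization, and negative controls.

The two negative controls calibrate what "no signal" looks like for a given
dataset: ``make_noise_control`` replaces expression with per-gene Gaussian
noise that preserves each cell's total count, and ``shuffle_prior`` destroys
the prior's gene labels while keeping its degree structure.
``add_random_prior_edges`` degrades a prior by adding false edges, for
robustness sweeps.
"""

from __future__ import annotations

import logging

import numpy as np

from .io_model import AdjacencyNetwork, GeneExpressionMatrix, ValidationError

logger = logging.getLogger("grninfer")


def filter_threshold(n_samples: int, per_cells: int) -> int:
    """Minimum total count for a gene to survive the 1-count-per-N-cells rule."""
    return max(1, n_samples // per_cells)


def filter_genes_by_total_count(expr: GeneExpressionMatrix, per_cells: int = 20
                                ) -> tuple[GeneExpressionMatrix, int]:
    """Remove genes with fewer than ``floor(n_samples / per_cells)`` total counts.

    Returns the filtered matrix and the threshold actually applied (clamped
    to at least 1, so with very few samples only all-zero genes are removed).
    """
    if not expr.is_counts:
        raise ValidationError("gene filtering operates on raw counts")
    if per_cells < 1:
        raise ValidationError("per_cells must be >= 1")
    threshold = filter_threshold(expr.n_samples, per_cells)
    totals = expr.values.sum(axis=1)
    keep = totals >= threshold
    if not keep.any():
        raise ValidationError(f"no gene reaches the count threshold {threshold}")
    logger.info("gene filter: threshold %d, kept %d / %d genes",
                threshold, int(keep.sum()), expr.n_genes)
    out = GeneExpressionMatrix(
        expr.values[keep],
        [g for g, k in zip(expr.gene_ids, keep) if k],
        expr.sample_ids, expr.task_labels, expr.is_counts)
    return out, threshold


def transform_counts(expr: GeneExpressionMatrix, method: str = "ftt"
                     ) -> GeneExpressionMatrix:
    """Apply a variance-stabilizing transform elementwise.

    ``ftt`` is the Freeman-Tukey transform sqrt(x+1) + sqrt(x) - 1 and
    ``log2`` is log2(x+1); both map 0 to 0 and are monotone.  ``raw`` is the
    identity.
    """
    x = expr.values
    if method == "raw":
        return expr
    if np.any(x < 0):
        raise ValidationError("transforms require nonnegative values")
    if method == "ftt":
        y = np.sqrt(x + 1.0) + np.sqrt(x) - 1.0
    elif method == "log2":
        y = np.log2(x + 1.0)
    else:
        raise ValidationError(f"unknown transform {method!r}")
    return expr.with_values(y, is_counts=False)


def depth_normalize(expr: GeneExpressionMatrix) -> GeneExpressionMatrix:
    """Scale each cell so its total count equals the median cell total.

    The median is computed over all cells, including empty ones; all-zero
    cells are left unchanged with a warning (there is nothing to scale).
    """
    if np.any(expr.values < 0):
        raise ValidationError("depth normalization requires nonnegative values")
    totals = expr.values.sum(axis=0)
    median = float(np.median(totals))
    zero = totals == 0
    if zero.any():
        logger.warning("depth normalize: %d all-zero cell(s) left unchanged",
                       int(zero.sum()))
    factors = np.where(zero, 1.0, median / np.where(zero, 1.0, totals))
    return expr.with_values(expr.values * factors[None, :], is_counts=False)


def noise_draws(expr: GeneExpressionMatrix, seed: int, clip: bool = True
                ) -> np.ndarray:
    """Per-gene Gaussian draws N(mu_i, sigma_i), before the column rescale.

    Exposed separately so the sampling distribution can be checked directly;
    ``make_noise_control`` applies the per-cell total-count constraint on top.
    """
    rng = np.random.default_rng(seed)
    mu = expr.values.mean(axis=1)
    sigma = expr.values.std(axis=1)
    draws = rng.normal(mu[:, None], sigma[:, None],
                       size=(expr.n_genes, expr.n_samples))
    if clip:
        draws = np.clip(draws, 0.0, None)
    return draws


def make_noise_control(expr: GeneExpressionMatrix, seed: int
                       ) -> GeneExpressionMatrix:
    """Replace expression by gene-wise Gaussian noise with cell totals preserved.

    Entries are drawn independently as N(mu_i, sigma_i) from each gene's
    observed mean and standard deviation, negatives are clipped to zero, and
    each cell is rescaled multiplicatively so its total matches the observed
    cell total (all-zero cells stay zero).
    """
    if np.any(expr.values < 0):
        raise ValidationError("the noise control requires nonnegative values")
    draws = noise_draws(expr, seed, clip=True)
    orig_totals = expr.values.sum(axis=0)
    draw_totals = draws.sum(axis=0)
    safe = np.where(draw_totals > 0, draw_totals, 1.0)
    scaled = draws * (orig_totals / safe)[None, :]
    scaled[:, orig_totals == 0] = 0.0
    return expr.with_values(scaled, is_counts=False)


def shuffle_prior(prior: AdjacencyNetwork, seed: int) -> AdjacencyNetwork:
    """Randomly permute the gene labels of a prior network.

    Equivalent to permuting the gene axis: each gene slot keeps its incoming
    edge pattern but acquires a uniformly random gene's label, so TF
    out-degrees and the multiset of gene in-degrees are preserved exactly.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(prior.gene_ids))
    return AdjacencyNetwork(prior.values[:, perm], prior.tf_ids,
                            list(prior.gene_ids), role=prior.role)


def add_random_prior_edges(prior: AdjacencyNetwork, fraction: float, seed: int
                           ) -> AdjacencyNetwork:
    """Add ``round(fraction * n_edges)`` random false edges (value +1) to a prior."""
    if fraction < 0:
        raise ValidationError("fraction must be >= 0")
    n_new = int(round(fraction * prior.n_edges))
    if n_new == 0:
        return AdjacencyNetwork(prior.values.copy(), list(prior.tf_ids),
                                list(prior.gene_ids), role=prior.role)
    flat = prior.values.ravel()
    empty = np.flatnonzero(flat == 0)
    if len(empty) < n_new:
        raise ValidationError(
            f"cannot place {n_new} new edges in {len(empty)} empty cells")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(empty, size=n_new, replace=False)
    values = prior.values.copy()
    values.ravel()[chosen] = 1.0
    return AdjacencyNetwork(values, list(prior.tf_ids), list(prior.gene_ids),
                            role=prior.role)
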