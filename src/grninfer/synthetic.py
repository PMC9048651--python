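"""Synthetic ground-truth networks and expression data for testing inference.

The generator follows the engines' modeling assumptions: a sparse signed
TF -> gene coefficient matrix W, i.i.d. standard-normal TF activities A, and
expression X = W^T A + noise (continuous mode) or Poisson counts with
log-linear rates (count mode, emulating sparse scRNA-seq).  TFs are a subset
of the genes and their expression rows track their own activity, so the
expression-fallback path of TF activity estimation is exercised.  Utilities
derive degraded priors (edges dropped/added) and multi-task families with a
controlled shared edge core.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_model import AdjacencyNetwork, ActivityMatrix, GeneExpressionMatrix, ValidationError

MEAN_DEPTH = 2000  # target mean counts per cell in count mode
COUNT_SCALE = 0.5  # log-rate scale c in rates ~ exp(c * Wt A)


@dataclass
class SyntheticTruth:
    """Ground-truth regulatory structure for a simulated system."""

    W: np.ndarray          # TFs x genes signed coefficients
    tf_ids: list[str]
    gene_ids: list[str]
    sparsity: float
    seed: int

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(self.W))

    def prior(self, role: str = "prior", signed: bool = True) -> AdjacencyNetwork:
        """True support as a network; signed keeps the real coefficients."""
        values = self.W.copy() if signed else (self.W != 0).astype(float)
        return AdjacencyNetwork(values, list(self.tf_ids), list(self.gene_ids),
                                role=role)


def generate_truth(n_genes: int, n_tfs: int, sparsity: float, seed: int
                   ) -> SyntheticTruth:
    """Random signed TF x gene network; each edge present with prob ``sparsity``.

    Nonzero coefficients are +-Uniform(0.5, 2).  TFs are the first
    ``n_tfs`` genes, so every TF has its own expression row.
    """
    if not 0 < sparsity < 1:
        raise ValidationError("sparsity must be in (0, 1)")
    if n_tfs > n_genes:
        raise ValidationError("TFs are a subset of genes")
    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i:04d}" for i in range(n_genes)]
    tf_ids = gene_ids[:n_tfs]
    mask = rng.random((n_tfs, n_genes)) < sparsity
    mag = rng.uniform(0.5, 2.0, size=(n_tfs, n_genes))
    sign = rng.choice([-1.0, 1.0], size=(n_tfs, n_genes))
    W = np.where(mask, sign * mag, 0.0)
    # TF genes carry no incoming edges: their expression rows report their
    # own activity, which keeps the linear model X = W^T A self-consistent
    W[:, :n_tfs] = 0.0
    return SyntheticTruth(W, tf_ids, gene_ids, sparsity, seed)


def simulate_dataset(truth: SyntheticTruth, n_samples: int, sigma: float,
                     mode: str = "continuous", seed: int = 0,
                     task_label: str = "task0"
                     ) -> tuple[GeneExpressionMatrix, ActivityMatrix]:
    """Simulate expression (and the true activities) from a ground truth.

    continuous: X = W^T A + N(0, sigma), with each TF's own expression row
    replaced by its activity plus noise.  counts: Poisson draws with rates
    exp(c * signal), columns scaled to a mean depth of 2000 counts/cell.
    """
    if n_samples < 2:
        raise ValidationError("need at least 2 samples")
    rng = np.random.default_rng(seed)
    n_tfs, n_genes = truth.W.shape
    A = rng.standard_normal((n_tfs, n_samples))
    signal = truth.W.T @ A  # genes x samples
    for i in range(n_tfs):  # TF expression tracks its own activity
        signal[i] = A[i]
    sample_ids = [f"{task_label}_S{j:05d}" for j in range(n_samples)]
    if mode == "continuous":
        X = signal + rng.normal(0.0, sigma, size=signal.shape)
        expr = GeneExpressionMatrix(X, list(truth.gene_ids), sample_ids,
                                    task_labels=[task_label] * n_samples,
                                    is_counts=False)
    elif mode == "counts":
        rates = np.exp(COUNT_SCALE * (signal + rng.normal(0.0, sigma,
                                                          size=signal.shape)))
        rates *= MEAN_DEPTH / rates.sum(axis=0, keepdims=True)
        X = rng.poisson(rates).astype(float)
        expr = GeneExpressionMatrix(X, list(truth.gene_ids), sample_ids,
                                    task_labels=[task_label] * n_samples,
                                    is_counts=True)
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    prov = {t: "estimated" for t in truth.tf_ids}
    return expr, ActivityMatrix(A, list(truth.tf_ids), sample_ids,
                                provenance=prov)


def make_multitask(truth: SyntheticTruth, n_tasks: int,
                   shared_fraction: float, n_samples: int, sigma: float,
                   seed: int, mode: str = "continuous"
                   ) -> tuple[list[SyntheticTruth],
                              list[GeneExpressionMatrix],
                              list[ActivityMatrix]]:
    """Derive per-task truths with a shared edge core, and simulate each task.

    ``round(shared_fraction * n_edges)`` edges of ``truth`` are common to all
    tasks; each task independently resamples the remaining edge mass at
    random empty cells (same count, fresh coefficients).
    """
    if not 0 <= shared_fraction <= 1:
        raise ValidationError("shared_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    edges = np.argwhere(truth.W != 0)
    n_core = int(round(shared_fraction * len(edges)))
    core_rows = rng.choice(len(edges), size=n_core, replace=False)
    core_mask = np.zeros_like(truth.W, dtype=bool)
    for r in core_rows:
        core_mask[edges[r][0], edges[r][1]] = True
    n_free = len(edges) - n_core

    truths, exprs, acts = [], [], []
    for k in range(n_tasks):
        W_k = np.where(core_mask, truth.W, 0.0)
        n_tfs = len(truth.tf_ids)
        candidates = np.argwhere(W_k == 0)
        candidates = candidates[candidates[:, 1] >= n_tfs]  # never into TF genes
        pick = rng.choice(len(candidates), size=n_free, replace=False)
        for r in pick:
            i, j = candidates[r]
            W_k[i, j] = rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 2.0)
        t_k = SyntheticTruth(W_k, list(truth.tf_ids), list(truth.gene_ids),
                             truth.sparsity, seed)
        label = f"task{k}"
        expr, act = simulate_dataset(t_k, n_samples, sigma, mode=mode,
                                     seed=seed + 1000 * (k + 1),
                                     task_label=label)
        truths.append(t_k)
        exprs.append(expr)
        acts.append(act)
    return truths, exprs, acts


def corrupt_prior(truth: SyntheticTruth, keep_fraction: float = 1.0,
                  add_fraction: float = 0.0, seed: int = 0,
                  signed: bool = True) -> AdjacencyNetwork:
    """Degraded prior: keep a fraction of true edges, add false ones.

    Keeps ``round(keep * n_edges)`` true edges uniformly at random, then adds
    ``round(add * n_kept)`` false edges (+1) at uniformly sampled empty
    cells.  By default kept edges carry the sign of the true coefficient, as
    curated priors in this field record activation vs repression; signs
    matter because activity estimation pseudoinverts the prior, and
    opposite-sign targets cancel if the sign is discarded.  ``signed=False``
    gives a membership-only prior.
    """
    if not 0 <= keep_fraction <= 1 or add_fraction < 0:
        raise ValidationError("invalid corruption fractions")
    rng = np.random.default_rng(seed)
    edges = np.argwhere(truth.W != 0)
    n_keep = int(round(keep_fraction * len(edges)))
    kept = rng.choice(len(edges), size=n_keep, replace=False)
    values = np.zeros_like(truth.W)
    for r in kept:
        i, j = edges[r]
        values[i, j] = np.sign(truth.W[i, j]) if signed else 1.0
    n_add = int(round(add_fraction * n_keep))
    if n_add:
        empty = np.argwhere((truth.W == 0) & (values == 0))
        if len(empty) < n_add:
            raise ValidationError("not enough empty cells for false edges")
        pick = rng.choice(len(empty), size=n_add, replace=False)
        for r in pick:
            values[empty[r][0], empty[r][1]] = 1.0
    return AdjacencyNetwork(values, list(truth.tf_ids), list(truth.gene_ids),
                            role="prior")
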