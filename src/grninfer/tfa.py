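"""Transcription-factor activity estimation.

A TF's activity is a latent per-sample quantity: the expression of its known
targets is modeled as a linear function of TF activities through the prior
network, X = P A, where P is the genes x TFs prior connectivity and X the
(transformed) expression.  Activities are recovered by the Moore-Penrose
pseudoinverse, A_hat = pinv(P) X.  TFs with no usable prior targets fall back
to their own expression profile when measured, and are dropped otherwise.
"""

from __future__ import annotations

import logging

import numpy as np

from .io_model import ActivityMatrix, AdjacencyNetwork, GeneExpressionMatrix, ValidationError

logger = logging.getLogger("grninfer")

# singular values below RCOND * sigma_max are treated as zero
RCOND = 1e-10


def estimate_tfa(expr: GeneExpressionMatrix, prior: AdjacencyNetwork
                 ) -> ActivityMatrix:
    """Estimate TF activities from expression and a prior network.

    The prior is restricted to genes present in the expression matrix and a
    TF's edge onto its own gene is removed before pseudoinversion (a TF
    trivially "explaining" itself would corrupt the estimate).  TFs whose
    prior column is empty after this are replaced by their own expression row
    (provenance ``expression_fallback``) or dropped if unmeasured.
    """
    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    shared = [g for g in prior.gene_ids if g in gene_pos]
    if not shared:
        raise ValidationError("prior and expression share no genes")

    # P: genes x TFs connectivity over shared genes, self-edges zeroed
    pg_idx = [prior.gene_ids.index(g) for g in shared]
    P = prior.values[:, pg_idx].T.astype(float).copy()
    shared_pos = {g: i for i, g in enumerate(shared)}
    for j, tf in enumerate(prior.tf_ids):
        if tf in shared_pos:
            P[shared_pos[tf], j] = 0.0

    X_shared = expr.values[[gene_pos[g] for g in shared], :]

    has_targets = np.any(P != 0, axis=0)
    tf_rows: list[np.ndarray] = []
    tf_ids: list[str] = []
    provenance: dict[str, str] = {}

    if has_targets.any():
        pinv = np.linalg.pinv(P[:, has_targets], rcond=RCOND)
        A_est = pinv @ X_shared
    else:
        A_est = np.empty((0, expr.n_samples))
    est_iter = iter(A_est)

    dropped: list[str] = []
    for j, tf in enumerate(prior.tf_ids):
        if has_targets[j]:
            tf_rows.append(next(est_iter))
            tf_ids.append(tf)
            provenance[tf] = "estimated"
        elif tf in gene_pos:
            tf_rows.append(expr.values[gene_pos[tf], :])
            tf_ids.append(tf)
            provenance[tf] = "expression_fallback"
        else:
            dropped.append(tf)
    if dropped:
        logger.warning("TFA: dropped %d TF(s) with no prior targets and no "
                       "measured expression: %s", len(dropped), dropped[:5])
    if not tf_ids:
        raise ValidationError("no TF has prior targets or measured expression")
    return ActivityMatrix(np.vstack(tf_rows), tf_ids, list(expr.sample_ids),
                          provenance=provenance)
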