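"""Holdout construction and gold-standard scoring of ranked networks.

Cross-validation holds a fraction of the prior's genes out: their prior
edges are zeroed before inference, and the learned network is scored only on
edges into the held-out genes, so performance reflects generalization rather
than recall of the prior itself.  Scoring is by area under the
precision-recall curve (AUPR) over the (gold TFs x gold genes) universe,
with MCC and F1 curves at every confidence block boundary and the random
baseline P / U (positives over universe size) for reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ensemble import f1_score, matthews_correlation
from .io_model import AdjacencyNetwork, RankedNetwork, ValidationError

logger = logging.getLogger("grninfer")


@dataclass
class HoldoutSplit:
    """A prior split for cross-validation: training prior + held-out genes."""

    training_prior: AdjacencyNetwork
    heldout_genes: list[str]
    fraction: float
    seed: int


@dataclass
class EvaluationResult:
    aupr: float
    random_baseline: float
    n_positives: int
    universe_size: int
    pr_curve: pd.DataFrame       # threshold, recall, precision
    mcc_curve: np.ndarray
    f1_curve: np.ndarray

    @property
    def max_mcc(self) -> float:
        return float(self.mcc_curve.max()) if len(self.mcc_curve) else 0.0

    @property
    def max_f1(self) -> float:
        return float(self.f1_curve.max()) if len(self.f1_curve) else 0.0


def split_prior_holdout(prior: AdjacencyNetwork, fraction: float = 0.2,
                        seed: int = 0) -> HoldoutSplit:
    """Hold out a random fraction of the prior's genes (those with >= 1 edge).

    The training prior has the held-out genes' columns zeroed; scoring later
    restricts to edges into those genes.
    """
    if not 0 <= fraction < 1:
        raise ValidationError("holdout fraction must be in [0, 1)")
    has_edge = np.flatnonzero(np.any(prior.values != 0, axis=0))
    if fraction > 0 and len(has_edge) < 5:
        raise ValidationError("prior needs >= 5 genes with edges to split")
    n_hold = int(round(fraction * len(has_edge)))
    rng = np.random.default_rng(seed)
    held_idx = np.sort(rng.choice(has_edge, size=n_hold, replace=False))
    heldout = [prior.gene_ids[i] for i in held_idx]
    values = prior.values.copy()
    values[:, held_idx] = 0.0
    if not np.any(values != 0):
        raise ValidationError("holdout removed every prior edge")
    training = AdjacencyNetwork(values, list(prior.tf_ids),
                                list(prior.gene_ids), role=prior.role)
    logger.info("holdout: %d / %d prior genes held out", n_hold, len(has_edge))
    return HoldoutSplit(training, heldout, fraction, seed)


def score_network(net: RankedNetwork, gold: AdjacencyNetwork,
                  restrict_to_genes: list[str] | None = None
                  ) -> EvaluationResult:
    """Score a ranked network against a gold standard.

    The scoring universe is (TFs in gold) x (genes in gold, intersected with
    ``restrict_to_genes`` when given).  Network edges outside the universe
    are ignored; universe pairs the network never scored are appended as one
    final all-tied block so they count toward recall.  Equal-confidence
    edges form blocks and precision is evaluated at block boundaries, which
    makes AUPR deterministic and fair under permutation of tied edges.
    """
    genes = list(gold.gene_ids)
    if restrict_to_genes is not None:
        allowed = set(restrict_to_genes)
        genes = [g for g in genes if g in allowed]
    if not genes or not gold.tf_ids:
        raise ValidationError("empty scoring universe")
    tfs = list(gold.tf_ids)
    tf_pos = {t: i for i, t in enumerate(tfs)}
    gene_pos = {g: j for j, g in enumerate(genes)}
    gidx = [gold.gene_ids.index(g) for g in genes]
    truth = gold.values[:, gidx] != 0
    P = int(truth.sum())
    U = len(tfs) * len(genes)
    if P == 0:
        raise ValidationError("gold standard has no positives in the universe")

    df = net.edges
    in_univ = df["tf"].isin(tf_pos) & df["target"].isin(gene_pos)
    df = df[in_univ].sort_values("confidence", ascending=False,
                                 kind="mergesort")
    is_pos = np.array([truth[tf_pos[t], gene_pos[g]]
                       for t, g in zip(df["tf"], df["target"])], bool)
    conf = df["confidence"].to_numpy()

    # block boundaries: distinct confidences, plus one final block of all
    # universe pairs the network did not score
    if len(conf):
        ends = list(np.flatnonzero(np.diff(conf) != 0)) + [len(conf) - 1]
    else:
        ends = []
    tp_cum = np.cumsum(is_pos) if len(is_pos) else np.array([], int)

    rows = []
    for e in ends:
        n_pred = e + 1
        tp = int(tp_cum[e])
        rows.append((float(conf[e]), n_pred, tp))
    if (len(conf) < U):  # the unscored remainder
        rows.append((-np.inf, U, P))

    aupr = 0.0
    prev_recall = 0.0
    pr_rows, mcc_vals, f1_vals = [], [], []
    for threshold, n_pred, tp in rows:
        fp = n_pred - tp
        fn = P - tp
        tn = U - n_pred - fn
        recall = tp / P
        precision = tp / n_pred if n_pred else 0.0
        aupr += (recall - prev_recall) * precision
        prev_recall = recall
        pr_rows.append((threshold, recall, precision))
        mcc_vals.append(matthews_correlation(tp, fp, fn, tn))
        f1_vals.append(f1_score(tp, fp, fn))

    return EvaluationResult(
        aupr=float(aupr),
        random_baseline=P / U,
        n_positives=P,
        universe_size=U,
        pr_curve=pd.DataFrame(pr_rows,
                              columns=["threshold", "recall", "precision"]),
        mcc_curve=np.array(mcc_vals),
        f1_curve=np.array(f1_vals),
    )
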