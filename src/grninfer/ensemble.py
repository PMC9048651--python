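"""Combine scored edge sets into a confidence-ranked network and size it.

Each bootstrap/task produces a scored edge set; within each set edges are
ranked by score (best rank 1, ties share the average rank) and any universe
pair the set does not score receives the worst rank U.  Rank sums across the
M sets map affinely onto confidences in [0, 1]:

    confidence = 1 - (rank_sum - M) / (M * (U - 1))

so an edge ranked first everywhere has confidence 1 and an edge scored
nowhere has confidence 0.  The aggregate network is then sized by sweeping
the confidence threshold that maximizes MCC (or F1) against a reference
network.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_model import AdjacencyNetwork, RankedNetwork, ScoredEdgeSet, ValidationError

logger = logging.getLogger("grninfer")


def rank_combine(edge_sets: list[ScoredEdgeSet]) -> RankedNetwork:
    """Rank-sum scored edge sets over their shared universe into one network.

    The result is invariant to the order of the input sets and to any
    strictly monotone transform of within-set scores.  Edges never scored by
    any set are omitted (their confidence would be exactly 0).
    """
    if not edge_sets:
        raise ValidationError("need at least one edge set")
    tfs, genes = edge_sets[0].tfs, edge_sets[0].genes
    for es in edge_sets[1:]:
        if es.tfs != tfs or es.genes != genes:
            raise ValidationError("edge sets must share a universe")
    U = len(tfs) * len(genes)
    M = len(edge_sets)
    sign_sum: dict[tuple[str, str], float] = {}
    seen: set[tuple[str, str]] = set()
    per_set_ranks: list[dict[tuple[str, str], float]] = []
    for es in edge_sets:
        ranks: dict[tuple[str, str], float] = {}
        if len(es.edges):
            r = rankdata(-es.edges["score"].to_numpy(), method="average")
            for (tf, tg, sg), rank in zip(
                    es.edges[["tf", "target", "sign"]].itertuples(index=False),
                    r):
                key = (tf, tg)
                ranks[key] = float(rank)
                sign_sum[key] = sign_sum.get(key, 0.0) + float(sg)
                seen.add(key)
        per_set_ranks.append(ranks)

    rows = []
    denom = M * (U - 1) if U > 1 else 1
    for key in seen:
        rsum = sum(ranks.get(key, float(U)) for ranks in per_set_ranks)
        confidence = 1.0 - (rsum - M) / denom
        mean_sign = int(np.sign(sign_sum.get(key, 0.0) / M))
        rows.append((key[0], key[1], confidence, rsum, mean_sign))
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    df = pd.DataFrame(rows, columns=["tf", "target", "confidence",
                                     "rank_sum", "sign"])
    logger.info("rank_combine: %d set(s) -> %d edges over universe %d",
                M, len(df), U)
    return RankedNetwork(df, list(tfs), list(genes), n_combined=M)


def _confusion_curve(net: RankedNetwork, reference: AdjacencyNetwork
                     ) -> pd.DataFrame:
    """TP/FP/FN/TN at every distinct confidence threshold (descending)."""
    ref = _reference_mask(net, reference)
    P = int(ref.sum())
    U = net.universe_size
    df = net.edges.sort_values("confidence", ascending=False,
                               kind="mergesort")
    tf_pos = {t: i for i, t in enumerate(net.tfs)}
    gene_pos = {g: j for j, g in enumerate(net.genes)}
    is_pos = np.array([ref[tf_pos[t], gene_pos[g]]
                       for t, g in zip(df["tf"], df["target"])], bool)
    conf = df["confidence"].to_numpy()
    # block boundaries at each distinct confidence
    boundaries = np.flatnonzero(np.diff(conf) != 0)
    ends = np.append(boundaries, len(conf) - 1) if len(conf) else np.array([], int)
    tp_cum = np.cumsum(is_pos)
    rows = []
    for e in ends:
        n_pred = e + 1
        tp = int(tp_cum[e])
        fp = n_pred - tp
        fn = P - tp
        tn = U - n_pred - fn
        rows.append((float(conf[e]), tp, fp, fn, tn))
    return pd.DataFrame(rows, columns=["threshold", "tp", "fp", "fn", "tn"])


def _reference_mask(net: RankedNetwork, reference: AdjacencyNetwork
                    ) -> np.ndarray:
    from .regression_bbsr import prior_on_namespace
    mask = prior_on_namespace(reference, net.tfs, net.genes) != 0
    if not mask.any():
        raise ValidationError("reference has no edges inside the network universe")
    return mask


def matthews_correlation(tp: int, fp: int, fn: int, tn: int) -> float:
    """MCC with the 0 convention when any marginal is empty."""
    denom = (math.sqrt(tp + fp) * math.sqrt(tp + fn)
             * math.sqrt(tn + fp) * math.sqrt(tn + fn))
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / denom


def f1_score(tp: int, fp: int, fn: int) -> float:
    return 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0


def threshold_max_mcc(net: RankedNetwork, reference: AdjacencyNetwork,
                      metric: str = "mcc"
                      ) -> tuple[float, RankedNetwork, pd.DataFrame]:
    """Pick the confidence threshold maximizing MCC (or F1) vs a reference.

    Sweeps every distinct confidence descending; predicted positives at
    threshold t are edges with confidence >= t, and the confusion counts are
    taken over the full TF x gene universe.  Returns the largest threshold
    achieving the maximum, the retained network, and the metric curve.
    """
    if metric not in {"mcc", "f1"}:
        raise ValidationError("metric must be 'mcc' or 'f1'")
    curve = _confusion_curve(net, reference)
    if curve.empty:
        raise ValidationError("network has no edges to threshold")
    if metric == "mcc":
        vals = [matthews_correlation(r.tp, r.fp, r.fn, r.tn)
                for r in curve.itertuples()]
    else:
        vals = [f1_score(r.tp, r.fp, r.fn) for r in curve.itertuples()]
    curve = curve.assign(**{metric: vals})
    best = int(np.argmax(vals))  # first occurrence = largest threshold
    t_star = float(curve["threshold"].iloc[best])
    kept = net.edges[net.edges["confidence"] >= t_star].reset_index(drop=True)
    filtered = RankedNetwork(kept, list(net.tfs), list(net.genes),
                             n_combined=net.n_combined)
    logger.info("threshold_max_%s: %s=%.4f at confidence %.6g, %d edges kept",
                metric, metric, vals[best], t_star, len(kept))
    return t_star, filtered, curve
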