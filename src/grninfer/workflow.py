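"""End-to-end orchestration: preprocessing, holdout CV, engines, scoring.

``run_workflow`` executes the full protocol: read -> align -> filter ->
controls -> normalize/transform -> per-replicate prior holdout -> TF
activity estimation per task -> model selection per task x bootstrap ->
rank combination -> scoring on the held-out genes.  Every random decision
derives from the config seed, so identical configs produce byte-identical
metrics regardless of worker count or input ordering.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable

import numpy as np

from . import preprocessing
from .ensemble import rank_combine
from .evaluation import score_network, split_prior_holdout
from .io_model import (AdjacencyNetwork, GeneExpressionMatrix, RankedNetwork,
                       ValidationError, WorkflowConfig, align_namespaces,
                       read_adjacency, read_expression, write_ranked_network)
from .regression_amusr import run_amusr
from .regression_bbsr import run_bbsr
from .regression_stars_lasso import run_stars_lasso
from .tfa import estimate_tfa

logger = logging.getLogger("grninfer")


def derive_seed(base_seed: int, *tokens) -> int:
    """Deterministic sub-seed from a base seed and arbitrary labels.

    Independent of process/worker identity, so parallel runs reproduce
    serial ones.  Stays below 2**31.
    """
    text = ":".join([str(base_seed)] + [str(t) for t in tokens])
    return zlib.crc32(text.encode()) & 0x7FFFFFFF


def _call_with_retry(fn: Callable, item):
    try:
        return fn(item)
    except Exception as exc:
        logger.warning("parallel_map: retrying %r after %s", item, exc)
        return fn(item)


def parallel_map(fn: Callable, items: Iterable, workers: int = 1) -> list:
    """Deterministic parallel map: output order matches input order.

    ``fn`` must be pure (any randomness seeded from its argument, never from
    worker identity), so results are identical for any worker count.  A
    failing item is retried once before the error surfaces.
    """
    items = list(items)
    if workers <= 1:
        return [_call_with_retry(fn, it) for it in items]
    from joblib import Parallel, delayed
    return Parallel(n_jobs=workers)(
        delayed(_call_with_retry)(fn, it) for it in items)


@dataclass
class _EngineJob:
    """One (task, bootstrap) unit of model selection."""

    method: str
    expr: GeneExpressionMatrix
    activities: object
    prior: AdjacencyNetwork
    seed: int
    task_name: str
    bootstrap: int
    config: WorkflowConfig


def _run_engine_job(job: _EngineJob):
    cfg = job.config
    if job.method == "bbsr":
        return run_bbsr(job.expr, job.activities, job.prior, n_bootstraps=1,
                        seed=job.seed, nK=cfg.nK,
                        prior_penalty_weight=cfg.prior_penalty_weight,
                        origin_prefix=job.task_name)[0]
    if job.method == "stars_lasso":
        return run_stars_lasso(job.expr, job.activities, job.prior,
                               n_bootstraps=1, seed=job.seed,
                               threshold=cfg.stars_threshold,
                               n_subsamples=cfg.stars_n_subsamples,
                               subsample_fraction=cfg.stars_subsample_fraction,
                               grid_size=cfg.lambda_grid_size,
                               origin_prefix=job.task_name)[0]
    raise ValidationError(f"unknown single-task method {job.method!r}")


def _split_tasks(expr: GeneExpressionMatrix) -> dict[str, GeneExpressionMatrix]:
    if expr.task_labels is None:
        return {"task0": expr}
    labels = sorted(set(expr.task_labels))
    return {lab: expr.subset_samples(
        [i for i, l in enumerate(expr.task_labels) if l == lab])
        for lab in labels}


def _infer_once(expr: GeneExpressionMatrix, training_prior: AdjacencyNetwork,
                config: WorkflowConfig, seed: int) -> RankedNetwork:
    """One full inference pass: TFA + engine over tasks x bootstraps."""
    tasks = _split_tasks(expr)
    names = sorted(tasks)
    if config.method == "amusr":
        exprs = [tasks[n] for n in names]
        acts = [estimate_tfa(tasks[n], training_prior) for n in names]
        # all tasks share the training prior here; per-task priors are
        # supported at the library level
        edge_sets = run_amusr(exprs, acts,
                              task_priors=[training_prior] * len(names),
                              n_bootstraps=config.n_bootstraps, seed=seed,
                              gamma=config.amusr_gamma,
                              prior_penalty_weight=config.prior_penalty_weight,
                              grid_size=config.lambda_grid_size,
                              task_names=names)
        # harmonize universes across tasks before combining
        edge_sets = _on_common_universe(edge_sets)
    else:
        jobs = []
        for name in names:
            acts = estimate_tfa(tasks[name], training_prior)
            for b in range(config.n_bootstraps):
                jobs.append(_EngineJob(config.method, tasks[name], acts,
                                       training_prior, seed + b, name, b,
                                       config))
        edge_sets = parallel_map(_run_engine_job, jobs,
                                 workers=config.workers)
        edge_sets = _on_common_universe(edge_sets)
    return rank_combine(edge_sets)


def _on_common_universe(edge_sets):
    from .io_model import ScoredEdgeSet
    tfs = sorted(set().union(*[set(es.tfs) for es in edge_sets]))
    genes = sorted(set().union(*[set(es.genes) for es in edge_sets]))
    return [ScoredEdgeSet(es.edges, tfs, genes, origin=es.origin)
            for es in edge_sets]


@dataclass
class WorkflowResult:
    metrics: dict
    network: RankedNetwork
    run_dir: Path | None = None


def run_workflow(config: WorkflowConfig,
                 expr: GeneExpressionMatrix | None = None,
                 prior: AdjacencyNetwork | None = None,
                 gold: AdjacencyNetwork | None = None,
                 write_outputs: bool = True) -> WorkflowResult:
    """Execute the full cross-validated inference protocol.

    Inputs may be passed in memory or read from the config paths.  Replicate
    r (1..n_replicates) reseeds everything as ``base_seed + r``.  When no
    separate gold standard is given, the full prior doubles as the scoring
    reference (standard for holdout evaluation).  Metrics report per-replicate
    AUPR on held-out genes with mean, standard deviation, and random baseline.
    """
    if expr is None:
        expr = read_expression(config.expression,
                               format=config.expression_format)
    if prior is None:
        prior = read_adjacency(config.prior, role="prior")
    if gold is None and config.gold_standard:
        gold = read_adjacency(config.gold_standard, role="gold_standard")

    expr, prior, gold = align_namespaces(expr, prior, gold)
    if gold is None:
        gold = AdjacencyNetwork(prior.values.copy(), list(prior.tf_ids),
                                list(prior.gene_ids), role="gold_standard")

    stages: list[str] = []
    if expr.is_counts:
        expr, threshold = preprocessing.filter_genes_by_total_count(
            expr, config.min_count_per_cells)
        stages.append(f"filter genes: threshold={threshold}, kept={expr.n_genes}")
    if config.control == "noise_data":
        expr = preprocessing.make_noise_control(expr, derive_seed(
            config.base_seed, "noise"))
        stages.append("control: noise_data")
    if config.depth_normalize:
        expr = preprocessing.depth_normalize(expr)
        stages.append("depth normalize")
    expr = preprocessing.transform_counts(expr, config.transform)
    stages.append(f"transform: {config.transform}")

    auprs, baselines = [], []
    network: RankedNetwork | None = None
    for r in range(1, config.n_replicates + 1):
        seed_r = config.base_seed + r
        if config.holdout_fraction > 0:
            split = split_prior_holdout(prior, config.holdout_fraction, seed_r)
            training_prior, heldout = split.training_prior, split.heldout_genes
        else:
            training_prior, heldout = prior, None
        if config.control == "shuffle_prior":
            training_prior = preprocessing.shuffle_prior(
                training_prior, derive_seed(seed_r, "shuffle"))
        net = _infer_once(expr, training_prior, config, seed_r)
        if network is None:
            network = net
        result = score_network(net, gold, restrict_to_genes=heldout)
        auprs.append(result.aupr)
        baselines.append(result.random_baseline)
        stages.append(f"replicate {r}: aupr={result.aupr:.6g} "
                      f"baseline={result.random_baseline:.6g}")
        logger.info(stages[-1])

    metrics = {
        "method": config.method,
        "transform": config.transform,
        "control": config.control,
        "n_replicates": config.n_replicates,
        "n_bootstraps": config.n_bootstraps,
        "holdout_fraction": config.holdout_fraction,
        "aupr": auprs,
        "aupr_mean": float(np.mean(auprs)),
        "aupr_sd": float(np.std(auprs)),
        "random_baseline": float(np.mean(baselines)),
    }

    run_dir = None
    if write_outputs:
        run_dir = Path(config.output_dir)
        run_dir.mkdir(parents=True, exist_ok=True)
        write_ranked_network(network, run_dir / "network.tsv")
        with open(run_dir / "metrics.json", "w") as fh:
            json.dump(metrics, fh, sort_keys=True, indent=2)
        config.to_yaml(run_dir / "resolved_config.yaml")
        (run_dir / "run_log.txt").write_text("\n".join(stages) + "\n")
    return WorkflowResult(metrics, network, run_dir)
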