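"""Domain types and file IO for network inference.

Conventions used throughout the package:

* expression matrices are genes x samples,
* adjacency networks (priors and gold standards) are TFs x genes,
* activity matrices are TFs x samples,
* identifiers are case-sensitive opaque strings; sorted outputs break ties
  lexicographically so every run is reproducible byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

logger = logging.getLogger("grninfer")

Role = Literal["prior", "gold_standard"]


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate {what} identifier(s): {dup[:5]}")
    return ids


@dataclass
class GeneExpressionMatrix:
    """Genes x samples expression matrix.

    ``is_counts`` records whether ``values`` are untransformed counts
    (nonnegative integers); variance-stabilizing transforms clear it.
    ``task_labels`` assigns each sample to a learning task (one label per
    sample; a single shared label means single-task inference).
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    task_labels: list[str] | None = None
    is_counts: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        if self.values.ndim != 2:
            raise ValidationError("expression values must be 2-D")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.task_labels is not None and len(self.task_labels) != len(self.sample_ids):
            raise ValidationError("need exactly one task label per sample")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite")
        if self.is_counts:
            if np.any(self.values < 0):
                raise ValidationError("counts must be nonnegative")
            if not np.allclose(self.values, np.round(self.values)):
                raise ValidationError("counts must be integral")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def with_values(self, values: np.ndarray, is_counts: bool | None = None) -> "GeneExpressionMatrix":
        return replace(self, values=values,
                       is_counts=self.is_counts if is_counts is None else is_counts)

    def subset_genes(self, gene_ids: Sequence[str]) -> "GeneExpressionMatrix":
        idx = [self.gene_ids.index(g) for g in gene_ids]
        return replace(self, values=self.values[idx], gene_ids=list(gene_ids))

    def subset_samples(self, keep: Sequence[int]) -> "GeneExpressionMatrix":
        keep = list(keep)
        return replace(
            self,
            values=self.values[:, keep],
            sample_ids=[self.sample_ids[i] for i in keep],
            task_labels=None if self.task_labels is None
            else [self.task_labels[i] for i in keep],
        )


@dataclass
class AdjacencyNetwork:
    """TF x gene adjacency matrix: a prior-knowledge network or a gold standard."""

    values: np.ndarray
    tf_ids: list[str]
    gene_ids: list[str]
    role: Role = "prior"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.tf_ids = _check_unique(self.tf_ids, "TF")
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        if self.values.shape != (len(self.tf_ids), len(self.gene_ids)):
            raise ValidationError("adjacency shape does not match identifier lists")
        if not np.any(self.values != 0):
            raise ValidationError(f"{self.role} network has no edges")
        self_edges = [t for t in self.tf_ids
                      if t in self.gene_ids
                      and self.values[self.tf_ids.index(t), self.gene_ids.index(t)] != 0]
        if self_edges:
            logger.warning("%s network contains %d self-edge(s), e.g. %s",
                           self.role, len(self_edges), self_edges[:3])

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(self.values))

    def edge_list(self) -> pd.DataFrame:
        tf_idx, gene_idx = np.nonzero(self.values)
        return pd.DataFrame({
            "tf": [self.tf_ids[i] for i in tf_idx],
            "target": [self.gene_ids[j] for j in gene_idx],
            "value": self.values[tf_idx, gene_idx],
        })


@dataclass
class ActivityMatrix:
    """TF x samples latent activity estimates.

    ``provenance`` records, per TF, whether its row was estimated from prior
    targets (``estimated``) or copied from the TF's own expression because it
    had no usable prior targets (``expression_fallback``).
    """

    values: np.ndarray
    tf_ids: list[str]
    sample_ids: list[str]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.tf_ids = _check_unique(self.tf_ids, "TF")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.tf_ids), len(self.sample_ids)):
            raise ValidationError("activity shape does not match identifier lists")
        missing = [t for t in self.tf_ids if t not in self.provenance]
        if missing:
            raise ValidationError(f"TFs without provenance tag: {missing[:5]}")


@dataclass
class ScoredEdgeSet:
    """Scored TF->gene edges from one (task, bootstrap) model-selection run."""

    edges: pd.DataFrame  # columns: tf, target, score, sign
    tfs: list[str]
    genes: list[str]
    origin: str = ""

    def __post_init__(self) -> None:
        required = {"tf", "target", "score", "sign"}
        if not required.issubset(self.edges.columns):
            raise ValidationError(f"edge table needs columns {sorted(required)}")
        self.edges = self.edges.reset_index(drop=True)
        if len(self.edges):
            if not np.all(np.isfinite(self.edges["score"])) or np.any(self.edges["score"] < 0):
                raise ValidationError("edge scores must be finite and >= 0")
            pairs = self.edges[["tf", "target"]].apply(tuple, axis=1)
            if pairs.duplicated().any():
                raise ValidationError("duplicate (tf, target) pair in edge set")
            tf_set, gene_set = set(self.tfs), set(self.genes)
            if not set(self.edges["tf"]) <= tf_set or not set(self.edges["target"]) <= gene_set:
                raise ValidationError("edge outside the declared universe")

    @property
    def universe_size(self) -> int:
        return len(self.tfs) * len(self.genes)


@dataclass
class RankedNetwork:
    """Confidence-ranked aggregate network from rank-combining edge sets."""

    edges: pd.DataFrame  # columns: tf, target, confidence, rank_sum, sign
    tfs: list[str]
    genes: list[str]
    n_combined: int = 1

    def __post_init__(self) -> None:
        required = {"tf", "target", "confidence", "rank_sum", "sign"}
        if not required.issubset(self.edges.columns):
            raise ValidationError(f"ranked network needs columns {sorted(required)}")
        self.edges = self.edges.reset_index(drop=True)
        if len(self.edges):
            conf = self.edges["confidence"].to_numpy()
            if np.any(conf < -1e-12) or np.any(conf > 1 + 1e-12):
                raise ValidationError("confidences must lie in [0, 1]")
            pairs = self.edges[["tf", "target"]].apply(tuple, axis=1)
            if pairs.duplicated().any():
                raise ValidationError("duplicate edge in ranked network")

    @property
    def universe_size(self) -> int:
        return len(self.tfs) * len(self.genes)


@dataclass
class WorkflowConfig:
    """Full specification of an inference run.

    Engine hyperparameter defaults: ``nK`` caps BBSR candidate sets at 10,
    StARS uses 20 subsamples of 63% of samples against an instability target
    of 0.05, the lasso/AMuSR penalty grids have 20 log-spaced points, AMuSR
    model selection uses EBIC with gamma = 1, and ``prior_penalty_weight`` = 1
    means prior edges receive no preferential penalty.
    """

    expression: str = ""
    prior: str = ""
    gold_standard: str | None = None
    output_dir: str = "run"
    expression_format: str = "dense_tsv"

    method: str = "bbsr"
    transform: str = "raw"
    depth_normalize: bool = False
    min_count_per_cells: int = 20
    holdout_fraction: float = 0.2
    n_replicates: int = 10
    n_bootstraps: int = 5
    control: str = "none"
    base_seed: int = 42
    workers: int = 1

    nK: int = 10
    stars_threshold: float = 0.05
    stars_n_subsamples: int = 20
    stars_subsample_fraction: float = 0.63
    lambda_grid_size: int = 20
    amusr_gamma: float = 1.0
    prior_penalty_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.method not in {"bbsr", "stars_lasso", "amusr"}:
            raise ValidationError(f"unknown method {self.method!r}")
        if self.transform not in {"raw", "ftt", "log2"}:
            raise ValidationError(f"unknown transform {self.transform!r}")
        if self.control not in {"none", "shuffle_prior", "noise_data"}:
            raise ValidationError(f"unknown control {self.control!r}")
        if not 0 <= self.holdout_fraction < 1:
            raise ValidationError("holdout_fraction must be in [0, 1)")
        if self.n_bootstraps < 1 or self.n_replicates < 1:
            raise ValidationError("n_bootstraps and n_replicates must be >= 1")
        if not 0 < self.stars_subsample_fraction <= 1:
            raise ValidationError("stars_subsample_fraction must be in (0, 1]")
        if self.prior_penalty_weight < 0:
            raise ValidationError("prior_penalty_weight must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "WorkflowConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_expression(path: str | Path, format: str = "dense_tsv", *,
                    gene_file: str | Path | None = None,
                    sample_file: str | Path | None = None,
                    is_counts: bool | str = "auto") -> GeneExpressionMatrix:
    """Read an expression matrix.

    ``dense_tsv``: genes as rows, first column gene ids, header row sample ids.
    ``sparse_triplet``: Matrix-Market coordinate file (genes x samples) with
    companion one-id-per-line gene and sample files (defaulting to
    ``<stem>_genes.txt`` / ``<stem>_samples.txt`` next to the matrix).
    ``is_counts="auto"`` flags the matrix as raw counts exactly when all
    values are nonnegative integers.
    """
    path = Path(path)
    if format == "dense_tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:  # pragma: no cover - pandas message passthrough
            raise ValidationError(f"malformed expression file {path}: {exc}") from exc
        if df.index.has_duplicates:
            raise ValidationError(f"duplicate gene ids in {path}")
        values = df.to_numpy(dtype=float)
        gene_ids, sample_ids = list(df.index.astype(str)), list(df.columns.astype(str))
    elif format == "sparse_triplet":
        gene_file = Path(gene_file) if gene_file else path.with_name(path.stem + "_genes.txt")
        sample_file = Path(sample_file) if sample_file else path.with_name(path.stem + "_samples.txt")
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:
            raise ValidationError(f"malformed Matrix-Market file {path}: {exc}") from exc
        values = np.asarray(scipy.sparse.coo_matrix(mat).todense(), dtype=float)
        gene_ids = Path(gene_file).read_text().split()
        sample_ids = Path(sample_file).read_text().split()
    else:
        raise ValidationError(f"unknown expression format {format!r}")
    if is_counts == "auto":
        is_counts = bool(np.all(values >= 0)
                         and np.allclose(values, np.round(values)))
    return GeneExpressionMatrix(values, gene_ids, sample_ids, is_counts=is_counts)


def write_expression(expr: GeneExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(expr.values, index=expr.gene_ids, columns=expr.sample_ids)
    df.to_csv(path, sep="\t", index_label="gene")


def read_adjacency(path: str | Path, role: Role = "prior", *,
                   keep_weights: bool = False) -> AdjacencyNetwork:
    """Read a TF x gene network from a 3-column edge list or dense labeled table.

    A file whose header has exactly three columns named like an edge list
    (or whose rows are (tf, gene, value) triplets) is treated as an edge list;
    anything else is read as a dense table with TFs as rows.  Gold standards
    are coerced to {-1, 0, 1} unless ``keep_weights`` requests real-valued
    scoring weights.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    is_edge_list = df.shape[1] == 3 and not _looks_dense(df)
    if is_edge_list:
        df.columns = ["tf", "target", "value"]
        try:
            vals = pd.to_numeric(df["value"])
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"non-numeric edge value in {path}: {exc}") from exc
        if df.duplicated(subset=["tf", "target"]).any():
            dup = df[df.duplicated(subset=["tf", "target"])].iloc[0]
            raise ValidationError(f"duplicate edge ({dup['tf']}, {dup['target']}) in {path}")
        tf_ids = sorted(df["tf"].astype(str).unique())
        gene_ids = sorted(df["target"].astype(str).unique())
        values = np.zeros((len(tf_ids), len(gene_ids)))
        ti = {t: i for i, t in enumerate(tf_ids)}
        gi = {g: j for j, g in enumerate(gene_ids)}
        for tf, gene, v in zip(df["tf"].astype(str), df["target"].astype(str), vals):
            values[ti[tf], gi[gene]] = v
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
        values = df.to_numpy(dtype=float)
        tf_ids, gene_ids = list(df.index.astype(str)), list(df.columns.astype(str))
    if role == "gold_standard" and not keep_weights:
        values = np.sign(values)
    return AdjacencyNetwork(values, tf_ids, gene_ids, role=role)


def _looks_dense(df: pd.DataFrame) -> bool:
    # a dense table's data columns are all numeric after the id column
    try:
        df.iloc[:, 1:].astype(float)
    except (ValueError, TypeError):
        return False
    # 3 columns with numeric 2nd column reads as dense 2-gene table; treat a
    # non-numeric second column as the edge-list target column
    return True


def write_adjacency(net: AdjacencyNetwork, path: str | Path, *,
                    as_edge_list: bool = True) -> None:
    if as_edge_list:
        net.edge_list().to_csv(path, sep="\t", index=False)
    else:
        pd.DataFrame(net.values, index=net.tf_ids, columns=net.gene_ids).to_csv(
            path, sep="\t", index_label="tf")


def align_namespaces(expr: GeneExpressionMatrix, prior: AdjacencyNetwork,
                     gold: AdjacencyNetwork | None = None):
    """Restrict prior/gold gene namespaces to the expression genes.

    Returns ``(expr, prior, gold)`` with gene orderings canonicalized
    lexicographically.  The TF list stays the prior's full TF list: a TF
    without measured expression can still have its activity estimated from
    its targets.  Genes present only in the prior or gold standard are
    dropped with a logged count.
    """
    expr_genes = sorted(expr.gene_ids)
    expr = expr.subset_genes(expr_genes)

    shared = sorted(set(expr_genes) & set(prior.gene_ids))
    if not shared:
        raise ValidationError("expression and prior share no genes")
    dropped = len(prior.gene_ids) - len(shared)
    if dropped:
        logger.info("align: dropped %d prior gene(s) absent from expression", dropped)
    gidx = [prior.gene_ids.index(g) for g in shared]
    tf_order = sorted(prior.tf_ids)
    tidx = [prior.tf_ids.index(t) for t in tf_order]
    prior = AdjacencyNetwork(prior.values[np.ix_(tidx, gidx)], tf_order, shared,
                             role=prior.role)
    absent_tfs = [t for t in tf_order if t not in set(expr_genes)]
    if absent_tfs:
        logger.info("align: %d TF(s) lack measured expression (activity from "
                    "targets only): %s", len(absent_tfs), absent_tfs[:5])

    if gold is not None:
        gshared = sorted(set(expr_genes) & set(gold.gene_ids))
        if not gshared:
            raise ValidationError("expression and gold standard share no genes")
        gdropped = len(gold.gene_ids) - len(gshared)
        if gdropped:
            logger.info("align: dropped %d gold-standard gene(s) absent from "
                        "expression", gdropped)
        ggidx = [gold.gene_ids.index(g) for g in gshared]
        gtf_order = sorted(gold.tf_ids)
        gtidx = [gold.tf_ids.index(t) for t in gtf_order]
        gold = AdjacencyNetwork(gold.values[np.ix_(gtidx, ggidx)], gtf_order,
                                gshared, role=gold.role)
    return expr, prior, gold


def write_ranked_network(net: RankedNetwork, path: str | Path) -> None:
    """Write a ranked network as TSV, best edges first, lexicographic ties."""
    df = net.edges.sort_values(
        by=["confidence", "tf", "target"], ascending=[False, True, True],
        kind="mergesort").reset_index(drop=True)
    out = df[["tf", "target", "confidence", "rank_sum", "sign"]].copy()
    out["confidence"] = out["confidence"].map(lambda v: f"{v:.10g}")
    out["rank_sum"] = out["rank_sum"].map(lambda v: f"{v:.10g}")
    out["sign"] = out["sign"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_ranked_network(path: str | Path, tfs: Sequence[str] | None = None,
                        genes: Sequence[str] | None = None,
                        n_combined: int = 1) -> RankedNetwork:
    df = pd.read_csv(path, sep="\t", dtype={"tf": str, "target": str})
    tfs = list(tfs) if tfs is not None else sorted(df["tf"].unique())
    genes = list(genes) if genes is not None else sorted(df["target"].unique())
    return RankedNetwork(df, tfs, genes, n_combined=n_combined)
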