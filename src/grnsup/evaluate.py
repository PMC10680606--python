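"""Per-gene ranking metrics and benchmark-level evaluation.

Each target gene is a small binary classification problem: rank the ``n_tf``
candidate TFs by score and compare against the true regulators.  Average
Precision ``AP = sum_n (R_n - R_{n-1}) * P_n`` over distinct-score
thresholds is preferred over AUPRC because positives are very sparse (often
a single regulator).  AUROC is the probability that a random positive
outscores a random negative, ties counted half.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .errors import ConsistencyError, MetricUndefinedError, ParameterError
from .features import FeaturizationParams, assemble_ml, assemble_sp, normalize, pair_stats_per_gene
from .network import ExpressionMatrix, RegulatoryNetwork


def average_precision(scores, labels) -> float:
    """AP over descending-score thresholds; requires at least one positive."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if not np.isfinite(s).all():
        raise ParameterError("scores must be finite")
    if y.sum() < 1:
        raise MetricUndefinedError("average precision undefined without positives")
    return float(average_precision_score(y, s))


def auroc(scores, labels) -> float:
    """Rank-sum AUROC with half-credit for ties; needs both classes present."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if not np.isfinite(s).all():
        raise ParameterError("scores must be finite")
    if y.sum() < 1 or y.sum() == len(y):
        raise MetricUndefinedError("AUROC undefined with single-class labels")
    return float(roc_auc_score(y, s))


def random_baseline_ap(n_pos: int, n_candidates: int, n_reps: int = 1000, seed: int = 0) -> float:
    """Monte-Carlo expected AP of a uniformly random ranking."""
    if not 0 < n_pos < n_candidates:
        raise ParameterError("need 0 < n_pos < n_candidates")
    rng = np.random.default_rng(seed)
    labels = np.zeros(n_candidates)
    labels[:n_pos] = 1
    total = 0.0
    for _ in range(n_reps):
        total += average_precision(rng.random(n_candidates), labels)
    return total / n_reps


@dataclass
class EdgePredictionSet:
    """Scores and ground truth for one gene's candidate-TF ranking."""

    gene: str
    tf_ids: list[str]
    scores: np.ndarray
    labels: np.ndarray

    def is_scorable(self) -> bool:
        s = int(self.labels.sum())
        return 0 < s < len(self.labels)


@dataclass
class BenchmarkReport:
    """Aggregated per-gene metrics over one benchmark."""

    ap: np.ndarray
    auroc: np.ndarray
    genes: list[str]
    excluded: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def mean_ap(self) -> float:
        return float(np.mean(self.ap))

    @property
    def median_ap(self) -> float:
        return float(np.median(self.ap))

    @property
    def mean_auroc(self) -> float:
        return float(np.mean(self.auroc))

    @property
    def median_auroc(self) -> float:
        return float(np.median(self.auroc))

    def summary(self) -> dict:
        return {
            "n_genes": len(self.genes),
            "excluded": self.excluded,
            "mean_ap": self.mean_ap,
            "median_ap": self.median_ap,
            "mean_auroc": self.mean_auroc,
            "median_auroc": self.median_auroc,
            **self.meta,
        }


def score_benchmark(
    model,
    benchmark: list[tuple[RegulatoryNetwork, ExpressionMatrix]],
    featurization: FeaturizationParams | None = None,
) -> list[EdgePredictionSet]:
    """Score every (gene, TF) pair of a benchmark with a trained model.

    SP models run one batched forward pass of ``n_tf`` inputs per gene; ML
    models one pass per gene.  Featurization settings must be the ones the
    model was trained with (enforced by callers holding a checkpoint).
    """
    feat = featurization or FeaturizationParams()
    out = []
    for k, (net, expr) in enumerate(benchmark):
        if net.n_tf != model.n_tf:
            raise ConsistencyError("benchmark n_tf does not match the model")
        norm = normalize(expr)
        tf_rows = [r for r, l in zip(norm.row_ids, norm.layers) if l == "TF"]
        gene_rows = [r for r, l in zip(norm.row_ids, norm.layers) if l == "G"]
        labels = net.label_matrix()
        for gi, (gene, stats) in enumerate(
            pair_stats_per_gene(norm, tf_rows, gene_rows, eps=feat.eps, mi_bins=feat.mi_bins)
        ):
            if model.variant == "sp":
                X = np.stack([assemble_sp(stats, tf, feat.feature_mask).X for tf in tf_rows])
                scores = model.forward(X, train=False)
            else:
                scores = model.forward(
                    assemble_ml(stats, feat.feature_mask).X[None], train=False
                )[0]
            out.append(
                EdgePredictionSet(f"grn{k}:{gene}", tf_rows, np.asarray(scores), labels[gi].astype(int))
            )
    return out


def report_from_predictions(preds: list[EdgePredictionSet], **meta) -> BenchmarkReport:
    """Per-gene AP/AUROC, excluding (and counting) genes without both classes."""
    ap, au, genes = [], [], []
    excluded = 0
    for p in preds:
        if not p.is_scorable():
            excluded += 1
            continue
        ap.append(average_precision(p.scores, p.labels))
        au.append(auroc(p.scores, p.labels))
        genes.append(p.gene)
    return BenchmarkReport(np.asarray(ap), np.asarray(au), genes, excluded, dict(meta))


def evaluate_model(
    model,
    benchmark: list[tuple[RegulatoryNetwork, ExpressionMatrix]],
    featurization: FeaturizationParams | None = None,
    **meta,
) -> BenchmarkReport:
    """Score a benchmark and aggregate per-gene AP / AUROC."""
    return report_from_predictions(score_benchmark(model, benchmark, featurization), **meta)
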