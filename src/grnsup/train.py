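"""Labeled-dataset construction from simulated benchmarks, and the training loop.

Positive labels are literal edges of the generating network: an SP sample is
one (gene, candidate TF) pair with a 0/1 label, an ML sample is one gene with
a length-``n_tf`` binary label vector.  Training follows a fixed recipe:
Adam (learning rate 2e-4, weight decay 5e-4), binary cross-entropy on logits
with positive-class weight 9, batch size 32, up to 300 epochs with early
stopping on a validation split held out by GRN (never by sample, so no
leakage between samples of one network).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConsistencyError, ParameterError
from .features import (
    FeaturizationParams,
    assemble_ml,
    assemble_sp,
    normalize,
    pair_stats_per_gene,
)
from .network import ExpressionMatrix, RegulatoryNetwork
from .nn import Adam, MLNet, SPNet, bce_with_logits


@dataclass
class TrainingConfig:
    learning_rate: float = 2e-4
    weight_decay: float = 5e-4
    pos_weight: float = 9.0
    batch_size: int = 32
    max_epochs: int = 300
    val_fraction: float = 0.1  # fraction of GRNs held out for validation
    patience: int = 20  # early-stopping patience in epochs (0 disables)
    seed: int = 0

    def validate(self) -> None:
        if min(self.learning_rate, self.weight_decay, self.pos_weight) <= 0:
            raise ParameterError("rates and the positive weight must be > 0")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ParameterError("batch_size and max_epochs must be >= 1")


@dataclass
class LabeledDataset:
    """Featurized samples with labels and provenance.

    SP: ``X`` is ``(n, 1 + n_tf, 5)``, ``y`` is ``(n,)``; ``tf_index`` gives
    the candidate TF of each sample.  ML: ``X`` is ``(n, n_pairs, 5)``, ``y``
    is ``(n, n_tf)``; ``tf_index`` is None.
    """

    X: np.ndarray
    y: np.ndarray
    grn_index: np.ndarray
    gene_index: np.ndarray
    tf_index: np.ndarray | None
    variant: str
    n_tf: int
    featurization: FeaturizationParams = field(default_factory=FeaturizationParams)

    def __len__(self) -> int:
        return len(self.X)


def build_dataset(
    benchmark: list[tuple[RegulatoryNetwork, ExpressionMatrix]],
    variant: str = "sp",
    featurization: FeaturizationParams | None = None,
) -> LabeledDataset:
    """Featurize a benchmark into one labeled dataset.

    Per GRN the expression matrix is normalized once and one pairwise-stat
    tensor is computed per gene, yielding ``n_tf * n_g`` SP samples or
    ``n_g`` ML samples per GRN.
    """
    if not benchmark:
        raise ParameterError("benchmark is empty")
    if variant not in ("sp", "ml"):
        raise ParameterError("variant must be 'sp' or 'ml'")
    feat = featurization or FeaturizationParams()
    Xs, ys, grn_idx, gene_idx, tf_idx = [], [], [], [], []
    n_tf = benchmark[0][0].n_tf
    for k, (net, expr) in enumerate(benchmark):
        if net.n_tf != n_tf:
            raise ConsistencyError("all GRNs in a dataset must share n_tf")
        if net.label_matrix().sum(axis=1).min() < 1:
            raise ConsistencyError("a gene has no regulators in the source network")
        norm = normalize(expr)
        tf_rows = [r for r, l in zip(norm.row_ids, norm.layers) if l == "TF"]
        gene_rows = [r for r, l in zip(norm.row_ids, norm.layers) if l == "G"]
        labels = net.label_matrix()
        for gi, (gene, stats) in enumerate(
            pair_stats_per_gene(norm, tf_rows, gene_rows, eps=feat.eps, mi_bins=feat.mi_bins)
        ):
            if variant == "sp":
                for ti, tf in enumerate(tf_rows):
                    Xs.append(assemble_sp(stats, tf, feat.feature_mask).X)
                    ys.append(labels[gi, ti])
                    grn_idx.append(k)
                    gene_idx.append(gi)
                    tf_idx.append(ti)
            else:
                Xs.append(assemble_ml(stats, feat.feature_mask).X)
                ys.append(labels[gi])
                grn_idx.append(k)
                gene_idx.append(gi)
    return LabeledDataset(
        X=np.asarray(Xs),
        y=np.asarray(ys, dtype=float),
        grn_index=np.asarray(grn_idx),
        gene_index=np.asarray(gene_idx),
        tf_index=np.asarray(tf_idx) if variant == "sp" else None,
        variant=variant,
        n_tf=n_tf,
        featurization=feat,
    )


@dataclass
class TrainingHistory:
    epoch: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1

    def to_rows(self):
        return list(zip(self.epoch, self.train_loss, self.val_loss))


def _epoch_loss(model, X, y, pos_weight, batch_size=256) -> float:
    tot, n = 0.0, 0
    for s in range(0, len(X), batch_size):
        z = model.forward(X[s : s + batch_size], train=False)
        loss, _ = bce_with_logits(z, y[s : s + batch_size], pos_weight)
        k = len(X[s : s + batch_size])
        tot += loss * k
        n += k
    return tot / max(n, 1)


def train(model: SPNet | MLNet, data: LabeledDataset, config: TrainingConfig | None = None):
    """Mini-batch training with per-epoch shuffling and early stopping.

    Returns ``(model, TrainingHistory)``; the model carries the best
    validation-loss weights when early stopping is active (otherwise the
    final-epoch weights).
    """
    config = config or TrainingConfig()
    config.validate()
    if model.variant != data.variant:
        raise ConsistencyError("model variant does not match dataset variant")
    if model.n_tf != data.n_tf:
        raise ConsistencyError("model n_tf does not match dataset")
    rng = np.random.default_rng(config.seed)

    grns = np.unique(data.grn_index)
    n_val = int(round(config.val_fraction * len(grns)))
    val_grns = set(rng.choice(grns, size=n_val, replace=False).tolist()) if n_val else set()
    is_val = np.isin(data.grn_index, list(val_grns))
    Xtr, ytr = data.X[~is_val], data.y[~is_val]
    Xva, yva = data.X[is_val], data.y[is_val]

    opt = Adam(model.parameters(), lr=config.learning_rate, weight_decay=config.weight_decay)
    hist = TrainingHistory()
    best = (np.inf, None, -1)
    bad_epochs = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(Xtr))
        run, seen = 0.0, 0
        for s in range(0, len(order), config.batch_size):
            idx = order[s : s + config.batch_size]
            z = model.forward(Xtr[idx], train=True)
            loss, dz = bce_with_logits(z, ytr[idx], config.pos_weight)
            if not np.isfinite(loss):
                raise ConsistencyError(f"training loss diverged (epoch {epoch})")
            opt.step(model.backward(dz))
            run += loss * len(idx)
            seen += len(idx)
        train_loss = run / seen
        val_loss = _epoch_loss(model, Xva, yva, config.pos_weight) if len(Xva) else np.nan
        hist.epoch.append(epoch)
        hist.train_loss.append(train_loss)
        hist.val_loss.append(val_loss)
        if len(Xva) and config.patience:
            if val_loss < best[0] - 1e-12:
                best = (val_loss, model.state_dict(), epoch)
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs >= config.patience:
                    break
    if best[1] is not None:
        model.load_state_dict(best[1])
        hist.best_epoch = best[2]
    else:
        hist.best_epoch = hist.epoch[-1] if hist.epoch else -1
    return model, hist
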