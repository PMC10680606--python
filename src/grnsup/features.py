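"""Normalization and pairwise co-expression featurization.

The classifier never sees raw expression.  Each row is Box-Cox transformed
(row-specific maximum-likelihood exponent) and z-scored, and five pairwise
statistics are computed across conditions for every TF-TF and TF-gene pair:
sample covariance, Pearson and Spearman correlation, discrete mutual
information (equal-width binning, natural log) and the entry of the
ridge-regularized precision matrix ``(Sigma + eps*I)^-1``.  The five values
per pair, in that fixed column order, form the rows of a model input.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

from .errors import ConsistencyError, ParameterError
from .network import ExpressionMatrix

FEATURE_NAMES = ("covariance", "pearson", "spearman", "mi", "precision")
ROLE_TF_GENE = 0
ROLE_TF_TF = 1

#: minimum value after the global positivity shift
SHIFT_TARGET = 1e-6


@dataclass
class FeaturizationParams:
    """Settings that must travel with a trained model checkpoint."""

    eps: float = 1e-3  # ridge constant in the precision matrix
    mi_bins: int | None = None  # None -> max(2, floor(sqrt(m)))
    feature_mask: tuple[int, int, int, int, int] = (1, 1, 1, 1, 1)

    def resolve_bins(self, m: int) -> int:
        if self.mi_bins is not None:
            if self.mi_bins < 2:
                raise ParameterError("mi_bins must be >= 2")
            return self.mi_bins
        return max(2, int(np.floor(np.sqrt(m))))


@dataclass
class PairStatTensor:
    """Five symmetric N x N statistics for one target gene's context.

    Row/column order: the candidate TFs in their fixed order, then the target
    gene at index ``N - 1``.
    """

    cov: np.ndarray
    pearson: np.ndarray
    spearman: np.ndarray
    mi: np.ndarray
    precision: np.ndarray
    ids: list[str]
    eps: float

    @property
    def n_tf(self) -> int:
        return len(self.ids) - 1

    def stacked(self) -> np.ndarray:
        """(N, N, 5) array in the fixed feature order."""
        return np.stack([self.cov, self.pearson, self.spearman, self.mi, self.precision], axis=-1)


@dataclass
class ModelInput:
    """One classifier input: ``n_pairs`` rows of five pairwise features."""

    X: np.ndarray  # (n_pairs, 5)
    roles: np.ndarray  # ROLE_TF_GENE / ROLE_TF_TF per row
    pair_ids: list[tuple[str, str]]
    variant: str  # "sp" | "ml"


# ------------------------------------------------------------------- normalize
def _boxcox_z_row(row: np.ndarray) -> np.ndarray:
    if np.ptp(row) == 0:  # constant row: transform undefined, map to zeros
        return np.zeros_like(row)
    t, _ = sps.boxcox(row)
    sd = t.std()
    if sd == 0:
        return np.zeros_like(t)
    return (t - t.mean()) / sd


def normalize(expr: ExpressionMatrix | np.ndarray):
    """Global positivity shift, per-row Box-Cox (MLE lambda), per-row z-score.

    If any entry is <= 0 the whole matrix is shifted by one constant so the
    minimum becomes ``SHIFT_TARGET``; strictly positive input is left
    unshifted.  Constant rows (possible after heavy dropout) come out as
    all-zero rows.  Requires at least 3 conditions.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else np.asarray(expr, dtype=float)
    if values.shape[1] < 3:
        raise ParameterError("normalization requires at least 3 conditions")
    vmin = values.min()
    shifted = values if vmin > 0 else values + (SHIFT_TARGET - vmin)
    out = np.vstack([_boxcox_z_row(shifted[i]) for i in range(shifted.shape[0])])
    if isinstance(expr, ExpressionMatrix):
        return ExpressionMatrix(out, list(expr.row_ids), list(expr.layers), list(expr.condition_ids))
    return out


# ------------------------------------------------------------------ statistics
def mutual_information(x: np.ndarray, y: np.ndarray, mi_bins: int) -> float:
    """Plug-in discrete MI of two vectors on an equal-width grid (natural log)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if mi_bins < 2:
        raise ParameterError("mi_bins must be >= 2")
    if x.shape != y.shape or x.size < 3:
        raise ParameterError("vectors must have equal length >= 3")
    bx = _equal_width_bins(x, mi_bins)
    by = _equal_width_bins(y, mi_bins)
    joint = np.bincount(bx * mi_bins + by, minlength=mi_bins * mi_bins).reshape(mi_bins, mi_bins)
    return _mi_from_joint(joint)


def _equal_width_bins(v: np.ndarray, bins: int) -> np.ndarray:
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros(v.size, dtype=np.int64)
    idx = np.floor((v - lo) / (hi - lo) * bins).astype(np.int64)
    return np.minimum(idx, bins - 1)


def _mi_from_joint(joint: np.ndarray) -> float:
    n = joint.sum()
    p = joint / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log(p / (px * py))
    return float(np.nansum(terms))


def _corr_with_constant_rule(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(pearson, spearman) with constant-vector correlations defined as 0, diagonal 1."""
    const = np.ptp(X, axis=1) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        pear = np.corrcoef(X)
        ranks = np.apply_along_axis(sps.rankdata, 1, X)
        spear = np.corrcoef(ranks)
    for M in (pear, spear):
        M[const, :] = 0.0
        M[:, const] = 0.0
        np.fill_diagonal(M, 1.0)
        np.nan_to_num(M, copy=False)
    return pear, spear


def _mi_matrix(X: np.ndarray, bins: int) -> np.ndarray:
    n = X.shape[0]
    b = np.vstack([_equal_width_bins(X[i], bins) for i in range(n)])
    M = np.zeros((n, n))
    for i in range(n):
        joint_ii = np.bincount(b[i] * bins + b[i], minlength=bins * bins).reshape(bins, bins)
        M[i, i] = _mi_from_joint(joint_ii)
        for j in range(i + 1, n):
            joint = np.bincount(b[i] * bins + b[j], minlength=bins * bins).reshape(bins, bins)
            M[i, j] = M[j, i] = _mi_from_joint(joint)
    return M


def _pair_stats_from_rows(X: np.ndarray, ids: list[str], eps: float, bins: int) -> PairStatTensor:
    cov = np.cov(X, ddof=1)
    pear, spear = _corr_with_constant_rule(X)
    mi = _mi_matrix(X, bins)
    prec = np.linalg.inv(cov + eps * np.eye(len(ids)))
    if not np.isfinite(prec).all():
        raise ConsistencyError("precision matrix is not finite")
    return PairStatTensor(cov, pear, spear, mi, prec, ids, eps)


def pair_stats(
    norm: ExpressionMatrix,
    tf_rows: list[str],
    gene_row: str,
    eps: float = 1e-3,
    mi_bins: int | None = None,
) -> PairStatTensor:
    """All five pairwise statistics for the (TFs + one gene) context."""
    if norm.m < 3:
        raise ParameterError("need at least 3 conditions")
    params = FeaturizationParams(eps=eps, mi_bins=mi_bins)
    idx = [norm.row_index(r) for r in tf_rows] + [norm.row_index(gene_row)]
    X = norm.values[idx]
    return _pair_stats_from_rows(X, tf_rows + [gene_row], eps, params.resolve_bins(norm.m))


def pair_stats_per_gene(
    norm: ExpressionMatrix,
    tf_rows: list[str],
    gene_rows: list[str],
    eps: float = 1e-3,
    mi_bins: int | None = None,
):
    """Yield ``(gene_row, PairStatTensor)`` for many genes sharing one TF panel.

    Covariance, correlations and MI of the TF-TF block are computed once and
    sliced per gene; the precision matrix is genuinely per-gene (the inverse
    of a submatrix is not a submatrix of the inverse) and is recomputed for
    each gene's (TFs + gene) covariance.
    """
    if norm.m < 3:
        raise ParameterError("need at least 3 conditions")
    bins = FeaturizationParams(eps=eps, mi_bins=mi_bins).resolve_bins(norm.m)
    idx = [norm.row_index(r) for r in tf_rows] + [norm.row_index(g) for g in gene_rows]
    X = norm.values[idx]
    n_tf = len(tf_rows)
    cov = np.cov(X, ddof=1)
    pear, spear = _corr_with_constant_rule(X)
    mi = _mi_matrix(X, bins)
    eye = np.eye(n_tf + 1)
    for gi, gene in enumerate(gene_rows):
        sel = list(range(n_tf)) + [n_tf + gi]
        sub = np.ix_(sel, sel)
        prec = np.linalg.inv(cov[sub] + eps * eye)
        yield gene, PairStatTensor(
            cov[sub], pear[sub], spear[sub], mi[sub], prec, tf_rows + [gene], eps
        )


# -------------------------------------------------------------------- assembly
def assemble_sp(stats: PairStatTensor, tf_i: str, feature_mask=None) -> ModelInput:
    """Input for the single-pair model: row 0 = (tf_i, gene), rows 1.. = (tf_i, tf_j)."""
    ids = stats.ids
    if tf_i not in ids[:-1]:
        raise ConsistencyError(f"{tf_i!r} is not among the candidate TFs")
    i = ids.index(tf_i)
    n_tf = stats.n_tf
    S = stats.stacked()
    X = np.vstack([S[i, n_tf][None, :], S[i, :n_tf]])
    roles = np.full(1 + n_tf, ROLE_TF_TF, dtype=np.int8)
    roles[0] = ROLE_TF_GENE
    pair_ids = [(tf_i, ids[-1])] + [(tf_i, ids[j]) for j in range(n_tf)]
    return ModelInput(_masked(X, feature_mask), roles, pair_ids, "sp")


def assemble_ml(stats: PairStatTensor, feature_mask=None) -> ModelInput:
    """Input for the multi-label model: n_TF TF-gene rows, then all TF-TF pairs (j<k)."""
    ids = stats.ids
    n_tf = stats.n_tf
    S = stats.stacked()
    tf_gene = S[:n_tf, n_tf]
    jk = list(combinations(range(n_tf), 2))
    tf_tf = np.array([S[j, k] for j, k in jk]).reshape(len(jk), 5)
    X = np.vstack([tf_gene, tf_tf])
    roles = np.concatenate(
        [np.full(n_tf, ROLE_TF_GENE, dtype=np.int8), np.full(len(jk), ROLE_TF_TF, dtype=np.int8)]
    )
    pair_ids = [(ids[j], ids[-1]) for j in range(n_tf)] + [(ids[j], ids[k]) for j, k in jk]
    return ModelInput(_masked(X, feature_mask), roles, pair_ids, "ml")


def _masked(X: np.ndarray, feature_mask) -> np.ndarray:
    if feature_mask is None:
        return X
    mask = np.asarray(feature_mask, dtype=float)
    if mask.shape != (5,):
        raise ParameterError("feature mask must have 5 entries")
    return X * mask[None, :]
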