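"""Ridge-regression mapping from structural edges to criticality indexes.

Subject connectomes are vectorized into upper-triangular edge vectors; a
per-training-fold PCA (components retaining 95% of variance) reduces
dimensionality; ridge weights are fit in closed form with the regularization
strength tuned by inner leave-one-out error; the outer leave-one-out loop
yields per-subject predictions, a printed-form R-squared, a permutation
p-value, and fold-averaged consensus edge weights back-projected through the
PCA basis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from neurocrit.synthetic import Parcellation

__all__ = [
    "EdgeVector",
    "RidgeModel",
    "PredictiveMap",
    "edge_vectorize",
    "edge_matrix",
    "ridge_closed_form",
    "ridge_loocv",
    "r_squared_printed",
    "permutation_pvalue",
    "consensus_map",
    "network_averages",
]

DEFAULT_LAMBDAS = np.logspace(-5, 5, 11)


@dataclass
class EdgeVector:
    """Upper-triangular off-diagonal entries in fixed row-major pair order."""

    values: np.ndarray
    pair_index: np.ndarray   # (E, 2) int, i < j
    n_nodes: int


@dataclass
class RidgeModel:
    lam: float
    weights: np.ndarray              # in PC space
    components: np.ndarray           # (k, E) PCA basis rows
    explained_variance_ratio: np.ndarray
    feature_mean: np.ndarray         # edge-space centering
    score_mean: np.ndarray
    score_sd: np.ndarray
    y_mean: float
    y_sd: float

    def edge_weights(self) -> np.ndarray:
        """Back-project PC-space weights to edge space (outcome scale)."""
        return self.y_sd * (self.weights / self.score_sd) @ self.components

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = (np.atleast_2d(X) - self.feature_mean) @ self.components.T
        z = (scores - self.score_mean) / self.score_sd
        return z @ self.weights * self.y_sd + self.y_mean


@dataclass
class PredictiveMap:
    r_squared: float
    consensus_edge_weights: np.ndarray
    permutation_p: float = float("nan")
    reliability_mask: Optional[np.ndarray] = None
    network_avg: Optional[pd.DataFrame] = None
    top_edges: Optional[pd.DataFrame] = None
    fold_lambdas: Optional[np.ndarray] = None
    predictions: Optional[np.ndarray] = None


def edge_vectorize(W: np.ndarray, atol: float = 1e-10) -> EdgeVector:
    """Vectorize a symmetric matrix into its upper-triangular edge values."""
    W = np.asarray(W)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(W, W.T, atol=atol):
        raise ValueError("matrix is asymmetric beyond tolerance")
    n = W.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    return EdgeVector(
        values=W[iu, ju].copy(),
        pair_index=np.column_stack([iu, ju]),
        n_nodes=n,
    )


def edge_matrix(values: np.ndarray, n_nodes: int) -> np.ndarray:
    """Back-project an edge vector to a symmetric zero-diagonal matrix."""
    values = np.asarray(values)
    iu, ju = np.triu_indices(n_nodes, k=1)
    if values.size != iu.size:
        raise ValueError("edge vector length does not match n_nodes")
    M = np.zeros((n_nodes, n_nodes), dtype=values.dtype)
    M[iu, ju] = values
    M[ju, iu] = values
    return M


def ridge_closed_form(X: np.ndarray, Y: np.ndarray, lam: float) -> np.ndarray:
    """Closed-form ridge solution W = (X'X + lam*I)^-1 X'Y."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    G = X.T @ X + lam * np.eye(X.shape[1])
    if lam == 0.0 and np.linalg.matrix_rank(G) < X.shape[1]:
        raise np.linalg.LinAlgError(
            "X'X is singular at lambda = 0; use lambda > 0"
        )
    return np.linalg.solve(G, X.T @ Y)


def r_squared_printed(
    Y: np.ndarray, Y_pred: np.ndarray, predicted_mean: bool = True
) -> float:
    """Coefficient of determination with the denominator centered on the
    mean of the *predictions* (printed form); set ``predicted_mean=False``
    for the conventional observed-mean centering."""
    Y = np.asarray(Y, dtype=float)
    Y_pred = np.asarray(Y_pred, dtype=float)
    if Y.shape != Y_pred.shape or Y.size < 2:
        raise ValueError("need equal-length vectors with >= 2 entries")
    center = Y_pred.mean() if predicted_mean else Y.mean()
    denom = ((Y - center) ** 2).sum()
    if denom == 0.0:
        return float("nan")
    return float(1.0 - ((Y - Y_pred) ** 2).sum() / denom)


def _pca_fit(X: np.ndarray, var_frac: float):
    """Thin-SVD PCA keeping components that explain >= var_frac of variance."""
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / max(X.shape[0] - 1, 1)
    total = var.sum()
    if total == 0:
        raise ValueError("features have zero variance")
    ratio = var / total
    k = int(np.searchsorted(np.cumsum(ratio), var_frac) + 1)
    k = min(k, len(s))
    return mean, Vt[:k], ratio[:k]


def _loo_mse(Z: np.ndarray, y: np.ndarray, lam: float) -> float:
    """Exact leave-one-out MSE of ridge on standardized scores via hat matrix."""
    n, k = Z.shape
    G = Z.T @ Z + lam * np.eye(k)
    Hinv = np.linalg.solve(G, Z.T)
    H = Z @ Hinv
    resid = y - H @ y
    denom = 1.0 - np.diag(H)
    denom = np.where(np.abs(denom) < 1e-12, 1e-12, denom)
    return float(((resid / denom) ** 2).mean())


def _fit_fold(
    Xtr: np.ndarray,
    ytr: np.ndarray,
    var_frac: float,
    lambdas: np.ndarray,
) -> RidgeModel:
    mean, components, ratio = _pca_fit(Xtr, var_frac)
    scores = (Xtr - mean) @ components.T
    score_mean = scores.mean(axis=0)
    score_sd = scores.std(axis=0)
    score_sd = np.where(score_sd == 0, 1.0, score_sd)
    Z = (scores - score_mean) / score_sd
    y_mean = float(ytr.mean())
    y_sd = float(ytr.std())
    if y_sd == 0:
        y_sd = 1.0
    yz = (ytr - y_mean) / y_sd
    errs = [_loo_mse(Z, yz, lam) for lam in lambdas]
    lam = float(lambdas[int(np.argmin(errs))])
    w = ridge_closed_form(Z, yz, lam)
    return RidgeModel(
        lam=lam, weights=w, components=components,
        explained_variance_ratio=ratio, feature_mean=mean,
        score_mean=score_mean, score_sd=score_sd, y_mean=y_mean, y_sd=y_sd,
    )


def ridge_loocv(
    features: np.ndarray,
    outcome: np.ndarray,
    var_frac: float = 0.95,
    lambdas: np.ndarray = DEFAULT_LAMBDAS,
) -> tuple[np.ndarray, PredictiveMap]:
    """Leave-one-subject-out PCA + ridge with inner-loop lambda tuning.

    PCA basis, score standardization and outcome standardization are fit on
    each training fold only (no leakage).  Returns per-subject predictions
    and a PredictiveMap carrying the printed-form R-squared and fold-averaged
    consensus edge weights; per-fold edge weights are stored for the
    reliability analysis.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(outcome, dtype=float)
    n = X.shape[0]
    if n < 5:
        raise ValueError("need at least 5 subjects for LOOCV")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("features and outcome must be finite")
    if np.std(y) == 0:
        warnings.warn("constant outcome; R-squared undefined", stacklevel=2)

    preds = np.empty(n)
    fold_weights = np.empty((n, X.shape[1]))
    fold_lams = np.empty(n)
    for i in range(n):
        tr = np.arange(n) != i
        model = _fit_fold(X[tr], y[tr], var_frac, np.asarray(lambdas, float))
        preds[i] = model.predict(X[i])[0]
        fold_weights[i] = model.edge_weights()
        fold_lams[i] = model.lam

    r2 = r_squared_printed(y, preds) if np.std(y) > 0 else float("nan")
    pmap = PredictiveMap(
        r_squared=r2,
        consensus_edge_weights=fold_weights.mean(axis=0),
        fold_lambdas=fold_lams,
        predictions=preds,
    )
    pmap._fold_weights = fold_weights   # kept for consensus_map
    return preds, pmap


def permutation_pvalue(
    observed_r2: float,
    features: np.ndarray,
    outcome: np.ndarray,
    n_perm: int = 10000,
    seed: int = 0,
    var_frac: float = 0.95,
    lambdas: np.ndarray = DEFAULT_LAMBDAS,
    collect_weights: bool = False,
    strict: bool = True,
):
    """Permutation p-value for a LOOCV R-squared.

    The outcome is permuted across subjects ``n_perm`` times and the full
    LOOCV is rerun for each draw.  With ``strict`` (the printed formula)
    p = #(null R2 > observed) / n_perm, so p = 0 is possible; otherwise the
    add-one convention is used.  Returns (p, null_r2s) and additionally the
    stacked null fold weights when ``collect_weights`` is set.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    y = np.asarray(outcome, dtype=float)
    null_r2 = np.empty(n_perm)
    null_weights = [] if collect_weights else None
    for b in range(n_perm):
        yb = rng.permutation(y)
        _, pm = ridge_loocv(features, yb, var_frac=var_frac, lambdas=lambdas)
        null_r2[b] = pm.r_squared
        if collect_weights:
            null_weights.append(pm._fold_weights)
    exceed = int(np.sum(null_r2 > observed_r2))
    p = exceed / n_perm if strict else (exceed + 1) / (n_perm + 1)
    if collect_weights:
        return p, null_r2, np.vstack(null_weights)
    return p, null_r2


def network_averages(
    edge_weights: np.ndarray, parcellation: Parcellation
) -> pd.DataFrame:
    """Average back-projected weight over all ordered node pairs of each
    resting-state-network pair: <W>_{X,Y} = sum_{i in X, j in Y} W_ij / (N_X N_Y)."""
    M = edge_matrix(edge_weights, parcellation.n_nodes)
    nets = sorted(set(parcellation.network))
    idx = {net: np.flatnonzero(parcellation.network == net) for net in nets}
    out = pd.DataFrame(0.0, index=nets, columns=nets)
    for a in nets:
        for b in nets:
            block = M[np.ix_(idx[a], idx[b])]
            out.loc[a, b] = block.sum() / (len(idx[a]) * len(idx[b]))
    return out


def consensus_map(
    fold_weights: np.ndarray,
    null_weights: Optional[np.ndarray],
    parcellation: Parcellation,
    fdr_alpha: float = 0.05,
    top_k: int = 200,
    r_squared: float = float("nan"),
    permutation_p: float = float("nan"),
) -> PredictiveMap:
    """Fold-averaged consensus weights with FDR reliability and network averages.

    Each edge's fold-weight distribution is compared against the pooled null
    distribution (from the permutation models) with a Welch t-test; the
    resulting p-values are Benjamini-Hochberg corrected at ``fdr_alpha``.
    """
    fold_weights = np.asarray(fold_weights, dtype=float)
    consensus = fold_weights.mean(axis=0)

    mask = None
    if null_weights is None:
        warnings.warn(
            "no null weight distributions; reliability mask omitted", stacklevel=2
        )
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            t = stats.ttest_ind(
                fold_weights, np.asarray(null_weights, float),
                axis=0, equal_var=False,
            )
        pvals = np.where(np.isfinite(t.pvalue), t.pvalue, 1.0)
        padj = stats.false_discovery_control(pvals)
        mask = padj < fdr_alpha

    iu, ju = np.triu_indices(parcellation.n_nodes, k=1)
    order = np.argsort(-np.abs(consensus))[:top_k]
    top = pd.DataFrame(
        {
            "i": iu[order],
            "j": ju[order],
            "weight": consensus[order],
            "reliable": mask[order] if mask is not None else False,
        }
    )
    return PredictiveMap(
        r_squared=r_squared,
        permutation_p=permutation_p,
        consensus_edge_weights=consensus,
        reliability_mask=mask,
        network_avg=network_averages(consensus, parcellation),
        top_edges=top,
    )
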