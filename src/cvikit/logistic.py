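"""Ridge-stabilized logistic regression with batched leave-pair-out refits.

The evaluation layer needs tens of thousands of logistic refits (one per
held-out positive-negative pair), so the Newton solver here is vectorized
over the pairs: all refits share the design matrix and differ only in a 0/1
case-weight vector. A tiny ridge penalty (default 1e-8, applied to all
coefficients of the standardized model, intercept included) keeps the
optimum finite and unique under perfect separation without materially
changing rankings.

Features are z-scored with cohort-level mean/sd before fitting. Maximum-
likelihood logistic scores are equivariant under affine feature transforms,
so with a negligible ridge this choice does not alter held-out score
orderings; it fixes the scale on which the ridge acts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LogisticScorer", "fit_logistic_array", "lpocv_pair_scores"]

_MAX_STEP = 5.0  # Newton trust region (inf-norm) on the standardized scale


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


@dataclass(frozen=True)
class LogisticScorer:
    """Fitted logistic model: linear risk score on standardized features."""

    beta: np.ndarray  # (d+1,) intercept first, standardized scale
    mean: np.ndarray
    scale: np.ndarray
    n_iter: int

    def decision(self, X: np.ndarray) -> np.ndarray:
        """Linear predictor (log-odds) for raw feature rows X (n, d)."""
        Xs = (np.asarray(X, dtype=float) - self.mean) / self.scale
        return self.beta[0] + Xs @ self.beta[1:]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return _sigmoid(self.decision(X))


def _standardize(X: np.ndarray, standardize: bool):
    if not standardize:
        return np.zeros(X.shape[1]), np.ones(X.shape[1])
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0  # constant columns stay constant (zero after centering)
    return mean, scale


def fit_logistic_array(
    X: np.ndarray,
    y: np.ndarray,
    ridge: float = 1e-8,
    standardize: bool = True,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> LogisticScorer:
    """Penalized maximum-likelihood logistic fit (Newton with trust region).

    Minimizes ``-loglik + (ridge/2) * ||beta||^2`` on z-scored features.
    Deterministic given the data. Raises if only one class is present.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n, d) with matching y")
    if ridge < 0:
        raise ValueError("ridge must be non-negative")
    classes = np.unique(y)
    if not np.all(np.isin(classes, [0.0, 1.0])) or classes.size < 2:
        raise ValueError("training data must contain both classes (0 and 1)")
    mean, scale = _standardize(X, standardize)
    Z = np.column_stack([np.ones(len(y)), (X - mean) / scale])
    d = Z.shape[1]
    beta = np.zeros(d)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = Z @ beta
        mu = _sigmoid(eta)
        grad = Z.T @ (mu - y) + ridge * beta
        if np.max(np.abs(grad)) < tol:
            break
        W = mu * (1.0 - mu)
        H = (Z * W[:, None]).T @ Z + ridge * np.eye(d)
        step = np.linalg.solve(H, grad)
        nrm = np.max(np.abs(step))
        if nrm > _MAX_STEP:
            step *= _MAX_STEP / nrm
        beta = beta - step
    return LogisticScorer(beta=beta, mean=mean, scale=scale, n_iter=n_iter)


def lpocv_pair_scores(
    X: np.ndarray,
    y: np.ndarray,
    ridge: float = 1e-8,
    standardize: bool = True,
    tol: float = 1e-8,
    max_iter: int = 200,
    chunk: int = 8192,
):
    """Held-out scores for every (positive, negative) pair.

    For each of the n_pos*n_neg pairs the model is refit on the remaining
    n-2 records (batched Newton, warm-started at the full-data fit) and the
    two held-out records are scored. Returns ``(pos_idx, neg_idx, s_pos,
    s_neg)`` flattened over pairs.

    Raises if fewer than two records of either class are available (every
    leave-pair-out training set would be single-class).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need at least one record per class")
    if pos.size < 2 or neg.size < 2:
        raise ValueError("leave-pair-out training sets would be single-class")
    full = fit_logistic_array(X, y, ridge=ridge, standardize=standardize, tol=tol)
    mean, scale = full.mean, full.scale
    Z = np.column_stack([np.ones(len(y)), (X - mean) / scale])
    n, d = Z.shape

    pi, ni = np.meshgrid(pos, neg, indexing="ij")
    pi, ni = pi.ravel(), ni.ravel()
    P = pi.size
    s_pos = np.empty(P)
    s_neg = np.empty(P)
    Zout = np.einsum("ni,nj->nij", Z, Z).reshape(n, d * d)
    eye = ridge * np.eye(d).ravel()

    for lo in range(0, P, chunk):
        hi = min(lo + chunk, P)
        idx_p, idx_n = pi[lo:hi], ni[lo:hi]
        m = hi - lo
        w = np.ones((m, n))
        rows = np.arange(m)
        w[rows, idx_p] = 0.0
        w[rows, idx_n] = 0.0
        beta = np.tile(full.beta, (m, 1))
        active = np.arange(m)
        for _ in range(max_iter):
            eta = beta[active] @ Z.T  # (act, n)
            mu = _sigmoid(eta)
            grad = ((mu - y) * w[active]) @ Z + ridge * beta[active]
            gmax = np.max(np.abs(grad), axis=1)
            conv = gmax < tol
            if np.all(conv):
                break
            keep = ~conv
            active = active[keep]
            grad = grad[keep]
            r = (mu * (1.0 - mu))[keep] * w[active]
            H = (r @ Zout).reshape(-1, d, d) + eye.reshape(d, d)
            step = np.linalg.solve(H, grad[..., None])[..., 0]
            nrm = np.max(np.abs(step), axis=1, keepdims=True)
            fac = np.minimum(1.0, _MAX_STEP / np.maximum(nrm, 1e-300))
            beta[active] = beta[active] - step * fac
            if active.size == 0:
                break
        s_pos[lo:hi] = np.einsum("md,md->m", beta, Z[idx_p])
        s_neg[lo:hi] = np.einsum("md,md->m", beta, Z[idx_n])
    return pi, ni, s_pos, s_neg
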