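"""Independent oracles used by the test suite.

Each oracle recomputes a quantity by a route independent of the package
implementation: scipy's trust-region optimizer for penalized logistic fits,
an explicit per-pair loop for leave-pair-out AUC, a radial finite-difference
discretization of the axisymmetric elasticity ODE, exhaustive threshold
enumeration for Youden's J, and a hand risk-set enumeration for the
log-rank test.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.optimize import minimize


def _sig(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def logistic_fit_oracle(X, y, ridge=1e-8):
    """Penalized-NLL logistic fit via scipy trust-exact.

    Same model convention as the package: features z-scored with full-data
    mean/sd, intercept first, ridge on all coefficients.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    m, s = X.mean(0), X.std(0)
    s = np.where(s == 0, 1.0, s)
    Z = np.column_stack([np.ones(len(y)), (X - m) / s])
    d = Z.shape[1]

    def f(b):
        eta = Z @ b
        return np.sum(np.logaddexp(0, eta) - y * eta) + 0.5 * ridge * np.sum(b**2)

    def g(b):
        return Z.T @ (_sig(Z @ b) - y) + ridge * b

    def h(b):
        mu = _sig(Z @ b)
        return (Z * (mu * (1 - mu))[:, None]).T @ Z + ridge * np.eye(d)

    res = minimize(f, np.zeros(d), jac=g, hess=h, method="trust-exact",
                   options={"gtol": 1e-12, "maxiter": 10000})
    return res.x, m, s


def lpocv_auc_oracle(X, y, ridge=1e-8):
    """Brute-force leave-pair-out AUC: explicit loop over all pos x neg pairs."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    m, s = X.mean(0), X.std(0)
    s = np.where(s == 0, 1.0, s)
    credits = []
    for i in pos:
        for j in neg:
            mask = np.ones(len(y), bool)
            mask[[i, j]] = False
            b, _, _ = _fit_on(X[mask], y[mask], m, s, ridge)
            si = b[0] + (X[i] - m) / s @ b[1:]
            sj = b[0] + (X[j] - m) / s @ b[1:]
            credits.append(1.0 if si > sj else (0.5 if si == sj else 0.0))
    return float(np.mean(credits))


def _fit_on(X, y, m, s, ridge):
    Z = np.column_stack([np.ones(len(y)), (X - m) / s])
    d = Z.shape[1]

    def f(b):
        eta = Z @ b
        return np.sum(np.logaddexp(0, eta) - y * eta) + 0.5 * ridge * np.sum(b**2)

    def g(b):
        return Z.T @ (_sig(Z @ b) - y) + ridge * b

    def h(b):
        mu = _sig(Z @ b)
        return (Z * (mu * (1 - mu))[:, None]).T @ Z + ridge * np.eye(d)

    res = minimize(f, np.zeros(d), jac=g, hess=h, method="trust-exact",
                   options={"gtol": 1e-12, "maxiter": 10000})
    return res.x, m, s


def fd_cap_hoop_oracle(a, b, Ec, nu_c, h_mm, Ep, nu_p, p, outer_bc="free",
                       n_cap=3000, n_plaque=7000):
    """Radial finite-difference solution of the two-layer plane-strain ODE.

    Discretizes u'' + u'/r - u/r^2 = 0 per layer on ~1e4 nodes with
    second-order one-sided stencils for the pressure, interface-flux and
    outer boundary conditions; returns the thickness-averaged cap hoop
    stress.
    """

    def lame(E, nu):
        return E * nu / ((1 + nu) * (1 - 2 * nu)), E / (2 * (1 + nu))

    rm = a + h_mm
    lam1, G1 = lame(Ec, nu_c)
    lam2, G2 = lame(Ep, nu_p)
    r1 = np.linspace(a, rm, n_cap + 1)
    r2 = np.linspace(rm, b, n_plaque + 1)
    r = np.concatenate([r1, r2[1:]])
    n = len(r)
    i_if = n_cap
    d1, d2 = r1[1] - r1[0], r2[1] - r2[0]
    A = sp.lil_matrix((n, n))
    rhs = np.zeros(n)

    def interior(i, d):
        A[i, i - 1] = 1 / d**2 - 1 / (2 * d * r[i])
        A[i, i] = -2 / d**2 - 1 / r[i] ** 2
        A[i, i + 1] = 1 / d**2 + 1 / (2 * d * r[i])

    for i in range(1, i_if):
        interior(i, d1)
    for i in range(i_if + 1, n - 1):
        interior(i, d2)
    cL, cR = lam1 + 2 * G1, lam2 + 2 * G2
    # sigma_rr(a) = -p
    A[0, 0] = cL * (-3) / (2 * d1) + lam1 / a
    A[0, 1] = cL * 4 / (2 * d1)
    A[0, 2] = cL * (-1) / (2 * d1)
    rhs[0] = -p
    # radial-traction continuity at the interface
    A[i_if, i_if - 2] = cL / (2 * d1)
    A[i_if, i_if - 1] = cL * (-4) / (2 * d1)
    A[i_if, i_if] = cL * 3 / (2 * d1) + lam1 / rm - (cR * (-3) / (2 * d2) + lam2 / rm)
    A[i_if, i_if + 1] = -cR * 4 / (2 * d2)
    A[i_if, i_if + 2] = cR / (2 * d2)
    if outer_bc == "free":
        A[n - 1, n - 3] = cR / (2 * d2)
        A[n - 1, n - 2] = cR * (-4) / (2 * d2)
        A[n - 1, n - 1] = cR * 3 / (2 * d2) + lam2 / b
    else:  # clamped
        A[n - 1, n - 1] = 1.0
    u = spla.spsolve(A.tocsr(), rhs)
    rc, uc = r[: i_if + 1], u[: i_if + 1]
    du = np.gradient(uc, rc)
    sig_theta = lam1 * du + (lam1 + 2 * G1) * uc / rc
    return float(np.trapezoid(sig_theta, rc) / h_mm)


def lame_avg_hoop_sublayer(a, b, lo, hi, p):
    """Closed-form average of the single-layer Lamé hoop stress over [lo, hi].

    sigma_tt(r) = p a^2/(b^2-a^2) (1 + b^2/r^2); its mean over the sub-layer
    [lo, hi] is c (1 + b^2/(lo*hi)) with c = p a^2/(b^2-a^2).
    """
    c = p * a**2 / (b**2 - a**2)
    return c * (1 + b**2 / (lo * hi))


def youden_oracle(scores, labels):
    """Exhaustive enumeration of every candidate threshold (all midpoints)."""
    scores = np.asarray(scores, float)
    y = np.asarray(labels, float)
    uniq = np.unique(scores)
    cands = 0.5 * (uniq[:-1] + uniq[1:])
    best_j, best_t, best = -np.inf, np.nan, None
    for t in cands:
        pred = scores >= t
        sens = np.sum(pred & (y == 1)) / y.sum()
        spec = np.sum(~pred & (y == 0)) / (1 - y).sum()
        j = sens + spec - 1
        if j > best_j + 1e-15:
            best_j, best_t, best = j, t, (sens, spec)
    return best_t, best[0], best[1], best_j


def logrank_oracle(times, events, group):
    """Two-group log-rank statistic by explicit risk-set enumeration."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    group = np.asarray(group, bool)
    obs1 = 0.0
    exp1 = 0.0
    var = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & group).sum()
        d = (events & (times == t)).sum()
        d1 = (events & (times == t) & group).sum()
        obs1 += d1
        exp1 += d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = (obs1 - exp1) ** 2 / var
    return float(chi2), float(obs1), float(exp1)
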