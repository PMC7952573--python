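"""Restricted maximum likelihood for the gBLUP variance model.

Estimates (sigma_g^2, sigma_e^2) under

    y = X beta + g + eps,   var(y) = V = A sigma_g^2 + I sigma_e^2,

by average-information REML: one EM-REML step to move off the starting
values, then Newton-type updates theta <- theta + AI^{-1} score with

    score_i = -1/2 [tr(P V_i) - y' P V_i P y],
    AI_ij   =  1/2  y' P V_i P V_j P y,          V_1 = A, V_2 = I,

where P = V^{-1} - V^{-1} X (X' V^{-1} X)^{-1} X' V^{-1}. A single
eigendecomposition A = U D U' is taken up front; rotating y and X by U
diagonalizes V, so every iteration costs O(n p^2) rather than O(n^3).
Components are constrained to >= 1e-6 var(y) (truncate and continue).
An AI step that would lower the restricted likelihood falls back to EM,
which never decreases it. SE(h^2) comes from the inverse AI matrix by
the delta method.

The restricted log-likelihood is reported up to the usual additive
constant as lR = -1/2 [log|V| + log|X'V^{-1}X| - log|X'X| + y'Py]; the
-log|X'X| term makes lR invariant to reparameterization of the
fixed-effect basis (X -> XT shifts both determinants by 2 log|det T|).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh


class UnidentifiableModelError(ValueError):
    """A = c I makes (sigma_g^2, sigma_e^2) unidentifiable."""


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    h2: float
    se_h2: float
    loglik: float
    n_iter: int
    converged: bool
    se_sigma_g2: float = float("nan")
    se_sigma_e2: float = float("nan")


def _prepare(y, x, a, eig=None):
    y = np.asarray(y, dtype=np.float64).ravel()
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 1:
        x = x[:, None]
    n = y.size
    if x.shape[0] != n:
        raise ValueError("X and y disagree on n")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("fixed-effect design X is rank deficient")
    amat = a.a if hasattr(a, "a") else np.asarray(a, dtype=np.float64)
    if amat.shape != (n, n):
        raise ValueError("GRM dimension does not match y")
    if eig is None:
        d, u = eigh(amat)
    else:
        d, u = eig
    return u.T @ y, u.T @ x, np.maximum(d, 0.0), n, x.shape[1]


class _RotatedREML:
    """REML quantities in the eigenbasis of A (V is diagonal there)."""

    def __init__(self, yt, xt, d):
        self.yt, self.xt, self.d = yt, xt, d
        _, self.logdet_xx = np.linalg.slogdet(xt.T @ xt)

    def core(self, sg, se):
        v = sg * self.d + se
        vinv = 1.0 / v
        xtv = self.xt * vinv[:, None]
        m = self.xt.T @ xtv  # X'V^-1 X
        xvy = xtv.T @ self.yt
        beta = np.linalg.solve(m, xvy)
        py = vinv * (self.yt - self.xt @ beta)
        sign, logdet_m = np.linalg.slogdet(m)
        ll = -0.5 * (np.sum(np.log(v)) + logdet_m - self.logdet_xx + self.yt @ py)
        return v, vinv, m, py, ll

    def pvec(self, z, vinv, m):
        """Apply P to a vector (rotated basis)."""
        xtv = self.xt * vinv[:, None]
        return vinv * z - xtv @ np.linalg.solve(m, xtv.T @ z)


def reml_ai(
    y,
    x,
    a,
    *,
    max_iter: int = 100,
    tol_loglik: float = 1e-4,
    tol_theta: float = 1e-6,
    eig=None,
) -> VarianceComponents:
    """AI-REML fit of var(y) = A sigma_g^2 + I sigma_e^2 with fixed effects X."""
    yt, xt, d, n, p = _prepare(y, x, a, eig=eig)
    if np.ptp(d) < 1e-10 * max(1.0, float(abs(d).max())):
        raise UnidentifiableModelError(
            "GRM eigenvalues are all equal (A proportional to I); "
            "genetic and residual variances cannot be separated"
        )
    rr = _RotatedREML(yt, xt, d)
    vary = float(np.var(np.asarray(y, dtype=np.float64)))
    if vary <= 0:
        raise ValueError("y is constant; variance components undefined")
    floor = 1e-6 * vary
    theta = np.array([0.5 * vary, 0.5 * vary])

    def quantities(theta):
        sg, se = theta
        v, vinv, m, py, ll = rr.core(sg, se)
        xtv = xt * vinv[:, None]
        minv_xtv = np.linalg.solve(m, xtv.T)
        # tr(P W) for diagonal W: sum(vinv*w) - sum over elements of
        # (M^-1 X'V^-1) .* (W V^-1 X)'
        def tr_pw(w):
            return float((vinv * w).sum() - np.einsum("ji,ij->", minv_xtv, (w * vinv)[:, None] * xt))
        tr_pa = tr_pw(d)
        tr_pi = tr_pw(np.ones_like(d))
        aq = d * py
        score = np.array(
            [-0.5 * (tr_pa - py @ aq), -0.5 * (tr_pi - py @ py)]
        )
        p_aq = rr.pvec(aq, vinv, m)
        p_q = rr.pvec(py, vinv, m)
        ai = 0.5 * np.array(
            [
                [aq @ p_aq, aq @ p_q],
                [aq @ p_q, py @ p_q],
            ]
        )
        return ll, score, ai, py

    ll, score, ai, py = quantities(theta)
    converged = False
    n_iter = 0
    ai_final = ai
    for it in range(1, max_iter + 1):
        n_iter = it
        if it == 1:
            # EM-REML step: theta_i += theta_i^2/n (y'P V_i P y - tr(P V_i))
            # = theta_i + (2 theta_i^2 / n) score_i; never decreases lR.
            new = theta + (2.0 * theta**2 / n) * score
        else:
            try:
                delta = np.linalg.solve(ai, score)
            except np.linalg.LinAlgError:
                delta = (2.0 * theta**2 / n) * score
            new = theta + delta
        new = np.maximum(new, floor)
        ll_new, score_new, ai_new, py = quantities(new)
        # Step-halve toward the current point if the AI step overshot.
        halvings = 0
        while ll_new < ll - 1e-10 and halvings < 20:
            new = np.maximum(theta + 0.5 ** (halvings + 1) * (new - theta), floor)
            ll_new, score_new, ai_new, py = quantities(new)
            halvings += 1
        dll = ll_new - ll
        dtheta = np.abs(new - theta).max()
        theta, ll, score, ai = new, ll_new, score_new, ai_new
        ai_final = ai
        if abs(dll) < tol_loglik and dtheta < tol_theta * vary:
            converged = True
            break

    sg, se = theta
    tot = sg + se
    h2 = float(sg / tot)
    try:
        cov = np.linalg.inv(ai_final)
        grad = np.array([se, -sg]) / tot**2
        se_h2 = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
        se_sg = float(np.sqrt(max(cov[0, 0], 0.0)))
        se_se = float(np.sqrt(max(cov[1, 1], 0.0)))
    except np.linalg.LinAlgError:
        se_h2 = se_sg = se_se = float("nan")
    return VarianceComponents(
        sigma_g2=float(sg),
        sigma_e2=float(se),
        h2=h2,
        se_h2=se_h2,
        loglik=float(ll),
        n_iter=n_iter,
        converged=converged,
        se_sigma_g2=se_sg,
        se_sigma_e2=se_se,
    )


def profile_loglik(y, x, a, h2_grid, *, eig=None) -> np.ndarray:
    """Restricted log-likelihood profiled over total variance on an h^2 grid.

    For fixed ratio h2, V0 = h2 A + (1 - h2) I; the total variance has the
    closed-form REML maximizer sigma_tot^2 = y'P0 y / (n - p), giving

        lR(h2) = -1/2 [(n-p) log sigma_tot^2 + log|V0| + log|X'V0^-1 X| + (n-p)],

    on the same additive-constant convention as :func:`reml_ai`. Grid values
    of exactly 1 are clipped just below (V0 may be singular at h2 = 1).
    """
    yt, xt, d, n, p = _prepare(y, x, a, eig=eig)
    rr = _RotatedREML(yt, xt, d)
    out = np.empty(len(h2_grid))
    for i, h2 in enumerate(np.asarray(h2_grid, dtype=np.float64)):
        if not 0.0 <= h2 <= 1.0:
            raise ValueError("h2 grid values must lie in [0, 1]")
        h2 = min(h2, 1.0 - 1e-8)
        v0, vinv, m, p0y, _ = rr.core(h2, 1.0 - h2)
        quad = float(yt @ p0y)
        sig = quad / (n - p)
        sign, logdet_m = np.linalg.slogdet(m)
        out[i] = -0.5 * (
            (n - p) * np.log(sig) + np.sum(np.log(v0)) + logdet_m
            - rr.logdet_xx + (n - p)
        )
    return out
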