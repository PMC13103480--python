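"""Genomic REML (GREML) variance components.

Single-trait heritability uses average-information (AI) REML with EM fallback
steps and step-halving, which guarantees a monotone accepted log-likelihood
sequence. The relationship matrix is eigendecomposed once, so each iteration
is O(n) — cheap enough for cross-validation loops that refit many times.

The bivariate model estimates 2x2 genetic and residual covariance matrices.
It maximizes the exact REML log-likelihood under a log-variance /
atanh-correlation parameterization, which keeps both covariance matrices
positive-semidefinite and bounds the genetic correlation to [-1, 1] by
construction. Standard errors come from the inverse observed information
(finite-difference Hessian) with the delta method for derived quantities.

A reliability gate mirrors common practice for genetic-correlation studies:
a trait enters bivariate analysis only if the standard error of its
heritability does not exceed the estimate itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator

from .genotypes import GRMatrix

__all__ = [
    "VarianceComponents",
    "GeneticCorrelation",
    "GREML",
    "BivariateGREML",
    "greml_single",
    "greml_bivariate",
    "reliability_gate",
]


@dataclass
class VarianceComponents:
    sigma2_G: float
    sigma2_e: float
    h2: float
    se_h2: float
    se_sigma2_G: float
    se_sigma2_e: float
    loglik: float
    converged: bool
    beta: np.ndarray
    at_boundary: bool = False


@dataclass
class GeneticCorrelation:
    sigma_G12: float
    r_g: float
    se_r_g: float
    h2_1: float
    h2_2: float
    se_h2_1: float
    se_h2_2: float
    loglik: float
    converged: bool


def _as_kernel(K) -> np.ndarray:
    return K.values if isinstance(K, GRMatrix) else np.asarray(K, dtype=float)


class GREML(BaseEstimator):
    """Single-trait AI-REML for y = Xb + g + e, g ~ N(0, K sigma2_G).

    Parameters
    ----------
    tol : convergence tolerance on the change in REML log-likelihood.
    max_iter : iteration cap; hitting it flags ``converged_ = False``
        rather than raising.
    var_floor_frac : variance components are constrained to at least this
        fraction of var(y).
    """

    def __init__(self, tol: float = 1e-6, max_iter: int = 200,
                 var_floor_frac: float = 1e-8):
        self.tol = tol
        self.max_iter = max_iter
        self.var_floor_frac = var_floor_frac

    # -- internals ---------------------------------------------------------
    def _quantities(self, theta, S, Xr, yr):
        sg, se = theta
        v = S * sg + se
        if np.any(v <= 0):
            return None
        wi = 1.0 / v
        Xw = Xr * wi[:, None]
        A = Xr.T @ Xw
        sign, logdetA = np.linalg.slogdet(A)
        if sign <= 0:
            return None
        beta = np.linalg.solve(A, Xw.T @ yr)
        r = yr - Xr @ beta
        Py = wi * r
        logl = -0.5 * (np.sum(np.log(v)) + logdetA + r @ Py)
        return dict(v=v, wi=wi, Xw=Xw, A=A, beta=beta, Py=Py, logl=logl)

    def _score_ai(self, q, S, Xr, n):
        wi, Py, A, Xw = q["wi"], q["Py"], q["A"], q["Xw"]
        Ainv = np.linalg.inv(A)
        # tr(P V_i) with V_g = diag(S), V_e = I in the rotated basis
        M_g = Xr.T @ (Xr * (wi**2 * S)[:, None])
        M_e = Xr.T @ (Xr * (wi**2)[:, None])
        trPK = np.sum(S * wi) - np.trace(Ainv @ M_g)
        trPI = np.sum(wi) - np.trace(Ainv @ M_e)
        yPKPy = Py @ (S * Py)
        yPIPy = Py @ Py
        score = np.array([-0.5 * (trPK - yPKPy), -0.5 * (trPI - yPIPy)])

        def P(t):
            return wi * t - Xw @ np.linalg.solve(A, Xw.T @ t)

        t_g, t_e = S * Py, Py
        Pt_g, Pt_e = P(t_g), P(t_e)
        ai = 0.5 * np.array(
            [[t_g @ Pt_g, t_g @ Pt_e], [t_e @ Pt_g, t_e @ Pt_e]]
        )
        return score, ai, np.array([yPKPy - trPK, yPIPy - trPI])

    # -- API ---------------------------------------------------------------
    def fit(self, K, y, X=None, eig=None):
        """Fit; ``eig=(S, U)`` supplies a precomputed eigendecomposition of K
        so replicate loops pay the O(n^3) cost once."""
        y = np.asarray(y, dtype=float)
        n = len(y)
        vy = y.var()
        if vy == 0:
            raise ValueError("phenotype has zero variance")
        if X is None:
            X = np.ones((n, 1))
        X = np.asarray(X, dtype=float)

        if eig is None:
            Km = _as_kernel(K)
            if Km.shape != (n, n):
                raise ValueError("kernel dimension does not match y")
            S, U = np.linalg.eigh(Km)
        else:
            S, U = eig
        S = np.clip(S, 0, None)
        yr, Xr = U.T @ y, U.T @ X
        floor = self.var_floor_frac * vy
        theta = np.array([vy / 2, vy / 2])
        q = self._quantities(theta, S, Xr, yr)
        path = [q["logl"]]
        converged = False
        ai = np.eye(2)
        for it in range(self.max_iter):
            score, ai, em_num = self._score_ai(q, S, Xr, n)
            try:
                delta = np.linalg.solve(ai, score)
                ai_ok = np.all(np.isfinite(delta))
            except np.linalg.LinAlgError:
                ai_ok = False
            if not ai_ok:
                delta = theta**2 * em_num / n  # EM-REML step
            step = 1.0
            accepted = None
            for _ in range(14):
                prop = np.maximum(theta + step * delta, floor)
                qp = self._quantities(prop, S, Xr, yr)
                if qp is not None and qp["logl"] >= q["logl"] - 1e-12:
                    accepted = (prop, qp)
                    break
                step /= 2.0
            if accepted is None:
                # fall back to an EM step, which cannot decrease the likelihood
                prop = np.maximum(theta + theta**2 * em_num / n, floor)
                qp = self._quantities(prop, S, Xr, yr)
                if qp is None or qp["logl"] < q["logl"] - 1e-8:
                    break
                accepted = (prop, qp)
            theta, q = accepted
            path.append(q["logl"])
            if abs(path[-1] - path[-2]) < self.tol:
                converged = True
                break

        sg, se = theta
        score, ai, _ = self._score_ai(q, S, Xr, n)
        try:
            cov = np.linalg.inv(ai)
        except np.linalg.LinAlgError:  # pragma: no cover - degenerate fits
            cov = np.full((2, 2), np.nan)
        total = sg + se
        h2 = sg / total
        grad = np.array([se, -sg]) / total**2
        se_h2 = float(np.sqrt(max(grad @ cov @ grad, 0.0)))

        self.sigma2_g_ = float(sg)
        self.sigma2_e_ = float(se)
        self.h2_ = float(h2)
        self.se_h2_ = se_h2
        self.se_sigma2_ = np.sqrt(np.clip(np.diag(cov), 0, None))
        self.beta_ = q["beta"]
        self.loglik_ = float(q["logl"])
        self.loglik_path_ = np.array(path)
        self.converged_ = converged
        self.n_iter_ = len(path) - 1
        self.at_boundary_ = bool(min(sg, se) <= floor * (1 + 1e-9))
        if not converged:
            warnings.warn("GREML did not converge; result flagged", stacklevel=2)
        return self

    def result(self) -> VarianceComponents:
        return VarianceComponents(
            sigma2_G=self.sigma2_g_,
            sigma2_e=self.sigma2_e_,
            h2=self.h2_,
            se_h2=self.se_h2_,
            se_sigma2_G=float(self.se_sigma2_[0]),
            se_sigma2_e=float(self.se_sigma2_[1]),
            loglik=self.loglik_,
            converged=self.converged_,
            beta=self.beta_,
            at_boundary=self.at_boundary_,
        )


def greml_single(y, fixed_design=None, grm=None, tol=1e-6, max_iter=200):
    """Functional wrapper around :class:`GREML`."""
    est = GREML(tol=tol, max_iter=max_iter).fit(grm, y, X=fixed_design)
    return est.result()


def reliability_gate(h2_estimate: float, h2_sd: float) -> bool:
    """Trait is reliable for correlation analysis iff SD(h2) <= h2."""
    if h2_sd < 0:
        raise ValueError("h2 standard deviation must be non-negative")
    return h2_sd <= h2_estimate


class BivariateGREML(BaseEstimator):
    """Bivariate REML for the genetic correlation between two traits.

    The two traits may be recorded on the same individuals, overlapping
    sets, or disjoint sets (e.g. the same trait in two collections); the
    residual covariance is only estimated where record sets overlap.
    """

    _Z = 7.0  # atanh bound; tanh(7) = 1 - 2e-6

    def __init__(self, max_iter: int = 400, gate: bool = True,
                 tol: float = 1e-8):
        self.max_iter = max_iter
        self.gate = gate
        self.tol = tol

    # -- likelihood (rotated fast path, same individuals) ------------------
    @staticmethod
    def _nll_rotated(theta, S, Y, Xr, estimate_re):
        vg1, vg2 = np.exp(theta[0]), np.exp(theta[1])
        rg = np.tanh(theta[2])
        ve1, ve2 = np.exp(theta[3]), np.exp(theta[4])
        re = np.tanh(theta[5]) if estimate_re else 0.0
        g12 = rg * np.sqrt(vg1 * vg2)
        e12 = re * np.sqrt(ve1 * ve2)
        a = S * vg1 + ve1
        d = S * vg2 + ve2
        b = S * g12 + e12
        det = a * d - b**2
        if np.any(det <= 0) or np.any(a <= 0):
            return np.inf
        ia, id_, ib = d / det, a / det, -b / det
        # X block-diagonal: trait-specific intercepts (rotated ones-vector)
        x = Xr[:, 0]
        XtVX = np.array(
            [[np.sum(x * ia * x), np.sum(x * ib * x)],
             [np.sum(x * ib * x), np.sum(x * id_ * x)]]
        )
        y1, y2 = Y[:, 0], Y[:, 1]
        XtVy = np.array(
            [np.sum(x * (ia * y1 + ib * y2)), np.sum(x * (ib * y1 + id_ * y2))]
        )
        sign, logdetA = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(XtVX, XtVy)
        r1 = y1 - x * beta[0]
        r2 = y2 - x * beta[1]
        quad = np.sum(r1 * (ia * r1 + ib * r2) + r2 * (ib * r1 + id_ * r2))
        return 0.5 * (np.sum(np.log(det)) + logdetA + quad)

    # -- likelihood (general dense path) -----------------------------------
    @staticmethod
    def _nll_dense(theta, K, idx1, idx2, y1, y2, X, overlap, estimate_re):
        vg1, vg2 = np.exp(theta[0]), np.exp(theta[1])
        rg = np.tanh(theta[2])
        ve1, ve2 = np.exp(theta[3]), np.exp(theta[4])
        re = np.tanh(theta[5]) if estimate_re else 0.0
        g12 = rg * np.sqrt(vg1 * vg2)
        e12 = re * np.sqrt(ve1 * ve2)
        n1, n2 = len(idx1), len(idx2)
        V = np.empty((n1 + n2, n1 + n2))
        V[:n1, :n1] = vg1 * K[np.ix_(idx1, idx1)] + ve1 * np.eye(n1)
        V[n1:, n1:] = vg2 * K[np.ix_(idx2, idx2)] + ve2 * np.eye(n2)
        C = g12 * K[np.ix_(idx1, idx2)] + e12 * overlap
        V[:n1, n1:] = C
        V[n1:, :n1] = C.T
        y = np.concatenate([y1, y2])
        try:
            Lc = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return np.inf
        logdetV = 2 * np.sum(np.log(np.diag(Lc)))
        Vi_y = np.linalg.solve(V, y)
        Vi_X = np.linalg.solve(V, X)
        XtVX = X.T @ Vi_X
        sign, logdetA = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(XtVX, X.T @ Vi_y)
        r = y - X @ beta
        quad = r @ np.linalg.solve(V, r)
        return 0.5 * (logdetV + logdetA + quad)

    def fit(self, K, y1, y2, idx1=None, idx2=None, gate_override=None):
        Km = _as_kernel(K)
        y1 = np.asarray(y1, dtype=float)
        y2 = np.asarray(y2, dtype=float)
        idx1 = np.arange(len(y1)) if idx1 is None else np.asarray(idx1, dtype=int)
        idx2 = np.arange(len(y2)) if idx2 is None else np.asarray(idx2, dtype=int)

        uni1 = GREML().fit(Km[np.ix_(idx1, idx1)], y1)
        uni2 = GREML().fit(Km[np.ix_(idx2, idx2)], y2)
        do_gate = self.gate if gate_override is None else not gate_override
        for label, est in (("trait 1", uni1), ("trait 2", uni2)):
            if do_gate and not reliability_gate(est.h2_, est.se_h2_):
                raise ValueError(
                    f"{label} fails the reliability gate: h2={est.h2_:.3f} "
                    f"< SD={est.se_h2_:.3f}; pass gate_override=True to force"
                )

        s1, s2 = y1.std(), y2.std()
        y1s, y2s = y1 / s1, y2 / s2
        same = len(idx1) == len(idx2) and np.array_equal(idx1, idx2)
        estimate_re = same or bool(np.intersect1d(idx1, idx2).size)

        def clip_log(v):
            return np.log(np.clip(v, 1e-6, 1e6))

        x0 = np.array(
            [
                clip_log(max(uni1.h2_, 0.05)),
                clip_log(max(uni2.h2_, 0.05)),
                0.0,
                clip_log(max(1 - uni1.h2_, 0.05)),
                clip_log(max(1 - uni2.h2_, 0.05)),
                0.0,
            ]
        )
        bounds = [(-12, 8)] * 2 + [(-self._Z, self._Z)] + [(-12, 8)] * 2 + [
            (-self._Z, self._Z)
        ]

        if same:
            S, U = np.linalg.eigh(Km[np.ix_(idx1, idx1)])
            S = np.clip(S, 0, None)
            Y = np.column_stack([U.T @ y1s, U.T @ y2s])
            Xr = (U.T @ np.ones(len(idx1)))[:, None]
            nll = lambda th: self._nll_rotated(th, S, Y, Xr, estimate_re)
        else:
            n1, n2 = len(idx1), len(idx2)
            overlap = (idx1[:, None] == idx2[None, :]).astype(float)
            X = np.zeros((n1 + n2, 2))
            X[:n1, 0] = 1.0
            X[n1:, 1] = 1.0
            nll = lambda th: self._nll_dense(
                th, Km, idx1, idx2, y1s, y2s, X, overlap, estimate_re
            )

        res = optimize.minimize(
            nll,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options=dict(maxiter=self.max_iter, ftol=self.tol),
        )
        th = res.x
        vg1, vg2 = np.exp(th[0]), np.exp(th[1])
        rg = float(np.tanh(th[2]))
        ve1, ve2 = np.exp(th[3]), np.exp(th[4])

        # observed information in theta; delta method for derived quantities
        free = [0, 1, 2, 3, 4] + ([5] if estimate_re else [])
        cov_th = _numerical_covariance(nll, th, free)

        def derived(t):
            a1, a2 = np.exp(t[0]), np.exp(t[1])
            b1, b2 = np.exp(t[3]), np.exp(t[4])
            return np.array(
                [np.tanh(t[2]), a1 / (a1 + b1), a2 / (a2 + b2)]
            )

        J = _numerical_jacobian(derived, th, free)
        cov_d = J @ cov_th @ J.T
        se_rg, se_h21, se_h22 = np.sqrt(np.clip(np.diag(cov_d), 0, None))

        self.r_g_ = rg
        self.se_r_g_ = float(se_rg)
        self.sigma_g12_ = float(rg * np.sqrt(vg1 * s1**2 * vg2 * s2**2))
        self.h2_ = (float(vg1 / (vg1 + ve1)), float(vg2 / (vg2 + ve2)))
        self.se_h2_ = (float(se_h21), float(se_h22))
        self.loglik_ = float(-res.fun)
        self.converged_ = bool(res.success)
        self.univariate_ = (uni1.result(), uni2.result())
        return self

    def result(self) -> GeneticCorrelation:
        return GeneticCorrelation(
            sigma_G12=self.sigma_g12_,
            r_g=self.r_g_,
            se_r_g=self.se_r_g_,
            h2_1=self.h2_[0],
            h2_2=self.h2_[1],
            se_h2_1=self.se_h2_[0],
            se_h2_2=self.se_h2_[1],
            loglik=self.loglik_,
            converged=self.converged_,
        )


def greml_bivariate(y1, y2, grm, idx1=None, idx2=None, gate_override=None):
    """Functional wrapper around :class:`BivariateGREML`."""
    est = BivariateGREML().fit(
        grm, y1, y2, idx1=idx1, idx2=idx2, gate_override=gate_override
    )
    return est.result()


def _numerical_covariance(nll, theta, free, eps=1e-4):
    k = len(free)
    H = np.zeros((k, k))
    f0 = nll(theta)
    for a in range(k):
        for b in range(a, k):
            ta = np.array(theta)
            tb = np.array(theta)
            tab = np.array(theta)
            ta[free[a]] += eps
            tb[free[b]] += eps
            tab[free[a]] += eps
            tab[free[b]] += eps
            H[a, b] = H[b, a] = (nll(tab) - nll(ta) - nll(tb) + f0) / eps**2
    try:
        cov_free = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov_free = np.full((k, k), np.nan)
    cov = np.zeros((len(theta), len(theta)))
    for a in range(k):
        for b in range(k):
            cov[free[a], free[b]] = cov_free[a, b]
    return cov


def _numerical_jacobian(fn, theta, free, eps=1e-5):
    f0 = fn(theta)
    J = np.zeros((len(f0), len(theta)))
    for p in free:
        t = np.array(theta)
        t[p] += eps
        J[:, p] = (fn(t) - f0) / eps
    return J
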