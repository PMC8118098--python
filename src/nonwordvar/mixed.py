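"""Mixed-effects models with crossed random factors.

Linear mixed models are estimated by optimising the profiled (RE)ML
deviance over the relative Cholesky factors of the random-effect covariance
blocks: with y = X b + Z u + e, e ~ N(0, s2 I) and u ~ N(0, s2 L Lt) the
fixed effects, the conditional modes and the residual variance all have
closed forms given L, so only the handful of Cholesky entries (theta) is
optimised numerically.  Any number of random terms is supported, each a
grouping factor with a random intercept and optional random slopes,
correlated or independent.

Degrees of freedom for the fixed-effect t tests use the Satterthwaite
approximation: the variance of each coefficient is differentiated
numerically with respect to the variance parameters and combined with the
observed information of those parameters, giving the fractional df familiar
from lmerTest.

Binomial (logit) mixed models are estimated by direct maximisation of the
Laplace approximation to the marginal likelihood: for each candidate
(beta, theta) the conditional mode of u is found by Newton iteration and
the log-determinant correction applied.  Wald z tests come from the
numerical Hessian at the optimum.

Variance explained is reported as marginal and conditional R2 (fixed
effects alone vs fixed plus random), with both the theoretical (pi^2/3)
and delta-method observation-level variances for the binomial case.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy.special import expit
from scipy.stats import norm, t as t_dist
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted


class ConvergenceError(RuntimeError):
    """The optimiser failed to reach an acceptable optimum."""


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation in a binomial model."""


@dataclass(frozen=True)
class RandomTerm:
    """One random-effects term: ``(1 + slopes | group)``.

    ``correlated=False`` constrains the intercept-slope correlations (and
    slope-slope correlations) to zero, i.e. ``(1 | g) + (0 + x | g)``.
    """

    group: str
    slopes: tuple[str, ...] = ()
    correlated: bool = True

    @property
    def q(self) -> int:
        return 1 + len(self.slopes)

    @property
    def n_theta(self) -> int:
        return self.q * (self.q + 1) // 2 if self.correlated else self.q

    def label(self) -> str:
        inner = "1" + "".join(f" + {s}" for s in self.slopes)
        sep = " | " if self.correlated else " || "
        return f"({inner}{sep}{self.group})"


def build_fixed_design(df: pd.DataFrame, terms: list[str]) -> tuple[np.ndarray, list[str]]:
    """Design matrix for an intercept plus the named numeric terms;
    'a:b' denotes the elementwise product of columns a and b."""
    cols = [np.ones(len(df))]
    names = ["(Intercept)"]
    for term in terms:
        parts = term.split(":")
        col = np.ones(len(df))
        for p in parts:
            col = col * df[p].to_numpy(dtype=float)
        cols.append(col)
        names.append(term)
    return np.column_stack(cols), names


def _random_design(df: pd.DataFrame, term: RandomTerm):
    """Raw Z for one term as an (n, m, q) array plus the level index."""
    levels, idx = np.unique(df[term.group].to_numpy(), return_inverse=True)
    n, m, q = len(df), len(levels), term.q
    Z = np.zeros((n, m, q))
    Z[np.arange(n), idx, 0] = 1.0
    for j, slope in enumerate(term.slopes, start=1):
        Z[np.arange(n), idx, j] = df[slope].to_numpy(dtype=float)
    return Z, levels


def _theta_init(terms: list[RandomTerm]) -> np.ndarray:
    parts = []
    for t in terms:
        if t.correlated:
            lam = np.eye(t.q)
            parts.append(lam[np.tril_indices(t.q)])
        else:
            parts.append(np.ones(t.q))
    return np.concatenate(parts) if parts else np.array([])


def _theta_bounds(terms: list[RandomTerm]) -> list[tuple]:
    bounds = []
    for t in terms:
        if t.correlated:
            rows, cols = np.tril_indices(t.q)
            for r, c in zip(rows, cols):
                bounds.append((0.0, None) if r == c else (None, None))
        else:
            bounds.extend([(0.0, None)] * t.q)
    return bounds


def _lambdas(theta: np.ndarray, terms: list[RandomTerm]) -> list[np.ndarray]:
    out, pos = [], 0
    for t in terms:
        lam = np.zeros((t.q, t.q))
        if t.correlated:
            k = t.n_theta
            lam[np.tril_indices(t.q)] = theta[pos:pos + k]
            pos += k
        else:
            np.fill_diagonal(lam, theta[pos:pos + t.q])
            pos += t.q
        out.append(lam)
    return out


class _LMMCore:
    """Precomputed designs and the profiled deviance for one LMM.

    For a single random term the mixed-model equations are block diagonal
    per group, so the solve runs on stacked q x q blocks; the general
    crossed case uses one dense Cholesky of the full random-effects system.
    """

    def __init__(self, y, X, Z_blocks, terms, reml):
        self.y, self.X = y, X
        self.Z_blocks = Z_blocks            # list of (n, m_k, q_k)
        self.terms = terms
        self.reml = reml
        self.n, self.p = X.shape
        if len(Z_blocks) == 1:
            Z3 = Z_blocks[0]
            # per-group cross-products for the block-diagonal fast path
            self._S = np.einsum("nmq,nmr->mqr", Z3, Z3)    # Z_g' Z_g
            self._T = np.einsum("nmq,np->mqp", Z3, X)      # Z_g' X
            self._v = np.einsum("nmq,n->mq", Z3, y)        # Z_g' y

    def _Zs(self, theta):
        lams = _lambdas(theta, self.terms)
        mats = []
        for Z3, lam in zip(self.Z_blocks, lams):
            n, m, q = Z3.shape
            mats.append((Z3 @ lam).reshape(n, m * q))
        return np.concatenate(mats, axis=1) if mats else np.zeros((self.n, 0))

    def solve(self, theta):
        if len(self.terms) == 1:
            return self._solve_single(theta)
        return self._solve_dense(theta)

    def _solve_single(self, theta):
        y, X, n, p = self.y, self.X, self.n, self.p
        lam = _lambdas(theta, self.terms)[0]
        q = lam.shape[0]
        # per-group system A_g = lam' Z_g'Z_g lam + I
        A = np.einsum("qr,mrs,st->mqt", lam.T, self._S, lam) + np.eye(q)
        sign, ld = np.linalg.slogdet(A)
        if np.any(sign <= 0):
            raise linalg.LinAlgError("non-PD random-effects system")
        ld_L = float(ld.sum())
        Ainv = np.linalg.inv(A)
        T = np.einsum("qr,mrp->mqp", lam.T, self._T)       # Zs_g' X
        v = np.einsum("qr,mr->mq", lam.T, self._v)         # Zs_g' y
        XtVX = X.T @ X - np.einsum("mqp,mqr,mrs->ps", T, Ainv, T)
        Xty = X.T @ y - np.einsum("mqp,mqr,mr->p", T, Ainv, v)
        LX = linalg.cholesky(XtVX, lower=True)
        beta = linalg.cho_solve((LX, True), Xty)
        u = np.einsum("mqr,mr->mq", Ainv, v - np.einsum("mqp,p->mq", T, beta))
        Z3 = self.Z_blocks[0]
        fitted = X @ beta + np.einsum("nmq,qr,mr->n", Z3, lam, u)
        resid = y - fitted
        pwrss = float(resid @ resid + np.sum(u * u))
        pwrss = max(pwrss, 1e-12 * (1.0 + float(y @ y)))  # guard perfect fits
        ld_LX = 2.0 * float(np.sum(np.log(np.diag(LX))))
        if self.reml:
            dev = ld_L + ld_LX + (n - p) * (1.0 + np.log(2.0 * np.pi * pwrss / (n - p)))
        else:
            dev = ld_L + n * (1.0 + np.log(2.0 * np.pi * pwrss / n))
        return {"dev": dev, "beta": beta, "u": u.ravel(), "pwrss": pwrss,
                "LX": LX, "ld_L": ld_L, "ld_LX": ld_LX}

    def _solve_dense(self, theta):
        y, X, n, p = self.y, self.X, self.n, self.p
        Zs = self._Zs(theta)
        qtot = Zs.shape[1]
        A = Zs.T @ Zs + np.eye(qtot)
        L = linalg.cholesky(A, lower=True)
        RZX = linalg.solve_triangular(L, Zs.T @ X, lower=True)
        cu = linalg.solve_triangular(L, Zs.T @ y, lower=True)
        XtVX = X.T @ X - RZX.T @ RZX
        LX = linalg.cholesky(XtVX, lower=True)
        beta = linalg.cho_solve((LX, True), X.T @ y - RZX.T @ cu)
        u = linalg.solve_triangular(L.T, cu - RZX @ beta, lower=False)
        resid = y - X @ beta - Zs @ u
        pwrss = float(resid @ resid + u @ u)
        pwrss = max(pwrss, 1e-12 * (1.0 + float(y @ y)))  # guard perfect fits
        ld_L = 2.0 * float(np.sum(np.log(np.diag(L))))
        ld_LX = 2.0 * float(np.sum(np.log(np.diag(LX))))
        if self.reml:
            dev = ld_L + ld_LX + (n - p) * (1.0 + np.log(2.0 * np.pi * pwrss / (n - p)))
        else:
            dev = ld_L + n * (1.0 + np.log(2.0 * np.pi * pwrss / n))
        return {"dev": dev, "beta": beta, "u": u, "pwrss": pwrss,
                "LX": LX, "ld_L": ld_L, "ld_LX": ld_LX, "Zs": Zs}

    def deviance(self, theta):
        try:
            dev = self.solve(theta)["dev"]
        except linalg.LinAlgError:
            return 1e12
        return dev if np.isfinite(dev) else 1e12

    def deviance_unprofiled(self, theta, sigma):
        """-2 log (restricted) likelihood at (theta, sigma), beta profiled."""
        try:
            s = self.solve(theta)
        except linalg.LinAlgError:
            return np.inf
        n, p = self.n, self.p
        dfree = n - p if self.reml else n
        dev = s["ld_L"] + dfree * np.log(2.0 * np.pi * sigma**2) + s["pwrss"] / sigma**2
        if self.reml:
            dev += s["ld_LX"]
        return dev

    def vcov_beta(self, theta, sigma2):
        s = self.solve(theta)
        inv = linalg.cho_solve((s["LX"], True), np.eye(self.p))
        return sigma2 * inv


def _numeric_hessian(f, x, h=1e-4):
    k = len(x)
    H = np.zeros((k, k))
    steps = h * np.maximum(1.0, np.abs(x))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = steps[i]
            ej = np.zeros(k); ej[j] = steps[j]
            fpp = f(x + ei + ej); fpm = f(x + ei - ej)
            fmp = f(x - ei + ej); fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])
    return H


def _numeric_grad(f, x, h=1e-5):
    g = np.zeros(len(x))
    steps = h * np.maximum(1.0, np.abs(x))
    for i in range(len(x)):
        e = np.zeros(len(x)); e[i] = steps[i]
        g[i] = (f(x + e) - f(x - e)) / (2 * steps[i])
    return g


class LinearMixedModel(BaseEstimator):
    """Linear mixed model with crossed random effects, fit by (RE)ML.

    Parameters
    ----------
    response : str
        Name of the response column.
    fixed : list[str]
        Fixed-effect terms (column names; 'a:b' for an interaction).  An
        intercept is always included.
    random : list[RandomTerm]
        Random-effect terms; crossed grouping factors are supported.
    reml : bool
        REML (default) or ML estimation.

    Attributes (after ``fit``)
    --------------------------
    fe_params_, fe_se_, fe_t_, fe_df_, fe_p_ : pd.Series
        Fixed-effect estimates, standard errors, t statistics,
        Satterthwaite degrees of freedom and two-sided p values.
    sigma2_ : float         residual variance
    varcomp_ : dict         per-term random-effect covariance matrices
    ranef_ : dict           per-term BLUPs (DataFrame indexed by level)
    r2_marginal_, r2_conditional_ : float
    converged_ : bool
    """

    def __init__(self, response: str, fixed: list[str],
                 random: list[RandomTerm], reml: bool = True,
                 satterthwaite: bool = True):
        self.response = response
        self.fixed = fixed
        self.random = random
        self.reml = reml
        self.satterthwaite = satterthwaite

    def fit(self, X: pd.DataFrame, y=None):
        df = X
        needed = [self.response] + [p for t in self.fixed for p in t.split(":")]
        for term in self.random:
            needed += [term.group, *term.slopes]
        miss = [c for c in dict.fromkeys(needed) if c not in df.columns]
        if miss:
            raise ValueError(f"missing columns {miss}")
        df = df.dropna(subset=list(dict.fromkeys(needed)))
        for term in self.random:
            if df[term.group].nunique() < 2:
                raise ValueError(f"grouping factor {term.group!r} has < 2 levels")

        yv = df[self.response].to_numpy(dtype=float)
        Xd, names = build_fixed_design(df, self.fixed)
        blocks, level_lists = [], []
        for term in self.random:
            Z3, levels = _random_design(df, term)
            blocks.append(Z3)
            level_lists.append(levels)

        core = _LMMCore(yv, Xd, blocks, self.random, self.reml)
        theta0 = _theta_init(self.random)
        bounds = _theta_bounds(self.random)
        res = optimize.minimize(core.deviance, theta0, method="Nelder-Mead",
                                bounds=bounds,
                                options={"maxiter": 2000 * max(1, len(theta0)),
                                         "xatol": 1e-8, "fatol": 1e-10})
        theta = res.x
        sol = core.solve(theta)
        n, p = core.n, core.p
        sigma2 = sol["pwrss"] / (n - p if self.reml else n)

        self.converged_ = bool(res.success)
        self.deviance_ = float(sol["dev"])
        self.theta_ = theta
        self.sigma2_ = float(sigma2)
        self.n_obs_ = n
        self.fe_names_ = names
        vcov = core.vcov_beta(theta, sigma2)
        self.vcov_ = pd.DataFrame(vcov, index=names, columns=names)
        se = np.sqrt(np.diag(vcov))
        beta = sol["beta"]
        self.fe_params_ = pd.Series(beta, index=names)
        self.fe_se_ = pd.Series(se, index=names)
        self.fe_t_ = pd.Series(beta / se, index=names)

        lams = _lambdas(theta, self.random)
        self.varcomp_ = {}
        self.ranef_ = {}
        pos = 0
        for term, lam, Z3, levels in zip(self.random, lams, blocks, level_lists):
            cov = sigma2 * lam @ lam.T
            colnames = ["(Intercept)", *term.slopes]
            self.varcomp_[term.label()] = pd.DataFrame(cov, index=colnames, columns=colnames)
            m, q = Z3.shape[1], term.q
            u_term = sol["u"][pos:pos + m * q].reshape(m, q)
            b = u_term @ lam.T
            self.ranef_[term.label()] = pd.DataFrame(b, index=levels, columns=colnames)
            pos += m * q

        # Nakagawa/Johnson variance decomposition
        var_fixed = float(np.var(Xd @ beta, ddof=1)) if n > 1 else 0.0
        var_random = 0.0
        for term, lam, Z3 in zip(self.random, lams, blocks):
            cov = sigma2 * lam @ lam.T
            var_random += float(np.mean(np.einsum("nmq,qr,nmr->n", Z3, cov, Z3)))
        tot = var_fixed + var_random + sigma2
        self.var_fixed_, self.var_random_ = var_fixed, var_random
        self.r2_marginal_ = var_fixed / tot if tot > 0 else 0.0
        self.r2_conditional_ = (var_fixed + var_random) / tot if tot > 0 else 0.0

        # Satterthwaite df per coefficient
        if self.satterthwaite:
            self.fe_df_ = pd.Series(self._satterthwaite_df(core, theta, np.sqrt(sigma2)),
                                    index=names)
        else:
            self.fe_df_ = pd.Series(np.full(p, n - p, dtype=float), index=names)
        self.fe_p_ = pd.Series(
            2 * t_dist.sf(np.abs(self.fe_t_), self.fe_df_.clip(lower=1.0)), index=names)
        self._core = core
        return self

    def _satterthwaite_df(self, core, theta, sigma):
        phi = np.concatenate([theta, [sigma]])

        def nll2(v):  # -2 log-likelihood in (theta, sigma)
            return core.deviance_unprofiled(v[:-1], abs(v[-1]))

        H = _numeric_hessian(nll2, phi)
        try:
            W = 2.0 * linalg.inv(H)
        except linalg.LinAlgError:
            return np.full(core.p, core.n - core.p, dtype=float)
        dfs = np.empty(core.p)
        for i in range(core.p):
            def vcov_ii(v, i=i):
                return core.vcov_beta(v[:-1], v[-1] ** 2)[i, i]
            f0 = vcov_ii(phi)
            g = _numeric_grad(vcov_ii, phi)
            denom = float(g @ W @ g)
            dfs[i] = 2.0 * f0**2 / denom if denom > 1e-300 else core.n - core.p
            if not np.isfinite(dfs[i]) or dfs[i] <= 0:
                dfs[i] = core.n - core.p
        return dfs

    def summary(self) -> pd.DataFrame:
        check_is_fitted(self, "fe_params_")
        return pd.DataFrame({
            "estimate": self.fe_params_, "se": self.fe_se_, "t": self.fe_t_,
            "df": self.fe_df_, "p": self.fe_p_,
        })


class BinomialMixedModel(BaseEstimator):
    """Binomial (logit) mixed model fit by Laplace approximation.

    Interface mirrors :class:`LinearMixedModel`; inference is by Wald z
    tests (``fe_z_``, ``fe_p_``).  ``r2_marginal_``/``r2_conditional_`` use
    the theoretical latent residual variance pi^2/3; the delta-method
    variants are in ``r2_marginal_delta_``/``r2_conditional_delta_``.
    """

    def __init__(self, response: str, fixed: list[str],
                 random: list[RandomTerm], maxiter: int = 200):
        self.response = response
        self.fixed = fixed
        self.random = random
        self.maxiter = maxiter

    # Laplace objective ----------------------------------------------------
    @staticmethod
    def _inner_mode(eta_fixed, Zs, y, u0, tol=1e-10, maxit=50):
        """Newton iteration for the conditional mode of u given beta, theta."""
        qtot = Zs.shape[1]
        u = u0.copy() if u0 is not None and len(u0) == qtot else np.zeros(qtot)
        for _ in range(maxit):
            eta = eta_fixed + Zs @ u
            mu = expit(eta)
            grad = Zs.T @ (y - mu) - u
            W = mu * (1 - mu)
            H = Zs.T @ (Zs * W[:, None]) + np.eye(qtot)
            L = linalg.cholesky(H, lower=True)
            step = linalg.cho_solve((L, True), grad)
            # step-halving on the penalized log-likelihood
            def pen_ll(uu):
                e = eta_fixed + Zs @ uu
                return float(y @ e - np.logaddexp(0.0, e).sum() - 0.5 * uu @ uu)
            ll0 = pen_ll(u)
            alpha = 1.0
            for _ in range(20):
                u_new = u + alpha * step
                if pen_ll(u_new) >= ll0 - 1e-12:
                    break
                alpha *= 0.5
            u = u_new
            if np.max(np.abs(alpha * step)) < tol:
                break
        eta = eta_fixed + Zs @ u
        mu = expit(eta)
        W = mu * (1 - mu)
        H = Zs.T @ (Zs * W[:, None]) + np.eye(qtot)
        L = linalg.cholesky(H, lower=True)
        ll = float(y @ eta - np.logaddexp(0.0, eta).sum() - 0.5 * u @ u)
        ld = 2.0 * float(np.sum(np.log(np.diag(L))))
        return u, ll - 0.5 * ld

    @staticmethod
    def _profiled_mode(Xd, Zs, y, beta0, u0, tol=1e-9, maxit=60):
        """Joint Newton over (beta, u) on the penalized log-likelihood."""
        n, p = Xd.shape
        qtot = Zs.shape[1]
        beta = beta0.copy()
        u = u0.copy() if u0 is not None and len(u0) == qtot else np.zeros(qtot)

        def pen_ll(b, uu):
            e = Xd @ b + Zs @ uu
            return float(y @ e - np.logaddexp(0.0, e).sum() - 0.5 * uu @ uu)

        for _ in range(maxit):
            eta = Xd @ beta + Zs @ u
            mu = expit(eta)
            W = mu * (1 - mu)
            r = y - mu
            H11 = Xd.T @ (Xd * W[:, None])
            H12 = Xd.T @ (Zs * W[:, None])
            H22 = Zs.T @ (Zs * W[:, None]) + np.eye(qtot)
            H = np.block([[H11, H12], [H12.T, H22]])
            g = np.concatenate([Xd.T @ r, Zs.T @ r - u])
            step = linalg.solve(H, g, assume_a="pos")
            ll0 = pen_ll(beta, u)
            alpha = 1.0
            for _ in range(20):
                b_new, u_new = beta + alpha * step[:p], u + alpha * step[p:]
                if pen_ll(b_new, u_new) >= ll0 - 1e-12:
                    break
                alpha *= 0.5
            beta, u = b_new, u_new
            if np.max(np.abs(alpha * step)) < tol:
                break
        eta = Xd @ beta + Zs @ u
        mu = expit(eta)
        W = mu * (1 - mu)
        H22 = Zs.T @ (Zs * W[:, None]) + np.eye(qtot)
        L = linalg.cholesky(H22, lower=True)
        ld = 2.0 * float(np.sum(np.log(np.diag(L))))
        return beta, u, pen_ll(beta, u) - 0.5 * ld

    def fit(self, X: pd.DataFrame, y=None):
        df = X
        yv = df[self.response].to_numpy(dtype=float)
        if not np.isin(yv, (0.0, 1.0)).all():
            raise ValueError("binomial response must be 0/1")
        Xd, names = build_fixed_design(df, self.fixed)
        blocks, level_lists = [], []
        for term in self.random:
            if df[term.group].nunique() < 2:
                raise ValueError(f"grouping factor {term.group!r} has < 2 levels")
            Z3, levels = _random_design(df, term)
            blocks.append(Z3)
            level_lists.append(levels)
        p = Xd.shape[1]

        # start beta at the plain logistic fit
        import statsmodels.api as sm
        glm = sm.GLM(yv, Xd, family=sm.families.Binomial()).fit()
        beta0 = np.asarray(glm.params)
        theta0 = _theta_init(self.random)
        state = {"u": None, "beta": beta0.copy()}

        def make_Zs(theta):
            lams = _lambdas(theta, self.random)
            mats = []
            for Z3, lam in zip(blocks, lams):
                n, m, q = Z3.shape
                mats.append((Z3 @ lam).reshape(n, m * q))
            return np.concatenate(mats, axis=1)

        def nll(phi):
            beta, theta = phi[:p], np.abs(phi[p:])
            try:
                Zs = make_Zs(theta)
                u, lap = self._inner_mode(Xd @ beta, Zs, yv, state["u"])
            except linalg.LinAlgError:
                return 1e12
            state["u"] = u
            return -lap if np.isfinite(lap) else 1e12

        def nll_profiled(theta):
            """Laplace criterion with beta profiled out by joint Newton on
            the penalized log-likelihood (fast start; polished below)."""
            try:
                Zs = make_Zs(np.abs(theta))
                beta, u, lap = self._profiled_mode(Xd, Zs, yv, state["beta"], state["u"])
            except linalg.LinAlgError:
                return 1e12
            state["beta"], state["u"] = beta, u
            return -lap if np.isfinite(lap) else 1e12

        res0 = optimize.minimize(nll_profiled, theta0, method="Nelder-Mead",
                                 options={"maxiter": 200 * max(1, len(theta0)),
                                          "xatol": 1e-5, "fatol": 1e-7})
        phi0 = np.concatenate([state["beta"], np.abs(res0.x)])
        res = optimize.minimize(nll, phi0, method="L-BFGS-B",
                                options={"maxiter": self.maxiter, "ftol": 1e-10,
                                         "gtol": 1e-7, "eps": 1e-5})
        phi = res.x if res.fun <= res0.fun + 1e-9 else phi0
        beta, theta = phi[:p], np.abs(phi[p:])
        self.converged_ = bool(res.success)
        self.loglik_ = -float(res.fun)
        self.theta_ = theta

        if np.max(np.abs(beta)) > 15:
            worst = names[int(np.argmax(np.abs(beta)))]
            raise SeparationError(
                f"estimate for {worst!r} diverged (|beta| > 15): separation likely")

        H = _numeric_hessian(nll, phi, h=1e-4)
        try:
            cov_all = linalg.inv(H)
            se = np.sqrt(np.clip(np.diag(cov_all)[:p], 0, None))
        except linalg.LinAlgError:
            se = np.full(p, np.nan)
        self.fe_names_ = names
        self.fe_params_ = pd.Series(beta, index=names)
        self.fe_se_ = pd.Series(se, index=names)
        self.fe_z_ = self.fe_params_ / self.fe_se_
        self.fe_p_ = pd.Series(2 * norm.sf(np.abs(self.fe_z_)), index=names)

        lams = _lambdas(theta, self.random)
        Zs = make_Zs(theta)
        u, _ = self._inner_mode(Xd @ beta, Zs, yv, state["u"], tol=1e-12)
        self.varcomp_ = {}
        self.ranef_ = {}
        pos = 0
        for term, lam, Z3, levels in zip(self.random, lams, blocks, level_lists):
            cov = lam @ lam.T
            colnames = ["(Intercept)", *term.slopes]
            self.varcomp_[term.label()] = pd.DataFrame(cov, index=colnames, columns=colnames)
            m, q = Z3.shape[1], term.q
            self.ranef_[term.label()] = pd.DataFrame(
                u[pos:pos + m * q].reshape(m, q) @ lam.T, index=levels, columns=colnames)
            pos += m * q

        var_fixed = float(np.var(Xd @ beta, ddof=1))
        var_random = 0.0
        for term, lam, Z3 in zip(self.random, lams, blocks):
            cov = lam @ lam.T
            var_random += float(np.mean(np.einsum("nmq,qr,nmr->n", Z3, cov, Z3)))
        self.var_fixed_, self.var_random_ = var_fixed, var_random
        var_theo = np.pi**2 / 3.0
        pbar = float(expit(np.mean(Xd @ beta)))
        var_delta = 1.0 / (pbar * (1.0 - pbar))
        for suffix, vr in (("", var_theo), ("_delta", var_delta)):
            tot = var_fixed + var_random + vr
            setattr(self, f"r2_marginal{suffix}_", var_fixed / tot)
            setattr(self, f"r2_conditional{suffix}_", (var_fixed + var_random) / tot)
        self.n_obs_ = len(yv)
        return self

    def summary(self) -> pd.DataFrame:
        check_is_fitted(self, "fe_params_")
        return pd.DataFrame({
            "estimate": self.fe_params_, "se": self.fe_se_,
            "z": self.fe_z_, "p": self.fe_p_,
        })
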