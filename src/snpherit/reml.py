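"""Restricted maximum likelihood for GRM-defined variance components.

The model is y ~ N(Xb, sum_c A_c sigma2_c + I sigma2_e). Maximization
uses average-information (AI) updates with step halving and an EM
fallback whenever an AI step would decrease the restricted likelihood.
Components whose estimates converge against the zero boundary are
constrained at zero and the remaining components re-maximized; standard
errors come from the inverse AI matrix at the solution and h2 ratios and
their SEs from the delta method.

For a single genetic component the GRM is eigendecomposed once and every
iteration runs in the rotated basis, where all matrices are diagonal;
this is algebraically identical to the dense path but O(n) per
iteration after the one-off O(n^3) decomposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

from .errors import ConvergenceError

_FLOOR_FRAC = 1e-8  # boundary floor as a fraction of phenotypic variance


@dataclass
class RemlModel:
    """Phenotype, fixed effects and named relationship components."""

    y: np.ndarray
    components: dict
    X: np.ndarray = None
    sample_ids: np.ndarray = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=np.float64)
        if self.y.ndim != 1:
            raise ValueError("y must be one-dimensional")
        n = self.y.shape[0]
        if self.X is None:
            self.X = np.ones((n, 1))
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        if self.X.shape[0] != n:
            raise ValueError("X and y row counts differ")
        self.components = dict(self.components)
        for name, A in self.components.items():
            A = np.asarray(A, dtype=np.float64)
            if A.shape != (n, n):
                raise ValueError(f"component {name!r} is not n x n")
            if not np.allclose(A, A.T, atol=1e-8):
                raise ValueError(f"component {name!r} is not symmetric")
            self.components[name] = A


@dataclass
class RemlFit:
    """Variance-component estimates and derived quantities."""

    component_names: tuple
    sigma2: np.ndarray
    sigma2_e: float
    se: np.ndarray  # per component, then residual
    sigma2_P: float
    h2: np.ndarray
    h2_se: np.ndarray
    logL: float
    logL0: float
    lrt: float
    lrt_p: float
    constrained: np.ndarray
    n_used: int
    iterations: int
    converged: bool
    covariance: np.ndarray = field(default=None, repr=False)
    logL_history: list = field(default_factory=list, repr=False)

    @property
    def n_components(self) -> int:
        return len(self.component_names)

    @property
    def h2_total(self) -> float:
        return float(self.h2.sum())

    @property
    def h2_total_se(self) -> float:
        """Delta-method SE of the summed genetic fraction."""
        if self.covariance is None:
            return float("nan")
        c = self.n_components
        sg = self.sigma2.sum()
        sp = self.sigma2_P
        g = np.empty(c + 1)
        g[:c] = (sp - sg) / sp**2
        g[c] = -sg / sp**2
        return float(np.sqrt(max(g @ self.covariance @ g, 0.0)))

    def h2_of(self, name: str) -> float:
        return float(self.h2[self.component_names.index(name)])


# ----------------------------------------------------------------------
# workspaces: dense and single-component eigen paths
# ----------------------------------------------------------------------
class _Quantities:
    __slots__ = ("logL", "grad", "ai", "ytPy", "trPA", "yPAPy")

    def __init__(self, logL, grad, ai, ytPy, trPA, yPAPy):
        self.logL = logL
        self.grad = grad
        self.ai = ai
        self.ytPy = ytPy
        self.trPA = trPA
        self.yPAPy = yPAPy


class _DenseWorkspace:
    def __init__(self, y, X, comps):
        self.y = y
        self.X = X
        self.comps = comps
        self.n, self.p = X.shape

    def _factor(self, sigma, active):
        V = np.zeros((self.n, self.n))
        for i in active:
            V += sigma[i] * self.comps[i]
        V[np.diag_indices(self.n)] += sigma[-1]
        for attempt in range(3):
            try:
                return cho_factor(V, lower=True)
            except np.linalg.LinAlgError:
                V[np.diag_indices(self.n)] += 10.0 ** (-10 + 2 * attempt) * sigma[-1]
        raise np.linalg.LinAlgError("V not positive definite after jitter retries")

    def loglik(self, sigma, active):
        cf = self._factor(sigma, active)
        Viy = cho_solve(cf, self.y)
        ViX = cho_solve(cf, self.X)
        XtViX = self.X.T @ ViX
        cfx = cho_factor(XtViX, lower=True)
        XtViy = self.X.T @ Viy
        ytPy = self.y @ Viy - XtViy @ cho_solve(cfx, XtViy)
        logdetV = 2.0 * np.log(np.diag(cf[0])).sum()
        logdetX = 2.0 * np.log(np.diag(cfx[0])).sum()
        return -0.5 * (logdetV + logdetX + ytPy)

    def quantities(self, sigma, active):
        cf = self._factor(sigma, active)
        Vi = cho_solve(cf, np.eye(self.n))
        ViX = Vi @ self.X
        XtViX = self.X.T @ ViX
        cfx = cho_factor(XtViX, lower=True)
        P = Vi - ViX @ cho_solve(cfx, ViX.T)
        P = (P + P.T) / 2.0
        Py = P @ self.y
        mats = [self.comps[i] for i in active]
        k = len(mats) + 1
        trPA = np.empty(k)
        us = []
        for j, A in enumerate(mats):
            trPA[j] = np.einsum("ij,ij->", P, A)
            us.append(A @ Py)
        trPA[-1] = np.trace(P)
        us.append(Py)
        U = np.column_stack(us)
        PU = P @ U
        yPAPy = Py @ U
        grad = -0.5 * (trPA - yPAPy)
        ai = 0.5 * (U.T @ PU)
        logdetV = 2.0 * np.log(np.diag(cf[0])).sum()
        logdetX = 2.0 * np.log(np.diag(cfx[0])).sum()
        ytPy = self.y @ Py
        logL = -0.5 * (logdetV + logdetX + ytPy)
        return _Quantities(logL, grad, ai, ytPy, trPA, yPAPy)


class _EigenWorkspace:
    """Single-GRM path: everything in the eigenbasis of the component."""

    def __init__(self, y, X, A):
        d, U = np.linalg.eigh(A)
        self.d = np.clip(d, 0.0, None)  # GRMs are PSD up to round-off
        self.yt = U.T @ y
        self.Xt = U.T @ X
        self.n, self.p = X.shape

    def _pieces(self, sigma, active):
        w = np.full(self.n, sigma[-1])
        if active:
            w = w + sigma[active[0]] * self.d
        w = np.maximum(w, 1e-300)
        Xw = self.Xt / w[:, None]
        XtViX = self.Xt.T @ Xw
        cfx = cho_factor(XtViX, lower=True)
        return w, Xw, cfx

    def _P_apply(self, v, w, Xw, cfx):
        return v / w - Xw @ cho_solve(cfx, self.Xt.T @ (v / w))

    def loglik(self, sigma, active):
        w, Xw, cfx = self._pieces(sigma, active)
        Py = self._P_apply(self.yt, w, Xw, cfx)
        logdetV = np.log(w).sum()
        logdetX = 2.0 * np.log(np.diag(cfx[0])).sum()
        return -0.5 * (logdetV + logdetX + self.yt @ Py)

    def quantities(self, sigma, active):
        w, Xw, cfx = self._pieces(sigma, active)
        Py = self._P_apply(self.yt, w, Xw, cfx)
        diags = [self.d] if active else []
        diags.append(np.ones(self.n))
        k = len(diags)
        trPA = np.empty(k)
        us = []
        for j, a in enumerate(diags):
            M = self.Xt.T @ (self.Xt * (a / w**2)[:, None])
            trPA[j] = (a / w).sum() - np.trace(cho_solve(cfx, M))
            us.append(a * Py)
        U = np.column_stack(us)
        PU = np.column_stack([self._P_apply(u, w, Xw, cfx) for u in us])
        yPAPy = Py @ U
        grad = -0.5 * (trPA - yPAPy)
        ai = 0.5 * (U.T @ PU)
        logdetV = np.log(w).sum()
        logdetX = 2.0 * np.log(np.diag(cfx[0])).sum()
        logL = -0.5 * (logdetV + logdetX + self.yt @ Py)
        return _Quantities(logL, grad, ai, self.yt @ Py, trPA, yPAPy)


# ----------------------------------------------------------------------
def _null_reml(y, X):
    """Closed-form restricted likelihood of the no-component model."""
    n, p = X.shape
    Q, R = np.linalg.qr(X)
    resid = y - Q @ (Q.T @ y)
    rss = float(resid @ resid)
    s2 = rss / (n - p)
    logdetXtX = 2.0 * np.log(np.abs(np.diag(R))).sum()
    logL = -0.5 * ((n - p) * np.log(s2) + logdetXtX + (n - p))
    return s2, logL


def restricted_loglik(y, X, components, sigma2) -> float:
    """Restricted log-likelihood at the given variances (diagnostic).

    ``sigma2`` lists the per-component variances followed by the residual
    variance; the constant -n log(2 pi)/2 term is omitted, matching the
    engine's internal convention.
    """
    y = np.asarray(y, dtype=float)
    X = np.ones((y.size, 1)) if X is None else np.asarray(X, dtype=float)
    comps = [np.asarray(A, dtype=float) for A in components]
    ws = _DenseWorkspace(y, X, comps)
    return float(ws.loglik(np.asarray(sigma2, dtype=float), list(range(len(comps)))))


_STEP_SCHEDULE = (1.0, 0.5, 0.25, 0.1, 0.03, 0.01)


def fit_reml(model: RemlModel, max_iter: int = 100, tol: float = 1e-8) -> RemlFit:
    """AI-REML fit of ``model`` with EM fallback and boundary constraints.

    ``tol`` is the relative change in restricted log-likelihood between
    accepted iterations below which the fit is declared converged.
    Raises :class:`ConvergenceError` (carrying the last state) if
    ``max_iter`` is exhausted.
    """
    keep = ~np.isnan(model.y)
    y = model.y[keep]
    X = model.X[keep]
    names = tuple(model.components)
    comps = [model.components[k][np.ix_(keep, keep)] for k in names]
    n = y.size
    c = len(comps)
    p = X.shape[1]
    if n <= p + c:
        raise ValueError(f"n_used={n} too small for {p} fixed effects + {c} components")

    s2_null, logL0 = _null_reml(y, X)
    if c == 0:
        return RemlFit(
            component_names=(),
            sigma2=np.empty(0),
            sigma2_e=s2_null,
            se=np.array([np.sqrt(2 * s2_null**2 / (n - p))]),
            sigma2_P=s2_null,
            h2=np.empty(0),
            h2_se=np.empty(0),
            logL=logL0,
            logL0=logL0,
            lrt=0.0,
            lrt_p=1.0,
            constrained=np.empty(0, dtype=bool),
            n_used=n,
            iterations=0,
            converged=True,
        )

    vp = float(y.var(ddof=1))
    floor = _FLOOR_FRAC * vp
    ws = _EigenWorkspace(y, X, comps[0]) if c == 1 else _DenseWorkspace(y, X, comps)

    sigma = np.full(c + 1, vp / (c + 1))
    active = list(range(c))
    constrained = np.zeros(c, dtype=bool)
    floor_hits = np.zeros(c, dtype=int)
    total_iter = 0
    converged = False
    history = []

    logL_prev = -np.inf
    while total_iter < max_iter:
        total_iter += 1
        q = ws.quantities(sigma, active)
        history.append((float(q.logL), tuple(active)))
        if abs(q.logL - logL_prev) < tol * max(1.0, abs(q.logL)):
            at_floor = [i for i in active if sigma[i] <= floor * 1.5]
            if at_floor:
                # converged against the boundary: constrain and re-maximize
                for i in at_floor:
                    sigma[i] = 0.0
                    active.remove(i)
                    constrained[i] = True
                logL_prev = -np.inf
                continue
            converged = True
            logL_prev = q.logL
            break
        logL_prev = q.logL

        # AI ascent with step halving, then EM fallback
        try:
            delta = np.linalg.solve(q.ai, q.grad)
        except np.linalg.LinAlgError:
            delta = np.linalg.pinv(q.ai) @ q.grad
        idx = active + [c]
        accepted = False
        for step in _STEP_SCHEDULE:
            prop = sigma.copy()
            prop[idx] = sigma[idx] + step * delta
            prop[active] = np.maximum(prop[active], floor)
            prop[c] = max(prop[c], floor)
            if ws.loglik(prop, active) >= q.logL - 1e-9 * max(1.0, abs(q.logL)):
                sigma = prop
                accepted = True
                break
        if not accepted:
            # EM-REML update: sigma_i' = sigma_i + sigma_i^2 (yPA_iPy - tr(PA_i)) / n
            prop = sigma.copy()
            for j, i in enumerate(idx):
                prop[i] = sigma[i] + sigma[i] ** 2 * (q.yPAPy[j] - q.trPA[j]) / n
            prop[active] = np.maximum(prop[active], floor)
            prop[c] = max(prop[c], floor)
            sigma = prop

        # components pinned to the floor converge to the boundary: constrain
        for i in list(active):
            if sigma[i] <= floor * 1.5:
                floor_hits[i] += 1
            else:
                floor_hits[i] = 0
            if floor_hits[i] >= 3:
                sigma[i] = 0.0
                active.remove(i)
                constrained[i] = True
                logL_prev = -np.inf  # re-anchor convergence on the reduced model

    if not converged:
        raise ConvergenceError(
            f"REML did not converge in {max_iter} iterations",
            last_state={"sigma2": sigma, "logL": logL_prev, "active": active},
        )

    logL = float(logL_prev)
    # SEs from the AI matrix over the full parameter set at the solution
    q_all = ws.quantities(sigma, list(range(c)))
    try:
        cov = np.linalg.inv(q_all.ai)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(q_all.ai)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))

    sigma_g = sigma[:c]
    sigma_e = float(sigma[c])
    sigma_p = float(sigma_g.sum() + sigma_e)
    h2 = sigma_g / sigma_p
    h2_se = np.empty(c)
    for i in range(c):
        g = np.full(c + 1, -sigma_g[i] / sigma_p**2)
        g[i] += 1.0 / sigma_p
        h2_se[i] = np.sqrt(max(g @ cov @ g, 0.0))

    lrt = max(0.0, 2.0 * (logL - logL0))
    if lrt < 1e-8 * max(1.0, abs(logL0)):  # numerically indistinguishable from 0
        lrt = 0.0
    return RemlFit(
        component_names=names,
        sigma2=sigma_g,
        sigma2_e=sigma_e,
        se=se,
        sigma2_P=sigma_p,
        h2=h2,
        h2_se=h2_se,
        logL=logL,
        logL0=logL0,
        lrt=lrt,
        lrt_p=mixture_lrt_pvalue(lrt, df=c),
        constrained=constrained,
        n_used=n,
        iterations=total_iter,
        converged=True,
        covariance=cov,
        logL_history=history,
    )


# ----------------------------------------------------------------------
def mixture_lrt_pvalue(stat: float, df: int = 1) -> float:
    """P-value from the 50:50 chi2_0 : chi2_df boundary mixture."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if stat < 0:
        stat = 0.0
    return float(0.5 * stats.chi2.sf(stat, df))


def plain_lrt_pvalue(stat: float, df: int = 1) -> float:
    """P-value from a plain chi2_df reference (no boundary mixture)."""
    return float(stats.chi2.sf(max(stat, 0.0), df))


def lrt_p(fit: RemlFit, null_fit: RemlFit = None, mixture: bool = True) -> float:
    """Likelihood-ratio p-value of ``fit`` against a null model.

    Without ``null_fit`` the null is the fixed-effects-only model (all
    genetic components dropped); otherwise the dropped-component count
    sets the mixture's degrees of freedom.
    """
    if null_fit is None:
        logL0, df = fit.logL0, fit.n_components
    else:
        logL0 = null_fit.logL
        df = fit.n_components - null_fit.n_components
        if df < 1:
            raise ValueError("null model must drop at least one component")
    stat = 2.0 * (fit.logL - logL0)
    if stat < -1e-6 * max(1.0, abs(logL0)):
        warnings.warn(
            f"alternative logL {fit.logL:.6f} below null logL {logL0:.6f}; "
            "statistic clamped at 0",
            stacklevel=2,
        )
    stat = max(stat, 0.0)
    return mixture_lrt_pvalue(stat, df) if mixture else plain_lrt_pvalue(stat, df)


def bonferroni_threshold(alpha: float = 0.05, k: int = 49) -> float:
    """Per-test threshold alpha / k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return alpha / k
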