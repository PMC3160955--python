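"""Variance-component mixed models by maximum likelihood.

The phenotype model is ``y = X beta + u + eps`` with ``u`` a sum of random
effects whose covariances are known incidence/correlation matrices (the
genetic matrices from the pedigree module, cage/litter indicators, ...)
scaled by unknown variance parameters, and ``eps ~ N(0, I sigma_e^2)``.
Fixed effects are profiled out by generalized least squares, so the
likelihood is maximized over the variance parameters only.  Estimation is
plain maximum likelihood (not REML); the default optimizer is Nelder-Mead,
chosen for numerical robustness on these boundary-prone surfaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats

__all__ = [
    "VarianceComponent",
    "VarianceModel",
    "FitResult",
    "neg_loglik",
    "fit_ml",
    "lrt_component",
    "select_components",
]

_PENALTY = 1e10
_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class VarianceComponent:
    """One random-effect component: a name, its n x n covariance structure
    (``None`` means the identity, i.e. the residual), and whether its
    parameter is a non-negative variance (the additive-dominance covariance
    term is the one signed exception)."""

    name: str
    matrix: np.ndarray | None = None
    nonnegative: bool = True


@dataclass
class VarianceModel:
    """An ordered set of variance components plus the fixed-effect design.

    The residual component (identity matrix) is appended automatically if
    absent; ``X`` defaults to an intercept.
    """

    components: list
    X: np.ndarray | None = None
    n: int | None = None

    def __post_init__(self):
        comps = []
        for c in self.components:
            if isinstance(c, VarianceComponent):
                comps.append(c)
            elif isinstance(c, str):
                comps.append(VarianceComponent(c, None))
            else:
                name, mat = c[0], c[1]
                nonneg = c[2] if len(c) > 2 else True
                comps.append(VarianceComponent(name, None if mat is None else np.asarray(mat, float), nonneg))
        if not any(c.matrix is None for c in comps):
            comps.append(VarianceComponent("residual", None))
        self.components = comps
        sizes = [c.matrix.shape[0] for c in comps if c.matrix is not None]
        if self.n is None:
            if sizes:
                self.n = sizes[0]
            elif self.X is not None:
                self.n = np.asarray(self.X).shape[0]
        if self.n is not None and any(s != self.n for s in sizes):
            raise ValueError("component matrices have inconsistent dimensions")
        if self.X is None and self.n is not None:
            self.X = np.ones((self.n, 1))
        elif self.X is not None:
            self.X = np.atleast_2d(np.asarray(self.X, float))
            if self.X.shape[0] != self.n:
                self.X = self.X.T
        for c in comps:
            if c.matrix is not None:
                c.matrix = 0.5 * (c.matrix + c.matrix.T)

    @property
    def names(self) -> list:
        return [c.name for c in self.components]

    def sigma(self, params) -> np.ndarray:
        """Assemble the phenotypic covariance for given parameters."""
        S = np.zeros((self.n, self.n))
        for c, p in zip(self.components, params):
            if c.matrix is None:
                S[np.diag_indices_from(S)] += p
            else:
                S += p * c.matrix
        return S


@dataclass
class FitResult:
    """Maximum-likelihood fit of a :class:`VarianceModel`."""

    model: VarianceModel
    estimates: dict
    beta: np.ndarray
    loglik: float
    sigma: np.ndarray
    converged: bool
    n_iter: int
    optimizer: str
    message: str = ""

    @property
    def params(self) -> np.ndarray:
        return np.array([self.estimates[n] for n in self.model.names])

    def summary(self) -> dict:
        return {
            "components": self.estimates,
            "beta": list(map(float, np.atleast_1d(self.beta))),
            "loglik": float(self.loglik),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "optimizer": self.optimizer,
        }


def _gls_profile(S: np.ndarray, X: np.ndarray, y: np.ndarray):
    """Cholesky-based GLS: returns (beta_hat, neg_loglik, cho_factor)."""
    c, low = linalg.cho_factor(S, lower=True, check_finite=False)
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    Si_y = linalg.cho_solve((c, low), y, check_finite=False)
    Si_X = linalg.cho_solve((c, low), X, check_finite=False)
    XtSiX = X.T @ Si_X
    beta = np.linalg.solve(XtSiX, X.T @ Si_y)
    r = y - X @ beta
    quad = float(r @ linalg.cho_solve((c, low), r, check_finite=False))
    n = len(y)
    nll = 0.5 * (n * _LOG2PI + logdet + quad)
    return beta, nll, (c, low)


def neg_loglik(vm: VarianceModel, params, y) -> float:
    """Negative profile log-likelihood at the given variance parameters.

    The fixed effects are replaced by their GLS estimates
    ``beta(params) = (X' S^-1 X)^-1 X' S^-1 y``.  A non-positive-definite
    covariance yields a large penalized value (keeps simplex searches in
    the feasible region) rather than an exception.
    """
    y = np.asarray(y, float)
    params = np.asarray(params, float)
    S = vm.sigma(params)
    try:
        _, nll, _ = _gls_profile(S, vm.X, y)
    except (np.linalg.LinAlgError, linalg.LinAlgError, ValueError):
        return _PENALTY * (1.0 + float(np.sum(params**2)))
    if not np.isfinite(nll):
        return _PENALTY * (1.0 + float(np.sum(params**2)))
    return nll


def _check_design(X: np.ndarray):
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify an offending column via QR pivoting
        _, r, piv = linalg.qr(X, pivoting=True, mode="economic")
        diag = np.abs(np.diag(r))
        bad = sorted(int(piv[k]) for k in range(len(diag)) if diag[k] < 1e-10 * diag.max())
        raise ValueError(f"fixed-effect design is rank-deficient; collinear column(s): {bad}")


def fit_ml(vm: VarianceModel, y, optimizer: str = "nelder-mead", init=None,
           tol: float = 1e-8, max_iter: int = 5000) -> FitResult:
    """Maximize the profile likelihood over the variance parameters.

    Non-negative parameters are searched on the log scale; the signed
    additive-dominance covariance (``nonnegative=False``) is searched
    untransformed.  ``optimizer`` is ``"nelder-mead"`` (default) or
    ``"bfgs"`` (finite-difference gradients).  Deterministic given ``init``.
    """
    y = np.asarray(y, float)
    if vm.n is None:
        vm.n = len(y)
        vm.__post_init__()
    if len(y) != vm.n:
        raise ValueError("y length does not match model dimension")
    if vm.n <= vm.X.shape[1]:
        raise ValueError("need more observations than fixed effects")
    _check_design(vm.X)
    comps = vm.components
    nonneg = np.array([c.nonnegative for c in comps])
    k = len(comps)
    if init is None:
        # equal split of the phenotypic variance across components
        v0 = max(float(np.var(y)), 1e-12) / max(1, int(nonneg.sum()))
        init = np.where(nonneg, v0, 0.0)
    init = np.asarray(init, float)

    def to_raw(z):
        p = np.array(z, float)
        p[nonneg] = np.exp(p[nonneg])
        return p

    z0 = np.array(init, float)
    z0[nonneg] = np.log(np.maximum(z0[nonneg], 1e-12))

    def obj(z):
        return neg_loglik(vm, to_raw(z), y)

    if optimizer in ("nelder-mead", "nelder_mead"):
        res = optimize.minimize(
            obj, z0, method="Nelder-Mead",
            options={"fatol": tol, "xatol": 1e-6, "maxiter": max_iter, "maxfev": 4 * max_iter},
        )
    elif optimizer == "bfgs":
        res = optimize.minimize(obj, z0, method="BFGS",
                                options={"gtol": 1e-8, "maxiter": max_iter})
    else:
        raise ValueError(f"unknown optimizer {optimizer!r}")

    params = to_raw(res.x)
    S = vm.sigma(params)
    beta, nll, _ = _gls_profile(S, vm.X, y)
    return FitResult(
        model=vm,
        estimates={c.name: float(p) for c, p in zip(comps, params)},
        beta=beta,
        loglik=-nll,
        sigma=S,
        converged=bool(res.success),
        n_iter=int(res.get("nit", res.get("nfev", 0))),
        optimizer=optimizer,
        message=str(res.message),
    )


def lrt_component(vm_full: VarianceModel, vm_reduced: VarianceModel, y,
                  boundary: bool = True, **fit_kw):
    """Likelihood-ratio test for extra variance component(s).

    The statistic is ``2 (l_full - l_reduced)``, clamped at zero.  For a
    single extra variance the default p-value uses the 50:50 mixture of a
    point mass at zero and chi-square(1), the correct null for a variance
    tested on its boundary; ``boundary=False`` gives the naive chi-square
    p-value instead (anti-conservative, flagged to the caller by choice).
    """
    full_names = set(vm_full.names)
    red_names = set(vm_reduced.names)
    if not red_names < full_names:
        raise ValueError("models are not nested (reduced components must be a strict subset)")
    extra = len(full_names) - len(red_names)
    fit_f = fit_ml(vm_full, y, **fit_kw)
    fit_r = fit_ml(vm_reduced, y, **fit_kw)
    stat = max(0.0, 2.0 * (fit_f.loglik - fit_r.loglik))
    if boundary and extra == 1:
        p = 1.0 if stat <= 0 else 0.5 * float(stats.chi2.sf(stat, 1))
    else:
        p = float(stats.chi2.sf(stat, extra)) if stat > 0 else 1.0
    return stat, p


@dataclass
class SelectionTrace:
    steps: list = field(default_factory=list)


def select_components(candidates, y, X=None, criterion: str = "aic",
                      alpha: float = 0.05, **fit_kw):
    """Greedy forward selection of variance components.

    Starts from the residual-only model and repeatedly adds the candidate
    that most improves the criterion (``"aic"``, default) or whose
    boundary-corrected LRT p-value is below ``alpha`` (``"lrt_forward"``);
    ties break on candidate order.  Returns ``(VarianceModel, FitResult,
    SelectionTrace)``.
    """
    if criterion not in ("aic", "lrt_forward"):
        raise ValueError(f"unknown criterion {criterion!r}")
    y = np.asarray(y, float)
    cand = []
    for c in candidates:
        if isinstance(c, VarianceComponent):
            cand.append(c)
        else:
            cand.append(VarianceComponent(c[0], np.asarray(c[1], float),
                                          c[2] if len(c) > 2 else True))
    chosen: list = []
    trace = SelectionTrace()
    current = VarianceModel(list(chosen), X=X, n=len(y))
    fit_cur = fit_ml(current, y, **fit_kw)
    while True:
        best = None
        for c in cand:
            if any(c.name == x.name for x in chosen):
                continue
            trial = VarianceModel(chosen + [c], X=X, n=len(y))
            fit_t = fit_ml(trial, y, **fit_kw)
            if criterion == "aic":
                aic_cur = 2 * (len(chosen) + 1) - 2 * fit_cur.loglik
                aic_t = 2 * (len(chosen) + 2) - 2 * fit_t.loglik
                score = aic_cur - aic_t  # positive = improvement
                accept = score > 0
            else:
                stat = max(0.0, 2.0 * (fit_t.loglik - fit_cur.loglik))
                p = 1.0 if stat <= 0 else 0.5 * float(stats.chi2.sf(stat, 1))
                score = -p
                accept = p < alpha
            if accept and (best is None or score > best[0]):
                best = (score, c, fit_t)
        if best is None:
            break
        _, c, fit_t = best
        chosen.append(c)
        trace.steps.append({"added": c.name, "loglik": float(fit_t.loglik)})
        fit_cur = fit_t
        current = fit_t.model
    return current, fit_cur, trace
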