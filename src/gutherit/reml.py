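"""REML variance-component estimation for the animal model with tank effect.

The model for one OTU trait is

    y = X b + Z_a a + Z_t t + e,
    a ~ N(0, G sigma_a^2),  t ~ N(0, I sigma_t^2),  e ~ N(0, I sigma_e^2),

with X a fixed-effect design (intercept + sampling-day factor), G a genomic
relationship matrix over the phenotyped animals, and tanks exchangeable.
Estimation maximises the restricted likelihood by average-information (AI)
updates with expectation-maximisation (EM) steps as a safe fallback, and
projects variance components that drift negative onto the zero boundary
(reported via per-component boundary flags, as mixed-model packages print
"restricted on the boundary of parameter space").

Heritability h^2 = sigma_a^2 / (sigma_a^2 + sigma_t^2 + sigma_e^2) and the
tank fraction c^2 = sigma_t^2 / (same denominator); standard errors of the
ratios come from a first-order delta method on the inverse AI matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnimalModelSpec",
    "VarCompFit",
    "RemlError",
    "fit_animal_model",
    "reml",
    "heritability",
    "tank_fraction",
    "lr_test_genetic",
    "restricted_loglik",
]


class RemlError(RuntimeError):
    """REML failure (non-convergence or singular mixed-model equations)."""

    def __init__(self, message: str, last_fit: "VarCompFit | None" = None):
        super().__init__(message)
        self.last_fit = last_fit


@dataclass
class AnimalModelSpec:
    """Data bundle for one animal-model REML fit.

    ``grm`` must cover every animal in ``data``; the fixed design is an
    intercept plus a sampling-day factor (plus any extra columns in
    ``fixed_covariates``, used by the phenotype-association stage where the
    log OTU abundances enter as regressions).
    """

    response: str
    data: pd.DataFrame  # columns: animal, tank, day, <response>, covariates
    grm: "object"  # gutherit.datatypes.Grm
    day_as_factor: bool = True
    fixed_covariates: tuple[str, ...] = ()

    def build(self):
        df = self.data
        for col in ("animal", "tank", "day", self.response):
            if col not in df.columns:
                raise ValueError(f"model data is missing column '{col}'")
        y = df[self.response].to_numpy(dtype=float)
        n = len(df)

        cols = [np.ones(n)]
        names = ["intercept"]
        if self.day_as_factor:
            days = pd.Categorical(df["day"])
            for lev in days.categories[1:]:
                cols.append((days == lev).astype(float))
                names.append(f"day_{lev}")
        else:
            cols.append(df["day"].to_numpy(dtype=float))
            names.append("day")
        for c in self.fixed_covariates:
            cols.append(df[c].to_numpy(dtype=float))
            names.append(c)
        X = np.column_stack(cols)

        G = self.grm.subset(list(df["animal"].astype(str)))
        tanks = pd.Categorical(df["tank"])
        Zt = np.eye(len(tanks.categories))[tanks.codes]
        T = Zt @ Zt.T
        return y, X, names, G.matrix, T


@dataclass
class VarCompFit:
    """REML estimates for one trait."""

    components: dict  # name -> variance estimate (includes "residual")
    se: dict  # name -> standard error (from inverse AI)
    h2: float | None
    c2: float | None
    h2_se: float | None
    c2_se: float | None
    loglik: float
    boundary: dict  # name -> bool, held at zero
    iterations: int
    converged: bool
    n: int = 0
    fixed_names: list = field(default_factory=list)
    beta: np.ndarray | None = None
    beta_se: np.ndarray | None = None
    beta_cov: np.ndarray | None = None
    ai_inverse: np.ndarray | None = None
    component_names: list = field(default_factory=list)

    @property
    def sigma_a2(self) -> float:
        return self.components.get("animal", 0.0)

    @property
    def sigma_t2(self) -> float:
        return self.components.get("tank", 0.0)

    @property
    def sigma_e2(self) -> float:
        return self.components["residual"]


def restricted_loglik(theta: np.ndarray, y: np.ndarray, X: np.ndarray,
                      structures: list[np.ndarray]) -> float:
    """Restricted log-likelihood at variance components ``theta``.

    -2 logL = log|V| + log|X'V^-1 X| + y'Py (constants dropped), where the
    last structure is the residual identity.  Exposed for oracle-style
    checks and profile-likelihood diagnostics.
    """
    n = len(y)
    V = sum(t * S for t, S in zip(theta, structures))
    L = np.linalg.cholesky(V)
    logdetV = 2.0 * np.sum(np.log(np.diag(L)))
    Vi_X = np.linalg.solve(V, X)
    XtViX = X.T @ Vi_X
    sign, logdetX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        raise np.linalg.LinAlgError("X'V^-1X not positive definite")
    Vi_y = np.linalg.solve(V, y)
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    Py = Vi_y - Vi_X @ beta
    return -0.5 * (logdetV + logdetX + float(y @ Py))


def _reml_inner(y, X, structures, names, tol_ll=1e-8, tol_par=1e-6,
                max_iter=200, n_em=3, held0=None, ridge=1e-6):
    """AI-REML with EM warm-up and zero-boundary projection.

    ``structures`` are the covariance matrices of the random terms, the
    last being the residual identity (never held at zero).  Returns the
    final parameter vector, restricted log-likelihood, AI matrix over all
    components, GLS fixed-effect solution, flags, and iteration count.
    """
    n, p = X.shape
    k = len(structures)
    vary = float(np.var(y, ddof=1))
    if vary <= 0:
        raise RemlError("response has zero variance")
    theta = np.full(k, vary / k)
    held = np.zeros(k, dtype=bool) if held0 is None else held0.copy()
    theta[held] = 0.0
    I_n = np.eye(n)

    ll_prev = -np.inf
    converged = False
    it = 0
    stalled = 0
    floor = 1e-10 * vary
    pin_val = 1e-5 * vary  # holding pen before a component is fixed at zero
    pins = np.zeros(k, dtype=int)
    for it in range(1, max_iter + 1):
        V = sum(t * S for t, S in zip(theta, structures))
        V[np.diag_indices_from(V)] += ridge * vary
        try:
            c = np.linalg.cholesky(V)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - safety
            raise RemlError(f"V not positive definite at iteration {it}") from exc
        Vinv = np.linalg.solve(V, I_n)
        A = Vinv @ X
        XtViX = X.T @ A
        try:
            B = np.linalg.solve(XtViX, A.T)
        except np.linalg.LinAlgError as exc:
            raise RemlError("singular mixed-model equations "
                            "(rank-deficient fixed design?)") from exc
        P = Vinv - A @ B
        Py = P @ y
        logdetV = 2.0 * np.sum(np.log(np.diag(c)))
        sign, logdetX = np.linalg.slogdet(XtViX)
        ll = -0.5 * (logdetV + logdetX + float(y @ Py))

        SPy = [S @ Py for S in structures]  # V_i P y
        trPS = np.array([float(np.sum(P * S)) for S in structures])
        yPSPy = np.array([float(Py @ s) for s in SPy])
        grad = 0.5 * (yPSPy - trPS)
        PSPy = [P @ s for s in SPy]
        AI = 0.5 * np.array([[float(SPy[i] @ PSPy[j]) for j in range(k)]
                             for i in range(k)])

        free = ~held

        def _em_update():
            new = theta.copy()
            new[free] = theta[free] + (theta[free] ** 2 / n) * (
                yPSPy[free] - trPS[free])
            return new

        def _project(cand):
            out = cand.copy()
            out[:k - 1] = np.maximum(out[:k - 1], 0.0)
            out[k - 1] = max(out[k - 1], floor)
            return out

        def _safe_ll(cand):
            try:
                return restricted_loglik(
                    cand + np.where(np.arange(k) == k - 1, ridge * vary, 0.0),
                    y, X, structures)
            except np.linalg.LinAlgError:
                return -np.inf

        if it <= n_em:
            new = _project(_em_update())
        else:
            AIf = AI[np.ix_(free, free)]
            try:
                step = np.linalg.solve(AIf, grad[free])
            except np.linalg.LinAlgError:
                step = grad[free] / np.maximum(np.diag(AIf), 1e-12)
            new = theta.copy()
            new[free] = theta[free] + step
            new = _project(new)
            # step-halve toward the current point if the AI step hurts
            factor = 1.0
            while _safe_ll(new) < ll - 1e-10 and factor > 1.0 / 64.0:
                factor *= 0.5
                new = theta.copy()
                new[free] = theta[free] + factor * step
                new = _project(new)
            if _safe_ll(new) < ll - 1e-10:
                new = _project(_em_update())

        # boundary handling: a negative proposal is first pinned at a small
        # positive value; only a component pinned repeatedly with the
        # gradient still pushing down is fixed at zero and held
        for i in range(k - 1):  # residual never held
            if not free[i]:
                continue
            if new[i] <= pin_val:
                new[i] = pin_val
                pins[i] += 1
                if pins[i] >= 3 and grad[i] < 0:
                    new[i] = 0.0
                    held[i] = True
            else:
                pins[i] = 0

        delta = np.max(np.abs(new - theta))
        theta = new
        if it > 1:
            rel_ll = abs(ll - ll_prev) / (abs(ll_prev) + 1.0)
            stalled = stalled + 1 if rel_ll < tol_ll else 0
            # converged when both objective and parameters settle, or when
            # the objective is stationary for several iterations (parameter
            # movement along a flat ridge of a non-identifiable split does
            # not change the fit)
            if rel_ll < tol_ll and (delta < tol_par * max(vary, 1.0)
                                    or stalled >= 3):
                converged = True
                ll_prev = ll
                break
        ll_prev = ll

    # final likelihood and AI at the returned estimates
    ll_final = restricted_loglik(
        np.maximum(theta, 0.0) + np.where(np.arange(k) == k - 1, ridge * vary, 0.0),
        y, X, structures)
    return theta, ll_final, AI, held, it, converged, (Vinv, P, Py, XtViX)


def reml(
    y: np.ndarray,
    X: np.ndarray,
    random_structures: list[tuple[str, np.ndarray]],
    tol_ll: float = 1e-8,
    tol_par: float = 1e-6,
    max_iter: int = 200,
    restart_boundary: bool = True,
    ridge: float = 1e-6,
    fixed_names: list | None = None,
) -> VarCompFit:
    """Fit a Gaussian mixed model by AI-REML.

    ``random_structures`` is a list of (name, covariance matrix) pairs; a
    residual identity term is appended automatically.  Components that hit
    zero are projected to the boundary and held; each held component is
    restarted once from a small positive value so that a spurious early
    boundary does not stick.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if n <= p:
        raise RemlError(f"need n > rank(X): n={n}, p={p}")
    if np.linalg.matrix_rank(X) < p:
        raise RemlError("fixed design X is rank deficient")
    names = [nm for nm, _ in random_structures] + ["residual"]
    structures = [np.asarray(S, dtype=float) for _, S in random_structures]
    structures.append(np.eye(n))
    k = len(structures)

    theta, ll, AI, held, it, converged, aux = _reml_inner(
        y, X, structures, names, tol_ll, tol_par, max_iter, ridge=ridge)

    if restart_boundary and held.any():
        # one restart of boundary components from a small positive value
        vary = float(np.var(y, ddof=1))
        held_try = np.zeros(k, dtype=bool)
        theta2, ll2, AI2, held2, it2, conv2, aux2 = _reml_inner(
            y, X, structures, names, tol_ll, tol_par, max_iter,
            n_em=6, held0=held_try, ridge=ridge)
        if conv2 and ll2 > ll + 1e-6:
            theta, ll, AI, held, converged, aux = theta2, ll2, AI2, held2, conv2, aux2
        it += it2

    if not converged:
        last = _pack_fit(theta, ll, AI, held, names, it, converged, y, X, aux)
        raise RemlError(f"REML did not converge in {max_iter} iterations", last)

    return _pack_fit(theta, ll, AI, held, names, it, converged, y, X, aux,
                     fixed_names=fixed_names)


def _pack_fit(theta, ll, AI, held, names, it, converged, y, X, aux,
              fixed_names=None):
    k = len(theta)
    try:
        AIinv = np.linalg.inv(AI)
        se_vec = np.sqrt(np.maximum(np.diag(AIinv), 0.0))
    except np.linalg.LinAlgError:
        AIinv = np.linalg.pinv(AI)
        se_vec = np.sqrt(np.maximum(np.diag(AIinv), 0.0))
    components = {nm: float(max(t, 0.0)) for nm, t in zip(names, theta)}
    se = {nm: float(s) for nm, s in zip(names, se_vec)}
    boundary = {nm: bool(h) for nm, h in zip(names, held)}

    total = sum(components.values())
    h2 = c2 = h2_se = c2_se = None
    if "animal" in components and total > 0:
        h2 = components["animal"] / total
        grad = _ratio_grad(names, "animal", theta)
        h2_se = float(np.sqrt(max(grad @ AIinv @ grad, 0.0)))
    if "tank" in components and total > 0:
        c2 = components["tank"] / total
        grad = _ratio_grad(names, "tank", theta)
        c2_se = float(np.sqrt(max(grad @ AIinv @ grad, 0.0)))

    Vinv, P, Py, XtViX = aux
    XtVi_y = X.T @ (Vinv @ y)
    beta = np.linalg.solve(XtViX, XtVi_y)
    beta_cov = np.linalg.inv(XtViX)
    beta_se = np.sqrt(np.diag(beta_cov))
    return VarCompFit(
        components=components,
        se=se,
        h2=h2,
        c2=c2,
        h2_se=h2_se,
        c2_se=c2_se,
        loglik=float(ll),
        boundary=boundary,
        iterations=it,
        converged=converged,
        n=len(y),
        fixed_names=list(fixed_names) if fixed_names else [],
        beta=beta,
        beta_se=beta_se,
        beta_cov=beta_cov,
        ai_inverse=AIinv,
        component_names=list(names),
    )


def _ratio_grad(names, num_name, theta):
    """d(theta_i / sum theta)/d theta for the delta method."""
    total = float(np.sum(np.maximum(theta, 0.0)))
    i = names.index(num_name)
    g = np.full(len(theta), -max(theta[i], 0.0) / total**2)
    g[i] = (total - max(theta[i], 0.0)) / total**2
    return g


def fit_animal_model(spec: AnimalModelSpec, include_genetic: bool = True,
                     include_tank: bool = True, **kwargs) -> VarCompFit:
    """REML fit of the animal model described by ``spec``.

    Setting ``include_genetic=False`` fits the null model for the
    likelihood-ratio test of the additive genetic component.
    """
    y, X, names, G, T = spec.build()
    rs = []
    if include_genetic:
        rs.append(("animal", G))
    if include_tank:
        rs.append(("tank", T))
    return reml(y, X, rs, fixed_names=names, **kwargs)


def heritability(va: float, vt: float, ve: float) -> float:
    """h^2 = sigma_a^2 / (sigma_a^2 + sigma_t^2 + sigma_e^2)."""
    for v in (va, vt, ve):
        if v < 0:
            raise ValueError("variance components must be non-negative")
    total = va + vt + ve
    if total <= 0:
        raise ValueError("total variance must be positive")
    return va / total


def tank_fraction(va: float, vt: float, ve: float) -> float:
    """c^2 = sigma_t^2 / (sigma_a^2 + sigma_t^2 + sigma_e^2)."""
    for v in (va, vt, ve):
        if v < 0:
            raise ValueError("variance components must be non-negative")
    total = va + vt + ve
    if total <= 0:
        raise ValueError("total variance must be positive")
    return vt / total


def lr_test_genetic(fit_h1: VarCompFit, fit_h0: VarCompFit,
                    boundary_mixture: bool = False) -> tuple[float, float]:
    """Likelihood-ratio test of the additive genetic component.

    LR = 2 (logL_H1 - logL_H0), floored at zero.  By default the p-value
    uses a chi-square with 1 df; ``boundary_mixture=True`` uses the
    boundary-corrected 1/2 chi2(0) : 1/2 chi2(1) mixture instead.
    """
    if fit_h1.n != fit_h0.n:
        raise ValueError("H1 and H0 fits are on different data sizes")
    lr = max(0.0, 2.0 * (fit_h1.loglik - fit_h0.loglik))
    if boundary_mixture:
        p = 0.5 * stats.chi2.sf(lr, df=1) if lr > 0 else 1.0
    else:
        p = float(stats.chi2.sf(lr, df=1)) if lr > 0 else 1.0
    return lr, float(p)
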