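"""BFGS maximization of the REML log-likelihood.

The likelihood is maximized over the free factor loadings by BFGS with a
golden-section line search; the inverse-Hessian approximation starts as a
scaled identity so the first iteration is a gradient-ascent step.  When the
search goes unstable (non-finite values or a failed line search) the
approximation is reinitialized; if instability persists, a single damped
Newton step using the average-information matrix is taken, after which BFGS
resumes.  Only likelihood and gradient evaluations are needed per ordinary
iteration, keeping the per-iteration cost at O(nT^2) for a saturated model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .exceptions import NumericalError
from .factors import (
    FactorModelSpec,
    ParameterVector,
    implied_variance_matrices,
    parameter_index,
)
from .kernel import average_information, reml_loglik, reml_loglik_and_gradient
from .transform import TransformedDataset

__all__ = [
    "FitConfig",
    "FitResult",
    "LineSearchResult",
    "golden_section_search",
    "initial_theta",
    "fit_model",
]

logger = logging.getLogger(__name__)

_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0  # 0.618...


@dataclass
class FitConfig:
    """Optimizer settings.

    grad_tol is the convergence threshold on the RMS gradient per retained
    observation (RMS(grad)/n), making it invariant to sample size.
    """

    grad_tol: float = 1e-5
    max_iter: int = 300
    gss_tol: float = 1e-6
    gss_max_bracket: int = 20
    reset_patience: int = 2
    ai_after_resets: int = 2
    seed: int = 0
    init_jitter: float = 0.01

    def __post_init__(self) -> None:
        if min(self.grad_tol, self.gss_tol) <= 0 or self.max_iter < 1:
            raise ValueError("tolerances must be positive and max_iter >= 1")


@dataclass
class TraceRecord:
    iteration: int
    loglik: float
    grad_rms_per_obs: float
    step: float
    tag: str


@dataclass
class FitResult:
    """Outcome of a REML fit: estimates, path and (optionally) curvature."""

    theta_hat: ParameterVector
    loglik: float
    n_iter: int
    converged: bool
    trace: list[TraceRecord]
    ai_matrix: np.ndarray | None = None
    theta_cov: np.ndarray | None = None
    spec_g: FactorModelSpec | None = None
    spec_e: FactorModelSpec | None = None


@dataclass
class LineSearchResult:
    step: float
    f_step: float
    n_eval: int
    success: bool


def golden_section_search(
    f,
    upper: float = 1.0,
    tol: float = 1e-6,
    max_bracket: int = 20,
) -> LineSearchResult:
    """Maximize f over step lengths in (0, upper-grown-geometrically].

    The bracket upper end is doubled while the objective keeps improving
    (at most ``max_bracket`` times), then the interval is contracted by the
    golden ratio to width ``tol``.  Non-finite values are treated as -inf.
    A result with ``success=False`` means no step improved on f(0).
    """

    def _f(s: float) -> float:
        val = f(s)
        return val if np.isfinite(val) else -np.inf

    n_eval = 0

    def ev(s: float) -> float:
        nonlocal n_eval
        n_eval += 1
        return _f(s)

    f0 = _f(0.0)
    if not np.isfinite(f0):
        raise NumericalError("line search started from a non-finite objective")

    hi = float(upper)
    f_hi = ev(hi)
    # geometric bracket growth while the end point keeps improving
    for _ in range(max_bracket):
        f_next = ev(2.0 * hi)
        if f_next <= f_hi:
            break
        hi *= 2.0
        f_hi = f_next

    lo = 0.0
    best_s, best_f = (hi, f_hi) if f_hi > f0 else (0.0, f0)
    c = hi - _INVPHI * (hi - lo)
    d = lo + _INVPHI * (hi - lo)
    f_c, f_d = ev(c), ev(d)
    for s, f_s in ((c, f_c), (d, f_d)):
        if f_s > best_f:
            best_s, best_f = s, f_s
    while hi - lo > tol:
        if f_c >= f_d:
            hi, d, f_d = d, c, f_c
            c = hi - _INVPHI * (hi - lo)
            f_c = ev(c)
            if f_c > best_f:
                best_s, best_f = c, f_c
        else:
            lo, c, f_c = c, d, f_d
            d = lo + _INVPHI * (hi - lo)
            f_d = ev(d)
            if f_d > best_f:
                best_s, best_f = d, f_d
    success = best_s > 0.0 and best_f > f0
    return LineSearchResult(step=best_s, f_step=best_f, n_eval=n_eval, success=success)


def initial_theta(
    td: TransformedDataset,
    spec_g: FactorModelSpec,
    spec_e: FactorModelSpec,
    seed: int = 0,
    jitter: float = 0.01,
) -> ParameterVector:
    """Starting values splitting each trait's variance 50/50.

    Free diagonal loadings start at sqrt(half the transformed-trait variance);
    off-diagonal free loadings at a tenth of the trait SD (nonzero to break
    the sign symmetry between factors).  A small seeded relative jitter makes
    restarts distinct yet reproducible.
    """
    index = parameter_index(spec_g, spec_e)
    var_t = np.maximum(np.var(td.Ystar, axis=1), 1e-12)
    sd_t = np.sqrt(var_t)
    values = np.empty(len(index))
    for i, (tag, t, f) in enumerate(index):
        values[i] = np.sqrt(0.5 * var_t[t]) if t == f else 0.1 * sd_t[t]
    if jitter > 0:
        rng = np.random.default_rng(seed)
        values *= 1.0 + jitter * rng.uniform(-1.0, 1.0, size=values.size)
    return ParameterVector(values=values, index=index)


def fit_model(
    td: TransformedDataset,
    spec_g: FactorModelSpec,
    spec_e: FactorModelSpec,
    cfg: FitConfig | None = None,
    theta0: ParameterVector | None = None,
) -> FitResult:
    """Maximize the REML log-likelihood over the free loadings by BFGS."""
    cfg = cfg or FitConfig()
    theta = theta0 or initial_theta(td, spec_g, spec_e, cfg.seed, cfg.init_jitter)
    p = len(theta)
    nobs = td.n

    def vs_of(values: np.ndarray):
        return implied_variance_matrices(theta.replace(values), spec_g, spec_e)

    def ll_only(values: np.ndarray) -> float:
        try:
            return reml_loglik(td, vs_of(values)).loglik
        except NumericalError:
            return -np.inf

    def ll_grad(values: np.ndarray):
        st = reml_loglik_and_gradient(td, vs_of(values), theta.replace(values))
        return st.loglik, st.grad

    x = theta.values.copy()
    ll, g = ll_grad(x)
    if not np.isfinite(ll):
        raise NumericalError("log-likelihood non-finite at the starting values")

    def fresh_h() -> np.ndarray:
        # scaled identity: makes the first golden-section bracket O(1) long
        return np.eye(p) / max(1.0, float(np.linalg.norm(g)))

    h = fresh_h()
    trace: list[TraceRecord] = []
    fail_streak = 0
    resets = 0
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        rms = float(np.sqrt(np.mean(g**2))) / nobs
        if rms < cfg.grad_tol:
            converged = True
            trace.append(TraceRecord(it, ll, rms, 0.0, "converged"))
            break
        direction = h @ g
        tag = "bfgs"
        if float(direction @ g) <= 0.0 or not np.isfinite(direction).all():
            h = fresh_h()
            direction = h @ g
            tag = "steepest"
        ls = golden_section_search(
            lambda s: ll_only(x + s * direction),
            upper=1.0,
            tol=cfg.gss_tol,
            max_bracket=cfg.gss_max_bracket,
        )
        if not ls.success:
            fail_streak += 1
            trace.append(TraceRecord(it, ll, rms, 0.0, "line-search-failed"))
            if fail_streak >= cfg.reset_patience:
                h = fresh_h()
                resets += 1
                fail_streak = 0
                trace.append(TraceRecord(it, ll, rms, 0.0, "hessian-reset"))
                if resets >= cfg.ai_after_resets:
                    ok, x, ll, g = _ai_step(td, spec_g, spec_e, theta, x, ll, g,
                                            ll_grad, trace, it, rms)
                    resets = 0
                    if not ok:
                        break
            continue
        fail_streak = 0
        x_new = x + ls.step * direction
        try:
            ll_new, g_new = ll_grad(x_new)
        except NumericalError:
            fail_streak += 1
            trace.append(TraceRecord(it, ll, rms, ls.step, "gradient-failed"))
            continue
        s_vec = x_new - x
        y_min = g - g_new  # gradient change of the minimized (-ll) objective
        sy = float(s_vec @ y_min)
        if sy > 1e-12 * float(np.linalg.norm(s_vec)) * float(np.linalg.norm(y_min)):
            hy = h @ y_min
            h = (
                h
                + ((sy + float(y_min @ hy)) / sy**2) * np.outer(s_vec, s_vec)
                - (np.outer(hy, s_vec) + np.outer(s_vec, hy)) / sy
            )
        # else: curvature condition failed; skip the update, keep h
        x, ll, g = x_new, ll_new, g_new
        trace.append(TraceRecord(it, ll, rms, ls.step, tag))
    else:
        logger.warning("REML did not converge in %d iterations", cfg.max_iter)

    return FitResult(
        theta_hat=theta.replace(x),
        loglik=ll,
        n_iter=it,
        converged=converged,
        trace=trace,
        spec_g=spec_g,
        spec_e=spec_e,
    )


def _ai_step(td, spec_g, spec_e, theta, x, ll, g, ll_grad, trace, it, rms):
    """One damped Newton step with the AI matrix as curvature (then back to BFGS).

    Solves (AI + ridge I) delta = grad with the ridge doubled, and the step
    halved, until the log-likelihood improves; gives up after a fixed number
    of attempts.
    """
    vs = implied_variance_matrices(theta.replace(x), spec_g, spec_e)
    try:
        ai = average_information(td, vs, theta.replace(x))
    except NumericalError:
        trace.append(TraceRecord(it, ll, rms, 0.0, "ai-failed"))
        return False, x, ll, g
    ridge = 1e-4 * max(float(np.trace(ai)) / ai.shape[0], 1e-8)
    for _ in range(30):
        try:
            delta = np.linalg.solve(ai + ridge * np.eye(ai.shape[0]), g)
        except np.linalg.LinAlgError:
            ridge *= 2.0
            continue
        cand = delta.copy()
        for _ in range(5):  # step halving
            try:
                ll_new, g_new = ll_grad(x + cand)
            except NumericalError:
                ll_new = -np.inf
            if np.isfinite(ll_new) and ll_new > ll:
                trace.append(TraceRecord(it, ll_new, rms, 1.0, "ai-step"))
                return True, x + cand, ll_new, g_new
            cand /= 2.0
        ridge *= 2.0
    trace.append(TraceRecord(it, ll, rms, 0.0, "ai-no-ascent"))
    return False, x, ll, g
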