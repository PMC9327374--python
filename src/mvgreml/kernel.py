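"""REML log-likelihood, gradient and average-information kernel.

After the canonical transform the model covariance is block diagonal with
T x T blocks V_j = d_j V_G + V_E.  One simultaneous diagonalization of
(V_G, V_E) per parameter value — Cholesky of V_E followed by a symmetric
eigensolve — yields a whitening transform W with W V_E W' = I and
W V_G W' = diag(lam), so that every block becomes diagonal:
W V_j W' = d_j diag(lam) + I.  Log-determinants and quadratic forms then cost
O(T^2) per block and the whole likelihood O(n T (T + k)).

The REML log-likelihood, omitting its additive constant, is

    ell = -1/2 ( log|V| + log|Z' V^-1 Z| + y' M y ),

with M = V^-1 - V^-1 Z (Z'V^-1 Z)^-1 Z' V^-1.  M is only ever applied to
vectors; the dense oracle below materializes everything and exists purely as
an independent correctness check at tiny problem sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .data import CovariateData, GrmData, PhenotypeMatrix, add_intercept
from .exceptions import NumericalError
from .factors import (
    FactorModelSpec,
    ParameterVector,
    VarianceStructure,
    implied_variance_matrices,
)
from .transform import TransformedDataset

__all__ = [
    "BlockDiagonalizer",
    "RemlKernelState",
    "diagonalize_pair",
    "reml_loglik",
    "reml_gradient",
    "reml_loglik_and_gradient",
    "average_information",
    "dense_reml_oracle",
]

_JITTER_REL = 1e-8
_BLOCK_FLOOR = 1e-12


@dataclass
class BlockDiagonalizer:
    """Simultaneous whitening of (V_G, V_E).

    W V_E W' = I and W V_G W' = diag(lam); hence for any block
    W V_j W' = d_j diag(lam) + I.
    """

    Lchol: np.ndarray
    U: np.ndarray
    lam: np.ndarray
    W: np.ndarray
    logdet_VE: float


@dataclass
class RemlKernelState:
    """Log-likelihood and the per-block aggregates behind it."""

    loglik: float
    logdetV: float
    logdetXtVinvX: float
    quad: float
    XtVinvX: np.ndarray | None
    XtVinvY: np.ndarray | None
    beta_gls: np.ndarray | None
    grad: np.ndarray | None = None


def diagonalize_pair(vs: VarianceStructure) -> BlockDiagonalizer:
    """Cholesky V_E = L L', eigensolve L^-1 V_G L^-T, whiten with W = U' L^-1.

    If V_E is not positive definite a single jitter of 1e-8 * mean(diag(V_E))
    is added; a second failure aborts with advice to bring the environmental
    model closer to saturated.
    """
    v_e = vs.V_E
    try:
        lch = scipy.linalg.cholesky(v_e, lower=True)
    except scipy.linalg.LinAlgError:
        scale = float(np.mean(np.diag(v_e)))
        if not np.isfinite(scale) or scale <= 0:
            raise NumericalError("V_E has a non-positive diagonal; model unfittable")
        try:
            lch = scipy.linalg.cholesky(
                v_e + _JITTER_REL * scale * np.eye(v_e.shape[0]), lower=True
            )
        except scipy.linalg.LinAlgError:
            raise NumericalError(
                "environmental variance matrix is singular; specify an "
                "environmental factor model that is (closer to) saturated"
            ) from None
    linv_vg = scipy.linalg.solve_triangular(lch, vs.V_G, lower=True)
    b = scipy.linalg.solve_triangular(lch, linv_vg.T, lower=True).T
    b = (b + b.T) / 2.0
    lam, u = scipy.linalg.eigh(b)
    lam = np.clip(lam, 0.0, None)
    w = scipy.linalg.solve_triangular(lch, u, lower=True, trans="T").T  # U' L^-1
    return BlockDiagonalizer(
        Lchol=lch,
        U=u,
        lam=lam,
        W=w,
        logdet_VE=2.0 * float(np.log(np.diag(lch)).sum()),
    )


def _whitened_pieces(td: TransformedDataset, bd: BlockDiagonalizer):
    """Per-block quantities in whitened coordinates, fully vectorized."""
    d = td.d
    denom = bd.lam[:, None] * d[None, :] + 1.0  # T x n
    if (denom <= _BLOCK_FLOOR).any():
        raise NumericalError("a covariance block is numerically singular")
    w = 1.0 / denom
    yw = bd.W @ td.Ystar  # T x n
    z3 = td.design_tensor
    if z3 is None:
        return w, yw, None, None
    zw = np.einsum("ab,nbp->nap", bd.W, z3)  # n x T x p
    phi = zw * w.T[:, :, None]  # V_j^-1-weighted design, whitened
    return w, yw, zw, phi


def _state(td: TransformedDataset, bd: BlockDiagonalizer):
    n = td.n
    w, yw, zw, phi = _whitened_pieces(td, bd)
    logdet_v = n * bd.logdet_VE - float(np.log(w).sum())
    y_vinv_y = float((w * yw**2).sum())
    if zw is None:
        state = RemlKernelState(
            loglik=-0.5 * (logdet_v + y_vinv_y),
            logdetV=logdet_v,
            logdetXtVinvX=0.0,
            quad=y_vinv_y,
            XtVinvX=None,
            XtVinvY=None,
            beta_gls=None,
        )
        return state, (w, yw, zw, phi, None)
    xtvx = np.einsum("nap,naq->pq", zw, phi)
    xtvy = np.einsum("nap,an->p", phi, yw)
    try:
        cho = scipy.linalg.cho_factor(xtvx)
    except scipy.linalg.LinAlgError:
        labels = ", ".join(f"{t}:{c}" for t, c in td.beta_labels)
        raise NumericalError(
            f"Z'V^-1 Z is rank deficient (collinear covariates?) among [{labels}]"
        ) from None
    beta = scipy.linalg.cho_solve(cho, xtvy)
    quad = y_vinv_y - float(xtvy @ beta)
    logdet_x = 2.0 * float(np.log(np.abs(np.diag(cho[0]))).sum())
    state = RemlKernelState(
        loglik=-0.5 * (logdet_v + logdet_x + quad),
        logdetV=logdet_v,
        logdetXtVinvX=logdet_x,
        quad=quad,
        XtVinvX=xtvx,
        XtVinvY=xtvy,
        beta_gls=beta,
    )
    return state, (w, yw, zw, phi, cho)


def reml_loglik(td: TransformedDataset, vs: VarianceStructure) -> RemlKernelState:
    """Evaluate the transformed REML log-likelihood (constant omitted)."""
    bd = diagonalize_pair(vs)
    state, _ = _state(td, bd)
    return state


def _residual_rho(w, yw, zw, beta):
    """Whitened, V^-1-weighted residuals: rho_j = D_j^-1 (y~_j - Z~_j beta)."""
    if zw is None:
        return w * yw
    fit = np.einsum("nap,p->an", zw, beta)
    return w * (yw - fit)


def reml_loglik_and_gradient(
    td: TransformedDataset,
    vs: VarianceStructure,
    theta: ParameterVector,
) -> RemlKernelState:
    """Log-likelihood plus the analytic gradient with respect to theta.

    Uses the standard REML identity
    d ell / d theta_i = -1/2 [ tr(M dV_i) - y' M dV_i M y ],
    with dV_i = D (x) dV_G or I (x) dV_E.  Because dV_G/dgamma_tf is the
    rank-2 matrix e_t c_f' + c_f e_t', all components reduce to the two T x T
    accumulators
        M_G = sum_j d_j ([M]_jj - r_j r_j'),   M_E = sum_j ([M]_jj - r_j r_j'),
    with r = M y, after which grad_G = -(M_G C_G) on the free cells (and
    analogously for the environment).
    """
    bd = diagonalize_pair(vs)
    state, (w, yw, zw, phi, cho) = _state(td, bd)
    d = td.d

    s_g = (w * d[None, :]).sum(axis=1)  # diag of sum_j d_j V_j^-1 (whitened)
    s_e = w.sum(axis=1)
    rho = _residual_rho(w, yw, zw, state.beta_gls)
    rg_w = (rho * d[None, :]) @ rho.T
    re_w = rho @ rho.T
    if zw is not None:
        ci = scipy.linalg.cho_solve(cho, np.eye(state.XtVinvX.shape[0]))
        psi = np.einsum("nap,pq->naq", phi, ci)
        kg_w = np.einsum("n,nap,nbp->ab", d, psi, phi)
        ke_w = np.einsum("nap,nbp->ab", psi, phi)
    else:
        kg_w = ke_w = 0.0

    mg = bd.W.T @ (np.diag(s_g) - kg_w - rg_w) @ bd.W
    me = bd.W.T @ (np.diag(s_e) - ke_w - re_w) @ bd.W
    grad_g_full = -(mg @ vs.C_G)
    grad_e_full = -(me @ vs.C_E)

    grad = np.empty(len(theta))
    for i, (tag, t, f) in enumerate(theta.index):
        grad[i] = grad_g_full[t, f] if tag == "G" else grad_e_full[t, f]
    state.grad = grad
    return state


def reml_gradient(
    td: TransformedDataset, vs: VarianceStructure, theta: ParameterVector
) -> np.ndarray:
    """Analytic gradient of the REML log-likelihood with respect to theta."""
    return reml_loglik_and_gradient(td, vs, theta).grad


def average_information(
    td: TransformedDataset,
    vs: VarianceStructure,
    theta: ParameterVector,
) -> np.ndarray:
    """Average-information matrix AI_ij = 1/2 y'M (dV_i) M (dV_j) M y.

    With r = M y and s_i = dV_i r, AI_ij = 1/2 s_i' M s_j; the rank-2 structure
    of each dV_i makes building every s_i an O(nT) operation.  Intended for use
    at the optimum, where AI is the information estimate behind the standard
    errors (skipped entirely under --no-se).
    """
    bd = diagonalize_pair(vs)
    state, (w, yw, zw, phi, cho) = _state(td, bd)
    d = td.d
    rho = _residual_rho(w, yw, zw, state.beta_gls)
    r = bd.W.T @ rho  # M y, per block, original coordinates

    p = len(theta)
    s_stack = np.empty((p, td.n_traits, td.n))
    for i, (tag, t, f) in enumerate(theta.index):
        c_vec = (vs.C_G if tag == "G" else vs.C_E)[:, f]
        scale = d if tag == "G" else 1.0
        cr = c_vec @ r  # length n
        s_i = np.outer(np.eye(td.n_traits)[t], cr) + np.outer(c_vec, r[t])
        s_stack[i] = s_i * scale
    sw = np.einsum("ab,ibn->ian", bd.W, s_stack)
    ai = np.einsum("ian,an,jan->ij", sw, w, sw)
    if zw is not None:
        b = np.einsum("nap,ian->ip", phi, sw)
        ai -= b @ scipy.linalg.cho_solve(cho, b.T)
    ai = (ai + ai.T) / 4.0  # the 1/2 factor, symmetrized
    return ai


# ---------------------------------------------------------------------------
# Dense oracle (test scale only)
# ---------------------------------------------------------------------------

def dense_reml_oracle(
    grm: GrmData,
    phen: PhenotypeMatrix,
    covar: CovariateData | None,
    vs: VarianceStructure,
    include_intercept: bool = True,
) -> float:
    """Untransformed REML log-likelihood with V = V_G (x) A + V_E (x) I_N.

    Materializes the full NT x NT covariance and the block-diagonal
    fixed-effect design; O((NT)^3), so test scale only.  Serves as the
    independent equivalence oracle for :func:`reml_loglik` at L = 0.
    """
    n, t = phen.n, phen.n_traits
    if include_intercept or covar is not None:
        covar = add_intercept(covar, phen.ids, t)
    v = np.kron(vs.V_G, grm.A) + np.kron(vs.V_E, np.eye(n))
    y = phen.Y.T.reshape(-1)  # (y_1; ...; y_T), trait-major

    sign, logdet_v = np.linalg.slogdet(v)
    if sign <= 0:
        raise NumericalError("dense covariance matrix is not positive definite")
    vinv_y = np.linalg.solve(v, y)
    quad_full = float(y @ vinv_y)

    if covar is None:
        return -0.5 * (logdet_v + quad_full)
    blocks = [covar.X[:, np.flatnonzero(covar.trait_map[i])] for i in range(t)]
    z = scipy.linalg.block_diag(*blocks)
    vinv_z = np.linalg.solve(v, z)
    xtvx = z.T @ vinv_z
    xtvy = z.T @ vinv_y
    sign_x, logdet_x = np.linalg.slogdet(xtvx)
    if sign_x <= 0:
        raise NumericalError("dense Z'V^-1 Z is singular")
    quad = quad_full - float(xtvy @ np.linalg.solve(xtvx, xtvy))
    return -0.5 * (logdet_v + logdet_x + quad)
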