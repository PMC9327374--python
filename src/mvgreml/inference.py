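"""From fitted loadings to heritabilities, correlations, SEs, GLS and LRTs.

SNP-based heritability of trait t is h2_t = sG_tt / (sG_tt + sE_tt) and the
genetic correlation between traits t and s is rho_G(t,s) =
sG_ts / sqrt(sG_tt sG_ss), both smooth functions of the free loadings theta
through V = C C'.  Standard errors come from first-order (delta-method)
propagation of the inverse average-information matrix.  Traits with zero
genetic variance have undefined genetic correlations, reported as NaN rather
than zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy import stats

from .exceptions import InputError, NumericalError
from .factors import (
    FactorModelSpec,
    ParameterVector,
    VarianceStructure,
    implied_variance_matrices,
)
from .transform import TransformedDataset

__all__ = [
    "HeritabilityReport",
    "LrtResult",
    "FixedEffectsReport",
    "heritability_and_correlations",
    "delta_method_ses",
    "gls_fixed_effects",
    "likelihood_ratio_test",
    "theta_covariance",
]

logger = logging.getLogger(__name__)


@dataclass
class HeritabilityReport:
    """Point estimates and SEs for h2, rho_G and rho_E (NaN where undefined)."""

    trait_labels: list[str]
    h2: np.ndarray
    h2_se: np.ndarray | None
    rhoG: np.ndarray
    rhoG_se: np.ndarray | None
    rhoE: np.ndarray
    rhoE_se: np.ndarray | None


@dataclass
class LrtResult:
    """Likelihood-ratio test of a main model against a nested one."""

    statistic: float
    df: int
    p_value: float
    ell_main: float
    ell_nested: float

    @classmethod
    def from_statistic(cls, statistic: float, df: int) -> "LrtResult":
        """Chi-square tail probability for an externally supplied statistic."""
        if statistic < 0 or df < 0:
            raise InputError("LRT statistic and df must be nonnegative")
        return cls(
            statistic=float(statistic),
            df=int(df),
            p_value=float(stats.chi2.sf(statistic, df)) if df > 0 else float(statistic == 0.0),
            ell_main=np.nan,
            ell_nested=np.nan,
        )


@dataclass
class FixedEffectsReport:
    """GLS estimates of the fixed effects, one row per (trait, covariate)."""

    labels: list[tuple[str, str]]
    beta: np.ndarray
    beta_se: np.ndarray


def heritability_and_correlations(
    vs: VarianceStructure,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """h2 vector plus genetic and environmental correlation matrices."""
    vg_d = np.diag(vs.V_G).copy()
    ve_d = np.diag(vs.V_E).copy()
    total = vg_d + ve_d
    if (total <= 0).any():
        raise InputError("a trait has zero total variance")
    h2 = vg_d / total
    rho_g = _correlation_from_cov(vs.V_G)
    rho_e = _correlation_from_cov(vs.V_E)
    return h2, rho_g, rho_e


def _correlation_from_cov(v: np.ndarray) -> np.ndarray:
    d = np.diag(v).copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = 1.0 / np.sqrt(d)
        rho = v * scale[:, None] * scale[None, :]
    rho[d <= 0, :] = np.nan  # undefined, never fabricated as 0
    rho[:, d <= 0] = np.nan
    return rho


# ---------------------------------------------------------------------------
# Delta-method standard errors
# ---------------------------------------------------------------------------

def _summary_jacobians(
    theta: ParameterVector, spec_g: FactorModelSpec, spec_e: FactorModelSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray, VarianceStructure]:
    """Analytic Jacobians of h2_t, rho_G(t,s), rho_E(t,s) w.r.t. theta.

    Chain rule through V = C C': d sigma_ab / d c_tf = delta_at C[b,f] +
    delta_bt C[a,f], composed with the derivatives of the variance-ratio and
    correlation maps.
    """
    vs = implied_variance_matrices(theta, spec_g, spec_e)
    t_n = vs.n_traits
    p = len(theta)
    vg, ve = vs.V_G, vs.V_E

    # d sigma / d theta_i as sparse rank-2 pieces, materialized per parameter
    dvg = np.zeros((p, t_n, t_n))
    dve = np.zeros((p, t_n, t_n))
    for i, (tag, t, f) in enumerate(theta.index):
        c = (vs.C_G if tag == "G" else vs.C_E)[:, f]
        d_mat = np.zeros((t_n, t_n))
        d_mat[t, :] += c
        d_mat[:, t] += c
        (dvg if tag == "G" else dve)[i] = d_mat

    tot = np.diag(vg) + np.diag(ve)
    jac_h2 = np.empty((t_n, p))
    for t in range(t_n):
        jac_h2[t] = (
            np.diag(ve)[t] * dvg[:, t, t] - np.diag(vg)[t] * dve[:, t, t]
        ) / tot[t] ** 2

    jac_rho_g = _correlation_jacobian(vg, dvg)
    jac_rho_e = _correlation_jacobian(ve, dve)
    return jac_h2, jac_rho_g, jac_rho_e, vs


def _correlation_jacobian(v: np.ndarray, dv: np.ndarray) -> np.ndarray:
    """Jacobian of rho(t,s) = v_ts / sqrt(v_tt v_ss), shape (T, T, p)."""
    t_n = v.shape[0]
    p = dv.shape[0]
    jac = np.full((t_n, t_n, p), np.nan)
    d = np.diag(v)
    for t in range(t_n):
        for s in range(t_n):
            if d[t] <= 0 or d[s] <= 0:
                continue
            denom = np.sqrt(d[t] * d[s])
            rho = v[t, s] / denom
            jac[t, s] = (
                dv[:, t, s] / denom
                - 0.5 * rho * (dv[:, t, t] / d[t] + dv[:, s, s] / d[s])
            )
    return jac


def theta_covariance(ai_matrix: np.ndarray) -> np.ndarray:
    """Invert the AI matrix (pseudo-inverse with a warning when ill-conditioned)."""
    cond = np.linalg.cond(ai_matrix)
    if not np.isfinite(cond) or cond > 1e12:
        warnings.warn(
            "AI matrix is ill-conditioned; using a pseudo-inverse for SEs",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.linalg.pinv(ai_matrix, hermitian=True)
    return np.linalg.inv(ai_matrix)


def delta_method_ses(
    theta: ParameterVector,
    theta_cov: np.ndarray,
    spec_g: FactorModelSpec,
    spec_e: FactorModelSpec,
    trait_labels: list[str] | None = None,
    check_finite_differences: bool = False,
) -> HeritabilityReport:
    """Delta-method SEs: SE(g(theta)) = sqrt(J Sigma J') per scalar summary."""
    p = len(theta)
    if theta_cov.shape != (p, p):
        raise InputError("theta covariance shape does not match theta")
    theta_cov = _ensure_psd(theta_cov)
    jac_h2, jac_rho_g, jac_rho_e, vs = _summary_jacobians(theta, spec_g, spec_e)
    if check_finite_differences:
        _crosscheck_jacobians(theta, spec_g, spec_e, jac_h2, jac_rho_g, jac_rho_e)
    h2, rho_g, rho_e = heritability_and_correlations(vs)

    def _se(jac: np.ndarray) -> np.ndarray:
        quad = np.einsum("...i,ij,...j->...", jac, theta_cov, jac)
        return np.sqrt(np.clip(quad, 0.0, None))

    return HeritabilityReport(
        trait_labels=list(trait_labels) if trait_labels else list(spec_g.trait_labels),
        h2=h2,
        h2_se=_se(jac_h2),
        rhoG=rho_g,
        rhoG_se=_se(jac_rho_g),
        rhoE=rho_e,
        rhoE_se=_se(jac_rho_e),
    )


def _ensure_psd(cov: np.ndarray) -> np.ndarray:
    vals = np.linalg.eigvalsh((cov + cov.T) / 2.0)
    if vals.min() >= -1e-10 * max(1.0, vals.max()):
        return cov
    warnings.warn(
        "theta covariance not PSD; projecting onto the nearest PSD matrix",
        RuntimeWarning,
        stacklevel=3,
    )
    w, q = np.linalg.eigh((cov + cov.T) / 2.0)
    return (q * np.clip(w, 0.0, None)) @ q.T


def _crosscheck_jacobians(theta, spec_g, spec_e, jac_h2, jac_rho_g, jac_rho_e, step=1e-6):
    """Central-finite-difference verification of the analytic Jacobians."""
    p = len(theta)

    def summaries(values):
        vs = implied_variance_matrices(theta.replace(values), spec_g, spec_e)
        h2, rg, re_ = heritability_and_correlations(vs)
        return h2, rg, re_

    for i in range(p):
        up = theta.values.copy()
        dn = theta.values.copy()
        up[i] += step
        dn[i] -= step
        h_u, g_u, e_u = summaries(up)
        h_d, g_d, e_d = summaries(dn)
        for analytic, fd in (
            (jac_h2[:, i], (h_u - h_d) / (2 * step)),
            (jac_rho_g[:, :, i], (g_u - g_d) / (2 * step)),
            (jac_rho_e[:, :, i], (e_u - e_d) / (2 * step)),
        ):
            mask = np.isfinite(analytic) & np.isfinite(fd)
            if not np.allclose(analytic[mask], fd[mask], atol=1e-5):
                raise NumericalError(
                    f"analytic Jacobian disagrees with finite differences at theta[{i}]"
                )


# ---------------------------------------------------------------------------
# GLS fixed effects and LRT
# ---------------------------------------------------------------------------

def gls_fixed_effects(td: TransformedDataset, vs: VarianceStructure) -> FixedEffectsReport:
    """GLS beta-hat = (Z'V^-1 Z)^-1 Z'V^-1 y with SEs from the inverse Gram.

    Uses the same per-block whitening as the likelihood kernel.
    """
    from .kernel import reml_loglik  # local import to avoid a cycle

    if td.n_fixed == 0:
        raise InputError("the model has no fixed-effect covariates")
    state = reml_loglik(td, vs)
    try:
        gram_inv = scipy.linalg.inv(state.XtVinvX)
    except scipy.linalg.LinAlgError:
        labels = ", ".join(f"{t}:{c}" for t, c in td.beta_labels)
        raise NumericalError(f"rank-deficient fixed-effect design among [{labels}]") from None
    return FixedEffectsReport(
        labels=td.beta_labels,
        beta=state.beta_gls,
        beta_se=np.sqrt(np.clip(np.diag(gram_inv), 0.0, None)),
    )


def likelihood_ratio_test(fit_main, fit_nested, df: int) -> LrtResult:
    """LRT = 2(ell_A - ell_0), chi-square with df free-coefficient difference.

    ``fit_main``/``fit_nested`` may be FitResult-like objects (with a
    ``loglik`` attribute) or plain log-likelihood floats.
    """
    ell_a = float(getattr(fit_main, "loglik", fit_main))
    ell_0 = float(getattr(fit_nested, "loglik", fit_nested))
    if df < 0:
        raise InputError("negative degrees of freedom")
    statistic = 2.0 * (ell_a - ell_0)
    if statistic < -1e-6:
        raise InputError(
            f"main model log-likelihood ({ell_a:.6f}) is below the nested one "
            f"({ell_0:.6f}): models are not nested or a fit failed to converge"
        )
    if statistic < 0:
        logger.warning("clipping a slightly negative LRT statistic (%.2e)", statistic)
        statistic = 0.0
    p_value = float(stats.chi2.sf(statistic, df)) if df > 0 else float(statistic == 0.0)
    return LrtResult(
        statistic=statistic, df=df, p_value=p_value, ell_main=ell_a, ell_nested=ell_0
    )
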