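"""Canonical transformation of the data by the GRM eigenbasis.

Rotating phenotypes and covariates by the eigenvectors of the GRM turns the
dense NT x NT model covariance V_G (x) A + V_E (x) I into n independent T x T
blocks V_j = d_j V_G + V_E, one per retained eigenvalue d_j.  Dropping the L
leading eigenvectors removes the leading genetic principal components from the
likelihood, which corrects for population stratification without extra
fixed-effect covariates.  The default is L = 20.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg

from .data import CovariateData, GrmData, PhenotypeMatrix, add_intercept
from .exceptions import FormatError, InputError

__all__ = [
    "GrmEigen",
    "TransformedDataset",
    "eigendecompose_grm",
    "canonical_transform",
    "save_eigen",
    "load_eigen",
]

logger = logging.getLogger(__name__)

DEFAULT_LEADING_PCS = 20

_EIG_CACHE_VERSION = 1


@dataclass
class GrmEigen:
    """Eigendecomposition of the GRM: A = Q diag(phi) Q'."""

    ids: list[tuple[str, str]]
    Q: np.ndarray
    phi: np.ndarray  # descending, clipped at zero

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class TransformedDataset:
    """Phenotypes and covariates rotated into the GRM eigenbasis.

    Attributes
    ----------
    d
        The n = N - L retained eigenvalues (those not among the L largest).
    Ystar
        T x n matrix of rotated traits (Y' P).
    Xstar
        n x k rotated covariates (P' X), or None when the model has no fixed
        effects.
    trait_map
        Binary T x k covariate-to-trait selection (S).
    """

    d: np.ndarray
    Ystar: np.ndarray
    Xstar: np.ndarray | None
    trait_map: np.ndarray | None
    trait_labels: list[str]
    covar_labels: list[str]
    L: int

    @property
    def n(self) -> int:
        return self.d.size

    @property
    def n_traits(self) -> int:
        return len(self.trait_labels)

    @property
    def n_fixed(self) -> int:
        """Total fixed-effect count p = sum_t K_t."""
        return 0 if self.trait_map is None else int(self.trait_map.sum())

    @property
    def beta_labels(self) -> list[tuple[str, str]]:
        """(trait, covariate) label per fixed-effect column, trait-major."""
        if self.trait_map is None:
            return []
        return [
            (self.trait_labels[t], self.covar_labels[k])
            for t in range(self.n_traits)
            for k in np.flatnonzero(self.trait_map[t])
        ]

    # Design tensor: Z3[j, t, :] is row t of Z_j = (I_T (x) x_j') S'.  Row t is
    # nonzero only in the columns belonging to trait t, where it carries the
    # covariates that apply to trait t.  Built once; theta-independent.
    _design: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def design_tensor(self) -> np.ndarray | None:
        if self.trait_map is None:
            return None
        if self._design is None:
            n, t, p = self.n, self.n_traits, self.n_fixed
            z3 = np.zeros((n, t, p))
            offset = 0
            for trait in range(t):
                cols = np.flatnonzero(self.trait_map[trait])
                z3[:, trait, offset : offset + cols.size] = self.Xstar[:, cols]
                offset += cols.size
            self._design = z3
        return self._design


def eigendecompose_grm(grm: GrmData) -> GrmEigen:
    """Symmetric EVD of the GRM, eigenvalues sorted descending.

    Numerically negative eigenvalues are clipped to zero (with a warning): the
    GRM is PSD in exact arithmetic whenever it is a Gram matrix of genotypes.
    """
    if not np.isfinite(grm.A).all():
        raise InputError("GRM contains non-finite entries")
    phi, q = scipy.linalg.eigh(grm.A)
    order = np.argsort(phi)[::-1]
    phi, q = phi[order], q[:, order]
    if (phi < 0).any():
        worst = phi.min()
        if worst < -1e-6 * max(1.0, abs(phi.max())):
            logger.warning("clipping substantially negative GRM eigenvalue %.3e", worst)
        else:
            logger.debug("clipping %d tiny negative eigenvalues", int((phi < 0).sum()))
        phi = np.clip(phi, 0.0, None)
    return GrmEigen(ids=list(grm.ids), Q=q, phi=phi)


def canonical_transform(
    eig: GrmEigen,
    phen: PhenotypeMatrix,
    covar: CovariateData | None = None,
    L: int = DEFAULT_LEADING_PCS,
    include_intercept: bool = True,
) -> TransformedDataset:
    """Rotate phenotypes/covariates by the retained GRM eigenvectors.

    P is the eigenvector columns whose eigenvalues are not among the L
    largest; the transformed traits are Y'P and covariates P'X.  Unless
    disabled, a constant intercept covariate applying to every trait is
    injected before the rotation.
    """
    if eig.ids != phen.ids or (covar is not None and covar.ids != phen.ids):
        raise InputError("samples not aligned; call align_samples first")
    n_total, t = phen.n, phen.n_traits
    if include_intercept or covar is not None:
        covar = add_intercept(covar, phen.ids, t)
    k = len(covar.covar_labels) if covar is not None else 0
    if not 0 <= L < n_total - t - k:
        raise InputError(
            f"L={L} out of range for N={n_total}, T={t}, k={k} (need 0 <= L < N-T-k)"
        )
    P = eig.Q[:, L:]
    return TransformedDataset(
        d=eig.phi[L:].copy(),
        Ystar=phen.Y.T @ P,
        Xstar=(P.T @ covar.X) if covar is not None else None,
        trait_map=covar.trait_map if covar is not None else None,
        trait_labels=list(phen.trait_labels),
        covar_labels=list(covar.covar_labels) if covar is not None else [],
        L=L,
    )


# ---------------------------------------------------------------------------
# EVD cache
# ---------------------------------------------------------------------------

def save_eigen(eig: GrmEigen, path: str | Path) -> None:
    """Cache an EVD to disk (npz) to amortize the O(N^3) cost across fits."""
    np.savez_compressed(
        path,
        version=_EIG_CACHE_VERSION,
        fids=np.array([f for f, _ in eig.ids]),
        iids=np.array([i for _, i in eig.ids]),
        phi=eig.phi,
        Q=eig.Q,
    )


def load_eigen(path: str | Path) -> GrmEigen:
    with np.load(path, allow_pickle=False) as dat:
        if int(dat["version"]) != _EIG_CACHE_VERSION:
            raise FormatError(f"{path}: unsupported EVD cache version")
        ids = list(zip(dat["fids"].tolist(), dat["iids"].tolist()))
        return GrmEigen(ids=ids, Q=dat["Q"], phi=dat["phi"])
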