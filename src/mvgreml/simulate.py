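"""Synthetic genotypes, GRMs and multivariate phenotypes with known truth.

The generator follows the infinitesimal GREML model: every SNP is causal,
per-trait effect sizes are jointly normal across traits with covariance
V_G / M, so genetic values have covariance V_G * A, and environmental
residuals are jointly normal with covariance V_E.  Three canned designs
mirror the validation study: (1) T=10 traits, h2=0.5, a uniform genetic
correlation across all pairs; (2) two clusters of five traits with random
within-cluster correlations and exactly zero between clusters; (3) T=50
uncorrelated traits with h2=0.5.  Every field can be overridden for
desk-scale runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .data import GrmData, PhenotypeMatrix, compute_grm, standardize_genotypes, write_grm_binary
from .exceptions import InputError

__all__ = [
    "SimulationDesign",
    "SimulatedDataset",
    "uniform_correlation",
    "two_cluster_correlation",
    "make_simulation_design",
    "simulate_dataset",
    "write_fixture",
]


@dataclass
class SimulationDesign:
    """Ground-truth configuration for one simulated study arm."""

    N: int = 20000
    M: int = 10000
    T: int = 10
    target_h2: np.ndarray = field(default_factory=lambda: np.full(10, 0.5))
    rho_structure: str = "uniform"  # uniform | two_cluster | zero
    rho: float = 0.3  # uniform off-diagonal genetic correlation (uniform only)
    cluster_sizes: tuple[int, int] = (5, 5)
    rho_env: float = 0.0  # uniform environmental correlation
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal_fraction: float = 1.0
    n_replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        self.target_h2 = np.asarray(self.target_h2, dtype=float)
        if self.target_h2.shape != (self.T,):
            raise InputError("target_h2 must have one value per trait")
        if ((self.target_h2 < 0) | (self.target_h2 > 1)).any():
            raise InputError("target_h2 values must lie in [0, 1]")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise InputError("maf_range must be within (0, 0.5]")
        if not 0 < self.causal_fraction <= 1:
            raise InputError("causal_fraction must be in (0, 1]")
        if self.rho_structure not in ("uniform", "two_cluster", "zero"):
            raise InputError(f"unknown rho_structure '{self.rho_structure}'")
        if self.rho_structure == "two_cluster" and sum(self.cluster_sizes) != self.T:
            raise InputError("cluster sizes must sum to the trait count")
        # reject infeasible correlation targets up front
        np.linalg.cholesky(
            self.target_correlation(np.random.default_rng(0)) + 1e-9 * np.eye(self.T)
        )

    def target_correlation(self, rng: np.random.Generator) -> np.ndarray:
        if self.rho_structure == "uniform":
            return uniform_correlation(self.T, self.rho)
        if self.rho_structure == "zero":
            return np.eye(self.T)
        return two_cluster_correlation(self.cluster_sizes, rng)


@dataclass
class SimulatedDataset:
    """One simulated replicate plus the truth used to generate it."""

    grm: GrmData
    phen: PhenotypeMatrix
    true_VG: np.ndarray
    true_VE: np.ndarray
    realized_h2: np.ndarray
    genetic_values: np.ndarray


def uniform_correlation(t: int, rho: float) -> np.ndarray:
    """Equicorrelation matrix; PSD requires rho >= -1/(T-1)."""
    r = np.full((t, t), rho)
    np.fill_diagonal(r, 1.0)
    return r


def two_cluster_correlation(
    sizes: tuple[int, int], rng: np.random.Generator
) -> np.ndarray:
    """Random within-cluster correlations, exact zeros between clusters.

    Each cluster block is a Gram matrix of random unit-norm loading rows
    (entries uniform on [-1, 1]), which guarantees a valid correlation matrix.
    """
    blocks = []
    for size in sizes:
        lam = rng.uniform(-1.0, 1.0, size=(size, size))
        lam /= np.linalg.norm(lam, axis=1, keepdims=True)
        blocks.append(lam @ lam.T)
    total = sum(sizes)
    r = np.zeros((total, total))
    off = 0
    for b in blocks:
        r[off : off + b.shape[0], off : off + b.shape[0]] = b
        off += b.shape[0]
    return r


def make_simulation_design(which: int, **overrides) -> SimulationDesign:
    """Canned designs 1-3 (see module docstring), with per-field overrides."""
    if which == 1:
        base = SimulationDesign(N=20000, M=10000, T=10,
                                target_h2=np.full(10, 0.5), rho_structure="uniform")
    elif which == 2:
        base = SimulationDesign(N=20000, M=10000, T=10,
                                target_h2=np.full(10, 0.5),
                                rho_structure="two_cluster", cluster_sizes=(5, 5))
    elif which == 3:
        base = SimulationDesign(N=20000, M=10000, T=50,
                                target_h2=np.full(50, 0.5), rho_structure="zero",
                                n_replicates=1)
    else:
        raise InputError(f"unknown design {which}; choose 1, 2 or 3")
    if "T" in overrides and "target_h2" not in overrides:
        overrides["target_h2"] = np.full(overrides["T"], float(base.target_h2[0]))
    if ("T" in overrides and base.rho_structure == "two_cluster"
            and "cluster_sizes" not in overrides):
        t = overrides["T"]
        overrides["cluster_sizes"] = (t // 2, t - t // 2)
    try:
        return replace(base, **overrides)
    except TypeError as exc:
        raise InputError(f"invalid design override: {exc}") from None


def simulate_dataset(design: SimulationDesign, replicate: int = 0) -> SimulatedDataset:
    """Draw one replicate, deterministic given (design.seed, replicate).

    Genotypes are Binomial(2, p) with p uniform on ``maf_range``, standardized
    in sample; the GRM is computed from them.  V_G has diagonal target_h2 and
    the design's target correlation structure; V_E is scaled so each trait's
    total variance is one.
    """
    rng = np.random.default_rng([design.seed, replicate])
    n, m, t = design.N, design.M, design.T

    p = rng.uniform(*design.maf_range, size=m)
    counts = rng.binomial(2, p, size=(n, m)).astype(float)
    g, kept = standardize_genotypes(counts)
    m_eff = kept.size
    if m_eff == 0:
        raise InputError("all simulated SNPs were monomorphic; increase N or the MAF range")

    ids = [("FAM" + str(i), "IND" + str(i)) for i in range(n)]
    grm = compute_grm(g, ids)

    h2 = design.target_h2
    r_g = design.target_correlation(rng)
    sd_g = np.sqrt(h2)
    true_vg = r_g * np.outer(sd_g, sd_g)
    r_e = uniform_correlation(t, design.rho_env)
    sd_e = np.sqrt(1.0 - h2)
    true_ve = r_e * np.outer(sd_e, sd_e)

    n_causal = max(1, int(round(design.causal_fraction * m_eff)))
    causal = rng.choice(m_eff, size=n_causal, replace=False) if n_causal < m_eff else np.arange(m_eff)
    # effect rows iid N(0, VG / n_causal): genetic values then have cov ~= A VG
    root_vg = _psd_sqrt(true_vg)
    effects = rng.standard_normal(size=(n_causal, t)) @ root_vg.T / np.sqrt(n_causal)
    genetic = g[:, causal] @ effects  # N x T, cov ~= A * VG

    root_ve = _psd_sqrt(true_ve)
    resid = rng.standard_normal(size=(n, t)) @ root_ve.T
    y = genetic + resid

    var_g = genetic.var(axis=0)
    var_e = resid.var(axis=0)
    realized_h2 = var_g / (var_g + var_e)

    phen = PhenotypeMatrix(
        ids=ids, trait_labels=[f"trait_{i}" for i in range(t)], Y=y
    )
    return SimulatedDataset(
        grm=grm,
        phen=phen,
        true_VG=true_vg,
        true_VE=true_ve,
        realized_h2=realized_h2,
        genetic_values=genetic,
    )


def _psd_sqrt(v: np.ndarray) -> np.ndarray:
    """Symmetric square root tolerant of exact zero variances/eigenvalues."""
    w, q = np.linalg.eigh((v + v.T) / 2.0)
    return (q * np.sqrt(np.clip(w, 0.0, None))) @ q.T


def write_fixture(ds: SimulatedDataset, prefix: str | Path) -> list[Path]:
    """Write GRM triple, phenotype table and a JSON truth file for tests."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    write_grm_binary(ds.grm, prefix)
    pheno_path = prefix.with_name(prefix.name + ".pheno.txt")
    with open(pheno_path, "w") as fh:
        fh.write("FID\tIID\t" + "\t".join(ds.phen.trait_labels) + "\n")
        for (fid, iid), row in zip(ds.phen.ids, ds.phen.Y):
            fh.write(fid + "\t" + iid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
    truth_path = prefix.with_name(prefix.name + ".truth.json")
    with open(truth_path, "w") as fh:
        json.dump(
            {
                "true_VG": ds.true_VG.tolist(),
                "true_VE": ds.true_VE.tolist(),
                "realized_h2": ds.realized_h2.tolist(),
            },
            fh,
            indent=1,
        )
    return [
        prefix.with_name(prefix.name + suf)
        for suf in (".grm.bin", ".grm.N.bin", ".grm.id", ".pheno.txt", ".truth.json")
    ]
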