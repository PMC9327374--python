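"""Genetic and environmental factor models.

A factor model constrains a T x T variance matrix to V = C C', where C is a
T x F loading matrix with a user-chosen binary pattern of free versus
zero-constrained loadings.  Because V is a Gram matrix it is positive
semidefinite for every value of the free loadings, which is what makes the
implied genetic-correlation matrices always valid.  The saturated model uses a
full lower-triangular C (T(T+1)/2 free loadings) and can represent any PSD
covariance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data import read_labeled_binary_matrix
from .exceptions import InputError, ModelSpecificationError

__all__ = [
    "FactorModelSpec",
    "ParameterVector",
    "VarianceStructure",
    "parse_spec",
    "write_spec",
    "saturated_spec",
    "empty_spec",
    "parameter_index",
    "implied_variance_matrices",
    "variance_derivative",
    "check_identification",
    "lrt_degrees_of_freedom",
]


@dataclass
class FactorModelSpec:
    """Binary T x F pattern of free (1) vs zero (0) factor loadings."""

    trait_labels: list[str]
    factor_labels: list[str]
    pattern: np.ndarray

    def __post_init__(self) -> None:
        self.pattern = np.asarray(self.pattern, dtype=int)
        t, f = len(self.trait_labels), len(self.factor_labels)
        if self.pattern.shape != (t, f):
            raise InputError("pattern shape does not match trait/factor labels")
        if not np.isin(self.pattern, (0, 1)).all():
            raise InputError("pattern entries must be 0 or 1")
        if f and (self.pattern.sum(axis=0) == 0).any():
            raise InputError("every factor must load on at least one trait")

    @property
    def n_traits(self) -> int:
        return len(self.trait_labels)

    @property
    def n_factors(self) -> int:
        return len(self.factor_labels)

    @property
    def n_free(self) -> int:
        """Number of free loadings (the model's free-coefficient count)."""
        return int(self.pattern.sum())

    def free_cells(self) -> list[tuple[int, int]]:
        """Row-major list of (trait, factor) positions of the free loadings."""
        return [(int(t), int(f)) for t, f in zip(*np.nonzero(self.pattern))]


@dataclass
class ParameterVector:
    """Flat vector of free loadings with a (matrix, trait, factor) index.

    ``index`` entries are ('G'|'E', t, f); genetic coefficients come first,
    row-major over the genetic pattern, then environmental ones.
    """

    values: np.ndarray
    index: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.index),):
            raise InputError("parameter values and index lengths differ")
        if len(set(self.index)) != len(self.index):
            raise InputError("duplicate entries in parameter index")

    def __len__(self) -> int:
        return len(self.index)

    def replace(self, values: np.ndarray) -> "ParameterVector":
        return ParameterVector(values=np.asarray(values, dtype=float), index=self.index)


@dataclass
class VarianceStructure:
    """Loading matrices and the variance matrices they imply (V = C C')."""

    C_G: np.ndarray
    C_E: np.ndarray
    V_G: np.ndarray
    V_E: np.ndarray

    @classmethod
    def from_loadings(cls, C_G: np.ndarray, C_E: np.ndarray) -> "VarianceStructure":
        C_G = np.atleast_2d(np.asarray(C_G, dtype=float))
        C_E = np.atleast_2d(np.asarray(C_E, dtype=float))
        return cls(C_G=C_G, C_E=C_E, V_G=C_G @ C_G.T, V_E=C_E @ C_E.T)

    @property
    def n_traits(self) -> int:
        return self.C_G.shape[0]


# ---------------------------------------------------------------------------
# Specification files and canned specs
# ---------------------------------------------------------------------------

def parse_spec(path: str | Path, trait_order: list[str]) -> FactorModelSpec:
    """Parse a factor-model file (factor-labeled header, trait-labeled rows).

    Rows are matched to ``trait_order`` by label and reordered accordingly.
    """
    row_labels, factor_labels, mat = read_labeled_binary_matrix(path)
    if sorted(row_labels) != sorted(trait_order):
        unknown = set(row_labels) - set(trait_order)
        missing = set(trait_order) - set(row_labels)
        raise InputError(
            f"{path}: trait labels do not match the phenotypes "
            f"(unknown: {sorted(unknown)}, missing: {sorted(missing)})"
        )
    row_of = {lab: i for i, lab in enumerate(row_labels)}
    pattern = np.stack([mat[row_of[t]] for t in trait_order])
    return FactorModelSpec(
        trait_labels=list(trait_order), factor_labels=list(factor_labels), pattern=pattern
    )


def write_spec(spec: FactorModelSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("trait\t" + "\t".join(spec.factor_labels) + "\n")
        for t, lab in enumerate(spec.trait_labels):
            fh.write(lab + "\t" + "\t".join(str(v) for v in spec.pattern[t]) + "\n")


def saturated_spec(trait_labels: list[str], tag: str = "factor") -> FactorModelSpec:
    """Lower-triangular pattern of ones: T(T+1)/2 free loadings."""
    t = len(trait_labels)
    if t < 1:
        raise InputError("need at least one trait")
    return FactorModelSpec(
        trait_labels=list(trait_labels),
        factor_labels=[f"{tag}_{i}" for i in range(t)],
        pattern=np.tril(np.ones((t, t), dtype=int)),
    )


def empty_spec(trait_labels: list[str]) -> FactorModelSpec:
    """No factors at all (zero variance component), e.g. a no-genetics null."""
    t = len(trait_labels)
    return FactorModelSpec(
        trait_labels=list(trait_labels),
        factor_labels=[],
        pattern=np.zeros((t, 0), dtype=int),
    )


# ---------------------------------------------------------------------------
# Parameter vector <-> variance matrices
# ---------------------------------------------------------------------------

def parameter_index(spec_g: FactorModelSpec, spec_e: FactorModelSpec) -> list[tuple[str, int, int]]:
    """Canonical theta ordering: genetic loadings first, then environmental."""
    return [("G", t, f) for t, f in spec_g.free_cells()] + [
        ("E", t, f) for t, f in spec_e.free_cells()
    ]


def implied_variance_matrices(
    theta: ParameterVector, spec_g: FactorModelSpec, spec_e: FactorModelSpec
) -> VarianceStructure:
    """Assemble C_G, C_E from theta and return the implied V_G, V_E."""
    expected = parameter_index(spec_g, spec_e)
    if theta.index != expected:
        raise InputError("parameter index does not match the factor patterns")
    C_G = np.zeros((spec_g.n_traits, spec_g.n_factors))
    C_E = np.zeros((spec_e.n_traits, spec_e.n_factors))
    for val, (tag, t, f) in zip(theta.values, theta.index):
        (C_G if tag == "G" else C_E)[t, f] = val
    return VarianceStructure.from_loadings(C_G, C_E)


def variance_derivative(
    theta: ParameterVector, i: int, vs: VarianceStructure
) -> tuple[str, np.ndarray, np.ndarray]:
    """Rank-<=2 derivative of V_G or V_E with respect to theta[i].

    For a genetic loading gamma_tf, dV_G/dgamma_tf = e_t c_f' + c_f e_t' with
    c_f the f-th column of C_G.  Returns (matrix tag, e_t, c_f); the dense
    matrix is ``np.outer(e, c) + np.outer(c, e)``.
    """
    tag, t, f = theta.index[i]
    C = vs.C_G if tag == "G" else vs.C_E
    e = np.zeros(C.shape[0])
    e[t] = 1.0
    return tag, e, C[:, f].copy()


# ---------------------------------------------------------------------------
# Identification and nesting
# ---------------------------------------------------------------------------

@dataclass
class IdentificationReport:
    identified: bool
    over_parameterized: bool
    jacobian_rank: int
    n_free: int
    duplicate_factor_columns: list[tuple[str, int, int]]
    messages: list[str]


def _half_vec(mat: np.ndarray) -> np.ndarray:
    return mat[np.tril_indices(mat.shape[0])]


def check_identification(
    spec_g: FactorModelSpec,
    spec_e: FactorModelSpec,
    n_draws: int = 3,
    seed: int = 0,
) -> IdentificationReport:
    """Diagnose local identification of the combined factor model.

    Structural checks: a matrix with more free loadings than T(T+1)/2 is
    over-parameterized; duplicated factor columns within a matrix imply a
    permutation symmetry and non-identification.  The decisive check is
    numerical: the Jacobian of the half-vectorized (V_G, V_E) with respect to
    theta must have full column rank at random parameter draws.
    """
    messages: list[str] = []
    t = spec_g.n_traits
    cap = t * (t + 1) // 2
    over = spec_g.n_free > cap or spec_e.n_free > cap
    if over:
        messages.append(
            f"a T={t} variance matrix supports at most {cap} free loadings"
        )

    duplicates: list[tuple[str, int, int]] = []
    for tag, spec in (("G", spec_g), ("E", spec_e)):
        for a in range(spec.n_factors):
            for b in range(a + 1, spec.n_factors):
                if np.array_equal(spec.pattern[:, a], spec.pattern[:, b]):
                    duplicates.append((tag, a, b))
    if duplicates:
        messages.append(
            "identical factor columns found (permutation symmetry): "
            + ", ".join(f"{tag}:{a}<->{b}" for tag, a, b in duplicates)
        )

    index = parameter_index(spec_g, spec_e)
    p = len(index)
    rng = np.random.default_rng(seed)
    best_rank = 0
    for _ in range(max(1, n_draws)):
        theta = ParameterVector(values=rng.normal(size=p) + 0.5, index=index)
        vs = implied_variance_matrices(theta, spec_g, spec_e)
        jac = np.empty((t * (t + 1), p))  # half-vec of V_G stacked on V_E
        for i in range(p):
            tag, e, c = variance_derivative(theta, i, vs)
            dv = np.outer(e, c) + np.outer(c, e)
            zero = np.zeros((t, t))
            block = (dv, zero) if tag == "G" else (zero, dv)
            jac[:, i] = np.concatenate([_half_vec(block[0]), _half_vec(block[1])])
        best_rank = max(best_rank, int(np.linalg.matrix_rank(jac, tol=1e-10)))
    rank_ok = best_rank == p
    if not rank_ok:
        messages.append(
            f"Jacobian rank {best_rank} < {p} free coefficients: not locally identified"
        )
    return IdentificationReport(
        identified=rank_ok and not over and not duplicates,
        over_parameterized=over,
        jacobian_rank=best_rank,
        n_free=p,
        duplicate_factor_columns=duplicates,
        messages=messages,
    )


def lrt_degrees_of_freedom(
    main: tuple[FactorModelSpec, FactorModelSpec],
    nested: tuple[FactorModelSpec, FactorModelSpec],
) -> int:
    """LRT df = (C_GA + C_EA) - (C_G0 + C_E0), the free-coefficient difference."""
    df = (main[0].n_free + main[1].n_free) - (nested[0].n_free + nested[1].n_free)
    if df < 0:
        raise InputError(
            "the 'nested' model has more free coefficients than the main model"
        )
    return df


def fix_loading_signs(vs: VarianceStructure) -> VarianceStructure:
    """Flip factor columns so each factor's first free loading is nonnegative.

    V = C C' is invariant to negating a column of C, so the likelihood is
    unaffected; this only normalizes reported loadings.
    """
    def _fix(C: np.ndarray) -> np.ndarray:
        C = C.copy()
        for f in range(C.shape[1]):
            nz = np.flatnonzero(C[:, f])
            if nz.size and C[nz[0], f] < 0:
                C[:, f] = -C[:, f]
        return C

    return VarianceStructure.from_loadings(_fix(vs.C_G), _fix(vs.C_E))
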