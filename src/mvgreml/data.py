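"""Reading, writing and aligning GRMs, phenotypes and covariates.

The genomic-relatedness matrix (GRM) is accepted in the GCTA binary dialect
(``prefix.grm.bin`` / ``prefix.grm.N.bin`` / ``prefix.grm.id``), the format
emitted by GCTA, PLINK and LDAK alike: the lower triangle including the
diagonal, row-major, as little-endian 32-bit floats.  Phenotype and covariate
tables are whitespace-delimited text with FID/IID as the first two columns and
a header row of labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError, InputError

__all__ = [
    "GrmData",
    "PhenotypeMatrix",
    "CovariateData",
    "read_grm_binary",
    "write_grm_binary",
    "compute_grm",
    "standardize_genotypes",
    "load_phenotypes",
    "load_covariates",
    "read_labeled_binary_matrix",
    "align_samples",
    "add_intercept",
]

IdPair = tuple[str, str]


def _check_unique_ids(ids: list[IdPair], what: str) -> None:
    if len(set(ids)) != len(ids):
        raise InputError(f"duplicate (FID, IID) pairs in {what}")


@dataclass
class GrmData:
    """Sample identifiers plus an N x N relatedness matrix.

    Attributes
    ----------
    ids
        Ordered (family-id, individual-id) string pairs, length N.
    A
        Symmetric N x N relatedness matrix (dimensionless).
    pair_counts
        N x N matrix of the number of SNPs contributing to each pair
        (constant and equal to M when the GRM comes from a single panel).
    """

    ids: list[IdPair]
    A: np.ndarray
    pair_counts: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.pair_counts = np.asarray(self.pair_counts, dtype=float)
        n = len(self.ids)
        _check_unique_ids(self.ids, "GRM")
        if self.A.shape != (n, n):
            raise InputError(f"GRM matrix shape {self.A.shape} does not match {n} ids")
        if self.pair_counts.shape != (n, n):
            raise InputError("pair_counts shape does not match the GRM")
        if not np.allclose(self.A, self.A.T, atol=1e-6):
            raise InputError("GRM matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def subset(self, order: list[int]) -> "GrmData":
        idx = np.asarray(order)
        return GrmData(
            ids=[self.ids[i] for i in order],
            A=self.A[np.ix_(idx, idx)],
            pair_counts=self.pair_counts[np.ix_(idx, idx)],
        )


@dataclass
class PhenotypeMatrix:
    """N x T trait matrix with sample ids and trait labels."""

    ids: list[IdPair]
    trait_labels: list[str]
    Y: np.ndarray

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        _check_unique_ids(self.ids, "phenotype table")
        if len(set(self.trait_labels)) != len(self.trait_labels):
            raise InputError("duplicate trait labels")
        if self.Y.shape != (len(self.ids), len(self.trait_labels)):
            raise InputError("phenotype matrix shape does not match ids/labels")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_traits(self) -> int:
        return len(self.trait_labels)

    def subset(self, order: list[int]) -> "PhenotypeMatrix":
        return PhenotypeMatrix(
            ids=[self.ids[i] for i in order],
            trait_labels=list(self.trait_labels),
            Y=self.Y[np.asarray(order)],
        )


@dataclass
class CovariateData:
    """N x k covariates plus a binary T x k trait-to-covariate map.

    Row t of ``trait_map`` encodes which covariates enter the fixed-effect
    design of trait t; by default every covariate applies to every trait.
    """

    ids: list[IdPair]
    covar_labels: list[str]
    X: np.ndarray
    trait_map: np.ndarray  # binary T x k

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.trait_map = np.asarray(self.trait_map)
        _check_unique_ids(self.ids, "covariate table")
        if self.X.shape != (len(self.ids), len(self.covar_labels)):
            raise InputError("covariate matrix shape does not match ids/labels")
        if self.trait_map.ndim != 2 or self.trait_map.shape[1] != len(self.covar_labels):
            raise InputError("trait_map shape does not match the covariates")
        if not np.isin(self.trait_map, (0, 1)).all():
            raise InputError("trait_map entries must be 0 or 1")

    @property
    def n(self) -> int:
        return len(self.ids)

    def subset(self, order: list[int]) -> "CovariateData":
        return CovariateData(
            ids=[self.ids[i] for i in order],
            covar_labels=list(self.covar_labels),
            X=self.X[np.asarray(order)],
            trait_map=self.trait_map.copy(),
        )


# ---------------------------------------------------------------------------
# GCTA binary GRM
# ---------------------------------------------------------------------------

def _read_id_file(path: Path) -> list[IdPair]:
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected at least two columns (FID IID)")
    return list(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_grm_binary(prefix: str | Path) -> GrmData:
    """Read a GCTA-format binary GRM triple ``prefix.grm.{bin,N.bin,id}``.

    The ``.grm.bin`` file stores the lower triangle including the diagonal,
    row-major, as 32-bit little-endian floats: N(N+1)/2 values for N ids.
    """
    prefix = Path(prefix)
    id_path = prefix.with_name(prefix.name + ".grm.id")
    bin_path = prefix.with_name(prefix.name + ".grm.bin")
    n_path = prefix.with_name(prefix.name + ".grm.N.bin")
    for p in (id_path, bin_path, n_path):
        if not p.exists():
            raise InputError(f"missing GRM file: {p}")
    ids = _read_id_file(id_path)
    _check_unique_ids(ids, str(id_path))
    n = len(ids)
    expected = n * (n + 1) // 2

    vals = np.fromfile(bin_path, dtype="<f4")
    if vals.size != expected:
        raise FormatError(
            f"{bin_path}: holds {vals.size} float32 values but {n} ids imply "
            f"{expected} lower-triangle entries"
        )
    A = _triangle_to_full(vals.astype(float), n)

    counts = np.fromfile(n_path, dtype="<f4")
    if counts.size == expected:
        pair_counts = _triangle_to_full(counts.astype(float), n)
    elif counts.size == 1:  # some tools store a single shared SNP count
        pair_counts = np.full((n, n), float(counts[0]))
    else:
        raise FormatError(
            f"{n_path}: holds {counts.size} values; expected {expected} or 1"
        )
    return GrmData(ids=ids, A=A, pair_counts=pair_counts)


def _triangle_to_full(tri: np.ndarray, n: int) -> np.ndarray:
    full = np.zeros((n, n))
    il = np.tril_indices(n)
    full[il] = tri
    full = full + full.T
    full[np.diag_indices(n)] /= 2.0
    return full


def write_grm_binary(grm: GrmData, prefix: str | Path) -> None:
    """Write a GRM as the GCTA binary triple (float32 lower triangle)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    il = np.tril_indices(grm.n)
    grm.A[il].astype("<f4").tofile(prefix.with_name(prefix.name + ".grm.bin"))
    grm.pair_counts[il].astype("<f4").tofile(
        prefix.with_name(prefix.name + ".grm.N.bin")
    )
    with open(prefix.with_name(prefix.name + ".grm.id"), "w") as fh:
        for fid, iid in grm.ids:
            fh.write(f"{fid}\t{iid}\n")


# ---------------------------------------------------------------------------
# GRM from genotypes
# ---------------------------------------------------------------------------

def standardize_genotypes(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Standardize 0/1/2 allele counts column-wise with in-sample frequencies.

    Each SNP column is centred at 2*p_hat and scaled by sqrt(2*p_hat*(1-p_hat));
    monomorphic columns (p_hat in {0, 1}) are dropped.  Returns the
    standardized matrix and the indices of the retained columns.
    """
    counts = np.asarray(counts, dtype=float)
    p_hat = counts.mean(axis=0) / 2.0
    keep = np.flatnonzero((p_hat > 0.0) & (p_hat < 1.0))
    p = p_hat[keep]
    G = (counts[:, keep] - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    return G, keep


def compute_grm(G: np.ndarray, ids: list[IdPair]) -> GrmData:
    """Compute A = G G' / M from an N x M standardized genotype matrix."""
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[0] != len(ids):
        raise InputError("genotype matrix shape does not match ids")
    m = G.shape[1]
    if m == 0:
        raise InputError("cannot compute a GRM from zero SNPs")
    A = G @ G.T / m
    A = (A + A.T) / 2.0
    return GrmData(ids=ids, A=A, pair_counts=np.full((len(ids), len(ids)), float(m)))


# ---------------------------------------------------------------------------
# Phenotypes and covariates
# ---------------------------------------------------------------------------

def _load_table(path: str | Path, what: str) -> tuple[list[IdPair], list[str], np.ndarray]:
    df = pd.read_csv(path, sep=r"\s+", dtype={0: str, 1: str})
    if df.shape[1] < 3:
        raise FormatError(f"{path}: {what} table needs FID, IID and >=1 value column")
    ids = list(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
    labels = [str(c) for c in df.columns[2:]]
    values = df.iloc[:, 2:].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    return ids, labels, values


def load_phenotypes(path: str | Path) -> PhenotypeMatrix:
    """Load a whitespace-delimited phenotype table (FID IID trait1 ...)."""
    ids, labels, values = _load_table(path, "phenotype")
    return PhenotypeMatrix(ids=ids, trait_labels=labels, Y=values)


def read_labeled_binary_matrix(path: str | Path) -> tuple[list[str], list[str], np.ndarray]:
    """Read a labeled binary matrix: header of column labels, labeled rows, 0/1 cells.

    Shared dialect for covariate-to-trait maps and factor-model specification
    files.  The header may optionally carry a corner label for the row-name
    column.  Returns (row_labels, column_labels, binary matrix).
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.split() for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0]
    rows = lines[1:]
    if not rows:
        raise FormatError(f"{path}: no data rows")
    width = len(rows[0]) - 1
    if len(header) == width + 1:  # corner label present
        header = header[1:]
    if len(header) != width:
        raise FormatError(f"{path}: header width does not match the rows")
    row_labels, cells = [], []
    for row in rows:
        if len(row) != width + 1:
            raise FormatError(f"{path}: ragged row for '{row[0]}'")
        row_labels.append(row[0])
        for cell in row[1:]:
            if cell not in ("0", "1"):
                raise FormatError(f"{path}: non-binary entry '{cell}' in row '{row[0]}'")
        cells.append([int(c) for c in row[1:]])
    return row_labels, header, np.asarray(cells, dtype=int)


def load_covariates(
    path: str | Path,
    trait_labels: list[str],
    map_path: str | Path | None = None,
) -> CovariateData:
    """Load a covariate table plus an optional covariate-to-trait map.

    Without a map every covariate applies to every trait.  The map file is a
    labeled binary matrix with one row per trait and one column per covariate.
    """
    ids, labels, values = _load_table(path, "covariate")
    t = len(trait_labels)
    if map_path is None:
        trait_map = np.ones((t, len(labels)), dtype=int)
    else:
        row_labels, col_labels, mat = read_labeled_binary_matrix(map_path)
        if sorted(row_labels) != sorted(trait_labels):
            raise InputError(f"{map_path}: row labels are not the trait labels")
        if sorted(col_labels) != sorted(labels):
            raise InputError(f"{map_path}: column labels are not the covariate labels")
        trait_map = np.zeros((t, len(labels)), dtype=int)
        row_of = {lab: i for i, lab in enumerate(row_labels)}
        col_of = {lab: j for j, lab in enumerate(col_labels)}
        for i, trait in enumerate(trait_labels):
            for j, cov in enumerate(labels):
                trait_map[i, j] = mat[row_of[trait], col_of[cov]]
        if (trait_map.sum(axis=1) == 0).any():
            raise InputError("every trait must have at least one applicable covariate")
    return CovariateData(ids=ids, covar_labels=labels, X=values, trait_map=trait_map)


def add_intercept(covar: CovariateData | None, ids: list[IdPair], n_traits: int) -> CovariateData:
    """Prepend a constant 'intercept' covariate applying to all traits."""
    ones = np.ones((len(ids), 1))
    if covar is None:
        return CovariateData(
            ids=list(ids),
            covar_labels=["intercept"],
            X=ones,
            trait_map=np.ones((n_traits, 1), dtype=int),
        )
    if "intercept" in covar.covar_labels:
        return covar
    return CovariateData(
        ids=list(covar.ids),
        covar_labels=["intercept"] + list(covar.covar_labels),
        X=np.hstack([ones, covar.X]),
        trait_map=np.hstack([np.ones((n_traits, 1), dtype=int), covar.trait_map]),
    )


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def align_samples(
    grm: GrmData,
    phen: PhenotypeMatrix,
    covar: CovariateData | None = None,
) -> tuple[GrmData, PhenotypeMatrix, CovariateData | None]:
    """Restrict GRM, phenotypes and covariates to shared, complete-case samples.

    The output order follows the GRM.  Individuals missing any trait value, or
    any covariate that applies to at least one trait, are dropped (complete-case
    analysis keeps the Kronecker covariance structure exact).
    """
    common = set(phen.ids).intersection(grm.ids)
    if covar is not None:
        common &= set(covar.ids)
    if not common:
        raise InputError("no samples shared between the GRM and the phenotype table")

    phen_row = {pid: i for i, pid in enumerate(phen.ids)}
    cov_row = {pid: i for i, pid in enumerate(covar.ids)} if covar is not None else {}
    applicable = (
        np.flatnonzero(covar.trait_map.sum(axis=0) > 0) if covar is not None else None
    )

    keep_grm, keep_phen, keep_cov = [], [], []
    for gi, pid in enumerate(grm.ids):
        if pid not in common:
            continue
        pi = phen_row[pid]
        if np.isnan(phen.Y[pi]).any():
            continue
        if covar is not None:
            ci = cov_row[pid]
            if np.isnan(covar.X[ci, applicable]).any():
                continue
            keep_cov.append(ci)
        keep_grm.append(gi)
        keep_phen.append(pi)

    if not keep_grm:
        raise InputError("no complete-case samples remain after alignment")
    n = len(keep_grm)
    k = len(covar.covar_labels) if covar is not None else 0
    if n < phen.n_traits + k:
        raise InputError(
            f"only {n} samples remain; too few for {phen.n_traits} traits "
            f"and {k} covariates"
        )
    return (
        grm.subset(keep_grm),
        phen.subset(keep_phen),
        covar.subset(keep_cov) if covar is not None else None,
    )
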