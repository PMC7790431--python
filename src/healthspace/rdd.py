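"""Relative disease disadvantage (RDD) and the binary incidence matrix.

RDD is the disease analogue of revealed comparative advantage: the share of
disease *d* in country *c*'s pool of cases divided by the disease's share in
the world pool,

    RDD[c, d] = (E[c, d] / Σ_d' E[c, d']) / (Σ_c' E[c', d] / Σ_c'd' E[c', d']).

A country is declared to have an RDD in a disease when the ratio is >= 1
(inclusive).  Row sums of the resulting binary matrix are country diversity,
column sums are disease ubiquity; the method of reflections alternates
averaging them across the bipartite network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .io_panel import CountryDiseaseMatrix


class DegenerateInputError(ValueError):
    """Input has a zero margin where a positive one is required."""


@dataclass
class RDDMatrix:
    R: np.ndarray
    countries: list[str]
    diseases: list[str]
    year: int | None = None
    age_mode: str | None = None

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        if (self.R < 0).any():
            raise ValueError("RDD values must be nonnegative")


@dataclass
class IncidenceMatrix:
    """Binary country x disease matrix M with its marginal counts."""

    M: np.ndarray
    countries: list[str]
    diseases: list[str]
    threshold: float = 1.0
    year: int | None = None
    age_mode: str | None = None
    diversity: np.ndarray = field(init=False)
    ubiquity: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M)
        if not np.isin(self.M, (0, 1)).all():
            raise ValueError("M must be binary")
        self.M = self.M.astype(np.int64)
        self.diversity = self.M.sum(axis=1)
        self.ubiquity = self.M.sum(axis=0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.M.shape


def compute_rdd(E: CountryDiseaseMatrix | np.ndarray) -> RDDMatrix:
    """Compute the RDD ratio matrix from a prevalence matrix.

    Cells with E[c, d] = 0 map to RDD 0.  Requires a positive grand total and
    no all-zero row or column (those carry no share information).
    """
    if isinstance(E, CountryDiseaseMatrix):
        arr, countries, diseases = E.E, E.countries, E.diseases
        year, age_mode = E.year, E.age_mode
    else:
        arr = np.asarray(E, dtype=float)
        countries = [f"c{i}" for i in range(arr.shape[0])]
        diseases = [f"d{j}" for j in range(arr.shape[1])]
        year = age_mode = None

    total = arr.sum()
    if total <= 0:
        raise DegenerateInputError("prevalence matrix has zero grand total")
    row = arr.sum(axis=1, keepdims=True)
    col = arr.sum(axis=0, keepdims=True)
    if (row == 0).any() or (col == 0).any():
        raise DegenerateInputError("all-zero row or column; drop it upstream")

    R = (arr / row) / (col / total)
    return RDDMatrix(R, countries, diseases, year=year, age_mode=age_mode)


def binarize(R: RDDMatrix | np.ndarray, threshold: float = 1.0) -> IncidenceMatrix:
    """Threshold an RDD matrix into the binary incidence matrix M (>= inclusive)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if isinstance(R, RDDMatrix):
        arr, countries, diseases = R.R, R.countries, R.diseases
        year, age_mode = R.year, R.age_mode
    else:
        arr = np.asarray(R, dtype=float)
        countries = [f"c{i}" for i in range(arr.shape[0])]
        diseases = [f"d{j}" for j in range(arr.shape[1])]
        year = age_mode = None
    M = (arr >= threshold).astype(np.int64)
    return IncidenceMatrix(
        M, countries, diseases, threshold=threshold, year=year, age_mode=age_mode
    )


def reflections(M: IncidenceMatrix | np.ndarray, N: int) -> tuple[np.ndarray, np.ndarray]:
    """N-th method-of-reflections iterates (country side, disease side).

    N = 0 returns (diversity, ubiquity).  For N >= 1 each side averages the
    other side's previous iterate over its links:

        k_c,N = (1/k_c0) Σ_d M[c,d] k_d,N-1
        k_d,N = (1/k_d0) Σ_c M[c,d] k_c,N-1

    so N = 1 yields average ubiquity (countries) and average diversity
    (diseases).
    """
    if N < 0:
        raise ValueError("N must be nonnegative")
    arr = M.M if isinstance(M, IncidenceMatrix) else np.asarray(M)
    kc0 = arr.sum(axis=1).astype(float)
    kd0 = arr.sum(axis=0).astype(float)
    if (kc0 == 0).any() or (kd0 == 0).any():
        raise DegenerateInputError("M has an all-zero row or column")
    kc, kd = kc0.copy(), kd0.copy()
    for _ in range(N):
        kc, kd = (arr @ kd) / kc0, (arr.T @ kc) / kd0
    return kc, kd


def nodf(M: IncidenceMatrix | np.ndarray) -> float:
    """NODF nestedness score in [0, 100] (paired overlap with decreasing fill).

    For every ordered pair of rows (and of columns) where the first has
    strictly larger fill, the pair contributes the percentage of the sparser
    line's ones that also appear in the denser line; equal fills contribute 0.
    The score is the mean contribution over all row pairs and column pairs.
    """
    arr = M.M if isinstance(M, IncidenceMatrix) else np.asarray(M)

    def _axis_score(A: np.ndarray) -> tuple[float, int]:
        fills = A.sum(axis=1)
        total, pairs = 0.0, 0
        for i, j in combinations(range(A.shape[0]), 2):
            hi, lo = (i, j) if fills[i] > fills[j] else (j, i)
            pairs += 1
            if fills[hi] == fills[lo] or fills[lo] == 0:
                continue
            overlap = int(np.logical_and(A[hi], A[lo]).sum())
            total += 100.0 * overlap / fills[lo]
        return total, pairs

    rs, rp = _axis_score(arr)
    cs, cp = _axis_score(arr.T)
    if rp + cp == 0:
        return 0.0
    return (rs + cs) / (rp + cp)


@dataclass
class MatrixOrdering:
    row_order: np.ndarray  # permutation of row indices, most diversified first
    col_order: np.ndarray
    nodf_score: float | None = None


def order_matrix(M: IncidenceMatrix, method: str = "sum_sort") -> MatrixOrdering:
    """Row/column permutation sorting by descending marginal sums.

    ``sum_sort`` orders rows by descending diversity and columns by descending
    ubiquity, ties broken by original position.  ``nodf_sort`` uses the same
    ordering (the canonical NODF pre-sort) and additionally reports the NODF
    nestedness score as a diagnostic.
    """
    if M.M.size == 0:
        raise ValueError("empty incidence matrix")
    row_order = np.argsort(-M.diversity, kind="stable")
    col_order = np.argsort(-M.ubiquity, kind="stable")
    if method == "sum_sort":
        return MatrixOrdering(row_order, col_order)
    if method == "nodf_sort":
        return MatrixOrdering(row_order, col_order, nodf_score=nodf(M))
    raise ValueError(f"unknown ordering method: {method!r}")
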