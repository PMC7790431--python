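"""Health and Disease Complexity Indices via the second-eigenvector method.

From the binary incidence matrix M the country-side similarity matrix

    M~[c, c'] = (1/k_c0) Σ_d M[c,d] M[c',d] / k_d0

is row-stochastic with spectrum in [0, 1]; its leading eigenpair is
(1, constant) and carries no information.  The HCI is the standardized
eigenvector of the second-largest eigenvalue.  Swapping the roles of
countries and diseases gives the disease-side matrix and the DCI.  Because
eigenvectors are sign-ambiguous, the sign is anchored: HCI correlates
positively with country diversity, DCI with the average diversity of the
countries holding the disease (so diseases prevalent in diversified
countries score high, matching the observed geography of complex disease).

The eigen-solve goes through the symmetric conjugate
D^{1/2} M~ D^{-1/2} (D the diagonal of diversity or ubiquity), which
guarantees a real spectrum and an orthogonal basis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse.csgraph

from .io_panel import ALL_AGES, PrevalencePanel, pivot_matrix
from .rdd import DegenerateInputError, IncidenceMatrix, binarize, compute_rdd, reflections

COUNTRIES = "countries"
DISEASES = "diseases"


class DisconnectedError(ValueError):
    """The co-occurrence graph is disconnected and strict mode is on."""


@dataclass
class SimilarityMatrix:
    Mtilde: np.ndarray
    labels: list[str]
    side: str
    degree: np.ndarray  # diversity (countries side) or ubiquity (diseases side)

    def __post_init__(self) -> None:
        self.Mtilde = np.asarray(self.Mtilde, dtype=float)
        if (self.Mtilde < 0).any():
            raise ValueError("similarity entries must be nonnegative")
        if not np.allclose(self.Mtilde.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("similarity matrix must be row-stochastic")


@dataclass
class ComplexityResult:
    """Standardized index vector for one year and side, with diagnostics.

    ``values`` has mean 0 and sd 1 over the entities actually scored; entities
    outside the component used are NaN.  ``eigenvalues`` is the full spectrum
    of the similarity matrix, descending.
    """

    values: np.ndarray
    labels: list[str]
    side: str
    year: int | None
    age_mode: str | None
    eigenvalues: np.ndarray
    second_eigenvalue: float
    eigengap: float
    sign_anchor_corr: float
    component_sizes: list[int]

    @property
    def codes(self) -> list[str]:
        return self.labels


def build_similarity(M: IncidenceMatrix | np.ndarray, side: str = COUNTRIES) -> SimilarityMatrix:
    """Row-stochastic similarity matrix on the chosen side of the network."""
    if isinstance(M, IncidenceMatrix):
        arr = M.M
        labels = M.countries if side == COUNTRIES else M.diseases
    else:
        arr = np.asarray(M)
        labels = None
    if side == DISEASES:
        arr = arr.T
    elif side != COUNTRIES:
        raise ValueError(f"unknown side: {side!r}")
    if labels is None:
        labels = [f"{side[0]}{i}" for i in range(arr.shape[0])]

    own = arr.sum(axis=1).astype(float)  # diversity (or ubiquity)
    other = arr.sum(axis=0).astype(float)  # ubiquity (or diversity)
    if (own == 0).any() or (other == 0).any():
        raise DegenerateInputError("zero diversity or ubiquity in incidence matrix")
    Mtilde = (arr / own[:, None]) @ (arr.T / other[None, :].T)
    return SimilarityMatrix(Mtilde, list(labels), side, degree=own)


def second_eigenvector(
    S: SimilarityMatrix, tol: float = 1e-9
) -> tuple[np.ndarray, float, float]:
    """Eigenvector of the second-largest eigenvalue of a similarity matrix.

    Returns (raw eigenvector, second eigenvalue, eigengap λ2 − λ3).  Raises
    :class:`DisconnectedError` when λ2 reaches 1 within ``tol`` (a
    disconnected co-occurrence graph has a multiple unit eigenvalue, and the
    second eigenvector then only separates components).
    """
    d = S.degree
    sym = (np.sqrt(d)[:, None] * S.Mtilde) / np.sqrt(d)[None, :]
    sym = (sym + sym.T) / 2  # symmetrize away rounding asymmetry
    eigvals, eigvecs = scipy.linalg.eigh(sym)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    n = len(eigvals)
    if n < 2:
        raise DegenerateInputError("need at least two entities for an index")
    lam2 = float(eigvals[1])
    if lam2 >= 1.0 - tol:
        raise DisconnectedError(
            "second eigenvalue is 1: similarity graph is disconnected"
        )
    raw = eigvecs[:, 1] / np.sqrt(d)  # undo the symmetric conjugation
    gap = float(lam2 - eigvals[2]) if n > 2 else lam2
    return raw, lam2, gap


def standardize_and_sign(
    raw: np.ndarray, anchor: np.ndarray, ddof: int = 0
) -> tuple[np.ndarray, float]:
    """Standardize to mean 0, sd 1 and fix the sign against an anchor.

    The sign is flipped when the Pearson correlation with ``anchor`` is
    negative; the (post-flip) correlation is returned with the vector.
    ``ddof=0`` divides by n (population sd); pass 1 for the sample convention.
    """
    raw = np.asarray(raw, dtype=float)
    sd = raw.std(ddof=ddof)
    if sd == 0:
        raise DegenerateInputError("constant eigenvector cannot be standardized")
    z = (raw - raw.mean()) / sd
    r = float(np.corrcoef(raw, np.asarray(anchor, dtype=float))[0, 1])
    if r < 0:
        z, r = -z, -r
    return z, r


def _component_labels(arr: np.ndarray, side: str) -> np.ndarray:
    """Connected components of the one-mode co-occurrence graph."""
    A = arr if side == COUNTRIES else arr.T
    co = (A @ A.T) > 0
    n_comp, labels = scipy.sparse.csgraph.connected_components(co, directed=False)
    return labels


def complexity_from_incidence(
    M: IncidenceMatrix,
    side: str = COUNTRIES,
    on_disconnected: str = "largest",
    ddof: int = 0,
) -> ComplexityResult:
    """HCI (side="countries") or DCI (side="diseases") from an incidence matrix.

    A disconnected co-occurrence graph is handled per ``on_disconnected``:
    "largest" scores the largest component and reports NaN elsewhere (loudly);
    "error" raises.
    """
    arr = M.M
    all_labels = list(M.countries if side == COUNTRIES else M.diseases)
    comp = _component_labels(arr, side)
    sizes = sorted(np.bincount(comp).tolist(), reverse=True)
    if len(sizes) > 1:
        if on_disconnected == "error":
            raise DisconnectedError(
                f"{side} co-occurrence graph has {len(sizes)} components: {sizes}"
            )
        warnings.warn(
            f"{side} co-occurrence graph disconnected (sizes {sizes}); "
            "scoring the largest component only",
            stacklevel=2,
        )
        keep_comp = np.argmax(np.bincount(comp))
        keep_c = comp == keep_comp if side == COUNTRIES else slice(None)
        keep_d = comp == keep_comp if side == DISEASES else slice(None)
        sub = arr[keep_c if side == COUNTRIES else slice(None), :]
        sub = sub[:, keep_d if side == DISEASES else slice(None)]
        # drop the other side's now-empty lines
        sub = sub[sub.sum(axis=1) > 0, :][:, sub.sum(axis=0) > 0]
        kept_mask = comp == keep_comp
    else:
        sub = arr
        kept_mask = np.ones(len(all_labels), dtype=bool)

    kept_labels = [lab for lab, k in zip(all_labels, kept_mask) if k]
    subM = IncidenceMatrix(
        sub,
        countries=(kept_labels if side == COUNTRIES else [f"c{i}" for i in range(sub.shape[0])]),
        diseases=(kept_labels if side == DISEASES else [f"d{j}" for j in range(sub.shape[1])]),
        threshold=M.threshold,
        year=M.year,
        age_mode=M.age_mode,
    )
    S = build_similarity(subM, side=side)
    raw, lam2, gap = second_eigenvector(S)

    if side == COUNTRIES:
        anchor = subM.diversity.astype(float)
    else:
        _, anchor = reflections(subM, 1)  # average diversity of holders
    z, r = standardize_and_sign(raw, anchor, ddof=ddof)

    values = np.full(len(all_labels), np.nan)
    values[kept_mask] = z
    sym_eigvals = np.sort(
        scipy.linalg.eigvalsh(
            (np.sqrt(S.degree)[:, None] * S.Mtilde) / np.sqrt(S.degree)[None, :]
        )
    )[::-1]
    return ComplexityResult(
        values=values,
        labels=all_labels,
        side=side,
        year=M.year,
        age_mode=M.age_mode,
        eigenvalues=sym_eigvals,
        second_eigenvalue=lam2,
        eigengap=gap,
        sign_anchor_corr=r,
        component_sizes=sizes,
    )


def compute_index(
    panel: PrevalencePanel,
    side: str = COUNTRIES,
    age_mode: str = ALL_AGES,
    years=None,
    threshold: float = 1.0,
    on_disconnected: str = "largest",
    ddof: int = 0,
) -> list[ComplexityResult]:
    """Per-year complexity indices from a long prevalence panel.

    Runs pivot → RDD → binarize → similarity → second eigenvector →
    standardize independently for each requested year (no pooling across
    years).  With ``age_mode="age_standardized"`` this yields the
    age-standardized variants (AHCI/ADCI).
    """
    if years is None:
        years = panel.years
    results = []
    for year in years:
        try:
            E = pivot_matrix(panel, year, age_mode)
            M = binarize(compute_rdd(E), threshold=threshold)
            results.append(
                complexity_from_incidence(
                    M, side=side, on_disconnected=on_disconnected, ddof=ddof
                )
            )
        except (ValueError, KeyError) as exc:
            raise type(exc)(f"year {year}: {exc}") from exc
    return results
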