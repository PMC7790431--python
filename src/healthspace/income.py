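"""The Disease-Income Complexity Index (DICI).

DICI links each disease to income: it is the average log GDP per capita of
the countries with an RDD in the disease, weighted by the disease's share
s[c, d] = E[c, d] / Σ_d' E[c, d'] of each country's case pool,

    DICI_d = Σ_c M[c,d] s[c,d] log(GDP_c) / N_d,   N_d = Σ_c M[c,d] s[c,d].

Being a convex combination, DICI always lies between the smallest and largest
log GDP among contributing countries; rescaling all GDP levels by a common
factor shifts every DICI by log(factor).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .io_panel import CountryDiseaseMatrix, GdpSeries
from .rdd import IncidenceMatrix


class InsufficientDataError(ValueError):
    pass


@dataclass
class ShareMatrix:
    """Row-stochastic l x k matrix of within-country disease shares."""

    s: np.ndarray
    countries: list[str]
    diseases: list[str]
    year: int | None = None
    age_mode: str | None = None

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        if (self.s < 0).any():
            raise ValueError("shares must be nonnegative")
        if not np.allclose(self.s.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("each country's shares must sum to 1")


def compute_shares(E: CountryDiseaseMatrix | np.ndarray) -> ShareMatrix:
    """Within-country disease shares s[c, d] = E[c, d] / rowsum_c."""
    if isinstance(E, CountryDiseaseMatrix):
        arr, countries, diseases = E.E, E.countries, E.diseases
        year, age_mode = E.year, E.age_mode
    else:
        arr = np.asarray(E, dtype=float)
        countries = [f"c{i}" for i in range(arr.shape[0])]
        diseases = [f"d{j}" for j in range(arr.shape[1])]
        year = age_mode = None
    row = arr.sum(axis=1, keepdims=True)
    if (row == 0).any():
        raise ValueError("all-zero country row; drop it upstream")
    return ShareMatrix(arr / row, countries, diseases, year=year, age_mode=age_mode)


def dici_values(
    s_arr: np.ndarray, M_arr: np.ndarray, log_gdp: np.ndarray, has_gdp: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Raw DICI arithmetic: weighted mean log GDP over RDD holders.

    Returns (dici, N_d); only cells with M = 1 and GDP present enter either
    sum, so the result is insensitive to shares at non-RDD cells.
    """
    W = M_arr * s_arr * has_gdp[:, None]
    N_d = W.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        dici = (W * np.where(has_gdp, log_gdp, 0.0)[:, None]).sum(axis=0) / N_d
    return dici, N_d


def compute_dici(
    s: ShareMatrix,
    M: IncidenceMatrix,
    gdp: GdpSeries,
    year: int,
    alias: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-disease DICI table for one year.

    Countries lacking a GDP record for the year are excluded from both sums
    (counted per disease in ``n_countries_missing_gdp``).  A disease whose
    every RDD country lacks GDP gets a NaN DICI with a warning, not an error.

    Returns a DataFrame with columns (disease, year, dici, n_countries,
    normalization, n_countries_missing_gdp).
    """
    if s.countries != M.countries or s.diseases != M.diseases:
        raise ValueError("share and incidence matrices must share label axes")
    log_gdp = gdp.log_gdp(year, alias=alias)
    has_gdp = np.array([c in log_gdp.index for c in s.countries])
    g = np.array([log_gdp.get(c, np.nan) for c in s.countries])

    dici, N_d = dici_values(s.s, M.M, g, has_gdp)

    n_holders = (M.M * has_gdp[:, None]).sum(axis=0)
    n_missing = (M.M * (~has_gdp)[:, None]).sum(axis=0)
    empty = N_d == 0
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} disease(s) have no RDD country with GDP data; "
            "DICI reported as NaN",
            stacklevel=2,
        )
        dici = np.where(empty, np.nan, dici)

    return pd.DataFrame(
        {
            "disease": s.diseases,
            "year": year,
            "dici": dici,
            "n_countries": n_holders,
            "normalization": N_d,
            "n_countries_missing_gdp": n_missing,
        }
    )


def dici_dci_correlation(
    dici: pd.DataFrame, dci, method: str = "pearson"
) -> tuple[float, float]:
    """Correlation between DICI and DCI across diseases, paired by code.

    ``dci`` is a ComplexityResult (labels are disease codes) or a mapping
    code → value.  Returns (coefficient, two-sided p-value).
    """
    if hasattr(dci, "labels"):
        dci_map = dict(zip(dci.labels, np.asarray(dci.values, dtype=float)))
    else:
        dci_map = dict(dci)
    merged = dici.dropna(subset=["dici"]).copy()
    merged["dci"] = merged["disease"].map(dci_map)
    merged = merged.dropna(subset=["dci"])
    if len(merged) < 3:
        raise InsufficientDataError("need at least 3 diseases with both indices")
    x, y = merged["dici"].to_numpy(), merged["dci"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InsufficientDataError("correlation undefined for a constant vector")
    if method == "pearson":
        r = scipy.stats.pearsonr(x, y)
    elif method == "spearman":
        r = scipy.stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method: {method!r}")
    return float(r.statistic), float(r.pvalue)
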