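"""Ingest and serialization for prevalence panels, GDP tables, indices and networks.

The canonical input is a long-format prevalence extract in the dialect of the
GBD results tool: one row per (location, cause, year, age group, metric) with
the value column holding a rate of cases per 100,000 population.  Only
``metric == "Rate"`` rows enter the panel; two age modes are supported,
"All Ages" and "Age-standardized".  The panel pivots into a dense country x
disease matrix ``E`` for one (year, age mode) stratum, which is the input to
every downstream computation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ALL_AGES = "all_ages"
AGE_STANDARDIZED = "age_standardized"

#: Column mapping for the GBD results-tool export dialect.
DEFAULT_DIALECT: dict[str, str] = {
    "country": "location_name",
    "disease_code": "cause_id",
    "disease_label": "cause_name",
    "disease_group": "cause_group",
    "year": "year",
    "age": "age_name",
    "metric": "metric_name",
    "value": "val",
}

#: Accepted spellings of the two age modes in raw extracts.
_AGE_MODE_MAP = {
    "all ages": ALL_AGES,
    "all_ages": ALL_AGES,
    "all": ALL_AGES,
    "age-standardized": AGE_STANDARDIZED,
    "age-standardised": AGE_STANDARDIZED,
    "age_standardized": AGE_STANDARDIZED,
    "std": AGE_STANDARDIZED,
}


class FormatError(ValueError):
    """Input file does not match the declared dialect."""


class IntegrityError(ValueError):
    """Input violates a panel invariant (e.g. duplicate keys)."""


class EmptySelectionError(ValueError):
    """No records match the requested (year, age mode) stratum."""


@dataclass
class ValidationReport:
    """Row accounting for one ingest: kept + dropped_* = input rows."""

    n_input: int
    n_kept: int
    n_dropped_missing: int = 0
    n_dropped_negative: int = 0
    n_ignored_metric: int = 0

    def __post_init__(self) -> None:
        total = (
            self.n_kept
            + self.n_dropped_missing
            + self.n_dropped_negative
            + self.n_ignored_metric
        )
        if total != self.n_input:
            raise IntegrityError(
                f"validation accounting mismatch: {total} != {self.n_input}"
            )


@dataclass
class PrevalencePanel:
    """Long-format prevalence records.

    ``data`` has canonical columns (country, disease_code, disease_label,
    disease_group, year, age_mode, rate); keys (country, disease_code, year,
    age_mode) are unique and rates are nonnegative.
    """

    data: pd.DataFrame
    report: ValidationReport | None = None

    COLUMNS = (
        "country",
        "disease_code",
        "disease_label",
        "disease_group",
        "year",
        "age_mode",
        "rate",
    )

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"panel missing canonical columns: {missing}")
        if (self.data["rate"] < 0).any():
            raise IntegrityError("panel contains negative rates")
        keys = ["country", "disease_code", "year", "age_mode"]
        dup = self.data.duplicated(subset=keys)
        if dup.any():
            first = self.data.loc[dup, keys].iloc[0].to_dict()
            raise IntegrityError(f"duplicate panel key, first: {first}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def years(self) -> list[int]:
        return sorted(self.data["year"].unique().tolist())


@dataclass
class CountryDiseaseMatrix:
    """Dense l x k matrix E of prevalence rates for one (year, age mode)."""

    E: np.ndarray
    countries: list[str]
    diseases: list[str]  # codes
    year: int
    age_mode: str
    disease_labels: list[str] | None = None
    disease_groups: list[str] | None = None

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, dtype=float)
        if self.E.ndim != 2:
            raise ValueError("E must be 2-D")
        l, k = self.E.shape
        if l != len(self.countries) or k != len(self.diseases):
            raise ValueError("label axes do not match E's shape")
        if (self.E < 0).any():
            raise ValueError("E has negative entries")

    @property
    def shape(self) -> tuple[int, int]:
        return self.E.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.E, index=self.countries, columns=self.diseases)


@dataclass
class GdpSeries:
    """GDP per capita levels per (country, year); levels strictly positive."""

    data: pd.DataFrame  # columns: country, year, gdp_pc
    log_base: float = 10.0

    def __post_init__(self) -> None:
        missing = [c for c in ("country", "year", "gdp_pc") if c not in self.data.columns]
        if missing:
            raise FormatError(f"GDP table missing columns: {missing}")
        if (self.data["gdp_pc"] <= 0).any():
            raise IntegrityError("GDP per capita must be strictly positive")
        if self.data.duplicated(subset=["country", "year"]).any():
            raise IntegrityError("duplicate (country, year) in GDP table")

    def log_gdp(self, year: int, alias: dict[str, str] | None = None) -> pd.Series:
        """Log GDP per capita for one year, indexed by country label."""
        sub = self.data[self.data["year"] == year]
        s = pd.Series(sub["gdp_pc"].to_numpy(), index=sub["country"].to_numpy())
        if alias:
            s = s.rename(index=alias)
        return np.log(s) / np.log(self.log_base)


def normalize_age_mode(value: str) -> str:
    key = str(value).strip().lower()
    if key not in _AGE_MODE_MAP:
        raise ValueError(f"unrecognized age mode: {value!r}")
    return _AGE_MODE_MAP[key]


def read_prevalence(
    path, dialect: dict[str, str] | None = None, metric: str = "Rate"
) -> PrevalencePanel:
    """Read a long-format prevalence CSV and validate it into a panel.

    Rows whose metric differs from ``metric`` are ignored (counted); rows with
    missing or negative rate are dropped (counted).  Duplicate
    (country, disease, year, age_mode) keys raise :class:`IntegrityError`.
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    raw = pd.read_csv(path)
    required = [v for k, v in dialect.items() if k != "disease_group"]
    for col in required:
        if col not in raw.columns:
            raise FormatError(f"missing required column: {col!r}")
    n_input = len(raw)

    metric_ok = raw[dialect["metric"]].astype(str) == metric
    n_ignored = int((~metric_ok).sum())
    raw = raw[metric_ok]

    group_col = dialect.get("disease_group")
    df = pd.DataFrame(
        {
            "country": raw[dialect["country"]].astype(str),
            "disease_code": raw[dialect["disease_code"]].astype(str),
            "disease_label": raw[dialect["disease_label"]].astype(str),
            "disease_group": (
                raw[group_col].astype(str)
                if group_col and group_col in raw.columns
                else ""
            ),
            "year": raw[dialect["year"]].astype(int),
            "age_mode": raw[dialect["age"]].map(normalize_age_mode),
            "rate": pd.to_numeric(raw[dialect["value"]], errors="coerce"),
        }
    )

    missing_mask = df["rate"].isna()
    n_missing = int(missing_mask.sum())
    df = df[~missing_mask]
    negative_mask = df["rate"] < 0
    n_negative = int(negative_mask.sum())
    df = df[~negative_mask].reset_index(drop=True)

    report = ValidationReport(
        n_input=n_input,
        n_kept=len(df),
        n_dropped_missing=n_missing,
        n_dropped_negative=n_negative,
        n_ignored_metric=n_ignored,
    )
    if n_missing or n_negative:
        logger.warning(
            "dropped %d missing-rate and %d negative-rate rows", n_missing, n_negative
        )
    return PrevalencePanel(df, report)


def read_gdp(path, log_base: float = 10.0, dialect: dict[str, str] | None = None) -> GdpSeries:
    """Read a GDP per capita table CSV with columns (country, year, gdp_pc)."""
    dialect = {**{"country": "country", "year": "year", "gdp_pc": "gdp_pc"}, **(dialect or {})}
    raw = pd.read_csv(path)
    for col in dialect.values():
        if col not in raw.columns:
            raise FormatError(f"missing required column: {col!r}")
    df = pd.DataFrame(
        {
            "country": raw[dialect["country"]].astype(str),
            "year": raw[dialect["year"]].astype(int),
            "gdp_pc": pd.to_numeric(raw[dialect["gdp_pc"]]),
        }
    )
    return GdpSeries(df, log_base=log_base)


def pivot_matrix(
    panel: PrevalencePanel, year: int, age_mode: str = ALL_AGES
) -> CountryDiseaseMatrix:
    """Pivot one (year, age mode) stratum to a dense country x disease matrix.

    Cells with no record are 0.  All-zero rows and columns are dropped with a
    warning — a country with no recorded cases (or a disease absent everywhere)
    carries no comparative information.
    """
    age_mode = normalize_age_mode(age_mode)
    sub = panel.data[(panel.data["year"] == year) & (panel.data["age_mode"] == age_mode)]
    if sub.empty:
        raise EmptySelectionError(f"no records for year={year}, age_mode={age_mode}")

    wide = sub.pivot(index="country", columns="disease_code", values="rate").fillna(0.0)
    wide = wide.sort_index(axis=0).sort_index(axis=1)

    zero_rows = wide.index[(wide.sum(axis=1) == 0)].tolist()
    zero_cols = wide.columns[(wide.sum(axis=0) == 0)].tolist()
    if zero_rows:
        warnings.warn(f"dropping all-zero countries: {zero_rows}", stacklevel=2)
        wide = wide.drop(index=zero_rows)
    if zero_cols:
        warnings.warn(f"dropping all-zero diseases: {zero_cols}", stacklevel=2)
        wide = wide.drop(columns=zero_cols)

    meta = (
        sub.drop_duplicates("disease_code")
        .set_index("disease_code")[["disease_label", "disease_group"]]
    )
    codes = list(wide.columns)
    return CountryDiseaseMatrix(
        E=wide.to_numpy(),
        countries=list(wide.index),
        diseases=codes,
        year=year,
        age_mode=age_mode,
        disease_labels=[meta.loc[c, "disease_label"] for c in codes],
        disease_groups=[meta.loc[c, "disease_group"] for c in codes],
    )


def panel_from_matrix(matrix: CountryDiseaseMatrix) -> pd.DataFrame:
    """Flatten a matrix back to long form, keeping only nonzero cells."""
    frame = matrix.to_frame().stack()
    frame = frame[frame > 0].rename("rate").reset_index()
    frame.columns = ["country", "disease_code", "rate"]
    frame["year"] = matrix.year
    frame["age_mode"] = matrix.age_mode
    return frame


def write_index_table(result, path) -> pd.DataFrame:
    """Write a complexity or DICI result as a CSV with dense ranks (1 = highest).

    ``result`` is either a ComplexityResult (duck-typed: labels/values/year/side)
    or a DataFrame with columns (label, code, year, value).
    """
    if hasattr(result, "values") and hasattr(result, "labels"):
        df = pd.DataFrame(
            {
                "label": result.labels,
                "code": getattr(result, "codes", None) or result.labels,
                "year": result.year,
                "value": np.asarray(result.values, dtype=float),
            }
        )
    else:
        df = pd.DataFrame(result).copy()
        for col in ("label", "code", "year", "value"):
            if col not in df.columns:
                raise FormatError(f"index table missing column {col!r}")
    if df.empty:
        raise ValueError("refusing to write an empty index table")
    df["rank"] = (
        df.groupby("year")["value"].rank(method="min", ascending=False).astype(int)
    )
    df.to_csv(path, index=False, float_format="%.17g")
    return df


def read_index_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_network(graph: nx.Graph, path, format: str = "graphml") -> None:
    """Serialize a labeled weighted graph as GraphML or a TSV edge list."""
    for node, data in graph.nodes(data=True):
        if "label" not in data:
            raise ValueError(f"node {node!r} has no 'label' attribute")
    for _, _, data in graph.edges(data=True):
        if "weight" not in data:
            raise ValueError("every edge needs a 'weight' attribute")
    if format == "graphml":
        nx.write_graphml(graph, path)
    elif format == "edge_list_tsv":
        rows = [
            {"source": u, "target": v, "weight": d["weight"]}
            for u, v, d in graph.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValueError(f"unknown network format: {format!r}")
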