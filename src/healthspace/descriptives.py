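"""Descriptive analyses: quadrants, income-group localization, ranks.

These reproduce the standard descriptive views of a country-disease
incidence matrix: the diversity vs average-ubiquity quadrant diagram,
the localization of diseases within income groups (a disease is "localized"
in a group when strictly more than half of the group's countries have an
RDD in it), per-year dense rankings of a complexity index, and plain
correlation summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .rdd import IncidenceMatrix, reflections


class UndefinedCorrelationError(ValueError):
    pass


@dataclass
class QuadrantAssignment:
    label: str
    x: float  # diversity (countries) or ubiquity (diseases)
    y: float  # average ubiquity (countries) or average diversity (diseases)
    quadrant: str  # UL, UR, LL, LR
    x_threshold: float
    y_threshold: float


def classify_quadrants(M: IncidenceMatrix, side: str = "countries") -> list[QuadrantAssignment]:
    """Quadrant assignment against the empirical means.

    Countries: x = diversity, y = average ubiquity of their diseases.
    Diseases: x = ubiquity, y = average diversity of their holders.
    Boundary ties go to the lower/left quadrant.
    """
    kc1, kd1 = reflections(M, 1)
    if side == "countries":
        labels, x, y = M.countries, M.diversity.astype(float), kc1
    elif side == "diseases":
        labels, x, y = M.diseases, M.ubiquity.astype(float), kd1
    else:
        raise ValueError(f"unknown side: {side!r}")
    tx, ty = float(np.mean(x)), float(np.mean(y))
    out = []
    for lab, xi, yi in zip(labels, x, y):
        horiz = "R" if xi > tx else "L"
        vert = "U" if yi > ty else "L"
        out.append(QuadrantAssignment(lab, float(xi), float(yi), vert + horiz, tx, ty))
    return out


def localize_by_group(M: IncidenceMatrix, groups: dict[str, str]) -> pd.DataFrame:
    """Disease x group binary table of income-group localization.

    Cell (d, g) is 1 iff strictly more than half of group g's countries have
    an RDD in disease d.  Every country must be mapped to exactly one group;
    empty groups are a configuration error.
    """
    unmapped = [c for c in M.countries if c not in groups]
    if unmapped:
        raise ValueError(f"countries without a group: {unmapped}")
    labels = sorted(set(groups[c] for c in M.countries))
    member = {
        g: np.array([groups[c] == g for c in M.countries]) for g in labels
    }
    for g, mask in member.items():
        if not mask.any():
            raise ValueError(f"group {g!r} has no countries")
    table = {
        g: (M.M[mask].sum(axis=0) > mask.sum() / 2).astype(int)
        for g, mask in member.items()
    }
    return pd.DataFrame(table, index=M.diseases)


def correlate(x, y, method: str = "pearson") -> tuple[float, float]:
    """Pearson or Spearman correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for constant input")
    if method == "pearson":
        r = scipy.stats.pearsonr(x, y)
    elif method == "spearman":
        r = scipy.stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method: {method!r}")
    return float(r.statistic), float(r.pvalue)


def rank_and_percentiles(results, percentile_cut: float = 80.0) -> pd.DataFrame:
    """Per-year dense ranks (1 = highest index) and percentile-band flags.

    ``results`` is a list of ComplexityResult for successive years.  Returns a
    long DataFrame (label, year, value, rank, above_cut) where ``above_cut``
    marks entities at or above the nearest-rank percentile for that year;
    entities with NaN values in a year carry NaN rank.
    """
    if not results:
        raise ValueError("need at least one year of results")
    frames = []
    for res in results:
        vals = np.asarray(res.values, dtype=float)
        df = pd.DataFrame({"label": res.labels, "year": res.year, "value": vals})
        df["rank"] = df["value"].rank(method="min", ascending=False)
        finite = df["value"].dropna().to_numpy()
        # nearest-rank percentile: smallest value with at least cut% at or below
        cut_val = np.sort(finite)[
            max(0, int(np.ceil(percentile_cut / 100.0 * len(finite))) - 1)
        ]
        df["above_cut"] = df["value"] > cut_val
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def rank_deltas(table: pd.DataFrame, year_from: int, year_to: int) -> pd.DataFrame:
    """Rank change between two years (positive = improved, moved up)."""
    a = table[table["year"] == year_from].set_index("label")["rank"]
    b = table[table["year"] == year_to].set_index("label")["rank"]
    return (a - b).rename("rank_delta").reset_index()
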