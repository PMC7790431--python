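import numpy as np
import pandas as pd
import pytest

from healthspace.rdd import IncidenceMatrix


@pytest.fixture
def prevalence_csv(tmp_path):
    """Write a small GBD-dialect prevalence CSV and return its path."""

    def _write(rows, name="prev.csv"):
        cols = [
            "location_name",
            "cause_id",
            "cause_name",
            "cause_group",
            "year",
            "age_name",
            "metric_name",
            "val",
        ]
        path = tmp_path / name
        pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
        return path

    return _write


@pytest.fixture
def six_row_fixture(prevalence_csv):
    """2 countries x 3 diseases, year 2016, all-ages rates."""
    rows = [
        ("Aland", c, f"Disease {c}", "A.1", 2016, "All Ages", "Rate", v)
        for c, v in [("d1", 10.0), ("d2", 20.0), ("d3", 30.0)]
    ] + [
        ("Borland", c, f"Disease {c}", "A.1", 2016, "All Ages", "Rate", v)
        for c, v in [("d1", 5.0), ("d2", 50.0), ("d3", 15.0)]
    ]
    return prevalence_csv(rows)


def random_incidence(rng, l, k, p=0.45):
    """Random binary matrix with no empty row or column (resample until)."""
    while True:
        M = (rng.uniform(size=(l, k)) < p).astype(int)
        if M.sum(axis=1).all() and M.sum(axis=0).all():
            return M


def incidence_from_array(arr) -> IncidenceMatrix:
    arr = np.asarray(arr)
    return IncidenceMatrix(
        arr,
        countries=[f"c{i}" for i in range(arr.shape[0])],
        diseases=[f"d{j}" for j in range(arr.shape[1])],
    )
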