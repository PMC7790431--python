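import numpy as np
import pytest

from healthspace.complexity import (
    DisconnectedError,
    build_similarity,
    complexity_from_incidence,
    compute_index,
    second_eigenvector,
    standardize_and_sign,
)
from healthspace.rdd import DegenerateInputError
from healthspace.synthetic import generate_world

from .conftest import incidence_from_array, random_incidence


def reflections_limit_oracle(M, side="countries", n_iter=200):
    """Standardized method-of-reflections limit, demeaned/rescaled each step.

    Built directly from M, independent of build_similarity: one step averages
    the other side's iterate over the links, twice (back to the same side),
    then standardizes.  Converges to the +/- standardized eigenvector of the
    second-largest eigenvalue.
    """
    A = np.asarray(M, dtype=float)
    if side == "diseases":
        A = A.T
    own = A.sum(axis=1)
    other = A.sum(axis=0)
    v = own.astype(float).copy()
    for _ in range(n_iter):
        v = (A @ ((A.T @ v) / other)) / own
        v = (v - v.mean()) / v.std()
    return v


class TestBuildSimilarity:
    def test_hand_example_countries_side(self):
        S = build_similarity(np.array([[1, 1], [1, 0]]), side="countries")
        np.testing.assert_allclose(S.Mtilde, [[0.75, 0.25], [0.5, 0.5]])

    def test_row_stochastic_on_random_input(self):
        rng = np.random.default_rng(8)
        for side in ("countries", "diseases"):
            S = build_similarity(random_incidence(rng, 8, 11), side=side)
            np.testing.assert_allclose(S.Mtilde.sum(axis=1), 1.0, atol=1e-12)

    def test_all_ones_gives_uniform(self):
        S = build_similarity(np.ones((4, 6), dtype=int), side="countries")
        np.testing.assert_allclose(S.Mtilde, 0.25)

    def test_zero_margin_errors(self):
        with pytest.raises(DegenerateInputError):
            build_similarity(np.array([[1, 0], [1, 0]]), side="countries")


class TestSecondEigenvector:
    def test_closed_form_two_by_two(self):
        S = build_similarity(np.array([[1, 1], [1, 0]]), side="countries")
        raw, lam2, _gap = second_eigenvector(S)
        assert lam2 == pytest.approx(0.25)
        # eigenvector proportional to (1, -2) in raw coordinates
        assert raw[0] / raw[1] == pytest.approx(-0.5)

    def test_leading_eigenpair_is_one_with_constant_vector(self):
        rng = np.random.default_rng(14)
        M = random_incidence(rng, 9, 12)
        S = build_similarity(M, side="countries")
        eigvals, eigvecs = np.linalg.eig(S.Mtilde)
        top = np.argmax(eigvals.real)
        assert eigvals[top].real == pytest.approx(1.0)
        v = eigvecs[:, top].real
        assert np.ptp(v / v[0]) == pytest.approx(0.0, abs=1e-9)

    def test_block_diagonal_raises(self):
        M = np.block(
            [[np.ones((3, 4), int), np.zeros((3, 4), int)],
             [np.zeros((3, 4), int), np.ones((3, 4), int)]]
        )
        S = build_similarity(M, side="countries")
        with pytest.raises(DisconnectedError):
            second_eigenvector(S)


class TestStandardize:
    def test_sample_sd_convention(self):
        z, r = standardize_and_sign(np.array([1.0, 2.0, 3.0]),
                                    np.array([1.0, 2.0, 3.0]), ddof=1)
        np.testing.assert_allclose(z, [-1.0, 0.0, 1.0])
        assert r == pytest.approx(1.0)

    def test_population_sd_convention(self):
        z, _ = standardize_and_sign(np.array([1.0, 2.0, 3.0]),
                                    np.array([1.0, 2.0, 3.0]), ddof=0)
        np.testing.assert_allclose(z, [-1.2247448713915890, 0.0, 1.2247448713915890])

    def test_anti_correlated_anchor_flips(self):
        raw = np.array([1.0, 2.0, 3.0])
        plus, _ = standardize_and_sign(raw, raw)
        minus, r = standardize_and_sign(raw, -raw)
        np.testing.assert_allclose(minus, -plus)
        assert r > 0

    def test_output_mean_zero(self):
        rng = np.random.default_rng(0)
        raw = rng.normal(size=50)
        z, _ = standardize_and_sign(raw, rng.normal(size=50))
        assert abs(z.mean()) < 1e-12

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateInputError):
            standardize_and_sign(np.ones(5), np.arange(5.0))


class TestComplexityFromIncidence:
    def test_matches_reflections_limit(self):
        rng = np.random.default_rng(23)
        checked = 0
        while checked < 10:
            M = incidence_from_array(random_incidence(rng, 10, 15))
            try:
                res = complexity_from_incidence(M, side="countries",
                                                on_disconnected="error")
            except DisconnectedError:
                continue
            if res.eigengap <= 0.05:
                continue
            oracle = reflections_limit_oracle(M.M, "countries")
            err = min(
                np.abs(res.values - oracle).max(),
                np.abs(res.values + oracle).max(),
            )
            assert err < 1e-6
            checked += 1

    def test_permutation_equivariance_and_sign_stability(self):
        rng = np.random.default_rng(31)
        M = incidence_from_array(random_incidence(rng, 12, 16))
        res = complexity_from_incidence(M, side="countries")
        perm = rng.permutation(12)
        Mp = incidence_from_array(M.M[perm])
        res_p = complexity_from_incidence(Mp, side="countries")
        np.testing.assert_allclose(res_p.values, res.values[perm], atol=1e-9)
        # repeated runs give identical (not flipped) indices
        res2 = complexity_from_incidence(M, side="countries")
        np.testing.assert_array_equal(res.values, res2.values)

    def test_cross_side_consistency_on_nested_world(self):
        """Countries with high HCI hold diseases of above-average DCI."""
        world = generate_world(l=40, k=60, noise=0.05, seed=6)
        M = incidence_from_array(world.M_true)
        hci = complexity_from_incidence(M, side="countries")
        dci = complexity_from_incidence(M, side="diseases")
        mean_dci = (M.M * dci.values).sum(axis=1) / M.diversity
        from scipy.stats import spearmanr

        assert spearmanr(hci.values, mean_dci).statistic > 0

    def test_disconnected_largest_component_reports_nan(self):
        block = np.array(
            [[1, 1, 1, 0, 0], [1, 1, 0, 1, 0], [1, 0, 1, 1, 1], [0, 1, 1, 1, 1]]
        )
        M = np.block(
            [[block, np.zeros((4, 3), int)],
             [np.zeros((2, 5), int), np.array([[1, 1, 0], [1, 0, 1]])]]
        )
        with pytest.warns(UserWarning, match="disconnected"):
            res = complexity_from_incidence(incidence_from_array(M), side="countries")
        assert np.isnan(res.values[-1]) and np.isnan(res.values[-2])
        kept = res.values[:4]
        assert abs(np.nanmean(kept)) < 1e-9


class TestComputeIndex:
    def test_per_year_standardization(self):
        worlds = [generate_world(l=25, k=40, noise=0.05, seed=s) for s in (1, 2)]
        import pandas as pd

        from healthspace.io_panel import PrevalencePanel

        frames = []
        for year, w in zip((2015, 2016), worlds):
            df = w.to_panel().data.copy()
            df["year"] = year
            frames.append(df)
        panel = PrevalencePanel(pd.concat(frames, ignore_index=True))
        results = compute_index(panel, side="countries")
        assert [r.year for r in results] == [2015, 2016]
        for r in results:
            vals = r.values[np.isfinite(r.values)]
            assert abs(vals.mean()) < 1e-9
            assert vals.std() == pytest.approx(1.0, abs=1e-9)
            assert r.sign_anchor_corr > 0
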