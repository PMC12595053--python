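"""Entropy Weight Method: formulas, invariants, estimator API, pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from ensotel.ewm import (
    EntropyWeightModel,
    build_inputs,
    entropy,
    ewm_pipeline,
    exposure_index,
    minmax_scale_rows,
    normalize,
    weights_from_entropy,
)
from ensotel.oni import EL_NINO, LA_NINA
from ensotel.reference import load_reference_entropies, recompute_weights
from ensotel.teleconnection import CorrelationMap


def _cmap(r, p, phase=EL_NINO, variable="v", lag=0, alpha=0.05):
    r = np.asarray(r, dtype=float)
    p = np.asarray(p, dtype=float)
    return CorrelationMap(variable=variable, phase=phase, lag=lag,
                          r=r, p=p, n=np.full(r.shape, 40), alpha=alpha)


class TestNormalize:
    def test_uniform_row(self):
        np.testing.assert_allclose(normalize(np.array([[1.0, 1, 1, 1]])),
                                   [[0.25, 0.25, 0.25, 0.25]])

    def test_single_mass(self):
        np.testing.assert_allclose(normalize(np.array([[2.0, 0, 0]])),
                                   [[1.0, 0, 0]])

    def test_hand_division(self):
        np.testing.assert_allclose(normalize(np.array([[1.0, 3.0]])),
                                   [[0.25, 0.75]])

    def test_zero_row_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            normalize(np.array([[0.0, 0.0]]))


class TestEntropy:
    def test_uniform_is_one(self):
        for n in (2, 5, 100):
            E = entropy(np.full((1, n), 1.0 / n))
            np.testing.assert_allclose(E, 1.0)

    def test_half_half_over_four_is_half(self):
        E = entropy(np.array([[0.5, 0.5, 0.0, 0.0]]), n=4)
        np.testing.assert_allclose(E, np.log(2) / np.log(4))
        assert abs(E[0] - 0.5) < 1e-15

    def test_degenerate_mass_is_zero(self):
        E = entropy(np.array([[1.0] + [0.0] * 9]))
        np.testing.assert_allclose(E, 0.0)

    def test_n_below_two_rejected(self):
        with pytest.raises(ValueError):
            entropy(np.array([[1.0]]), n=1)


class TestWeights:
    def test_table_block_reproduces_published_weights(self):
        E = np.array([0.7093, 0.7453, 0.6312, 0.6666, 0.6714, 0.6751])
        _, w = weights_from_entropy(E)
        np.testing.assert_allclose(
            np.round(w, 4), [0.1529, 0.1340, 0.1940, 0.1754, 0.1728, 0.1709])

    def test_equal_entropies_give_equal_weights(self):
        _, w = weights_from_entropy(np.full(6, 0.7))
        np.testing.assert_allclose(w, 1 / 6)

    def test_hand_normalization(self):
        d, w = weights_from_entropy(np.array([0.9, 0.8]))
        np.testing.assert_allclose(d, [0.1, 0.2])
        np.testing.assert_allclose(w, [1 / 3, 2 / 3])

    def test_all_uniform_variables_rejected_with_guidance(self):
        with pytest.raises(ValueError, match="no information|contrast"):
            weights_from_entropy(np.ones(4))


class TestExposure:
    def test_single_weight_passthrough(self, rng):
        X = rng.random((3, 10))
        out = exposure_index(np.array([1.0, 0, 0]), X)
        np.testing.assert_allclose(out, X[0])

    def test_constant_signal(self):
        X = np.full((4, 7), 0.3)
        w = np.full(4, 0.25)
        np.testing.assert_allclose(exposure_index(w, X), 0.3)

    def test_hand_dot_product(self):
        out = exposure_index(np.array([0.25, 0.75]),
                             np.array([[0.4], [0.8]]))
        np.testing.assert_allclose(out, [0.7])


class TestEwmInvariants:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(hnp.arrays(np.float64, shape=st.tuples(st.integers(2, 6),
                                                  st.integers(2, 40)),
                      elements=st.floats(0.0, 10.0)))
    def test_rows_sum_one_entropy_bounded_weights_sum_one(self, X):
        keep = X.sum(axis=1) > 0
        if not keep.any() or np.allclose(np.ptp(X[keep], axis=1), 0.0):
            return
        P = normalize(X[keep])
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
        E = entropy(P)
        assert np.all(E >= -1e-12) and np.all(E <= 1 + 1e-12)
        try:
            _, w = weights_from_entropy(np.clip(E, 0, 1))
        except ValueError:
            return   # all-uniform corner
        assert np.all(w >= 0)
        assert abs(w.sum() - 1.0) < 1e-12

    def test_entropy_permutation_invariant(self, rng):
        X = rng.random((3, 30))
        P = normalize(X)
        perm = rng.permutation(30)
        np.testing.assert_allclose(entropy(P), entropy(P[:, perm]))

    def test_duplicating_pixels_leaves_weights_unchanged(self, rng):
        X = rng.random((4, 25))
        _, w1 = weights_from_entropy(entropy(normalize(X)))
        X2 = np.concatenate([X, X], axis=1)
        _, w2 = weights_from_entropy(entropy(normalize(X2)))
        np.testing.assert_allclose(w1, w2, atol=1e-12)

    def test_concentration_never_increases_entropy(self, rng):
        """Mean-preserving transfer of share toward a heavier pixel lowers E."""
        P = normalize(rng.random((1, 20)) + 0.1)
        i, j = np.argmax(P[0]), np.argmin(P[0])
        Q = P.copy()
        delta = Q[0, j] / 2
        Q[0, i] += delta
        Q[0, j] -= delta
        assert entropy(Q)[0] <= entropy(P)[0] + 1e-12


class TestBuildInputsAndPipeline:
    def test_no_significant_pixels_gives_empty_domain_status(self):
        maps = [_cmap(np.full((3, 3), 0.4), np.full((3, 3), 0.5),
                      variable=f"v{i}") for i in range(6)]
        res = ewm_pipeline(maps)
        assert res.status == "empty-domain"
        assert np.isnan(res.exposure_grid).all()

    def test_single_significant_entry_is_absolute_r(self):
        r = np.zeros((2, 2)); p = np.ones((2, 2))
        r[0, 0], p[0, 0] = -0.6, 0.01
        other = _cmap(np.full((2, 2), 0.3), np.full((2, 2), 0.02),
                      variable="b")
        inputs = build_inputs([_cmap(r, p, variable="a"), other])
        row_a = inputs.X[0]
        assert 0.6 in row_a and row_a.sum() == pytest.approx(0.6)

    def test_hand_assembled_two_variable_three_pixel_case(self):
        r1 = np.array([[0.5, -0.4, 0.0]])
        p1 = np.array([[0.01, 0.02, 0.9]])
        r2 = np.array([[0.0, 0.8, 0.3]])
        p2 = np.array([[0.7, 0.001, 0.04]])
        inputs = build_inputs([_cmap(r1, p1, variable="a"),
                               _cmap(r2, p2, variable="b")])
        np.testing.assert_allclose(inputs.X,
                                   [[0.5, 0.4, 0.0], [0.0, 0.8, 0.3]])
        np.testing.assert_array_equal(inputs.directions,
                                      [[1, -1, 0], [0, 1, 1]])

    def test_lanina_direction_flipped(self):
        r = np.array([[0.5]]); p = np.array([[0.01]])
        maps = [_cmap(r, p, phase=LA_NINA, variable="a"),
                _cmap(r, p, phase=LA_NINA, variable="b")]
        inputs = build_inputs(maps)
        assert (inputs.directions == -1).all()

    def test_mixed_phases_rejected(self):
        with pytest.raises(ValueError, match="phase"):
            build_inputs([_cmap(np.zeros((1, 2)), np.ones((1, 2))),
                          _cmap(np.zeros((1, 2)), np.ones((1, 2)),
                                phase=LA_NINA)])

    def test_patchy_variable_receives_largest_weight(self, rng):
        # five spatially even variables, one concentrated on a few pixels
        n = 400
        shape = (20, 20)
        maps = []
        for i in range(5):
            r = rng.uniform(0.4, 0.5, size=shape) * np.sign(rng.normal(size=shape))
            maps.append(_cmap(r, np.full(shape, 0.01), variable=f"even{i}"))
        r_patchy = np.zeros(shape)
        r_patchy.ravel()[: n // 20] = 0.9
        p_patchy = np.where(r_patchy != 0, 0.001, 0.9)
        maps.append(_cmap(r_patchy, p_patchy, variable="patchy"))
        res = ewm_pipeline(maps)
        assert res.variables[int(np.argmax(res.weights))] == "patchy"

    def test_exposure_grid_in_unit_interval(self, rng):
        shape = (10, 10)
        maps = [_cmap(rng.uniform(-0.8, 0.8, shape),
                      rng.uniform(0, 0.2, shape), variable=f"v{i}")
                for i in range(6)]
        res = ewm_pipeline(maps)
        vals = res.exposure_grid[np.isfinite(res.exposure_grid)]
        assert vals.min() >= 0.0 and vals.max() <= 1.0 + 1e-12
        assert abs(res.weights.sum() - 1.0) < 1e-12

    def test_single_pixel_domain_rejected(self):
        r = np.array([[0.9, 0.0]]); p = np.array([[0.001, 0.9]])
        maps = [_cmap(r, p, variable="a"), _cmap(r, p, variable="b")]
        with pytest.raises(ValueError, match="2"):
            ewm_pipeline(maps)


class TestEntropyWeightModel:
    def test_sklearn_api_roundtrip(self, rng):
        X = rng.random((50, 4))
        model = EntropyWeightModel().fit(X)
        assert model.get_params() == {"scale": "minmax"}
        assert model.n_features_in_ == 4
        assert abs(model.weights_.sum() - 1.0) < 1e-12
        out = model.transform(X)
        assert out.shape == (50, 1)
        assert out.min() >= 0.0 and out.max() <= 1.0 + 1e-12
        cloned = EntropyWeightModel(**model.get_params())
        np.testing.assert_allclose(cloned.fit(X).weights_, model.weights_)

    def test_matches_functional_pipeline(self, rng):
        X = rng.random((30, 3))
        model = EntropyWeightModel().fit(X)
        _, w = weights_from_entropy(entropy(normalize(X.T)))
        np.testing.assert_allclose(model.weights_, w, atol=1e-12)
        np.testing.assert_allclose(
            model.transform(X).ravel(),
            exposure_index(w, minmax_scale_rows(X.T)), atol=1e-12)

    def test_rejects_negative_and_unfitted_use(self, rng):
        with pytest.raises(ValueError):
            EntropyWeightModel().fit(-np.ones((5, 2)))
        from sklearn.exceptions import NotFittedError
        with pytest.raises(NotFittedError):
            EntropyWeightModel().transform(rng.random((5, 2)))


def test_reference_table_recomputation_structure():
    df = recompute_weights(load_reference_entropies())
    assert len(df) == 24
    assert set(df["crop"]) == {"coffee", "cacao"}
    # per-block weights sum to 1 exactly by construction
    sums = df.groupby(["crop", "phase"])["weight_recomputed"].sum()
    np.testing.assert_allclose(sums, 1.0, atol=1e-12)
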