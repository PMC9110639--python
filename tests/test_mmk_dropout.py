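import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nisc.data_model import ExpressionMatrix
from nisc.mmk_dropout import (
    MichaelisMentenDropout,
    dropout_probability,
    estimate_km,
    fit,
)


class TestDropoutProbability:
    @pytest.mark.parametrize(
        "s, km, expected",
        [
            (0.0, 1.0, 1.0),
            (0.0, 123.4, 1.0),
            (2.5, 2.5, 0.5),
            (3.0, 1.0, 0.25),  # s = 3*km -> 1 - 3/4
        ],
    )
    def test_analytic_values(self, s, km, expected):
        assert dropout_probability(s, km) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            dropout_probability(1.0, 0.0)
        with pytest.raises(ValueError):
            dropout_probability(-1.0, 1.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        s=st.floats(0.0, 1e3),
        ds=st.floats(1e-2, 1e3),
        km=st.floats(1e-3, 1e3),
    )
    def test_strictly_decreasing_in_s(self, s, ds, km):
        assert dropout_probability(s + ds, km) < dropout_probability(s, km)

    @settings(derandomize=True, max_examples=50)
    @given(
        s=st.floats(1e-2, 1e3),
        km=st.floats(1e-3, 1e2),
        dk=st.floats(1e-2, 1e2),
    )
    def test_strictly_increasing_in_km_for_positive_s(self, s, km, dk):
        assert dropout_probability(s, km + dk) > dropout_probability(s, km)


def _mm_matrix(km: float, n_genes: int, n_cells: int, seed: int) -> ExpressionMatrix:
    """Matrix whose per-gene zero fractions follow the MM curve at a known km.

    The curve relates a gene's zero fraction to its observed mean m_g (zeros
    included). Targeting mean t_g, each cell is zeroed with probability
    km/(km + t_g) and expressed cells carry km + t_g, so in expectation both
    the zero fraction and the observed mean sit exactly on the km curve.
    """
    rng = np.random.default_rng(seed)
    t = rng.gamma(2.0, km, size=n_genes) + 0.1
    p_zero = km / (km + t)
    dropped = rng.random((n_genes, n_cells)) < p_zero[:, None]
    values = np.where(dropped, 0.0, (km + t)[:, None])
    return ExpressionMatrix(values)


class TestEstimateKm:
    def test_recovers_known_km(self):
        em = _mm_matrix(km=3.0, n_genes=400, n_cells=500, seed=7)
        assert estimate_km(em) == pytest.approx(3.0, rel=0.05)

    def test_recovery_within_one_percent_with_exact_fractions(self):
        # zero counts chosen so each gene sits exactly on the km = 3 curve:
        # with z of n cells zeroed and expressed value km*n/z, the zero
        # fraction z/n equals km/(km + m_g) for the observed mean m_g
        km, n_cells = 3.0, 100
        zero_counts = np.arange(10, 91)
        values = np.zeros((len(zero_counts), n_cells))
        for g, z in enumerate(zero_counts):
            values[g, z:] = km * n_cells / z
        assert estimate_km(ExpressionMatrix(values)) == pytest.approx(km, rel=0.01)

    def test_degenerate_two_gene_matrix_gives_finite_positive(self):
        em = ExpressionMatrix(np.array([[4.0] * 5, [0.0] * 5]))
        km = estimate_km(em)
        assert np.isfinite(km) and km > 0

    def test_invariant_to_cell_permutation(self, rng):
        em = _mm_matrix(km=2.0, n_genes=150, n_cells=200, seed=3)
        perm = rng.permutation(em.n_cells)
        shuffled = ExpressionMatrix(em.values[:, perm])
        assert estimate_km(em) == pytest.approx(estimate_km(shuffled), rel=1e-9)

    def test_no_zero_matrix_warns_and_returns_tiny(self):
        em = ExpressionMatrix(np.full((3, 3), 5.0))
        with pytest.warns(UserWarning, match="no zero entries"):
            km = estimate_km(em)
        assert 0 < km < 1e-100

    def test_all_zero_matrix_raises(self):
        with pytest.raises(ValueError, match="all-zero"):
            estimate_km(ExpressionMatrix(np.zeros((3, 3))))


class TestFit:
    def test_two_by_two_analytic_case(self):
        km = 2.0
        em = ExpressionMatrix(np.array([[0.0, km], [km, 0.0]]))
        model = fit(em, km=km)
        np.testing.assert_allclose(model.prob, [[1.0, 0.5], [0.5, 1.0]])
        np.testing.assert_allclose(model.weight, [[0.0, 0.5], [0.5, 0.0]])

    def test_weights_zero_exactly_at_zeros(self, small_matrix):
        model = fit(small_matrix, km=1.7)
        zeros = small_matrix.values == 0
        assert np.all(model.weight[zeros] == 0.0)
        assert np.all(model.prob[zeros] == 1.0)
        assert np.all(model.weight[~zeros] > 0.0)

    def test_saturation_limit(self):
        em = ExpressionMatrix(np.full((3, 4), 1e6))
        model = fit(em, km=1.0)
        assert np.all(model.weight > 0.999)

    def test_matches_elementwise_loop(self, rng):
        values = rng.poisson(3.0, size=(15, 12)).astype(float)
        em = ExpressionMatrix(values)
        model = fit(em, km=2.5)
        for i in range(15):
            for j in range(12):
                expected = 1.0 - values[i, j] / (2.5 + values[i, j])
                assert model.prob[i, j] == pytest.approx(expected, abs=1e-12)
                assert model.weight[i, j] == pytest.approx(1 - expected, abs=1e-12)


class TestEstimatorWrapper:
    def test_fit_sets_km_and_weights_match_module(self, rng):
        em = _mm_matrix(km=2.0, n_genes=100, n_cells=80, seed=5)
        est = MichaelisMentenDropout().fit(em.values.T)
        model = fit(em)
        assert est.km_ == pytest.approx(model.km)
        np.testing.assert_allclose(est.weights(em.values.T), model.weight.T)

    def test_get_set_params_round_trip(self):
        est = MichaelisMentenDropout(km=4.0)
        assert MichaelisMentenDropout(**est.get_params()).km == 4.0
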