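import numpy as np
import pytest

from paneval import DomainError, evaluate_topsis
from paneval.panel import IndicatorPanel, IndicatorSchema
from paneval.topsis import closeness, distances, rank_topsis, weighted_normalized

from test_panel import make_panel


class TestWeightedNormalized:
    def test_china_column_maxima_match_reference_ideal(self, china_raw, china_weights):
        z = weighted_normalized(china_raw, china_weights.weights)
        np.testing.assert_allclose(
            np.round(z.max(axis=0), 4),
            [0.0417, 0.0534, 0.0610, 0.0515, 0.0521, 0.0218],
            atol=1e-4,
        )

    def test_china_column_minima_match_reference_anti_ideal(self, china_raw, china_weights):
        z = weighted_normalized(china_raw, china_weights.weights)
        np.testing.assert_allclose(
            np.round(z.min(axis=0), 4),
            [0.0158, 0.0488, 0.0509, 0.0479, 0.0472, 0.0181],
            atol=1e-4,
        )

    def test_weights_must_sum_to_one(self, china_raw):
        with pytest.raises(DomainError, match="sum to 1"):
            weighted_normalized(china_raw, np.full(6, 0.5))

    def test_weight_length_mismatch(self, china_raw):
        with pytest.raises(DomainError):
            weighted_normalized(china_raw, np.full(3, 1 / 3))

    def test_difference_cotrend_selectable(self, china_raw, china_weights):
        panel = china_raw.with_schema(
            (IndicatorSchema("cost", cost_reference=100000.0, cotrend_method="difference"),)
            + china_raw.schema[1:]
        )
        z = weighted_normalized(panel, china_weights.weights)
        # difference co-trend leaves the mortality column nearly constant,
        # far from the reciprocal column's 0.0417 maximum
        assert z[:, 0].max() == pytest.approx(0.0298, abs=1e-3)
        assert np.ptp(z[:, 0]) < 1e-4

    def test_column_rescale_invariance(self, rng, china_raw, china_weights):
        scaled = IndicatorPanel(
            china_raw.alternatives,
            china_raw.indicators,
            china_raw.values * np.array([1.0, 7.5, 0.2, 3.0, 1.0, 10.0]),
            china_raw.schema,
        )
        np.testing.assert_allclose(
            evaluate_topsis(scaled, china_weights.weights).closeness,
            evaluate_topsis(china_raw, china_weights.weights).closeness,
            atol=1e-12,
        )


class TestDistances:
    def test_row_equal_to_ideal(self):
        z = np.array([[1.0, 2.0], [0.0, 0.0]])
        dp, dm = distances(z, z.max(0), z.min(0))
        assert dp[0] == 0.0 and dm[1] == 0.0

    def test_single_column_absolute_difference(self):
        z = np.array([[0.3], [0.8]])
        dp, dm = distances(z, np.array([0.9]), np.array([0.1]))
        np.testing.assert_allclose(dp, [0.6, 0.1])
        np.testing.assert_allclose(dm, [0.2, 0.7])

    def test_china_2004_dplus(self, china_topsis):
        assert china_topsis.d_plus[0] == pytest.approx(0.0291, abs=5e-5)

    def test_full_dplus_column(self, china_topsis):
        expected = [0.0291, 0.0287, 0.0265, 0.0239, 0.0224, 0.0198, 0.0173,
                    0.0135, 0.0110, 0.0090, 0.0067, 0.0037, 0.0034, 0.0031, 0.0026]
        np.testing.assert_allclose(np.round(china_topsis.d_plus, 4), expected, atol=1e-4)

    def test_dimension_mismatch(self):
        with pytest.raises(DomainError):
            distances(np.ones((2, 3)), np.ones(2), np.ones(3))

    def test_brute_force_oracle(self, rng):
        z = rng.uniform(0, 1, size=(8, 4))
        ap, am = z.max(0), z.min(0)
        dp, dm = distances(z, ap, am)
        for i in range(8):
            assert dp[i] == pytest.approx(
                np.sqrt(sum((ap[j] - z[i, j]) ** 2 for j in range(4))), abs=1e-12
            )
            assert dm[i] == pytest.approx(
                np.sqrt(sum((am[j] - z[i, j]) ** 2 for j in range(4))), abs=1e-12
            )


class TestCloseness:
    def test_at_ideal(self):
        assert closeness([0.0], [0.5])[0] == 1.0

    def test_at_anti_ideal(self):
        assert closeness([0.5], [0.0])[0] == 0.0

    def test_degenerate_gives_half_with_warning(self):
        with pytest.warns(UserWarning):
            out = closeness([0.0], [0.0])
        assert out[0] == 0.5

    def test_range(self, rng):
        dp = rng.uniform(0, 1, 20)
        dm = rng.uniform(0, 1, 20)
        c = closeness(dp, dm)
        assert np.all((c >= 0) & (c <= 1))

    def test_oracle_random_matrices(self, rng):
        for _ in range(10):
            z = rng.uniform(0, 1, size=(8, 4))
            dp, dm = distances(z, z.max(0), z.min(0))
            np.testing.assert_allclose(closeness(dp, dm), dm / (dp + dm), atol=1e-12)


class TestRanks:
    def test_china_extremes(self, china_topsis):
        assert china_topsis.rank_of("2018") == 1
        assert china_topsis.rank_of("2004") == 15

    def test_china_rank_order_strictly_chronological(self, china_topsis):
        np.testing.assert_array_equal(china_topsis.ranks, np.arange(15, 0, -1))

    def test_strictly_increasing_values(self):
        np.testing.assert_array_equal(rank_topsis([0.1, 0.2, 0.3]), [3, 2, 1])

    def test_all_equal_input_order(self):
        np.testing.assert_array_equal(rank_topsis([0.5, 0.5, 0.5]), [1, 2, 3])

    def test_permutation_property(self, rng):
        r = rank_topsis(rng.uniform(0, 1, 25))
        assert sorted(r) == list(range(1, 26))


class TestEvaluate:
    def test_invariants(self, china_topsis):
        t = china_topsis
        np.testing.assert_array_equal(t.ideal, t.weighted_matrix.max(0))
        np.testing.assert_array_equal(t.anti_ideal, t.weighted_matrix.min(0))
        assert np.all(t.d_plus >= 0) and np.all(t.d_minus >= 0)
        assert np.all((t.closeness >= 0) & (t.closeness <= 1))

    def test_single_indicator(self):
        p = make_panel([[1.0], [2.0], [3.0]])
        res = evaluate_topsis(p, [1.0])
        assert res.rank_of("a2") == 1
        np.testing.assert_allclose(res.closeness, [0.0, 0.5, 1.0], atol=1e-12)

    def test_dominance_monotonicity(self, rng):
        # strictly improving rows must be ranked in order
        base = np.linspace(1.0, 2.0, 10)
        values = np.column_stack([base, base**1.5, base * 3.0])
        res = evaluate_topsis(make_panel(values), np.array([0.2, 0.5, 0.3]))
        assert np.all(np.diff(res.closeness) > 0)
        np.testing.assert_array_equal(res.ranks, np.arange(10, 0, -1))

    def test_dominance_cost_column(self):
        values = np.column_stack([np.linspace(40, 20, 8), np.linspace(80, 99, 8)])
        panel = IndicatorPanel(
            tuple(f"y{i}" for i in range(8)),
            ("bad", "good"),
            values,
            (IndicatorSchema("cost"), IndicatorSchema("benefit")),
        )
        res = evaluate_topsis(panel, np.array([0.5, 0.5]))
        assert np.all(np.diff(res.closeness) > 0)
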