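"""Closed-form moment formulas: worked examples and structural invariants."""

import numpy as np
import pytest

from neurocov.architectures import (
    CouplingSpec,
    MomentSet,
    StimulusDrive,
    feedforward_covariance,
    gain_covariance,
    predicted_average_correlations,
    predicted_population_moments,
    recurrent_covariance,
    steady_state_rates,
    transfer_matrix,
)
from neurocov.exceptions import DimensionError, StabilityError


class TestTransferMatrix:
    @pytest.mark.parametrize(
        "g, expected",
        [
            (np.zeros((2, 2)), np.eye(2)),
            ([[0, 0.5], [0, 0]], [[1, 0.5], [0, 1]]),  # nilpotent: series ends
            ([[0, 0.5], [0.5, 0]], [[4 / 3, 2 / 3], [2 / 3, 4 / 3]]),
        ],
    )
    def test_closed_form(self, g, expected):
        b = transfer_matrix(CouplingSpec("recurrent_direct", g))
        np.testing.assert_allclose(b, expected, atol=1e-12)

    def test_inverse_relation(self, rng):
        g = rng.normal(0, 0.05, (8, 8))
        spec = CouplingSpec("recurrent_direct", g)
        b = transfer_matrix(spec)
        np.testing.assert_allclose(b @ (np.eye(8) - g), np.eye(8), atol=1e-10)

    def test_singular_coupling_rejected(self):
        with pytest.raises(StabilityError):
            CouplingSpec("recurrent_direct", [[0, 1], [1, 0]])

    def test_neumann_series_oracle(self, rng):
        """B equals the truncated series sum_k G^k for spectral radius <= 0.5."""
        for _ in range(5):
            g = rng.normal(0, 0.1, (6, 6))
            g *= 0.5 / np.abs(np.linalg.eigvals(g)).max()
            b = transfer_matrix(CouplingSpec("recurrent_direct", g))
            series = np.zeros_like(g)
            term = np.eye(6)
            for _k in range(60):
                series += term
                term = term @ g
            np.testing.assert_allclose(b, series, atol=1e-6)


class TestSteadyStateRates:
    def test_uncoupled_identity(self):
        spec = CouplingSpec("recurrent_direct", np.zeros((2, 2)))
        r = steady_state_rates(spec, StimulusDrive.poisson([1.0, 2.0]))
        np.testing.assert_allclose(r, [1, 2])

    def test_symmetric_pair(self):
        spec = CouplingSpec("recurrent_direct", [[0, 0.5], [0.5, 0]])
        r = steady_state_rates(spec, StimulusDrive.poisson([1.0, 1.0]))
        np.testing.assert_allclose(r, [2, 2], rtol=1e-9)

    def test_feedforward_product(self):
        spec = CouplingSpec("feedforward", [[1, 1], [1, 1]])
        r = steady_state_rates(spec, StimulusDrive.poisson([1.0, 0.0]))
        np.testing.assert_allclose(r, [1, 1])

    def test_dimension_mismatch(self):
        spec = CouplingSpec("feedforward", np.eye(3))
        with pytest.raises(DimensionError):
            steady_state_rates(spec, StimulusDrive.poisson([1.0, 2.0]))


class TestRecurrentCovariance:
    def test_independent_poisson_limit(self):
        """B = I, no external noise: variance equals rate (Fano factor one)."""
        c = recurrent_covariance(np.eye(2), [1.0, 2.0])
        np.testing.assert_allclose(c, np.diag([1, 2]))

    def test_hand_evaluation(self):
        c = recurrent_covariance([[1, 0.5], [0, 1]], [1.0, 1.0])
        np.testing.assert_allclose(c, [[1.25, 0.5], [0.5, 1.0]])

    def test_additive_external_variance(self):
        c = recurrent_covariance(np.eye(2), [1.0, 1.0], v_ext=[0.5, 0.5])
        np.testing.assert_allclose(c, np.diag([1.5, 1.5]))

    def test_negative_drive_warns(self):
        with pytest.warns(RuntimeWarning, match="diagonal drive"):
            recurrent_covariance(np.eye(2), [-3.0, 1.0], offset_a=1.0)

    def test_symmetric_psd_for_nonnegative_drive(self, rng):
        for _ in range(10):
            b = rng.normal(0.1, 0.2, (7, 7))
            rates = rng.uniform(0, 10, 7)
            v = rng.uniform(0, 5, 7)
            c = recurrent_covariance(b, rates, v, offset_a=1.0)
            np.testing.assert_allclose(c, c.T, atol=1e-12)
            eigs = np.linalg.eigvalsh(c)
            assert eigs.min() >= -1e-8 * np.trace(c)


class TestFeedforwardCovariance:
    def test_poisson_in_poisson_out(self):
        c = feedforward_covariance(np.eye(2), [1.0, 2.0], v_ext=[1.0, 2.0])
        np.testing.assert_allclose(c, np.diag([2, 4]))

    def test_shared_input_hand_evaluation(self):
        c = feedforward_covariance([[1, 1], [1, 1]], [1.0, 1.0], v_ext=[1.0, 0.0])
        np.testing.assert_allclose(c, [[2, 1], [1, 2]])

    def test_no_shared_noise_is_diagonal(self, rng):
        f = rng.normal(0, 1, (5, 5))
        rates = rng.uniform(0, 5, 5)
        c = feedforward_covariance(f, rates, v_ext=0.0, offset_a=0.5)
        np.testing.assert_allclose(c, np.diag(rates + 0.5))


class TestGainCovariance:
    @pytest.mark.parametrize(
        "rates, v, expected",
        [
            ([1.0, 2.0], 0.0, np.diag([1, 2])),
            ([1.0, 2.0], 0.5, [[1.5, 1.0], [1.0, 4.0]]),
            ([1.0, 1.0], 0.53, [[1.53, 0.53], [0.53, 1.53]]),
        ],
    )
    def test_closed_form(self, rates, v, expected):
        np.testing.assert_allclose(gain_covariance(rates, v), expected)

    def test_offdiagonal_ratio_is_constant(self, rng):
        """C_ij / ((r_i + a)(r_j + a)) equals V_ext for every pair, exactly."""
        rates = rng.uniform(0.5, 10, 8)
        a, v = 1.5, 0.7
        c = gain_covariance(rates, v, offset_a=a)
        u = rates + a
        off = ~np.eye(8, dtype=bool)
        ratios = (c / np.outer(u, u))[off]
        np.testing.assert_allclose(ratios, v, rtol=1e-12)


class TestPopulationPredictions:
    def test_recurrent_row(self):
        out = predicted_population_moments(
            "recurrent", n=100, mean_w=0.1, var_w=0.01, mean_rate=5.0, mean_v_ext=5.0
        )
        assert out["mean_var"] == pytest.approx(20.0)
        assert out["mean_cov"] == pytest.approx(10.0)

    def test_feedforward_row(self):
        out = predicted_population_moments(
            "feedforward", n=100, mean_w=0.1, var_w=0.01, mean_rate=5.0, mean_v_ext=1.0
        )
        assert out["mean_var"] == pytest.approx(7.0)
        assert out["mean_cov"] == pytest.approx(1.0)

    def test_gain_row(self):
        out = predicted_population_moments(
            "gain", n=3, mean_rate=2.0, rates=[1.0, 2.0, 3.0], v_ext_scalar=0.5
        )
        assert out["mean_var"] == pytest.approx(13 / 3)
        assert out["mean_cov"] == pytest.approx(2.0)

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            predicted_population_moments("mixed", n=10, mean_rate=1.0)

    def test_recurrent_matches_sampled_ensemble(self, rng):
        """Prediction within 3 ensemble SE of the average over sampled matrices."""
        n, mean_w, sd_w = 40, 0.1, 0.1
        rates = rng.uniform(1, 9, n)
        v_ext = np.full(n, 2.0)
        mean_vars, mean_covs = [], []
        off = ~np.eye(n, dtype=bool)
        for _ in range(25):
            b = rng.normal(mean_w, sd_w, (n, n))
            c = recurrent_covariance(b, rates, v_ext, offset_a=1.0)
            mean_vars.append(np.diag(c).mean())
            mean_covs.append(c[off].mean())
        pred = predicted_population_moments(
            "recurrent", n=n, mean_w=mean_w, var_w=sd_w**2,
            mean_rate=float(rates.mean()), offset_a=1.0, mean_v_ext=2.0,
        )
        for key, samples in (("mean_var", mean_vars), ("mean_cov", mean_covs)):
            se = np.std(samples) / np.sqrt(len(samples))
            assert abs(np.mean(samples) - pred[key]) < 3 * se


class TestAverageCorrelations:
    @pytest.mark.parametrize(
        "rho, c_in, n, c_n, c_s",
        [
            (0.0, 0.0, 10, 1.0, 1.0),
            (1.0, 0.0, 10, 0.5, 0.5),
            (1.0, 0.05, 60, 0.5, 3.95 / 4.95),
        ],
    )
    def test_recurrent_formulas(self, rho, c_in, n, c_n, c_s):
        out = predicted_average_correlations("recurrent", rho, c_in, n)
        assert out["c_N"] == pytest.approx(c_n)
        assert out["c_S"] == pytest.approx(c_s, rel=1e-6)

    def test_gain_has_no_signal_prediction(self):
        out = predicted_average_correlations("gain", 1.0, 0.0, 10)
        assert out["c_N"] is None and out["c_S"] is None


class TestMomentSet:
    def test_asymmetric_covariance_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            MomentSet(rates=[1.0, 1.0], cov=[[1.0, 0.5], [0.1, 1.0]])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(DimensionError):
            MomentSet(rates=[1.0, 1.0, 1.0], cov=np.eye(2))
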