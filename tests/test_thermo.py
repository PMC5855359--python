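import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tetrafit as tf
from tetrafit.thermo import statistical_weights

from _oracles import microstate_probabilities

WT = tf.WT_DEGENERACIES

finite_energy = st.floats(-3.0, 3.0, allow_nan=False)
log_conc = st.floats(-9.0, 0.0)


class TestParamsValidation:
    @pytest.mark.parametrize(
        "overrides",
        [{"k_a": -1.0}, {"gamma": 0.0}, {"d": 0.0}, {"a": 1.5}, {"nu": float("nan")}],
    )
    def test_invalid_parameters_rejected(self, best_fit, overrides):
        with pytest.raises(ValueError):
            tf.ThermoParams(**{**best_fit.to_dict(), **overrides})

    def test_conductance_bound_configurable(self, best_fit):
        d = best_fit.to_dict()
        d["a"] = 1.5
        tf.ThermoParams(**d, conductance_bound=2.0)  # no raise

    def test_degeneracy_invariants(self):
        with pytest.raises(ValueError):
            tf.DegeneracyVector((1, 4, 6, 4, 0))  # unliganded-only ensembles excluded
        with pytest.raises(ValueError):
            tf.DegeneracyVector((0, 0, 0, 0, 1))
        with pytest.raises(ValueError):
            tf.DegeneracyVector((1, 4, 6, 4))


class TestCoopWeight:
    @pytest.mark.parametrize(
        "k,expected",
        [
            (0, 1.0),
            (1, 1.0),
            (2, 0.928),  # = gamma
            (3, 0.928**3 * 0.4529),  # gamma^3 mu, direct arithmetic
            (4, 1.7531177721757423),  # gamma^6 mu^4 nu, high-precision arithmetic
        ],
    )
    def test_best_fit_weights(self, best_fit, k, expected):
        assert tf.coop_weight(k, best_fit) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("k", [-1, 5])
    def test_out_of_range_index(self, best_fit, k):
        with pytest.raises(ValueError):
            tf.coop_weight(k, best_fit)

    def test_non_integer_index(self, best_fit):
        with pytest.raises(TypeError):
            tf.coop_weight(2.5, best_fit)


class TestOccupancy:
    def test_zero_concentration_is_unliganded(self, best_fit):
        prof = tf.occupancy_probabilities(best_fit, WT, 0.0)
        assert prof.p == (1.0, 0.0, 0.0, 0.0, 0.0)

    def test_negative_concentration_rejected(self, best_fit):
        with pytest.raises(ValueError):
            tf.occupancy_probabilities(best_fit, WT, -1e-6)

    def test_statistical_weights_at_10uM(self, best_fit):
        # denominator terms of the probability expressions at [L] = 1e-5 M
        z = statistical_weights(best_fit, WT, 1e-5)
        assert z == pytest.approx(
            [1.0, 7.22, 18.1406832, 8.514082603745385, 18.60886637627763], rel=1e-12
        )

    def test_p4_at_10uM_matches_enumeration(self, best_fit):
        prof = tf.occupancy_probabilities(best_fit, WT, 1e-5)
        assert prof[4] == pytest.approx(0.3479357257121429, rel=1e-10)
        # independent check through the energy representation + 2^4 microstates
        e = tf.coefficients_to_energies(best_fit)
        oracle = microstate_probabilities(e.delta_e, e.j, e.k, e.m, 1e-5)
        assert prof.as_array() == pytest.approx(oracle, abs=1e-12)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(de=finite_energy, j=finite_energy, k=finite_energy, m=finite_energy,
           lg=log_conc)
    def test_closed_form_equals_microstate_oracle(self, de, j, k, m, lg):
        """The configuration probabilities equal a brute-force Boltzmann sum
        over all 16 site-occupancy patterns, for arbitrary coupling energies."""
        coeffs = tf.energies_to_coefficients(tf.EnergyParams(de, j, k, m))
        params = tf.ThermoParams(*coeffs, a=0.5, b=0.5, c=0.5, d=0.5)
        prof = tf.occupancy_probabilities(params, WT, 10.0**lg)
        oracle = microstate_probabilities(de, j, k, m, 10.0**lg)
        assert prof.as_array() == pytest.approx(oracle, abs=1e-10)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000), lg=st.floats(-12.0, 0.0))
    def test_probabilities_normalized(self, seed, lg):
        from conftest import random_thermo_params

        params = random_thermo_params(np.random.default_rng(seed))
        prof = tf.occupancy_probabilities(params, WT, 10.0**lg)
        assert abs(sum(prof.p) - 1.0) < 1e-12

    def test_binomial_limit(self, best_fit):
        """With no cooperativity the tetramer reduces to independent sites:
        p_k = C(4,k) x^k / (1+x)^4."""
        params = tf.ThermoParams(k_a=best_fit.k_a, gamma=1, mu=1, nu=1,
                                 a=1, b=1, c=1, d=1)
        for x in (0.01, 0.5, 1.0, 7.3):
            conc = x / params.k_a
            prof = tf.occupancy_probabilities(params, WT, conc)
            expected = [math.comb(4, k) * x**k / (1 + x) ** 4 for k in range(5)]
            assert prof.as_array() == pytest.approx(expected, abs=1e-12)
            # x = 1 makes all configurations equally likely up to degeneracy
            if x == 1.0:
                assert prof.as_array() == pytest.approx(np.array([1, 4, 6, 4, 1]) / 16)

    def test_p0_decreasing_p4_increasing(self, best_fit):
        conc = np.logspace(-9, -2, 80)
        probs = tf.occupancy_curve(best_fit, WT, conc)
        assert np.all(np.diff(probs[:, 0]) < 0)
        assert np.all(np.diff(probs[:, 4]) > 0)


class TestResponse:
    def test_zero_concentration(self, best_fit):
        assert tf.response(best_fit, WT, 0.0) == 0.0

    def test_value_at_10uM(self, best_fit):
        assert tf.response(best_fit, WT, 1e-5) == pytest.approx(
            0.5291948311217467, rel=1e-10
        )

    def test_high_concentration_asymptote_is_d(self, best_fit):
        assert tf.response(best_fit, WT, 10.0) == pytest.approx(best_fit.d, rel=1e-4)

    def test_bounded_by_largest_conductance(self, best_fit):
        conc = np.logspace(-10, 0, 50)
        y = tf.response(best_fit, WT, conc)
        assert np.all(y >= 0) and np.all(y <= max(best_fit.conductances))

    def test_binomial_limit_closed_form(self):
        params = tf.ThermoParams(k_a=1e5, gamma=1, mu=1, nu=1,
                                 a=0.7, b=0.7, c=0.7, d=0.7)
        conc = np.logspace(-8, -2, 20)
        x = params.k_a * conc
        assert tf.response(params, WT, conc) == pytest.approx(
            0.7 * (1 - (1 + x) ** -4.0), abs=1e-12
        )


class TestAverageOccupancy:
    def test_zero_concentration(self, best_fit):
        assert tf.average_occupancy(best_fit, WT, 0.0) == 0.0

    def test_langmuir_limit(self):
        params = tf.ThermoParams(k_a=1e5, gamma=1, mu=1, nu=1, a=1, b=1, c=1, d=1)
        conc = np.logspace(-8, -2, 25)
        x = params.k_a * conc
        assert tf.average_occupancy(params, WT, conc) == pytest.approx(
            4 * x / (1 + x), abs=1e-12
        )

    def test_value_at_10uM(self, best_fit):
        assert tf.average_occupancy(best_fit, WT, 1e-5) == pytest.approx(
            2.6826726957025624, rel=1e-10
        )

    def test_equals_activity_derivative_of_log_partition(self, best_fit):
        """<N> must equal x d(lnZ)/dx; checked by central differences."""
        for conc in (1e-7, 1e-6, 1e-5, 1e-4):
            h = 1e-6
            z_plus = statistical_weights(best_fit, WT, conc * (1 + h)).sum()
            z_minus = statistical_weights(best_fit, WT, conc * (1 - h)).sum()
            deriv = (math.log(z_plus) - math.log(z_minus)) / (2 * h)
            assert tf.average_occupancy(best_fit, WT, conc) == pytest.approx(
                deriv, abs=1e-6
            )

    def test_monotone_nondecreasing(self, best_fit):
        conc = np.logspace(-9, -2, 60)
        assert np.all(np.diff(tf.average_occupancy(best_fit, WT, conc)) >= 0)


class TestEnergyConversions:
    def test_zero_energies_give_unit_coefficients(self):
        coeffs = tf.energies_to_coefficients(tf.EnergyParams(0, 0, 0, 0))
        assert coeffs == pytest.approx((1.0, 1.0, 1.0, 1.0))

    def test_quadruple_coupling_energy_magnitude(self, best_fit):
        # nu = 65.24 corresponds to ~2.47 kcal/mol of (favourable) coupling
        energies = tf.coefficients_to_energies(best_fit)
        assert abs(energies.m) == pytest.approx(2.47, abs=5e-3)

    def test_natural_units_log_inverse(self):
        # gamma = e^-1 at beta = 1 (T chosen so k_B T = 1 kcal/mol) gives J = 1
        temp = 1.0 / tf.thermo.KB_KCAL_PER_MOL_K
        e = tf.coefficients_to_energies(
            tf.BindingCoefficients(1.0, math.exp(-1.0), 1.0, 1.0), temperature=temp
        )
        assert e.j == pytest.approx(1.0, rel=1e-12)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(de=finite_energy, j=finite_energy, k=finite_energy, m=finite_energy,
           temp=st.floats(200.0, 400.0))
    def test_round_trip(self, de, j, k, m, temp):
        coeffs = tf.energies_to_coefficients(tf.EnergyParams(de, j, k, m, temp))
        back = tf.coefficients_to_energies(coeffs, temperature=temp)
        assert (back.delta_e, back.j, back.k, back.m) == pytest.approx(
            (de, j, k, m), rel=1e-12, abs=1e-12
        )

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            tf.EnergyParams(0, 0, 0, 0, temperature=-5.0)
        with pytest.raises(ValueError):
            tf.coefficients_to_energies(
                tf.BindingCoefficients(1, 1, 1, 1), temperature=0.0
            )


class TestKdEc50:
    def test_kd_of_best_fit(self, best_fit):
        assert tf.kd(best_fit) * 1e6 == pytest.approx(5.54, abs=5e-3)

    @pytest.mark.parametrize("k_a,expected", [(1.0, 1.0), (2e6, 5e-7)])
    def test_kd_reciprocal(self, best_fit, k_a, expected):
        params = tf.ThermoParams(**{**best_fit.to_dict(), "k_a": k_a})
        assert tf.kd(params) == pytest.approx(expected, rel=1e-14)

    def test_ec50_closed_form_binomial(self):
        """For independent identical sites and equal conductances, half the
        plateau sits at x = 2^(1/4) - 1."""
        params = tf.ThermoParams(k_a=1e6, gamma=1, mu=1, nu=1, a=1, b=1, c=1, d=1)
        assert tf.ec50(params, WT) == pytest.approx(
            (2 ** 0.25 - 1) / 1e6, rel=1e-10
        )

    def test_ec50_best_fit_matches_bisection_oracle(self, best_fit):
        from _oracles import bisect_half_response

        value = tf.ec50(best_fit, WT)
        oracle = bisect_half_response(
            lambda c: tf.response(best_fit, WT, c), 0.5 * best_fit.d, 1e-9, 1e-2
        )
        assert value == pytest.approx(oracle, rel=1e-8)
        assert value == pytest.approx(9.000752667584051e-06, rel=1e-8)

    def test_ec50_observed_definition_available(self, best_fit):
        obs = tf.ec50(best_fit, WT, definition="observed", bracket=(1e-12, 1e-3))
        assert obs > 0

    def test_non_monotone_response_reports_all_crossings(self):
        # strong pair anti-cooperativity + conductive CF1 makes the response
        # overshoot, dip below half-plateau, then recover: 2 crossings
        params = tf.ThermoParams(k_a=1e6, gamma=1e-3, mu=1e-3, nu=1e9,
                                 a=0.9, b=0.01, c=0.01, d=0.3)
        with pytest.raises(ValueError, match="more than once"):
            tf.ec50(params, WT)
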