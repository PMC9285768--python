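"""Unit and property tests for diet mapping, feeding, and the ODEs."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from warmsize.communities import (
    diet_weights,
    functional_response,
    maturation_rate,
    net_production,
    rhs,
)
from warmsize.errors import ConfigError, InputError
from warmsize.scenarios import community_config


class TestDietWeights:
    def test_full_specialisation_at_p1(self):
        assert diet_weights("I", "CS", 1.0) == (1.0, 0.0)
        assert diet_weights("I", "CL", 1.0) == (0.0, 1.0)

    def test_identical_diets_at_p_half(self):
        assert diet_weights("I", "CS", 0.5) == diet_weights("I", "CL", 0.5)
        assert diet_weights("II", "J", 0.5) == (0.5, 0.5)

    def test_community3_middle_classes_identical_at_p0(self):
        assert diet_weights("III", "AS", 0.0) == diet_weights("III", "JL", 0.0)
        assert diet_weights("III", "AS", 0.0) == (0.5, 0.5)

    def test_community3_extreme_classes_are_specialists(self):
        for p in (0.0, 0.4, 1.0):
            assert diet_weights("III", "JS", p) == (1.0, 0.0)
            assert diet_weights("III", "AL", p) == (0.0, 1.0)

    def test_community3_swap_mapping_disjoint_at_p1(self):
        assert diet_weights("III", "AS", 1.0, mapping="swap") == (1.0, 0.0)
        assert diet_weights("III", "JL", 1.0, mapping="swap") == (0.0, 1.0)

    def test_out_of_range_preference_rejected(self):
        with pytest.raises(InputError):
            diet_weights("I", "CS", 0.4)
        with pytest.raises(InputError):
            diet_weights("III", "AS", 1.2)

    @given(p=st.floats(0.5, 1.0))
    def test_weights_sum_to_one_and_mirror(self, p):
        ws = diet_weights("I", "CS", p)
        wl = diet_weights("I", "CL", p)
        assert sum(ws) == pytest.approx(1.0)
        assert ws == wl[::-1]


class TestFunctionalResponse:
    def test_no_food_no_intake(self):
        total, split = functional_response((0.3, 0.7), 0.0, 0.0, 2.0, 40.0)
        assert total == 0.0 and split == (0.0, 0.0)

    def test_half_saturation_identity(self):
        total, _ = functional_response((1.0, 0.0), 40.0, 123.0, 2.0, 40.0)
        assert total == pytest.approx(1.0)     # Imax/2

    def test_even_split_at_equal_availability(self):
        total, split = functional_response((0.5, 0.5), 40.0, 40.0, 2.0, 40.0)
        assert total == pytest.approx(1.0)
        assert split[0] == pytest.approx(0.5)
        assert split[1] == pytest.approx(0.5)

    def test_nonpositive_half_saturation_rejected(self):
        with pytest.raises(InputError):
            functional_response((1, 0), 1.0, 1.0, 2.0, 0.0)

    @given(ws=st.floats(0, 1), rs=st.floats(0, 1e4), rl=st.floats(0, 1e4))
    def test_split_sums_to_total_below_imax(self, ws, rs, rl):
        imax, h = 2.0, 40.0
        total, split = functional_response((ws, 1 - ws), rs, rl, imax, h)
        assert total == pytest.approx(sum(split))
        assert 0 <= total < imax

    def test_independent_mode_saturates_per_resource(self):
        total, split = functional_response((0.5, 0.5), 1e9, 1e9, 2.0, 40.0,
                                           mode="independent")
        assert total == pytest.approx(2.0, rel=1e-6)


class TestNetProduction:
    def test_maintenance_ration_is_zero(self):
        assert net_production(0.6, 0.5, 0.3) == pytest.approx(0.0)

    def test_pure_starvation(self):
        assert net_production(0.6, 0.0, 0.2) == pytest.approx(-0.2)

    def test_arithmetic(self):
        assert net_production(0.6, 1.0, 0.2) == pytest.approx(0.4)


class TestMaturationRate:
    def test_starving_juveniles_do_not_mature(self):
        assert maturation_rate(-0.5, 0.01, 0.1) == 0.0
        assert maturation_rate(0.0, 0.01, 0.1) == 0.0

    def test_removable_singularity_limit(self):
        # L'Hopital limit mu / ln(1/z) at nu_J = mu_J
        assert maturation_rate(0.01, 0.01, 0.1) == pytest.approx(
            0.01 / math.log(10), rel=1e-9)

    def test_limit_approached_numerically_from_both_sides(self):
        target = 0.01 / math.log(10)
        for eps in (1e-4, 1e-6, 1e-8):
            # convergence to the removable-singularity limit is first order
            tol = max(5 * eps / 0.01, 1e-6)
            assert maturation_rate(0.01 + eps, 0.01, 0.1) == pytest.approx(
                target, rel=tol)
            assert maturation_rate(0.01 - eps, 0.01, 0.1) == pytest.approx(
                target, rel=tol)

    def test_high_food_limit(self):
        # mu/nu -> 0: gamma -> (nu - mu)/(1 - z)
        nu, mu, z = 5.0, 0.001, 0.1
        assert maturation_rate(nu, mu, z) == pytest.approx(
            (nu - mu) / (1 - z), rel=1e-3)

    def test_tiny_positive_production_gives_vanishing_rate(self):
        assert maturation_rate(1e-12, 0.01, 0.1) == 0.0

    def test_invalid_mass_ratio_rejected(self):
        with pytest.raises(InputError):
            maturation_rate(0.1, 0.01, 1.5)

    @given(nu=st.floats(-1, 5), mu=st.floats(0, 0.5), z=st.floats(0.01, 0.99))
    def test_nonnegative_everywhere(self, nu, mu, z):
        assert maturation_rate(nu, mu, z) >= 0.0


class TestRhs:
    def test_semichemostat_rest_point(self):
        cfg = community_config("I", 0.85, 25.0)
        from warmsize.thermal import resource_carrying_capacity
        th = cfg.params.thermal
        state = pd.Series({
            "RS": resource_carrying_capacity("RS", 25.0, th),
            "RL": resource_carrying_capacity("RL", 25.0, th),
            "CS": 0.0, "CL": 0.0})
        assert np.allclose(rhs(state, cfg), 0.0, atol=1e-12)

    def test_supply_only_limit(self):
        cfg = community_config("I", 0.85, 25.0)
        from warmsize.thermal import resource_carrying_capacity
        th = cfg.params.thermal
        state = pd.Series({"RS": 0.0, "RL": 10.0, "CS": 0.0, "CL": 0.0})
        d = rhs(state, cfg)
        assert d.RS == pytest.approx(
            cfg.params.delta * resource_carrying_capacity("RS", 25.0, th))

    def test_absent_unstructured_consumer_stays_absent(self):
        cfg = community_config("I", 0.85, 25.0)
        state = pd.Series({"RS": 50.0, "RL": 50.0, "CS": 0.0, "CL": 5.0})
        assert rhs(state, cfg).CS == 0.0

    def test_specialist_leaves_other_resource_untouched(self):
        cfg = community_config("I", 1.0, 25.0)
        from warmsize.thermal import resource_carrying_capacity
        th = cfg.params.thermal
        rl_max = resource_carrying_capacity("RL", 25.0, th)
        state = pd.Series({"RS": 30.0, "RL": rl_max, "CS": 10.0, "CL": 0.0})
        # CS has weight (1, 0): RL stays at its consumer-free rest point
        assert rhs(state, cfg).RL == pytest.approx(0.0, abs=1e-12)

    def test_negative_state_rejected(self):
        cfg = community_config("I", 0.85, 25.0)
        with pytest.raises(InputError):
            rhs(pd.Series({"RS": -1.0, "RL": 0.0, "CS": 0.0, "CL": 0.0}), cfg)

    def test_mislabelled_state_rejected(self):
        cfg = community_config("I", 0.85, 25.0)
        with pytest.raises(InputError):
            rhs(pd.Series({"RS": 1.0, "RL": 1.0, "CS": 1.0, "XX": 1.0}), cfg)

    @given(data=st.tuples(*[st.floats(0, 500)] * 4))
    def test_biomass_conservation_closed_system(self, data):
        # mu = m = 0, beta = 1, delta -> 0: rhs conserves total biomass
        cfg = community_config(
            "II", 0.85, 25.0,
            overrides={"mortality": 0.0, "metab_coeff": 0.0,
                       "conversion_efficiency": 1.0, "delta": 0.0})
        d = rhs(np.asarray(data, dtype=float), cfg)
        total = float(d.sum())
        scale = max(float(np.max(np.abs(d))), 1.0)
        assert abs(total) < 1e-12 * scale

    @given(data=st.tuples(*[st.floats(0, 500)] * 4))
    def test_stage_fluxes_cancel_within_species(self, data):
        # maturation and reproduction only move biomass between J and A:
        # d(J+A)/dt must equal nu_J J + nu_A A - mu_J J - mu_A A
        cfg = community_config("II", 0.85, 25.0)
        y = np.asarray(data, dtype=float)
        d = rhs(y, cfg)
        dyn = __import__("warmsize.communities", fromlist=["dynamics_for"]
                         ).dynamics_for(cfg)
        total_intake, _ = dyn.intake(y[0], y[1])
        nu = dyn.beta * total_intake - dyn.metab
        expected = (nu[0] - dyn.mort[0]) * y[2] + (nu[1] - dyn.mort[1]) * y[3]
        scale = max(abs(expected), 1.0)
        assert d.J + d.A == pytest.approx(expected, abs=1e-10 * scale)

    def test_symmetry_of_neutral_pair(self):
        # identical masses, mirrored diets, no interactions: swapping
        # (CS, RS) with (CL, RL) maps rhs onto itself
        cfg = community_config("I", 0.8, 27.0,
                               flags=__import__("warmsize.scenarios",
                                                fromlist=["NO_INTERACTION"]
                                                ).NO_INTERACTION,
                               overrides={"mass:CS": 10.0})
        y = np.array([30.0, 70.0, 12.0, 5.0])
        swapped = np.array([70.0, 30.0, 5.0, 12.0])
        d1 = rhs(y, cfg).to_numpy()
        d2 = rhs(swapped, cfg).to_numpy()
        assert np.allclose(d1, d2[[1, 0, 3, 2]], rtol=1e-12, atol=1e-12)


class TestConfigValidation:
    def test_out_of_range_p_rejected(self):
        with pytest.raises((ConfigError, InputError)):
            community_config("I", 0.4, 20.0)

    def test_unknown_override_rejected(self):
        with pytest.raises(ConfigError):
            community_config("I", 0.85, 20.0, overrides={"nonsense": 1.0})

    def test_juvenile_must_be_smaller_than_adult(self):
        with pytest.raises(ConfigError):
            community_config("II", 0.85, 20.0, overrides={"mass:J": 20.0})
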