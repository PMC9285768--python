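"""Equilibrium engine: oracle equivalence, stability, multistart."""

import numpy as np
import pandas as pd
import pytest

from warmsize.communities import dynamics_for, rhs
from warmsize.equilibrium import (
    analytic_equilibrium_1c1r,
    extinction_threshold,
    find_equilibrium,
    multistart_equilibria,
    stability_check,
)
from warmsize.scenarios import community_config, initial_states


def _random_overrides(rng):
    return {
        "imax_coeff": rng.uniform(1.5, 4.0),
        "metab_coeff": rng.uniform(0.02, 0.08),
        "half_saturation": rng.uniform(20.0, 80.0),
        "conversion_efficiency": rng.uniform(0.4, 0.8),
        "delta": rng.uniform(0.05, 0.3),
        "mortality": rng.uniform(0.0, 0.03),
    }


class TestSemichemostat:
    def test_resources_equilibrate_at_carrying_capacity(self):
        cfg = community_config("I", 0.85, 25.0)
        eq = find_equilibrium(cfg, initial_states(cfg, "resource-only"))
        from warmsize.thermal import resource_carrying_capacity
        th = cfg.params.thermal
        assert eq.converged
        # consumers could invade at 25 C, so this boundary state is not
        # a community attractor and must be flagged unstable
        assert eq.stable is False
        assert eq.state.RS == pytest.approx(
            resource_carrying_capacity("RS", 25.0, th), rel=1e-8)
        assert eq.state.CS == 0.0 and eq.state.CL == 0.0
        # beyond both thermal limits the same state is the attractor
        hot = community_config("I", 0.85, 44.0)
        eq_hot = find_equilibrium(hot, initial_states(hot, "resource-only"))
        assert eq_hot.stable is True

    def test_resource_only_eigenvalues_are_minus_delta(self):
        cfg = community_config("I", 0.85, 25.0)
        eq = find_equilibrium(cfg, initial_states(cfg, "resource-only"))
        dyn = dynamics_for(cfg)
        jac = dyn.jacobian(eq.state.to_numpy(), active=np.array([0, 1]))
        eig = np.sort(np.linalg.eigvals(jac).real)
        assert np.allclose(eig, -cfg.params.delta, rtol=1e-4)


class TestOracle1C1R:
    def test_closed_form_zeroes_the_reduced_rhs_at_general_p(self):
        # substitute (R*, C*) back into the one-consumer-one-resource
        # subsystem: machine-precision balance for arbitrary p
        rng = np.random.default_rng(11)
        for _ in range(20):
            p = rng.uniform(0.55, 1.0)
            t = rng.uniform(5.0, 32.0)
            cfg = community_config("I", p, t,
                                   overrides=_random_overrides(rng))
            r_star, c_star, viable = analytic_equilibrium_1c1r(
                cfg.params, p, t)
            if not viable:
                continue
            state = pd.Series({"RS": r_star, "RL": 0.0,
                               "CS": c_star, "CL": 0.0})
            d = rhs(state, cfg)
            scale = max(c_star, r_star)
            assert abs(d.RS) < 1e-10 * scale
            assert abs(d.CS) < 1e-10 * scale

    def test_numerical_equilibrium_matches_closed_form(self):
        # p = 1 decouples Community I into two genuine 1C1R pairs
        rng = np.random.default_rng(3)
        checked = 0
        for _ in range(15):
            t = rng.uniform(5.0, 30.0)
            ovr = _random_overrides(rng)
            cfg = community_config("I", 1.0, t, overrides=ovr)
            eq = find_equilibrium(cfg, check_stability=False)
            for resource, consumer, mass in (("RS", "CS", 1.0),
                                             ("RL", "CL", 10.0)):
                r_star, c_star, viable = analytic_equilibrium_1c1r(
                    cfg.params, 1.0, t, mass=mass, resource=resource)
                if not viable or c_star < 1e-3:
                    continue
                assert eq.state[resource] == pytest.approx(r_star, rel=1e-6)
                assert eq.state[consumer] == pytest.approx(c_star, rel=1e-6)
                checked += 1
        assert checked >= 10

    def test_invasion_threshold_returns_consumer_free_branch(self):
        cfg = community_config("I", 1.0, 20.0,
                               overrides={"imax_coeff": 0.09})
        r_star, c_star, viable = analytic_equilibrium_1c1r(cfg.params, 1.0,
                                                           20.0)
        assert not viable and c_star == 0.0
        assert r_star == pytest.approx(
            cfg.params.thermal.rmax_ref)


class TestFindEquilibrium:
    def test_idempotent_on_returned_state(self):
        cfg = community_config("II", 0.85, 26.0)
        eq = find_equilibrium(cfg)
        again = find_equilibrium(cfg, eq.state)
        assert np.allclose(again.state.to_numpy(), eq.state.to_numpy(),
                           rtol=1e-6, atol=1e-9)

    def test_residual_below_tolerance(self):
        cfg = community_config("I", 0.85, 18.0)
        eq = find_equilibrium(cfg)
        scale = float(eq.state.max())
        assert eq.residual < 1e-8 * scale

    def test_hot_temperature_drives_both_consumers_extinct(self):
        for p in (0.6, 0.9):
            cfg = community_config("I", p, 45.0)
            eq = find_equilibrium(cfg)
            assert eq.persistent == ()

    def test_extinction_truncation_is_consistent(self):
        cfg = community_config("I", 0.85, 36.0)   # CL extinct here
        eq = find_equilibrium(cfg)
        assert "CL" not in eq.persistent
        truncated = eq.state.copy()
        truncated["CL"] = 0.0
        again = find_equilibrium(cfg, truncated)
        assert again.persistent == eq.persistent

    def test_deterministic_given_config(self):
        cfg = community_config("II", 0.9, 24.0)
        a = find_equilibrium(cfg).state.to_numpy()
        b = find_equilibrium(cfg).state.to_numpy()
        assert np.array_equal(a, b)


class TestStability:
    def test_interior_equilibria_on_default_grids_are_stable(self):
        for kind, p, t in (("I", 0.85, 12.0), ("I", 0.7, 28.0),
                           ("II", 0.85, 30.0), ("III", 0.7, 18.0)):
            cfg = community_config(kind, p, t)
            eq = find_equilibrium(cfg)
            assert eq.stable is True

    def test_1c1r_equilibrium_is_stable(self):
        cfg = community_config("I", 1.0, 20.0)
        eq = find_equilibrium(cfg)
        assert stability_check(cfg, eq.state) is True


class TestMultistart:
    def test_unique_state_for_unstructured_community(self):
        cfg = community_config("I", 0.85, 20.0)
        states = multistart_equilibria(cfg, seed=5, n_random=6)
        assert len(states) == 1

    def test_alternative_states_high_p_warm(self):
        cfg = community_config("II", 0.95, 28.0)
        states = multistart_equilibria(cfg, seed=5, n_random=6)
        assert len(states) == 2
        doms = set()
        for eq in states:
            doms.add("adult" if eq.state.A > eq.state.J else "juvenile")
        assert doms == {"adult", "juvenile"}

    def test_bistability_lost_at_high_mortality(self):
        cfg = community_config("II", 0.95, 28.0,
                               overrides={"mortality": 0.05})
        states = multistart_equilibria(cfg, seed=5, n_random=6)
        assert len(states) == 1

    def test_seeded_runs_are_reproducible(self):
        cfg = community_config("II", 0.95, 28.0)
        a = multistart_equilibria(cfg, seed=9, n_random=4)
        b = multistart_equilibria(cfg, seed=9, n_random=4)
        assert len(a) == len(b)
        for x, y in zip(a, b):
            assert np.array_equal(x.state.to_numpy(), y.state.to_numpy())


class TestInitialStates:
    def test_resource_only_has_no_consumers(self):
        cfg = community_config("III", 0.5, 20.0)
        y = initial_states(cfg, "resource-only")
        assert np.all(y[2:] == 0.0)

    def test_juvenile_heavy_ratio(self):
        cfg = community_config("II", 0.85, 20.0)
        y = initial_states(cfg, "juvenile-heavy")
        assert y[2] / y[3] == pytest.approx(100.0)

    def test_random_states_reproducible_and_bounded(self):
        cfg = community_config("II", 0.85, 20.0)
        a = initial_states(cfg, "random", seed=4)
        b = initial_states(cfg, "random", seed=4)
        assert np.array_equal(a, b)
        eps = extinction_threshold(cfg)
        assert np.all(a[2:] >= eps)
        assert np.all(a[2:] <= 10 * cfg.params.thermal.rmax_ref)

    def test_unknown_variant_rejected(self):
        cfg = community_config("I", 0.85, 20.0)
        with pytest.raises(Exception):
            initial_states(cfg, "bogus")
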