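"""Equilibrium solver: closed forms, oracle agreement, conservation laws."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fxarev import (
    NO_BINDING,
    EquilibriumSystem,
    oracle_solve,
    solve_species_equilibrium,
    unbound_inhibitor_fraction,
)

S100 = dict(S_total=100.0, Km=82.2)


def assert_states_close(a, b, rtol=1e-6, atol=1e-12):
    for name in ("E_free", "EI", "ES", "I_free", "AI", "A_free"):
        va, vb = getattr(a, name), getattr(b, name)
        assert va == pytest.approx(vb, rel=rtol, abs=atol), name


class TestClosedForms:
    def test_michaelis_partition_without_inhibitor(self):
        state = solve_species_equilibrium(
            EquilibriumSystem(E_total=1.0, I_total=0.0, A_total=0.0, **S100)
        )
        e_free = 1.0 / (1.0 + 100.0 / 82.2)
        assert state.E_free == pytest.approx(e_free, rel=1e-12)
        assert state.ES == pytest.approx(1.0 - e_free, rel=1e-12)
        assert state.EI == state.AI == state.I_free == state.A_free == 0.0
        assert state.converged

    def test_empty_system_is_all_zero(self):
        state = solve_species_equilibrium(
            EquilibriumSystem(E_total=0.0, I_total=0.0, A_total=0.0, S_total=0.0)
        )
        assert state.converged
        for name in ("E_free", "EI", "ES", "I_free", "AI", "A_free"):
            assert getattr(state, name) == 0.0

    def test_two_species_quadratic_matches_enzyme_free_solver(self):
        frac = unbound_inhibitor_fraction(5.0, 50.0, 0.98)
        state = solve_species_equilibrium(
            EquilibriumSystem(E_total=0.0, I_total=5.0, A_total=50.0, Ki=NO_BINDING,
                              Kd=0.98, **S100)
        )
        assert frac == pytest.approx(state.I_free / 5.0, rel=1e-9)
        oracle = oracle_solve(
            EquilibriumSystem(E_total=0.0, I_total=5.0, A_total=50.0, Kd=0.98, **S100)
        )
        assert frac == pytest.approx(oracle.I_free / 5.0, rel=1e-6)

    @pytest.mark.parametrize(
        "i_total,a_total,kd,expected",
        [(5.0, 0.0, 0.98, 1.0), (0.0, 50.0, 0.98, 1.0), (5.0, 5.0, 1e-12, 0.0)],
    )
    def test_unbound_fraction_limits(self, i_total, a_total, kd, expected):
        assert unbound_inhibitor_fraction(i_total, a_total, kd) == pytest.approx(
            expected, abs=1e-5
        )


class TestOracleAgreement:
    def test_tight_binding_reference_system(self):
        system = EquilibriumSystem(
            E_total=3.0, I_total=5.0, A_total=50.0, Ki=0.122, Kd=0.98, **S100
        )
        fast = solve_species_equilibrium(system)
        slow = oracle_solve(system)
        assert fast.converged and slow.converged
        assert_states_close(fast, slow)

    def test_oracle_requires_dense_grid(self):
        system = EquilibriumSystem(E_total=1.0, I_total=1.0, A_total=0.0, Ki=1.0, **S100)
        with pytest.raises(ValueError):
            oracle_solve(system, grid_points=100)

    def test_oracle_with_no_inhibitor(self):
        state = oracle_solve(
            EquilibriumSystem(E_total=1.0, I_total=0.0, A_total=10.0, Kd=1.0, **S100)
        )
        assert state.I_free == state.EI == state.AI == 0.0
        assert state.A_free == 10.0


class TestValidation:
    @pytest.mark.parametrize("field,value", [
        ("E_total", -1.0), ("I_total", -0.5), ("Km", 0.0), ("Ki", -2.0), ("Kd", 0.0),
    ])
    def test_invalid_inputs_rejected(self, field, value):
        kwargs = dict(E_total=1.0, I_total=1.0, A_total=0.0, S_total=100.0,
                      Km=82.2, Ki=1.0, Kd=1.0)
        kwargs[field] = value
        with pytest.raises(ValueError):
            EquilibriumSystem(**kwargs)

    def test_unbound_fraction_validation(self):
        with pytest.raises(ValueError):
            unbound_inhibitor_fraction(-1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            unbound_inhibitor_fraction(1.0, 1.0, 0.0)


concentration = st.floats(min_value=0.0, max_value=1e3)
constant = st.floats(min_value=1e-3, max_value=1e3)


class TestProperties:
    @given(e=concentration, i=concentration, a=concentration, ki=constant, kd=constant)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_conservation_and_equilibrium_relations(self, e, i, a, ki, kd):
        system = EquilibriumSystem(E_total=e, I_total=i, A_total=a, Ki=ki, Kd=kd, **S100)
        s = solve_species_equilibrium(system)
        assert s.converged
        assert s.residual_norm <= 1e-9
        for value in (s.E_free, s.EI, s.ES, s.I_free, s.AI, s.A_free):
            assert value >= 0.0
        # Mass balances, relative 1e-9
        assert s.E_free + s.ES + s.EI == pytest.approx(e, rel=1e-9, abs=1e-9)
        assert s.I_free + s.EI + s.AI == pytest.approx(i, rel=1e-9, abs=1e-9)
        assert s.A_free + s.AI == pytest.approx(a, rel=1e-9, abs=1e-9)
        # Equilibrium relations wherever the complex is formed
        if s.EI > 1e-12:
            assert s.E_free * s.I_free / s.EI == pytest.approx(ki, rel=1e-6)
        if s.AI > 1e-12:
            assert s.A_free * s.I_free / s.AI == pytest.approx(kd, rel=1e-6)
        if s.ES > 1e-12:
            assert s.E_free * 100.0 / s.ES == pytest.approx(82.2, rel=1e-6)

    @given(i=st.floats(min_value=0.0, max_value=20.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_es_nonincreasing_in_inhibitor(self, i):
        base = dict(E_total=1.0, A_total=0.0, Ki=0.2, Kd=NO_BINDING, **S100)
        es_lo = solve_species_equilibrium(EquilibriumSystem(I_total=i, **base)).ES
        es_hi = solve_species_equilibrium(EquilibriumSystem(I_total=i + 1.0, **base)).ES
        assert es_hi <= es_lo + 1e-12

    @given(a=st.floats(min_value=0.0, max_value=500.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_es_nondecreasing_in_decoy(self, a):
        base = dict(E_total=1.0, I_total=5.0, Ki=0.2, Kd=1.0, **S100)
        es_lo = solve_species_equilibrium(EquilibriumSystem(A_total=a, **base)).ES
        es_hi = solve_species_equilibrium(EquilibriumSystem(A_total=a + 10.0, **base)).ES
        assert es_hi >= es_lo - 1e-12

    def test_weak_binding_matches_classical_competitive_formula(self):
        e, i, ki = 0.01, 50.0, 200.0  # Ki >= 1e4 * E_total
        state = solve_species_equilibrium(
            EquilibriumSystem(E_total=e, I_total=i, A_total=0.0, Ki=ki, **S100)
        )
        classical = e * 100.0 / (100.0 + 82.2 * (1.0 + state.I_free / ki))
        assert state.ES == pytest.approx(classical, rel=1e-3)

    def test_saturating_decoy_restores_uninhibited_rate(self):
        base = dict(E_total=1.0, Ki=0.1, Kd=0.98, **S100)
        uninhibited = solve_species_equilibrium(
            EquilibriumSystem(I_total=0.0, A_total=0.0, **base)
        ).ES
        saturated = solve_species_equilibrium(
            EquilibriumSystem(I_total=5.0, A_total=5e6, **base)
        ).ES
        assert saturated == pytest.approx(uninhibited, rel=1e-3)
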