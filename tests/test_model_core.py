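import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crossfeed.model_core import (
    Capabilities,
    ConsortiumModel,
    DomainError,
    InteractionMatrix,
    PARAM_SLOTS,
    ParameterError,
    QpcrCalibration,
    SpeciesParams,
    Trajectory,
    biomass_to_copies,
    build_rhs,
    interaction_multiplier,
    percent_abundance,
    qpcr_copies_per_ml,
    simulate,
    specific_growth_rate,
)
from crossfeed.reference import reference_model

from helpers import exact_monod_quarter, exact_qpcr, rk4_integrate


# ---------------------------------------------------------------------------
# SpeciesParams
# ---------------------------------------------------------------------------

class TestSpeciesParams:
    def test_seventeen_slots(self):
        assert len(PARAM_SLOTS) == 17

    def test_vector_round_trip(self, ref_species):
        p = ref_species["Ec"]
        vec = p.to_vector()
        assert vec.shape == (17,)
        q = SpeciesParams.from_vector("Ec", vec, p.capabilities)
        assert q == p

    def test_dict_round_trip(self, ref_species):
        p = ref_species["Bi"]
        assert SpeciesParams.from_dict(p.to_dict()) == p

    @pytest.mark.parametrize("kwargs", [
        {"mu_max": -0.1},
        {"K_s": 0.0},
        {"Y_sx": 0.0},
        {"Y_sx": 1.5},
        {"I_a": -1.0},
        {"t_lag": -2.0},
        {"K_rep": 0.0},
    ])
    def test_invariant_violations_raise(self, kwargs):
        base = dict(name="X", mu_max=0.5, K_s=0.1, Y_sx=0.2)
        base.update(kwargs)
        with pytest.raises(ParameterError):
            SpeciesParams(**base)

    def test_yield_sum_capped(self):
        with pytest.raises(ParameterError):
            SpeciesParams(name="X", mu_max=0.5, K_s=0.1, Y_sx=0.2,
                          Y_a=0.7, Y_l=0.5,
                          capabilities=Capabilities(produces_acetate=True,
                                                    produces_lactate=True))

    def test_capability_flags_force_zero(self):
        p = SpeciesParams(name="X", mu_max=0.5, K_s=0.1, Y_sx=0.2,
                          Y_a=0.3, Y_l=0.2, mu_maxA=0.1, Y_sxA=0.2)
        assert p.Y_a == 0.0 and p.Y_l == 0.0
        assert p.mu_maxA == 0.0 and p.Y_sxA == 0.0

    def test_consumer_needs_positive_yield(self):
        with pytest.raises(ParameterError):
            SpeciesParams(name="X", mu_max=0.5, K_s=0.1, Y_sx=0.2,
                          mu_maxA=0.1, Y_sxA=0.0,
                          capabilities=Capabilities(consumes_acetate=True))


# ---------------------------------------------------------------------------
# growth laws
# ---------------------------------------------------------------------------

class TestSpecificGrowthRate:
    def setup_method(self):
        self.p = SpeciesParams(
            name="X", mu_max=0.8, K_s=0.5, Y_sx=0.25, Y_a=0.3, Y_l=0.2,
            I_a=4.0, I_l=3.0, t_lag=2.0,
            capabilities=Capabilities(produces_acetate=True, produces_lactate=True))

    def test_no_substrate_no_growth(self):
        assert specific_growth_rate(self.p, 0.0, 1.0, 1.0, 10.0) == 0.0

    def test_half_saturation_identity(self):
        mu = specific_growth_rate(self.p, self.p.K_s, 0.0, 0.0, 10.0)
        assert mu == pytest.approx(self.p.mu_max / 2, rel=1e-12)

    def test_lag_phase_is_input(self):
        assert specific_growth_rate(self.p, 10.0, 0.0, 0.0, 1.9) == 0.0
        assert specific_growth_rate(self.p, 10.0, 0.0, 0.0, 2.0) > 0.0

    def test_quarter_rate_at_both_inhibition_constants(self):
        # closed form checked against exact rational arithmetic
        S = 1e9
        mu = specific_growth_rate(self.p, S, self.p.I_a, self.p.I_l, 10.0)
        expected = exact_monod_quarter(self.p.mu_max, S, self.p.K_s)
        assert mu == pytest.approx(expected, rel=1e-12)

    def test_negative_concentration_rejected(self):
        with pytest.raises(DomainError):
            specific_growth_rate(self.p, -1.0, 0.0, 0.0, 5.0)

    def test_zero_ef_rejected(self):
        with pytest.raises(ParameterError):
            specific_growth_rate(self.p, 10.0, 0.0, 0.0, 5.0, [(0.0, 0.5)])

    @settings(max_examples=50, deadline=None)
    @given(S=st.floats(0, 50), A=st.floats(0, 20), L=st.floats(0, 20),
           dA=st.floats(0, 5), dS=st.floats(0, 5))
    def test_monotonicity_properties(self, S, A, L, dA, dS):
        mu = specific_growth_rate(self.p, S, A, L, 10.0)
        assert mu >= 0.0
        assert specific_growth_rate(self.p, S, A + dA, L, 10.0) <= mu + 1e-15
        assert specific_growth_rate(self.p, S, A, L + dA, 10.0) <= mu + 1e-15
        assert specific_growth_rate(self.p, S + dS, A, L, 10.0) >= mu - 1e-15


class TestInteractionMultiplier:
    def test_absent_neighbor_is_neutral(self):
        assert interaction_multiplier(0.16, 0.0) == 1.0

    def test_near_limit_is_near_null(self):
        # reported no-effect magnitude: 99.99
        expected = 1.0 - 0.5 / 99.99
        assert interaction_multiplier(99.99, 0.5) == pytest.approx(expected, rel=1e-12)
        assert interaction_multiplier(99.99, 0.5) > 0.99

    def test_small_positive_ef_arrests_growth(self):
        # reported strong inhibition magnitude: 0.16
        assert interaction_multiplier(0.16, 0.5) == 0.0

    def test_negative_ef_promotes(self):
        assert interaction_multiplier(-40.52, 0.5) > 1.0

    def test_promotion_clamped(self):
        assert interaction_multiplier(-0.02, 10.0) == 2.0

    def test_zero_ef_rejected(self):
        with pytest.raises(ParameterError):
            interaction_multiplier(0.0, 0.5)

    def test_negative_biomass_rejected(self):
        with pytest.raises(DomainError):
            interaction_multiplier(1.0, -0.5)


class TestInteractionMatrix:
    def test_diagonal_is_nan(self, ref_interactions):
        assert np.all(np.isnan(np.diag(ref_interactions.ef)))

    def test_zero_entry_rejected(self):
        with pytest.raises(ParameterError):
            InteractionMatrix(["a", "b"], [[np.nan, 0.0], [1.0, np.nan]])

    def test_above_limit_rejected(self):
        with pytest.raises(ParameterError):
            InteractionMatrix(["a", "b"], [[np.nan, 101.0], [1.0, np.nan]])

    def test_orientation(self, ref_interactions):
        # strong inhibition from Ec onto Bv sits at row Bv, column Ec
        assert ref_interactions.get("Bv", "Ec") == pytest.approx(0.16)
        assert ref_interactions.get("Ec", "Bv") == pytest.approx(-57.14)

    def test_submatrix_and_round_trip(self, ref_interactions):
        sub = ref_interactions.submatrix(("Bv", "Ec"))
        assert sub.get("Bv", "Ec") == pytest.approx(0.16)
        assert InteractionMatrix.from_dict(sub.to_dict()) == sub


# ---------------------------------------------------------------------------
# ODE assembly and simulation
# ---------------------------------------------------------------------------

class TestBuildRhs:
    @pytest.mark.parametrize("members,dim", [
        (("Bi",), 5),          # mono model: 5 state equations
        (("Bi", "Ec"), 7),     # paired model: 7 state equations
        (("Bi", "Bv", "Ec", "La"), 11),  # four-species model: 11 equations
    ])
    def test_state_dimension(self, members, dim):
        model = reference_model(members)
        assert model.state_dim == dim
        rhs = build_rhs(model)
        d = rhs(0.0, model.initial_state())
        assert d.shape == (dim,)

    def test_zero_biomass_species_is_inert(self, ref_species):
        model = reference_model(("Bi", "Ec"), inoculum={"Ec": 0.0})
        rhs = build_rhs(model)
        d = rhs(5.0, model.initial_state())
        assert d[5] == 0.0 and d[6] == 0.0  # X_Ec, Xm_Ec

    def test_pluggable_growth_law(self, bi_mono_model):
        rhs = build_rhs(bi_mono_model, growth_law=lambda *a, **k: 0.0)
        d = rhs(10.0, bi_mono_model.initial_state())
        # growth silenced: pools untouched, only intrinsic decay remains
        kd = bi_mono_model.species[0].k_d
        assert np.allclose(d[:3], 0.0)
        assert d[3] == pytest.approx(-kd * 0.01)
        assert d[4] == 0.0


class TestSimulate:
    def test_no_biomass_no_dynamics(self, ref_species):
        model = reference_model(("Bi",), inoculum={"Bi": 0.0})
        traj = simulate(model, np.linspace(0, 24, 25))
        assert np.allclose(traj.S, model.S0)
        assert np.allclose(traj.A, 0.0)
        assert np.allclose(traj.L, 0.0)

    def test_grid_must_start_at_zero(self, bi_mono_model):
        with pytest.raises(DomainError):
            simulate(bi_mono_model, [1.0, 2.0])

    def test_mass_balance(self, simple_producer):
        # with death/maintenance/uptake off: Y*(S0-S) tracks each pool
        model = ConsortiumModel(species=(simple_producer,), S0=10.0, X0=(0.01,))
        traj = simulate(model, np.linspace(0, 48, 49), rtol=1e-10, atol=1e-12)
        dS = model.S0 - traj.S
        p = simple_producer
        mask = dS > 1e-3
        assert np.allclose((traj.X("P") - 0.01)[mask] / dS[mask], p.Y_sx, rtol=1e-5)
        assert np.allclose(traj.A[mask] / dS[mask], p.Y_a, rtol=1e-5)
        assert np.allclose(traj.L[mask] / dS[mask], p.Y_l, rtol=1e-5)

    def test_yield_identity_at_depletion(self, simple_producer):
        model = ConsortiumModel(species=(simple_producer,), S0=10.0, X0=(0.01,))
        traj = simulate(model, np.linspace(0, 72, 73))
        consumed = model.S0 - traj.S[-1]
        assert consumed == pytest.approx(10.0, rel=1e-3)
        assert traj.A[-1] / consumed == pytest.approx(simple_producer.Y_a, rel=1e-5)
        assert traj.L[-1] / consumed == pytest.approx(simple_producer.Y_l, rel=1e-5)

    def test_rk4_oracle_equivalence(self, pair_model):
        grid = np.linspace(0, 24, 25)
        ref = rk4_integrate(build_rhs(pair_model), pair_model.initial_state(),
                            24.0, 1e-3, grid)
        traj = simulate(pair_model, grid, rtol=1e-10, atol=1e-12)
        scale = np.maximum(np.abs(ref).max(axis=0), 1e-6)
        assert np.max(np.abs(traj.states - ref) / scale) < 1e-4

    def test_pair_reduces_to_mono(self):
        mono = reference_model(("Bi",))
        pair = reference_model(("Bi", "Ec"), inoculum={"Ec": 0.0})
        grid = np.linspace(0, 48, 49)
        t1 = simulate(mono, grid, rtol=1e-11, atol=1e-13)
        t2 = simulate(pair, grid, rtol=1e-11, atol=1e-13)
        assert np.max(np.abs(t1.states - t2.states[:, :5])) < 1e-8

    def test_four_species_reduces_to_mono(self):
        mono = reference_model(("Bi",))
        full = reference_model(inoculum={"Bv": 0.0, "Ec": 0.0, "La": 0.0})
        grid = np.linspace(0, 48, 25)
        t1 = simulate(mono, grid, rtol=1e-11, atol=1e-13)
        t2 = simulate(full, grid, rtol=1e-11, atol=1e-13)
        assert np.max(np.abs(t1.states - t2.states[:, :5])) < 1e-8

    def test_permutation_invariance(self):
        grid = np.linspace(0, 48, 49)
        ta = simulate(reference_model(("Bi", "Ec", "La", "Bv")), grid)
        tb = simulate(reference_model(("Bv", "La", "Ec", "Bi")), grid)
        for name in ("Bi", "Bv", "Ec", "La"):
            assert np.allclose(ta.Xm(name), tb.Xm(name), atol=1e-6)
        assert np.allclose(ta.S, tb.S, atol=1e-6)

    def test_monotonicity(self, full_model):
        traj = simulate(full_model, np.linspace(0, 72, 145))
        assert np.all(np.diff(traj.S) <= 1e-9)
        for name in full_model.names:
            assert np.all(np.diff(traj.Xm(name)) >= -1e-9)

    def test_states_nonnegative(self, full_model):
        traj = simulate(full_model, np.linspace(0, 72, 145))
        assert np.all(traj.states >= 0.0)

    def test_trajectory_frame_round_trip(self, pair_model):
        traj = simulate(pair_model, np.linspace(0, 24, 25))
        back = Trajectory.from_frame(traj.to_frame())
        assert back.species == traj.species
        assert np.allclose(back.states, traj.states)


# ---------------------------------------------------------------------------
# observation operators
# ---------------------------------------------------------------------------

class TestQpcr:
    cal = QpcrCalibration(genome_size=2.0e6, copies_16s=1)

    def test_zero_dna_zero_copies(self):
        assert qpcr_copies_per_ml(0.0, self.cal) == 0.0

    def test_linearity_in_copy_number(self):
        double = QpcrCalibration(genome_size=2.0e6, copies_16s=2)
        assert qpcr_copies_per_ml(1e-6, double) == pytest.approx(
            2 * qpcr_copies_per_ml(1e-6, self.cal), rel=1e-12)

    def test_worked_value(self):
        # independent exact-arithmetic oracle: ~4.562e8 copies/mL
        expected = exact_qpcr(1e-6, 2.0e6, 1)
        got = qpcr_copies_per_ml(1e-6, self.cal)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(4.562e8, rel=1e-3)

    def test_inverse_in_genome_size(self):
        big = QpcrCalibration(genome_size=4.0e6, copies_16s=1)
        assert qpcr_copies_per_ml(1e-6, big) == pytest.approx(
            qpcr_copies_per_ml(1e-6, self.cal) / 2, rel=1e-12)

    def test_invalid_calibration(self):
        with pytest.raises(ParameterError):
            QpcrCalibration(genome_size=0.0)

    def test_biomass_copies_round_trip(self):
        x = np.array([0.0, 0.5, 2.0])
        from crossfeed.model_core import copies_to_biomass
        assert np.allclose(copies_to_biomass(biomass_to_copies(x, self.cal), self.cal), x)


def _traj_from_xm(xm_by_species, times=None):
    names = tuple(xm_by_species)
    n = len(names)
    t = np.asarray(times if times is not None else np.arange(len(next(iter(xm_by_species.values()))), dtype=float))
    states = np.zeros((t.size, 3 + 2 * n))
    states[:, 0] = 10.0
    for i, name in enumerate(names):
        states[:, 4 + 2 * i] = xm_by_species[name]
    if t[0] == t[-1]:
        raise ValueError
    return Trajectory(times=t + (0 if t[0] == 0 else 0), states=states, species=names)


class TestPercentAbundance:
    cal = QpcrCalibration(genome_size=2e6, copies_16s=1, cells_per_gram=1e12)

    def test_single_species_is_100(self):
        traj = _traj_from_xm({"A": np.array([0.1, 0.2, 0.3])})
        pct = percent_abundance(traj, self.cal)
        assert np.allclose(pct["A"], 100.0)

    def test_equal_copies_split_evenly(self):
        traj = _traj_from_xm({"A": np.array([0.2, 0.4]), "B": np.array([0.2, 0.4])})
        pct = percent_abundance(traj, self.cal)
        assert np.allclose(pct[["A", "B"]], 50.0)

    def test_four_to_one_ratios(self):
        traj = _traj_from_xm({"a": np.array([0.4]* 2), "b": np.array([0.3] * 2),
                              "c": np.array([0.2] * 2), "d": np.array([0.1] * 2)})
        pct = percent_abundance(traj, self.cal)
        assert np.allclose(pct[["a", "b", "c", "d"]].iloc[0], [40, 30, 20, 10])

    def test_rows_sum_to_100(self, full_model, ref_calibrations):
        traj = simulate(full_model, np.linspace(0, 72, 73))
        pct = percent_abundance(traj, ref_calibrations)
        assert np.allclose(pct[list(full_model.names)].sum(axis=1), 100.0, atol=1e-9)

    def test_calibration_changes_shares(self):
        traj = _traj_from_xm({"A": np.array([0.2, 0.2]), "B": np.array([0.2, 0.2])})
        cals = {"A": QpcrCalibration(genome_size=2e6, cells_per_gram=3e12),
                "B": QpcrCalibration(genome_size=2e6, cells_per_gram=1e12)}
        pct = percent_abundance(traj, cals)
        assert np.allclose(pct["A"], 75.0)

    def test_all_zero_row_flagged_nan(self):
        traj = _traj_from_xm({"A": np.array([0.0, 0.5]), "B": np.array([0.0, 0.5])})
        pct = percent_abundance(traj, self.cal)
        assert pct[["A", "B"]].iloc[0].isna().all()
        assert np.allclose(pct[["A", "B"]].iloc[1], 50.0)
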