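"""Core engine: rate laws, RHS assembly, integration, crossings, moieties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coagsim.network import (
    ModelValidationError,
    NetworkModel,
    ParameterSet,
    RateLaw,
    RateTerm,
    ReactionDef,
    SimControls,
    SpeciesDef,
    Trajectory,
    assemble_rhs,
    conserved_moiety_residual,
    eval_rate,
    first_crossing_time,
    simulate,
    write_trajectory_csv,
)


def tiny_model(reversible=False, k=1.0):
    """A -> B (optionally reversible) with unit-ish rate constants."""
    species = [SpeciesDef("A", 1.0), SpeciesDef("B", 0.0)]
    params = {"kf": k, "kr": k}
    rxns = [
        ReactionDef(
            "fwd", (("A", 1),), (("B", 1),), RateLaw.mass_action(["kf"], ["A"])
        )
    ]
    if reversible:
        rxns.append(
            ReactionDef(
                "rev", (("B", 1),), (("A", 1),), RateLaw.mass_action(["kr"], ["B"])
            )
        )
    return NetworkModel(species, rxns, ParameterSet(params))


class TestEvalRate:
    def test_zero_factor_annihilates_term(self, model):
        r9 = model.reaction("R9")
        state = model.initial_state()
        state["Xa"] = 0.0
        assert eval_rate(r9.rate, state, model.parameters) == 0.0

    def test_second_order_monomial_arithmetic(self, model):
        # v = k16 * [Xa] * [II] for prothrombin activation by Xa
        r9 = model.reaction("R9")
        params = model.parameters.updated({"k16": 1e8})
        state = dict.fromkeys(model.species_names, 0.0)
        state.update({"Xa": 1e-9, "II": 1.4e-6})
        assert eval_rate(r9.rate, state, params) == pytest.approx(1.4e-7, rel=1e-12)

    def test_reversible_law_vanishes_at_equilibrium(self, model):
        # kf*(A*B - Ki*AB) = 0 when A*B = Ki*AB (inhibitor-binding pattern)
        from coagsim.drugs import DRUGS

        riva = DRUGS["rivaroxaban"]
        rbay1 = next(r for r in riva.reactions if r.id == "RBay1")
        params = ParameterSet(riva.constants)
        ki = riva.constants["kBay_Ki_Xa"]
        state = {"Bay59_7939": 2e-9, "Xa": ki / 2.0, "Bay59_7939_Xa": 1e-9}
        assert eval_rate(rbay1.rate, state, params) == pytest.approx(0.0, abs=1e-25)

    def test_unknown_symbol_is_named_in_error(self):
        law = RateLaw.mass_action(["k_missing"], ["A"])
        with pytest.raises(ModelValidationError, match="k_missing"):
            eval_rate(law, {"A": 1.0}, ParameterSet({}))


class TestAssembleRhs:
    def test_single_reaction_mass_action(self):
        deriv = assemble_rhs(tiny_model(k=2.0))
        d = deriv({"A": 0.5, "B": 0.0})
        assert d["A"] == pytest.approx(-1.0)
        assert d["B"] == pytest.approx(+1.0)

    def test_stoichiometric_conversion_of_prothrombin(self, model):
        # reaction R9 contributes -v to d[II]/dt and +v to d[IIa]/dt
        state = dict.fromkeys(model.species_names, 0.0)
        state.update({"Xa": 1e-9, "II": 1e-6, "Albumin_Factor": 1.0})
        v = eval_rate(model.reaction("R9").rate, state, model.parameters)
        d = assemble_rhs(model)(state)
        assert v > 0
        assert d["II"] == pytest.approx(-v, rel=1e-12)
        # IIa only produced (R9) and consumed by nothing at this state
        assert d["IIa"] == pytest.approx(+v, rel=1e-12)

    def test_rhs_matches_per_reaction_brute_force(self, model):
        """S @ v(c) equals an independent reaction-by-reaction accumulation."""
        rng = np.random.default_rng(42)
        deriv = assemble_rhs(model)
        names = model.species_names
        for _ in range(100):
            state = dict(zip(names, rng.uniform(0.0, 1e-6, len(names))))
            expected = dict.fromkeys(names, 0.0)
            for rxn in model.reactions:
                v = eval_rate(rxn.rate, state, model.parameters)
                for name, coeff in rxn.reactants:
                    expected[name] -= coeff * v
                for name, coeff in rxn.products:
                    expected[name] += coeff * v
            for s in model.species:  # pool species are frozen
                if s.constant:
                    expected[s.name] = 0.0
            got = deriv(state)
            scale = max(abs(x) for x in expected.values()) or 1.0
            for name in names:
                assert got[name] == pytest.approx(
                    expected[name], rel=1e-12, abs=1e-12 * scale
                )


class TestSimulate:
    def test_exponential_decay_closed_form(self):
        traj = simulate(tiny_model(k=1.0), 5.0)
        a, b = traj.dense(1.0)
        assert a == pytest.approx(math.exp(-1.0), rel=1e-6)
        assert b == pytest.approx(1.0 - math.exp(-1.0), rel=1e-6)

    def test_reversible_equilibrium_is_symmetric(self):
        traj = simulate(tiny_model(reversible=True, k=5.0), 20.0)
        assert traj["A"][-1] == pytest.approx(0.5, rel=1e-6)
        assert traj["B"][-1] == pytest.approx(0.5, rel=1e-6)

    def test_first_row_is_initial_condition(self, model):
        traj = simulate(model, 1.0)
        assert np.array_equal(traj.concentrations[0], model.initial_vector())

    def test_horizon_must_be_positive(self, model):
        with pytest.raises(ValueError):
            simulate(model, 0.0)

    def test_fibrin_is_monotone_in_pt_scenario(self, model):
        from coagsim.assays import run_pt

        traj = run_pt(model).trajectory
        ia = traj["Ia"]
        assert np.all(np.diff(ia) >= -1e-12 * ia.max())

    def test_no_species_below_negative_floor(self, model):
        from coagsim.assays import run_pt

        traj = run_pt(model).trajectory
        assert traj.concentrations.min() >= 0.0  # clipped output


class TestFirstCrossing:
    def test_linear_interpolation(self):
        traj = Trajectory(
            np.array([0.0, 200.0]), np.array([[0.0], [200e-9]]), ("c",)
        )
        assert first_crossing_time(traj, "c", 100e-9) == pytest.approx(100.0)

    def test_no_crossing_below_threshold(self):
        traj = Trajectory(
            np.array([0.0, 100.0]), np.array([[1e-9], [1e-9]]), ("c",)
        )
        assert first_crossing_time(traj, "c", 100e-9) is None

    def test_refinement_agrees_with_fine_reintegration(self, model):
        """Crossing from the coarse grid matches a 100x finer one to <0.5%."""
        from coagsim.assays import PT_ASSAY, _prepare

        _, initials = _prepare(model, PT_ASSAY, None, None)
        coarse = simulate(
            model, 120.0, controls=SimControls(n_points=40), initials=initials
        )
        fine = simulate(
            model, 120.0, controls=SimControls(n_points=4000), initials=initials
        )
        t_coarse = first_crossing_time(coarse, "Ia", 100e-9)
        t_fine = first_crossing_time(fine, "Ia", 100e-9)
        assert t_coarse == pytest.approx(t_fine, rel=5e-3)


PROTHROMBIN_MOIETY = {
    "II": 1, "Xa_Va_II_lipid": 1, "mIIa": 1, "IIa": 1,
    "IIa_Tm": 1, "mIIa_ATIII": 1, "IIa_ATIII": 1,
}


class TestConservedMoiety:
    def test_two_species_moiety_is_flat(self):
        m = tiny_model()
        traj = simulate(m, 5.0)
        assert conserved_moiety_residual(traj, {"A": 1, "B": 1}, m) < 1e-9

    def test_prothrombin_moiety_conserved_over_pt_run(self, model):
        from coagsim.assays import run_pt

        traj = run_pt(model).trajectory
        res = conserved_moiety_residual(traj, PROTHROMBIN_MOIETY, model)
        assert res < 1e-6 * (1.4e-6 / 3)

    def test_non_null_vector_weights_rejected(self, model):
        with pytest.raises(ModelValidationError):
            conserved_moiety_residual(
                simulate(model, 1.0), {"II": 1}, model
            )

    def test_open_system_rejects_transported_moiety(self, model):
        """Transport breaks closure: the open model must refuse the moiety."""
        from coagsim.flow import FlowConfig, open_system

        om = open_system(model, FlowConfig(alpha=1e4))
        traj = simulate(om, 1.0)
        with pytest.raises(ModelValidationError):
            conserved_moiety_residual(traj, PROTHROMBIN_MOIETY, om)


class TestValidation:
    def test_duplicate_species_rejected(self):
        with pytest.raises(ModelValidationError, match="duplicate"):
            NetworkModel(
                [SpeciesDef("A"), SpeciesDef("A")], [], ParameterSet({})
            )

    def test_stoichiometric_matrix_columns(self, model):
        j = [r.id for r in model.reactions].index("R9")
        col = model.stoichiometric_matrix[:, j]
        assert col[model.index["II"]] == -1
        assert col[model.index["IIa"]] == +1
        assert col[model.index["Xa"]] == 0  # catalyst: net zero

    def test_negative_initial_concentration_rejected(self):
        with pytest.raises(ModelValidationError):
            SpeciesDef("A", -1.0)


@settings(max_examples=25, deadline=None)
@given(
    xa=st.floats(0, 1e-6, allow_nan=False),
    ii=st.floats(0, 1e-5, allow_nan=False),
    k=st.floats(1e2, 1e9),
)
def test_mass_action_monomial_is_multiplicative(xa, ii, k):
    """The rate of a two-species monomial is exactly k*[A]*[B]."""
    law = RateLaw.mass_action(["k"], ["Xa", "II"])
    v = eval_rate(law, {"Xa": xa, "II": ii}, ParameterSet({"k": k}))
    assert v == pytest.approx(k * xa * ii, rel=1e-12, abs=0.0)


def test_trajectory_csv_roundtrip(tmp_path):
    m = tiny_model()
    traj = simulate(m, 1.0, controls=SimControls(n_points=5))
    path = tmp_path / "traj.csv"
    write_trajectory_csv(traj, str(path))
    lines = path.read_text().splitlines()
    assert lines[0] == "time_s,species,concentration_mol_per_l"
    assert len(lines) == 1 + len(traj.times) * 2
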