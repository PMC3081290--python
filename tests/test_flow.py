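"""Open-system transport, in-vivo scenarios and the alpha_crit bisection."""

import math

import numpy as np
import pytest

from coagsim.flow import (
    SCENARIOS,
    AlphaCritResult,
    ClotDecision,
    FlowConfig,
    NoClotAtRestError,
    TriggerScenario,
    alpha_crit,
    open_system,
    run_scenario,
)
from coagsim.network import (
    NetworkModel,
    ParameterSet,
    RateLaw,
    ReactionDef,
    SimControls,
    SpeciesDef,
    simulate,
)


class TestOpenSystem:
    def test_alpha_zero_matches_closed_model(self, model):
        """With no coupling the open system is the static model."""
        ini = model.initial_state()
        ini["TF"] = 4e-9
        closed = simulate(model, 60.0, initials=ini)
        om = open_system(model, FlowConfig(alpha=0.0))
        opened = simulate(om, 60.0, initials=ini)
        scale = closed.concentrations.max()
        assert np.allclose(
            closed.concentrations, opened.concentrations, atol=1e-9 * scale
        )

    def test_reaction_free_species_relax_exponentially(self):
        m = NetworkModel(
            [SpeciesDef("A", 0.0, mobile=True)], [], ParameterSet({})
        )
        alpha, d = 2.0e6, 5e-7  # alpha*D = 1/s
        om = open_system(m, FlowConfig(alpha, d, {"A": 1.0}))
        traj = simulate(om, 5.0)
        a = traj.dense(1.0)[0]
        assert a == pytest.approx(1.0 - math.exp(-1.0), rel=1e-6)

    def test_immobile_species_get_no_transport(self, model):
        om = open_system(model, FlowConfig(alpha=1e6))
        ids = {r.id for r in om.reactions}
        for name in ("TF", "TF_VIIa", "Ia"):
            assert f"T_{name}" not in ids
        assert "T_Xa" in ids and "T_II" in ids

    def test_transport_decay_toward_blood_is_monotone(self, model):
        """In a reaction-free open system the deviation from the pool decays."""
        species = [SpeciesDef(s.name, s.initial_concentration, s.mobile)
                   for s in model.species if not s.constant]
        bare = NetworkModel(species, [], ParameterSet({}))
        blood = {s.name: 1e-8 for s in species}
        om = open_system(bare, FlowConfig(2e6, blood_concentrations=blood))
        traj = simulate(om, 10.0)
        dev = np.abs(traj.concentrations - 1e-8).sum(axis=1)
        assert np.all(np.diff(dev) <= 1e-12)


class TestScenarios:
    def test_panel_matches_trigger_table(self):
        assert SCENARIOS["extrinsic_strong"].tf == 1e-11
        assert SCENARIOS["extrinsic_weak"].tf == 1e-14
        assert SCENARIOS["intrinsic_strong"].xiia == 1e-11
        assert SCENARIOS["intrinsic_weak"].xiia == 1e-14

    def test_exactly_one_trigger_enforced(self):
        with pytest.raises(ValueError):
            TriggerScenario("both", tf=1e-11, xiia=1e-11)
        with pytest.raises(ValueError):
            TriggerScenario("neither")

    def test_strong_extrinsic_clots_at_rest(self, model):
        out = run_scenario(model, SCENARIOS["extrinsic_strong"])
        assert out.clotted and out.clotting_time < 3600.0

    def test_unactivated_cascade_does_not_clot(self, model):
        """Zero trigger: no thrombin, no fibrin, no event."""
        decision = ClotDecision()
        traj = simulate(model, decision.horizon,
                        controls=SimControls(rtol=1e-6))
        assert traj["IIa"].max() < decision.iia_threshold
        assert traj["Ia"].max() < decision.ia_threshold

    def test_washout_never_converts_no_clot_into_clot(self, model):
        sc = SCENARIOS["extrinsic_strong"]
        clotted = [run_scenario(model, sc, alpha=a).clotted
                   for a in (0.0, 1e3, 1e5, 1e7)]
        # once suppression sets in it persists at higher alpha
        first_no = clotted.index(False) if False in clotted else len(clotted)
        assert all(not c for c in clotted[first_no:])


class TestAlphaCrit:
    def test_trigger_strength_orders_the_threshold(self, model):
        strong = alpha_crit(model, SCENARIOS["extrinsic_strong"], rel_tol=1e-2)
        weak = alpha_crit(model, SCENARIOS["extrinsic_weak"], rel_tol=1e-2)
        assert strong.value > weak.value

    def test_bracket_invariant_and_tolerance_contract(self, model):
        coarse = alpha_crit(model, SCENARIOS["extrinsic_strong"], rel_tol=4e-2)
        fine = alpha_crit(model, SCENARIOS["extrinsic_strong"], rel_tol=2e-2)
        lo, hi = coarse.bracket
        assert lo < coarse.value <= hi
        assert (hi - lo) / lo <= 4e-2
        # halving the tolerance moves the estimate by less than the coarse one
        assert abs(fine.value - coarse.value) / coarse.value < 4e-2

    def test_result_independent_of_starting_bracket(self, model):
        a = alpha_crit(model, SCENARIOS["extrinsic_strong"], rel_tol=1e-2,
                       bracket=(1e3, 1e9))
        b = alpha_crit(model, SCENARIOS["extrinsic_strong"], rel_tol=1e-2,
                       bracket=(1e2, 1e7))
        assert a.value == pytest.approx(b.value, rel=2e-2)

    def test_no_clot_at_rest_is_signalled(self, model):
        from coagsim.drugs import DrugState, mass_to_molar

        # heavy inhibition suppresses the weak trigger without any flow
        heavy = DrugState("rivaroxaban", mass_to_molar("rivaroxaban", 400.0))
        with pytest.raises(NoClotAtRestError):
            alpha_crit(model, SCENARIOS["extrinsic_weak"], drug=heavy,
                       rel_tol=1e-2)

    def test_anticoagulation_lowers_alpha_crit(self, model):
        from coagsim.drugs import DrugState, mass_to_molar

        sc = SCENARIOS["extrinsic_strong"]
        free = alpha_crit(model, sc, rel_tol=1e-2)
        trough = alpha_crit(
            model, sc, rel_tol=1e-2,
            drug=DrugState("rivaroxaban", mass_to_molar("rivaroxaban", 13.66)),
        )
        cmax = alpha_crit(
            model, sc, rel_tol=1e-2,
            drug=DrugState("rivaroxaban", mass_to_molar("rivaroxaban", 195.15)),
        )
        assert cmax.value <= trough.value <= free.value


class TestClotDecision:
    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            ClotDecision(iia_threshold=0.0)

    def test_flow_config_validation(self):
        with pytest.raises(ValueError):
            FlowConfig(alpha=-1.0)
        with pytest.raises(ValueError):
            FlowConfig(alpha=1.0, diffusion_constant=0.0)
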