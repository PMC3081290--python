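"""Flow-coupled open system and the critical washout threshold alpha_crit.

In vivo, the clotting region exchanges material with an effectively
infinite pool of fresh plasma.  Each mobile species j gains a linear
transport term

    dc_j/dt += alpha * D_j * (c_j,blood - c_j)

where alpha is a general coupling constant (blood flow strength and
vessel geometry) and D_j a diffusion-convection constant, identical for
all species (5e-7 cm^2/s).  Species bound to immobile tissue or to the
thrombus (tissue factor with all its complexes, and the fibrin product
Ia) are not transported.  With alpha = 0 the open system reduces
exactly to the static (closed) model.

alpha_crit is the lowest exchange rate that suppresses a coagulation
event for a given trigger scenario; it is found by bisection between a
clotting and a suppressing alpha.  Only relative orderings of
alpha_crit between therapies are interpreted, not its absolute value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .drugs import DrugState, WarfarinState, apply_warfarin, attach_drug
from .network import (
    NetworkModel,
    RateLaw,
    RateTerm,
    ReactionDef,
    SimControls,
    Trajectory,
    first_crossing_time,
    simulate,
)

__all__ = [
    "FlowConfig",
    "TriggerScenario",
    "SCENARIOS",
    "ClotDecision",
    "ClottingOutcome",
    "AlphaCritResult",
    "NoClotAtRestError",
    "BracketExpansionError",
    "open_system",
    "run_scenario",
    "alpha_crit",
]


class NoClotAtRestError(RuntimeError):
    """The scenario does not clot even without flow (alpha = 0)."""


class BracketExpansionError(RuntimeError):
    """No suppressing alpha found within the admissible bracket."""


@dataclass(frozen=True)
class FlowConfig:
    """Coupling to the infinite blood pool.

    ``alpha * diffusion_constant`` acts as a first-order exchange rate
    (1/s) with D in cm^2/s, so alpha carries 1/cm^2; alpha_crit values
    are reported in this consistent unit and only compared relatively.
    """

    alpha: float  # general coupling constant, 1/cm^2
    diffusion_constant: float = 5.0e-7  # cm^2/s, same for all species
    blood_concentrations: Mapping[str, float] | None = None  # default: initials

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.diffusion_constant <= 0:
            raise ValueError("diffusion constant must be positive")


@dataclass(frozen=True)
class TriggerScenario:
    """One physiologically plausible in-vivo trigger (exactly one non-zero)."""

    name: str
    tf: float = 0.0  # mol/l
    xiia: float = 0.0  # mol/l

    def __post_init__(self) -> None:
        if (self.tf > 0) == (self.xiia > 0):
            raise ValueError("exactly one of TF/XIIa must be non-zero")


#: the four-scenario panel: strong/weak extrinsic and intrinsic triggers
SCENARIOS: dict[str, TriggerScenario] = {
    "extrinsic_strong": TriggerScenario("extrinsic_strong", tf=1e-11),
    "extrinsic_weak": TriggerScenario("extrinsic_weak", tf=1e-14),
    "intrinsic_strong": TriggerScenario("intrinsic_strong", xiia=1e-11),
    "intrinsic_weak": TriggerScenario("intrinsic_weak", xiia=1e-14),
}


@dataclass(frozen=True)
class ClotDecision:
    """Two independent thresholds: thrombin-based and fibrin-based.

    A coagulation event occurs iff either threshold is crossed within
    the horizon.  The threshold magnitudes are configuration defaults
    (thrombin ~0.1% of prothrombin; fibrin reusing the PT criterion).
    """

    iia_threshold: float = 2.0e-9  # mol/l
    ia_threshold: float = 100e-9  # mol/l
    horizon: float = 3600.0  # s

    def __post_init__(self) -> None:
        if self.iia_threshold <= 0 or self.ia_threshold <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class ClottingOutcome:
    clotted: bool
    clotting_time: float | None  # earliest threshold crossing, s
    trajectory: Trajectory | None = None


@dataclass(frozen=True)
class AlphaCritResult:
    value: float
    bracket: tuple[float, float]  # (lo clots, hi suppresses)
    iterations: int
    scenario: str
    label: str = ""


def open_system(model: NetworkModel, flow: FlowConfig) -> NetworkModel:
    """Attach blood-pool transport reactions to every mobile species.

    The blood pool is an infinite reservoir held at the given
    concentrations (default: the model's own undiluted initial
    conditions, which include any attached drug).
    """
    blood = dict(flow.blood_concentrations
                 if flow.blood_concentrations is not None
                 else model.initial_state())
    extra_params: dict[str, float] = {
        "alpha": flow.alpha,
        "D_flow": flow.diffusion_constant,
    }
    transport: list[ReactionDef] = []
    for sp in model.species:
        if not sp.mobile or sp.constant:
            continue
        cb_sym = f"cblood_{sp.name}"
        extra_params[cb_sym] = float(blood.get(sp.name, 0.0))
        rate = RateLaw(
            (
                RateTerm(+1, ("alpha", "D_flow", cb_sym), ()),
                RateTerm(-1, ("alpha", "D_flow"), (sp.name,)),
            )
        )
        transport.append(
            ReactionDef(f"T_{sp.name}", (), ((sp.name, 1),), rate, group="transport")
        )
    params = model.parameters.updated(extra_params, provenance="external-constant")
    out = NetworkModel(model.species, tuple(model.reactions) + tuple(transport), params)
    out.lipid = getattr(model, "lipid", None)  # type: ignore[attr-defined]
    return out


def run_scenario(
    model: NetworkModel,
    scenario: TriggerScenario,
    drug: DrugState | None = None,
    warfarin: WarfarinState | None = None,
    alpha: float = 0.0,
    decision: ClotDecision | None = None,
    flow: FlowConfig | None = None,
    controls: SimControls | None = None,
    keep_trajectory: bool = False,
) -> ClottingOutcome:
    """One in-vivo trigger scenario at a given flow coupling strength.

    Undiluted physiological initials (plus drug) with the scenario's
    trigger in the clotting region; the blood pool carries the same
    concentrations without the trigger.  No-clot is a valid outcome.
    """
    decision = decision or ClotDecision()
    if drug is not None:
        model = attach_drug(model, drug)
    initials = model.initial_state()
    if warfarin is not None:
        initials = apply_warfarin(initials, warfarin)
    blood = dict(initials)  # fresh plasma: no trigger
    initials["TF"] = scenario.tf
    initials["XIIa"] = scenario.xiia
    if alpha > 0:
        base = flow or FlowConfig(alpha)
        cfg = FlowConfig(alpha, base.diffusion_constant, blood)
        model = open_system(model, cfg)
    traj = simulate(
        model,
        decision.horizon,
        controls=controls,
        initials=initials,
        stop_conditions=[("IIa", decision.iia_threshold),
                         ("Ia", decision.ia_threshold)],
    )
    times = [
        t
        for t in (
            first_crossing_time(traj, "IIa", decision.iia_threshold),
            first_crossing_time(traj, "Ia", decision.ia_threshold),
        )
        if t is not None
    ]
    ct = min(times) if times else None
    return ClottingOutcome(
        clotted=ct is not None,
        clotting_time=ct,
        trajectory=traj if keep_trajectory else None,
    )


def alpha_crit(
    model: NetworkModel,
    scenario: TriggerScenario,
    drug: DrugState | None = None,
    warfarin: WarfarinState | None = None,
    bracket: tuple[float, float] = (1e3, 1e9),
    rel_tol: float = 1e-3,
    decision: ClotDecision | None = None,
    flow: FlowConfig | None = None,
    controls: SimControls | None = None,
    label: str = "",
) -> AlphaCritResult:
    """Lowest alpha that suppresses the coagulation event, by bisection.

    The bracket is auto-expanded until its low end clots and its high
    end suppresses; bisection proceeds in log space until the relative
    bracket width is below ``rel_tol``.  Deterministic: the result is
    independent of the starting bracket within the tolerance.
    """

    def clots(a: float) -> bool:
        return run_scenario(
            model, scenario, drug=drug, warfarin=warfarin, alpha=a,
            decision=decision, flow=flow, controls=controls,
        ).clotted

    if not clots(0.0):
        raise NoClotAtRestError(
            f"scenario {scenario.name!r} does not clot at alpha = 0"
        )
    lo, hi = bracket
    iterations = 0
    while not clots(lo):  # low end must clot
        hi = min(hi, lo)
        lo /= 10.0
        iterations += 1
        if lo < 1e-6:
            # suppression at arbitrarily small alpha: threshold is ~0
            return AlphaCritResult(lo, (0.0, lo), iterations, scenario.name, label)
    while clots(hi):  # high end must suppress
        hi *= 10.0
        iterations += 1
        if hi > 1e14:
            raise BracketExpansionError(
                f"clot persists up to alpha = {hi:.1e} in {scenario.name!r}"
            )
    while (hi - lo) / lo > rel_tol:
        mid = math.sqrt(lo * hi)
        if clots(mid):
            lo = mid
        else:
            hi = mid
        iterations += 1
    return AlphaCritResult(
        math.sqrt(lo * hi), (lo, hi), iterations, scenario.name, label
    )
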