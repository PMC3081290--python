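"""Virtual clotting assays: PT, aPTT, INR, thrombin generation, factor variation.

All assays share one recipe: dilute plasma (reagent mixing), preactivate
1% of Factor V, set the reagent phospholipid and the trigger species at
their final in-assay concentrations, integrate, and read the clotting
time as the first time fibrin ("Ia") reaches 100 nM.  That fibrin
threshold corresponds to just over 4% of the (diluted) physiological
fibrinogen pool being converted, which is where massive fibrinogen
cleavage begins.  The INR is PT(drug)/PT(control) with an ISI exponent
of 1.  The same clot criterion is used for PT and aPTT: the assays
differ only in trigger (tissue factor vs contact factors XIa + XIIa).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .assembly import dilute, lipid_sites, preactivate_factor_v
from .drugs import DrugState, WarfarinState, apply_warfarin, attach_drug
from .network import (
    NetworkModel,
    SimControls,
    Trajectory,
    first_crossing_time,
    simulate,
)

__all__ = [
    "AssayConfig",
    "AssayResult",
    "PT_ASSAY",
    "APTT_ASSAY",
    "TGA_ASSAY",
    "run_pt",
    "run_aptt",
    "inr",
    "thrombin_generation",
    "factor_variation_curve",
]


class AssayError(RuntimeError):
    """The drug-free control failed to clot: the assay is misconfigured."""


@dataclass(frozen=True)
class AssayConfig:
    """Recipe of one in-vitro scenario.

    Trigger and reagent concentrations are final in-assay values applied
    after dilution.
    """

    dilution: float
    triggers: tuple[tuple[str, float], ...]
    fv_preactivation: float = 0.01
    phospholipid_molecules: float = 4.0e-6  # mol/l, reagent vesicles
    clot_species: str = "Ia"
    clot_threshold: float = 100e-9  # mol/l
    horizon: float = 600.0  # s

    def __post_init__(self) -> None:
        if self.clot_threshold <= 0:
            raise ValueError("clot threshold must be positive")
        if not self.triggers:
            raise ValueError("assay needs a trigger set")


#: PT: tissue-factor trigger, one-third dilution
PT_ASSAY = AssayConfig(dilution=1 / 3, triggers=(("TF", 4.0e-9),))

#: aPTT: contact trigger, one-third dilution
APTT_ASSAY = AssayConfig(dilution=1 / 3, triggers=(("XIa", 2.2e-9), ("XIIa", 50e-9)))

#: thrombin generation: weak TF trigger, 2:3 dilution, longer horizon
TGA_ASSAY = AssayConfig(
    dilution=2 / 3, triggers=(("TF", 5.0e-12),), horizon=3600.0
)


@dataclass
class AssayResult:
    clotting_time: float | None  # s; None = no clot within horizon
    inr: float | None = None
    peak_thrombin: float | None = None  # mol/l
    peak_time: float | None = None  # s
    trajectory: Trajectory | None = None


def _prepare(
    model: NetworkModel,
    config: AssayConfig,
    drug: DrugState | None,
    warfarin: WarfarinState | None,
) -> tuple[NetworkModel, dict[str, float]]:
    if drug is not None:
        model = attach_drug(model, drug)
    initials = model.initial_state()
    if warfarin is not None:
        initials = apply_warfarin(initials, warfarin)
    initials = dilute(initials, config.dilution)
    initials = preactivate_factor_v(initials, config.fv_preactivation)
    lipid = getattr(model, "lipid", None)
    site_species = lipid.site_species if lipid else "PhosphoLipid"
    initials[site_species] = lipid_sites(config.phospholipid_molecules, lipid)
    for name, conc in config.triggers:
        initials[name] = conc
    return model, initials


def _run_clotting(
    model: NetworkModel,
    config: AssayConfig,
    drug: DrugState | None,
    warfarin: WarfarinState | None,
    controls: SimControls | None,
) -> AssayResult:
    model, initials = _prepare(model, config, drug, warfarin)
    traj = simulate(
        model,
        config.horizon,
        controls=controls,
        initials=initials,
        stop_species=config.clot_species,
        stop_threshold=config.clot_threshold,
    )
    ct = first_crossing_time(traj, config.clot_species, config.clot_threshold)
    if ct is None and drug is None and warfarin is None:
        raise AssayError(
            f"drug-free control did not clot within {config.horizon} s"
        )
    return AssayResult(clotting_time=ct, trajectory=traj)


def run_pt(
    model: NetworkModel,
    drug: DrugState | None = None,
    warfarin: WarfarinState | None = None,
    config: AssayConfig = PT_ASSAY,
    controls: SimControls | None = None,
) -> AssayResult:
    """Prothrombin time: extrinsic trigger (TF 4 nM), dilution 1/3."""
    return _run_clotting(model, config, drug, warfarin, controls)


def run_aptt(
    model: NetworkModel,
    drug: DrugState | None = None,
    warfarin: WarfarinState | None = None,
    config: AssayConfig = APTT_ASSAY,
    controls: SimControls | None = None,
) -> AssayResult:
    """aPTT: contact trigger (XIa 2.2 nM + XIIa 50 nM), dilution 1/3."""
    return _run_clotting(model, config, drug, warfarin, controls)


def inr(pt_drug: float, pt_control: float) -> float:
    """International normalized ratio with ISI = 1: PT(drug) / PT(control)."""
    if pt_drug <= 0 or pt_control <= 0:
        raise ValueError("clotting times must be positive")
    return pt_drug / pt_control


def thrombin_generation(
    model: NetworkModel,
    drug: DrugState | None = None,
    warfarin: WarfarinState | None = None,
    config: AssayConfig = TGA_ASSAY,
    controls: SimControls | None = None,
) -> AssayResult:
    """Thrombin-generation assay: peak thrombin and time-to-peak.

    The peak is refined on the solver's dense interpolant around the
    coarse-grid maximum.
    """
    model, initials = _prepare(model, config, drug, warfarin)
    traj = simulate(model, config.horizon, controls=controls, initials=initials)
    iia = traj["IIa"]
    i = int(np.argmax(iia))
    peak, peak_t = float(iia[i]), float(traj.times[i])
    if traj.dense is not None and 0 < i < len(traj.times) - 1:
        k = traj.index["IIa"]
        tt = np.linspace(traj.times[i - 1], traj.times[i + 1], 201)
        vals = traj.dense(tt)[k]
        j = int(np.argmax(vals))
        peak, peak_t = float(vals[j]), float(tt[j])
    ct = first_crossing_time(traj, config.clot_species, config.clot_threshold)
    return AssayResult(
        clotting_time=ct, peak_thrombin=peak, peak_time=peak_t, trajectory=traj
    )


def factor_variation_curve(
    model: NetworkModel,
    factor: str,
    levels: Sequence[float],
    assay: str = "pt",
    controls: SimControls | None = None,
) -> list[tuple[float, float]]:
    """INR (PT assay) or clotting time (aPTT) as one factor's level varies.

    ``levels`` are relative to the physiological concentration (1.0 =
    normal).  Only that factor's initial concentration is scaled.
    """
    if factor not in model.index:
        raise KeyError(f"unknown factor {factor!r}")
    if any(lv <= 0 for lv in levels):
        raise ValueError("levels must be positive")
    runner = {"pt": run_pt, "aptt": run_aptt}[assay]
    base = model.initial_state()[factor]
    control = runner(model, controls=controls).clotting_time
    out: list[tuple[float, float]] = []
    for lv in levels:
        if lv == 1.0:
            ct = control
        else:
            varied = model.with_initials({factor: base * lv})
            varied.lipid = getattr(model, "lipid", None)
            try:
                ct = runner(varied, controls=controls).clotting_time
            except AssayError:
                ct = None
        if ct is None:
            out.append((lv, float("inf")))
        elif assay == "pt":
            out.append((lv, inr(ct, control)))
        else:
            out.append((lv, ct))
    return out
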