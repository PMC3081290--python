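"""Anticoagulant drug-action mechanisms.

Each kinetic drug (rivaroxaban, DX-9065a, melagatran as the active
metabolite of ximelagatran, enoxaparin) is attached to the network as a
set of extra species and mass-action reactions: complexation with the
target factor(s), reversible plasma-protein binding against the albumin
pool, and for enoxaparin the catalytic activation of antithrombin with
release of the drug after each neutralisation.  Warfarin is never a
kinetic species: it is represented purely as a shift in the initial
concentrations of the vitamin K-dependent factors (II, VII, IX, X,
protein C, protein S), all reduced simultaneously to the same fraction
of normal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from scipy.optimize import brentq

from .model_data import VITAMIN_K_SPECIES
from .network import (
    ModelValidationError,
    NetworkModel,
    RateLaw,
    RateTerm,
    ReactionDef,
    SpeciesDef,
)

__all__ = [
    "DrugState",
    "WarfarinState",
    "DRUGS",
    "attach_drug",
    "apply_warfarin",
    "warfarin_fraction_for_inr",
    "mass_to_molar",
]

#: anti-Factor Xa activity of enoxaparin, units per mg
ENOXAPARIN_UNITS_PER_MG = 100.0


@dataclass(frozen=True)
class DrugDefinition:
    """Mechanism of one anticoagulant: species, reactions, constants."""

    name: str
    free_species: str
    bound_species: str
    extra_species: tuple[str, ...]
    reactions: tuple[ReactionDef, ...]
    constants: dict[str, float]
    constant_provenance: dict[str, str]
    molecular_weight: float  # g/mol
    unbound_fraction: float  # fu


def _term(sign: int, constants: Sequence[str], species: Sequence[str]) -> RateTerm:
    return RateTerm(sign, tuple(constants), tuple(species))


def _rxn(rid: str, reactants: Sequence[tuple[str, int]],
         products: Sequence[tuple[str, int]], terms: Sequence[RateTerm],
         group: str) -> ReactionDef:
    return ReactionDef(rid, tuple(reactants), tuple(products), RateLaw(tuple(terms)), group)


def _build_rivaroxaban() -> DrugDefinition:
    g = "drug:rivaroxaban"
    bay = "Bay59_7939"
    rxns = (
        # Bay59_7939 + Xa -> Bay59_7939_Xa
        _rxn("RBay1", [(bay, 1), ("Xa", 1)], [(f"{bay}_Xa", 1)],
             [_term(+1, ["kBay1"], [bay, "Xa"]),
              _term(-1, ["kBay1", "kBay_Ki_Xa"], [f"{bay}_Xa"])], g),
        _rxn("RBay1s", [(bay, 1), ("Xa_lipid", 1)], [(f"{bay}_Xa_lipid", 1)],
             [_term(+1, ["kBay1"], [bay, "Xa_lipid"]),
              _term(-1, ["kBay1", "kBay_Ki_Xa"], [f"{bay}_Xa_lipid"])], g),
        _rxn("RBay2", [(bay, 1), ("Xa_Va_lipid", 1)], [(f"{bay}_Xa_Va_lipid", 1)],
             [_term(+1, ["kBay3"], [bay, "Xa_Va_lipid"]),
              _term(-1, ["kBay3", "kBay_Ki_XaVa"], [f"{bay}_Xa_Va_lipid"])], g),
        # protein binding: written as release of the bound drug
        _rxn("RBay3", [(f"{bay}_Bound", 1)], [(bay, 1)],
             [_term(+1, ["kBay_fu_on", "kBay_fu"], [f"{bay}_Bound"]),
              _term(-1, ["kBay_fu_on"], ["Albumin_Factor", bay])], g),
        _rxn("RBay4", [(f"{bay}_Xa", 1), ("ATIII", 1)], [(f"{bay}_Xa_ATIII", 1)],
             [_term(+1, ["kBay5"], [f"{bay}_Xa", "ATIII"])], g),
        _rxn("RBay5", [(bay, 1), ("Xa_ATIII", 1)], [(f"{bay}_Xa_ATIII", 1)],
             [_term(+1, ["kBay6"], [bay, "Xa_ATIII"]),
              _term(-1, ["kBay6", "kBay_Ki_XaATIII"], [f"{bay}_Xa_ATIII"])], g),
    )
    constants = {
        "kBay1": 1.7e7,          # measured on-rate for Factor Xa
        "kBay_Ki_Xa": 4.0e-10,   # measured Ki, free and lipid-bound Xa
        "kBay3": 1.0e6,
        "kBay_Ki_XaVa": 2.0e-8,  # prothrombinase: protected, weaker effective Ki
        "kBay5": 1.0e2,
        "kBay6": 1.0e6,
        "kBay_Ki_XaATIII": 1.0e-8,
        "kBay_fu_on": 1.0,
        "kBay_fu": 0.0526,       # unbound fraction ~5%
    }
    prov = {k: "external-constant" for k in ("kBay1", "kBay_Ki_Xa", "kBay_fu")}
    prov.update({k: "fitted-here" for k in
                 ("kBay3", "kBay_Ki_XaVa", "kBay5", "kBay6", "kBay_Ki_XaATIII",
                  "kBay_fu_on")})
    return DrugDefinition(
        "rivaroxaban", bay, f"{bay}_Bound",
        (bay, f"{bay}_Bound", f"{bay}_Xa", f"{bay}_Xa_lipid",
         f"{bay}_Xa_Va_lipid", f"{bay}_Xa_ATIII"),
        rxns, constants, prov, molecular_weight=435.88, unbound_fraction=0.05,
    )


def _build_dx9065a() -> DrugDefinition:
    g = "drug:DX-9065a"
    dx = "DX9065a"
    rxns = (
        _rxn("RDx1", [(dx, 1), ("Xa", 1)], [(f"{dx}_Xa", 1)],
             [_term(+1, ["kDx1"], [dx, "Xa"]),
              _term(-1, ["kDx2"], [f"{dx}_Xa"])], g),
        _rxn("RDx1s", [(dx, 1), ("Xa_lipid", 1)], [(f"{dx}_Xa_lipid", 1)],
             [_term(+1, ["kDx1"], [dx, "Xa_lipid"]),
              _term(-1, ["kDx2"], [f"{dx}_Xa_lipid"])], g),
        _rxn("RDx2", [(dx, 1), ("Xa_Va_lipid", 1)], [(f"{dx}_Xa_Va_lipid", 1)],
             [_term(+1, ["kDx3"], [dx, "Xa_Va_lipid"]),
              _term(-1, ["kDx4"], [f"{dx}_Xa_Va_lipid"])], g),
        _rxn("RDx3", [(f"{dx}_Xa", 1), ("ATIII", 1)], [(f"{dx}_Xa_ATIII", 1)],
             [_term(+1, ["kDx5"], [f"{dx}_Xa", "ATIII"])], g),
        _rxn("RDx4", [(dx, 1)], [(f"{dx}_Bound", 1)],
             [_term(+1, ["kDx_fu_on"], ["Albumin_Factor", dx]),
              _term(-1, ["kDx_fu_on", "kDx_fu"], [f"{dx}_Bound"])], g),
        _rxn("RDx5", [(dx, 1), ("Xa_ATIII", 1)], [(f"{dx}_Xa_ATIII", 1)],
             [_term(+1, ["kDx6"], [dx, "Xa_ATIII"]),
              _term(-1, ["kDx7"], [f"{dx}_Xa_ATIII"])], g),
    )
    constants = {
        "kDx1": 1.0e7,
        "kDx2": 0.41,   # kDx1 * Ki(Xa) with measured Ki = 41 nM
        "kDx3": 1.0e7,
        "kDx4": 1.0,
        "kDx5": 1.0e2,
        "kDx6": 1.0e6,
        "kDx7": 1.0e-2,
        "kDx_fu_on": 1.0,
        "kDx_fu": 1.0,  # unbound fraction ~50%
    }
    prov = {k: "external-constant" for k in ("kDx1", "kDx2", "kDx_fu")}
    prov.update({k: "fitted-here" for k in
                 ("kDx3", "kDx4", "kDx5", "kDx6", "kDx7", "kDx_fu_on")})
    return DrugDefinition(
        "DX-9065a", dx, f"{dx}_Bound",
        (dx, f"{dx}_Bound", f"{dx}_Xa", f"{dx}_Xa_lipid",
         f"{dx}_Xa_Va_lipid", f"{dx}_Xa_ATIII"),
        rxns, constants, prov, molecular_weight=571.7, unbound_fraction=0.5,
    )


def _build_melagatran() -> DrugDefinition:
    g = "drug:ximelagatran"
    rxns = (
        _rxn("RXi1", [("Xim", 1), ("IIa", 1)], [("IIa_Xim", 1)],
             [_term(+1, ["kXim1"], ["IIa", "Xim"]),
              _term(-1, ["kXim2"], ["IIa_Xim"])], g),
        _rxn("RXi2", [("Xim", 1), ("mIIa", 1)], [("mIIa_Xim", 1)],
             [_term(+1, ["kXim3"], ["mIIa", "Xim"]),
              _term(-1, ["kXim4"], ["mIIa_Xim"])], g),
        _rxn("RXi3", [("Xim", 1), ("IIa_Tm", 1)], [("IIa_Tm_Xim", 1)],
             [_term(+1, ["kXim5"], ["IIa_Tm", "Xim"]),
              _term(-1, ["kXim6"], ["IIa_Tm_Xim"])], g),
        _rxn("RXi4", [("Xim", 1)], [("Xim_Bound", 1)],
             [_term(+1, ["kXim_fu_on"], ["Albumin_Factor", "Xim"]),
              _term(-1, ["kXim_fu_on", "kXim_fu"], ["Xim_Bound"])], g),
    )
    constants = {
        "kXim1": 1.6e7,
        "kXim2": 3.2e-2,  # kXim1 * Ki(IIa) with measured Ki = 2 nM
        "kXim3": 1.0e7,
        "kXim4": 4.0e-2,
        "kXim5": 1.0e7,
        "kXim6": 2.0e-2,
        "kXim_fu_on": 1.0,
        "kXim_fu": 5.667,  # unbound fraction ~85%
    }
    prov = {k: "external-constant" for k in ("kXim1", "kXim2", "kXim_fu")}
    prov.update({k: "fitted-here" for k in
                 ("kXim3", "kXim4", "kXim5", "kXim6", "kXim_fu_on")})
    return DrugDefinition(
        "ximelagatran", "Xim", "Xim_Bound",
        ("Xim", "Xim_Bound", "IIa_Xim", "mIIa_Xim", "IIa_Tm_Xim"),
        rxns, constants, prov, molecular_weight=429.5, unbound_fraction=0.85,
    )


def _build_enoxaparin() -> DrugDefinition:
    g = "drug:enoxaparin"
    rxns = (
        _rxn("RHep1", [("Hep", 1)], [("Hep_Bound", 1)],
             [_term(+1, ["kHep_fu_on"], ["Albumin_Factor", "Hep"]),
              _term(-1, ["kHep_fu_on", "kHep_fu"], ["Hep_Bound"])], g),
        _rxn("RHep2", [("ATIII", 1), ("Hep", 1)], [("ATIIIa", 1)],
             [_term(+1, ["kHep_ATIII_on"], ["ATIII", "Hep"]),
              _term(-1, ["kHep_ATIII_on", "kHep_Ki_ATIII"], ["ATIIIa"])], g),
        # neutralisation by activated antithrombin releases the drug, which
        # can then activate another antithrombin molecule
        _rxn("RHep3", [("Xa", 1), ("ATIIIa", 1)], [("Xa_ATIII", 1), ("Hep", 1)],
             [_term(+1, ["kHep_Xa_ATIIIa"], ["Xa", "ATIIIa"])], g),
        _rxn("RHep4", [("Xa_lipid", 1), ("ATIIIa", 1)],
             [("Xa_ATIII", 1), ("PhosphoLipid", 1), ("Hep", 1)],
             [_term(+1, ["kHep_Xa_ATIIIa"], ["Xa_lipid", "ATIIIa"])], g),
        _rxn("RHep5", [("Xa_Va_lipid", 1), ("ATIIIa", 1)],
             [("Xa_ATIII", 1), ("Hep", 1), ("Va_lipid", 1)],
             [_term(+1, ["kHep_XaVa_ATIIIa"], ["Xa_Va_lipid", "ATIIIa"])], g),
        _rxn("RHep6", [("IIa", 1), ("ATIIIa", 1)], [("IIa_ATIII", 1), ("Hep", 1)],
             [_term(+1, ["kHep_IIa_ATIIIa"], ["IIa", "ATIIIa"])], g),
        _rxn("RHep7", [("mIIa", 1), ("ATIIIa", 1)], [("mIIa_ATIII", 1), ("Hep", 1)],
             [_term(+1, ["kHep_IIa_ATIIIa"], ["mIIa", "ATIIIa"])], g),
        _rxn("RHep8", [("ATIIIa", 1), ("IXa", 1)], [("IXa_ATIII", 1), ("Hep", 1)],
             [_term(+1, ["kHep_IXa_ATIIIa"], ["ATIIIa", "IXa"])], g),
        _rxn("RHep9", [("ATIIIa", 1), ("IXa_lipid", 1)],
             [("IXa_ATIII", 1), ("PhosphoLipid", 1), ("Hep", 1)],
             [_term(+1, ["kHep_IXa_ATIIIa"], ["ATIIIa", "IXa_lipid"])], g),
        _rxn("RHep10", [("XIa", 1), ("ATIIIa", 1)], [("XIa_ATIII", 1), ("Hep", 1)],
             [_term(+1, ["kHep_XIa_ATIIIa"], ["XIa", "ATIIIa"])], g),
        _rxn("RHep11", [("XIa_lipid", 1), ("ATIIIa", 1)],
             [("XIa_ATIII", 1), ("PhosphoLipid", 1), ("Hep", 1)],
             [_term(+1, ["kHep_XIa_ATIIIa"], ["XIa_lipid", "ATIIIa"])], g),
    )
    constants = {
        "kHep_fu_on": 1.0,
        "kHep_fu": 4.0,          # unbound fraction ~80%
        # effective affinity folds in the fraction of chains carrying the
        # high-affinity pentasaccharide
        "kHep_ATIII_on": 2.0e6,
        "kHep_Ki_ATIII": 1.0e-6,
        # anti-Xa is the dominant activity of enoxaparin: the Factor Xa
        # constant is the largest of the neutralisation set; prothrombinase
        # is protected, and anti-IIa is weak for the short LMWH chains
        "kHep_Xa_ATIIIa": 3.0e5,
        "kHep_XaVa_ATIIIa": 1.0e4,
        "kHep_IIa_ATIIIa": 5.0e4,
        "kHep_IXa_ATIIIa": 2.0e4,
        "kHep_XIa_ATIIIa": 1.0e4,
    }
    prov = {k: "external-constant" for k in ("kHep_ATIII_on", "kHep_fu")}
    prov.update({k: "fitted-here" for k in
                 ("kHep_Ki_ATIII", "kHep_Xa_ATIIIa", "kHep_XaVa_ATIIIa",
                  "kHep_IIa_ATIIIa", "kHep_IXa_ATIIIa", "kHep_XIa_ATIIIa",
                  "kHep_fu_on")})
    return DrugDefinition(
        "enoxaparin", "Hep", "Hep_Bound",
        ("Hep", "Hep_Bound", "ATIIIa"),
        rxns, constants, prov, molecular_weight=4500.0, unbound_fraction=0.8,
    )


DRUGS: dict[str, DrugDefinition] = {
    d.name: d
    for d in (_build_rivaroxaban(), _build_dx9065a(), _build_melagatran(),
              _build_enoxaparin())
}
# ximelagatran dosing refers to the same mechanism (active metabolite)
DRUGS["melagatran"] = DRUGS["ximelagatran"]


@dataclass(frozen=True)
class DrugState:
    """One anticoagulant at a total plasma concentration (mol/l)."""

    name: str
    total_concentration: float  # mol/l

    def __post_init__(self) -> None:
        if self.name not in DRUGS:
            raise KeyError(
                f"unknown drug {self.name!r}; known: {sorted(set(DRUGS))}"
            )
        if self.total_concentration < 0:
            raise ValueError("drug concentration must be non-negative")

    @property
    def definition(self) -> DrugDefinition:
        return DRUGS[self.name]


@dataclass(frozen=True)
class WarfarinState:
    """Vitamin K antagonism as a simultaneous initial-condition shift."""

    factor_fraction: float
    affected_species: tuple[str, ...] = field(default=VITAMIN_K_SPECIES)

    def __post_init__(self) -> None:
        if not 0 < self.factor_fraction <= 1:
            raise ValueError(
                f"factor fraction must be in (0, 1], got {self.factor_fraction}"
            )


def mass_to_molar(drug: str, value: float, unit: str = "ug/l") -> float:
    """Convert a plasma drug level to mol/l.

    Accepted units: ``ug/l``, ``mg/l``, ``uM``, ``mol/l`` and, for
    enoxaparin, ``antiXa_U/ml`` (100 anti-Xa units per mg, average
    molecular weight 4500 g/mol).
    """
    definition = DRUGS[drug]
    mw = definition.molecular_weight
    if mw <= 0:
        raise ValueError(f"no molecular weight configured for {drug!r}")
    if unit == "ug/l":
        return value * 1e-6 / mw
    if unit == "mg/l":
        return value * 1e-3 / mw
    if unit == "uM":
        return value * 1e-6
    if unit == "mol/l":
        return value
    if unit == "antiXa_U/ml":
        if definition.name != "enoxaparin":
            raise ValueError("anti-Xa units apply to enoxaparin only")
        mg_per_l = value / ENOXAPARIN_UNITS_PER_MG * 1e3
        return mg_per_l * 1e-3 / mw
    raise ValueError(f"unknown unit {unit!r}")


def _partition_initials(defn: DrugDefinition, total: float,
                        albumin: float, atiii_total: float) -> dict[str, float]:
    """Equilibrium split of the total drug over free/albumin-bound (and,
    for enoxaparin, antithrombin-complexed) pools."""
    kfu = defn.constants[
        {"rivaroxaban": "kBay_fu", "DX-9065a": "kDx_fu",
         "ximelagatran": "kXim_fu", "enoxaparin": "kHep_fu"}[defn.name]
    ]
    a = 1.0 + albumin / kfu
    if defn.name != "enoxaparin":
        free = total / a
        return {defn.free_species: free,
                defn.bound_species: total - free}
    ki = defn.constants["kHep_Ki_ATIII"]
    # total = a*Hep + AT_tot*Hep/(Ki+Hep)  ->  positive quadratic root
    b = a * ki + atiii_total - total
    c = -total * ki
    hep = (-b + math.sqrt(b * b - 4 * a * c)) / (2 * a)
    atiiia = atiii_total * hep / (ki + hep)
    return {"Hep": hep, "Hep_Bound": (a - 1.0) * hep, "ATIIIa": atiiia}


def attach_drug(model: NetworkModel, drug: DrugState) -> NetworkModel:
    """Return a new model with the drug's species and reactions attached.

    The total plasma concentration is pre-partitioned over the free and
    protein-bound (and antithrombin-activated) pools at their binding
    equilibrium so that simulations start without a binding transient;
    the same concentrations define the drug's presence in the blood
    reservoir of flow-coupled simulations.
    """
    defn = drug.definition
    collisions = set(defn.extra_species) & set(model.index)
    if collisions:
        raise ModelValidationError(
            f"species name collision attaching {defn.name!r}: {sorted(collisions)}"
        )
    albumin = model.initial_state().get("Albumin_Factor", 1.0)
    atiii = model.initial_state().get("ATIII", 0.0)
    split = _partition_initials(defn, drug.total_concentration, albumin, atiii)
    new_species = list(model.species) + [
        SpeciesDef(name, initial_concentration=split.get(name, 0.0))
        for name in defn.extra_species
    ]
    # enoxaparin sequesters part of antithrombin into ATIIIa
    if defn.name == "enoxaparin":
        new_species = [
            SpeciesDef(s.name, atiii - split["ATIIIa"], s.mobile, s.lipid_bound,
                       s.constant) if s.name == "ATIII" else s
            for s in new_species
        ]
    params = model.parameters.updated(defn.constants)
    for sym, tag in defn.constant_provenance.items():
        params.provenance[sym] = tag
    out = NetworkModel(new_species, tuple(model.reactions) + defn.reactions, params)
    out.lipid = getattr(model, "lipid", None)  # type: ignore[attr-defined]
    return out


def apply_warfarin(initials: Mapping[str, float], w: WarfarinState) -> dict[str, float]:
    """Scale the vitamin K-dependent species by the factor fraction."""
    out = dict(initials)
    for name in w.affected_species:
        if name in out:
            out[name] = out[name] * w.factor_fraction
    return out


def warfarin_fraction_for_inr(
    model: NetworkModel,
    target_inr: float,
    rel_tol: float = 1e-3,
    f_bracket: tuple[float, float] = (0.05, 1.0),
    controls=None,
) -> float:
    """Factor fraction f such that the simulated INR equals ``target_inr``.

    PT prolongation is monotone as the vitamin K-dependent factors drop,
    so a bracketing root-finder on f in (0, 1] converges; the result is
    accurate to ``rel_tol`` relative on the INR.
    """
    from .assays import inr, run_pt  # local import to avoid a cycle

    if target_inr < 1.0:
        raise ValueError("target INR must be >= 1")
    if target_inr == 1.0:
        return 1.0
    pt_control = run_pt(model, controls=controls).clotting_time

    def objective(f: float) -> float:
        pt = run_pt(model, warfarin=WarfarinState(f), controls=controls).clotting_time
        if pt is None:
            return math.inf
        return inr(pt, pt_control) - target_inr

    lo, hi = f_bracket
    if objective(lo) < 0:
        raise ValueError(
            f"target INR {target_inr} not reachable with factor fraction >= {lo}"
        )
    f = brentq(objective, lo, hi, xtol=min(1e-5, rel_tol))
    return float(f)
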