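"""Transcription of the unified coagulation network.

The network couples an extrinsic (tissue-factor) core, an intrinsic
(contact) pathway, fibrinogen cleavage, the protein C/S negative
feedback, phospholipid adsorption and von Willebrand factor protection
of Factor VIII into one mass-action model (base units mol/l and
seconds).

Provenance tags on every parameter record where each number comes from:

``source-model``
    taken from the published model the corresponding sub-network is
    adapted from (extrinsic core: Hockin et al.'s tissue-factor model,
    whose k1..k42 constant numbering is kept verbatim; intrinsic chain:
    Kogan et al.'s aPTT model, constants prefixed ``Kog``; protein C/S
    and adsorption: Bungay et al. / Kuharsky & Fogelson; vWF: Saenko et
    al.).
``external-constant``
    standard reference values (plasma concentrations, drug molecular
    weights, measured Ki/kon values).
``fitted-here``
    calibrated against clotting-test behaviour (the antithrombin
    neutralisation constants, which are deliberately reduced relative to
    the extrinsic-core source, and drug constants without direct
    measurements).

The extrinsic core is exactly 32 reactions (R1..R32): each reversible
binding is one reaction with a reversible rate law, each
enzyme-substrate scheme is split into binding + catalysis, and the
two directions of VIIIa dissociation are separate reactions.  Reaction
R9 is Xa-catalysed prothrombin activation with rate constant k16.
Reactions suffixed ``d`` duplicate a solution-phase reaction for the
lipid-bound form of a component.
"""

from __future__ import annotations

from typing import Any

FORMAT_VERSION = 1

#: phospholipid molecules per protein-binding site on vesicles
MOLECULES_PER_SITE = 333.0

#: physiological plasma fibrinogen, mol/l
FIBRINOGEN_PLASMA = 7.0e-6

#: immobile species: bound to tissue (TF and its complexes) or thrombus (Ia)
IMMOBILE = (
    "TF",
    "TF_VII",
    "TF_VIIa",
    "TF_VIIa_X",
    "TF_VIIa_Xa",
    "TF_VIIa_IX",
    "TF_VIIa_Xa_TFPI",
    "TF_VIIa_ATIII",
    "Ia",
)

#: vitamin K-dependent species rescaled by warfarin therapy
VITAMIN_K_SPECIES = ("II", "VII", "VIIa", "IX", "X", "PC", "PS")


def _sp(name: str, initial: float = 0.0, **kw: Any) -> dict[str, Any]:
    d = {"name": name, "initial": initial, "mobile": name not in IMMOBILE,
         "lipid_bound": name.endswith("_lipid"), "constant": False}
    d.update(kw)
    return d


# --- species: non-zero initials are standard plasma values ------------------

SPECIES: list[dict[str, Any]] = [
    # extrinsic core
    _sp("TF"),
    _sp("VII", 1.0e-8),
    _sp("TF_VII"),
    _sp("VIIa", 1.0e-10),
    _sp("TF_VIIa"),
    _sp("Xa"),
    _sp("IIa"),
    _sp("X", 1.6e-7),
    _sp("TF_VIIa_X"),
    _sp("TF_VIIa_Xa"),
    _sp("IX", 9.0e-8),
    _sp("TF_VIIa_IX"),
    _sp("IXa"),
    _sp("II", 1.4e-6),
    _sp("VIII", 2.0e-10),
    _sp("VIIIa"),
    _sp("IXa_VIIIa"),
    _sp("IXa_VIIIa_X"),
    _sp("VIIIa1_L"),
    _sp("VIIIa2"),
    _sp("V", 2.0e-8),
    _sp("Va"),
    _sp("Xa_Va_lipid"),
    _sp("Xa_Va_II_lipid"),
    _sp("mIIa"),
    _sp("TFPI", 2.5e-9),
    _sp("Xa_TFPI"),
    _sp("TF_VIIa_Xa_TFPI"),
    _sp("ATIII", 3.4e-6),
    _sp("Xa_ATIII"),
    _sp("mIIa_ATIII"),
    _sp("IXa_ATIII"),
    _sp("IIa_ATIII"),
    _sp("TF_VIIa_ATIII"),
    # intrinsic pathway
    _sp("XI", 3.1e-8),
    _sp("XIa"),
    _sp("XIIa"),
    _sp("XIa_ATIII"),
    _sp("XIIa_inact"),
    # fibrinogen / fibrin
    _sp("I", FIBRINOGEN_PLASMA),
    _sp("Ia"),
    # protein C/S system
    _sp("PC", 6.5e-8),
    _sp("APC"),
    _sp("PS", 3.0e-7),
    _sp("APC_PS"),
    _sp("Va_inact"),
    _sp("VIIIa_inact"),
    _sp("APC_inact"),
    _sp("Tm", 1.0e-9),
    _sp("IIa_Tm"),
    # phospholipid binding sites and lipid-bound factors
    _sp("PhosphoLipid", 1.2e-8),
    _sp("Xa_lipid"),
    _sp("Va_lipid"),
    _sp("IXa_lipid"),
    _sp("XIa_lipid"),
    # von Willebrand factor protection of VIII
    _sp("vWF", 1.5e-9),
    _sp("VIII_vWF", 5.0e-10),
    # dimensionless albumin pool for drug protein binding; scaled by dilution
    _sp("Albumin_Factor", 1.0, constant=True),
]


# --- parameters -------------------------------------------------------------

def _par(symbol: str, value: float, provenance: str) -> dict[str, Any]:
    return {"symbol": symbol, "value": value, "provenance": provenance}


PARAMETERS: list[dict[str, Any]] = [
    # extrinsic core (Hockin numbering, l/(mol*s) or 1/s)
    _par("k1", 3.1e-3, "source-model"),
    _par("k2", 3.2e6, "source-model"),
    _par("k3", 3.1e-3, "source-model"),
    _par("k4", 2.3e7, "source-model"),
    _par("k5", 4.4e5, "source-model"),
    _par("k6", 1.3e7, "source-model"),
    _par("k7", 2.3e4, "source-model"),
    _par("k8", 2.5e7, "source-model"),
    _par("k9", 1.05, "source-model"),
    _par("k10", 6.0, "source-model"),
    _par("k11", 19.0, "source-model"),
    _par("k12", 2.2e7, "source-model"),
    _par("k13", 2.4, "source-model"),
    _par("k14", 1.0e7, "source-model"),
    _par("k15", 1.8, "source-model"),
    _par("k16", 7.5e3, "source-model"),
    _par("k17", 2.0e7, "source-model"),
    _par("k18", 5.0e-3, "source-model"),
    _par("k19", 1.0e7, "source-model"),
    _par("k20", 1.0e-3, "source-model"),
    _par("k21", 1.0e8, "source-model"),
    _par("k22", 8.2, "source-model"),
    _par("k23", 2.2e4, "source-model"),
    _par("k24", 6.0e-3, "source-model"),
    _par("k25", 1.0e-3, "source-model"),
    _par("k26", 2.0e7, "source-model"),
    _par("k27", 0.2, "source-model"),
    _par("k28", 4.0e8, "source-model"),
    _par("k29", 103.0, "source-model"),
    _par("k30", 1.0e8, "source-model"),
    _par("k31", 63.5, "source-model"),
    _par("k32", 1.5e7, "source-model"),
    _par("k33", 3.6e-4, "source-model"),
    _par("k34", 9.0e5, "source-model"),
    _par("k35", 1.1e-4, "source-model"),
    _par("k36", 3.2e8, "source-model"),
    _par("k37", 5.0e7, "source-model"),
    # antithrombin neutralisation: halved relative to the extrinsic-core
    # source, whose values sit at the upper end of measured ranges
    _par("k38", 7.5e2, "fitted-here"),
    _par("k39", 3.55e3, "fitted-here"),
    _par("k40", 2.45e2, "fitted-here"),
    _par("k41", 3.55e3, "fitted-here"),
    _par("k42", 1.15e2, "fitted-here"),
    # intrinsic pathway (contact chain)
    _par("Kog1", 1.0e5, "source-model"),   # XIIa activates XI
    _par("Kog2", 1.0e7, "source-model"),   # XIa activates IX
    _par("Kog3", 1.0e2, "source-model"),   # IXa activates X, solution phase
    _par("Kog4", 1.0e4, "source-model"),   # IIa feedback on XI
    _par("Kog5", 3.0e2, "external-constant"),  # XIa + ATIII
    _par("Kog6", 1.0e-3, "external-constant"),  # XIIa neutralisation (C1-inh lumped)
    _par("Kog2d", 1.0e7, "source-model"),  # lipid-bound XIa activates IX
    _par("Kog3d", 1.0e4, "source-model"),  # lipid-bound IXa activates X
    # fibrinogen cleavage (kcat/Km as a second-order constant)
    _par("kRI", 1.17e7, "source-model"),
    # duplicated solution/lipid reactions
    _par("k16d", 7.5e3, "source-model"),
    _par("k38d", 7.5e2, "fitted-here"),
    _par("k40d", 2.45e2, "fitted-here"),
    # protein C/S
    _par("kBu1_on", 1.0e8, "source-model"),
    _par("kBu1_off", 5.0e-2, "source-model"),
    _par("kBu2", 1.0e7, "source-model"),
    _par("kBu3_on", 1.0e6, "source-model"),
    _par("kBu3_off", 1.0e-1, "source-model"),
    _par("kBu4", 1.0e7, "source-model"),
    _par("kBu4a", 5.0e6, "source-model"),
    _par("kBu4b", 1.0e7, "source-model"),
    _par("kBu5", 6.0e-4, "source-model"),
    # adsorption to phospholipid sites
    _par("kad1_on", 1.0e7, "source-model"),
    _par("kad1_off", 2.0e-1, "source-model"),
    _par("kad2_on", 1.0e7, "source-model"),
    _par("kad2_off", 1.0e-1, "source-model"),
    _par("kad3_on", 1.0e7, "source-model"),
    _par("kad3_off", 2.5e-1, "source-model"),
    _par("kad4_on", 1.0e6, "source-model"),
    _par("kad4_off", 1.0e-1, "source-model"),
    # vWF
    _par("kvwf_on", 4.0e6, "source-model"),
    _par("kvwf_off", 1.6e-3, "source-model"),
    _par("kvwf_act", 2.0e7, "source-model"),
]


# --- reactions --------------------------------------------------------------

def _irr(rid: str, group: str, reactants: list[str], products: list[str],
         constants: list[str], rate_species: list[str] | None = None) -> dict[str, Any]:
    """Irreversible mass-action reaction; rate species default to reactants."""
    return {
        "id": rid,
        "group": group,
        "reactants": [[s, reactants.count(s)] for s in dict.fromkeys(reactants)],
        "products": [[s, products.count(s)] for s in dict.fromkeys(products)],
        "rate": [[+1, constants, rate_species if rate_species is not None else reactants]],
    }


def _rev(rid: str, group: str, reactants: list[str], products: list[str],
         kf: str, kr: str, reverse_species: list[str] | None = None) -> dict[str, Any]:
    """Reversible reaction, rate = kf*prod(reactants) - kr*prod(rev_species)."""
    return {
        "id": rid,
        "group": group,
        "reactants": [[s, reactants.count(s)] for s in dict.fromkeys(reactants)],
        "products": [[s, products.count(s)] for s in dict.fromkeys(products)],
        "rate": [
            [+1, [kf], reactants],
            [-1, [kr], reverse_species if reverse_species is not None else products],
        ],
    }


E = "extrinsic"
K = "intrinsic"
F = "fibrin"
B = "protein_cs"
A = "adsorption"
W = "vwf"

REACTIONS: list[dict[str, Any]] = [
    # ---- extrinsic core: exactly 32 reactions, R9 carries k16 ----
    _rev("R1", E, ["TF", "VII"], ["TF_VII"], "k2", "k1"),
    _rev("R2", E, ["TF", "VIIa"], ["TF_VIIa"], "k4", "k3"),
    _irr("R3", E, ["TF_VIIa", "VII"], ["TF_VIIa", "VIIa"], ["k5"]),
    _irr("R4", E, ["Xa", "VII"], ["Xa", "VIIa"], ["k6"]),
    _irr("R5", E, ["IIa", "VII"], ["IIa", "VIIa"], ["k7"]),
    _rev("R6", E, ["TF_VIIa", "X"], ["TF_VIIa_X"], "k8", "k9"),
    _irr("R7", E, ["TF_VIIa_X"], ["TF_VIIa_Xa"], ["k10"]),
    _rev("R8", E, ["TF_VIIa", "Xa"], ["TF_VIIa_Xa"], "k12", "k11"),
    _irr("R9", E, ["Xa", "II"], ["Xa", "IIa"], ["k16"]),
    _rev("R10", E, ["TF_VIIa", "IX"], ["TF_VIIa_IX"], "k14", "k13"),
    _irr("R11", E, ["TF_VIIa_IX"], ["TF_VIIa", "IXa"], ["k15"]),
    _irr("R12", E, ["IIa", "VIII"], ["IIa", "VIIIa"], ["k17"]),
    _rev("R13", E, ["IXa", "VIIIa"], ["IXa_VIIIa"], "k19", "k18"),
    _rev("R14", E, ["IXa_VIIIa", "X"], ["IXa_VIIIa_X"], "k21", "k20"),
    _irr("R15", E, ["IXa_VIIIa_X"], ["IXa_VIIIa", "Xa"], ["k22"]),
    _irr("R16", E, ["VIIIa"], ["VIIIa1_L", "VIIIa2"], ["k24"]),
    _irr("R17", E, ["VIIIa1_L", "VIIIa2"], ["VIIIa"], ["k23"]),
    _irr("R18", E, ["IXa_VIIIa_X"], ["VIIIa1_L", "VIIIa2", "X", "IXa"], ["k25"]),
    _irr("R19", E, ["IXa_VIIIa"], ["VIIIa1_L", "VIIIa2", "IXa"], ["k25"]),
    _irr("R20", E, ["IIa", "V"], ["IIa", "Va"], ["k26"]),
    _rev("R21", E, ["Xa", "Va_lipid"], ["Xa_Va_lipid"], "k28", "k27"),
    _rev("R22", E, ["Xa_Va_lipid", "II"], ["Xa_Va_II_lipid"], "k30", "k29"),
    _irr("R23", E, ["Xa_Va_II_lipid"], ["Xa_Va_lipid", "mIIa"], ["k31"]),
    _irr("R24", E, ["mIIa", "Xa_Va_lipid"], ["IIa", "Xa_Va_lipid"], ["k32"]),
    _rev("R25", E, ["Xa", "TFPI"], ["Xa_TFPI"], "k34", "k33"),
    _rev("R26", E, ["TF_VIIa_Xa", "TFPI"], ["TF_VIIa_Xa_TFPI"], "k36", "k35"),
    _irr("R27", E, ["TF_VIIa", "Xa_TFPI"], ["TF_VIIa_Xa_TFPI"], ["k37"]),
    _irr("R28", E, ["Xa", "ATIII"], ["Xa_ATIII"], ["k38"]),
    _irr("R29", E, ["mIIa", "ATIII"], ["mIIa_ATIII"], ["k39"]),
    _irr("R30", E, ["IXa", "ATIII"], ["IXa_ATIII"], ["k40"]),
    _irr("R31", E, ["IIa", "ATIII"], ["IIa_ATIII"], ["k41"]),
    _irr("R32", E, ["TF_VIIa", "ATIII"], ["TF_VIIa_ATIII"], ["k42"]),
    # ---- intrinsic (contact) pathway ----
    _irr("R33", K, ["XIIa", "XI"], ["XIIa", "XIa"], ["Kog1"]),
    _irr("R34", K, ["XIa", "IX"], ["XIa", "IXa"], ["Kog2"]),
    _irr("R35", K, ["IXa", "X"], ["IXa", "Xa"], ["Kog3"]),
    _irr("R36", K, ["IIa", "XI"], ["IIa", "XIa"], ["Kog4"]),
    _irr("R37", K, ["XIa", "ATIII"], ["XIa_ATIII"], ["Kog5"]),
    _irr("R38", K, ["XIIa"], ["XIIa_inact"], ["Kog6"]),
    _irr("R34d", K, ["XIa_lipid", "IX"], ["XIa_lipid", "IXa"], ["Kog2d"]),
    _irr("R35d", K, ["IXa_lipid", "X"], ["IXa_lipid", "Xa"], ["Kog3d"]),
    # ---- fibrinogen cleavage (second clot threshold species) ----
    _irr("RI", F, ["IIa", "I"], ["IIa", "Ia"], ["kRI"]),
    # ---- protein C/S negative feedback ----
    _rev("RBu1", B, ["IIa", "Tm"], ["IIa_Tm"], "kBu1_on", "kBu1_off"),
    _irr("RBu2", B, ["IIa_Tm", "PC"], ["IIa_Tm", "APC"], ["kBu2"]),
    _rev("RBu3", B, ["APC", "PS"], ["APC_PS"], "kBu3_on", "kBu3_off"),
    _irr("RBu4", B, ["APC_PS", "Va"], ["APC_PS", "Va_inact"], ["kBu4"]),
    _irr("RBu4a", B, ["APC_PS", "VIIIa"], ["APC_PS", "VIIIa_inact"], ["kBu4a"]),
    _irr("RBu4b", B, ["APC_PS", "Va_lipid"], ["APC_PS", "Va_inact", "PhosphoLipid"],
         ["kBu4b"]),
    _irr("RBu5", B, ["APC"], ["APC_inact"], ["kBu5"]),
    # ---- adsorption to phospholipid sites ----
    _rev("Rad1", A, ["Xa", "PhosphoLipid"], ["Xa_lipid"], "kad1_on", "kad1_off"),
    _rev("Rad2", A, ["Va", "PhosphoLipid"], ["Va_lipid"], "kad2_on", "kad2_off"),
    _rev("Rad3", A, ["IXa", "PhosphoLipid"], ["IXa_lipid"], "kad3_on", "kad3_off"),
    _rev("Rad4", A, ["XIa", "PhosphoLipid"], ["XIa_lipid"], "kad4_on", "kad4_off"),
    # duplicated reactions for lipid-bound components
    _irr("R9d", A, ["Xa_lipid", "II"], ["Xa_lipid", "IIa"], ["k16d"]),
    _irr("R28d", A, ["Xa_lipid", "ATIII"], ["Xa_ATIII", "PhosphoLipid"], ["k38d"]),
    _irr("R30d", A, ["IXa_lipid", "ATIII"], ["IXa_ATIII", "PhosphoLipid"], ["k40d"]),
    # ---- von Willebrand factor ----
    _rev("Rvwf1", W, ["VIII", "vWF"], ["VIII_vWF"], "kvwf_on", "kvwf_off"),
    _irr("Rvwf2", W, ["IIa", "VIII_vWF"], ["IIa", "VIIIa", "vWF"], ["kvwf_act"]),
]


def build_model_definition() -> dict[str, Any]:
    """The canonical model-definition document (JSON-serialisable)."""
    return {
        "format_version": FORMAT_VERSION,
        "lipid": {"molecules_per_site": MOLECULES_PER_SITE,
                  "site_species": "PhosphoLipid"},
        "species": [dict(s) for s in SPECIES],
        "reactions": [dict(r) for r in REACTIONS],
        "parameters": [dict(p) for p in PARAMETERS],
    }
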