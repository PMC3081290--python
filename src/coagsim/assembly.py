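"""Loading, validation and preparation of the coagulation model.

The model ships as a single JSON document (``data/coagulation_model.json``)
holding species, reactions, rate-law terms and provenance-tagged
parameters; an equivalent TSV triple can be exported for auditing.  This
module also implements the scenario preparation steps shared by the
virtual assays: plasma dilution, Factor V preactivation and the
conversion of phospholipid molecule concentrations into vesicle
binding-site concentrations (333 molecules per site).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

from . import model_data
from .network import (
    ModelValidationError,
    NetworkModel,
    ParameterSet,
    RateLaw,
    RateTerm,
    ReactionDef,
    SpeciesDef,
)

__all__ = [
    "LipidConfig",
    "load_model",
    "model_to_definition",
    "write_model_json",
    "write_model_tsv",
    "dilute",
    "preactivate_factor_v",
    "lipid_sites",
]

SUPPORTED_FORMAT_VERSIONS = (1,)

PROVENANCE_TAGS = ("supplement", "source-model", "external-constant", "fitted-here")


@dataclass(frozen=True)
class LipidConfig:
    """Phospholipid vesicles expose one protein-binding site per 333 molecules."""

    molecules_per_site: float = model_data.MOLECULES_PER_SITE
    site_species: str = "PhosphoLipid"

    def __post_init__(self) -> None:
        if self.molecules_per_site <= 0:
            raise ValueError("molecules_per_site must be positive")


def _definition_to_model(definition: Mapping[str, Any]) -> NetworkModel:
    version = definition.get("format_version")
    if version not in SUPPORTED_FORMAT_VERSIONS:
        raise ModelValidationError(f"unsupported model format version: {version!r}")

    species = []
    for entry in definition["species"]:
        try:
            species.append(
                SpeciesDef(
                    name=entry["name"],
                    initial_concentration=float(entry.get("initial", 0.0)),
                    mobile=bool(entry.get("mobile", True)),
                    lipid_bound=bool(entry.get("lipid_bound", False)),
                    constant=bool(entry.get("constant", False)),
                )
            )
        except KeyError as exc:
            raise ModelValidationError(f"species entry missing field {exc}") from None

    values: dict[str, float] = {}
    provenance: dict[str, str] = {}
    for entry in definition["parameters"]:
        sym = entry["symbol"]
        if sym in values:
            raise ModelValidationError(f"duplicate parameter symbol {sym!r}")
        tag = entry.get("provenance")
        if tag not in PROVENANCE_TAGS:
            raise ModelValidationError(
                f"parameter {sym!r}: missing or unknown provenance tag {tag!r}"
            )
        values[sym] = float(entry["value"])
        provenance[sym] = tag

    reactions = []
    for entry in definition["reactions"]:
        try:
            terms = tuple(
                RateTerm(int(sign), tuple(consts), tuple(specs))
                for sign, consts, specs in entry["rate"]
            )
            reactions.append(
                ReactionDef(
                    id=entry["id"],
                    reactants=tuple((s, int(c)) for s, c in entry["reactants"]),
                    products=tuple((s, int(c)) for s, c in entry["products"]),
                    rate=RateLaw(terms),
                    group=entry.get("group", ""),
                )
            )
        except KeyError as exc:
            raise ModelValidationError(
                f"reaction entry {entry.get('id', '?')!r} missing field {exc}"
            ) from None

    model = NetworkModel(species, reactions, ParameterSet(values, provenance))
    lipid = definition.get("lipid", {})
    model.lipid = LipidConfig(  # type: ignore[attr-defined]
        molecules_per_site=float(lipid.get("molecules_per_site",
                                           model_data.MOLECULES_PER_SITE)),
        site_species=lipid.get("site_species", "PhosphoLipid"),
    )
    return model


def load_model(source: str | Path | Mapping[str, Any] | None = None) -> NetworkModel:
    """Load and validate the coagulation model.

    ``source`` may be a path to a model-definition JSON file, an
    already-parsed definition mapping, or ``None`` for the packaged
    canonical model.  Validation is total: undeclared species, missing
    rate constants, duplicate ids and missing provenance tags all raise
    :class:`ModelValidationError` naming the offending entry.
    """
    if source is None:
        ref = resources.files("coagsim").joinpath("data/coagulation_model.json")
        definition = json.loads(ref.read_text())
    elif isinstance(source, (str, Path)):
        definition = json.loads(Path(source).read_text())
    else:
        definition = source
    return _definition_to_model(definition)


def model_to_definition(model: NetworkModel) -> dict[str, Any]:
    """Serialise a model back to the JSON definition structure."""
    lipid = getattr(model, "lipid", LipidConfig())
    return {
        "format_version": model_data.FORMAT_VERSION,
        "lipid": {"molecules_per_site": lipid.molecules_per_site,
                  "site_species": lipid.site_species},
        "species": [
            {
                "name": s.name,
                "initial": s.initial_concentration,
                "mobile": s.mobile,
                "lipid_bound": s.lipid_bound,
                "constant": s.constant,
            }
            for s in model.species
        ],
        "reactions": [
            {
                "id": r.id,
                "group": r.group,
                "reactants": [[s, c] for s, c in r.reactants],
                "products": [[s, c] for s, c in r.products],
                "rate": [
                    [t.sign, list(t.constants), list(t.species)] for t in r.rate.terms
                ],
            }
            for r in model.reactions
        ],
        "parameters": [
            {
                "symbol": sym,
                "value": val,
                "provenance": model.parameters.provenance.get(sym, "source-model"),
            }
            for sym, val in model.parameters.values.items()
        ],
    }


def write_model_json(model: NetworkModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model_to_definition(model), indent=1) + "\n")


def write_model_tsv(model: NetworkModel, directory: str | Path) -> None:
    """Export the species/reactions/parameters tables as three TSV files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "species.tsv", "w") as fh:
        fh.write("name\tinitial_mol_per_l\tmobile\tlipid_bound\tconstant\n")
        for s in model.species:
            fh.write(
                f"{s.name}\t{s.initial_concentration!r}\t{s.mobile}\t"
                f"{s.lipid_bound}\t{s.constant}\n"
            )
    with open(directory / "reactions.tsv", "w") as fh:
        fh.write("id\tgroup\treactants\tproducts\trate\n")
        for r in model.reactions:
            lhs = " + ".join(f"{c}*{s}" if c > 1 else s for s, c in r.reactants)
            rhs = " + ".join(f"{c}*{s}" if c > 1 else s for s, c in r.products)
            rate = " ".join(
                ("+" if t.sign > 0 else "-")
                + "*".join((*t.constants, *t.species))
                for t in r.rate.terms
            )
            fh.write(f"{r.id}\t{r.group}\t{lhs}\t{rhs}\t{rate}\n")
    with open(directory / "parameters.tsv", "w") as fh:
        fh.write("symbol\tvalue\tprovenance\n")
        for sym, val in model.parameters.values.items():
            fh.write(f"{sym}\t{val!r}\t{model.parameters.provenance.get(sym, '')}\n")


# ---------------------------------------------------------------------------
# scenario preparation
# ---------------------------------------------------------------------------


def dilute(initials: Mapping[str, float], factor: float) -> dict[str, float]:
    """Multiply every plasma concentration by ``factor`` (in-vitro dilution).

    The albumin pool used for drug protein binding is a species in
    ``initials`` and is scaled identically, which is what raises the
    unbound drug fraction in diluted assays.  Trigger and reagent
    species are set to their final in-assay concentrations *after* this
    step by the assay drivers, so they are never further diluted.
    """
    if not 0 < factor <= 1:
        raise ValueError(f"dilution factor must be in (0, 1], got {factor}")
    return {name: value * factor for name, value in initials.items()}


def preactivate_factor_v(
    initials: Mapping[str, float], fraction: float = 0.01
) -> dict[str, float]:
    """Move ``fraction`` of Factor V into Factor Va (total V moiety unchanged)."""
    if not 0 <= fraction <= 1:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    out = dict(initials)
    moved = out.get("V", 0.0) * fraction
    out["V"] = out.get("V", 0.0) - moved
    out["Va"] = out.get("Va", 0.0) + moved
    return out


def lipid_sites(lipid_molecules: float, cfg: LipidConfig | None = None) -> float:
    """Phospholipid molecule concentration -> binding-site concentration."""
    if lipid_molecules < 0:
        raise ValueError("lipid concentration must be non-negative")
    cfg = cfg or LipidConfig()
    return lipid_molecules / cfg.molecules_per_site
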