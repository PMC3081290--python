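"""Anticoagulant benchmarking: clotting times and alpha_crit per regimen.

Every dosing regimen (drug at its C_trough / C_mean / C_max plasma
levels, or warfarin titrated to a target INR) is run against the panel
of four physiologically plausible trigger scenarios, for two metrics:

``clot_time``
    clotting time of the static (no-flow) system under the scenario's
    trigger;
``alpha_crit``
    the lowest flow coupling that suppresses the coagulation event.

Warfarin titrated to INR 3 is the safety reference, warfarin at INR 1.5
the efficacy reference.  Under the clot-time metric a therapy is *safe*
if its strong-extrinsic clotting time does not exceed the INR-3
reference and *efficacious* if it reaches at least the INR-1.5
reference in all three efficacy scenarios; under the alpha_crit metric
both inequalities flip (more anticoagulation means a clot is suppressed
by less flow).  Flags are assigned at C_mean; the C_trough-C_max spread
is reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .drugs import DrugState, WarfarinState, mass_to_molar, warfarin_fraction_for_inr
from .flow import (
    SCENARIOS,
    ClotDecision,
    NoClotAtRestError,
    TriggerScenario,
    alpha_crit,
    run_scenario,
)
from .network import NetworkModel, SimControls

__all__ = [
    "Regimen",
    "ReferenceTherapy",
    "load_regimens",
    "benchmark",
    "classify",
    "therapeutic_window",
    "warfarin_comparison_curve",
]

EFFICACY_SCENARIOS = ("extrinsic_weak", "intrinsic_strong", "intrinsic_weak")
SAFETY_SCENARIO = "extrinsic_strong"


@dataclass(frozen=True)
class Regimen:
    """One dosing regimen with its plasma levels (Table-style input)."""

    drug: str
    label: str
    unit: str  # ug/l, mg/l, uM or INR
    cmax: float | None = None
    cmean: float | None = None
    ctrough: float | None = None
    inr: float | None = None  # warfarin rows only
    daily_dose_mg: float | None = None

    def __post_init__(self) -> None:
        levels = [x for x in (self.ctrough, self.cmean, self.cmax) if x is not None]
        if levels != sorted(levels):
            raise ValueError(
                f"regimen {self.drug} {self.label!r}: requires "
                "C_trough <= C_mean <= C_max"
            )
        if self.unit == "INR" and self.inr is None:
            raise ValueError("warfarin regimen needs a target INR")

    def level(self, which: str) -> float | None:
        return {"cmax": self.cmax, "cmean": self.cmean, "ctrough": self.ctrough}[which]

    def drug_state(self, which: str) -> DrugState | None:
        value = self.level(which)
        if value is None:
            return None
        return DrugState(self.drug, mass_to_molar(self.drug, value, self.unit))


@dataclass(frozen=True)
class ReferenceTherapy:
    """Warfarin reference INRs framing the efficacy/safety window."""

    efficacy_inr: float = 1.5
    safety_inr: float = 3.0

    def __post_init__(self) -> None:
        if not self.safety_inr > self.efficacy_inr:
            raise ValueError("safety INR must exceed efficacy INR")


def load_regimens(path: str | Path | None = None) -> list[Regimen]:
    """Regimen table (packaged TSV mirrors the published dosing table)."""
    if path is None:
        ref = resources.files("coagsim").joinpath("data/regimens.tsv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        def val(x):
            return None if pd.isna(x) else float(x)
        out.append(
            Regimen(
                drug=row.drug,
                label=row.label,
                unit=row.unit,
                cmax=val(row.cmax),
                cmean=val(row.cmean),
                ctrough=val(row.ctrough),
                inr=val(row.inr) if hasattr(row, "inr") else None,
                daily_dose_mg=val(row.daily_dose_mg),
            )
        )
    return out


def _metric_value(
    model: NetworkModel,
    scenario: TriggerScenario,
    metric: str,
    drug: DrugState | None,
    warfarin: WarfarinState | None,
    decision: ClotDecision,
    alpha_rel_tol: float,
    controls: SimControls | None,
) -> float:
    if metric == "clot_time":
        out = run_scenario(
            model, scenario, drug=drug, warfarin=warfarin, alpha=0.0,
            decision=decision, controls=controls,
        )
        return out.clotting_time if out.clotted else math.inf
    if metric == "alpha_crit":
        try:
            return alpha_crit(
                model, scenario, drug=drug, warfarin=warfarin,
                rel_tol=alpha_rel_tol, decision=decision, controls=controls,
            ).value
        except NoClotAtRestError:
            return 0.0  # already suppressed without any flow
    raise ValueError(f"unknown metric {metric!r}")


def benchmark(
    model: NetworkModel,
    regimens: Sequence[Regimen],
    scenarios: Mapping[str, TriggerScenario] = SCENARIOS,
    metric: str = "clot_time",
    levels: Sequence[str] = ("cmean", "ctrough", "cmax"),
    decision: ClotDecision | None = None,
    alpha_rel_tol: float = 1e-2,
    controls: SimControls | None = None,
    include_control: bool = True,
) -> pd.DataFrame:
    """Run the regimen x scenario grid for one metric.

    Returns a tidy frame with one row per (regimen, scenario) carrying
    the metric at each requested level; warfarin INR rows have a single
    value (stored under every level column).  Infinite clotting time
    encodes "no clot within the horizon"; alpha_crit 0 encodes "already
    suppressed at rest".  Deterministic: identical input gives an
    identical table.
    """
    decision = decision or ClotDecision()
    rows: list[dict] = []
    warfarin_cache: dict[float, float] = {}

    def warfarin_state(target_inr: float) -> WarfarinState:
        if target_inr not in warfarin_cache:
            warfarin_cache[target_inr] = warfarin_fraction_for_inr(
                model, target_inr, controls=controls
            )
        return WarfarinState(warfarin_cache[target_inr])

    work: list[tuple[str, str, float | None, object]] = []
    if include_control:
        work.append(("control", "control", None, None))
    for reg in regimens:
        work.append((reg.drug, reg.label, reg.daily_dose_mg, reg))

    for drug_name, label, daily_dose, reg in work:
        for sc_name, scenario in scenarios.items():
            row: dict = {
                "drug": drug_name,
                "label": label,
                "daily_dose_mg": daily_dose,
                "scenario": sc_name,
                "metric": metric,
            }
            for level in levels:
                if reg is None:  # drug-free control
                    drug = warf = None
                elif reg.unit == "INR":
                    drug, warf = None, warfarin_state(reg.inr)
                else:
                    drug, warf = reg.drug_state(level), None
                    if drug is None:
                        row[level] = math.nan  # missing level: flagged partial
                        continue
                row[level] = _metric_value(
                    model, scenario, metric, drug, warf, decision,
                    alpha_rel_tol, controls,
                )
            rows.append(row)
    return pd.DataFrame(rows)


def classify(
    table: pd.DataFrame,
    refs: ReferenceTherapy = ReferenceTherapy(),
    level: str = "cmean",
) -> pd.DataFrame:
    """Safe/efficacious flags per regimen against the warfarin references.

    Requires the warfarin INR-1.5 and INR-3.0 rows in the table.  Order
    of rows does not affect the outcome.
    """
    metric = table["metric"].iloc[0]
    if not (table["metric"] == metric).all():
        raise ValueError("mixed metrics in one table")

    def ref_value(target_inr: float, scenario: str) -> float:
        label = f"INR {target_inr:.1f}"
        sel = table[(table["drug"] == "warfarin") & (table["label"] == label)
                    & (table["scenario"] == scenario)]
        if sel.empty:
            raise ValueError(f"missing warfarin reference row {label!r}")
        return float(sel[level].iloc[0])

    out_rows = []
    for (drug, label), sub in table.groupby(["drug", "label"], sort=False):
        if drug == "control":
            continue
        by_scenario = {r["scenario"]: float(r[level]) for _, r in sub.iterrows()}
        if metric == "clot_time":
            safe = by_scenario[SAFETY_SCENARIO] <= ref_value(
                refs.safety_inr, SAFETY_SCENARIO
            )
            efficacious = all(
                by_scenario[sc] >= ref_value(refs.efficacy_inr, sc)
                for sc in EFFICACY_SCENARIOS
            )
        else:  # alpha_crit: inequalities invert
            safe = by_scenario[SAFETY_SCENARIO] >= ref_value(
                refs.safety_inr, SAFETY_SCENARIO
            )
            efficacious = all(
                by_scenario[sc] <= ref_value(refs.efficacy_inr, sc)
                for sc in EFFICACY_SCENARIOS
            )
        daily = sub["daily_dose_mg"].iloc[0]
        out_rows.append(
            {"drug": drug, "label": label, "daily_dose_mg": daily,
             "safe": bool(safe), "efficacious": bool(efficacious)}
        )
    return pd.DataFrame(out_rows)


@dataclass
class TherapeuticWindow:
    """Dose window from the flag pattern over one drug's regimens."""

    min_efficacious_daily_dose: float | None
    max_safe_daily_dose: float | None
    empty: bool
    anomalies: list[str]


def therapeutic_window(flags: pd.DataFrame, drug: str = "rivaroxaban") -> TherapeuticWindow:
    """Window endpoints (total daily dose, mg) from the safe/efficacious flags.

    Non-monotone flag patterns over dose are reported, not masked.
    """
    sub = flags[(flags["drug"] == drug) & flags["daily_dose_mg"].notna()]
    sub = sub.sort_values("daily_dose_mg")
    if sub.empty:
        raise ValueError(f"no dosed regimens for {drug!r}")
    eff = sub[sub["efficacious"]]
    safe = sub[sub["safe"]]
    anomalies: list[str] = []
    eff_seq = list(sub["efficacious"])
    if eff_seq != sorted(eff_seq):  # False..True expected with dose
        anomalies.append("efficacy flags not monotone in daily dose")
    safe_seq = list(sub["safe"])
    if safe_seq != sorted(safe_seq, reverse=True):  # True..False expected
        anomalies.append("safety flags not monotone in daily dose")
    if eff.empty or safe.empty:
        return TherapeuticWindow(None, None, True, anomalies)
    lo = float(eff["daily_dose_mg"].min())
    hi = float(safe["daily_dose_mg"].max())
    return TherapeuticWindow(lo, hi, lo > hi, anomalies)


def warfarin_comparison_curve(
    model: NetworkModel,
    tf_grid: Iterable[float],
    rivaroxaban_levels_ugl: tuple[float, float] = (13.66, 195.15),
    warfarin_inrs: tuple[float, float] = (1.5, 3.0),
    decision: ClotDecision | None = None,
    controls: SimControls | None = None,
) -> pd.DataFrame:
    """Clotting time vs TF trigger concentration, as therapy bands.

    For each TF value the static clotting time is computed for
    rivaroxaban at C_trough and C_max of one regimen and for warfarin at
    the two reference INRs — the band data behind the TF-sensitivity
    comparison of the two mechanisms.
    """
    decision = decision or ClotDecision()
    states: list[tuple[str, DrugState | None, WarfarinState | None]] = [
        ("control", None, None)
    ]
    for ugl in rivaroxaban_levels_ugl:
        states.append(
            (f"rivaroxaban {ugl:g} ug/l",
             DrugState("rivaroxaban", mass_to_molar("rivaroxaban", ugl)), None)
        )
    for target in warfarin_inrs:
        f = warfarin_fraction_for_inr(model, target, controls=controls)
        states.append((f"warfarin INR {target:g}", None, WarfarinState(f)))
    rows = []
    for tf in tf_grid:
        scenario = TriggerScenario(f"TF {tf:g}", tf=tf)
        for name, drug, warf in states:
            out = run_scenario(
                model, scenario, drug=drug, warfarin=warf, alpha=0.0,
                decision=decision, controls=controls,
            )
            rows.append(
                {"tf_mol_per_l": tf, "therapy": name,
                 "clot_time_s": out.clotting_time if out.clotted else math.inf}
            )
    return pd.DataFrame(rows)
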