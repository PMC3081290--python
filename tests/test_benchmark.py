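"""Regimen table, benchmarking grid, classification and dose window."""

import math

import pandas as pd
import pytest

from coagsim.benchmark import (
    Regimen,
    ReferenceTherapy,
    TherapeuticWindow,
    benchmark,
    classify,
    load_regimens,
    therapeutic_window,
    warfarin_comparison_curve,
)
from coagsim.flow import SCENARIOS


@pytest.fixture(scope="module")
def regimens():
    return load_regimens()


@pytest.fixture(scope="module")
def small_table(model, regimens):
    """Clot-time grid for two rivaroxaban regimens + warfarin references."""
    keep = [r for r in regimens
            if (r.drug == "rivaroxaban" and r.label in ("5 OD", "20 BD"))
            or (r.drug == "warfarin" and r.inr in (1.5, 3.0))]
    return benchmark(model, keep, metric="clot_time", levels=("cmean",))


class TestRegimenTable:
    def test_level_ordering_holds_for_every_row(self, regimens):
        for reg in regimens:
            levels = [x for x in (reg.ctrough, reg.cmean, reg.cmax)
                      if x is not None]
            assert levels == sorted(levels), reg.label

    def test_misordered_levels_rejected(self):
        with pytest.raises(ValueError):
            Regimen("rivaroxaban", "bad", "ug/l", cmax=1.0, cmean=2.0, ctrough=0.5)

    def test_high_dose_rows_double_the_20mg_exposure(self, regimens):
        by = {(r.drug, r.label): r for r in regimens}
        assert by[("rivaroxaban", "53 OD")].cmean == pytest.approx(
            2 * by[("rivaroxaban", "20 OD")].cmean, rel=0.01
        )
        assert by[("rivaroxaban", "53 BD")].cmean == pytest.approx(
            2 * by[("rivaroxaban", "20 BD")].cmean, rel=0.01
        )

    def test_warfarin_rows_carry_inr_not_levels(self, regimens):
        warf = [r for r in regimens if r.drug == "warfarin"]
        assert {r.inr for r in warf} == {1.5, 2.0, 2.5, 3.0, 3.5, 4.0}
        assert all(r.cmean is None for r in warf)

    def test_infusion_rows_are_constant_levels(self, regimens):
        dx = [r for r in regimens if r.drug == "DX-9065a"]
        assert len(dx) == 2
        for r in dx:
            assert r.cmax == r.cmean == r.ctrough


class TestBenchmark:
    def test_control_clots_fastest(self, small_table):
        for sc in SCENARIOS:
            sub = small_table[small_table["scenario"] == sc]
            control = float(sub[sub["drug"] == "control"]["cmean"].iloc[0])
            others = sub[sub["drug"] != "control"]["cmean"]
            assert (others >= control).all()

    def test_dose_ordering_of_prolongation(self, small_table):
        sc = small_table[small_table["scenario"] == "extrinsic_strong"]
        lo = float(sc[sc["label"] == "5 OD"]["cmean"].iloc[0])
        hi = float(sc[sc["label"] == "20 BD"]["cmean"].iloc[0])
        assert hi >= lo

    def test_deterministic_table(self, model, regimens, small_table):
        keep = [r for r in regimens
                if (r.drug == "rivaroxaban" and r.label in ("5 OD", "20 BD"))
                or (r.drug == "warfarin" and r.inr in (1.5, 3.0))]
        again = benchmark(model, keep, metric="clot_time", levels=("cmean",))
        pd.testing.assert_frame_equal(small_table, again)


class TestClassify:
    def test_warfarin_references_sit_on_their_boundaries(self, small_table):
        flags = classify(small_table)
        warf = flags[flags["drug"] == "warfarin"].set_index("label")
        assert bool(warf.loc["INR 3.0", "safe"])  # reflexive, <=
        assert bool(warf.loc["INR 1.5", "efficacious"])  # reflexive

    def test_row_order_invariance(self, small_table):
        shuffled = small_table.sample(frac=1.0, random_state=7).reset_index(drop=True)
        a = classify(small_table).sort_values(["drug", "label"]).reset_index(drop=True)
        b = classify(shuffled).sort_values(["drug", "label"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_reference_rows_raise(self, small_table):
        no_refs = small_table[small_table["drug"] != "warfarin"]
        with pytest.raises(ValueError, match="reference"):
            classify(no_refs)

    def test_reference_inr_ordering_enforced(self):
        with pytest.raises(ValueError):
            ReferenceTherapy(efficacy_inr=3.0, safety_inr=1.5)


class TestTherapeuticWindow:
    @staticmethod
    def _flags(rows):
        return pd.DataFrame(
            rows, columns=["drug", "label", "daily_dose_mg", "safe", "efficacious"]
        )

    def test_window_endpoints_are_simulated_doses(self):
        flags = self._flags([
            ("rivaroxaban", "a", 5.0, True, False),
            ("rivaroxaban", "b", 20.0, True, True),
            ("rivaroxaban", "c", 40.0, True, True),
            ("rivaroxaban", "d", 106.0, False, True),
        ])
        w = therapeutic_window(flags)
        assert w.min_efficacious_daily_dose == 20.0
        assert w.max_safe_daily_dose == 40.0
        assert not w.empty and not w.anomalies

    def test_all_safe_none_efficacious_is_empty_window(self):
        flags = self._flags([
            ("rivaroxaban", "a", 5.0, True, False),
            ("rivaroxaban", "b", 20.0, True, False),
        ])
        w = therapeutic_window(flags)
        assert w.empty
        assert w.min_efficacious_daily_dose is None

    def test_non_monotone_patterns_are_reported(self):
        flags = self._flags([
            ("rivaroxaban", "a", 5.0, True, True),
            ("rivaroxaban", "b", 20.0, True, False),
            ("rivaroxaban", "c", 40.0, False, True),
        ])
        w = therapeutic_window(flags)
        assert w.anomalies


@pytest.fixture(scope="module")
def bands(model):
    return warfarin_comparison_curve(model, tf_grid=(1e-14, 1e-12, 1e-11))


class TestWarfarinComparison:
    def test_clot_time_decreases_with_trigger_strength(self, bands):
        for therapy, sub in bands.groupby("therapy"):
            times = sub.sort_values("tf_mol_per_l")["clot_time_s"].tolist()
            finite = [t for t in times if math.isfinite(t)]
            assert all(b <= a for a, b in zip(finite, finite[1:]))

    def test_therapies_prolong_over_control(self, bands):
        for tf, sub in bands.groupby("tf_mol_per_l"):
            control = float(
                sub[sub["therapy"] == "control"]["clot_time_s"].iloc[0]
            )
            assert (sub["clot_time_s"] >= control - 1e-9).all()
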