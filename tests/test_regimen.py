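import datetime as dt

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from asthmasteps import (
    DoseBand,
    MedicationClass,
    Regimen,
    apply_run_in,
    build_events,
    build_regimen,
    condense_same_day,
)

START = dt.date(2009, 1, 31)


def history(rows):
    return pd.DataFrame(
        rows,
        columns=["patient_id", "prescribed_date", "medication_key",
                 "medication_class", "daily_dose_mcg"],
    )


def rx(day, key, cls, dose=None, patient="P1"):
    return {
        "patient_id": patient,
        "prescribed_date": START + dt.timedelta(days=day),
        "medication_key": key,
        "medication_class": cls,
        "daily_dose_mcg": dose,
    }


class TestBuildRegimen:
    def test_ics_plus_laba_within_window(self, catalogue_map):
        h = history([rx(0, "beclometasone", "ICS", 400),
                     rx(60, "salmeterol", "LABA")])
        regimen = build_regimen(h, START + dt.timedelta(days=100), catalogue_map)
        assert regimen.ics_band == DoseBand.LOW
        assert regimen.addons == {MedicationClass.LABA}
        assert regimen.label == "Low-strength ICS + LABA"

    def test_saba_only_regimen(self, catalogue_map):
        h = history([rx(10, "salbutamol", "SABA")])
        regimen = build_regimen(h, START + dt.timedelta(days=20), catalogue_map)
        assert regimen.saba_only
        assert regimen.ics_band == DoseBand.NONE and not regimen.addons
        assert regimen.label == "SABA"

    def test_old_ics_outside_window_ignored(self, catalogue_map):
        h = history([rx(0, "beclometasone", "ICS", 400),
                     rx(110, "salbutamol", "SABA")])
        regimen = build_regimen(h, START + dt.timedelta(days=121), catalogue_map)
        assert regimen.saba_only
        # day 120 still inside the inclusive 120-day window
        regimen = build_regimen(h, START + dt.timedelta(days=119), catalogue_map)
        assert regimen.ics_band == DoseBand.LOW

    def test_empty_window_yields_no_regimen(self, catalogue_map):
        h = history([rx(300, "beclometasone", "ICS", 400)])
        assert build_regimen(h, START + dt.timedelta(days=100), catalogue_map) is None

    def test_combination_inhaler_contributes_band_and_laba(self, catalogue_map):
        h = history([rx(0, "fluticasone-salmeterol", "ICS_LABA", 1000)])
        regimen = build_regimen(h, START + dt.timedelta(days=10), catalogue_map)
        assert regimen.ics_band == DoseBand.HIGH
        assert regimen.addons == {MedicationClass.LABA}
        assert regimen.label == "High-strength ICS + LABA"

    def test_most_recent_prescription_per_product_sets_band(self, catalogue_map):
        h = history([rx(0, "beclometasone", "ICS", 1000),
                     rx(50, "beclometasone", "ICS", 400)])
        regimen = build_regimen(h, START + dt.timedelta(days=60), catalogue_map)
        assert regimen.ics_band == DoseBand.LOW

    def test_max_band_across_concurrent_products(self, catalogue_map):
        h = history([rx(0, "beclometasone", "ICS", 400),
                     rx(10, "fluticasone", "ICS", 1000)])
        regimen = build_regimen(h, START + dt.timedelta(days=20), catalogue_map)
        assert regimen.ics_band == DoseBand.HIGH

    def test_solution_steroid_counts_as_other_controller(self, catalogue_map):
        h = history([rx(0, "budesonide", "ORAL_OR_NEB_STEROID", 500)])
        regimen = build_regimen(h, START + dt.timedelta(days=5), catalogue_map)
        assert regimen.ics_band == DoseBand.NONE
        assert regimen.addons == {MedicationClass.OTHER_CONTROLLER}

    @given(st.permutations(range(4)))
    def test_row_order_never_changes_the_regimen(self, catalogue_map, order):
        rows = [rx(0, "beclometasone", "ICS", 400),
                rx(30, "salmeterol", "LABA"),
                rx(60, "montelukast", "LTRA", 10000),
                rx(90, "salbutamol", "SABA")]
        h = history([rows[i] for i in order])
        regimen = build_regimen(h, START + dt.timedelta(days=100), catalogue_map)
        assert regimen.ics_band == DoseBand.LOW
        assert regimen.addons == {MedicationClass.LABA, MedicationClass.LTRA}

    def test_saba_never_in_addons(self, catalogue_map):
        h = history([rx(0, "beclometasone", "ICS", 400),
                     rx(1, "salbutamol", "SABA")])
        regimen = build_regimen(h, START + dt.timedelta(days=10), catalogue_map)
        assert MedicationClass.SABA not in regimen.addons
        assert not regimen.saba_only


class TestCondenseAndEvents:
    def test_same_day_prescriptions_condense_to_one_event(self, catalogue_map):
        h = history([rx(10, "beclometasone", "ICS", 400),
                     rx(10, "salbutamol", "SABA")])
        events = condense_same_day(h)
        assert len(events) == 1
        built = build_events(h, catalogue_map)
        assert len(built) == 1
        assert built["ics_band"].iloc[0] == "LOW"

    def test_duplicate_product_rows_count_once(self, catalogue_map):
        h = history([rx(10, "beclometasone", "ICS", 400),
                     rx(10, "beclometasone", "ICS", 400)])
        built = build_events(h, catalogue_map)
        assert len(built) == 1
        assert built["ics_band"].iloc[0] == "LOW"

    def test_empty_input(self, catalogue_map):
        assert condense_same_day(history([])).empty
        assert build_events(history([]), catalogue_map).empty


class TestRunIn:
    def test_boundary_days(self):
        events = pd.DataFrame(
            {"patient_id": ["P1"] * 3,
             "event_date": [START + dt.timedelta(days=d) for d in (119, 120, 200)]}
        )
        kept = apply_run_in(events, START, window_days=120)
        days = [(d - START).days for d in pd.to_datetime(kept["event_date"]).dt.date]
        assert days == [120, 200]

    def test_empty_events(self):
        assert apply_run_in(pd.DataFrame(), START).empty


class TestRegimenInvariants:
    def test_saba_only_regimen_is_consistent(self):
        with pytest.raises(ValueError):
            Regimen(DoseBand.LOW, frozenset(), saba_only=True)

    def test_label_is_pure_function_of_fields(self):
        a = Regimen(DoseBand.HIGH, frozenset({MedicationClass.LABA, MedicationClass.LTRA}))
        b = Regimen(DoseBand.HIGH, frozenset({MedicationClass.LTRA, MedicationClass.LABA}))
        assert a.label == b.label == "High-strength ICS + LABA + LTRA"
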