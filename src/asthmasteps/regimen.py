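"""Assemble treatment regimens from prescriptions in a 120-day lookback window.

A *prescription event* is any day on which a patient has at least one retained
asthma prescription.  The regimen at an event is the combination of controller
therapies prescribed in the lookback window ending on (and including) the
event day: the ICS dose band plus the set of non-ICS controller classes.
SABA is a reliever and never counts as an add-on; it only marks the
SABA-only regimen.  A run-in period at the start of the study is discarded so
that staggered refills have had time to accumulate into a full regimen.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .banding import DoseBand, band_for_entry
from .catalog import ADDON_CLASSES, ICS_CLASSES, MedicationClass, MedicationEntry

__all__ = [
    "DEFAULT_WINDOW_DAYS",
    "Regimen",
    "condense_same_day",
    "build_regimen",
    "build_events",
    "apply_run_in",
]

DEFAULT_WINDOW_DAYS = 120

_ADDON_ORDER = {cls: i for i, cls in enumerate(ADDON_CLASSES)}
_ADDON_LABEL = {
    MedicationClass.LABA: "LABA",
    MedicationClass.LTRA: "LTRA",
    MedicationClass.THEOPHYLLINE: "Theophylline",
    MedicationClass.OTHER_CONTROLLER: "Other controller",
}
_BAND_LABEL = {
    DoseBand.LOW: "Low",
    DoseBand.MEDIUM: "Medium",
    DoseBand.HIGH: "High",
    DoseBand.UNKNOWN: "Unknown",
}


@dataclass(frozen=True)
class Regimen:
    """ICS dose band plus the set of non-ICS controller classes in the window."""

    ics_band: DoseBand
    addons: frozenset[MedicationClass] = field(default_factory=frozenset)
    saba_only: bool = False

    def __post_init__(self) -> None:
        if self.saba_only and (self.ics_band != DoseBand.NONE or self.addons):
            raise ValueError("a SABA-only regimen has no ICS band and no add-ons")
        if not frozenset(self.addons) <= frozenset(ADDON_CLASSES):
            raise ValueError(f"invalid add-on classes: {set(self.addons) - set(ADDON_CLASSES)}")
        object.__setattr__(self, "addons", frozenset(self.addons))

    @property
    def label(self) -> str:
        """Canonical text rendering, e.g. ``"High-strength ICS + LABA + LTRA"``."""
        parts = []
        if self.ics_band != DoseBand.NONE:
            parts.append(f"{_BAND_LABEL[self.ics_band]}-strength ICS")
        parts.extend(
            _ADDON_LABEL[cls]
            for cls in sorted(self.addons, key=_ADDON_ORDER.__getitem__)
        )
        if parts:
            return " + ".join(parts)
        return "SABA" if self.saba_only else "No controller therapy"


def condense_same_day(records: pd.DataFrame) -> pd.DataFrame:
    """One candidate prescription event per (patient, date).

    All of a day's medications still contribute to that day's window content;
    condensing only collapses the event grain so there is at most one regimen
    (and one step) per patient per day.
    """
    if records.empty:
        return pd.DataFrame(columns=["patient_id", "event_date"])
    events = (
        records[["patient_id", "prescribed_date"]]
        .drop_duplicates()
        .rename(columns={"prescribed_date": "event_date"})
        .sort_values(["patient_id", "event_date"], kind="stable")
        .reset_index(drop=True)
    )
    return events


def build_regimen(
    history: pd.DataFrame,
    index_date: dt.date,
    catalogue: Mapping[str, MedicationEntry],
    window_days: int = DEFAULT_WINDOW_DAYS,
) -> Optional[Regimen]:
    """Regimen active in the window ``[index_date - window_days + 1, index_date]``.

    ``history`` needs columns ``prescribed_date``, ``medication_key``,
    ``medication_class`` and ``daily_dose_mcg``.  For each distinct
    ICS-containing product, the most recent prescription's daily dose is
    banded on that product's own thresholds; the regimen's ICS band is the
    maximum band observed (LOW < MEDIUM < HIGH < UNKNOWN).  Returns ``None``
    when the window holds no prescriptions (no event).
    """
    if window_days <= 0:
        raise ValueError("window_days must be positive")
    start = index_date - dt.timedelta(days=window_days - 1)
    dates = pd.to_datetime(history["prescribed_date"]).dt.date
    window = history.loc[(dates >= start) & (dates <= index_date)]
    if window.empty:
        return None
    return _regimen_from_window(
        window["medication_key"].tolist(),
        [MedicationClass(c) for c in window["medication_class"]],
        pd.to_datetime(window["prescribed_date"]).dt.date.tolist(),
        window["daily_dose_mcg"].tolist(),
        catalogue,
    )


def _regimen_from_window(
    keys: list[str],
    classes: list[MedicationClass],
    dates: list[dt.date],
    doses: list[Optional[float]],
    catalogue: Mapping[str, MedicationEntry],
) -> Regimen:
    addons = set()
    saba_seen = False
    ics_latest: dict[str, tuple[dt.date, Optional[float]]] = {}
    for key, cls, date, dose in zip(keys, classes, dates, doses):
        if cls in ICS_CLASSES:
            dose = None if dose is None or pd.isna(dose) else float(dose)
            prev = ics_latest.get(key)
            # most recent wins; same-day ties keep the larger dose (deterministic)
            if (
                prev is None
                or date > prev[0]
                or (date == prev[0] and (prev[1] is None or (dose or 0) > prev[1]))
            ):
                ics_latest[key] = (date, dose)
        if cls == MedicationClass.ICS_LABA:
            addons.add(MedicationClass.LABA)
        elif cls == MedicationClass.ORAL_OR_NEB_STEROID:
            addons.add(MedicationClass.OTHER_CONTROLLER)
        elif cls in _ADDON_ORDER:
            addons.add(cls)
        elif cls == MedicationClass.SABA:
            saba_seen = True

    band = DoseBand.NONE
    for key, (_, dose) in ics_latest.items():
        # a product with no recoverable daily dose cannot be placed in a band
        product_band = (
            band_for_entry(catalogue[key], dose) if dose is not None else DoseBand.UNKNOWN
        )
        if product_band.rank > band.rank:
            band = product_band

    if band == DoseBand.NONE and not addons:
        return Regimen(DoseBand.NONE, frozenset(), saba_only=saba_seen)
    return Regimen(band, frozenset(addons))


def build_events(
    records: pd.DataFrame,
    catalogue: Mapping[str, MedicationEntry],
    window_days: int = DEFAULT_WINDOW_DAYS,
) -> pd.DataFrame:
    """Regimen at every prescription event for every patient.

    ``records`` is the retained-prescription table (columns ``patient_id``,
    ``prescribed_date``, ``medication_key``, ``medication_class``,
    ``daily_dose_mcg``).  Returns one row per (patient, event date) with the
    regimen's band, add-ons and label.  Row order of the input is irrelevant.
    """
    columns = [
        "patient_id", "event_date", "ics_band", "addons", "saba_only", "regimen_label",
    ]
    if records.empty:
        return pd.DataFrame(columns=columns)
    rows = []
    records = records.copy()
    records["prescribed_date"] = pd.to_datetime(records["prescribed_date"]).dt.date
    for patient_id, group in records.groupby("patient_id", sort=True):
        dates = np.array(sorted(group["prescribed_date"]))
        keys = group["medication_key"].to_numpy()
        classes = [MedicationClass(c) for c in group["medication_class"]]
        rec_dates = group["prescribed_date"].to_numpy()
        doses = group["daily_dose_mcg"].to_numpy(dtype=object)
        order = np.argsort(rec_dates, kind="stable")
        keys, rec_dates = keys[order], rec_dates[order]
        classes = [classes[i] for i in order]
        doses = doses[order]
        for event_date in np.unique(dates):
            start = event_date - dt.timedelta(days=window_days - 1)
            lo = np.searchsorted(rec_dates, start, side="left")
            hi = np.searchsorted(rec_dates, event_date, side="right")
            regimen = _regimen_from_window(
                list(keys[lo:hi]),
                classes[lo:hi],
                list(rec_dates[lo:hi]),
                list(doses[lo:hi]),
                catalogue,
            )
            if regimen is None:
                continue
            rows.append(
                {
                    "patient_id": patient_id,
                    "event_date": event_date,
                    "ics_band": regimen.ics_band.value,
                    "addons": ";".join(
                        sorted(c.value for c in regimen.addons)
                    ),
                    "saba_only": regimen.saba_only,
                    "regimen_label": regimen.label,
                }
            )
    return pd.DataFrame(rows, columns=columns)


def apply_run_in(
    events: pd.DataFrame,
    study_start: dt.date,
    window_days: int = DEFAULT_WINDOW_DAYS,
) -> pd.DataFrame:
    """Drop events inside the run-in period (before study_start + window_days).

    An event exactly ``window_days`` after the study start is the first one
    retained, since only then can a full lookback window have accumulated.
    """
    if events.empty:
        return events.copy()
    cutoff = study_start + dt.timedelta(days=window_days)
    dates = pd.to_datetime(events["event_date"]).dt.date
    return events.loc[dates >= cutoff].reset_index(drop=True)
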