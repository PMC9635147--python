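"""End-to-end pipeline: raw prescription table -> steps, episodes, summaries.

Stages run in a fixed order — identify medications, exclude, extract dose
text, impute, validate strengths, band, condense same-day rows, build
120-day-window regimens, classify steps, drop the run-in, and compute
trajectory statistics — with an attrition report counting every record's
disposition.  Malformed rows (no patient identifier or unparseable
prescription date) are quarantined to a reject table, never silently dropped.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .banding import DoseBand, band_for_entry
from .catalog import (
    ExclusionReason,
    ExclusionRule,
    ICS_CLASSES,
    MedicationClass,
    MedicationEntry,
    PrescriptionRecord,
    apply_exclusions,
    load_catalogue,
    load_exclusion_rules,
    match_medication,
    reclassify_solution,
)
from .dose_text import (
    impute_frame_by_mode,
    load_frequency_keywords,
    parse_dose,
    validate_strength,
)
from .regimen import DEFAULT_WINDOW_DAYS, apply_run_in, build_events, condense_same_day
from .steps import StepRuleSet, load_step_rules
from .trajectories import (
    duration_summary_table,
    episodes_table,
    person_year_summary,
    summarise_durations,
    transition_matrix,
)

__all__ = ["AttritionReport", "PipelineResult", "run_pipeline", "summarise_band_mix"]


@dataclass
class AttritionReport:
    """Stage-by-stage accounting of record dispositions.

    Conservation invariant: ``total_input = retained + sum(excluded.values())
    + malformed``; quarantined malformed rows are counted separately from the
    reasoned exclusions.
    """

    total_input: int = 0
    excluded: dict[str, int] = field(default_factory=dict)
    malformed: int = 0
    retained: int = 0
    events_after_condensing: int = 0
    events_after_run_in: int = 0
    unique_patients: int = 0

    def validate(self) -> None:
        if self.total_input != self.retained + sum(self.excluded.values()) + self.malformed:
            raise ValueError(
                "attrition counts do not conserve: "
                f"{self.total_input} != {self.retained} retained "
                f"+ {sum(self.excluded.values())} excluded + {self.malformed} malformed"
            )
        if not (
            self.events_after_run_in <= self.events_after_condensing <= max(self.retained, 0)
        ):
            raise ValueError("event counts must not exceed retained record count")

    def to_dict(self) -> dict:
        return {
            "total_input": self.total_input,
            "excluded": dict(sorted(self.excluded.items())),
            "malformed": self.malformed,
            "retained": self.retained,
            "events_after_condensing": self.events_after_condensing,
            "events_after_run_in": self.events_after_run_in,
            "unique_patients": self.unique_patients,
        }

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


@dataclass
class PipelineResult:
    attrition: AttritionReport
    retained: pd.DataFrame
    exclusions: pd.DataFrame
    rejects: pd.DataFrame
    events: pd.DataFrame
    episodes: pd.DataFrame
    duration_summary: dict
    duration_table: pd.DataFrame
    transitions: pd.DataFrame
    transition_fractions: dict
    person_years: pd.DataFrame
    band_mix: pd.DataFrame

    def write(self, out_dir: Union[str, Path]) -> None:
        """Write all tabular outputs (CSV) and the attrition report (JSON)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.retained.to_csv(out / "retained_prescriptions.csv", index=False)
        self.exclusions.to_csv(out / "excluded_prescriptions.csv", index=False)
        self.rejects.to_csv(out / "rejected_rows.csv", index=False)
        self.events.to_csv(out / "prescription_events.csv", index=False)
        self.episodes.to_csv(out / "step_episodes.csv", index=False)
        self.duration_table.to_csv(out / "duration_summary.csv", index=False)
        self.transitions.stack().rename("count").reset_index().rename(
            columns={"level_0": "step_from", "level_1": "step_to"}
        ).to_csv(out / "step_transitions.csv", index=False)
        self.person_years.to_csv(out / "person_year_summary.csv", index=False)
        self.band_mix.to_csv(out / "band_mix.csv", index=False)
        self.attrition.to_json(out / "attrition_report.json")


def _coerce_date(value) -> Optional[dt.date]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    ts = pd.to_datetime(str(value), errors="coerce")
    return None if pd.isna(ts) else ts.date()


def run_pipeline(
    input_table: Union[pd.DataFrame, str, Path],
    *,
    catalogue: Optional[Union[Sequence[MedicationEntry], str, Path]] = None,
    exclusion_rules: Optional[Union[Sequence[ExclusionRule], str, Path]] = None,
    frequency_keywords: Optional[Union[Sequence[tuple[str, int]], str, Path]] = None,
    step_rules: Optional[Union[StepRuleSet, str, Path]] = None,
    study_start: Optional[dt.date] = None,
    study_end: Optional[dt.date] = None,
    window_days: int = DEFAULT_WINDOW_DAYS,
    run_in_days: Optional[int] = None,
) -> PipelineResult:
    """Run the full classification pipeline over a raw prescription table.

    ``study_start``/``study_end`` default to the observed date range; the
    run-in period (default: one window length) is discarded after regimen
    construction.  Deterministic: identical inputs and configuration yield
    identical outputs.
    """
    frame = (
        input_table.copy()
        if isinstance(input_table, pd.DataFrame)
        else pd.read_csv(input_table, dtype=str)
    )
    entries = catalogue if isinstance(catalogue, (list, tuple)) else load_catalogue(catalogue)
    entry_map = {e.generic_name: e for e in entries}
    rules = (
        exclusion_rules
        if isinstance(exclusion_rules, (list, tuple))
        else load_exclusion_rules(exclusion_rules)
    )
    keywords = (
        frequency_keywords
        if isinstance(frequency_keywords, (list, tuple))
        else load_frequency_keywords(frequency_keywords)
    )
    tree = step_rules if isinstance(step_rules, StepRuleSet) else load_step_rules(step_rules)
    run_in = window_days if run_in_days is None else run_in_days

    report = AttritionReport(
        total_input=len(frame),
        excluded={reason.value: 0 for reason in ExclusionReason},
    )

    if frame.empty:
        return _empty_result(report, tree)

    parsed_dates = [_coerce_date(v) for v in frame.get("prescribed_date", pd.Series(dtype=object))]
    if study_start is None:
        observed = [d for d in parsed_dates if d is not None]
        study_start = min(observed) if observed else dt.date(1900, 1, 1)
    if study_end is None:
        observed = [d for d in parsed_dates if d is not None]
        study_end = max(observed) if observed else dt.date(2100, 1, 1)

    retained_rows, exclusion_rows, reject_rows = [], [], []
    for idx, (row, date) in enumerate(zip(frame.to_dict("records"), parsed_dates)):
        patient_id = row.get("patient_id")
        if patient_id is None or (isinstance(patient_id, float) and pd.isna(patient_id)) \
                or str(patient_id).strip() == "" or date is None:
            reject_rows.append({**row, "reject_reason": "MALFORMED"})
            continue
        record = PrescriptionRecord(
            patient_id=str(patient_id),
            prescribed_date=date,
            medication_name=str(row.get("medication_name") or ""),
            dose_text=str(row.get("dose_text") or ""),
            formulation=row.get("formulation"),
            bnf_code=row.get("bnf_code"),
        )
        entry = match_medication(record.medication_name, entries)
        reason = apply_exclusions(record, entry, rules, (study_start, study_end))
        if reason is not None:
            exclusion_rows.append({**row, "exclusion_reason": reason.value})
            continue
        assert entry is not None
        med_class = reclassify_solution(record, entry)
        parsed = parse_dose(
            record.dose_text,
            record.medication_name,
            keywords,
            is_combo=entry.medication_class == MedicationClass.ICS_LABA,
        )
        retained_rows.append(
            {
                "row_index": idx,
                "patient_id": record.patient_id,
                "prescribed_date": record.prescribed_date,
                "medication_name": record.medication_name,
                "medication_key": entry.generic_name,
                "medication_class": med_class.value,
                "frequency_per_day": parsed.frequency_per_day,
                "quantity_per_dose": parsed.quantity_per_dose,
                "strength_mcg": parsed.strength_mcg,
                "laba_component_mcg": parsed.laba_component_mcg,
            }
        )

    report.malformed = len(reject_rows)
    retained = pd.DataFrame(
        retained_rows,
        columns=["row_index", "patient_id", "prescribed_date", "medication_name",
                 "medication_key", "medication_class", "frequency_per_day",
                 "quantity_per_dose", "strength_mcg", "laba_component_mcg"],
    )

    # mode imputation, then strength validation against licensed strengths
    if not retained.empty:
        retained = impute_frame_by_mode(retained, key_col="medication_key")
        bad = []
        for i, row in retained.iterrows():
            strength = row["strength_mcg"]
            if pd.notna(strength) and not validate_strength(
                entry_map[row["medication_key"]], float(strength)
            ):
                bad.append(i)
        if bad:
            flagged = retained.loc[bad]
            for _, row in flagged.iterrows():
                exclusion_rows.append(
                    {**frame.iloc[int(row["row_index"])].to_dict(),
                     "exclusion_reason": ExclusionReason.STRENGTH_OUT_OF_RANGE.value}
                )
            retained = retained.drop(index=bad).reset_index(drop=True)
        retained["daily_dose_mcg"] = [
            None
            if pd.isna(f) or pd.isna(q) or pd.isna(s)
            else float(f) * float(q) * float(s)
            for f, q, s in zip(
                retained["frequency_per_day"],
                retained["quantity_per_dose"],
                retained["strength_mcg"],
            )
        ]
    else:
        retained["daily_dose_mcg"] = pd.Series(dtype=float)

    exclusions = pd.DataFrame(exclusion_rows)
    for reason_value, count in (
        exclusions["exclusion_reason"].value_counts().items() if not exclusions.empty else []
    ):
        report.excluded[reason_value] = int(count)
    report.retained = len(retained)

    # events, steps, run-in
    candidate_events = condense_same_day(retained)
    report.events_after_condensing = len(candidate_events)
    events = build_events(retained, entry_map, window_days=window_days)
    if not events.empty:
        events["step"] = [
            tree.step_for(DoseBand(band), 0 if addons == "" else addons.count(";") + 1)
            for band, addons in zip(events["ics_band"], events["addons"])
        ]
    else:
        events["step"] = pd.Series(dtype=int)
    events = apply_run_in(events, study_start, window_days=run_in)
    report.events_after_run_in = len(events)
    report.unique_patients = int(events["patient_id"].nunique()) if not events.empty else 0
    report.validate()

    episodes = episodes_table(events)
    transitions, fractions = transition_matrix(episodes, exclude_step0=True)
    return PipelineResult(
        attrition=report,
        retained=retained,
        exclusions=exclusions,
        rejects=pd.DataFrame(reject_rows),
        events=events,
        episodes=episodes,
        duration_summary=summarise_durations(episodes),
        duration_table=duration_summary_table(episodes),
        transitions=transitions,
        transition_fractions=fractions,
        person_years=person_year_summary(events),
        band_mix=summarise_band_mix(retained, entry_map),
    )


def _empty_result(report: AttritionReport, tree: StepRuleSet) -> PipelineResult:
    report.validate()
    empty = pd.DataFrame()
    episodes = episodes_table(pd.DataFrame())
    transitions, fractions = transition_matrix(episodes)
    return PipelineResult(
        attrition=report,
        retained=empty,
        exclusions=empty.copy(),
        rejects=empty.copy(),
        events=pd.DataFrame(
            columns=["patient_id", "event_date", "ics_band", "addons", "saba_only",
                     "regimen_label", "step"]
        ),
        episodes=episodes,
        duration_summary=summarise_durations(episodes),
        duration_table=duration_summary_table(episodes),
        transitions=transitions,
        transition_fractions=fractions,
        person_years=person_year_summary(pd.DataFrame()),
        band_mix=pd.DataFrame(columns=["medication_key", "band", "proportion"]),
    )


def summarise_band_mix(
    retained: pd.DataFrame, entry_map: dict[str, MedicationEntry]
) -> pd.DataFrame:
    """Dose-band proportions per ICS-bearing medication type.

    Each banded prescription (daily dose available) contributes one count to
    its own product's thresholds; proportions sum to 1 within each type.
    """
    columns = ["medication_key", "band", "proportion", "n"]
    if retained.empty:
        return pd.DataFrame(columns=columns)
    ics = retained.loc[
        retained["medication_class"].isin([c.value for c in ICS_CLASSES])
        & retained["daily_dose_mcg"].notna()
    ]
    rows = []
    for key, group in ics.groupby("medication_key"):
        entry = entry_map[key]
        bands = [band_for_entry(entry, float(d)).value for d in group["daily_dose_mcg"]]
        counts = pd.Series(bands).value_counts()
        for band in (DoseBand.LOW, DoseBand.MEDIUM, DoseBand.HIGH, DoseBand.UNKNOWN):
            n = int(counts.get(band.value, 0))
            rows.append(
                {
                    "medication_key": key,
                    "band": band.value,
                    "proportion": n / len(group),
                    "n": n,
                }
            )
    return pd.DataFrame(rows, columns=columns)
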