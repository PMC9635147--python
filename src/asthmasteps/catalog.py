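"""Asthma medication identification from prescription name and formulation fields.

Prescription records name medications inconsistently: brand names (``CLENIL
MODULITE``), generic ingredients (``BECLOMETASONE``), or a mixture with
strengths and device names appended.  This module matches the free-text
medication name against a lookup catalogue of UK-licensed asthma products,
applies keyword/formulation/brand exclusion rules for non-asthma indications
(nasal sprays, dermatology, Crohn's disease ...), and reclassifies
corticosteroid *solutions* (nebuliser respules, sachets) away from the inhaled
ICS class, since they do not contribute to inhaled dose banding.

The shipped catalogue and exclusion list under ``asthmasteps/data`` are
reconstructions and are meant to be replaced or extended by the user.
"""

from __future__ import annotations

import datetime as dt
import enum
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "MedicationClass",
    "InhalerType",
    "ExclusionReason",
    "RuleField",
    "MedicationEntry",
    "ExclusionRule",
    "PrescriptionRecord",
    "AmbiguousMatchError",
    "normalise_text",
    "match_medication",
    "apply_exclusions",
    "reclassify_solution",
    "load_catalogue",
    "load_exclusion_rules",
    "default_catalogue_path",
    "default_exclusions_path",
]


class MedicationClass(str, enum.Enum):
    ICS = "ICS"
    ICS_LABA = "ICS_LABA"
    LABA = "LABA"
    SABA = "SABA"
    LTRA = "LTRA"
    THEOPHYLLINE = "THEOPHYLLINE"
    OTHER_CONTROLLER = "OTHER_CONTROLLER"
    ORAL_OR_NEB_STEROID = "ORAL_OR_NEB_STEROID"


#: Classes that carry an inhaled corticosteroid component (subject to banding).
ICS_CLASSES = frozenset({MedicationClass.ICS, MedicationClass.ICS_LABA})

#: Non-ICS controller classes that count as regimen add-ons.
ADDON_CLASSES = (
    MedicationClass.LABA,
    MedicationClass.LTRA,
    MedicationClass.THEOPHYLLINE,
    MedicationClass.OTHER_CONTROLLER,
)


class InhalerType(str, enum.Enum):
    DPI = "DPI"
    MDI = "MDI"
    NA = "NA"


class ExclusionReason(str, enum.Enum):
    OUT_OF_PERIOD = "OUT_OF_PERIOD"
    DELETED = "DELETED"
    NO_MATCH = "NO_MATCH"
    FORMULATION_EXCLUDED = "FORMULATION_EXCLUDED"
    NON_ASTHMA_INDICATION = "NON_ASTHMA_INDICATION"
    NON_ASTHMA_BRAND = "NON_ASTHMA_BRAND"
    STRENGTH_OUT_OF_RANGE = "STRENGTH_OUT_OF_RANGE"


class RuleField(str, enum.Enum):
    """Record field an exclusion keyword is matched against."""

    DOSE_TEXT = "DOSE_TEXT"
    MEDICATION_NAME = "MEDICATION_NAME"
    FORMULATION = "FORMULATION"
    BRAND = "BRAND"


_WHITESPACE = re.compile(r"\s+")


def normalise_text(text: Optional[str]) -> str:
    """Uppercase and single-space a free-text field (empty string for missing)."""
    if text is None or (isinstance(text, float) and pd.isna(text)):
        return ""
    return _WHITESPACE.sub(" ", str(text)).strip().upper()


@dataclass(frozen=True)
class MedicationEntry:
    """One catalogue row: a drug (or brand-safe product group) and its banding data.

    ``band_low`` / ``band_medium`` / ``band_high`` are the guideline daily-dose
    values in mcg/day for the low, medium and high categories; any may be
    absent except that ICS-bearing entries need at least one.
    """

    generic_name: str
    medication_class: MedicationClass
    brand_names: tuple[str, ...] = ()
    inhaler_type: InhalerType = InhalerType.NA
    licensed_strengths_mcg: tuple[float, ...] = ()
    band_low: Optional[float] = None
    band_medium: Optional[float] = None
    band_high: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.generic_name:
            raise ValueError("generic_name must be non-empty")
        if any(s <= 0 for s in self.licensed_strengths_mcg):
            raise ValueError(f"{self.generic_name}: licensed strengths must be positive")
        thresholds = [
            t for t in (self.band_low, self.band_medium, self.band_high) if t is not None
        ]
        if self.medication_class in ICS_CLASSES and not thresholds:
            raise ValueError(
                f"{self.generic_name}: ICS-bearing entries need at least one band threshold"
            )
        if any(t <= 0 for t in thresholds):
            raise ValueError(f"{self.generic_name}: band thresholds must be positive")
        if thresholds != sorted(thresholds) or len(set(thresholds)) != len(thresholds):
            raise ValueError(
                f"{self.generic_name}: band thresholds must be strictly increasing"
            )

    @property
    def match_tokens(self) -> tuple[str, ...]:
        """Uppercased tokens whose presence in a name identifies this entry."""
        return tuple(
            normalise_text(t) for t in (self.generic_name, *self.brand_names)
        )


@dataclass(frozen=True)
class ExclusionRule:
    keyword: str
    applies_to: RuleField
    reason: ExclusionReason

    def __post_init__(self) -> None:
        if not self.keyword:
            raise ValueError("exclusion keyword must be non-empty")
        object.__setattr__(self, "keyword", normalise_text(self.keyword))


@dataclass(frozen=True)
class PrescriptionRecord:
    """One row of the raw prescribing table."""

    patient_id: str
    prescribed_date: Optional[dt.date]
    medication_name: str = ""
    dose_text: str = ""
    formulation: Optional[str] = None
    bnf_code: Optional[str] = None
    dispensed_date: Optional[dt.date] = None
    prescribed_quantity: Optional[float] = None
    dispensed_quantity: Optional[float] = None


class AmbiguousMatchError(ValueError):
    """Two distinct catalogue entries both match a medication name.

    This flags a catalogue defect (overlapping name/brand tokens) and is never
    resolved silently.
    """

    def __init__(self, name_text: str, entries: Sequence[MedicationEntry]):
        self.name_text = name_text
        self.entries = tuple(entries)
        names = ", ".join(e.generic_name for e in entries)
        super().__init__(f"medication name {name_text!r} matches multiple entries: {names}")


def match_medication(
    name_text: str, catalogue: Sequence[MedicationEntry]
) -> Optional[MedicationEntry]:
    """Match a medication name to the unique catalogue entry it names.

    Matching is case-insensitive substring search of each entry's generic name
    and brand names within the uppercased, single-spaced ``name_text``.
    Returns ``None`` when nothing matches; raises :class:`AmbiguousMatchError`
    when more than one distinct entry matches.
    """
    text = normalise_text(name_text)
    if not text:
        return None
    hits = [e for e in catalogue if any(tok and tok in text for tok in e.match_tokens)]
    if not hits:
        return None
    if len(hits) > 1:
        raise AmbiguousMatchError(text, hits)
    return hits[0]


def apply_exclusions(
    record: PrescriptionRecord,
    entry: Optional[MedicationEntry],
    rules: Iterable[ExclusionRule],
    study_period: tuple[dt.date, dt.date],
) -> Optional[ExclusionReason]:
    """Return the exclusion reason for a record, or ``None`` to keep it.

    Precedence (first match wins): OUT_OF_PERIOD, DELETED, NO_MATCH,
    FORMULATION_EXCLUDED (ICS-bearing entries only, per the spray/drop rule),
    NON_ASTHMA_INDICATION keywords, NON_ASTHMA_BRAND keywords.
    """
    if record.prescribed_date is None:
        raise ValueError("record has no prescription date and cannot be processed")
    start, end = study_period
    if not (start <= record.prescribed_date <= end):
        return ExclusionReason.OUT_OF_PERIOD

    rules = list(rules)
    dose_text = normalise_text(record.dose_text)
    name_text = normalise_text(record.medication_name)
    formulation = normalise_text(record.formulation)
    field_text = {
        RuleField.DOSE_TEXT: dose_text,
        RuleField.MEDICATION_NAME: name_text,
        RuleField.FORMULATION: formulation,
        RuleField.BRAND: name_text,
    }

    def first_hit(reason: ExclusionReason) -> bool:
        return any(
            r.reason == reason and r.keyword in field_text[r.applies_to]
            for r in rules
        )

    if first_hit(ExclusionReason.DELETED):
        return ExclusionReason.DELETED
    if entry is None:
        return ExclusionReason.NO_MATCH
    if entry.medication_class in ICS_CLASSES and any(
        r.reason == ExclusionReason.FORMULATION_EXCLUDED
        and r.applies_to == RuleField.FORMULATION
        and r.keyword in formulation
        for r in rules
    ):
        return ExclusionReason.FORMULATION_EXCLUDED
    if first_hit(ExclusionReason.NON_ASTHMA_INDICATION):
        return ExclusionReason.NON_ASTHMA_INDICATION
    if first_hit(ExclusionReason.NON_ASTHMA_BRAND):
        return ExclusionReason.NON_ASTHMA_BRAND
    return None


#: Formulation code and keywords marking a corticosteroid solution rather than
#: an inhaled formulation.
SOLUTION_FORMULATION = "SOL"
SOLUTION_KEYWORDS = ("SACHET", "RESPULE", "NEB", "VIAL", "AMPOULE")


def reclassify_solution(
    record: PrescriptionRecord, entry: MedicationEntry
) -> MedicationClass:
    """Distinguish corticosteroid solutions from inhaled ICS formulations.

    Returns ``ORAL_OR_NEB_STEROID`` when the formulation is ``SOL`` or any of
    the solution keywords occurs in the dose text or medication name; only ICS
    entries are ever reclassified.
    """
    if entry.medication_class != MedicationClass.ICS:
        return entry.medication_class
    if normalise_text(record.formulation) == SOLUTION_FORMULATION:
        return MedicationClass.ORAL_OR_NEB_STEROID
    haystack = f"{normalise_text(record.dose_text)} {normalise_text(record.medication_name)}"
    if any(kw in haystack for kw in SOLUTION_KEYWORDS):
        return MedicationClass.ORAL_OR_NEB_STEROID
    return MedicationClass.ICS


# ---------------------------------------------------------------------------
# Loading


def default_catalogue_path() -> Path:
    return Path(str(resources.files("asthmasteps").joinpath("data/medication_catalogue.csv")))


def default_exclusions_path() -> Path:
    return Path(str(resources.files("asthmasteps").joinpath("data/exclusion_keywords.csv")))


def _split_list(raw: object) -> list[str]:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)) or raw == "":
        return []
    return [part.strip() for part in str(raw).split(";") if part.strip()]


def load_catalogue(path: Optional[str | Path] = None) -> list[MedicationEntry]:
    """Load the medication catalogue CSV (``#`` lines are comments)."""
    path = Path(path) if path is not None else default_catalogue_path()
    frame = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    entries = []
    for row in frame.to_dict("records"):
        entries.append(
            MedicationEntry(
                generic_name=row["generic_name"].strip(),
                medication_class=MedicationClass(row["class"].strip()),
                brand_names=tuple(_split_list(row["brand_names"])),
                inhaler_type=InhalerType(row["inhaler_type"].strip()),
                licensed_strengths_mcg=tuple(
                    float(s) for s in _split_list(row["licensed_strengths_mcg"])
                ),
                band_low=_opt_float(row["band_low"]),
                band_medium=_opt_float(row["band_medium"]),
                band_high=_opt_float(row["band_high"]),
            )
        )
    names = [e.generic_name for e in entries]
    if len(set(names)) != len(names):
        raise ValueError("catalogue generic_name keys must be unique")
    return entries


def _opt_float(raw: object) -> Optional[float]:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)) or str(raw).strip() == "":
        return None
    return float(raw)


def load_exclusion_rules(path: Optional[str | Path] = None) -> list[ExclusionRule]:
    path = Path(path) if path is not None else default_exclusions_path()
    frame = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    return [
        ExclusionRule(
            keyword=row.keyword,
            applies_to=RuleField(row.applies_to.strip()),
            reason=ExclusionReason(row.reason.strip()),
        )
        for row in frame.itertuples(index=False)
    ]
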