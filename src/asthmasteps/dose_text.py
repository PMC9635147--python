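"""Rule-based extraction of dose frequency, quantity and strength from free text.

Prescription dose directions ("TAKE TWO PUFFS TWICE DAILY") encode the three
components of the prescribed daily dose:

* **frequency** — doses per day, recovered from a keyword table of phrases
  ("TWICE", "4 TIMES", "MORNING AND NIGHT", "BD", ...);
* **quantity** — puffs (units) per dose, recovered from the numbers one to
  four, numerals or written out, anchored by "TAKE"/"INHALE" before or
  "DAILY"/"AT"/"TO BE TAKEN"/"PUF"/"P " after the number ("PUF" with a single
  'F' tolerates the common "PUFS" typo);
* **strength** — micrograms per unit, recovered by scanning a fixed list of
  microgram values (then milligram values, converted x1000) in descending
  order so that "250MCG" is never read as "50MCG" and "0.5MG" never as "5MG".

Missing components are imputed with the per-medication mode (smallest value on
ties).  The prescribed daily dose is the product frequency x quantity x
strength.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .catalog import MedicationEntry, normalise_text

__all__ = [
    "MICROGRAM_VALUES",
    "MILLIGRAM_VALUES",
    "ParsedDose",
    "extract_frequency",
    "extract_quantity",
    "extract_strength",
    "parse_dose",
    "impute_by_mode",
    "validate_strength",
    "daily_dose",
    "load_frequency_keywords",
    "default_frequency_keywords_path",
]

#: Microgram unit strengths searched for, in this exact (descending) order.
MICROGRAM_VALUES: tuple[float, ...] = (
    10000, 5000, 4000, 2000, 1000, 500, 400, 320, 250, 200,
    184, 160, 125, 100, 92, 80, 65, 50,
)

#: Milligram unit strengths searched for (after micrograms), 0.5 first so that
#: "0.5MG" is not read as "5MG".
MILLIGRAM_VALUES: tuple[float, ...] = (0.5, 20, 10, 5, 4, 2, 1)


@dataclass(frozen=True)
class ParsedDose:
    """Extracted (and possibly imputed) daily-dose components for one record."""

    frequency_per_day: Optional[int] = None
    quantity_per_dose: Optional[int] = None
    strength_mcg: Optional[float] = None
    laba_component_mcg: Optional[float] = None
    imputed_frequency: bool = False
    imputed_quantity: bool = False
    imputed_strength: bool = False


# ---------------------------------------------------------------------------
# Frequency


def default_frequency_keywords_path() -> Path:
    return Path(str(resources.files("asthmasteps").joinpath("data/frequency_keywords.csv")))


def load_frequency_keywords(
    path: Optional[str | Path] = None,
) -> list[tuple[str, int]]:
    """Load the phrase -> doses/day table, sorted longest phrase first."""
    path = Path(path) if path is not None else default_frequency_keywords_path()
    frame = pd.read_csv(path, comment="#", dtype={"phrase": str, "doses_per_day": int}, keep_default_na=False)
    pairs = [
        (normalise_text(row["phrase"]), int(row["doses_per_day"]))
        for row in frame.to_dict("records")
    ]
    return sorted(pairs, key=lambda p: -len(p[0]))


def extract_frequency(
    dose_text: str, frequency_keywords: Sequence[tuple[str, int]]
) -> Optional[int]:
    """Doses per day from the first (longest-phrase-first) keyword hit, else None."""
    text = normalise_text(dose_text)
    if not text:
        return None
    for phrase, value in sorted(frequency_keywords, key=lambda p: -len(p[0])):
        if re.search(rf"\b{re.escape(phrase)}\b", text):
            return value
    return None


# ---------------------------------------------------------------------------
# Quantity

_NUMBER_WORDS = {"ONE": 1, "TWO": 2, "THREE": 3, "FOUR": 4, "1": 1, "2": 2, "3": 3, "4": 4}
_NUM = r"(ONE|TWO|THREE|FOUR|[1-4])"
# number preceded by "take" or "inhale"
_QTY_PRECEDED = re.compile(rf"\b(?:TAKE|INHALE)\s+{_NUM}\b")
# number followed by "daily", "at", "to be taken", "puf..." or "p "
_QTY_FOLLOWED = re.compile(rf"\b{_NUM}\s*(?:TO BE TAKEN|DAILY|AT\b|PUF|P\s)")


def extract_quantity(dose_text: str) -> Optional[int]:
    """Units per dose (1-4) from the anchored-number rules, else None.

    The "take"/"inhale" anchors are tried before the trailing anchors; numbers
    above four never match and such records fall through to imputation.
    """
    text = normalise_text(dose_text)
    if not text:
        return None
    for pattern in (_QTY_PRECEDED, _QTY_FOLLOWED):
        m = pattern.search(text)
        if m:
            return _NUMBER_WORDS[m.group(1)]
    return None


# ---------------------------------------------------------------------------
# Strength


def _fmt(value: float) -> str:
    return str(int(value)) if float(value).is_integer() else str(value)


def _unit_pattern(value: float, units: str) -> re.Pattern:
    # no digit or decimal point immediately before the value, so a longer
    # number never yields its suffix even out of search order
    return re.compile(rf"(?<![\d.]){re.escape(_fmt(value))}\s*(?:{units})")


def _slash_pattern(value: float) -> re.Pattern:
    return re.compile(rf"(?<![\d.]){re.escape(_fmt(value))}/(\d+(?:\.\d+)?)")


_MCG_PATTERNS = [(v, _unit_pattern(v, "MCG|MICROGRAM")) for v in MICROGRAM_VALUES]
_MG_PATTERNS = [(v, _unit_pattern(v, "MG|MILLIGRAM")) for v in MILLIGRAM_VALUES]
_MCG_SLASH = [(v, _slash_pattern(v)) for v in MICROGRAM_VALUES]


def extract_strength(
    text: str, is_combo: bool = False
) -> Optional[tuple[float, Optional[float]]]:
    """Unit strength in micrograms from free text, else None.

    Returns ``(strength_mcg, laba_component_mcg)``.  Micrograms are searched
    before milligrams, each list in descending value order, first match wins;
    milligram hits are converted x1000.  For combination (ICS+LABA) products a
    ``value/value`` token with no spaces yields the ICS component before the
    slash and the LABA component after it.
    """
    haystack = normalise_text(text)
    if not haystack:
        return None
    for value, pattern in _MCG_PATTERNS:
        if pattern.search(haystack):
            return float(value), None
    if is_combo:
        for value, pattern in _MCG_SLASH:
            m = pattern.search(haystack)
            if m:
                return float(value), float(m.group(1))
    for value, pattern in _MG_PATTERNS:
        if pattern.search(haystack):
            return float(value) * 1000.0, None
    return None


def parse_dose(
    dose_text: str,
    medication_name: str,
    frequency_keywords: Sequence[tuple[str, int]],
    is_combo: bool = False,
) -> ParsedDose:
    """Parse all three dose components from a record's free-text fields.

    Strength is searched in the dose text first, then in the medication name
    (strengths are often embedded in product names, e.g. "SERETIDE 250").
    """
    strength = extract_strength(dose_text, is_combo)
    if strength is None:
        strength = extract_strength(medication_name, is_combo)
    return ParsedDose(
        frequency_per_day=extract_frequency(dose_text, frequency_keywords),
        quantity_per_dose=extract_quantity(dose_text),
        strength_mcg=strength[0] if strength else None,
        laba_component_mcg=strength[1] if strength else None,
    )


# ---------------------------------------------------------------------------
# Imputation, validation, daily dose

_IMPUTABLE = {
    "frequency_per_day": "imputed_frequency",
    "quantity_per_dose": "imputed_quantity",
    "strength_mcg": "imputed_strength",
}


def impute_by_mode(
    parsed: Sequence[tuple[str, ParsedDose]]
) -> list[tuple[str, ParsedDose]]:
    """Fill absent dose components with the per-medication mode.

    ``parsed`` is a sequence of ``(medication_key, ParsedDose)``.  The mode is
    taken over non-absent values of the same medication key; ties break to the
    smallest value (deterministic and never dose-inflating).  A component with
    no observed value anywhere for its medication stays absent.  Observed
    values are never altered.
    """
    modes: dict[tuple[str, str], object] = {}
    for column in _IMPUTABLE:
        by_key: dict[str, list] = {}
        for key, dose in parsed:
            value = getattr(dose, column)
            if value is not None:
                by_key.setdefault(key, []).append(value)
        for key, values in by_key.items():
            series = pd.Series(values)
            candidates = series.mode()
            modes[(key, column)] = min(candidates)
    out = []
    for key, dose in parsed:
        updates = {}
        for column, flag in _IMPUTABLE.items():
            if getattr(dose, column) is None and (key, column) in modes:
                updates[column] = modes[(key, column)]
                updates[flag] = True
        out.append((key, replace(dose, **updates) if updates else dose))
    return out


def impute_frame_by_mode(frame: pd.DataFrame, key_col: str = "medication_key") -> pd.DataFrame:
    """Vectorised :func:`impute_by_mode` over a parsed-prescription DataFrame.

    Expects columns ``frequency_per_day``, ``quantity_per_dose``,
    ``strength_mcg``; adds/overwrites the ``imputed_*`` flag columns.
    """
    frame = frame.copy()
    for column, flag in _IMPUTABLE.items():
        missing = frame[column].isna()
        frame[flag] = missing
        # smallest mode per medication key
        modes = (
            frame.loc[~missing]
            .groupby(key_col)[column]
            .agg(lambda s: min(s.mode()))
        )
        fill = frame.loc[missing, key_col].map(modes)
        frame.loc[missing, column] = fill
        frame[flag] = frame[flag] & frame[column].notna()
    return frame


def validate_strength(entry: MedicationEntry, strength_mcg: float) -> bool:
    """True when the strength is one of the entry's licensed unit strengths."""
    return any(abs(strength_mcg - s) < 1e-9 for s in entry.licensed_strengths_mcg)


def daily_dose(parsed: ParsedDose) -> Optional[float]:
    """Prescribed daily dose in mcg/day: frequency x quantity x strength.

    Absent whenever any component is still absent after imputation.
    """
    if (
        parsed.frequency_per_day is None
        or parsed.quantity_per_dose is None
        or parsed.strength_mcg is None
    ):
        return None
    return float(parsed.frequency_per_day * parsed.quantity_per_dose * parsed.strength_mcg)
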