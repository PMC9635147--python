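"""Parse free-text dose directions into daily-dose components.

Each prescription's daily dose is frequency (doses/day) x quantity
(puffs/dose) x strength (mcg/puff); the three are extracted from the dose
text and medication name by keyword and anchored-number rules, and the daily
dose is then banded on the product's own low/medium/high thresholds.
"""

from asthmasteps import (
    ParsedDose,
    daily_dose,
    load_catalogue,
    load_frequency_keywords,
    match_medication,
    parse_dose,
)
from asthmasteps.banding import band_for_entry

catalogue = load_catalogue()
keywords = load_frequency_keywords()

examples = [
    ("CLENIL MODULITE 100MCG INHALER", "TAKE TWO PUFFS TWICE DAILY"),
    ("SERETIDE 250/25 EVOHALER", "2 PUFS MORNING AND NIGHT"),  # typo tolerated
    ("FLIXOTIDE 125MCG INHALER", "INHALE TWO PUFFS BD"),
    ("VENTOLIN 100MCG INHALER", "USE AS DIRECTED"),            # nothing extractable
]

for name, dose_text in examples:
    entry = match_medication(name, catalogue)
    parsed = parse_dose(dose_text, name, keywords,
                        is_combo=entry.medication_class == "ICS_LABA")
    dose = daily_dose(parsed)
    band = (
        band_for_entry(entry, dose).value
        if dose and entry.medication_class in ("ICS", "ICS_LABA")
        else "-"
    )
    print(f"{name:30s} | {dose_text:28s} -> freq={parsed.frequency_per_day} "
          f"qty={parsed.quantity_per_dose} strength={parsed.strength_mcg} "
          f"daily={dose} band={band}")

# The last line shows absent components: in a full pipeline run they would be
# imputed with the per-medication mode before the daily dose is computed.
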