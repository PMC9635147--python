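"""Daily ICS dose banding into low / medium / high / unknown categories.

The BTS/SIGN guideline prints a single daily-dose value per category for each
drug and inhaler type.  Observed prescribed daily doses rarely land exactly on
those values, so each category value is widened into a range:

* low:    (0, band_low]
* medium: [band_low + 1, band_medium]; lower limit band_medium/2 when the
  guideline lists no low dose for the product
* high:   [band_medium + 1, 4 x band_medium]; when no medium dose is listed,
  [band_high/2, 2 x band_high]

Doses above the high upper limit are categorised ``UNKNOWN``.  Classification
uses the upper limits as cutpoints (smallest band whose upper limit covers the
dose), which coincides with range containment wherever the ranges are
contiguous and keeps the mapping total when a low or medium range is absent.
Daily doses are compared at 1-mcg integer granularity (fractions rounded
half-up), matching the "+1 microgram" boundary construction.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional

from .catalog import MedicationEntry

__all__ = ["DoseBand", "BandRanges", "derive_band_ranges", "classify_daily_dose", "band_for_entry"]


class DoseBand(str, enum.Enum):
    """Ordered ICS dose category; UNKNOWN (above-range) ranks above HIGH."""

    NONE = "NONE"
    LOW = "LOW"
    MEDIUM = "MEDIUM"
    HIGH = "HIGH"
    UNKNOWN = "UNKNOWN"

    @property
    def rank(self) -> int:
        return _BAND_RANK[self]

    def __lt__(self, other: object):  # type: ignore[override]
        if isinstance(other, DoseBand):
            return self.rank < other.rank
        return NotImplemented


_BAND_RANK = {
    DoseBand.NONE: 0,
    DoseBand.LOW: 1,
    DoseBand.MEDIUM: 2,
    DoseBand.HIGH: 3,
    DoseBand.UNKNOWN: 4,
}


@dataclass(frozen=True)
class BandRanges:
    """Daily-dose (mcg/day) range limits for one drug + inhaler type."""

    low_upper: Optional[float]
    medium_lower: Optional[float]
    medium_upper: Optional[float]
    high_lower: float
    high_upper: float

    def __post_init__(self) -> None:
        limits = [
            self.low_upper,
            self.medium_lower,
            self.medium_upper,
            self.high_lower,
            self.high_upper,
        ]
        present = [x for x in limits if x is not None]
        if any(x <= 0 for x in present):
            raise ValueError("band range limits must be positive")
        if self.low_upper is not None and self.medium_lower is not None:
            if not self.low_upper < self.medium_lower:
                raise ValueError("low range must end below the medium range")
        if self.medium_upper is not None and not self.high_lower > self.medium_upper:
            raise ValueError("medium range must end below the high range")
        if self.high_lower > self.high_upper:
            raise ValueError("high range limits out of order")


def derive_band_ranges(
    band_low: Optional[float],
    band_medium: Optional[float],
    band_high: Optional[float],
) -> BandRanges:
    """Widen guideline category values into classification ranges.

    ``band_high`` is required; it only shapes the high range when
    ``band_medium`` is absent (otherwise the high range is
    [band_medium + 1, 4 x band_medium]).
    """
    if band_high is None:
        raise ValueError("band_high is required to derive dose ranges")
    thresholds = [t for t in (band_low, band_medium, band_high) if t is not None]
    if thresholds != sorted(thresholds) or len(set(thresholds)) != len(thresholds):
        raise ValueError("band thresholds must be strictly increasing where present")

    low_upper = band_low
    if band_medium is not None:
        medium_lower = band_low + 1 if band_low is not None else band_medium / 2
        medium_upper = band_medium
        high_lower = band_medium + 1
        high_upper = 4 * band_medium
    else:
        medium_lower = None
        medium_upper = None
        high_lower = band_high / 2
        high_upper = 2 * band_high
    return BandRanges(low_upper, medium_lower, medium_upper, high_lower, high_upper)


def classify_daily_dose(dose_mcg_per_day: float, ranges: BandRanges) -> DoseBand:
    """Band a positive daily dose; UNKNOWN above the high upper limit."""
    if dose_mcg_per_day is None or dose_mcg_per_day <= 0:
        raise ValueError("daily dose must be positive")
    dose = math.floor(dose_mcg_per_day + 0.5)  # 1-mcg granularity, half-up
    if ranges.low_upper is not None and dose <= ranges.low_upper:
        return DoseBand.LOW
    if ranges.medium_upper is not None and dose <= ranges.medium_upper:
        return DoseBand.MEDIUM
    if dose <= ranges.high_upper:
        return DoseBand.HIGH
    return DoseBand.UNKNOWN


def band_for_entry(entry: MedicationEntry, dose_mcg_per_day: float) -> DoseBand:
    """Band a daily dose on a catalogue entry's own thresholds."""
    ranges = derive_band_ranges(entry.band_low, entry.band_medium, entry.band_high)
    return classify_daily_dose(dose_mcg_per_day, ranges)
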