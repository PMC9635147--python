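"""Map treatment regimens to BTS/SIGN treatment steps 0-4 via an ordered rule tree.

The adult ladder, informally: no ICS -> step 0 (including SABA-only and the
contraindicated LABA-only regimens); low-dose ICS alone -> step 1 (the unique
step-1 regimen); low ICS + one add-on -> step 2; medium ICS (or low ICS with
two or more add-ons) -> step 3; high or above-range ICS dose, or medium ICS
with two or more add-ons -> step 4.

The tree is configuration data: an ordered list of rules over the ICS band
and the add-on count, first match wins.  Totality — every enumerable regimen
configuration receives a step, so no manual assignment is ever needed — is
validated when a rule set is loaded.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from itertools import chain, combinations
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import yaml

from .banding import DoseBand
from .catalog import ADDON_CLASSES, MedicationClass
from .regimen import Regimen

__all__ = [
    "StepRule",
    "StepRuleSet",
    "TotalityError",
    "classify_step",
    "enumerate_regimen_space",
    "load_step_rules",
    "default_step_rules_path",
    "paediatric_step_rules_path",
]


class TotalityError(ValueError):
    """A rule set leaves some regimen configurations without a step."""

    def __init__(self, uncovered: Sequence[tuple[DoseBand, frozenset]]):
        self.uncovered = list(uncovered)
        listing = "; ".join(
            f"({band.value}, {{{', '.join(sorted(c.value for c in addons))}}})"
            for band, addons in self.uncovered
        )
        super().__init__(f"step rules do not cover: {listing}")


@dataclass(frozen=True)
class StepRule:
    """One branch: bands it applies to, an add-on count window, and the step."""

    bands: frozenset[DoseBand]
    step: int
    min_addons: int = 0
    max_addons: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0 <= self.step <= 4:
            raise ValueError("step must be in 0..4")
        if self.min_addons < 0:
            raise ValueError("min_addons must be non-negative")
        if self.max_addons is not None and self.max_addons < self.min_addons:
            raise ValueError("max_addons below min_addons")

    def matches(self, band: DoseBand, n_addons: int) -> bool:
        return (
            band in self.bands
            and n_addons >= self.min_addons
            and (self.max_addons is None or n_addons <= self.max_addons)
        )


@dataclass(frozen=True)
class StepRuleSet:
    """Ordered rules plus the add-on classes the tree discriminates on."""

    rules: tuple[StepRule, ...]
    addon_classes: tuple[MedicationClass, ...] = tuple(ADDON_CLASSES)

    def step_for(self, band: DoseBand, n_addons: int) -> int:
        for rule in self.rules:
            if rule.matches(band, n_addons):
                return rule.step
        raise TotalityError([(band, frozenset())])

    def validate(self) -> None:
        """Raise :class:`TotalityError` unless every configuration is covered."""
        uncovered = []
        for band in DoseBand:
            for n in range(len(self.addon_classes) + 1):
                if not any(rule.matches(band, n) for rule in self.rules):
                    uncovered.append((band, frozenset(list(self.addon_classes)[:n])))
        if uncovered:
            raise TotalityError(uncovered)


def classify_step(regimen: Regimen, rules: StepRuleSet) -> int:
    """Treatment step 0-4 for a regimen (total by construction)."""
    return rules.step_for(regimen.ics_band, len(regimen.addons))


def enumerate_regimen_space(rules: StepRuleSet) -> pd.DataFrame:
    """The full band x add-on-subset cross product with each assigned step.

    Used to audit totality and the step-1 uniqueness guarantee; raises
    :class:`TotalityError` when any configuration is uncovered.
    """
    rules.validate()
    rows = []
    addon_classes = list(rules.addon_classes)
    subsets = chain.from_iterable(
        combinations(addon_classes, r) for r in range(len(addon_classes) + 1)
    )
    for subset in subsets:
        for band in DoseBand:
            rows.append(
                {
                    "ics_band": band.value,
                    "addons": ";".join(sorted(c.value for c in subset)),
                    "n_addons": len(subset),
                    "step": rules.step_for(band, len(subset)),
                }
            )
    return pd.DataFrame(rows, columns=["ics_band", "addons", "n_addons", "step"])


# ---------------------------------------------------------------------------
# Loading


def default_step_rules_path() -> Path:
    return Path(str(resources.files("asthmasteps").joinpath("data/step_rules_adult.yaml")))


def paediatric_step_rules_path() -> Path:
    return Path(str(resources.files("asthmasteps").joinpath("data/step_rules_paediatric.yaml")))


def load_step_rules(path: Optional[str | Path] = None) -> StepRuleSet:
    """Load and validate an ordered step-rule config (YAML)."""
    path = Path(path) if path is not None else default_step_rules_path()
    raw = yaml.safe_load(Path(path).read_text())
    addon_classes = tuple(
        MedicationClass(c) for c in raw.get("addon_classes", [c.value for c in ADDON_CLASSES])
    )
    rules = tuple(
        StepRule(
            bands=frozenset(DoseBand(b) for b in spec["bands"]),
            step=int(spec["step"]),
            min_addons=int(spec.get("min_addons", 0)),
            max_addons=(int(spec["max_addons"]) if "max_addons" in spec else None),
        )
        for spec in raw["rules"]
    )
    rule_set = StepRuleSet(rules=rules, addon_classes=addon_classes)
    rule_set.validate()
    return rule_set
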