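"""Synthetic prescription-record cohorts with known ground truth.

Real prescribing EHR extracts of the kind this package targets are access-
controlled, so every pipeline stage is exercised against generated data whose
truth is known by construction.  Each patient follows a latent treatment-step
trajectory (a Markov walk over steps 0-4 whose dwell times before a step-down
are longer on average than before a step-up, mirroring clinical prescribing
behaviour).  Each step interval is realised as a concrete regimen consistent
with that step under the adult decision tree, and each regimen component is
emitted as ~30-day refills with jitter.  Dose directions are rendered from
phrase templates with configurable noise: the "PUFS" typo, missing strength
or frequency, unit spacing variants, and brand versus generic product names.

Ground truth carries, per record, the true frequency/quantity/strength and,
per prescription day, both the latent step and the *expected* step — the step
implied by the true medications in that day's lookback window.  The two
differ transiently after a latent change because old refills remain in the
window; the expected step is what a correct pipeline must reproduce exactly.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .catalog import MedicationClass, MedicationEntry, load_catalogue
from .regimen import DEFAULT_WINDOW_DAYS, _regimen_from_window
from .steps import StepRuleSet, load_step_rules

__all__ = [
    "TextNoise",
    "SimulationConfig",
    "GroundTruth",
    "simulate_cohort",
    "render_dose_text",
    "load_dose_templates",
]


@dataclass(frozen=True)
class TextNoise:
    """Probabilities of free-text imperfections (all zero = canonical text)."""

    p_typo_puf: float = 0.05
    p_missing_strength: float = 0.10
    p_missing_frequency: float = 0.05
    p_unit_space: float = 0.20
    p_generic_name: float = 0.35

    def __post_init__(self) -> None:
        for name in ("p_typo_puf", "p_missing_strength", "p_missing_frequency",
                     "p_unit_space", "p_generic_name"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")

    @classmethod
    def none(cls) -> "TextNoise":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults emulate the structure of a Scottish primary-care prescribing
    extract: ~30-day refills, a 2009 study start with a 120-day run-in,
    step-down dwell times (~300-day mean) longer than step-up dwell times
    (~130-day mean), and a small admixture of non-asthma decoy rows.
    """

    n_patients: int = 200
    seed: int = 0
    study_start: dt.date = dt.date(2009, 1, 31)
    study_end: dt.date = dt.date(2014, 1, 31)
    refill_interval_days: int = 30
    refill_jitter_days: int = 3
    dwell_mean_up_days: float = 130.0
    dwell_mean_down_days: float = 300.0
    initial_step_weights: tuple[float, ...] = (0.26, 0.16, 0.07, 0.21, 0.30)
    window_days: int = DEFAULT_WINDOW_DAYS
    noise: TextNoise = field(default_factory=TextNoise)
    decoy_rate: float = 0.02
    nasal_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        if self.study_start >= self.study_end:
            raise ValueError("study_start must precede study_end")
        if abs(sum(self.initial_step_weights) - 1.0) > 1e-9 or len(self.initial_step_weights) != 5:
            raise ValueError("initial_step_weights must be 5 probabilities summing to 1")


@dataclass(frozen=True)
class GroundTruth:
    """Latent truth emitted alongside a synthetic prescription table."""

    records: pd.DataFrame      # per emitted record: true dose components
    events: pd.DataFrame       # per (patient, date): latent and expected step
    trajectories: pd.DataFrame # per latent step interval


# ---------------------------------------------------------------------------
# Product menu (must stay consistent with the shipped catalogue)

@dataclass(frozen=True)
class _Product:
    key: str
    cls: MedicationClass
    brands: tuple[str, ...]
    strength: float            # ICS component for combos, unit strength otherwise
    freq: int
    qty: int
    laba_component: Optional[float] = None
    form: str = "INH"
    generic_ok: bool = True    # False for products whose generic text would be ambiguous
    generic_render: Optional[str] = None
    unit: str = "MCG"

    @property
    def is_combo(self) -> bool:
        return self.cls == MedicationClass.ICS_LABA


def _p(key, cls, brands, strength, freq=2, qty=2, **kw) -> _Product:
    return _Product(key, cls, tuple(brands), float(strength), freq, qty, **kw)


_LOW_ICS = (
    _p("beclometasone", MedicationClass.ICS, ("CLENIL MODULITE", "CLENIL"), 100),
    _p("budesonide", MedicationClass.ICS, ("PULMICORT", "EASYHALER BUDESONIDE"), 100),
    _p("fluticasone", MedicationClass.ICS, ("FLIXOTIDE",), 50),
    _p("qvar", MedicationClass.ICS, ("QVAR",), 50, generic_ok=False),
)
_MEDIUM_ICS = (
    _p("beclometasone", MedicationClass.ICS, ("CLENIL MODULITE", "BECLAZONE"), 200),
    _p("fluticasone", MedicationClass.ICS, ("FLIXOTIDE",), 125),
)
_HIGH_ICS = (
    _p("fluticasone", MedicationClass.ICS, ("FLIXOTIDE",), 250),
    _p("beclometasone", MedicationClass.ICS, ("CLENIL MODULITE",), 250),
)
_LOW_COMBO = (
    _p("fluticasone-salmeterol", MedicationClass.ICS_LABA, ("SERETIDE",), 50,
       laba_component=25.0, generic_ok=False),
    _p("budesonide-formoterol", MedicationClass.ICS_LABA, ("SYMBICORT",), 100,
       laba_component=6.0, generic_ok=False),
)
_MEDIUM_COMBO = (
    _p("fluticasone-salmeterol", MedicationClass.ICS_LABA, ("SERETIDE",), 125,
       laba_component=25.0, generic_ok=False),
    _p("budesonide-formoterol", MedicationClass.ICS_LABA, ("SYMBICORT",), 200,
       laba_component=6.0, generic_ok=False),
)
_HIGH_COMBO = (
    _p("fluticasone-salmeterol", MedicationClass.ICS_LABA, ("SERETIDE",), 250,
       laba_component=25.0, generic_ok=False),
    _p("budesonide-formoterol", MedicationClass.ICS_LABA, ("SYMBICORT",), 400,
       laba_component=12.0, generic_ok=False),
)
_SALMETEROL = _p("salmeterol", MedicationClass.LABA, ("SEREVENT",), 25)
_SABA = _p("salbutamol", MedicationClass.SABA, ("VENTOLIN", "SALAMOL", "AIROMIR"), 100)
_LTRA = _p("montelukast", MedicationClass.LTRA, ("SINGULAIR",), 10, freq=1, qty=1,
           form="TAB", unit="MG")
_THEO = _p("theophylline", MedicationClass.THEOPHYLLINE, ("UNIPHYLLIN", "NUELIN"), 200,
           freq=2, qty=1, form="TAB", unit="MG")

_DECOY_NAMES = (
    "AMOXICILLIN 500MG CAPSULES",
    "PARACETAMOL 500MG TABLETS",
    "SIMVASTATIN 40MG TABLETS",
    "LISINOPRIL 10MG TABLETS",
)


def _pick(rng: np.random.Generator, options):
    return options[int(rng.integers(len(options)))]


def _realise_regimen(rng: np.random.Generator, step: int) -> list[_Product]:
    """A concrete medication bundle consistent with a treatment step."""
    u = rng.random()
    if step == 0:
        if u < 0.70:
            components = [_SABA]
        elif u < 0.95:
            components = [_SALMETEROL]
        else:
            components = [_LTRA]
    elif step == 1:
        components = [_pick(rng, _LOW_ICS)]
    elif step == 2:
        if u < 0.60:
            components = [_pick(rng, _LOW_COMBO)]
        else:
            components = [_pick(rng, _LOW_ICS), _SALMETEROL]
    elif step == 3:
        if u < 0.50:
            components = [_pick(rng, _MEDIUM_COMBO)]
        elif u < 0.70:
            components = [_pick(rng, _MEDIUM_ICS)]
        else:
            components = [_pick(rng, _LOW_COMBO), _LTRA]
    else:
        if u < 0.50:
            components = [_pick(rng, _HIGH_COMBO)]
        elif u < 0.70:
            components = [_pick(rng, _HIGH_COMBO), _LTRA]
        elif u < 0.85:
            components = [_pick(rng, _HIGH_ICS), _SALMETEROL, _THEO]
        else:
            components = [_pick(rng, _MEDIUM_COMBO), _LTRA, _THEO]
    if step >= 1 and rng.random() < 0.7:
        components.append(_SABA)  # reliever co-prescription
    return components


# ---------------------------------------------------------------------------
# Text rendering

_FREQ_PHRASES = {
    1: ("ONCE DAILY", "OD", "NOCTE"),
    2: ("TWICE DAILY", "MORNING AND NIGHT", "BD"),
    3: ("THREE TIMES DAILY", "TDS"),
    4: ("4 TIMES A DAY", "QDS"),
}
_QTY_WORDS = {1: "ONE", 2: "TWO", 3: "THREE", 4: "FOUR"}


def default_dose_templates_path() -> Path:
    return Path(str(resources.files("asthmasteps").joinpath("data/dose_templates.csv")))


def load_dose_templates(path: Optional[str | Path] = None) -> dict[str, str]:
    path = Path(path) if path is not None else default_dose_templates_path()
    frame = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    return dict(zip(frame["template_id"], frame["pattern"]))


_TEMPLATES = load_dose_templates()
_INHALER_TEMPLATES = ("take_word", "numeral_puffs", "inhale_word", "p_shorthand", "take_numeral")


def render_dose_text(
    frequency: int,
    quantity: int,
    strength_mcg: Optional[float],
    template_id: str,
    noise: TextNoise = TextNoise.none(),
    rng: Optional[np.random.Generator] = None,
    templates: Optional[dict[str, str]] = None,
) -> str:
    """Render a dose direction that parses back to its inputs when noise is off.

    The strength argument is unused in the direction text itself (strengths
    live in the medication name) but is accepted so templates can be extended.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    templates = templates if templates is not None else _TEMPLATES
    pattern = templates[template_id]
    if noise.p_missing_frequency and rng.random() < noise.p_missing_frequency:
        freq_phrase = "AS DIRECTED"
    else:
        freq_phrase = _pick(rng, _FREQ_PHRASES[frequency])
    text = pattern.format(
        qty=quantity, qty_word=_QTY_WORDS[quantity], freq_phrase=freq_phrase
    )
    if noise.p_typo_puf and rng.random() < noise.p_typo_puf:
        text = text.replace("PUFFS", "PUFS")
    return text


def _render_name(
    product: _Product, noise: TextNoise, rng: np.random.Generator
) -> str:
    drop_strength = noise.p_missing_strength and rng.random() < noise.p_missing_strength
    generic = (
        product.generic_ok
        and noise.p_generic_name
        and rng.random() < noise.p_generic_name
    )
    base = product.key.upper() if generic else _pick(rng, product.brands)
    suffix = "TABLETS" if product.form == "TAB" else "INHALER"
    if drop_strength:
        return f"{base} {suffix}"
    if product.is_combo:
        laba = product.laba_component
        laba_txt = str(int(laba)) if float(laba).is_integer() else str(laba)
        token = f"{int(product.strength)}/{laba_txt}"
    else:
        space = " " if (noise.p_unit_space and rng.random() < noise.p_unit_space) else ""
        value = int(product.strength) if float(product.strength).is_integer() else product.strength
        token = f"{value}{space}{product.unit}"
    return f"{base} {token} {suffix}"


# ---------------------------------------------------------------------------
# Cohort generation


def simulate_cohort(
    config: SimulationConfig,
    step_rules: Optional[StepRuleSet] = None,
    catalogue: Optional[list[MedicationEntry]] = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a prescription table and its ground truth.

    Identical configs (including seed) produce identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    rules = step_rules if step_rules is not None else load_step_rules()
    entries = catalogue if catalogue is not None else load_catalogue()
    entry_map = {e.generic_name: e for e in entries}

    prescription_rows: list[dict] = []
    truth_rows: list[dict] = []
    traj_rows: list[dict] = []
    event_rows: list[dict] = []

    for i in range(config.n_patients):
        patient_id = f"ID{i:05d}"
        intervals = _latent_trajectory(rng, config)
        for step, start, end in intervals:
            traj_rows.append(
                {"patient_id": patient_id, "step": step,
                 "start_date": start, "end_date": end}
            )
        patient_truth: list[dict] = []
        for step, start, end in intervals:
            regimen = _realise_regimen(rng, step)
            for comp_idx, product in enumerate(regimen):
                offset = int(rng.integers(0, 8))
                date = start + dt.timedelta(days=offset)
                while date < end:
                    row, truth = _emit(rng, config, patient_id, date, product, step)
                    prescription_rows.append(row)
                    patient_truth.append(truth)
                    jitter = int(rng.integers(-config.refill_jitter_days,
                                              config.refill_jitter_days + 1))
                    date = date + dt.timedelta(days=max(1, config.refill_interval_days + jitter))
        truth_rows.extend(patient_truth)
        event_rows.extend(
            _expected_events(patient_truth, entry_map, rules, config.window_days)
        )

    _append_decoys(rng, config, prescription_rows, truth_rows)

    prescriptions = pd.DataFrame(
        prescription_rows,
        columns=["patient_id", "prescribed_date", "dispensed_date", "medication_name",
                 "bnf_code", "formulation", "prescribed_quantity", "dispensed_quantity",
                 "dose_text"],
    ).sort_values(["patient_id", "prescribed_date", "medication_name"],
                  kind="stable").reset_index(drop=True)
    truth = GroundTruth(
        records=pd.DataFrame(
            truth_rows,
            columns=["patient_id", "prescribed_date", "medication_key",
                     "medication_class", "true_frequency", "true_quantity",
                     "true_strength_mcg", "true_daily_dose_mcg", "latent_step",
                     "is_decoy"],
        ).sort_values(["patient_id", "prescribed_date", "medication_key"],
                      kind="stable").reset_index(drop=True),
        events=pd.DataFrame(
            event_rows,
            columns=["patient_id", "event_date", "latent_step", "expected_step",
                     "expected_regimen_label"],
        ),
        trajectories=pd.DataFrame(
            traj_rows, columns=["patient_id", "step", "start_date", "end_date"]
        ),
    )
    return prescriptions, truth


def _latent_trajectory(
    rng: np.random.Generator, config: SimulationConfig
) -> list[tuple[int, dt.date, dt.date]]:
    """(step, start, end) intervals from entry until the study end."""
    t = config.study_start + dt.timedelta(days=int(rng.integers(0, 60)))
    step = int(rng.choice(5, p=np.asarray(config.initial_step_weights)))
    intervals = []
    while t < config.study_end:
        if step == 0:
            next_step = 1 if rng.random() < 0.8 else 2
        elif step == 4:
            next_step = 3 if rng.random() < 0.8 else 2
        else:
            magnitude = 1 if rng.random() < 0.8 else 2
            direction = 1 if rng.random() < 0.5 else -1
            next_step = int(np.clip(step + direction * magnitude, 0, 4))
            if next_step == step:
                next_step = step + direction
        mean = (
            config.dwell_mean_up_days
            if next_step > step
            else config.dwell_mean_down_days
        )
        dwell = max(config.refill_interval_days, int(round(rng.exponential(mean))))
        end = min(t + dt.timedelta(days=dwell), config.study_end)
        intervals.append((step, t, end))
        t = end
        step = next_step
    return intervals


def _emit(
    rng: np.random.Generator,
    config: SimulationConfig,
    patient_id: str,
    date: dt.date,
    product: _Product,
    latent_step: int,
) -> tuple[dict, dict]:
    template_id = "tablet" if product.form == "TAB" else _pick(rng, _INHALER_TEMPLATES)
    dose_text = render_dose_text(
        product.freq, product.qty, product.strength, template_id, config.noise, rng
    )
    name = _render_name(product, config.noise, rng)
    strength_mcg = product.strength * (1000.0 if product.unit == "MG" else 1.0)
    row = {
        "patient_id": patient_id,
        "prescribed_date": date,
        "dispensed_date": date + dt.timedelta(days=int(rng.integers(0, 4))),
        "medication_name": name,
        "bnf_code": "0301" if product.form == "INH" else "0302",
        "formulation": product.form,
        "prescribed_quantity": 1,
        "dispensed_quantity": 1,
        "dose_text": dose_text,
    }
    truth = {
        "patient_id": patient_id,
        "prescribed_date": date,
        "medication_key": product.key,
        "medication_class": product.cls.value,
        "true_frequency": product.freq,
        "true_quantity": product.qty,
        "true_strength_mcg": strength_mcg,
        "true_daily_dose_mcg": product.freq * product.qty * strength_mcg,
        "latent_step": latent_step,
        "is_decoy": False,
    }
    return row, truth


def _expected_events(
    patient_truth: list[dict],
    entry_map: dict[str, MedicationEntry],
    rules: StepRuleSet,
    window_days: int,
) -> list[dict]:
    """Expected (window-derived) step per prescription day, from true values.

    Theophylline's true strength is outside the parser's value lists, so its
    daily dose is treated as unrecoverable here exactly as in the pipeline;
    add-on presence is all that matters for it.
    """
    if not patient_truth:
        return []
    records = sorted(patient_truth, key=lambda r: r["prescribed_date"])
    dates = [r["prescribed_date"] for r in records]
    out = []
    for event_date in sorted({r["prescribed_date"] for r in records}):
        start = event_date - dt.timedelta(days=window_days - 1)
        window = [r for r in records if start <= r["prescribed_date"] <= event_date]
        regimen = _regimen_from_window(
            [r["medication_key"] for r in window],
            [MedicationClass(r["medication_class"]) for r in window],
            [r["prescribed_date"] for r in window],
            [r["true_daily_dose_mcg"] for r in window],
            entry_map,
        )
        latent = max(
            (r["latent_step"] for r in records if r["prescribed_date"] == event_date),
        )
        out.append(
            {
                "patient_id": records[0]["patient_id"],
                "event_date": event_date,
                "latent_step": latent,
                "expected_step": rules.step_for(regimen.ics_band, len(regimen.addons)),
                "expected_regimen_label": regimen.label,
            }
        )
    return out


def _append_decoys(
    rng: np.random.Generator,
    config: SimulationConfig,
    prescription_rows: list[dict],
    truth_rows: list[dict],
) -> None:
    """Mix in non-asthma decoy rows and nasal-spray rows (both excluded upstream)."""
    n_asthma = len(prescription_rows)
    span = (config.study_end - config.study_start).days
    for rate, maker in ((config.decoy_rate, _decoy_row), (config.nasal_rate, _nasal_row)):
        n = int(round(rate * n_asthma))
        for _ in range(n):
            patient_id = f"ID{int(rng.integers(config.n_patients or 1)):05d}"
            date = config.study_start + dt.timedelta(days=int(rng.integers(span)))
            row = maker(rng, patient_id, date)
            prescription_rows.append(row)
            truth_rows.append(
                {
                    "patient_id": patient_id,
                    "prescribed_date": date,
                    "medication_key": "",
                    "medication_class": "",
                    "true_frequency": None,
                    "true_quantity": None,
                    "true_strength_mcg": None,
                    "true_daily_dose_mcg": None,
                    "latent_step": None,
                    "is_decoy": True,
                }
            )


def _decoy_row(rng: np.random.Generator, patient_id: str, date: dt.date) -> dict:
    return {
        "patient_id": patient_id,
        "prescribed_date": date,
        "dispensed_date": date + dt.timedelta(days=int(rng.integers(0, 4))),
        "medication_name": _pick(rng, _DECOY_NAMES),
        "bnf_code": "0501",
        "formulation": "TAB",
        "prescribed_quantity": 1,
        "dispensed_quantity": 1,
        "dose_text": "TAKE ONE TABLET TWICE DAILY",
    }


def _nasal_row(rng: np.random.Generator, patient_id: str, date: dt.date) -> dict:
    return {
        "patient_id": patient_id,
        "prescribed_date": date,
        "dispensed_date": date + dt.timedelta(days=int(rng.integers(0, 4))),
        "medication_name": "BECLOMETASONE AQUEOUS NASAL SPRAY",
        "bnf_code": "1201",
        "formulation": "SPRAY",
        "prescribed_quantity": 1,
        "dispensed_quantity": 1,
        "dose_text": "TWO SPRAYS INTO EACH NOSTRIL ONCE DAILY",
    }
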