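"""Step-change episodes, durations with censoring, transitions and person-years.

A *step episode* is a maximal run of consecutive prescription events at one
treatment step.  Its duration runs from the episode's first event to the
first event of the next episode — step status is only observable at
prescription events, so that is the finest resolution available.  Each
patient's final episode is censored (the time to the next change is unknown)
and is excluded from duration summaries, with the censored percentage
reported per step.  Regimen changes between consecutive events at an
unchanged step are counted as within-step changes.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "ChangeDirection",
    "StepEpisode",
    "build_episodes",
    "episodes_table",
    "summarise_durations",
    "transition_matrix",
    "person_year_summary",
]


class ChangeDirection(str, enum.Enum):
    UP = "UP"
    DOWN = "DOWN"
    WITHIN = "WITHIN"  # reserved for zero-step "changes"; unused after merging
    CENSORED = "CENSORED"


@dataclass(frozen=True)
class StepEpisode:
    patient_id: str
    step: int
    start_date: dt.date
    end_date: dt.date
    duration_days: int
    next_step: Optional[int]
    direction: ChangeDirection
    regimen_changes_within: int

    def __post_init__(self) -> None:
        if self.duration_days != (self.end_date - self.start_date).days:
            raise ValueError("duration_days inconsistent with episode dates")
        if (self.next_step is None) != (self.direction == ChangeDirection.CENSORED):
            raise ValueError("censoring iff next_step is unknown")


def build_episodes(events: pd.DataFrame) -> list[StepEpisode]:
    """Episodes for ONE patient's date-ordered events (one event per date).

    ``events`` needs columns ``event_date``, ``step`` and (optionally)
    ``regimen_label``.  Consecutive events at the same step merge into one
    episode; a duplicate event (same date, same step) never alters the result.
    The last episode is censored with its end at the last observed event.
    """
    if events.empty:
        return []
    patient_id = str(events["patient_id"].iloc[0]) if "patient_id" in events else ""
    frame = events.sort_values("event_date", kind="stable")
    dates = pd.to_datetime(frame["event_date"]).dt.date.tolist()
    steps = [int(s) for s in frame["step"]]
    labels = (
        frame["regimen_label"].tolist()
        if "regimen_label" in frame
        else [""] * len(frame)
    )

    # group consecutive events by step
    runs: list[dict] = []
    for date, step, label in zip(dates, steps, labels):
        if runs and runs[-1]["step"] == step:
            run = runs[-1]
            if date == run["last_date"] and label == run["last_label"]:
                continue  # exact duplicate event
            if label != run["last_label"]:
                run["within_changes"] += 1
            run["last_date"], run["last_label"] = date, label
        else:
            runs.append(
                {"step": step, "start": date, "last_date": date,
                 "last_label": label, "within_changes": 0}
            )

    episodes = []
    for i, run in enumerate(runs):
        last = i == len(runs) - 1
        end = runs[i + 1]["start"] if not last else run["last_date"]
        next_step = runs[i + 1]["step"] if not last else None
        if next_step is None:
            direction = ChangeDirection.CENSORED
        else:
            direction = ChangeDirection.UP if next_step > run["step"] else ChangeDirection.DOWN
        episodes.append(
            StepEpisode(
                patient_id=patient_id,
                step=run["step"],
                start_date=run["start"],
                end_date=end,
                duration_days=(end - run["start"]).days,
                next_step=next_step,
                direction=direction,
                regimen_changes_within=run["within_changes"],
            )
        )
    return episodes


def episodes_table(events: pd.DataFrame) -> pd.DataFrame:
    """Episode table over all patients (events need ``patient_id``)."""
    columns = [
        "patient_id", "step", "start_date", "end_date", "duration_days",
        "next_step", "direction", "regimen_changes_within",
    ]
    rows = []
    if not events.empty:
        for _, group in events.groupby("patient_id", sort=True):
            for ep in build_episodes(group):
                rows.append(
                    {
                        "patient_id": ep.patient_id,
                        "step": ep.step,
                        "start_date": ep.start_date,
                        "end_date": ep.end_date,
                        "duration_days": ep.duration_days,
                        "next_step": ep.next_step,
                        "direction": ep.direction.value,
                        "regimen_changes_within": ep.regimen_changes_within,
                    }
                )
    return pd.DataFrame(rows, columns=columns)


def _duration_stats(durations: pd.Series) -> Optional[dict]:
    if durations.empty:
        return None
    q1, median, q3 = np.percentile(durations.to_numpy(dtype=float), [25, 50, 75])
    return {"n": int(len(durations)), "median": float(median), "q1": float(q1), "q3": float(q3)}


def summarise_durations(episodes: pd.DataFrame) -> dict:
    """Median/IQR of days until step change, overall, by direction and by step.

    Censored episodes are excluded from every duration summary; the per-step
    percent censored is reported alongside.  A stratum with no uncensored
    episodes yields no summary (absent, not zero).
    """
    out: dict = {"overall": None, "by_direction": {}, "by_step": {}}
    if episodes.empty:
        return out
    uncensored = episodes.loc[episodes["direction"] != ChangeDirection.CENSORED.value]
    out["overall"] = _duration_stats(uncensored["duration_days"])
    for direction in (ChangeDirection.UP, ChangeDirection.DOWN):
        stats = _duration_stats(
            uncensored.loc[uncensored["direction"] == direction.value, "duration_days"]
        )
        if stats is not None:
            out["by_direction"][direction.value] = stats
    for step, group in episodes.groupby("step"):
        stats = _duration_stats(
            group.loc[group["direction"] != ChangeDirection.CENSORED.value, "duration_days"]
        )
        pct_censored = 100.0 * (group["direction"] == ChangeDirection.CENSORED.value).mean()
        out["by_step"][int(step)] = {
            "summary": stats,
            "percent_censored": float(pct_censored),
            "n_episodes": int(len(group)),
        }
    return out


def duration_summary_table(episodes: pd.DataFrame) -> pd.DataFrame:
    """Per-step duration summary as a flat table (step, median, IQR, % censored)."""
    summary = summarise_durations(episodes)
    rows = []
    for step, info in sorted(summary["by_step"].items()):
        stats = info["summary"] or {}
        rows.append(
            {
                "step": step,
                "n_uncensored": stats.get("n", 0),
                "median_days": stats.get("median"),
                "iqr_low_days": stats.get("q1"),
                "iqr_high_days": stats.get("q3"),
                "percent_censored": info["percent_censored"],
            }
        )
    return pd.DataFrame(
        rows,
        columns=["step", "n_uncensored", "median_days", "iqr_low_days",
                 "iqr_high_days", "percent_censored"],
    )


def transition_matrix(
    episodes: pd.DataFrame, exclude_step0: bool = True
) -> tuple[pd.DataFrame, dict]:
    """Step-to-step transition counts and single-step-move fractions.

    Off-diagonal entry (i, j) counts uncensored episodes at step i followed by
    step j; diagonal entry (i, i) counts within-step regimen changes inside
    episodes at step i.  With ``exclude_step0`` (transitions to and from
    step 0 often reflect non-adherence rather than sanctioned changes), any
    transition touching step 0 is dropped.  The second return value reports
    the fraction of one-step moves among step-ups and step-downs separately.
    """
    steps = range(5)
    matrix = pd.DataFrame(0, index=list(steps), columns=list(steps))
    fractions: dict = {"single_step_up_pct": None, "single_step_down_pct": None}
    if episodes.empty:
        return matrix, fractions
    moved = episodes.loc[episodes["next_step"].notna()].copy()
    moved["next_step"] = moved["next_step"].astype(int)
    within = episodes.copy()
    if exclude_step0:
        moved = moved.loc[(moved["step"] != 0) & (moved["next_step"] != 0)]
        within = within.loc[within["step"] != 0]
    for row in moved.itertuples(index=False):
        matrix.loc[int(row.step), int(row.next_step)] += 1
    for step, group in within.groupby("step"):
        matrix.loc[int(step), int(step)] += int(group["regimen_changes_within"].sum())
    ups = moved.loc[moved["next_step"] > moved["step"]]
    downs = moved.loc[moved["next_step"] < moved["step"]]
    if len(ups):
        fractions["single_step_up_pct"] = float(
            100.0 * (ups["next_step"] - ups["step"] == 1).mean()
        )
    if len(downs):
        fractions["single_step_down_pct"] = float(
            100.0 * (downs["step"] - downs["next_step"] == 1).mean()
        )
    return matrix, fractions


def person_year_summary(events: pd.DataFrame) -> pd.DataFrame:
    """Distinct steps and step changes per person-year.

    Person-years are rolling 365-day blocks anchored at each patient's first
    event (anchored years avoid partial first years; calendar alignment is a
    documented alternative).  Only blocks containing at least one event are
    returned.  Changes count step differences between consecutive events
    within the block.
    """
    columns = ["patient_id", "year_index", "n_events", "n_distinct_steps", "n_step_changes"]
    if events.empty:
        return pd.DataFrame(columns=columns)
    rows = []
    frame = events.copy()
    frame["event_date"] = pd.to_datetime(frame["event_date"]).dt.date
    for patient_id, group in frame.groupby("patient_id", sort=True):
        group = group.sort_values("event_date", kind="stable")
        first = group["event_date"].iloc[0]
        year_idx = [ (d - first).days // 365 for d in group["event_date"] ]
        group = group.assign(_year=year_idx)
        for year, block in group.groupby("_year"):
            steps = [int(s) for s in block["step"]]
            changes = sum(a != b for a, b in zip(steps, steps[1:]))
            rows.append(
                {
                    "patient_id": patient_id,
                    "year_index": int(year),
                    "n_events": len(block),
                    "n_distinct_steps": len(set(steps)),
                    "n_step_changes": changes,
                }
            )
    return pd.DataFrame(rows, columns=columns)
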