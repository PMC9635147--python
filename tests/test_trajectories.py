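import datetime as dt
from itertools import product

import pandas as pd
import pytest

from asthmasteps import (
    build_episodes,
    episodes_table,
    person_year_summary,
    summarise_durations,
    transition_matrix,
)

BASE = dt.date(2010, 1, 1)


def events_frame(day_steps, patient="P1", labels=None):
    days, steps = zip(*day_steps) if day_steps else ((), ())
    return pd.DataFrame(
        {
            "patient_id": [patient] * len(days),
            "event_date": [BASE + dt.timedelta(days=d) for d in days],
            "step": list(steps),
            "regimen_label": labels if labels is not None else [str(s) for s in steps],
        }
    )


def naive_episodes(day_steps):
    """Brute-force reference: collapse runs, duration to next run's start,
    final run censored."""
    runs = []
    for day, step in day_steps:
        if runs and runs[-1][0] == step:
            runs[-1][2] = day
        else:
            runs.append([step, day, day])
    out = []
    for i, (step, start, last) in enumerate(runs):
        if i + 1 < len(runs):
            nxt_step, nxt_start, _ = runs[i + 1]
            out.append((step, nxt_start - start, "UP" if nxt_step > step else "DOWN"))
        else:
            out.append((step, last - start, "CENSORED"))
    return out


class TestBuildEpisodes:
    def test_merge_and_direction(self):
        eps = build_episodes(events_frame([(0, 1), (100, 1), (200, 2)]))
        assert [(e.step, e.duration_days, e.direction.value) for e in eps] == [
            (1, 200, "UP"),
            (2, 0, "CENSORED"),
        ]

    def test_single_event_is_censored(self):
        eps = build_episodes(events_frame([(0, 3)]))
        assert len(eps) == 1
        assert eps[0].direction.value == "CENSORED"
        assert eps[0].next_step is None

    def test_up_then_down(self):
        eps = build_episodes(events_frame([(0, 3), (50, 4), (300, 3)]))
        assert [(e.duration_days, e.direction.value) for e in eps] == [
            (50, "UP"), (250, "DOWN"), (0, "CENSORED"),
        ]

    def test_duplicate_event_is_inert(self):
        base = events_frame([(0, 1), (100, 1), (200, 2)])
        dup = pd.concat([base, base.iloc[[1]]]).sort_values("event_date")
        assert [
            (e.step, e.duration_days) for e in build_episodes(base)
        ] == [(e.step, e.duration_days) for e in build_episodes(dup)]

    def test_within_step_regimen_changes_counted(self):
        frame = events_frame(
            [(0, 3), (30, 3), (60, 3), (90, 4)],
            labels=["Medium-strength ICS + LABA", "Medium-strength ICS",
                    "Medium-strength ICS + LABA", "High-strength ICS + LABA"],
        )
        eps = build_episodes(frame)
        assert eps[0].regimen_changes_within == 2

    def test_exhaustive_against_bruteforce_oracle(self):
        """All trajectories of <=5 events over steps 0-4 match the naive
        reference for durations, directions and censoring."""
        days = (0, 50, 100, 150, 200)
        for n in range(1, 6):
            for steps in product(range(5), repeat=n):
                day_steps = list(zip(days[:n], steps))
                got = [
                    (e.step, e.duration_days, e.direction.value)
                    for e in build_episodes(events_frame(day_steps))
                ]
                assert got == naive_episodes(day_steps), day_steps


class TestSummariseDurations:
    def test_median_and_iqr(self):
        frame = events_frame([(0, 1), (100, 2), (300, 1), (600, 2), (650, 1)])
        summary = summarise_durations(episodes_table(frame))
        assert summary["overall"]["n"] == 4
        assert summary["by_direction"]["UP"]["n"] == 2
        assert summary["by_direction"]["DOWN"]["n"] == 2

    def test_all_censored_stratum_absent_not_zero(self):
        frame = events_frame([(0, 2)])
        summary = summarise_durations(episodes_table(frame))
        assert summary["overall"] is None
        assert summary["by_step"][2]["summary"] is None
        assert summary["by_step"][2]["percent_censored"] == 100.0

    def test_simple_median(self):
        episodes = episodes_table(
            pd.concat(
                [
                    events_frame([(0, 1), (d, 2)], patient=f"P{i}")
                    for i, d in enumerate((100, 200, 300))
                ]
            )
        )
        summary = summarise_durations(episodes)
        assert summary["by_direction"]["UP"]["median"] == 200.0

    def test_empty(self):
        summary = summarise_durations(episodes_table(pd.DataFrame()))
        assert summary["overall"] is None and summary["by_step"] == {}


class TestTransitionMatrix:
    def test_counts(self):
        frames = [
            events_frame([(0, 1), (10, 2)], patient="A"),
            events_frame([(0, 2), (10, 1)], patient="B"),
            events_frame([(0, 1), (10, 2)], patient="C"),
        ]
        episodes = episodes_table(pd.concat(frames))
        matrix, fractions = transition_matrix(episodes, exclude_step0=False)
        assert matrix.loc[1, 2] == 2
        assert matrix.loc[2, 1] == 1
        assert fractions["single_step_up_pct"] == 100.0
        assert fractions["single_step_down_pct"] == 100.0

    def test_step0_transitions_excluded(self):
        episodes = episodes_table(events_frame([(0, 0), (10, 1), (20, 0), (30, 2)]))
        matrix, _ = transition_matrix(episodes, exclude_step0=True)
        assert matrix.loc[0].sum() == 0 and matrix[0].sum() == 0

    def test_diagonal_holds_within_step_changes(self):
        frame = events_frame(
            [(0, 3), (30, 3), (90, 4)],
            labels=["Medium-strength ICS + LABA", "Medium-strength ICS",
                    "High-strength ICS + LABA"],
        )
        matrix, _ = transition_matrix(episodes_table(frame), exclude_step0=False)
        assert matrix.loc[3, 3] == 1


class TestPersonYears:
    def test_single_step_year(self):
        frame = events_frame([(0, 3), (100, 3), (200, 3)])
        out = person_year_summary(frame)
        assert len(out) == 1
        assert out.iloc[0]["n_distinct_steps"] == 1
        assert out.iloc[0]["n_step_changes"] == 0

    def test_two_steps_two_changes(self):
        frame = events_frame([(0, 2), (100, 3), (200, 2)])
        out = person_year_summary(frame)
        assert out.iloc[0]["n_distinct_steps"] == 2
        assert out.iloc[0]["n_step_changes"] == 2

    def test_years_anchored_at_first_event(self):
        frame = events_frame([(0, 1), (400, 2)])
        out = person_year_summary(frame)
        assert list(out["year_index"]) == [0, 1]
        # the empty middle of the follow-up contributes no empty blocks
        assert out["n_events"].tolist() == [1, 1]

    def test_empty(self):
        assert person_year_summary(pd.DataFrame()).empty
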