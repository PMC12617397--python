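"""Derived-item scoring for the self-report instruments and behavioural tasks.

Instruments: a 28-item adolescent mental-health screener (4-point items, 0-3)
embedding the PHQ-A depression and GAD-7 anxiety item sets; a 15-item short
form of the Difficulties in Emotion Regulation Scale (5-point items, 0-4,
three reverse-coded); and the 8-item Disruptive Behavior International Scale
(0-3).  Some screener symptoms were probed with several sub-questions; those
domains are scored as the maximum of their constituents before summation.
Tasks: an emotional go/no-go (false-alarm percentage of all responses) and a
delay discounting task (immediate-choice percentage of responded trials).

Scores are computed on complete rows only; any missing constituent yields NaN
(imputation happens upstream, with totals re-derived passively afterwards).
"""

from __future__ import annotations

import numbers

import numpy as np
import pandas as pd

__all__ = [
    "MISSING_CODES",
    "MMAPP_ITEMS",
    "DERS_ITEMS",
    "DERS_REVERSE",
    "DBIS_ITEMS",
    "GAD7_ITEMS",
    "PHQA_ITEMS",
    "MMAPP_TOTAL_ROSTER_75",
    "score_phqa",
    "score_gad7",
    "score_mmapp_total",
    "score_ders",
    "score_dbis",
    "score_egng",
    "score_ddt",
    "score_items_table",
    "OUTCOME_NAMES",
]

#: Categorical responses treated as missing until imputation.
MISSING_CODES = frozenset({"other", "dont_know", "prefer_not_to_say", "empty", ""})

# Multi-probe symptom domains: score is the max of the constituents.
PHQA_MOOD = ("sad_depressed", "annoyed_irritable", "hopeless")
PHQA_SLEEP = ("difficulty_falling_asleep", "waking_up_at_night", "sleeping_too_much")
PHQA_MOTOR = ("moving_slowly", "restless")
PHQA_SINGLE = (
    "not_enjoying",
    "easily_tired",
    "appetite_changes",
    "felt_like_failure",
    "trouble_concentrating",
    "self_harm_thoughts",
)
#: 14 screener items entering the 9-domain depression score (max 27).
PHQA_ITEMS = PHQA_MOOD + PHQA_SLEEP + PHQA_MOTOR + PHQA_SINGLE

#: Seven anxiety items (two shared with the depression set); plain sum, max 21.
GAD7_ITEMS = (
    "nervous_anxious",
    "cant_stop_worrying",
    "worried_different_things",
    "difficulty_relaxing",
    "restless",
    "annoyed_irritable",
    "worried_bad_things",
)

_MMAPP_EXTRA = (
    "lonely",
    "worthless",
    "panic_episodes",
    "angry_outbursts",
    "avoid_people",
    "physical_complaints",
    "crying_spells",
    "fearful",
    "difficulty_making_decisions",
)

#: Full 28-item screener roster (0-3 each).
MMAPP_ITEMS = PHQA_ITEMS + tuple(i for i in GAD7_ITEMS if i not in PHQA_ITEMS) + _MMAPP_EXTRA

#: 24-item summation roster for the total score calibrated so that
#: max(sleep) + sum(roster) has theoretical maximum 3 + 24*3 = 75, the scale
#: maximum implied by the 5%-of-maximum equivalence bound of 3.75.  The three
#: sleep probes (already represented through their max) and the doubly shared
#: "restless" probe are excluded.
MMAPP_TOTAL_ROSTER_75 = tuple(
    i for i in MMAPP_ITEMS if i not in PHQA_SLEEP and i != "restless"
)

DERS_REVERSE = (
    "pay_attention_to_feelings",
    "care_about_feelings",
    "aware_of_emotions",
)
DERS_ITEMS = DERS_REVERSE + (
    "overwhelmed_by_emotions",
    "embarrassed_by_feelings",
    "difficulty_focusing_when_upset",
    "out_of_control_when_upset",
    "stay_upset_long_time",
    "ashamed_when_upset",
    "difficulty_working_when_upset",
    "believe_will_stay_upset",
    "irritated_with_self_when_upset",
    "feel_weak_when_upset",
    "difficulty_thinking_when_upset",
    "emotions_unbearable",
)

DBIS_ITEMS = (
    "argues_with_adults",
    "loses_temper",
    "fights_with_peers",
    "breaks_rules",
    "blames_others",
    "annoys_others_on_purpose",
    "takes_things",
    "refuses_to_obey",
)

OUTCOME_NAMES = (
    "ders",
    "false_alarm_pct",
    "immediate_reward_pct",
    "mmapp_gad7",
    "mmapp_phqa",
    "mmapp_total",
    "dbis",
)


def _value(items, name, max_level):
    """Numeric item value, or None when missing/miscoded."""
    try:
        v = items[name]
    except (KeyError, IndexError):
        return None
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    if isinstance(v, str):
        if v.strip().lower() in MISSING_CODES:
            return None
        try:
            v = float(v)
        except ValueError:
            return None
    if not isinstance(v, numbers.Number) or not np.isfinite(v):
        return None
    v = float(v)
    if not 0 <= v <= max_level:
        raise ValueError(f"item {name} value {v} outside 0..{max_level}")
    return v


def _collect(items, names, max_level):
    vals = [_value(items, n, max_level) for n in names]
    if any(v is None for v in vals):
        return None
    return vals


def score_phqa(items) -> float:
    """Nine-domain depression score: three max-domains + six single items."""
    mood = _collect(items, PHQA_MOOD, 3)
    sleep = _collect(items, PHQA_SLEEP, 3)
    motor = _collect(items, PHQA_MOTOR, 3)
    single = _collect(items, PHQA_SINGLE, 3)
    if None in (mood, sleep, motor, single):
        return float("nan")
    return max(mood) + max(sleep) + max(motor) + sum(single)


def score_gad7(items) -> float:
    vals = _collect(items, GAD7_ITEMS, 3)
    return float("nan") if vals is None else sum(vals)


def score_mmapp_total(items, roster=MMAPP_ITEMS) -> float:
    """Max of the three sleep probes plus the sum over ``roster``.

    The published rule sums all 28 items (maximum 87); the roster is
    configurable, and :data:`MMAPP_TOTAL_ROSTER_75` reproduces the maximum of
    75 implied by the corresponding equivalence bound.
    """
    sleep = _collect(items, PHQA_SLEEP, 3)
    body = _collect(items, roster, 3)
    if sleep is None or body is None:
        return float("nan")
    return max(sleep) + sum(body)


def score_ders(items) -> float:
    """Sum of 15 emotion-dysregulation items, three reverse-coded (x -> 4-x)."""
    vals = _collect(items, DERS_ITEMS, 4)
    if vals is None:
        return float("nan")
    total = 0.0
    for name, v in zip(DERS_ITEMS, vals):
        total += (4 - v) if name in DERS_REVERSE else v
    return total


def score_dbis(items) -> float:
    vals = _collect(items, DBIS_ITEMS, 3)
    return float("nan") if vals is None else sum(vals)


def score_egng(trials: pd.DataFrame, denominator: str = "responses") -> float:
    """False-alarm percentage: responses on no-go trials / all responses * 100.

    ``trials`` has one row per trial with columns ``stimulus`` ("go"/"no_go"),
    ``response`` (bool) and ``practice`` (bool).  Practice trials are dropped.
    The published rule divides by all responses; ``denominator="nogo_trials"``
    switches to the conventional per-no-go-trial rate instead.
    """
    t = trials[~trials["practice"].astype(bool)]
    responses = t["response"].astype(bool)
    fa = int((responses & (t["stimulus"] == "no_go")).sum())
    if denominator == "responses":
        denom = int(responses.sum())
    elif denominator == "nogo_trials":
        denom = int((t["stimulus"] == "no_go").sum())
    else:
        raise ValueError(f"unknown denominator rule {denominator!r}")
    if denom == 0:
        return float("nan")
    return 100.0 * fa / denom


def score_ddt(trials: pd.DataFrame) -> float:
    """Immediate-reward percentage over responded delay-discounting trials."""
    t = trials[~trials["practice"].astype(bool)] if "practice" in trials else trials
    responded = t["choice"].isin(["immediate", "delayed"])
    n_resp = int(responded.sum())
    if n_resp == 0:
        return float("nan")
    return 100.0 * int((t["choice"] == "immediate").sum()) / n_resp


def score_items_table(
    table: pd.DataFrame, mmapp_total_roster=MMAPP_ITEMS
) -> pd.DataFrame:
    """Score every row of a wide item table.

    Returns a frame keyed like ``table`` with columns ``mmapp_phqa``,
    ``mmapp_gad7``, ``mmapp_total``, ``ders``, ``dbis``; rows with any missing
    constituent score NaN.
    """
    def block(names):
        sub = table[list(names)].apply(pd.to_numeric, errors="coerce")
        return sub

    # NaN-propagating max/sum keep incomplete rows undefined
    mmapp = block(MMAPP_ITEMS)
    mood = mmapp[list(PHQA_MOOD)].max(axis=1, skipna=False)
    sleep = mmapp[list(PHQA_SLEEP)].max(axis=1, skipna=False)
    motor = mmapp[list(PHQA_MOTOR)].max(axis=1, skipna=False)
    single = mmapp[list(PHQA_SINGLE)].sum(axis=1, skipna=False)
    ders = block(DERS_ITEMS)
    rev = 4 - ders[list(DERS_REVERSE)]
    ders_sum = rev.sum(axis=1, skipna=False) + ders[
        [c for c in DERS_ITEMS if c not in DERS_REVERSE]
    ].sum(axis=1, skipna=False)
    out = pd.DataFrame(
        {
            "mmapp_phqa": mood + sleep + motor + single,
            "mmapp_gad7": mmapp[list(GAD7_ITEMS)].sum(axis=1, skipna=False),
            "mmapp_total": sleep + mmapp[list(mmapp_total_roster)].sum(axis=1, skipna=False),
            "ders": ders_sum,
            "dbis": block(DBIS_ITEMS).sum(axis=1, skipna=False),
        },
        index=table.index,
    )
    return out
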