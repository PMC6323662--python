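"""Reference summaries and count-level fixtures for the modeled trial.

The subject-level data of the first-in-human study this package models are
not public; what is available are cohort-level counts and summary
statistics.  This module types those reported values in and provides
builders that expand the counts into minimal subject-level fixtures (ADA
timelines, adverse-event rosters) on which the analysis engines must
reproduce the reported percentages exactly.
"""

from __future__ import annotations

import math

import pandas as pd

from .immunogenicity import ADASample, ADATimeline

__all__ = [
    "SC_GM_AUC_INF",
    "IV_GM_AUC_INF",
    "SC_GM_CMAX",
    "RAC_CMAX_REPORTED",
    "T_HALF_MEAN_RANGE_DAYS",
    "PART_A_ADA_POSITIVE",
    "PART_B_ADA_POSITIVE",
    "PART_A_ADA_DAYS",
    "PART_B_ADA_DAYS",
    "build_part_a_ada_timelines",
    "build_part_b_ada_timelines",
    "build_teae_fixture",
]

# Geometric-mean AUC from time 0 to infinity (day*ng/mL) by dose, single dose.
SC_GM_AUC_INF = {30.0: 141766.6, 90.0: 389887.4, 300.0: 1347765.9}
IV_GM_AUC_INF = {300.0: 1240187.8, 750.0: 3793134.2}

# Geometric-mean Cmax (ng/mL), single SC doses.
SC_GM_CMAX = {30.0: 2861.3, 90.0: 9564.4, 300.0: 39204.9}

# Mean Cmax accumulation ratios for the three multiple-dose cohorts.
RAC_CMAX_REPORTED = {"F": 1.607, "G": 1.703, "H": 1.956}

# Range of cohort-mean terminal half-lives, single-dose part (days).
T_HALF_MEAN_RANGE_DAYS = (16.42, 25.50)

# ADA-positive counts among evaluable treated subjects, per cohort.
PART_A_ADA_POSITIVE = {"A": (0, 6), "B": (4, 6), "C": (3, 6), "D": (5, 6), "E": (4, 6)}
PART_B_ADA_POSITIVE = {"F": (4, 5), "G": (6, 6), "H": (6, 6)}

PART_A_ADA_DAYS = (1, 29, 57, 85)
PART_B_ADA_DAYS = (1, 29, 43, 57, 113, 141)


def _neg(day: float) -> ADASample:
    return ADASample(day, "negative")


def _pos(day: float, titer: float) -> ADASample:
    return ADASample(day, "positive", titer)


def _timeline(sid, arm, cohort, samples) -> ADATimeline:
    return ADATimeline(sid, arm, samples, first_dose_day=1.0, cohort=cohort)


def _pattern(days, pattern: dict[float, float | None]):
    """Samples over ``days``: day -> titer for positives, absent -> negative."""
    out = []
    for d in days:
        if d in pattern:
            out.append(_pos(d, pattern[d]))
        else:
            out.append(_neg(d))
    return out


def build_part_a_ada_timelines() -> list[ADATimeline]:
    """Subject-level ADA fixture expanding the single-dose part's counts.

    41 subjects (31 treated, 10 placebo).  Encoded structure: 16/30 evaluable
    treated positives (0/4/3/5/4 by cohort) splitting into 7 induced-transient,
    8 induced-persistent and 1 enhanced-transient; 3/39 baseline-positive
    subjects; one treated subject with no baseline sample and one withdrawn
    treated subject with no postbaseline samples.
    """
    d = PART_A_ADA_DAYS
    tl: list[ADATimeline] = []
    n = 0

    def add(cohort, arm, samples):
        nonlocal n
        n += 1
        tl.append(_timeline(f"S{n:02d}", arm, cohort, samples))

    # Cohort A: no positives; one stable baseline-positive (no qualifying rise).
    add("A", "active", _pattern(d, {1: 1.00, 29: 1.20, 57: 1.30, 85: 1.10}))
    for _ in range(5):
        add("A", "active", _pattern(d, {}))
    # Cohort B: 1 enhanced-transient (baseline positive), 1 induced-transient,
    # 2 induced-persistent, 2 negative.
    add("B", "active", _pattern(d, {1: 1.00, 29: 1.60}))
    add("B", "active", _pattern(d, {29: 1.50}))
    add("B", "active", _pattern(d, {57: 1.80, 85: 1.90}))
    add("B", "active", _pattern(d, {29: 1.70, 57: 1.70, 85: 1.80}))
    add("B", "active", _pattern(d, {}))
    add("B", "active", _pattern(d, {}))
    # Cohort C: 1 induced-transient, 2 induced-persistent, 2 negative, and one
    # evaluable negative subject with no baseline sample.
    add("C", "active", _pattern(d, {29: 1.40}))
    add("C", "active", _pattern(d, {57: 2.00, 85: 2.10}))
    add("C", "active", _pattern(d, {29: 1.60, 85: 1.70}))
    add("C", "active", _pattern(d, {}))
    add("C", "active", _pattern(d, {}))
    add("C", "active", _pattern(d[1:], {}))  # missing Day 1 sample
    # Cohort D: 7 treated; 1 withdrew before any postbaseline sample
    # (not evaluable); 5 of the remaining 6 positive (3 transient, 2 persistent).
    add("D", "active", [])  # withdrawn, no samples
    add("D", "active", _pattern(d, {29: 1.30}))
    add("D", "active", _pattern(d, {29: 1.50}))
    add("D", "active", _pattern(d, {29: 1.40, 57: 1.40}))
    add("D", "active", _pattern(d, {57: 1.90, 85: 2.00}))
    add("D", "active", _pattern(d, {85: 2.20}))
    add("D", "active", _pattern(d, {}))
    # Cohort E: 4 positive (2 transient, 2 persistent), 2 negative.
    add("E", "active", _pattern(d, {29: 1.20}))
    add("E", "active", _pattern(d, {29: 1.30, 57: 1.30}))
    add("E", "active", _pattern(d, {29: 1.80, 57: 1.90, 85: 2.00}))
    add("E", "active", _pattern(d, {85: 1.60}))
    add("E", "active", _pattern(d, {}))
    add("E", "active", _pattern(d, {}))
    # Placebo (10): 1 borderline induced-transient, 1 stable baseline-positive.
    add("A", "placebo", _pattern(d, {29: 1.10}))
    add("B", "placebo", _pattern(d, {1: 1.10, 29: 1.20, 57: 1.30, 85: 1.20}))
    for cohort in ("A", "B", "C", "C", "D", "D", "E", "E"):
        add(cohort, "placebo", _pattern(d, {}))
    return tl


def build_part_b_ada_timelines() -> list[ADATimeline]:
    """Subject-level ADA fixture expanding the multiple-dose part's counts.

    26 subjects (20 treated including the single terminated-cohort patient,
    6 placebo).  Encoded structure: 16/17 evaluable treated positives
    (4 induced-transient, 11 induced-persistent, 1 enhanced-persistent);
    1/22 baseline-positive; three treated subjects and one placebo subject
    without postbaseline samples.
    """
    d = PART_B_ADA_DAYS
    tl: list[ADATimeline] = []
    n = 0

    def add(cohort, arm, samples):
        nonlocal n
        n += 1
        tl.append(_timeline(f"M{n:02d}", arm, cohort, samples))

    # Cohort F: 7 treated, 2 withdrew before sampling; 4 of 5 evaluable are
    # positive (1 transient, 3 persistent).
    add("F", "active", [])
    add("F", "active", [])
    add("F", "active", _pattern(d, {29: 1.50}))
    add("F", "active", _pattern(d, {43: 1.80, 57: 1.90, 113: 2.00, 141: 2.00}))
    add("F", "active", _pattern(d, {57: 2.10, 141: 2.20}))
    add("F", "active", _pattern(d, {113: 1.70, 141: 1.70}))
    add("F", "active", _pattern(d, {}))
    # Cohort G: all 6 positive; 2 transient, 3 induced-persistent,
    # 1 enhanced-persistent (the part's only baseline positive).
    add("G", "active", _pattern(d, {29: 1.40}))
    add("G", "active", _pattern(d, {29: 1.30, 43: 1.30}))
    add("G", "active", _pattern(d, {43: 1.90, 141: 2.00}))
    add("G", "active", _pattern(d, {57: 2.00, 113: 2.10, 141: 2.20}))
    add("G", "active", _pattern(d, {29: 1.60, 57: 1.70, 113: 1.80, 141: 1.90}))
    add("G", "active", _pattern(d, {1: 1.00, 43: 1.70, 57: 1.80, 113: 1.90, 141: 2.00}))
    # Cohort H: all 6 positive; 1 transient, 5 persistent.
    add("H", "active", _pattern(d, {43: 1.50}))
    add("H", "active", _pattern(d, {29: 1.70, 141: 1.80}))
    add("H", "active", _pattern(d, {43: 1.80, 113: 1.90, 141: 2.00}))
    add("H", "active", _pattern(d, {57: 2.00, 141: 2.10}))
    add("H", "active", _pattern(d, {113: 1.60, 141: 1.70}))
    add("H", "active", _pattern(d, {29: 1.90, 57: 2.00, 113: 2.10, 141: 2.20}))
    # Cohort I: single patient, sample not available for testing.
    add("I", "active", [])
    # Placebo (6): one positive at Day 57 only, one lost to follow-up.
    add("F", "placebo", _pattern(d, {57: 1.10}))
    add("F", "placebo", _pattern(d, {}))
    add("G", "placebo", _pattern(d, {}))
    add("G", "placebo", _pattern(d, {}))
    add("H", "placebo", _pattern(d, {}))
    add("H", "placebo", [])  # lost to follow-up
    return tl


def build_teae_fixture(part: str = "A") -> tuple[pd.DataFrame, pd.DataFrame]:
    """(events, subjects) expanding the reported TEAE counts.

    Part A: 12 of 31 treated subjects with 15 events, 5 of 10 placebo
    subjects with 8 events.  Part B: 6 of 20 treated with 8 events, 3 of 6
    placebo with 3 events.
    """
    if part == "A":
        n_active, n_placebo = 31, 10
        active_affected, active_events = 12, 15
        placebo_affected, placebo_events = 5, 8
        prefix = "S"
    elif part == "B":
        n_active, n_placebo = 20, 6
        active_affected, active_events = 6, 8
        placebo_affected, placebo_events = 3, 3
        prefix = "M"
    else:
        raise ValueError("part must be 'A' or 'B'")
    subj_rows = []
    for i in range(n_active):
        subj_rows.append({"subject_id": f"{prefix}A{i + 1:02d}", "cohort": part, "arm": "active"})
    for i in range(n_placebo):
        subj_rows.append({"subject_id": f"{prefix}P{i + 1:02d}", "cohort": part, "arm": "placebo"})
    subjects = pd.DataFrame(subj_rows)
    terms = [
        ("Fatigue", "General disorders and administration site conditions"),
        ("Upper respiratory tract infection", "Infections and infestations"),
        ("Headache", "Nervous system disorders"),
        ("Nausea", "Gastrointestinal disorders"),
    ]

    def _events(ids, n_affected, n_events):
        rows = []
        for j in range(n_events):
            sid = ids[j % n_affected]  # recurrences land on already-affected subjects
            term, soc = terms[j % len(terms)]
            rows.append(
                {"subject_id": sid, "term": term, "soc": soc, "grade": 1, "onset_day": 2 + j,
                 "related": False, "serious": False, "clinically_significant": False}
            )
        return rows
    active_ids = [r["subject_id"] for r in subj_rows if r["arm"] == "active"]
    placebo_ids = [r["subject_id"] for r in subj_rows if r["arm"] == "placebo"]
    events = pd.DataFrame(
        _events(active_ids, active_affected, active_events) + _events(placebo_ids, placebo_affected, placebo_events)
    )
    return events, subjects
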