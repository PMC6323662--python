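"""Safety-event adjudication and TEAE tabulation.

Treatment-emergent adverse events (TEAEs) are tabulated by system organ
class and preferred term with subject-level counting (a subject counts once
per term regardless of recurrences).  Rule-based flags cover:

* DLAE (dose-limiting adverse event): a related, clinically significant
  TEAE of Grade >= 2 with onset inside the monitoring window (14 days after
  dosing), any allergic/hypersensitivity reaction, or severe neutropenia
  (absolute neutrophil count < 1000 cells/uL).
* AESI (adverse event of special interest): Hy's-law liver signal
  (transaminase >= 3x ULN with total bilirubin >= 2x ULN inside a 14-day
  window), serious hypersensitivity/anaphylaxis, injection-site reaction of
  Grade >= 2, infection of Grade >= 3, suspected infectious transmission.
* Eosinophilia grading: Grade >= 2 strictly above 1500 cells/uL, with the
  remaining ladder boundaries configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SafetyFlags",
    "flag_teae",
    "flag_dlae",
    "flag_aesi",
    "grade_eosinophilia",
    "summarize_teae",
    "safety_flags_table",
]

HYPERSENSITIVITY_TERMS = {"Anaphylactic reaction", "Hypersensitivity", "Drug hypersensitivity", "Allergic reaction"}
INJECTION_SITE_TERMS = {"Injection site reaction", "Infusion site erythema", "Injection site bruising", "Injection site erythema"}
INFECTION_SOC = "Infections and infestations"

# Absolute eosinophil count grade lower bounds (cells/uL, exclusive).
DEFAULT_EOS_GRADE_BOUNDS = {1: 500.0, 2: 1500.0, 3: 5000.0}


@dataclass(frozen=True)
class SafetyFlags:
    subject_id: str
    term: str
    is_teae: bool
    is_dlae: bool
    dlae_reason: str
    aesi_category: str  # none | hy_law | serious_hypersensitivity | injection_site_ge2 | infection_ge3 | infectious_transmission


def flag_teae(event: pd.Series | dict, first_dose_day: float, study_end_day: float) -> bool:
    """Treatment-emergent: onset on/after the first dose and within the study."""
    onset = event["onset_day"]
    return bool(first_dose_day <= onset <= study_end_day)


def _concurrent_neutropenia(labs: pd.DataFrame | None, subject_id: str, threshold: float = 1000.0) -> bool:
    if labs is None or labs.empty:
        return False
    anc = labs[(labs["subject_id"] == subject_id) & (labs["test"] == "ANC")]
    return bool((anc["value"] < threshold).any())


def flag_dlae(
    event: pd.Series | dict,
    labs: pd.DataFrame | None = None,
    first_dose_day: float = 1.0,
    window_days: float = 14.0,
) -> tuple[bool, str]:
    """Dose-limiting adverse event flag with the clause that fired."""
    if event["term"] in HYPERSENSITIVITY_TERMS:
        return True, "allergic or hypersensitivity reaction"
    if _concurrent_neutropenia(labs, event["subject_id"]):
        return True, "severe neutropenia (ANC < 1000 cells/uL)"
    if (
        event["grade"] >= 2
        and first_dose_day <= event["onset_day"] <= first_dose_day + window_days
        and bool(event["related"])
        and bool(event.get("clinically_significant", False) if isinstance(event, dict) else event["clinically_significant"])
    ):
        return True, "related clinically significant Grade >= 2 within window"
    return False, ""


def flag_aesi(event: pd.Series | dict, labs: pd.DataFrame | None = None, window_days: float = 14.0) -> str:
    """AESI category for one event (lab streams drive the Hy's-law clause)."""
    if hy_law_flag(labs, event["subject_id"], window_days):
        return "hy_law"
    term = event["term"]
    if term in HYPERSENSITIVITY_TERMS and bool(event["serious"]):
        return "serious_hypersensitivity"
    if term in INJECTION_SITE_TERMS and event["grade"] >= 2:
        return "injection_site_ge2"
    if event["soc"] == INFECTION_SOC and event["grade"] >= 3:
        return "infection_ge3"
    if term == "Suspected transmission of infectious agent":
        return "infectious_transmission"
    return "none"


def hy_law_flag(labs: pd.DataFrame | None, subject_id: str, window_days: float = 14.0) -> bool:
    """Transaminase >= 3x ULN with bilirubin >= 2x ULN within ``window_days``."""
    if labs is None or labs.empty:
        return False
    sl = labs[labs["subject_id"] == subject_id]
    tx = sl[(sl["test"].isin(("ALT", "AST"))) & (sl["value"] >= 3.0 * sl["uln"])]
    bi = sl[(sl["test"] == "BILI") & (sl["value"] >= 2.0 * sl["uln"])]
    for _, t in tx.iterrows():
        if (abs(bi["day"] - t["day"]) <= window_days).any():
            return True
    return False


def grade_eosinophilia(labs: pd.DataFrame, bounds: dict[int, float] | None = None) -> pd.DataFrame:
    """Per-record eosinophil grade plus per-subject worst grade and its day.

    Grade g is assigned when the count strictly exceeds ``bounds[g]``; the
    Grade-2 boundary is fixed at 1500 cells/uL by convention, the others are
    configurable.
    """
    bounds = bounds or DEFAULT_EOS_GRADE_BOUNDS
    aec = labs[labs["test"] == "AEC"].copy()
    if (aec["value"] < 0).any():
        raise ValueError("negative absolute eosinophil count")
    def _grade(v: float) -> int:
        g = 0
        for grade in sorted(bounds):
            if v > bounds[grade]:
                g = grade
        return g
    aec["grade"] = aec["value"].map(_grade)
    worst = aec.sort_values(["grade", "value"]).groupby("subject_id").tail(1)
    worst = worst.rename(columns={"grade": "worst_grade", "day": "worst_day", "value": "worst_value"})
    return aec.merge(worst[["subject_id", "worst_grade", "worst_day", "worst_value"]], on="subject_id")


def summarize_teae(events: pd.DataFrame, subjects: pd.DataFrame, cohorts=None) -> dict:
    """Arm-level TEAE table: totals plus subject counts n (%) by SOC and term.

    Percentages use the arm's full roster as denominator.  Raises if an
    event references a subject missing from the roster.
    """
    roster = subjects if cohorts is None else subjects[subjects["cohort"].isin(cohorts)]
    ids = set(roster["subject_id"])
    ev = events[events["subject_id"].isin(set(events["subject_id"]) & ids)]
    orphans = set(events["subject_id"]) - set(subjects["subject_id"])
    if orphans:
        raise ValueError(f"events reference unknown subjects: {sorted(orphans)}")
    out = {}
    for arm, arm_roster in roster.groupby("arm"):
        denom = len(arm_roster)
        arm_ev = ev[ev["subject_id"].isin(set(arm_roster["subject_id"]))]
        affected = arm_ev["subject_id"].nunique()
        soc_rows = []
        for soc, g in arm_ev.groupby("soc"):
            soc_rows.append({"level": "soc", "soc": soc, "term": "", "n_subjects": g["subject_id"].nunique(),
                             "pct": 100.0 * g["subject_id"].nunique() / denom})
            for term, tg in g.groupby("term"):
                soc_rows.append({"level": "term", "soc": soc, "term": term, "n_subjects": tg["subject_id"].nunique(),
                                 "pct": 100.0 * tg["subject_id"].nunique() / denom})
        out[arm] = {
            "n_subjects": denom,
            "total_events": int(len(arm_ev)),
            "subjects_with_event": int(affected),
            "pct_with_event": 100.0 * affected / denom if denom else math.nan,
            "table": pd.DataFrame(soc_rows, columns=["level", "soc", "term", "n_subjects", "pct"]),
        }
    return out


def safety_flags_table(
    events: pd.DataFrame,
    labs: pd.DataFrame,
    dosing: pd.DataFrame,
    study_end_day: float = 141.0,
    window_days: float = 14.0,
) -> pd.DataFrame:
    """Per-event TEAE/DLAE/AESI flags for a whole dataset."""
    first_dose = dosing.groupby("subject_id")["day"].min().to_dict()
    rows = []
    for _, ev in events.iterrows():
        fd = first_dose.get(ev["subject_id"], 1.0)
        teae = flag_teae(ev, fd, study_end_day)
        dlae, reason = flag_dlae(ev, labs, fd, window_days) if teae else (False, "")
        aesi = flag_aesi(ev, labs, window_days) if teae else "none"
        rows.append(
            {
                "subject_id": ev["subject_id"],
                "term": ev["term"],
                "soc": ev["soc"],
                "grade": ev["grade"],
                "onset_day": ev["onset_day"],
                "is_teae": teae,
                "is_dlae": dlae,
                "dlae_reason": reason,
                "aesi_category": aesi,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["subject_id", "term", "soc", "grade", "onset_day", "is_teae", "is_dlae", "dlae_reason", "aesi_category"],
    )
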