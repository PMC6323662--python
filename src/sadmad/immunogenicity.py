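"""Anti-drug-antibody (ADA) adjudication.

Per-subject timelines of assay status and titer are classified on two axes:

* mechanism — *treatment-induced* (baseline negative or missing, at least one
  positive postbaseline sample) or *treatment-enhanced* (baseline positive
  with a postbaseline titer at least 0.60 titer units above baseline,
  threshold inclusive); otherwise the subject is ADA-negative, including
  subjects positive at baseline whose titer never rises by the threshold.
* duration — *persistent* (positive at the last postbaseline sampling
  timepoint, or first-to-last positive span of at least 16 weeks = 112 days)
  or *transient* (everything else among ADA-positive subjects: a single
  positive that is not the last timepoint, or a sub-16-week run ending in a
  negative final sample).

Subjects with no postbaseline sample (e.g. early withdrawal) are not
evaluable and drop out of the incidence denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ADASample",
    "ADATimeline",
    "ADAClassification",
    "TITER_THRESHOLD",
    "PERSISTENCE_DAYS",
    "classify_mechanism",
    "classify_duration",
    "classify_timeline",
    "timelines_from_frame",
    "classification_table",
    "compute_prevalence_incidence",
    "overlay_ada_pk",
]

TITER_THRESHOLD = 0.60  # titer units, additive on the log-type titer scale
PERSISTENCE_DAYS = 112  # 16 weeks on study-day arithmetic


@dataclass(frozen=True)
class ADASample:
    day: float
    status: str  # "positive" | "negative" | "missing"
    titer: float = math.nan

    def __post_init__(self):
        if self.status not in ("positive", "negative", "missing"):
            raise ValueError(f"bad ADA status {self.status!r}")
        if not math.isnan(self.titer) and self.status != "positive":
            raise ValueError("titer present implies positive status")


@dataclass
class ADATimeline:
    subject_id: str
    arm: str
    samples: list  # time-ordered ADASamples
    first_dose_day: float = 1.0
    cohort: str = ""

    def __post_init__(self):
        days = [s.day for s in self.samples]
        if days != sorted(days):
            raise ValueError("samples must be time-ordered")

    @property
    def baseline(self) -> ADASample | None:
        """Latest sample at or before the first dose, if any."""
        pre = [s for s in self.samples if s.day <= self.first_dose_day]
        return pre[-1] if pre else None

    @property
    def postbaseline(self) -> list:
        return [s for s in self.samples if s.day > self.first_dose_day]


@dataclass(frozen=True)
class ADAClassification:
    subject_id: str
    arm: str
    cohort: str
    baseline_status: str  # "positive" | "negative" | "missing"
    evaluable: bool
    ada_positive: bool
    mechanism: str  # "none" | "treatment_induced" | "treatment_enhanced"
    duration: str  # "none" | "transient" | "persistent"


def classify_mechanism(timeline: ADATimeline, titer_threshold: float = TITER_THRESHOLD) -> str:
    """Mechanism axis; raises if the timeline has no postbaseline sample."""
    post = timeline.postbaseline
    if not post:
        raise ValueError("no postbaseline samples; timeline is not evaluable")
    base = timeline.baseline
    base_status = base.status if base is not None else "missing"
    post_positive = [s for s in post if s.status == "positive"]
    if base_status in ("negative", "missing"):
        return "treatment_induced" if post_positive else "none"
    # baseline positive: only a qualifying titer rise counts
    base_titer = base.titer
    for s in post_positive:
        if not math.isnan(s.titer) and s.titer >= base_titer + titer_threshold:
            return "treatment_enhanced"
    return "none"


def classify_duration(timeline: ADATimeline, mechanism: str, persistence_days: float = PERSISTENCE_DAYS) -> str:
    """Duration axis for an ADA-positive subject (mechanism != none)."""
    if mechanism == "none":
        raise ValueError("duration is undefined for ADA-negative subjects")
    post = timeline.postbaseline
    positives = [s for s in post if s.status == "positive"]
    if post[-1].status == "positive":
        return "persistent"
    if positives and positives[-1].day - positives[0].day >= persistence_days:
        return "persistent"
    return "transient"


def classify_timeline(
    timeline: ADATimeline,
    titer_threshold: float = TITER_THRESHOLD,
    persistence_days: float = PERSISTENCE_DAYS,
) -> ADAClassification:
    base = timeline.baseline
    base_status = base.status if base is not None else "missing"
    if not timeline.postbaseline:
        return ADAClassification(
            timeline.subject_id, timeline.arm, timeline.cohort, base_status,
            evaluable=False, ada_positive=False, mechanism="none", duration="none",
        )
    mech = classify_mechanism(timeline, titer_threshold)
    dur = classify_duration(timeline, mech, persistence_days) if mech != "none" else "none"
    return ADAClassification(
        timeline.subject_id, timeline.arm, timeline.cohort, base_status,
        evaluable=True, ada_positive=mech != "none", mechanism=mech, duration=dur,
    )


def timelines_from_frame(ada: pd.DataFrame, subjects: pd.DataFrame, first_dose_day: float = 1.0) -> list[ADATimeline]:
    """Build per-subject timelines from ``ada.csv``/``subjects.csv`` tables.

    Every rostered subject yields a timeline (possibly empty, hence not
    evaluable), so withdrawal-driven denominators fall out naturally.
    """
    out = []
    grouped = {sid: g.sort_values("day") for sid, g in ada.groupby("subject_id")}
    for _, srow in subjects.iterrows():
        sid = srow["subject_id"]
        g = grouped.get(sid)
        samples = []
        if g is not None:
            for _, r in g.iterrows():
                titer = float(r["titer"]) if r["status"] == "positive" and pd.notna(r["titer"]) else math.nan
                samples.append(ADASample(float(r["day"]), str(r["status"]), titer))
        out.append(ADATimeline(sid, srow["arm"], samples, first_dose_day, cohort=srow.get("cohort", "")))
    return out


def classification_table(timelines: list[ADATimeline], **kwargs) -> pd.DataFrame:
    rows = [vars(classify_timeline(t, **kwargs)) for t in timelines]
    return pd.DataFrame(rows)


def compute_prevalence_incidence(classifications: pd.DataFrame, arm: str | None = None, cohorts=None) -> dict:
    """Baseline prevalence and postdose incidence percentages with denominators.

    Prevalence: % baseline-positive among subjects with a baseline sample
    (both arms unless ``arm`` given).  Incidence: % ADA-positive among
    evaluable subjects of the selected arm.  Zero denominators yield NaN with
    a reason.
    """
    df = classifications
    if cohorts is not None:
        df = df[df["cohort"].isin(cohorts)]
    with_base = df[df["baseline_status"] != "missing"]
    prev_n = len(with_base)
    prev_k = int((with_base["baseline_status"] == "positive").sum())
    sub = df if arm is None else df[df["arm"] == arm]
    evaluable = sub[sub["evaluable"]]
    inc_n = len(evaluable)
    inc_k = int(evaluable["ada_positive"].sum())
    return {
        "prevalence_pct": 100.0 * prev_k / prev_n if prev_n else math.nan,
        "prevalence_numerator": prev_k,
        "prevalence_denominator": prev_n,
        "incidence_pct": 100.0 * inc_k / inc_n if inc_n else math.nan,
        "incidence_numerator": inc_k,
        "incidence_denominator": inc_n,
        "reason": "" if prev_n and inc_n else "zero denominator",
    }


def overlay_ada_pk(classifications: pd.DataFrame, nca_subject: pd.DataFrame, profile: str = "day1") -> pd.DataFrame:
    """PK stratified by ADA status: per cohort x status, half-life and
    apparent clearance as mean +/- SD, individual values when n <= 2, and
    "NA" for empty strata.  Only span-valid terminal fits contribute.
    """
    nca = nca_subject[nca_subject["profile"] == profile]
    merged = nca.merge(
        classifications[["subject_id", "ada_positive", "evaluable"]], on="subject_id", how="left", indicator=True
    )
    dropped = merged[merged["_merge"] != "both"]["subject_id"].tolist()
    merged = merged[(merged["_merge"] == "both") & merged["evaluable"]]
    rows = []
    for cohort, cgrp in merged.groupby("cohort"):
        for status, flag in (("ADA-", False), ("ADA+", True)):
            grp = cgrp[cgrp["ada_positive"] == flag]
            grp = grp[grp["lambda_valid"].astype(bool)]
            entry = {"cohort": cohort, "ada_status": status, "n": len(grp)}
            for col, name in (("t_half_day", "t_half"), ("cl_over_f_l_day", "clearance")):
                vals = grp[col].to_numpy(dtype=float)
                vals = vals[np.isfinite(vals)]
                if len(vals) == 0:
                    entry[f"{name}_display"] = "NA"
                    entry[f"{name}_mean"] = math.nan
                    entry[f"{name}_sd"] = math.nan
                elif len(vals) <= 2:
                    entry[f"{name}_display"] = ", ".join(f"{v:.3g}" for v in vals)
                    entry[f"{name}_mean"] = float(vals.mean())
                    entry[f"{name}_sd"] = math.nan
                else:
                    entry[f"{name}_display"] = f"{vals.mean():.3g} ± {vals.std(ddof=1):.2g}"
                    entry[f"{name}_mean"] = float(vals.mean())
                    entry[f"{name}_sd"] = float(vals.std(ddof=1))
            rows.append(entry)
    out = pd.DataFrame(rows)
    out.attrs["excluded_subjects"] = dropped
    return out
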