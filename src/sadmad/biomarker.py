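"""Total-target biomarker handling and engagement summaries.

Serum total IL-17AA and IL-17FF rise after dosing because antibody capture
extends the cytokine's circulating half-life; the rise is therefore direct
evidence of target engagement.  Values below each assay's minimum
quantifiable concentration (MQC: 8 pg/mL for IL-17AA, 6 pg/mL for IL-17FF)
are analyzed — and plotted — as half the MQC.

The engagement call is necessarily an extrinsic criterion (the underlying
observation is qualitative): a subject is flagged *elevated* when the peak
postdose value reaches at least ``fold * baseline`` and exceeds baseline by
at least one MQC, both configurable.  Peaks are found on the natural scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .simulate import MQC_PG_ML

__all__ = [
    "EngagementSummary",
    "impute_blq",
    "summarize_engagement",
    "engagement_table",
    "dose_trend",
]


@dataclass(frozen=True)
class EngagementSummary:
    subject_id: str
    analyte: str
    baseline: float  # pg/mL, on the imputed analysis scale
    peak: float  # pg/mL, max postdose
    peak_day: float
    elevated: bool
    evaluable: bool = True
    reason: str = ""


def impute_blq(records: pd.DataFrame, mqc: dict[str, float] | None = None) -> pd.DataFrame:
    """Replace BLQ biomarker values by MQC/2 on the analysis scale.

    Idempotent: already-imputed records stay put because the flag, not the
    value, drives the substitution.  Quantified values are untouched.
    """
    mqc = mqc or MQC_PG_ML
    unknown = set(records["analyte"]) - set(mqc)
    if unknown:
        raise ValueError(f"unknown analyte(s): {sorted(unknown)}")
    out = records.copy()
    half = out["analyte"].map(mqc) / 2.0
    out["value_pg_ml"] = np.where(out["blq_flag"], half, out["value_pg_ml"])
    return out


def summarize_engagement(
    records: pd.DataFrame,
    first_dose_day: float = 1.0,
    fold: float = 2.0,
    mqc: dict[str, float] | None = None,
) -> EngagementSummary:
    """Engagement summary for one subject x analyte block of imputed records.

    Baseline is the last value at or before the first dose; peak is the
    maximum strictly-postdose value.  ``elevated`` iff
    ``peak >= max(fold*baseline, baseline + MQC)``.
    """
    mqc = mqc or MQC_PG_ML
    sid = records["subject_id"].iloc[0]
    analyte = records["analyte"].iloc[0]
    rec = records.sort_values("day")
    pre = rec[rec["day"] <= first_dose_day]
    post = rec[rec["day"] > first_dose_day]
    if pre.empty or post.empty:
        return EngagementSummary(sid, analyte, math.nan, math.nan, math.nan, False, False,
                                 "missing baseline" if pre.empty else "no postdose records")
    baseline = float(pre["value_pg_ml"].iloc[-1])
    i = post["value_pg_ml"].idxmax()
    peak = float(post.loc[i, "value_pg_ml"])
    peak_day = float(post.loc[i, "day"])
    threshold = max(fold * baseline, baseline + mqc[analyte])
    return EngagementSummary(sid, analyte, baseline, peak, peak_day, bool(peak >= threshold))


def engagement_table(
    biomarker: pd.DataFrame,
    dosing: pd.DataFrame | None = None,
    fold: float = 2.0,
    mqc: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-subject x analyte engagement table from raw biomarker records."""
    first_dose = {}
    if dosing is not None and not dosing.empty:
        first_dose = dosing.groupby("subject_id")["day"].min().to_dict()
    imputed = impute_blq(biomarker, mqc)
    rows = []
    for (sid, analyte), grp in imputed.groupby(["subject_id", "analyte"]):
        fd = first_dose.get(sid, 1.0)
        rows.append(vars(summarize_engagement(grp, first_dose_day=fd, fold=fold, mqc=mqc)))
    return pd.DataFrame(rows)


def dose_trend(
    peaks: pd.DataFrame,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> dict:
    """Rank correlation between dose and cohort-median peak level.

    ``peaks`` needs columns ``cohort``, ``dose_mg``, ``peak``.  Spearman rho
    is computed on (dose level, cohort median peak); the one-sided p-value
    (increasing trend) comes from permuting subjects across cohorts while
    keeping cohort sizes fixed.
    """
    df = peaks.dropna(subset=["peak"])
    doses = df.groupby("cohort")["dose_mg"].first()
    if doses.nunique() < 2:
        raise ValueError("dose-trend analysis needs >= 2 dose levels")
    values = df["peak"].to_numpy(dtype=float)
    labels = sorted(doses.index)
    groups = [np.flatnonzero((df["cohort"] == lab).to_numpy()) for lab in labels]
    dose_ranks = sps.rankdata([doses[lab] for lab in labels])

    def _rho(v: np.ndarray) -> float:
        med = [np.median(v[g]) for g in groups]
        ranks = sps.rankdata(med)
        if np.ptp(ranks) == 0:
            return 0.0
        return float(np.corrcoef(dose_ranks, ranks)[0, 1])

    rho_obs = _rho(values)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        hits += _rho(rng.permutation(values)) >= rho_obs
    p = (1 + hits) / (1 + n_permutations)
    return {"rho": rho_obs, "p_value": float(p), "n_permutations": n_permutations}
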