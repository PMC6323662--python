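"""Synthetic ascending-dose trial generation.

Every downstream stage (NCA, immunogenicity, biomarker, safety) is exercised
on data produced here: permuted-block randomization, a one-compartment PK
model with superposition over repeated doses, BLQ censoring at the drug
assay's quantification limit, scripted anti-drug-antibody titer scenarios,
a saturating total-target biomarker response, and adverse-event / laboratory
streams with injectable rule-testing edge cases.

Randomness is reproducible: one master seed; each subject draws from
substreams derived by stable hashing of its subject id, so adding a subject
to a dataset never perturbs any other subject's data.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import CohortSpec, InvalidDesignError, PKModelParams, SubjectRecord

__all__ = [
    "LLOQ_NG_ML",
    "MQC_PG_ML",
    "ADA_SCENARIOS",
    "generate_randomization",
    "predicted_concentration",
    "sc_peak_time",
    "simulate_concentration_profile",
    "apply_blq_censoring",
    "simulate_ada_titers",
    "simulate_biomarker",
    "simulate_safety_streams",
    "TrialDataset",
    "simulate_trial",
    "write_trial_dataset",
    "read_trial_dataset",
]

# Lower limit of quantification of the serum drug assay (ng/mL).
LLOQ_NG_ML = 140.0

# Minimum quantifiable concentration of the two total-target biomarker
# assays (pg/mL).
MQC_PG_ML = {"IL17AA": 8.0, "IL17FF": 6.0}

ADA_SCENARIOS = (
    "never",
    "induced_transient",
    "induced_persistent",
    "enhanced",
    "baseline_positive_stable",
)

# Small fixed preferred-term -> system-organ-class map used in place of a
# full regulatory dictionary.
AE_TERM_SOC = {
    "Fatigue": "General disorders and administration site conditions",
    "Influenza like illness": "General disorders and administration site conditions",
    "Injection site reaction": "General disorders and administration site conditions",
    "Infusion site erythema": "General disorders and administration site conditions",
    "Injection site bruising": "General disorders and administration site conditions",
    "Upper respiratory tract infection": "Infections and infestations",
    "Viral upper respiratory tract infection": "Infections and infestations",
    "Otitis media": "Infections and infestations",
    "Furuncle": "Infections and infestations",
    "Pharyngitis streptococcal": "Infections and infestations",
    "Nausea": "Gastrointestinal disorders",
    "Abdominal pain upper": "Gastrointestinal disorders",
    "Headache": "Nervous system disorders",
    "Dizziness": "Nervous system disorders",
    "Syncope": "Nervous system disorders",
    "Oropharyngeal pain": "Respiratory, thoracic and mediastinal disorders",
    "Erythema": "Skin and subcutaneous tissue disorders",
    "Ligament sprain": "Injury, poisoning and procedural complications",
}

_STREAM_TAGS = {"arm": 0, "pk_bsv": 1, "pk_noise": 2, "ada": 3, "biomarker": 4, "safety": 5, "weight": 6}


def _subject_rng(seed: int, subject_id: str, stream: str) -> np.random.Generator:
    """Generator for one subject/stream, stable under roster changes."""
    tag = zlib.crc32(subject_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag, _STREAM_TAGS[stream]]))


# ---------------------------------------------------------------------------
# Randomization
# ---------------------------------------------------------------------------

def generate_randomization(spec: CohortSpec, seed: int, block_size: int | None = None) -> list[str]:
    """Permuted-block arm assignments for one cohort.

    The default block is the whole cohort (n_active + n_placebo), so the
    allocation ratio (e.g. 6:2, or 12:4) is exact at cohort completion.  A
    smaller ``block_size`` must hold the reduced ratio an integer number of
    times.
    """
    if spec.n_total <= 0:
        raise InvalidDesignError("cohort size must be positive")
    n_act, n_plc = spec.n_active, spec.n_placebo
    g = np.gcd(n_act, n_plc) if n_plc else n_act
    unit = (n_act + n_plc) // g if g else n_act + n_plc
    if block_size is None:
        block_size = spec.n_total
    if block_size % unit or spec.n_total % block_size:
        raise InvalidDesignError(
            f"block_size {block_size} incompatible with ratio {n_act}:{n_plc} and cohort size {spec.n_total}"
        )
    per_block_act = block_size * n_act // spec.n_total
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(spec.label.encode()), _STREAM_TAGS["arm"]]))
    out: list[str] = []
    for _ in range(spec.n_total // block_size):
        block = ["active"] * per_block_act + ["placebo"] * (block_size - per_block_act)
        out.extend(rng.permutation(block).tolist())
    return out


# ---------------------------------------------------------------------------
# Concentration model
# ---------------------------------------------------------------------------

def sc_peak_time(ka: float, k: float) -> float:
    """Peak time of a single first-order-absorption dose: ln(ka/k)/(ka-k)."""
    if np.isclose(ka, k, rtol=1e-9):
        return 1.0 / k
    return float(np.log(ka / k) / (ka - k))


def _conc_single_dose(tau, dose_ng, route, duration_days, CL_mL, V_mL, ka, F_abs):
    """Concentration (ng/mL) at times ``tau`` (days) after one dose; 0 for tau<0."""
    tau = np.asarray(tau, dtype=float)
    k = CL_mL / V_mL
    c = np.zeros_like(tau)
    on = tau >= 0
    t = tau[on]
    if route == "SC":
        if np.isclose(ka, k, rtol=1e-8):
            # limiting form as ka -> k
            c[on] = F_abs * dose_ng * ka * t / V_mL * np.exp(-k * t)
        else:
            c[on] = (
                F_abs * dose_ng * ka / (V_mL * (ka - k)) * (np.exp(-k * t) - np.exp(-ka * t))
            )
    else:  # IV
        if duration_days <= 0:
            c[on] = dose_ng / V_mL * np.exp(-k * t)
        else:
            rate = dose_ng / duration_days
            during = t <= duration_days
            c_on = np.empty_like(t)
            c_on[during] = rate / CL_mL * (1.0 - np.exp(-k * t[during]))
            c_end = rate / CL_mL * (1.0 - np.exp(-k * duration_days))
            c_on[~during] = c_end * np.exp(-k * (t[~during] - duration_days))
            c[on] = c_on
    return c


def predicted_concentration(
    times_days,
    doses: list[tuple[float, float]],
    route: str,
    params: PKModelParams,
    infusion_duration_h: float = 0.0,
) -> np.ndarray:
    """Noiseless superposition concentration (ng/mL) at ``times_days``.

    ``doses`` is a list of (dose_time_days, dose_mg); times are days after
    the first dose.  Negative evaluation times are an error.
    """
    times = np.asarray(times_days, dtype=float)
    if (times < 0).any():
        raise ValueError("negative evaluation time")
    CL_mL, V_mL = params.CL * 1000.0, params.V * 1000.0
    dur = infusion_duration_h / 24.0
    total = np.zeros_like(times)
    for t_dose, dose_mg in doses:
        total += _conc_single_dose(
            times - t_dose, dose_mg * 1e6, route, dur, CL_mL, V_mL, params.ka, params.F_abs
        )
    return total


def _sampling_times(spec: CohortSpec) -> np.ndarray:
    """Days post first dose at which PK serum samples are drawn.

    Calendar days map to day-1 offsets; IV cohorts add an end-of-infusion
    sample, where the observed peak occurs.
    """
    t = np.asarray(spec.pk_sampling_days, dtype=float) - 1.0
    if spec.route == "IV" and spec.infusion_duration_h > 0:
        extra = [td - 1.0 + spec.infusion_duration_h / 24.0 for td in spec.dosing_days]
        t = np.unique(np.concatenate([t, extra]))
    return t


def simulate_concentration_profile(
    subject: SubjectRecord,
    spec: CohortSpec,
    params: PKModelParams,
    seed: int,
) -> pd.DataFrame:
    """Serum concentrations for one subject at the cohort's sampling times.

    Active subjects get individual parameters (log-normal between-subject
    variability on CL, V, ka) and proportional log-normal residual noise;
    placebo subjects yield an all-zero series.  Returns columns
    ``subject_id, day_decimal, conc_ng_ml, blq_flag`` (flag all-False here;
    censoring is applied separately).
    """
    if subject.cohort != spec.label:
        raise ValueError(f"subject {subject.subject_id} is not in cohort {spec.label}")
    times = _sampling_times(spec)
    if subject.withdrawal_day is not None:
        times = times[times <= subject.withdrawal_day - 1]
    if subject.arm == "placebo":
        conc = np.zeros_like(times)
    else:
        bsv = _subject_rng(seed, subject.subject_id, "pk_bsv")
        indiv = PKModelParams(
            CL=params.CL * float(np.exp(params.omega_cl * bsv.standard_normal())),
            V=params.V * float(np.exp(params.omega_v * bsv.standard_normal())),
            ka=params.ka * float(np.exp(params.omega_ka * bsv.standard_normal())),
            F_abs=params.F_abs,
            sigma_prop=params.sigma_prop,
        )
        doses = [(d - 1.0, spec.dose_mg) for d in spec.dosing_days if subject.withdrawal_day is None or d <= subject.withdrawal_day]
        conc = predicted_concentration(times, doses, spec.route, indiv, spec.infusion_duration_h)
        if params.sigma_prop > 0:
            noise = _subject_rng(seed, subject.subject_id, "pk_noise")
            s = np.sqrt(np.log1p(params.sigma_prop**2))
            conc = conc * np.exp(s * noise.standard_normal(conc.shape))
    return pd.DataFrame(
        {
            "subject_id": subject.subject_id,
            "day_decimal": times + 1.0,
            "conc_ng_ml": conc,
            "blq_flag": False,
        }
    )


def apply_blq_censoring(conc: pd.DataFrame, lloq: float = LLOQ_NG_ML) -> pd.DataFrame:
    """Set concentrations below ``lloq`` to zero and flag them BLQ.

    Values exactly at the limit are quantifiable.  Idempotent; never changes
    the number of records.
    """
    if lloq <= 0:
        raise ValueError("lloq must be positive")
    out = conc.copy()
    below = out["conc_ng_ml"] < lloq
    out.loc[below, "conc_ng_ml"] = 0.0
    out["blq_flag"] = out["blq_flag"] | below
    return out


# ---------------------------------------------------------------------------
# ADA titers
# ---------------------------------------------------------------------------

def simulate_ada_titers(
    subject: SubjectRecord,
    spec: CohortSpec,
    scenario: str,
    seed: int,
    titer_threshold: float = 0.60,
) -> pd.DataFrame:
    """Scripted anti-drug-antibody status/titer series for one scenario.

    Each scenario forces the downstream classifier's verdict:

    - ``never``: all samples negative.
    - ``induced_transient``: baseline negative, a single positive at the
      first postbaseline visit (never the last) then negative.
    - ``induced_persistent``: baseline negative, positive from the second
      postbaseline visit through the final visit.
    - ``enhanced``: baseline positive; postbaseline titers rise by at least
      the enhancement threshold and stay positive through the final visit.
    - ``baseline_positive_stable``: positive throughout with a rise below
      the threshold (treatment-unaffected, hence ADA-negative downstream).

    Titer values are on the log-type "titer units" scale.
    """
    if scenario not in ADA_SCENARIOS:
        raise ValueError(f"unknown ADA scenario {scenario!r}")
    rng = _subject_rng(seed, subject.subject_id, "ada")
    days = [d for d in spec.ada_sampling_days]
    if subject.withdrawal_day is not None:
        days = [d for d in days if d <= subject.withdrawal_day]
    first_dose = spec.first_dose_day
    post = [d for d in days if d > first_dose]
    status = {d: "negative" for d in days}
    titer = {d: np.nan for d in days}
    base = round(float(rng.uniform(1.0, 1.8)), 2)
    if scenario == "never":
        pass
    elif scenario == "induced_transient":
        if post:
            pick = post[0] if len(post) == 1 else post[0]
            if pick == post[-1] and len(post) > 1:
                pick = post[0]
            status[pick] = "positive"
            titer[pick] = round(float(rng.uniform(1.0, 2.5)), 2)
    elif scenario == "induced_persistent":
        start = post[1] if len(post) > 1 else post[0] if post else None
        for d in post:
            if start is not None and d >= start:
                status[d] = "positive"
                titer[d] = round(float(rng.uniform(1.2, 3.0)), 2)
    elif scenario == "enhanced":
        status[days[0]] = "positive"
        titer[days[0]] = base
        for d in post:
            status[d] = "positive"
            titer[d] = round(base + titer_threshold + float(rng.uniform(0.0, 1.0)), 2)
    elif scenario == "baseline_positive_stable":
        for d in days:
            status[d] = "positive"
            titer[d] = round(base + float(rng.uniform(0.0, max(titer_threshold - 0.11, 0.0))), 2)
    return pd.DataFrame(
        {
            "subject_id": subject.subject_id,
            "day": days,
            "status": [status[d] for d in days],
            "titer": [titer[d] for d in days],
        }
    )


# ---------------------------------------------------------------------------
# Biomarker (total target)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BiomarkerParams:
    """Saturating total-target response: baseline + Emax*C/(C50+C).

    Drug binding extends the circulating half-life of the captured cytokine,
    so total target accumulates with exposure.  ``frac_below_mqc`` is the
    fraction of subjects whose baseline lies below the assay's MQC.
    """

    emax_pg_ml: float
    c50_ng_ml: float = 5000.0
    frac_below_mqc: float = 0.8
    sigma_ln: float = 0.2


BIOMARKER_DEFAULTS = {
    "IL17AA": BiomarkerParams(emax_pg_ml=40.0),
    "IL17FF": BiomarkerParams(emax_pg_ml=25.0),
}


def simulate_biomarker(
    subject: SubjectRecord,
    conc: pd.DataFrame,
    analyte: str,
    seed: int,
    params: BiomarkerParams | None = None,
) -> pd.DataFrame:
    """Total-target serum levels sampled in parallel with PK.

    ``conc`` must be the subject's (uncensored or censored) concentration
    series; placebo subjects (all-zero drug) stay at baseline apart from
    measurement noise.  Values below the analyte MQC are flagged BLQ but the
    measured value is retained (imputation is an analysis-stage choice).
    """
    if analyte not in MQC_PG_ML:
        raise ValueError(f"unknown analyte {analyte!r}")
    p = params or BIOMARKER_DEFAULTS[analyte]
    mqc = MQC_PG_ML[analyte]
    rng = _subject_rng(seed, subject.subject_id + analyte, "biomarker")
    if rng.uniform() < p.frac_below_mqc:
        baseline = float(rng.uniform(0.2, 0.9) * mqc)
    else:
        baseline = float(rng.uniform(1.0, 2.5) * mqc)
    c = conc["conc_ng_ml"].to_numpy(dtype=float)
    value = baseline + p.emax_pg_ml * c / (p.c50_ng_ml + c)
    if p.sigma_ln > 0:
        value = value * np.exp(p.sigma_ln * rng.standard_normal(value.shape))
    return pd.DataFrame(
        {
            "subject_id": subject.subject_id,
            "day": conc["day_decimal"].to_numpy(),
            "analyte": analyte,
            "value_pg_ml": value,
            "blq_flag": value < mqc,
        }
    )


# ---------------------------------------------------------------------------
# Safety streams
# ---------------------------------------------------------------------------

_LAB_DAYS = (1, 8, 29, 57, 85)
_LAB_SPECS = {
    # test: (log-mean, log-sd, units, uln)
    "AEC": (np.log(200.0), 0.5, "cells/uL", np.nan),
    "ANC": (np.log(4000.0), 0.25, "cells/uL", np.nan),
    "ALT": (np.log(22.0), 0.3, "U/L", 40.0),
    "AST": (np.log(24.0), 0.3, "U/L", 40.0),
    "BILI": (np.log(0.6), 0.3, "mg/dL", 1.2),
}


def simulate_safety_streams(
    subject: SubjectRecord,
    seed: int,
    ae_rate: float = 0.49,
    study_end_day: int = 85,
    edge_cases: tuple[str, ...] = (),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Adverse-event and laboratory streams for one subject.

    ``ae_rate`` is the expected number of treatment-emergent events over the
    study (Poisson).  ``edge_cases`` may inject deterministic rule-testing
    patterns: ``"eosinophilia"`` (an absolute eosinophil trajectory exceeding
    1500 cells/uL on a raised baseline), ``"neutropenia"`` (a neutrophil
    value below 1000 cells/uL) and ``"hy_law"`` (concurrent transaminase
    >=3x and bilirubin >=2x upper limit of normal).
    """
    rng = _subject_rng(seed, subject.subject_id, "safety")
    terms = sorted(AE_TERM_SOC)
    n_ae = int(rng.poisson(ae_rate))
    ae_rows = []
    for _ in range(n_ae):
        term = terms[int(rng.integers(len(terms)))]
        grade = 1 if rng.uniform() < 0.85 else 2
        related = bool(rng.uniform() < 0.4)
        ae_rows.append(
            {
                "subject_id": subject.subject_id,
                "term": term,
                "soc": AE_TERM_SOC[term],
                "grade": grade,
                "onset_day": int(rng.integers(1, study_end_day + 1)),
                "related": related,
                "serious": False,
                "clinically_significant": bool(related and grade >= 2),
            }
        )
    lab_rows = []
    for day in _LAB_DAYS:
        if day > study_end_day:
            continue
        for test, (mu, sd, units, uln) in _LAB_SPECS.items():
            lab_rows.append(
                {
                    "subject_id": subject.subject_id,
                    "day": day,
                    "test": test,
                    "value": float(np.exp(mu + sd * rng.standard_normal())),
                    "units": units,
                    "uln": uln,
                }
            )
    labs = pd.DataFrame(lab_rows, columns=["subject_id", "day", "test", "value", "units", "uln"])
    if "eosinophilia" in edge_cases:
        traj = [(1, 3100.0), (57, 13600.0), (61, 14200.0), (85, 300.0)]
        extra = pd.DataFrame(
            [
                {"subject_id": subject.subject_id, "day": d, "test": "AEC", "value": v, "units": "cells/uL", "uln": np.nan}
                for d, v in traj
            ]
        )
        labs = pd.concat([labs[labs["test"] != "AEC"], extra], ignore_index=True)
    if "neutropenia" in edge_cases:
        labs = pd.concat(
            [labs, pd.DataFrame([{"subject_id": subject.subject_id, "day": 8, "test": "ANC", "value": 900.0, "units": "cells/uL", "uln": np.nan}])],
            ignore_index=True,
        )
    if "hy_law" in edge_cases:
        hy = [
            {"subject_id": subject.subject_id, "day": 15, "test": "ALT", "value": 4 * 40.0, "units": "U/L", "uln": 40.0},
            {"subject_id": subject.subject_id, "day": 15, "test": "BILI", "value": 2.5 * 1.2, "units": "mg/dL", "uln": 1.2},
        ]
        labs = pd.concat([labs, pd.DataFrame(hy)], ignore_index=True)
    ae = pd.DataFrame(
        ae_rows,
        columns=["subject_id", "term", "soc", "grade", "onset_day", "related", "serious", "clinically_significant"],
    )
    labs = labs.sort_values(["day", "test"], kind="stable").reset_index(drop=True)
    return ae, labs


# ---------------------------------------------------------------------------
# Whole-trial assembly and CSV interchange
# ---------------------------------------------------------------------------

# Default per-arm ADA scenario mixes.  Treated mixes differ between single-
# and multiple-dose cohorts: repeated dosing of this molecule produced a much
# higher ADA incidence, so multiple-dose cohorts default to a near-saturating
# positive fraction while single-dose cohorts sit near one half.
DEFAULT_ADA_PROBS = {
    "active_single": {"never": 0.45, "induced_transient": 0.24, "induced_persistent": 0.26, "enhanced": 0.03, "baseline_positive_stable": 0.02},
    "active_multiple": {"never": 0.06, "induced_transient": 0.24, "induced_persistent": 0.60, "enhanced": 0.06, "baseline_positive_stable": 0.04},
    "placebo": {"never": 0.82, "induced_transient": 0.13, "induced_persistent": 0.0, "enhanced": 0.0, "baseline_positive_stable": 0.05},
}


@dataclass
class TrialDataset:
    """All tables of one simulated trial, keyed by a single master seed."""

    design: list[CohortSpec]
    subjects: pd.DataFrame
    dosing: pd.DataFrame
    pk_conc: pd.DataFrame
    ada: pd.DataFrame
    biomarker: pd.DataFrame
    labs: pd.DataFrame
    ae: pd.DataFrame
    seed: int

    TABLES = ("subjects", "dosing", "pk_conc", "ada", "biomarker", "labs", "ae")

    def validate(self) -> None:
        roster = set(self.subjects["subject_id"])
        for name in self.TABLES[1:]:
            tab = getattr(self, name)
            orphans = set(tab["subject_id"]) - roster
            if orphans:
                raise ValueError(f"{name} references unknown subjects: {sorted(orphans)}")


def _choose_scenario(rng: np.random.Generator, probs: dict[str, float]) -> str:
    names = list(probs)
    p = np.asarray([probs[n] for n in names], dtype=float)
    p = p / p.sum()
    return names[int(rng.choice(len(names), p=p))]


def simulate_trial(
    design: list[CohortSpec],
    seed: int,
    pk_params: PKModelParams | None = None,
    ada_probs: dict | None = None,
    ae_rate_active: float = 0.49,
    ae_rate_placebo: float = 0.69,
    lloq: float = LLOQ_NG_ML,
    withdrawal_prob: float = 0.0,
) -> TrialDataset:
    """Generate a complete synthetic trial for ``design`` under one seed."""
    pk_params = pk_params or PKModelParams()
    ada_probs = ada_probs or DEFAULT_ADA_PROBS
    subj_rows, dose_rows = [], []
    conc_parts, ada_parts, bio_parts, lab_parts, ae_parts = [], [], [], [], []
    for spec in design:
        arms = generate_randomization(spec, seed)
        for i, arm in enumerate(arms, start=1):
            sid = f"{spec.label}{i:02d}"
            wrng = _subject_rng(seed, sid, "weight")
            weight = float(np.clip(wrng.normal(78.0, 16.0), 50.0, 120.0))
            withdrawal = None
            if withdrawal_prob > 0 and wrng.uniform() < withdrawal_prob:
                withdrawal = int(wrng.choice(spec.pk_sampling_days[2:]))
            subject = SubjectRecord(sid, spec.label, arm, weight, withdrawal)
            subj_rows.append(
                {"subject_id": sid, "cohort": spec.label, "arm": arm, "weight_kg": round(weight, 1),
                 "withdrawal_day": withdrawal if withdrawal is not None else ""}
            )
            if arm == "active":
                for d in spec.dosing_days:
                    if withdrawal is not None and d > withdrawal:
                        continue
                    dose_rows.append(
                        {"subject_id": sid, "day": d, "dose_mg": spec.dose_mg, "route": spec.route,
                         "duration_h": spec.infusion_duration_h}
                    )
            conc = simulate_concentration_profile(subject, spec, pk_params, seed)
            conc = apply_blq_censoring(conc, lloq)
            conc_parts.append(conc)
            multiple = len(spec.dosing_days) > 1
            if arm == "active":
                key = "active_multiple" if multiple else "active_single"
            else:
                key = "placebo"
            srng = _subject_rng(seed, sid, "ada")
            scenario = _choose_scenario(srng, ada_probs[key])
            ada_parts.append(simulate_ada_titers(subject, spec, scenario, seed))
            for analyte in MQC_PG_ML:
                bio_parts.append(simulate_biomarker(subject, conc, analyte, seed))
            rate = ae_rate_active if arm == "active" else ae_rate_placebo
            ae, labs = simulate_safety_streams(subject, seed, ae_rate=rate, study_end_day=spec.last_scheduled_day)
            ae_parts.append(ae)
            lab_parts.append(labs)
    ds = TrialDataset(
        design=list(design),
        subjects=pd.DataFrame(subj_rows),
        dosing=pd.DataFrame(dose_rows, columns=["subject_id", "day", "dose_mg", "route", "duration_h"]),
        pk_conc=pd.concat(conc_parts, ignore_index=True) if conc_parts else pd.DataFrame(columns=["subject_id", "day_decimal", "conc_ng_ml", "blq_flag"]),
        ada=pd.concat(ada_parts, ignore_index=True) if ada_parts else pd.DataFrame(columns=["subject_id", "day", "status", "titer"]),
        biomarker=pd.concat(bio_parts, ignore_index=True) if bio_parts else pd.DataFrame(columns=["subject_id", "day", "analyte", "value_pg_ml", "blq_flag"]),
        labs=pd.concat(lab_parts, ignore_index=True) if lab_parts else pd.DataFrame(columns=["subject_id", "day", "test", "value", "units", "uln"]),
        ae=pd.concat(ae_parts, ignore_index=True) if ae_parts else pd.DataFrame(columns=["subject_id", "term", "soc", "grade", "onset_day", "related", "serious", "clinically_significant"]),
        seed=seed,
    )
    ds.validate()
    return ds


def _design_to_records(design: list[CohortSpec]) -> list[dict]:
    return [
        {
            "label": s.label, "dose_mg": s.dose_mg, "route": s.route,
            "n_active": s.n_active, "n_placebo": s.n_placebo,
            "dosing_days": list(s.dosing_days), "pk_sampling_days": list(s.pk_sampling_days),
            "ada_sampling_days": list(s.ada_sampling_days), "infusion_duration_h": s.infusion_duration_h,
        }
        for s in design
    ]


def _design_from_records(records: list[dict]) -> list[CohortSpec]:
    return [
        CohortSpec(
            r["label"], r["dose_mg"], r["route"], r["n_active"], r["n_placebo"],
            tuple(r["dosing_days"]), tuple(r["pk_sampling_days"]), tuple(r["ada_sampling_days"]),
            r.get("infusion_duration_h", 0.0),
        )
        for r in records
    ]


def write_trial_dataset(dataset: TrialDataset, directory) -> dict:
    """Write the dataset as CSV tables plus a JSON manifest; returns the manifest."""
    from pathlib import Path

    dataset.validate()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {}
    if dataset.design:
        for name in TrialDataset.TABLES:
            path = directory / f"{name}.csv"
            getattr(dataset, name).to_csv(path, index=False, lineterminator="\n", float_format="%.10g")
            files[f"{name}.csv"] = hashlib.sha256(path.read_bytes()).hexdigest()
    manifest = {
        "seed": dataset.seed,
        "design": _design_to_records(dataset.design),
        "config_hash": hashlib.sha256(
            json.dumps(_design_to_records(dataset.design), sort_keys=True).encode()
        ).hexdigest(),
        "files": files,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def read_trial_dataset(directory) -> TrialDataset:
    """Read a dataset previously written by :func:`write_trial_dataset`."""
    from pathlib import Path

    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    tables = {}
    for name in TrialDataset.TABLES:
        path = directory / f"{name}.csv"
        if not path.exists():
            tables[name] = pd.DataFrame()
            continue
        tables[name] = pd.read_csv(path)
    if not tables["subjects"].empty:
        tables["subjects"]["withdrawal_day"] = tables["subjects"]["withdrawal_day"].astype(object).fillna("")
    return TrialDataset(design=_design_from_records(manifest["design"]), seed=manifest["seed"], **tables)
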