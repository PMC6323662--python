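"""End-to-end orchestration: simulate -> NCA -> ADA -> biomarker -> safety -> report.

A :class:`PipelineConfig` (YAML-loadable) fixes the design, the master seed
and the analysis options; a run is bit-reproducible under a fixed config and
seed.  Each stage writes its CSV artifacts into the output directory; the
bundle manifest lists every artifact with a content hash and the config hash,
and the log records counts in/out and every flagged exclusion with a reason.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import biomarker as bm
from . import immunogenicity as im
from . import nca as nca_mod
from . import safety as sf
from . import simulate as sim
from .design import CohortSpec, InvalidDesignError, PKModelParams, default_study_design

__all__ = ["PipelineConfig", "PipelineError", "ValidationError", "run_pipeline", "render_report", "load_config"]

STAGES = ("simulate", "nca", "ada", "biomarker", "safety", "report")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


class ValidationError(ValueError):
    pass


@dataclass
class PipelineConfig:
    seed: int = 20160301
    output_dir: str = "trial_run"
    design: list | None = None  # list of CohortSpec dicts; None -> default design
    include_asthma_cohort: bool = False
    # PK model
    pk_params: dict = field(default_factory=dict)
    lloq_ng_ml: float = sim.LLOQ_NG_ML
    # NCA options
    auc_method: str = "lin_up_log_down"
    min_lambda_points: int = 3
    # ADA options
    titer_threshold: float = im.TITER_THRESHOLD
    persistence_days: float = im.PERSISTENCE_DAYS
    ada_probs: dict | None = None
    # Biomarker engagement criterion
    engagement_fold: float = 2.0
    # Safety
    ae_rate_active: float = 0.49
    ae_rate_placebo: float = 0.69
    dlae_window_days: float = 14.0

    def validate(self) -> None:
        if not isinstance(self.seed, int):
            raise ValidationError("seed must be an integer")
        if self.auc_method not in ("linear", "lin_up_log_down"):
            raise ValidationError(f"unknown AUC method {self.auc_method!r}")
        if self.min_lambda_points < 3:
            raise ValidationError("min_lambda_points must be >= 3")
        if self.titer_threshold <= 0 or self.persistence_days <= 0:
            raise ValidationError("ADA thresholds must be positive")
        if self.design is not None and len(self.design) == 0:
            raise ValidationError("design must contain at least one cohort")
        self.cohorts()  # raises InvalidDesignError -> surfaced as validation

    def cohorts(self) -> list[CohortSpec]:
        if self.design is None:
            return default_study_design(self.include_asthma_cohort)
        try:
            return sim._design_from_records(self.design)
        except (KeyError, InvalidDesignError) as exc:
            raise ValidationError(str(exc)) from exc

    def model_params(self) -> PKModelParams:
        return PKModelParams(**self.pk_params)

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True, default=str).encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = PipelineConfig.__dataclass_fields__
    unknown = set(raw) - set(known)
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


def _write(df: pd.DataFrame, path: Path, log: list, stage: str) -> None:
    tmp = path.with_suffix(".tmp")
    df.to_csv(tmp, index=False, lineterminator="\n", float_format="%.10g")
    tmp.replace(path)
    log.append(f"[{stage}] wrote {path.name}: {len(df)} rows")


def run_pipeline(config: PipelineConfig, stages=STAGES) -> dict:
    """Run the requested stages; returns the bundle manifest."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"config hash {config.config_hash()}, seed {config.seed}"]
    manifest = {"seed": config.seed, "config_hash": config.config_hash(), "artifacts": {}}

    def fail(stage, exc):
        raise PipelineError(stage, str(exc)) from exc

    dataset = None
    if "simulate" in stages:
        try:
            dataset = sim.simulate_trial(
                config.cohorts(),
                seed=config.seed,
                pk_params=config.model_params(),
                ada_probs=config.ada_probs,
                ae_rate_active=config.ae_rate_active,
                ae_rate_placebo=config.ae_rate_placebo,
                lloq=config.lloq_ng_ml,
            )
            sim.write_trial_dataset(dataset, out / "data")
            log.append(f"[simulate] {len(dataset.subjects)} subjects, {len(dataset.pk_conc)} PK records")
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - stage boundary
            fail("simulate", exc)
    else:
        try:
            dataset = sim.read_trial_dataset(out / "data")
        except Exception as exc:  # noqa: BLE001
            fail("load", exc)

    nca_subj = None
    if "nca" in stages:
        try:
            nca_subj = nca_mod.nca_subject_table(
                dataset.pk_conc, dataset.dosing, dataset.subjects,
                method=config.auc_method, min_points=config.min_lambda_points,
            )
            _write(nca_subj, out / "nca_subject.csv", log, "nca")
            _write(nca_mod.nca_summary_table(nca_subj), out / "nca_summary.csv", log, "nca")
            n_invalid = int((~nca_subj["lambda_valid"].astype(bool)).sum())
            log.append(f"[nca] {n_invalid} profiles with invalid terminal fits (span or slope rule)")
        except Exception as exc:  # noqa: BLE001
            fail("nca", exc)

    if "ada" in stages:
        try:
            timelines = im.timelines_from_frame(dataset.ada, dataset.subjects)
            cls = im.classification_table(
                timelines, titer_threshold=config.titer_threshold, persistence_days=config.persistence_days
            )
            _write(cls, out / "ada_class.csv", log, "ada")
            not_eval = cls[~cls["evaluable"]]["subject_id"].tolist()
            if not_eval:
                log.append(f"[ada] excluded from incidence (not evaluable): {not_eval}")
            summaries = []
            for arm in ("active", "placebo"):
                s = im.compute_prevalence_incidence(cls, arm=arm)
                summaries.append({"arm": arm} | s)
            _write(pd.DataFrame(summaries), out / "ada_summary.csv", log, "ada")
            if nca_subj is None and (out / "nca_subject.csv").exists():
                nca_subj = pd.read_csv(out / "nca_subject.csv")
            if nca_subj is not None and not nca_subj.empty:
                _write(im.overlay_ada_pk(cls, nca_subj), out / "ada_pk_overlay.csv", log, "ada")
        except Exception as exc:  # noqa: BLE001
            fail("ada", exc)

    if "biomarker" in stages:
        try:
            eng = bm.engagement_table(dataset.biomarker, dataset.dosing, fold=config.engagement_fold)
            eng.attrs["criterion"] = f"peak >= max({config.engagement_fold}*baseline, baseline + MQC)"
            _write(eng, out / "engagement.csv", log, "biomarker")
        except Exception as exc:  # noqa: BLE001
            fail("biomarker", exc)

    if "safety" in stages:
        try:
            flags = sf.safety_flags_table(dataset.ae, dataset.labs, dataset.dosing, window_days=config.dlae_window_days)
            _write(flags, out / "safety_flags.csv", log, "safety")
            teae_rows = []
            for arm, res in sf.summarize_teae(dataset.ae, dataset.subjects).items():
                teae_rows.append(
                    {"arm": arm, "level": "overall", "soc": "", "term": "",
                     "n_subjects": res["subjects_with_event"], "pct": res["pct_with_event"],
                     "total_events": res["total_events"], "denominator": res["n_subjects"]}
                )
                t = res["table"].copy()
                t.insert(0, "arm", arm)
                t["total_events"] = np.nan
                t["denominator"] = res["n_subjects"]
                teae_rows.extend(t.to_dict("records"))
            _write(pd.DataFrame(teae_rows), out / "teae_table.csv", log, "safety")
        except Exception as exc:  # noqa: BLE001
            fail("safety", exc)

    if "report" in stages:
        try:
            render_report(out)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            fail("report", exc)

    for p in sorted(out.rglob("*")):
        if p.is_file() and p.suffix in (".csv", ".json", ".txt", ".png"):
            manifest["artifacts"][str(p.relative_to(out))] = hashlib.sha256(p.read_bytes()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    (out / "pipeline.log").write_text("\n".join(log) + "\n")
    return manifest


def render_report(bundle_dir, make_plots: bool = True) -> Path:
    """Assemble a plain-text report from a complete bundle directory.

    Raises :class:`PipelineError` naming the first missing stage output.
    """
    out = Path(bundle_dir)
    required = {
        "nca": ["nca_summary.csv", "nca_subject.csv"],
        "ada": ["ada_class.csv", "ada_summary.csv"],
        "biomarker": ["engagement.csv"],
        "safety": ["teae_table.csv", "safety_flags.csv"],
    }
    for stage, files in required.items():
        for f in files:
            if not (out / f).exists():
                raise PipelineError("report", f"missing output of stage '{stage}': {f}")
    subjects = pd.read_csv(out / "data" / "subjects.csv")
    lines = ["Synthetic ascending-dose trial report", "=" * 40, ""]
    lines.append("Disposition and demographics")
    demo = subjects.groupby(["cohort", "arm"]).agg(n=("subject_id", "count"), weight_kg=("weight_kg", "mean"))
    lines.append(demo.round(1).to_string())
    lines.append("")
    lines.append("PK summary (per cohort/profile/parameter)")
    lines.append(pd.read_csv(out / "nca_summary.csv").round(4).to_string(index=False))
    lines.append("")
    lines.append("ADA incidence/prevalence")
    lines.append(pd.read_csv(out / "ada_summary.csv").round(1).to_string(index=False))
    lines.append("")
    lines.append("TEAE summary")
    lines.append(pd.read_csv(out / "teae_table.csv").round(1).to_string(index=False))
    lines.append("")
    eng = pd.read_csv(out / "engagement.csv")
    lines.append("Target engagement (elevated fraction by analyte)")
    lines.append(eng.groupby("analyte")["elevated"].mean().round(3).to_string())
    report_path = out / "report.txt"
    report_path.write_text("\n".join(lines) + "\n")
    if make_plots:
        _plot_bundle(out)
    return report_path


def _plot_bundle(out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    conc = pd.read_csv(out / "data" / "pk_conc.csv")
    subjects = pd.read_csv(out / "data" / "subjects.csv")
    merged = conc.merge(subjects[["subject_id", "cohort", "arm"]], on="subject_id")
    active = merged[merged["arm"] == "active"]
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for cohort, g in active.groupby("cohort"):
        prof = g.groupby("day_decimal")["conc_ng_ml"].mean()
        ax.semilogy(prof.index, prof.clip(lower=1.0), marker="o", ms=3, label=f"Cohort {cohort}")
    ax.axhline(sim.LLOQ_NG_ML, ls="--", color="grey", lw=0.8)
    ax.set_xlabel("Study day")
    ax.set_ylabel("Mean serum concentration (ng/mL)")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(out / "concentration_profiles.png", dpi=120)
    plt.close(fig)

    bio = pd.read_csv(out / "data" / "biomarker.csv")
    bio = bio.merge(subjects[["subject_id", "arm"]], on="subject_id")
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=False)
    for ax2, analyte in zip(axes, sorted(bio["analyte"].unique())):
        half = sim.MQC_PG_ML[analyte] / 2.0
        sub = bio[bio["analyte"] == analyte].copy()
        sub.loc[sub["blq_flag"].astype(bool), "value_pg_ml"] = half  # plotted at MQC/2
        for sid, g in sub.groupby("subject_id"):
            color = "black" if g["arm"].iloc[0] == "active" else "0.7"
            ax2.plot(g["day"], g["value_pg_ml"], color=color, lw=0.6, alpha=0.6)
        ax2.set_title(analyte)
        ax2.set_xlabel("Study day")
        ax2.set_ylabel("Total target (pg/mL)")
    fig.tight_layout()
    fig.savefig(out / "biomarker_profiles.png", dpi=120)
    plt.close(fig)
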