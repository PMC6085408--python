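"""End-to-end orchestration: simulate -> features -> outcomes -> classify -> report.

A run directory receives every stage's artifact plus a resolved copy of
the validated configuration, so reruns with the same config and seed are
reproducible file-for-file.  Stages communicate only through the files
they write (recordings CSV/JSON, feature CSV, label JSON, report JSON).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import classify as clf
from . import features as feat
from . import outcomes as oc
from . import synth
from .schemes import DEFAULT_BANDS, DEFAULT_CHANNELS

logger = logging.getLogger(__name__)

MODEL_TYPES = ("core", "shell", "core-vs-shell")


class PlantedEffectConfig(BaseModel):
    kind: Literal["coherence", "power"] = "coherence"
    channels: tuple[str, ...] = ("cl", "cr")
    band: str = "hγ"
    delta: float = 0.4


class CohortConfig(BaseModel):
    n_per_group: int = Field(6, ge=2)
    sessions_per_animal: int = Field(2, ge=1)
    duration_s: float = Field(60.0, gt=0)
    fs: float = Field(1000.0, gt=0)
    base_coherence: float = Field(0.15, ge=0, lt=1)
    animal_gain_sd: float = 0.05
    session_jitter_sd: float = 0.05
    planted_effects: list[PlantedEffectConfig] = Field(
        default_factory=lambda: [PlantedEffectConfig()]
    )


class BingeConfig(BaseModel):
    baseline_mean_kcal: float = Field(40.0, gt=0)
    baseline_cv: float = Field(0.13, gt=0)
    n_sessions: int = Field(3, ge=1)
    responder_effect_pct: float = -60.0
    nonresponder_effect_pct: float = -10.0

    @field_validator("responder_effect_pct")
    @classmethod
    def _responder_reduces(cls, v: float) -> float:
        if v >= 0:
            raise ValueError("responder effect must be a reduction (negative percent)")
        return v


class CVConfig(BaseModel):
    k: int = Field(4, ge=2)
    reps: int = Field(20, ge=1)
    n_perms: int = Field(3, ge=1)
    top_k: int = Field(5, ge=0)


class PipelineConfig(BaseModel):
    """Validated configuration for a full synthetic-cohort run."""

    seed: int = 0
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    binge: BingeConfig = Field(default_factory=BingeConfig)
    cv: CVConfig = Field(default_factory=CVConfig)
    welch_window_s: float = Field(2.0, gt=0)
    threshold_pct: float | None = None  # None -> refit 2-SD rule from baselines

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.model_dump(mode="json"), allow_unicode=True)
        )


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # annotate failures with the stage name
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


@_stage("simulate")
def _simulate(config: PipelineConfig, out: Path) -> list[synth.CohortRecording]:
    spec = synth.CohortSpec(
        n_per_group=config.cohort.n_per_group,
        group_labels=("shell", "core"),  # second group carries the planted effects
        planted_effects=tuple(
            synth.PlantedEffect(e.kind, tuple(e.channels), e.band, e.delta)
            for e in config.cohort.planted_effects
        ),
        sessions_per_animal=config.cohort.sessions_per_animal,
        animal_gain_sd=config.cohort.animal_gain_sd,
        session_jitter_sd=config.cohort.session_jitter_sd,
        base_coherence=config.cohort.base_coherence,
        fs=config.cohort.fs,
        duration=config.cohort.duration_s,
        seed=config.seed,
    )
    cohort = synth.simulate_cohort(spec)
    rec_dir = out / "recordings"
    for item in cohort:
        item.recording.save(rec_dir, f"{item.animal_id}_{item.session_id}")
    (rec_dir / "manifest.json").write_text(
        json.dumps(
            [
                {"animal_id": c.animal_id, "session_id": c.session_id, "group": c.group}
                for c in cohort
            ],
            indent=1,
        )
    )
    return cohort


@_stage("features")
def _extract_features(
    config: PipelineConfig, cohort: list[synth.CohortRecording], out: Path
) -> pd.DataFrame:
    welch = feat.WelchParams(window_s=config.welch_window_s)
    vectors = [
        feat.extract_feature_vector(
            c.recording, welch=welch, animal_id=c.animal_id, session_id=c.session_id
        )
        for c in cohort
    ]
    table = feat.features_to_frame(vectors)
    table.insert(2, "group", [c.group for c in cohort])
    table.to_csv(out / "features.csv", index=False)
    return table


@_stage("outcomes")
def _binge_outcomes(
    config: PipelineConfig, cohort: list[synth.CohortRecording], out: Path
) -> tuple[list[oc.OutcomeLabel], dict[str, int]]:
    animals = sorted({(c.animal_id, c.group) for c in cohort})
    effects = []
    for _, group in animals:
        hit, miss = config.binge.responder_effect_pct, config.binge.nonresponder_effect_pct
        effects.append(
            {"core": hit, "shell": miss} if group == "core" else {"core": miss, "shell": hit}
        )
    spec = synth.BingeGenSpec(
        baseline_mean_kcal=config.binge.baseline_mean_kcal,
        baseline_cv=config.binge.baseline_cv,
        n_baseline=config.binge.n_sessions,
        n_stim=config.binge.n_sessions,
        n_post=config.binge.n_sessions,
        effects=effects,
        seed=config.seed + 101,
    )
    records = synth.simulate_binge_cohort(spec, n_rats=len(animals))
    rename = {f"rat{i:02d}": a for i, (a, _) in enumerate(animals)}
    records = [dataclasses.replace(r, animal_id=rename[r.animal_id]) for r in records]
    pd.DataFrame(
        [
            {
                "animal_id": r.animal_id,
                "session_index": r.session_index,
                "session_type": r.session_type,
                "target": r.target,
                "intake_kcal": r.intake_kcal,
            }
            for r in records
        ]
    ).to_csv(out / "intake.csv", index=False)
    labels = oc.compute_outcomes(
        records, threshold_pct=config.threshold_pct, n_required=config.binge.n_sessions
    )
    profile = oc.summarize_response_profiles(labels)
    (out / "labels.json").write_text(
        json.dumps(
            {
                "profile_counts": profile,
                "animals": {
                    l.animal_id: {
                        "status": dict(l.status),
                        "mean_change": dict(l.mean_change),
                        "optimal_target": l.optimal_target,
                    }
                    for l in labels
                },
            },
            indent=1,
        )
    )
    return labels, profile


def _model_labels(labels: list[oc.OutcomeLabel], model: str) -> dict[str, int]:
    if model == "core":
        return {l.animal_id: int(l.status["core"] == "responder") for l in labels}
    if model == "shell":
        return {l.animal_id: int(l.status["shell"] == "responder") for l in labels}
    if model == "core-vs-shell":
        return {
            l.animal_id: int(l.optimal_target == "core")
            for l in labels
            if l.optimal_target in ("core", "shell")
        }
    raise ValueError(f"unknown model type {model!r}")


@_stage("classify")
def _classify(
    config: PipelineConfig,
    table: pd.DataFrame,
    labels: list[oc.OutcomeLabel],
    out: Path,
) -> dict:
    report: dict = {}
    for model in MODEL_TYPES:
        lab = _model_labels(labels, model)
        dm = clf.make_design_matrix(table, lab)
        cv = clf.fit_lasso_repeated_cv(
            dm, k=config.cv.k, reps=config.cv.reps, seed=config.seed + 7
        )
        null = clf.permutation_null(
            dm,
            n_perms=config.cv.n_perms,
            k=config.cv.k,
            reps=config.cv.reps,
            seed=config.seed + 13,
        )
        effect = clf.compare_distributions(cv.accuracies, null.pooled_accuracies)
        univ = {
            name: clf.univariate_logistic_loocv(dm.X[name], dm.y, dm.groups)
            for name in dm.feature_names
        }
        top = clf.build_feature_report(cv, univ, k=config.cv.top_k)
        feature_cols = [c for c in table.columns if c not in ("animal_id", "session_id", "group")]
        stability = feat.feature_stability(
            table[table["animal_id"].isin(lab)], {a: str(v) for a, v in lab.items()},
            feature_columns=feature_cols,
        )
        report[model] = {
            "observed": {
                "mean": cv.mean,
                "sd": cv.sd,
                "accuracies": cv.accuracies.tolist(),
            },
            "permuted": {
                "mean": float(np.mean(null.pooled_accuracies)),
                "sd": float(np.std(null.pooled_accuracies, ddof=1)),
                "n_permutations": config.cv.n_perms,
            },
            "effect_size": {
                "U": effect.U,
                "z": effect.z,
                "d": effect.d,
                "direction": effect.direction,
            },
            "top_by_accuracy": top.logistic_top.to_dict(orient="records"),
            "top_by_survival": top.lasso_top.to_dict(orient="records"),
            "stability": {
                "min_ratio_feature": str(stability["ratio"].idxmin()),
                "min_ratio": float(stability["ratio"].min()),
            },
        }
        top.univariate.assign(model=model).to_csv(
            out / f"table1_{model.replace('-', '_')}.csv", index=False
        )
    (out / "report.json").write_text(json.dumps(report, ensure_ascii=False, indent=1))
    return report


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute all stages into ``out_dir`` and return the run directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.resolved.yaml")
    cohort = _simulate(config, out)
    table = _extract_features(config, cohort, out)
    labels, profile = _binge_outcomes(config, cohort, out)
    _classify(config, table, labels, out)
    render_report(out)
    logger.info("run complete: %s", out)
    return out


def render_report(run_dir: str | Path) -> str:
    """Human-readable summary of a finished run (also written to report.txt)."""
    run_dir = Path(run_dir)
    report_path = run_dir / "report.json"
    if not report_path.exists():
        raise FileNotFoundError(f"missing classify output {report_path}; run classify first")
    report = json.loads(report_path.read_text())
    lines = ["Stimulation-outcome classification from resting LFP features", ""]
    labels_path = run_dir / "labels.json"
    if labels_path.exists():
        profile = json.loads(labels_path.read_text())["profile_counts"]
        lines.append(
            f"Response profiles (n={profile['n']}): "
            f"{profile['core_only']} core-only, {profile['shell_only']} shell-only, "
            f"{profile['both']} both, {profile['neither']} neither "
            f"({profile['single_target']} single-target)"
        )
        lines.append("")
    for model, sec in report.items():
        obs, perm, eff = sec["observed"], sec["permuted"], sec["effect_size"]
        lines.append(f"== Model: {model} ==")
        lines.append(
            f"mean accuracy {100 * obs['mean']:.0f}% (SD ± {100 * obs['sd']:.0f}%) "
            f"vs permuted {100 * perm['mean']:.0f}% (SD ± {100 * perm['sd']:.0f}%), "
            f"d = {eff['d']:.2f}"
        )
        if sec["top_by_accuracy"]:
            lines.append("  top features by % accuracy (logistic):")
            for row in sec["top_by_accuracy"]:
                lines.append(
                    f"    {row['direction']} {row['feature']:<12} {row['pct_accuracy']:.0f}"
                )
            lines.append("  top features by % survival (lasso):")
            for row in sec["top_by_survival"]:
                lines.append(
                    f"    {row['direction']} {row['feature']:<12} {row['pct_survival']:.0f}"
                )
        else:
            lines.append("  direction feature %")
        stab = sec["stability"]
        flag = " — stable discriminative feature" if stab["min_ratio"] < 1 else ""
        lines.append(
            f"  stability: {stab['min_ratio_feature']} within/between ratio "
            f"{stab['min_ratio']:.2f}{flag}"
        )
        lines.append("")
    text = "\n".join(lines)
    (run_dir / "report.txt").write_text(text)
    return text
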