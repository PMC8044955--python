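"""Pipeline orchestration: validated config, staged artifacts, manifests.

Each stage reads and writes declared artifacts under the output
directory; the ``all`` mode chains simulate -> orthogonal design ->
design execution -> effect analysis -> best-parameter selection ->
retraining at the optimum -> episode-based evaluation.  Every random
stage derives its seed deterministically from the global seed, and
floating-point artifacts are written at fixed precision so a rerun with
the same config and seed reproduces them byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import evaluate as ev
from . import oed
from .features import concat_matrices, extract_matrix
from .model import RFParams, macro_metrics, pooled_metrics, topk_select, train_and_eval
from .preprocess import SegmentationParams, highpass_detrend, replace_outliers, segment_and_label
from .synth import GaitSimParams, read_recording, simulate_cohort, write_recording

__all__ = [
    "PipelineConfig",
    "ConfigError",
    "MissingArtifactError",
    "DegenerateDataError",
    "load_config",
    "run_pipeline",
    "MODES",
]

logger = logging.getLogger(__name__)

MODES = (
    "simulate", "preprocess", "extract", "design", "run-oed",
    "analyze", "train", "select", "evaluate", "all",
)

FLOAT_FMT = "%.9g"


class ConfigError(ValueError):
    """Configuration failed schema validation (exit code 2)."""


class MissingArtifactError(FileNotFoundError):
    """A required upstream artifact is absent (exit code 3)."""


class DegenerateDataError(RuntimeError):
    """Data degenerate for the requested stage (exit code 4)."""


class SimConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    # inter-freeze gaps must exceed the largest window plus the largest
    # preFOG label duration, or some design runs lose the normal class
    n_patients: int = 6
    duration_s: float = 50.0
    fog_schedule: list[tuple[float, float]] = Field(
        default_factory=lambda: [(14.0, 5.0), (33.0, 5.0)]
    )
    sampling_rate_hz: float = 100.0
    n_sensors: int = 7
    step_frequency_hz: float = 1.8
    gait_amplitude: float = 1.0
    fog_amplitude: float = 2.0
    prefog_drift: float = 0.6
    prefog_ramp_s: float = 3.0
    noise_sd: float = 0.1
    burst_outlier_rate: float = 0.001

    def to_params(self, seed: int) -> GaitSimParams:
        return GaitSimParams(
            sampling_rate_hz=self.sampling_rate_hz,
            n_sensors=self.n_sensors,
            step_frequency_hz=self.step_frequency_hz,
            gait_amplitude=self.gait_amplitude,
            fog_amplitude=self.fog_amplitude,
            prefog_drift=self.prefog_drift,
            prefog_ramp_s=self.prefog_ramp_s,
            noise_sd=self.noise_sd,
            burst_outlier_rate=self.burst_outlier_rate,
            seed=seed,
        )


class SegConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    window_size: int = 500
    step: int = 20
    prefog_duration: int = 250

    def to_params(self) -> SegmentationParams:
        return SegmentationParams(self.window_size, self.step, self.prefog_duration)


class DesignConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    scheme: Literal["l16", "full"] = "l16"
    window_size_levels: tuple[int, int, int, int] = (128, 256, 400, 500)
    step_levels: tuple[int, int, int, int] = (5, 10, 20, 30)
    prefog_duration_levels: tuple[int, int, int, int] = (150, 250, 500, 600)

    def factors(self) -> list[oed.FactorSpec]:
        return [
            oed.FactorSpec("window_size", self.window_size_levels),
            oed.FactorSpec("step", self.step_levels),
            oed.FactorSpec("prefog_duration", self.prefog_duration_levels),
        ]


class RFConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_estimators: int = 800
    max_features: float = 0.1
    max_depth: int = 4
    min_samples_split: int = 4
    min_samples_leaf: int = 4

    def to_params(self, seed: int) -> RFParams:
        return RFParams(
            n_estimators=self.n_estimators,
            max_features=self.max_features,
            max_depth=self.max_depth,
            min_samples_split=self.min_samples_split,
            min_samples_leaf=self.min_samples_leaf,
            seed=seed,
        )


class OEDConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    response: Literal["f1", "kappa"] = "f1"
    interactions: list[str] = Field(
        default_factory=lambda: ["window_size:prefog_duration"]
    )
    replicates: int = 1
    # Smaller screening forest for the 16 x n_patients design fits; the
    # final model is always retrained with the full RF config.
    screening_n_estimators: Optional[int] = 100


class EvalConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    horizon_s: float = 6.0
    gap_tolerance_windows: int = 0


class SelectConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    k_grid: list[int] = Field(default_factory=lambda: [50, 100, 200, 462, 924])


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    out_dir: Path = Path("fogcast_artifacts")
    log_level: str = "INFO"
    simulate: SimConfig = Field(default_factory=SimConfig)
    segmentation: SegConfig = Field(default_factory=SegConfig)
    design: DesignConfig = Field(default_factory=DesignConfig)
    rf: RFConfig = Field(default_factory=RFConfig)
    oed: OEDConfig = Field(default_factory=OEDConfig)
    select: SelectConfig = Field(default_factory=SelectConfig)
    evaluate: EvalConfig = Field(default_factory=EvalConfig)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path | None, overrides: dict | None = None) -> PipelineConfig:
    data = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise MissingArtifactError(f"config file {p} not found")
        data = yaml.safe_load(p.read_text()) or {}
    data.update(overrides or {})
    try:
        return PipelineConfig(**data)
    except ValidationError as exc:
        lines = "; ".join(
            f"{'.'.join(str(x) for x in e['loc'])}: {e['msg']}" for e in exc.errors()
        )
        raise ConfigError(lines) from exc


def _seed_for(cfg: PipelineConfig, stage: str) -> int:
    h = hashlib.sha256(f"{cfg.seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _write_manifest(cfg: PipelineConfig, stage: str, artifacts: list[Path]) -> None:
    manifest = {
        "stage": stage,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "artifacts": {
            str(a.name): hashlib.sha256(a.read_bytes()).hexdigest()
            for a in artifacts if a.exists()
        },
    }
    path = cfg.out_dir / f"manifest_{stage.replace('-', '_')}.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))


def _data_dir(cfg: PipelineConfig) -> Path:
    return cfg.out_dir / "data"


def _load_cohort(cfg: PipelineConfig, cleaned: bool = False):
    d = cfg.out_dir / ("cleaned" if cleaned else "data")
    if not d.exists():
        producer = "preprocess" if cleaned else "simulate"
        raise MissingArtifactError(
            f"{d} not found; run the '{producer}' mode first"
        )
    bases = sorted({p.name.removesuffix(".signals.csv") for p in d.glob("*.signals.csv")})
    if not bases:
        producer = "preprocess" if cleaned else "simulate"
        raise MissingArtifactError(
            f"no recordings under {d}; run the '{producer}' mode first"
        )
    return [read_recording(d / b) for b in bases]


def _stage_simulate(cfg: PipelineConfig) -> list[Path]:
    params = cfg.simulate.to_params(_seed_for(cfg, "simulate"))
    cohort = simulate_cohort(
        params, cfg.simulate.n_patients, cfg.simulate.duration_s,
        cfg.simulate.fog_schedule,
    )
    out = []
    for rec, ann in cohort:
        sig, annp = write_recording(rec, ann, _data_dir(cfg) / rec.patient_id)
        out += [sig, annp]
    return out


def _stage_preprocess(cfg: PipelineConfig) -> list[Path]:
    cohort = _load_cohort(cfg)
    out = []
    p = cfg.segmentation.to_params()
    index_rows = []
    for rec, ann in cohort:
        clean = highpass_detrend(replace_outliers(rec))
        sig, annp = write_recording(clean, ann, cfg.out_dir / "cleaned" / rec.patient_id)
        out += [sig, annp]
        ws = segment_and_label(clean, ann, p)
        index_rows += [
            {"patient_id": w.patient_id, "start": w.start, "end": w.end, "label": w.label}
            for w in ws.windows
        ]
    idx = cfg.out_dir / "windows.csv"
    pd.DataFrame(index_rows).to_csv(idx, index=False)
    return out + [idx]


def _stage_extract(cfg: PipelineConfig) -> list[Path]:
    cohort = _load_cohort(cfg, cleaned=True)
    p = cfg.segmentation.to_params()
    mats = [extract_matrix(segment_and_label(rec, ann, p)) for rec, ann in cohort]
    fm = concat_matrices(mats)
    path = cfg.out_dir / "features.csv"
    fm.to_frame().to_csv(path, index=False, float_format=FLOAT_FMT)
    return [path]


def _stage_design(cfg: PipelineConfig) -> list[Path]:
    factors = cfg.design.factors()
    d = (
        oed.build_l16_4_3(factors)
        if cfg.design.scheme == "l16"
        else oed.full_factorial(factors)
    )
    report = oed.verify_orthogonality(d)
    if cfg.design.scheme == "l16" and not report.passed:
        raise DegenerateDataError(f"design fails balance checks: {report.failures}")
    path = cfg.out_dir / "design.csv"
    d.to_csv(path)
    return [path]


def _clean_cohort(cfg: PipelineConfig):
    try:
        return _load_cohort(cfg, cleaned=True)
    except MissingArtifactError:
        cohort = _load_cohort(cfg)
        return [(highpass_detrend(replace_outliers(rec)), ann) for rec, ann in cohort]


def _stage_run_oed(cfg: PipelineConfig) -> list[Path]:
    dpath = cfg.out_dir / "design.csv"
    if not dpath.exists():
        raise MissingArtifactError("design.csv not found; run the 'design' mode first")
    d = oed.DesignTable.from_csv(dpath, cfg.design.scheme)
    cohort = _clean_cohort(cfg)
    rf = cfg.rf.to_params(_seed_for(cfg, "run-oed"))
    if cfg.oed.screening_n_estimators:
        from dataclasses import replace
        rf = replace(rf, n_estimators=cfg.oed.screening_n_estimators)
    seeds = [_seed_for(cfg, f"run-oed-rep{i}") for i in range(cfg.oed.replicates)]
    resp = oed.run_design(d, cohort, rf, seeds=seeds)
    path = cfg.out_dir / "responses.csv"
    resp.rows.to_csv(path, index=False, float_format=FLOAT_FMT)
    return [path]


def _stage_analyze(cfg: PipelineConfig) -> list[Path]:
    rpath = cfg.out_dir / "responses.csv"
    dpath = cfg.out_dir / "design.csv"
    if not rpath.exists():
        raise MissingArtifactError("responses.csv not found; run the 'run-oed' mode first")
    if not dpath.exists():
        raise MissingArtifactError("design.csv not found; run the 'design' mode first")
    d = oed.DesignTable.from_csv(dpath)
    r = oed.ResponseTable.from_csv(rpath)
    summary = oed.effects_analysis(
        d, r, response=cfg.oed.response, interactions=cfg.oed.interactions
    )
    best = oed.select_best(summary)
    effects_path = cfg.out_dir / "effects.csv"
    summary.terms.to_csv(effects_path, index=False, float_format=FLOAT_FMT)
    means_path = cfg.out_dir / "effects.json"
    means_path.write_text(json.dumps(
        {
            "response": summary.response,
            "coding": summary.coding,
            "level_means": {
                f: {str(k): round(float(v), 9) for k, v in m.items()}
                for f, m in summary.level_means.items()
            },
        }, indent=1, sort_keys=True,
    ))
    best_path = cfg.out_dir / "best_params.json"
    best_path.write_text(json.dumps(asdict(best), indent=1, sort_keys=True))
    return [effects_path, means_path, best_path]


def _best_params(cfg: PipelineConfig) -> SegmentationParams:
    best_path = cfg.out_dir / "best_params.json"
    if best_path.exists():
        d = json.loads(best_path.read_text())
        return SegmentationParams(d["window_size"], d["step"], d["prefog_duration"])
    return cfg.segmentation.to_params()


def _stage_train(cfg: PipelineConfig) -> list[Path]:
    cohort = _clean_cohort(cfg)
    p = _best_params(cfg)
    mats = [extract_matrix(segment_and_label(rec, ann, p)) for rec, ann in cohort]
    fm = concat_matrices(mats)
    if fm.labels.nunique() < 2:
        raise DegenerateDataError("training data contain a single class")
    rf = cfg.rf.to_params(_seed_for(cfg, "train"))
    folds = train_and_eval(fm, rf)
    f1, kap = pooled_metrics(folds)
    mf1, mkap = macro_metrics(folds)
    rows = pd.DataFrame(
        [
            {"patient_id": f.patient_id, "tp": f.tp, "fp": f.fp, "fn": f.fn,
             "tn": f.tn, "f1": f.f1, "kappa": f.kappa}
            for f in folds
        ]
    )
    path = cfg.out_dir / "fold_metrics.csv"
    rows.to_csv(path, index=False, float_format=FLOAT_FMT)
    summary_path = cfg.out_dir / "train_summary.json"
    summary_path.write_text(json.dumps(
        {
            "segmentation": asdict(p),
            "rf": asdict(rf),
            "f1_pooled": round(f1, 9), "kappa_pooled": round(kap, 9),
            "f1_macro": round(mf1, 9), "kappa_macro": round(mkap, 9),
        }, indent=1, sort_keys=True,
    ))
    return [path, summary_path]


def _stage_select(cfg: PipelineConfig) -> list[Path]:
    cohort = _clean_cohort(cfg)
    p = _best_params(cfg)
    mats = [extract_matrix(segment_and_label(rec, ann, p)) for rec, ann in cohort]
    fm = concat_matrices(mats)
    rf = cfg.rf.to_params(_seed_for(cfg, "select"))
    k_grid = [k for k in cfg.select.k_grid if k <= fm.n_features]
    if not k_grid:
        raise DegenerateDataError("k_grid has no entry within the feature count")
    best, all_k = topk_select(fm, rf, k_grid)
    path = cfg.out_dir / "selection.json"
    path.write_text(json.dumps(
        {
            "best_k": best.k,
            "f1": round(best.f1, 9),
            "kappa": round(best.kappa, 9),
            "base_feature_ranking": best.base_feature_ranking,
            "per_k": [
                {"k": r.k, "f1": round(r.f1, 9), "kappa": round(r.kappa, 9)}
                for r in all_k
            ],
        }, indent=1, sort_keys=True,
    ))
    return [path]


def _stage_evaluate(cfg: PipelineConfig) -> list[Path]:
    cohort = _clean_cohort(cfg)
    p = _best_params(cfg)
    rf = cfg.rf.to_params(_seed_for(cfg, "evaluate"))
    score = ev.end_to_end_eval(
        cohort, p, rf,
        horizon_s=cfg.evaluate.horizon_s,
        gap_tolerance_windows=cfg.evaluate.gap_tolerance_windows,
    )
    path = cfg.out_dir / "episode_score.json"
    path.write_text(json.dumps(
        {
            "n_episodes": score.n_episodes,
            "n_hits": score.n_hits,
            "n_alarms": score.n_alarms,
            "n_false_alarms": score.n_false_alarms,
            "hit_rate": None if score.hit_rate is None else round(score.hit_rate, 9),
            "false_positive_rate": None if score.false_positive_rate is None
            else round(score.false_positive_rate, 9),
            "mpt_s": None if score.mpt_s is None else round(score.mpt_s, 9),
            "flags": score.flags,
        }, indent=1, sort_keys=True,
    ))
    return [path]


_STAGES = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "extract": _stage_extract,
    "design": _stage_design,
    "run-oed": _stage_run_oed,
    "analyze": _stage_analyze,
    "train": _stage_train,
    "select": _stage_select,
    "evaluate": _stage_evaluate,
}


def run_pipeline(cfg: PipelineConfig, mode: str) -> list[Path]:
    """Run one stage (or the whole chain for ``all``); returns artifacts."""
    if mode not in MODES:
        raise ConfigError(f"unknown mode {mode!r}; choose from {MODES}")
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    stages = (
        ["simulate", "design", "run-oed", "analyze", "train", "evaluate"]
        if mode == "all"
        else [mode]
    )
    artifacts: list[Path] = []
    for stage in stages:
        logger.info("stage %s", stage)
        produced = _STAGES[stage](cfg)
        _write_manifest(cfg, stage, produced)
        artifacts += produced
    return artifacts
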