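"""End-to-end orchestration: simulate -> features -> classify -> indices ->
time course -> composition, with on-disk hand-off between stages so each can
be re-run independently, and a manifest hashing every output."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import SvmConfig, classify_grid, results_frame
from .composition import fit_presence_model, presence_rates
from .datatypes import ATTRIBUTES, PHASES, EffectConfig
from .features import extract_features, load_features_npz, save_features_npz
from .indices import (
    THRESHOLDS,
    count_occurrences,
    modality_specificity,
    phase_specificity,
    prominence,
    window_bin_profile,
)
from .synth import DEFAULT_SAMPLE_RATE_HZ, make_dataset, make_population
from .temporal import time_course

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and an error code."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Flat run configuration; every default is the analysis's standard value."""

    seed: int = 0
    n_callers: int = 10
    n_calls: int = 60
    sample_rate_hz: int = DEFAULT_SAMPLE_RATE_HZ
    effect_size: float = 1.0          # 0 gives the no-signal null dataset
    context_travel_weight: float = 139 / 221
    context_feeding_weight: float = 82 / 221
    attributes: tuple[str, ...] = ATTRIBUTES
    phases: tuple[str, ...] = PHASES
    windows_ms: tuple[int, ...] = tuple(range(50, 3251, 50))
    onsets_ms: tuple[int, ...] = tuple(range(0, 3001, 100))
    thresholds: tuple[int, ...] = THRESHOLDS
    repeats: int = 10
    temporal_repeats: int = 3
    tuning_fraction: float = 0.10
    train_fraction: float = 0.80

    def svm_config(self) -> SvmConfig:
        return SvmConfig(
            tuning_fraction=self.tuning_fraction,
            train_fraction=self.train_fraction,
        )

    def effects(self) -> EffectConfig:
        if self.effect_size == 0:
            return EffectConfig.null()
        return EffectConfig.defaults(self.effect_size)

    def context_mix(self) -> dict[str, float]:
        return {
            "travel": self.context_travel_weight,
            "feeding": self.context_feeding_weight,
        }

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("attributes", "phases", "windows_ms", "onsets_ms", "thresholds"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(self).items()},
                fh,
            )

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _timed(manifest: dict, stage: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s started", stage)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            manifest.setdefault("stages", {})[stage] = {"seconds": round(dt, 2)}
            if exc_type is None:
                logger.info("stage %s finished in %.1fs", stage, dt)
            else:
                logger.error("stage %s failed after %.1fs: %s", stage, dt, exc)
            return False

    return _Timer()


def _record(manifest: dict, path: Path) -> None:
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    manifest.setdefault("outputs", {})[path.name] = digest


def stage_simulate(config: RunConfig, outdir: Path, manifest: dict) -> pd.DataFrame:
    from .synth import write_dataset

    population = make_population(config.n_callers, seed=config.seed)
    recordings, meta = make_dataset(
        population,
        config.n_calls,
        context_mix=config.context_mix(),
        effects=config.effects(),
        seed=config.seed,
        sample_rate_hz=config.sample_rate_hz,
    )
    write_dataset(recordings, outdir / "audio")
    meta.to_csv(outdir / "metadata.csv", index=False)
    _record(manifest, outdir / "metadata.csv")
    return meta


def stage_features(config: RunConfig, outdir: Path, manifest: dict) -> dict:
    from .features import read_wav

    audio_meta = pd.read_csv(outdir / "audio" / "metadata.csv")
    features = {}
    for _, row in audio_meta.iterrows():
        wav, rate = read_wav(outdir / "audio" / row["wav_path"], config.sample_rate_hz)
        clip_id = f"{row['call_id']}:{row['phase']}"
        features[clip_id] = extract_features(wav, rate, clip_id=clip_id)
    save_features_npz(outdir / "features.npz", features)
    _record(manifest, outdir / "features.npz")
    return features


def stage_classify(config: RunConfig, outdir: Path, manifest: dict) -> pd.DataFrame:
    meta = pd.read_csv(outdir / "metadata.csv")
    features = load_features_npz(outdir / "features.npz")
    cells = classify_grid(
        features,
        meta,
        attributes=config.attributes,
        phases=config.phases,
        windows=config.windows_ms,
        config=config.svm_config(),
        repeats=config.repeats,
        master_seed=config.seed,
    )
    df = results_frame(cells)
    df.to_csv(outdir / "classification.csv", index=False)
    _record(manifest, outdir / "classification.csv")
    return df


def stage_indices(config: RunConfig, outdir: Path, manifest: dict) -> None:
    results = pd.read_csv(outdir / "classification.csv")
    occ = count_occurrences(results, config.thresholds)
    tables = {
        "occurrences.csv": occ,
        "prominence.csv": prominence(occ),
        "modality_specificity.csv": modality_specificity(occ),
        "phase_specificity.csv": phase_specificity(occ),
        "window_bins.csv": window_bin_profile(results),
    }
    for name, table in tables.items():
        table.to_csv(outdir / name)
        _record(manifest, outdir / name)
    sidecar = {
        "thresholds": list(config.thresholds),
        "normalization": "counts summed over thresholds before normalization",
    }
    (outdir / "indices.json").write_text(json.dumps(sidecar, indent=2))
    _record(manifest, outdir / "indices.json")


def stage_timecourse(config: RunConfig, outdir: Path, manifest: dict) -> pd.DataFrame:
    meta = pd.read_csv(outdir / "metadata.csv")
    features = load_features_npz(outdir / "features.npz")
    course = time_course(
        features,
        meta,
        attributes=config.attributes,
        phases=config.phases,
        onsets_ms=config.onsets_ms,
        windows=config.windows_ms,
        config=config.svm_config(),
        repeats=config.temporal_repeats,
        master_seed=config.seed,
    )
    course.to_csv(outdir / "timecourse.csv", index=False)
    _record(manifest, outdir / "timecourse.csv")
    return course


def stage_composition(config: RunConfig, outdir: Path, manifest: dict) -> None:
    meta = pd.read_csv(outdir / "metadata.csv")
    calls = meta.drop_duplicates("call_id")
    rates = presence_rates(calls)
    rates.to_csv(outdir / "presence_rates.csv", index=False)
    _record(manifest, outdir / "presence_rates.csv")
    diagnostics = {}
    tables = []
    for phase in ("build-up", "let-down"):
        res = fit_presence_model(calls, phase)
        tab = res.coef_table()
        tab.insert(0, "phase", phase)
        tables.append(tab)
        diagnostics[phase] = {
            "converged": res.converged,
            "possible_separation": res.possible_separation,
            "random_intercept_sd": res.vc_sd,
            "llf": res.llf,
            "n_calls": res.n_calls,
        }
    pd.concat(tables).to_csv(outdir / "composition_coefficients.csv")
    _record(manifest, outdir / "composition_coefficients.csv")
    (outdir / "composition_diagnostics.json").write_text(json.dumps(diagnostics, indent=2))
    _record(manifest, outdir / "composition_diagnostics.json")


STAGES = {
    "simulate": stage_simulate,
    "features": stage_features,
    "classify": stage_classify,
    "indices": stage_indices,
    "timecourse": stage_timecourse,
    "composition": stage_composition,
}


def run_full_analysis(config: RunConfig, outdir) -> dict:
    """Run all stages in order; returns the manifest. Idempotent per seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "versions": {"panthoot": __version__, "numpy": np.__version__},
    }
    config.to_yaml(outdir / "config.yaml")
    for name, fn in STAGES.items():
        with _timed(manifest, name):
            try:
                fn(config, outdir, manifest)
            except StageError:
                raise
            except Exception as err:  # noqa: BLE001 - re-tag with the stage name
                raise StageError(name, str(err)) from err
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
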