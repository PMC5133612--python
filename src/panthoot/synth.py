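"""Synthetic pant-hoot generator.

Field recordings of the study community are not publicly deposited, so the
pipeline is exercised on synthetic calls whose *statistical* structure matches
what the analysis assumes: four sequential phases with phase-specific spectral
templates, caller-attribute signatures injected into configurable phases, and
context-dependent omission of the build-up and let-down. No attempt is made at
perceptual realism — only separability of the classes matters downstream.

Each phase is an additive harmonic source (fundamental plus harmonics with a
power-law spectral tilt and a Gaussian formant-like resonance) shaped by a
pulsed amplitude envelope, plus a small seeded noise floor. Attribute effects
enter as additive offsets on the generative parameters (F0, pulse rate,
spectral tilt, resonance position), scaled by the per-(attribute, phase)
effect size; with all effect sizes zero the waveform distribution is
independent of every caller attribute.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    CONTEXTS,
    OPTIONAL_PHASES,
    PHASES,
    CallMetadata,
    CallRecording,
    CallerProfile,
    EffectConfig,
    age_class_of,
    metadata_frame,
    rank_class_of,
)
from .features import write_wav

DEFAULT_SAMPLE_RATE_HZ = 44100

#: mean phase durations (s); the introduction tends to be the longest phase.
DEFAULT_DURATIONS_S: dict[str, float] = {
    "introduction": 4.0,
    "build-up": 2.5,
    "climax": 2.0,
    "let-down": 1.5,
}
DURATION_JITTER_SIGMA = 0.13  # lognormal sigma, ~ +/-30% at 2 sigma

#: default context mixture (travel-heavy, matching the corpus composition).
DEFAULT_CONTEXT_MIX: dict[str, float] = {"travel": 139 / 221, "feeding": 82 / 221}


@dataclass(frozen=True)
class _PhaseTemplate:
    f0_hz: float          # fundamental of the voiced source
    amp: float            # peak amplitude target
    rate_hz: float        # unit / pulse rate of the envelope
    rate_slope: float     # fractional rate change across the phase
    duty: float           # envelope sharpness exponent (higher = sharper pulses)
    tilt: float           # power-law rolloff exponent over harmonic number
    formant_hz: float     # center of the resonance emphasis
    formant_bw_hz: float  # its bandwidth


# qualitative templates: slow low-F0 tonal introduction, accelerating pulsed
# build-up, high-amplitude high-F0 scream climax, faint pulsed let-down.
_TEMPLATES: dict[str, _PhaseTemplate] = {
    "introduction": _PhaseTemplate(120.0, 0.18, 1.2, 0.0, 1.5, 1.0, 900.0, 400.0),
    "build-up": _PhaseTemplate(170.0, 0.28, 3.0, 0.8, 2.5, 1.1, 1200.0, 500.0),
    "climax": _PhaseTemplate(850.0, 0.90, 1.0, 0.0, 0.3, 0.8, 2500.0, 700.0),
    "let-down": _PhaseTemplate(150.0, 0.12, 3.0, -0.3, 2.5, 1.2, 1000.0, 450.0),
}

_AGE_CENTER, _AGE_HALFSPAN = 22.5, 8.5


def make_population(
    n_callers: int,
    age_range: tuple[int, int] = (14, 31),
    seed: int | None = None,
) -> list[CallerProfile]:
    """Draw a population of callers with distinct IDs and a rank permutation.

    Ages are stratified across the two age-class bins when the requested range
    spans both, so a 10-caller population splits 5/5 as in the study group.
    """
    if n_callers < 2:
        raise ValueError("need at least 2 callers for any classification task")
    lo, hi = age_range
    if not (13 <= lo <= hi <= 50):
        raise ValueError("age_range must lie within [13, 50]")
    rng = np.random.default_rng(seed)
    ranks = rng.permutation(n_callers) + 1

    ages = np.empty(n_callers, dtype=int)
    if lo <= 19 and hi >= 20:
        # stratify: first half young (<=19), second half old (>=20)
        n_young = n_callers // 2 + n_callers % 2
        ages[:n_young] = rng.integers(max(lo, 14), 19 + 1, size=n_young)
        ages[n_young:] = rng.integers(20, hi + 1, size=n_callers - n_young)
    else:
        ages[:] = rng.integers(lo, hi + 1, size=n_callers)

    profiles = []
    for i in range(n_callers):
        profiles.append(
            CallerProfile(
                caller_id=i + 1,
                age_years=int(ages[i]),
                elo_rank=int(ranks[i]),
                age_class=age_class_of(int(ages[i])),
                rank_class=rank_class_of(int(ranks[i])),
                base_f0_hz=float(rng.uniform(250.0, 350.0)),
                vocal_tract_scale=float(rng.uniform(0.85, 1.15)),
            )
        )
    return profiles


def _perturbed_params(
    phase: str, profile: CallerProfile, context: str, effects: EffectConfig
) -> _PhaseTemplate:
    """Apply additive attribute offsets to the phase template."""
    t = _TEMPLATES[phase]
    # caller-idiosyncratic signature traits, roughly in [-1, 1]
    id_f0 = (profile.base_f0_hz - 300.0) / 50.0
    id_vt = (profile.vocal_tract_scale - 1.0) / 0.15
    z_age = np.clip((profile.age_years - _AGE_CENTER) / _AGE_HALFSPAN, -1.5, 1.5)
    z_rank = (profile.rank_class - 2.5) / 1.5
    z_ctx = 1.0 if context == "feeding" else -1.0

    e_id = effects.effect("identity", phase)
    e_age = effects.effect("age", phase)
    e_rank = effects.effect("social_status", phase)
    e_ctx = effects.effect("context", phase)

    f0 = t.f0_hz + (
        e_id * id_f0 * 0.10 * t.f0_hz
        - e_age * z_age * 0.06 * t.f0_hz
        + e_rank * z_rank * 0.08 * t.f0_hz
    )
    formant = t.formant_hz + (
        e_id * id_vt * 0.20 * t.formant_hz
        - e_age * z_age * 0.10 * t.formant_hz
        + e_rank * z_rank * 0.15 * t.formant_hz
        + e_ctx * z_ctx * 0.12 * t.formant_hz
    )
    tilt = t.tilt + e_age * z_age * 0.15 + e_ctx * z_ctx * 0.10
    rate = t.rate_hz * (1.0 + e_ctx * z_ctx * 0.15)
    return _PhaseTemplate(
        f0_hz=max(f0, 40.0),
        amp=t.amp,
        rate_hz=max(rate, 0.2),
        rate_slope=t.rate_slope,
        duty=t.duty,
        tilt=max(tilt, 0.2),
        formant_hz=max(formant, 200.0),
        formant_bw_hz=t.formant_bw_hz,
    )


def synthesize_phase(
    phase: str,
    profile: CallerProfile,
    context: str,
    duration_s: float,
    sample_rate_hz: int = DEFAULT_SAMPLE_RATE_HZ,
    effects: EffectConfig | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """One phase waveform; deterministic for a fixed seed.

    With all effect sizes zero the output is identical for every profile and
    context (all caller dependence is routed through the effect offsets).
    """
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}")
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    effects = effects if effects is not None else EffectConfig.null()
    p = _perturbed_params(phase, profile, context, effects)
    rng = np.random.default_rng(seed)

    n = int(round(duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz

    # slowly varying F0: vibrato plus smoothed seeded jitter
    jitter = rng.standard_normal(max(n // 2048, 4))
    jitter = np.interp(np.linspace(0, 1, n), np.linspace(0, 1, jitter.size), jitter)
    f0_traj = p.f0_hz * (1.0 + 0.015 * np.sin(2 * np.pi * 4.5 * t) + 0.02 * jitter)
    phase_int = 2 * np.pi * np.cumsum(f0_traj) / sample_rate_hz

    n_harm = max(1, min(24, int(0.45 * sample_rate_hz / p.f0_hz)))
    k = np.arange(1, n_harm + 1)
    resonance = np.exp(-((k * p.f0_hz - p.formant_hz) ** 2) / (2 * p.formant_bw_hz**2))
    amp_k = k ** (-p.tilt) * (0.25 + resonance)
    x = np.zeros(n)
    for kk, a in zip(k, amp_k):
        x += a * np.sin(kk * phase_int)

    # pulsed amplitude envelope with a rate ramp across the phase
    rate_traj = p.rate_hz * (1.0 + p.rate_slope * (t / duration_s - 0.5))
    env_phase = 2 * np.pi * np.cumsum(rate_traj) / sample_rate_hz
    env = (0.5 - 0.5 * np.cos(env_phase)) ** p.duty
    fade = np.minimum(1.0, np.minimum(t, duration_s - t) / 0.05)  # 50 ms edge fades
    env *= fade

    x = x * env + 0.02 * rng.standard_normal(n) * (0.2 + env)
    peak = np.max(np.abs(x))
    if peak > 0:
        x *= p.amp / peak
    return np.clip(x, -1.0, 1.0)


def synthesize_pant_hoot(
    profile: CallerProfile,
    context: str,
    effects: EffectConfig | None = None,
    seed: int | None = None,
    sample_rate_hz: int = DEFAULT_SAMPLE_RATE_HZ,
    durations_s: dict[str, float] | None = None,
    call_id: str = "call",
) -> CallRecording:
    """Concatenate phases in canonical order with context-dependent omission.

    The build-up and let-down are independently dropped with probability
    1 - presence_prob(phase, context); introduction and climax always occur.
    """
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    effects = effects if effects is not None else EffectConfig.null()
    durations_s = durations_s or DEFAULT_DURATIONS_S
    rng = np.random.default_rng(seed)

    present = {phase: True for phase in PHASES}
    for phase in OPTIONAL_PHASES:
        present[phase] = bool(rng.random() < effects.presence(phase, context))

    pieces, spans = [], []
    cursor = 0.0
    for phase in PHASES:
        if not present[phase]:
            continue
        dur = float(durations_s[phase] * rng.lognormal(0.0, DURATION_JITTER_SIGMA))
        w = synthesize_phase(
            phase, profile, context, dur, sample_rate_hz, effects,
            seed=int(rng.integers(2**31)),
        )
        pieces.append(w)
        start = cursor
        cursor += len(w) / sample_rate_hz
        spans.append((phase, start, cursor))

    md = CallMetadata(
        caller_id=profile.caller_id,
        age_years=profile.age_years,
        age_class=profile.age_class,
        elo_rank=profile.elo_rank,
        rank_class=profile.rank_class,
        context=context,
        has_buildup=present["build-up"],
        has_letdown=present["let-down"],
    )
    return CallRecording(
        call_id=call_id,
        waveform=np.concatenate(pieces),
        sample_rate_hz=sample_rate_hz,
        phase_spans=spans,
        metadata=md,
    )


def _draw_composition(
    profile: CallerProfile, context: str, effects: EffectConfig, rng: np.random.Generator
) -> CallMetadata:
    """Presence flags only (no audio) — for composition-model simulations."""
    return CallMetadata(
        caller_id=profile.caller_id,
        age_years=profile.age_years,
        age_class=profile.age_class,
        elo_rank=profile.elo_rank,
        rank_class=profile.rank_class,
        context=context,
        has_buildup=bool(rng.random() < effects.presence("build-up", context)),
        has_letdown=bool(rng.random() < effects.presence("let-down", context)),
    )


def _assign_calls(
    population: list[CallerProfile],
    n_calls: int,
    context_mix: dict[str, float] | None,
    rng: np.random.Generator,
) -> list[tuple[CallerProfile, str]]:
    if not population:
        raise ValueError("population must be non-empty")
    if n_calls < 1:
        raise ValueError("n_calls must be >= 1")
    mix = context_mix or DEFAULT_CONTEXT_MIX
    total = sum(mix.values())
    names = list(mix)
    probs = np.array([mix[c] / total for c in names])
    contexts = rng.choice(names, size=n_calls, p=probs)
    return [(population[i % len(population)], contexts[i]) for i in range(n_calls)]


def make_dataset(
    population: list[CallerProfile],
    n_calls: int,
    context_mix: dict[str, float] | None = None,
    effects: EffectConfig | None = None,
    seed: int | None = None,
    sample_rate_hz: int = DEFAULT_SAMPLE_RATE_HZ,
    durations_s: dict[str, float] | None = None,
) -> tuple[list[CallRecording], pd.DataFrame]:
    """Round-robin caller assignment, seeded contexts; recordings plus table."""
    effects = effects if effects is not None else EffectConfig.null()
    rng = np.random.default_rng(seed)
    recs = []
    for i, (profile, context) in enumerate(_assign_calls(population, n_calls, context_mix, rng)):
        recs.append(
            synthesize_pant_hoot(
                profile, context, effects,
                seed=int(rng.integers(2**31)),
                sample_rate_hz=sample_rate_hz,
                durations_s=durations_s,
                call_id=f"call{i:04d}",
            )
        )
    return recs, metadata_frame(recs)


def make_composition_table(
    population: list[CallerProfile],
    n_calls: int,
    context_mix: dict[str, float] | None = None,
    effects: EffectConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-call metadata with presence flags, without synthesizing audio.

    Draws composition from the same presence probabilities as
    :func:`synthesize_pant_hoot`; used for phase-presence model simulations
    where waveforms are irrelevant.
    """
    effects = effects if effects is not None else EffectConfig.null()
    rng = np.random.default_rng(seed)
    rows = []
    for i, (profile, context) in enumerate(_assign_calls(population, n_calls, context_mix, rng)):
        md = _draw_composition(profile, context, effects, rng)
        rows.append(
            {
                "call_id": f"call{i:04d}",
                "caller_id": md.caller_id,
                "age_years": md.age_years,
                "age_class": md.age_class,
                "elo_rank": md.elo_rank,
                "rank_class": md.rank_class,
                "context": md.context,
                "has_buildup": md.has_buildup,
                "has_letdown": md.has_letdown,
            }
        )
    return pd.DataFrame(rows)


def write_dataset(recordings: list[CallRecording], outdir) -> Path:
    """One WAV per phase clip plus a metadata CSV; returns the CSV path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / "metadata.csv"
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["call_id", "phase", "caller_id", "age_years", "age_class", "elo_rank",
             "rank_class", "context", "wav_path", "duration_s"]
        )
        for rec in recordings:
            md = rec.metadata
            for phase, start, end in rec.phase_spans:
                wav_name = f"{rec.call_id}_{phase.replace('-', '')}.wav"
                write_wav(outdir / wav_name, rec.phase_waveform(phase), rec.sample_rate_hz)
                writer.writerow(
                    [rec.call_id, phase, md.caller_id, md.age_years, md.age_class,
                     md.elo_rank, md.rank_class, md.context, wav_name, f"{end - start:.4f}"]
                )
    return csv_path
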