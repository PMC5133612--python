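"""Core domain containers shared across the pipeline.

The unit of analysis is a single pant hoot: a four-phase long-distance call
(introduction, build-up, climax, let-down, produced in this order, with the
build-up and let-down optionally omitted). A recording is a mono waveform plus
phase-span annotations; metadata carries the caller attributes whose acoustic
correlates the pipeline quantifies (identity, age, social status, context).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

PHASES: tuple[str, ...] = ("introduction", "build-up", "climax", "let-down")
ATTRIBUTES: tuple[str, ...] = ("identity", "age", "social_status", "context")
CONTEXTS: tuple[str, ...] = ("travel", "feeding")

#: phases a caller may omit; a call without a climax is not a pant hoot.
OPTIONAL_PHASES: tuple[str, ...] = ("build-up", "let-down")

#: age-class bins (years, inclusive): class 1 = late adolescent / young adult,
#: class 2 = older adult.
AGE_CLASS_BINS: dict[int, tuple[int, int]] = {1: (14, 19), 2: (20, 31)}

#: rank-class bins over Elo-rank positions (1 = highest-ranking).
RANK_CLASS_BINS: dict[int, tuple[int, int]] = {1: (1, 3), 2: (4, 6), 3: (7, 9), 4: (10, 12)}


def age_class_of(age_years: int) -> int:
    """Map age in years to its class label (1: 14-19, 2: 20-31)."""
    for cls, (lo, hi) in AGE_CLASS_BINS.items():
        if lo <= age_years <= hi:
            return cls
    # outside the study's bins: split at the 19/20 boundary
    return 1 if age_years <= 19 else 2


def rank_class_of(elo_rank: int) -> int:
    """Map an Elo-rank position (1 = top) to its class, groups of three."""
    if elo_rank < 1:
        raise ValueError(f"elo_rank must be >= 1, got {elo_rank}")
    return min((elo_rank - 1) // 3 + 1, 4)


@dataclass(frozen=True)
class CallerProfile:
    """One simulated male: stable attributes plus caller-specific vocal traits.

    ``base_f0_hz`` and ``vocal_tract_scale`` are the caller's idiosyncratic
    source and filter traits; they only reach the waveform through a nonzero
    identity effect size.
    """

    caller_id: int
    age_years: int
    elo_rank: int
    age_class: int = field(default=0)
    rank_class: int = field(default=0)
    base_f0_hz: float = 300.0
    vocal_tract_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.age_class == 0:
            object.__setattr__(self, "age_class", age_class_of(self.age_years))
        if self.rank_class == 0:
            object.__setattr__(self, "rank_class", rank_class_of(self.elo_rank))
        if self.base_f0_hz <= 0:
            raise ValueError("base_f0_hz must be positive")
        if self.vocal_tract_scale <= 0:
            raise ValueError("vocal_tract_scale must be positive")


# presence probabilities of the droppable phases per context; the four values
# are the observed presence percentages in travelling vs feeding contexts.
DEFAULT_PRESENCE_PROB: dict[tuple[str, str], float] = {
    ("build-up", "travel"): 0.9558,
    ("build-up", "feeding"): 0.7317,
    ("let-down", "travel"): 0.9352,
    ("let-down", "feeding"): 0.5488,
}

#: default placement of attribute signatures: which phases carry acoustic
#: correlates of which attribute (identity: introduction+climax, age:
#: introduction+build-up, social status: climax, context: let-down).
DEFAULT_EFFECT_PLACEMENT: dict[str, tuple[str, ...]] = {
    "identity": ("introduction", "climax"),
    "age": ("introduction", "build-up"),
    "social_status": ("climax",),
    "context": ("let-down",),
}


@dataclass(frozen=True)
class EffectConfig:
    """How strongly each caller attribute perturbs each phase's acoustics.

    ``effect_sizes[(attribute, phase)]`` is a non-negative multiplier on the
    attribute's parameter offsets in that phase; 0 means no acoustic correlate.
    ``presence_prob[(phase, context)]`` is the probability that an optional
    phase is produced at all in that context (the complement is the omission
    probability). The introduction and climax are never omitted.
    """

    effect_sizes: Mapping[tuple[str, str], float] = field(default_factory=dict)
    presence_prob: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_PRESENCE_PROB)
    )

    def __post_init__(self) -> None:
        for (attr, phase), e in self.effect_sizes.items():
            if attr not in ATTRIBUTES:
                raise ValueError(f"unknown attribute {attr!r}")
            if phase not in PHASES:
                raise ValueError(f"unknown phase {phase!r}")
            if e < 0:
                raise ValueError("effect sizes must be non-negative")
        for (phase, context), p in self.presence_prob.items():
            if phase not in OPTIONAL_PHASES:
                raise ValueError(f"{phase!r} cannot be omitted")
            if context not in CONTEXTS:
                raise ValueError(f"unknown context {context!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError("presence probabilities must lie in [0, 1]")

    def effect(self, attribute: str, phase: str) -> float:
        return float(self.effect_sizes.get((attribute, phase), 0.0))

    def presence(self, phase: str, context: str) -> float:
        return float(self.presence_prob.get((phase, context), 1.0))

    @classmethod
    def null(cls) -> "EffectConfig":
        """All effect sizes zero: no attribute has an acoustic correlate."""
        return cls(effect_sizes={})

    @classmethod
    def defaults(cls, effect_size: float = 1.0) -> "EffectConfig":
        """The study-condition placement of signatures at a common strength."""
        sizes = {
            (attr, phase): effect_size
            for attr, phases in DEFAULT_EFFECT_PLACEMENT.items()
            for phase in phases
        }
        return cls(effect_sizes=sizes)

    @classmethod
    def single(cls, attribute: str, phase: str, effect_size: float) -> "EffectConfig":
        """A single attribute signature in a single phase; all else silent."""
        return cls(effect_sizes={(attribute, phase): effect_size})

    def with_presence(self, presence: Mapping[tuple[str, str], float]) -> "EffectConfig":
        merged = dict(self.presence_prob)
        merged.update(presence)
        return replace(self, presence_prob=merged)


@dataclass(frozen=True)
class CallMetadata:
    """Caller attributes and composition flags for one pant hoot."""

    caller_id: int
    age_years: int
    age_class: int
    elo_rank: int
    rank_class: int
    context: str
    has_buildup: bool
    has_letdown: bool

    def label(self, attribute: str):
        """The class label of this call under one of the four label schemes."""
        if attribute == "identity":
            return self.caller_id
        if attribute == "age":
            return self.age_class
        if attribute == "social_status":
            return self.rank_class
        if attribute == "context":
            return self.context
        raise ValueError(f"unknown attribute {attribute!r}")


@dataclass
class CallRecording:
    """One pant hoot: waveform, phase spans, and caller metadata."""

    call_id: str
    waveform: np.ndarray
    sample_rate_hz: int
    phase_spans: list[tuple[str, float, float]]
    metadata: CallMetadata

    def __post_init__(self) -> None:
        dur = len(self.waveform) / self.sample_rate_hz
        phases_present = [p for p, _, _ in self.phase_spans]
        if "climax" not in phases_present:
            raise ValueError("a call without a climax is not a pant hoot")
        order = [p for p in PHASES if p in phases_present]
        if phases_present != order:
            raise ValueError("phase spans out of canonical order")
        prev_end = 0.0
        for phase, start, end in self.phase_spans:
            if not (0.0 <= start < end <= dur + 1e-9):
                raise ValueError(f"span for {phase} outside the waveform")
            if start < prev_end - 1e-9:
                raise ValueError("phase spans overlap")
            prev_end = end
        if np.max(np.abs(self.waveform), initial=0.0) > 1.0 + 1e-9:
            raise ValueError("waveform amplitude exceeds [-1, 1]")

    @property
    def duration_s(self) -> float:
        return len(self.waveform) / self.sample_rate_hz

    def phases_present(self) -> list[str]:
        return [p for p, _, _ in self.phase_spans]

    def phase_waveform(self, phase: str) -> np.ndarray:
        for p, start, end in self.phase_spans:
            if p == phase:
                i0 = int(round(start * self.sample_rate_hz))
                i1 = int(round(end * self.sample_rate_hz))
                return self.waveform[i0:i1]
        raise KeyError(f"phase {phase!r} not present in call {self.call_id}")


def metadata_frame(recordings: Iterable[CallRecording]):
    """Flat per-phase-clip table: one row per (call, present phase)."""
    import pandas as pd

    rows = []
    for rec in recordings:
        md = rec.metadata
        for phase, start, end in rec.phase_spans:
            rows.append(
                {
                    "call_id": rec.call_id,
                    "clip_id": f"{rec.call_id}:{phase}",
                    "phase": phase,
                    "caller_id": md.caller_id,
                    "age_years": md.age_years,
                    "age_class": md.age_class,
                    "elo_rank": md.elo_rank,
                    "rank_class": md.rank_class,
                    "context": md.context,
                    "has_buildup": md.has_buildup,
                    "has_letdown": md.has_letdown,
                    "duration_s": end - start,
                }
            )
    return pd.DataFrame(rows)
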