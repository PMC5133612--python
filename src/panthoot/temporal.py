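"""Onset-locked time-course analysis.

The classification is re-run with segments anchored at fixed onsets (0-3000 ms
in 100 ms steps, relative to each phase clip's own onset) instead of random
positions. Scores are averaged over the evaluable segment lengths at each
onset, and the five onsets with the highest mean performance are flagged per
(attribute, phase); ties break toward earlier onsets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classify import SvmConfig, classify_grid
from .datatypes import ATTRIBUTES, PHASES
from .features import FeatureMatrix

STANDARD_ONSETS_MS: tuple[int, ...] = tuple(range(0, 3001, 100))
TOP_N = 5


def time_course(
    features: dict[str, FeatureMatrix],
    meta: pd.DataFrame,
    attributes: tuple[str, ...] = ATTRIBUTES,
    phases: tuple[str, ...] = PHASES,
    onsets_ms: tuple[int, ...] = STANDARD_ONSETS_MS,
    windows: tuple[int, ...] = (),
    config: SvmConfig | None = None,
    repeats: int = 3,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Mean percent correct per (attribute, phase, onset), plus top-5 flags.

    Onsets beyond every clip of a phase produce fully padded segments and a
    missing (NaN) cell. The average at each onset runs over the window
    lengths that produced a score there, and the count is recorded.
    """
    frames = []
    for onset in onsets_ms:
        cells = classify_grid(
            features, meta,
            attributes=attributes, phases=phases, windows=windows,
            config=config, repeats=repeats, master_seed=master_seed,
            onset_ms=float(onset),
        )
        for r in cells:
            frames.append(
                {
                    "attribute": r.attribute,
                    "phase": r.phase,
                    "onset_ms": float(onset),
                    "window_ms": r.window_ms,
                    "percent_correct": r.percent_correct,
                }
            )
    long = pd.DataFrame(frames)

    out = (
        long.groupby(["attribute", "phase", "onset_ms"], sort=False)
        .agg(
            mean_percent_correct=("percent_correct", lambda s: np.nanmean(s) if s.notna().any() else np.nan),
            n_lengths=("percent_correct", lambda s: int(s.notna().sum())),
        )
        .reset_index()
    )
    out["is_top5"] = False
    for (_, _), grp in out.groupby(["attribute", "phase"], sort=False):
        valid = grp.dropna(subset=["mean_percent_correct"])
        # highest mean first; ties toward earlier onsets
        ranked = valid.sort_values(
            ["mean_percent_correct", "onset_ms"], ascending=[False, True]
        )
        out.loc[ranked.index[:TOP_N], "is_top5"] = True
    return out


def top_onsets(course: pd.DataFrame, attribute: str, phase: str) -> list[float]:
    """The flagged top-5 onsets of one cell, in ascending onset order."""
    sel = course[
        (course["attribute"] == attribute)
        & (course["phase"] == phase)
        & course["is_top5"]
    ]
    return sorted(sel["onset_ms"].tolist())
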