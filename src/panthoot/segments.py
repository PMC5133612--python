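"""Fixed-length feature segments and train-only feature normalization.

Classification never sees a whole phase clip: for each call exactly one
segment of a predetermined length (50-3250 ms in 50 ms steps) is cut from the
clip's feature matrix, at a random or fixed onset. Windows longer than the
clip are padded with NaN markers; the padded positions are imputed as 0 only
after scaling, i.e. at the per-dimension scaled mean, the least informative
constant. Scaling maps each dimension to [0, 1] on the training set and then
subtracts the training mean of the scaled values; test data pass through the
same affine map unclipped.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass

import numpy as np

from .features import HOP_MS, FeatureMatrix, expected_frame_count

WINDOW_STEP_MS = 50
WINDOW_MIN_MS = 50
WINDOW_MAX_MS = 3250

STANDARD_WINDOWS_MS = tuple(range(WINDOW_MIN_MS, WINDOW_MAX_MS + 1, WINDOW_STEP_MS))


def validate_window(window_ms: int) -> None:
    if (
        window_ms < WINDOW_MIN_MS
        or window_ms > WINDOW_MAX_MS
        or window_ms % WINDOW_STEP_MS != 0
    ):
        raise ValueError(
            f"window_ms must be a multiple of {WINDOW_STEP_MS} in "
            f"[{WINDOW_MIN_MS}, {WINDOW_MAX_MS}], got {window_ms}"
        )


def frames_in_window(window_ms: int) -> int:
    """Number of analysis frames a window of this length spans."""
    validate_window(window_ms)
    return expected_frame_count(window_ms)


@dataclass
class SegmentVector:
    """One flattened feature segment (frame-major) with a missing mask."""

    clip_id: str
    phase: str
    window_ms: int
    onset_ms: float
    values: np.ndarray        # (frames_in_window * n_coeffs,)
    missing_mask: np.ndarray  # boolean, same shape; True where padded

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())


def extract_segment(
    features: FeatureMatrix,
    window_ms: int,
    mode: str = "random",
    onset_ms: float | None = None,
    rng: np.random.Generator | None = None,
    phase: str = "",
) -> SegmentVector:
    """Cut one fixed-length segment from a clip's feature matrix.

    ``random`` mode draws a uniformly random admissible onset (0 when the
    window exceeds the clip); ``fixed`` uses ``onset_ms``. Onsets are snapped
    to the 15 ms hop grid. Frames beyond the clip's last frame are NaN and
    flagged in the missing mask.
    """
    n_needed = frames_in_window(window_ms)
    stacked = features.stacked
    n_have, n_coeffs = stacked.shape

    if mode == "random":
        if rng is None:
            raise ValueError("random mode requires an rng")
        start = int(rng.integers(0, max(n_have - n_needed, 0) + 1))
    elif mode == "fixed":
        if onset_ms is None or onset_ms < 0:
            raise ValueError("fixed mode requires a non-negative onset_ms")
        start = int(round(onset_ms / HOP_MS))
        if start >= n_have:
            warnings.warn(
                f"onset {onset_ms} ms beyond clip {features.clip_id!r}; "
                "segment is fully padded",
                stacklevel=2,
            )
    else:
        raise ValueError(f"unknown mode {mode!r}")

    seg = np.full((n_needed, n_coeffs), np.nan)
    n_copy = max(0, min(n_needed, n_have - start))
    if n_copy:
        seg[:n_copy] = stacked[start : start + n_copy]
    mask = np.isnan(seg)
    return SegmentVector(
        clip_id=features.clip_id,
        phase=phase,
        window_ms=window_ms,
        onset_ms=start * HOP_MS,
        values=seg.ravel(),
        missing_mask=mask.ravel(),
    )


def segments_frame(segments: list[SegmentVector]):
    """Bookkeeping table for a batch of segments (one row per segment)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "clip_id": s.clip_id,
                "phase": s.phase,
                "window_ms": s.window_ms,
                "onset_ms": s.onset_ms,
                "n_missing": s.n_missing,
            }
            for s in segments
        ]
    )


def segment_matrix(segments: list[SegmentVector]) -> np.ndarray:
    """Stack segments (all of one window length) into an (n, d) matrix."""
    lengths = {s.values.size for s in segments}
    if len(lengths) != 1:
        raise ValueError("segments have inconsistent vector lengths")
    return np.stack([s.values for s in segments])


@dataclass
class FeatureScaler:
    """Train-set min/range scaling followed by mean normalization.

    State is fitted once on training vectors and applied unchanged to test
    vectors (re-fitting on test data is data snooping and is guarded against
    by recording a state hash).
    """

    mins: np.ndarray
    ranges: np.ndarray
    means: np.ndarray  # mean of the scaled train values, per dimension

    @property
    def state_hash(self) -> str:
        h = hashlib.sha256()
        for a in (self.mins, self.ranges, self.means):
            h.update(np.ascontiguousarray(a).tobytes())
        return h.hexdigest()[:16]

    @classmethod
    def fit(cls, train: np.ndarray) -> "FeatureScaler":
        if train.ndim != 2 or train.shape[0] == 0:
            raise ValueError("need a non-empty (n, d) training matrix")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            mins = np.nanmin(train, axis=0)
            maxs = np.nanmax(train, axis=0)
        mins = np.where(np.isnan(mins), 0.0, mins)
        maxs = np.where(np.isnan(maxs), 0.0, maxs)
        ranges = maxs - mins
        safe = np.where(ranges > 0, ranges, 1.0)
        scaled = (train - mins) / safe
        scaled = np.where(ranges > 0, scaled, 0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means = np.nanmean(scaled, axis=0)
        means = np.where(np.isnan(means), 0.0, means)
        return cls(mins=mins, ranges=ranges, means=means)

    def transform(self, x: np.ndarray) -> np.ndarray:
        safe = np.where(self.ranges > 0, self.ranges, 1.0)
        out = (x - self.mins) / safe - self.means
        out = np.where(self.ranges > 0, out, 0.0)
        return np.where(np.isnan(out), 0.0, out)  # impute padding at scaled mean


def scale_and_normalize(
    train: np.ndarray, test: np.ndarray
) -> tuple[np.ndarray, np.ndarray, FeatureScaler]:
    """Fit on train only; apply to both. Returns the scaler state as well."""
    scaler = FeatureScaler.fit(train)
    return scaler.transform(train), scaler.transform(test), scaler
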