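"""Mel-frequency cepstral features for phase clips.

The analysis frames each phase clip into 30 ms Hamming windows with 50%
overlap, takes the short-time power spectrum, pools it through a 32-band
triangular mel filterbank spanning 1-20050 Hz, log-compresses the band
energies and applies an orthonormal DCT-II, keeping all 32 cepstral
coefficients. Delta coefficients (regression slope over +/-2 frames) double
the per-frame dimension to 64.

The mel scale follows the HTK convention m = 2595*log10(1 + f/700); the 32
band centers are linearly spaced in mel between m(1 Hz) and m(20050 Hz)
inclusive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.fft import dct, rfft
from scipy.io import wavfile
from scipy.signal import resample_poly

logger = logging.getLogger(__name__)

FRAME_MS = 30.0
HOP_MS = 15.0
N_BANDS = 32
FMIN_HZ = 1.0
FMAX_HZ = 20050.0
LOG_FLOOR = 1e-12  # clamp for band energies before the log (silence guard)


def hz_to_mel(f_hz):
    """HTK mel scale, m = 2595*log10(1 + f/700). Rejects negative input."""
    f = np.asarray(f_hz, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    return 2595.0 * np.log10(1.0 + f / 700.0)


def mel_to_hz(m):
    """Exact inverse of :func:`hz_to_mel`."""
    m = np.asarray(m, dtype=float)
    if np.any(m < 0):
        raise ValueError("mel value must be non-negative")
    return 700.0 * (10.0 ** (m / 2595.0) - 1.0)


@dataclass(frozen=True)
class MelFilterbank:
    """Triangular mel filterbank with peak weight 1 (HTK-style).

    Band k peaks at center k and falls linearly (in mel) to the neighbouring
    centers; the first and last bands are anchored at ``fmin_hz`` and
    ``fmax_hz``. Bands above the Nyquist frequency simply collect no energy.
    """

    n_bands: int
    fmin_hz: float
    fmax_hz: float
    sample_rate_hz: int
    n_fft: int
    center_mels: np.ndarray
    center_hz: np.ndarray
    weights: np.ndarray  # (n_bands, n_fft // 2 + 1)


def build_mel_filterbank(
    sample_rate_hz: int,
    n_fft: int,
    n_bands: int = N_BANDS,
    fmin_hz: float = FMIN_HZ,
    fmax_hz: float = FMAX_HZ,
) -> MelFilterbank:
    if n_bands < 1:
        raise ValueError("n_bands must be >= 1")
    if fmin_hz >= fmax_hz:
        raise ValueError("fmin_hz must be below fmax_hz")
    center_mels = np.linspace(hz_to_mel(fmin_hz), hz_to_mel(fmax_hz), n_bands)
    center_hz = mel_to_hz(center_mels)

    # triangle anchors in mel space; virtual edges at fmin/fmax
    edges = np.concatenate(([hz_to_mel(fmin_hz)], center_mels, [hz_to_mel(fmax_hz)]))
    bin_hz = np.arange(n_fft // 2 + 1) * sample_rate_hz / n_fft
    bin_mels = hz_to_mel(bin_hz)

    weights = np.zeros((n_bands, bin_hz.size))
    for k in range(n_bands):
        left, center, right = edges[k], edges[k + 1], edges[k + 2]
        up = (bin_mels - left) / (center - left) if center > left else (bin_mels >= center) * 1.0
        down = (right - bin_mels) / (right - center) if right > center else (bin_mels <= center) * 1.0
        weights[k] = np.clip(np.minimum(up, down), 0.0, 1.0)
    return MelFilterbank(
        n_bands=n_bands,
        fmin_hz=fmin_hz,
        fmax_hz=fmax_hz,
        sample_rate_hz=sample_rate_hz,
        n_fft=n_fft,
        center_mels=center_mels,
        center_hz=center_hz,
        weights=weights,
    )


def expected_frame_count(duration_ms: float, frame_ms: float = FRAME_MS, hop_ms: float = HOP_MS) -> int:
    """floor((clip_ms - frame_ms)/hop_ms) + 1, zero for clips under one frame."""
    if duration_ms < frame_ms - 1e-9:
        return 0
    return int(np.floor((duration_ms - frame_ms) / hop_ms + 1e-9)) + 1


def frame_signal(
    waveform: np.ndarray,
    sample_rate_hz: int,
    frame_ms: float = FRAME_MS,
    overlap: float = 0.5,
) -> np.ndarray:
    """Slice into Hamming-windowed frames; returns (n_frames, frame_len).

    Frame starts are placed on the exact hop grid in time (hop = frame *
    (1 - overlap)) so the frame count matches the duration formula even at
    sample rates where the hop is not a whole number of samples. A clip
    shorter than one frame yields an empty result and a warning.
    """
    x = np.asarray(waveform, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("waveform must be a non-empty 1-D array")
    frame_len = int(round(frame_ms * 1e-3 * sample_rate_hz))
    hop_ms = frame_ms * (1.0 - overlap)
    duration_ms = x.size / sample_rate_hz * 1e3
    n_frames = expected_frame_count(duration_ms, frame_ms, hop_ms)
    if n_frames == 0:
        warnings.warn(
            f"clip of {duration_ms:.1f} ms is shorter than one {frame_ms:.0f} ms frame",
            stacklevel=2,
        )
        return np.empty((0, frame_len))
    starts = np.round(np.arange(n_frames) * hop_ms * 1e-3 * sample_rate_hz).astype(int)
    starts = np.minimum(starts, x.size - frame_len)
    window = np.hamming(frame_len)
    return x[starts[:, None] + np.arange(frame_len)] * window


def mfcc(frames: np.ndarray, filterbank: MelFilterbank) -> np.ndarray:
    """Per-frame cepstra: power spectrum -> band energies -> log -> DCT-II."""
    if frames.ndim != 2:
        raise ValueError("frames must be 2-D (n_frames, frame_len)")
    if frames.shape[1] > filterbank.n_fft:
        raise ValueError(
            f"frame length {frames.shape[1]} exceeds filterbank FFT size {filterbank.n_fft}"
        )
    if frames.shape[0] == 0:
        return np.empty((0, filterbank.n_bands))
    spectrum = rfft(frames, n=filterbank.n_fft, axis=1)
    power = np.abs(spectrum) ** 2
    energies = power @ filterbank.weights.T
    log_e = np.log(np.maximum(energies, LOG_FLOOR))
    return dct(log_e, type=2, norm="ortho", axis=1)


def delta(coeffs: np.ndarray, width: int = 2) -> np.ndarray:
    """Regression-slope delta over +/-``width`` frames with edge replication."""
    c = np.asarray(coeffs, dtype=float)
    if c.ndim != 2 or c.shape[0] == 0:
        raise ValueError("need a non-empty (n_frames, n_coeffs) matrix")
    padded = np.concatenate([c[:1].repeat(width, axis=0), c, c[-1:].repeat(width, axis=0)])
    denom = 2 * sum(n * n for n in range(1, width + 1))
    out = np.zeros_like(c)
    for n in range(1, width + 1):
        out += n * (padded[width + n : width + n + c.shape[0]] - padded[width - n : width - n + c.shape[0]])
    return out / denom


def next_pow2(n: int) -> int:
    return 1 << (int(n) - 1).bit_length()


@dataclass
class FeatureMatrix:
    """MFCC + delta coefficients for one phase clip."""

    clip_id: str
    mfcc: np.ndarray   # (frames, n_bands)
    delta: np.ndarray  # (frames, n_bands)
    frame_ms: float = FRAME_MS
    overlap: float = 0.5
    n_bands: int = N_BANDS
    fmin_hz: float = FMIN_HZ
    fmax_hz: float = FMAX_HZ

    def __post_init__(self) -> None:
        if self.mfcc.shape != self.delta.shape:
            raise ValueError("mfcc and delta must have identical shape")

    @property
    def frames(self) -> int:
        return self.mfcc.shape[0]

    @property
    def stacked(self) -> np.ndarray:
        """(frames, 2*n_bands): MFCCs then deltas, per frame."""
        return np.concatenate([self.mfcc, self.delta], axis=1)


def extract_features(
    waveform: np.ndarray,
    sample_rate_hz: int,
    clip_id: str = "",
    n_bands: int = N_BANDS,
    fmin_hz: float = FMIN_HZ,
    fmax_hz: float = FMAX_HZ,
    filterbank: MelFilterbank | None = None,
) -> FeatureMatrix:
    """Full front end for one clip; deterministic (no randomness involved)."""
    frame_len = int(round(FRAME_MS * 1e-3 * sample_rate_hz))
    n_fft = next_pow2(frame_len)
    if filterbank is None or filterbank.n_fft != n_fft or filterbank.sample_rate_hz != sample_rate_hz:
        filterbank = build_mel_filterbank(sample_rate_hz, n_fft, n_bands, fmin_hz, fmax_hz)
    frames = frame_signal(waveform, sample_rate_hz)
    m = mfcc(frames, filterbank)
    return FeatureMatrix(
        clip_id=clip_id,
        mfcc=m,
        delta=delta(m) if m.shape[0] else np.empty_like(m),
        n_bands=n_bands,
        fmin_hz=fmin_hz,
        fmax_hz=fmax_hz,
    )


def read_wav(path, target_rate_hz: int | None = None) -> tuple[np.ndarray, int]:
    """Read a mono WAV as float in [-1, 1]; resample if a rate is requested."""
    rate, data = wavfile.read(path)
    x = np.asarray(data)
    if x.ndim > 1:
        x = x.mean(axis=1)
    if np.issubdtype(x.dtype, np.integer):
        x = x / float(np.iinfo(data.dtype).max)
    x = x.astype(float)
    if target_rate_hz is not None and target_rate_hz != rate:
        logger.info("resampling %s from %d to %d Hz", path, rate, target_rate_hz)
        from math import gcd

        g = gcd(int(target_rate_hz), int(rate))
        x = resample_poly(x, target_rate_hz // g, rate // g)
        rate = target_rate_hz
    return x, int(rate)


def write_wav(path, waveform: np.ndarray, sample_rate_hz: int) -> None:
    wavfile.write(path, sample_rate_hz, np.asarray(waveform, dtype=np.float32))


def save_features_npz(path, features: dict[str, FeatureMatrix]) -> None:
    """All clips of a run in one NPZ container with provenance fields."""
    arrays: dict[str, np.ndarray] = {"__clip_ids__": np.array(list(features), dtype=object)}
    for cid, fm in features.items():
        arrays[f"mfcc:{cid}"] = fm.mfcc
        arrays[f"delta:{cid}"] = fm.delta
    first = next(iter(features.values()), None)
    if first is not None:
        arrays["__params__"] = np.array(
            [first.frame_ms, first.overlap, first.n_bands, first.fmin_hz, first.fmax_hz]
        )
    np.savez_compressed(path, **arrays, allow_pickle=True)


def load_features_npz(path) -> dict[str, FeatureMatrix]:
    with np.load(path, allow_pickle=True) as z:
        clip_ids = list(z["__clip_ids__"])
        params = z["__params__"] if "__params__" in z else [FRAME_MS, 0.5, N_BANDS, FMIN_HZ, FMAX_HZ]
        return {
            cid: FeatureMatrix(
                clip_id=cid,
                mfcc=z[f"mfcc:{cid}"],
                delta=z[f"delta:{cid}"],
                frame_ms=float(params[0]),
                overlap=float(params[1]),
                n_bands=int(params[2]),
                fmin_hz=float(params[3]),
                fmax_hz=float(params[4]),
            )
            for cid in clip_ids
        }
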