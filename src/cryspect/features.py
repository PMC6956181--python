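"""Short-time intensity metering and spectral features for cry audio.

The measurement core mirrors a clinical cry-recording application that
reports, for every non-overlapping 100 ms frame of a mono recording:

* **VU** (volume unit meter) — the *average* sound intensity of the frame,
* **PPM** (peak program meter) — the *maximum* sound intensity of the frame,
* a magnitude **spectrum** per frame (spectrogram),

all expressed in an arbitrary intensity unit "U" rather than dB.  Here one
U is one count of 16-bit PCM sample magnitude: a sample ``x`` in [-1, 1]
contributes ``|round(x * 32767)|`` U, so a full-scale signal meters at
32767 U.  An autocorrelation fundamental-frequency tracker covers the
neonatal phonation band (roughly 250-450 Hz in healthy newborns).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.signal.windows import hann

FULL_SCALE_U = 32767
#: Default metering frame length (the application reports one value per 100 ms).
DEFAULT_FRAME_MS = 100.0
#: Neonatal F0 search band, Hz; healthy newborns phonate near 250-450 Hz.
DEFAULT_F0_BAND = (150.0, 800.0)


@dataclass
class Waveform:
    """Mono audio: normalized samples in [-1, 1] at a given sample rate."""

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional (mono)")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate


@dataclass
class MeterTrace:
    """Per-frame intensity values in U (either VU or PPM flavor)."""

    kind: Literal["VU", "PPM"]
    values: np.ndarray
    frame_ms: float = DEFAULT_FRAME_MS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.kind not in ("VU", "PPM"):
            raise ValueError(f"unknown meter kind: {self.kind!r}")
        if self.frame_ms <= 0:
            raise ValueError("frame_ms must be positive")

    @property
    def n_frames(self) -> int:
        return self.values.size

    @property
    def frame_s(self) -> float:
        return self.frame_ms / 1000.0


@dataclass
class SpectrumSeries:
    """Frames x frequency-bin magnitude matrix in U."""

    magnitudes: np.ndarray  # shape (n_frames, n_bins)
    bin_width: float
    frame_ms: float = DEFAULT_FRAME_MS

    def __post_init__(self) -> None:
        self.magnitudes = np.atleast_2d(np.asarray(self.magnitudes, dtype=np.float64))

    @property
    def n_frames(self) -> int:
        return self.magnitudes.shape[0]

    @property
    def frequencies(self) -> np.ndarray:
        return np.arange(self.magnitudes.shape[1]) * self.bin_width

    def frame_peaks(self) -> np.ndarray:
        """Per-frame peak magnitude (U) — the spectral intensity of a frame."""
        return self.magnitudes.max(axis=1)


@dataclass
class F0Track:
    """Per-frame fundamental frequency in Hz; NaN marks unvoiced frames."""

    values: np.ndarray
    band: tuple[float, float]
    frame_ms: float = DEFAULT_FRAME_MS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)

    @property
    def voiced(self) -> np.ndarray:
        return self.values[np.isfinite(self.values)]


@dataclass
class TraceSummary:
    mean: float
    min: float
    max: float
    n_frames: int


def to_units(x: np.ndarray) -> np.ndarray:
    """Map normalized samples to 16-bit magnitude units U."""
    return np.abs(np.rint(np.asarray(x, dtype=np.float64) * FULL_SCALE_U))


def frame_signal(w: Waveform, frame_ms: float = DEFAULT_FRAME_MS) -> np.ndarray:
    """Split into non-overlapping frames; a trailing partial frame is dropped.

    Returns an array of shape (n_frames, frame_len).  A signal shorter than
    one frame yields an empty (0, frame_len) array.
    """
    if frame_ms <= 0:
        raise ValueError("frame_ms must be positive")
    frame_len = int(round(frame_ms * w.sample_rate / 1000.0))
    if frame_len <= 0:
        raise ValueError("frame shorter than one sample")
    n = w.samples.size // frame_len
    return w.samples[: n * frame_len].reshape(n, frame_len)


def compute_vu(w: Waveform, frame_ms: float = DEFAULT_FRAME_MS) -> MeterTrace:
    """Average intensity per frame: VU = mean over samples of |round(x*32767)|."""
    frames = frame_signal(w, frame_ms)
    values = to_units(frames).mean(axis=1) if frames.size else np.zeros(frames.shape[0])
    return MeterTrace(kind="VU", values=values, frame_ms=frame_ms)


def compute_ppm(w: Waveform, frame_ms: float = DEFAULT_FRAME_MS) -> MeterTrace:
    """Peak intensity per frame: PPM = max over samples of |round(x*32767)|."""
    frames = frame_signal(w, frame_ms)
    values = to_units(frames).max(axis=1) if frames.size else np.zeros(frames.shape[0])
    return MeterTrace(kind="PPM", values=values, frame_ms=frame_ms)


def compute_spectrum(
    w: Waveform, frame_ms: float = DEFAULT_FRAME_MS, fft_size: int = 4096
) -> SpectrumSeries:
    """Per-frame Hann-windowed magnitude spectrum, scaled to U.

    The scaling is chosen so a full-scale sinusoid peaks near 32767 U
    (amplitude-spectrum normalization by half the window sum).  Bins run
    from 0 to the Nyquist frequency.
    """
    frames = frame_signal(w, frame_ms)
    frame_len = frames.shape[1]
    if fft_size < frame_len:
        raise ValueError("fft_size must be at least the frame length")
    window = hann(frame_len, sym=False)
    spec = np.abs(np.fft.rfft(frames * window, n=fft_size, axis=1))
    scale = 2.0 / window.sum() * FULL_SCALE_U
    return SpectrumSeries(
        magnitudes=spec * scale if frames.shape[0] else np.zeros((0, fft_size // 2 + 1)),
        bin_width=w.sample_rate / fft_size,
        frame_ms=frame_ms,
    )


def default_activity_threshold(vu_values: np.ndarray) -> float:
    """Voice-activity threshold on a VU trace: max(50 U, 5% of trace max).

    The absolute floor keeps low-level recording noise unvoiced; the
    relative part adapts to the overall loudness of the recording.
    """
    if np.size(vu_values) == 0:
        return 50.0
    return max(50.0, 0.05 * float(np.max(vu_values)))


def estimate_f0(
    w: Waveform,
    band: tuple[float, float] = DEFAULT_F0_BAND,
    frame_ms: float = DEFAULT_FRAME_MS,
    activity_threshold: float | None = None,
) -> F0Track:
    """Autocorrelation F0 per frame, restricted to ``band``; unvoiced -> NaN.

    A frame is voiced when its VU value exceeds the activity threshold
    (auto-derived from the trace when not given).  The autocorrelation peak
    lag is refined by parabolic interpolation.
    """
    lo, hi = band
    nyquist = w.sample_rate / 2.0
    if not (0 < lo < hi < nyquist):
        raise ValueError("band must satisfy 0 < low < high < Nyquist")
    frames = frame_signal(w, frame_ms)
    vu = to_units(frames).mean(axis=1) if frames.size else np.zeros(frames.shape[0])
    if activity_threshold is None:
        activity_threshold = default_activity_threshold(vu)

    lag_min = int(np.floor(w.sample_rate / hi))
    lag_max = int(np.ceil(w.sample_rate / lo))
    lag_max = min(lag_max, frames.shape[1] - 1) if frames.shape[0] else lag_max

    values = np.full(frames.shape[0], np.nan)
    for i in range(frames.shape[0]):
        if vu[i] <= activity_threshold:
            continue
        x = frames[i] - frames[i].mean()
        # FFT-based autocorrelation of the frame
        nfft = int(2 ** np.ceil(np.log2(2 * x.size)))
        acf = np.fft.irfft(np.abs(np.fft.rfft(x, nfft)) ** 2)[: x.size]
        if lag_min >= acf.size:
            continue
        seg = acf[lag_min : min(lag_max + 1, acf.size)]
        if seg.size == 0 or seg.max() <= 0:
            continue
        k = lag_min + int(np.argmax(seg))
        # parabolic interpolation around the peak lag
        if 0 < k < acf.size - 1:
            denom = acf[k - 1] - 2 * acf[k] + acf[k + 1]
            if denom != 0:
                k = k + 0.5 * (acf[k - 1] - acf[k + 1]) / denom
        f0 = w.sample_rate / k
        if lo <= f0 <= hi:
            values[i] = f0
    return F0Track(values=values, band=(lo, hi), frame_ms=frame_ms)


def summarize_trace(
    trace: MeterTrace | SpectrumSeries,
    voiced_only: bool = False,
    activity_threshold: float | None = None,
    voiced_mask: Sequence[bool] | None = None,
) -> TraceSummary:
    """Mean/min/max over frames of a meter trace or spectrum series.

    For spectra the per-frame spectral peak magnitude is summarized.  With
    ``voiced_only`` the summary is restricted to cry-active frames —
    either an explicit ``voiced_mask`` (e.g. from segmentation) or frames
    above the activity threshold — mirroring cry-intensity statistics
    whose minima are nonzero rather than recording-silence zeros.
    """
    if isinstance(trace, SpectrumSeries):
        values = trace.frame_peaks()
    else:
        values = trace.values
    if values.size == 0:
        raise ValueError("cannot summarize an empty trace")
    if voiced_only:
        if voiced_mask is not None:
            mask = np.asarray(voiced_mask, dtype=bool)
            if mask.size != values.size:
                raise ValueError("voiced_mask length must match frame count")
        else:
            if activity_threshold is None:
                activity_threshold = default_activity_threshold(values)
            mask = values > activity_threshold
        values = values[mask]
        if values.size == 0:
            raise ValueError("no voiced frames to summarize")
    return TraceSummary(
        mean=float(values.mean()),
        min=float(values.min()),
        max=float(values.max()),
        n_frames=int(values.size),
    )
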