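"""Vascular sound index computation.

A bruit recording is scored in five steps: short-time Fourier transform,
band-pass weighting (50-1500 Hz), low-pass weighting (300 Hz, 4th-order
Butterworth magnitude response), rectified time-averaging of the filtered
spectrum, and logarithmic normalization onto a 0-999 integer scale.

The normalization constants of the commercial monitor are not public, so
scores carry a ``calibration_id`` naming the constants used; only rank
behaviour (higher flow -> higher score) is claimed, not numeric equality
with any device.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "AudioSignal",
    "SpectralPower",
    "HVSIResult",
    "Calibration",
    "DEFAULT_CONFIG",
    "compute_spectrogram",
    "apply_band_filters",
    "band_power",
    "normalize_to_index",
    "compute_hvsi",
]

#: Default analysis configuration.  ``calibration`` is tuned once against the
#: bruit simulator's default scenario so that simulated flows spanning
#: 160-3000 mL/min map onto roughly [40, 999] (see scripts/tune_calibration.py).
DEFAULT_CONFIG: dict = {
    "stft": {"window_s": 0.256, "overlap": 0.5},
    "filter": {"band": [50.0, 1500.0], "lowpass": 300.0, "lowpass_order": 4},
    "calibration": {"p_min": None, "p_max": None, "id": None},  # filled below
    "analysis": {"window_s": 5.0, "onset_trim_s": 0.25, "target_fs": 4000},
}

# Calibration constants (band-power units of the magnitude convention) fixed
# by scripts/tune_calibration.py; regenerating them reproduces these values.
_DEFAULT_P_MIN = 657.0
_DEFAULT_P_MAX = 22800.0
_DEFAULT_CAL_ID = "bruitsim-v1"
DEFAULT_CONFIG["calibration"] = {
    "p_min": _DEFAULT_P_MIN,
    "p_max": _DEFAULT_P_MAX,
    "id": _DEFAULT_CAL_ID,
}


@dataclass(frozen=True)
class Calibration:
    """Normalization constants mapping band power onto the 0-999 scale."""

    p_min: float
    p_max: float
    calibration_id: str = "custom"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.p_min) and np.isfinite(self.p_max)):
            raise ValueError("calibration constants must be finite")
        if self.p_min <= 0 or self.p_max <= 0:
            raise ValueError("calibration constants must be positive")
        if not self.p_min < self.p_max:
            raise ValueError(
                f"invalid calibration: p_min ({self.p_min}) must be < p_max ({self.p_max})"
            )

    @classmethod
    def default(cls) -> "Calibration":
        return cls(_DEFAULT_P_MIN, _DEFAULT_P_MAX, _DEFAULT_CAL_ID)


@dataclass
class AudioSignal:
    """Mono vascular sound waveform.

    Parameters
    ----------
    samples
        Dimensionless amplitudes, nominally in [-1, 1].
    sampling_rate
        Sampling rate in Hz.  Scoring requires >= 3000 Hz so the 1500 Hz
        band edge is resolvable.
    """

    samples: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError(
                f"expected a mono (1-D) signal, got shape {self.samples.shape}; "
                "pre-mix stereo recordings to mono"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("signal contains non-finite samples")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return self.samples.size / self.sampling_rate

    def validate_for_scoring(self) -> None:
        """Enforce the scoring preconditions (rate and minimum duration)."""
        if self.sampling_rate < 3000:
            raise ValueError(
                f"sampling_rate {self.sampling_rate} Hz < 3000 Hz; cannot resolve "
                "the 1500 Hz band edge"
            )
        if self.duration < 3.0:
            raise ValueError(
                f"recording too short ({self.duration:.2f} s); need >= 3 s"
            )


@dataclass
class SpectralPower:
    """Magnitude spectrogram (frequency x time) with band-power access.

    ``magnitude`` holds rectified (absolute-value) STFT coefficients; the
    scalar ``band_power`` is the time-average over frames of the
    frequency-integrated magnitude.
    """

    frame_times: np.ndarray
    frequencies: np.ndarray
    magnitude: np.ndarray

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        if self.magnitude.shape != (self.frequencies.size, self.frame_times.size):
            raise ValueError("magnitude must have shape (n_frequencies, n_frames)")
        if np.any(self.magnitude < 0):
            raise ValueError("magnitude must be nonnegative")

    @property
    def band_power(self) -> float:
        return band_power(self)


@dataclass
class HVSIResult:
    """Per-replicate integer scores and their arithmetic mean."""

    replicate_scores: list[int]
    mean_score: float
    band_power_per_replicate: list[float]
    calibration_id: str = field(default=_DEFAULT_CAL_ID)

    def __post_init__(self) -> None:
        if not 1 <= len(self.replicate_scores) <= 3:
            raise ValueError("1-3 replicates expected (3 is the standard protocol)")
        for s in self.replicate_scores:
            if not 0 <= s <= 999:
                raise ValueError(f"replicate score {s} outside [0, 999]")


def compute_spectrogram(
    signal: AudioSignal,
    window_length: float = 0.256,
    overlap_fraction: float = 0.5,
) -> SpectralPower:
    """Magnitude STFT with a Hann window.

    Frames are fully contained in the signal (no zero padding), so
    spectral energy obeys Parseval's relation against the windowed
    time-domain energy.

    Parameters
    ----------
    window_length
        Window length in seconds.
    overlap_fraction
        Fractional overlap between consecutive windows, in [0, 1).
    """
    if not 0 <= overlap_fraction < 1:
        raise ValueError("overlap_fraction must be in [0, 1)")
    if not np.all(np.isfinite(signal.samples)):
        raise ValueError("signal contains non-finite samples")
    fs = signal.sampling_rate
    nperseg = int(round(window_length * fs))
    if nperseg < 2:
        raise ValueError("window_length too small for the sampling rate")
    x = signal.samples
    if x.size < nperseg:
        raise ValueError(
            f"signal too short ({x.size} samples) for a {nperseg}-sample window"
        )
    hop = max(1, int(round(nperseg * (1 - overlap_fraction))))
    starts = np.arange(0, x.size - nperseg + 1, hop)
    win = sps.get_window("hann", nperseg, fftbins=True)
    frames = (
        np.lib.stride_tricks.sliding_window_view(x, nperseg)[starts] * win
    )
    mag = np.abs(np.fft.rfft(frames, axis=1)).T  # (freq, time)
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / fs)
    times = (starts + nperseg / 2) / fs
    return SpectralPower(frame_times=times, frequencies=freqs, magnitude=mag)


def _lowpass_weight(freqs: np.ndarray, cutoff: float, order: int) -> np.ndarray:
    """Butterworth magnitude response: -3 dB at ``cutoff``."""
    return 1.0 / np.sqrt(1.0 + (freqs / cutoff) ** (2 * order))


def apply_band_filters(
    spec: SpectralPower,
    bandpass_low: float = 50.0,
    bandpass_high: float = 1500.0,
    lowpass_cutoff: float = 300.0,
    lowpass_order: int = 4,
) -> SpectralPower:
    """Frequency-domain filtering of a spectrogram.

    A brick-wall band-pass [bandpass_low, bandpass_high] is applied first,
    then a low-pass weight with the magnitude response of a Butterworth
    filter (-3 dB at ``lowpass_cutoff``).  The spectrogram is weighted
    rather than the waveform filtered, since scoring only needs filtered
    spectral magnitudes.
    """
    if not 0 < bandpass_low < lowpass_cutoff <= bandpass_high:
        raise ValueError(
            "cutoff ordering violated: need 0 < bandpass_low < lowpass_cutoff "
            f"<= bandpass_high, got ({bandpass_low}, {lowpass_cutoff}, {bandpass_high})"
        )
    nyquist = spec.frequencies[-1]
    if bandpass_high > nyquist:
        raise ValueError(
            f"bandpass_high {bandpass_high} Hz exceeds the spectrogram's maximum "
            f"frequency {nyquist} Hz"
        )
    f = spec.frequencies
    weight = ((f >= bandpass_low) & (f <= bandpass_high)).astype(float)
    weight *= _lowpass_weight(f, lowpass_cutoff, lowpass_order)
    return SpectralPower(
        frame_times=spec.frame_times,
        frequencies=spec.frequencies,
        magnitude=spec.magnitude * weight[:, None],
    )


def band_power(spec: SpectralPower) -> float:
    """Time-averaged, frequency-integrated rectified magnitude.

    Linear in signal amplitude (magnitude convention): scaling the input
    waveform by ``c`` scales the returned power by ``c``.
    """
    if spec.frame_times.size == 0:
        raise ValueError("empty spectrogram: no frames")
    if spec.frequencies.size < 2:
        raise ValueError("spectrogram needs >= 2 frequency bins")
    df = float(spec.frequencies[1] - spec.frequencies[0])
    per_frame = spec.magnitude.sum(axis=0) * df
    return float(per_frame.mean())


def normalize_to_index(power: float, calibration: Calibration) -> int:
    """Map a band power onto the 0-999 integer scale.

    The map is affine in log10(power), clipped to [0, 1] and rounded
    half-up.  ``power == 0`` maps to 0 by convention (silence scores 0).
    """
    if power < 0:
        raise ValueError("power must be nonnegative")
    if power == 0:
        return 0
    lo = math.log10(calibration.p_min)
    hi = math.log10(calibration.p_max)
    frac = (math.log10(power) - lo) / (hi - lo)
    frac = min(1.0, max(0.0, frac))
    return int(math.floor(999 * frac + 0.5))


def _merge_config(config: dict | None) -> dict:
    cfg = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}
    if config:
        for section, values in config.items():
            if section not in cfg:
                raise ValueError(f"unknown config section {section!r}")
            cfg[section].update(values)
    return cfg


def _resample(x: np.ndarray, fs: float, target_fs: int) -> tuple[np.ndarray, float]:
    if abs(fs - target_fs) < 1e-9:
        return x, fs
    ratio = Fraction(int(target_fs), int(round(fs))).limit_denominator(10000)
    return sps.resample_poly(x, ratio.numerator, ratio.denominator), float(target_fs)


def _analysis_segment(x: np.ndarray, fs: float, window_s: float, trim_s: float) -> np.ndarray:
    # Long recordings: drop the contact-onset transient, then keep a fixed
    # window so time-averaging is comparable across durations.  Recordings
    # of 3-{trim+window} s are analyzed whole.
    n_trim = int(round(trim_s * fs))
    n_win = int(round(window_s * fs))
    if x.size >= n_trim + int(round(3.0 * fs)):
        x = x[n_trim:]
    return x[:n_win] if x.size > n_win else x


def score_single(signal: AudioSignal, config: dict | None = None) -> tuple[int, float]:
    """Score one recording; returns ``(index, band_power)``."""
    cfg = _merge_config(config)
    signal.validate_for_scoring()
    x, fs = _resample(
        signal.samples, signal.sampling_rate, cfg["analysis"]["target_fs"]
    )
    x = _analysis_segment(
        x, fs, cfg["analysis"]["window_s"], cfg["analysis"]["onset_trim_s"]
    )
    spec = compute_spectrogram(
        AudioSignal(x, fs),
        window_length=cfg["stft"]["window_s"],
        overlap_fraction=cfg["stft"]["overlap"],
    )
    lo, hi = cfg["filter"]["band"]
    filtered = apply_band_filters(
        spec,
        bandpass_low=lo,
        bandpass_high=hi,
        lowpass_cutoff=cfg["filter"]["lowpass"],
        lowpass_order=cfg["filter"]["lowpass_order"],
    )
    power = band_power(filtered)
    cal = Calibration(
        cfg["calibration"]["p_min"],
        cfg["calibration"]["p_max"],
        cfg["calibration"]["id"],
    )
    return normalize_to_index(power, cal), power


def compute_hvsi(
    recordings: Sequence[AudioSignal], config: dict | None = None
) -> HVSIResult:
    """Score 1-3 replicate recordings and average them.

    The standard protocol records the bruit three times and reports the
    arithmetic mean of the three integer replicate scores.
    """
    if not 1 <= len(recordings) <= 3:
        raise ValueError(f"expected 1-3 recordings, got {len(recordings)}")
    cfg = _merge_config(config)
    scores: list[int] = []
    powers: list[float] = []
    for i, rec in enumerate(recordings, start=1):
        try:
            s, p = score_single(rec, config)
        except ValueError as exc:
            raise ValueError(f"replicate {i}: {exc}") from exc
        scores.append(s)
        powers.append(p)
    return HVSIResult(
        replicate_scores=scores,
        mean_score=float(np.mean(scores)),
        band_power_per_replicate=powers,
        calibration_id=cfg["calibration"]["id"],
    )
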