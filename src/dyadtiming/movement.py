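"""Wavelet-based movement classification from force-plate traces.

Each performer stands on a force plate whose four corner weight sensors are
digitized to MIDI control-change values (integers 0-127).  Body sway shows
up as low-frequency periodic power.  Per plate, the sensor with the largest
peak-to-peak amplitude is analyzed with a continuous wavelet transform; only
the movement-relevant 0.25-5 Hz band is considered, and the frequency band
with the highest time-averaged magnitude summarizes the plate.  The couple's
movement magnitude is the mean over the two plates, and a trial counts as
"moving" when that mean is strictly above a threshold of 25.

Absolute CWT magnitudes depend on the wavelet family and normalization, so
magnitudes here are amplitude-calibrated: each scale is divided by the
transform's response to a unit-amplitude sinusoid at that scale's frequency.
A pure sway of MIDI amplitude A therefore yields a band magnitude of about
A, which puts the threshold on the same 0-127 scale as the sensor data; the
threshold stays configurable for recalibration under other settings.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
import pywt
from sklearn.base import BaseEstimator, ClassifierMixin

from .exceptions import InsufficientDataError, InvalidInputError

__all__ = [
    "SensorSeries",
    "MovementSummary",
    "select_max_sensor",
    "band_magnitude",
    "classify_movement",
    "assess_couple",
    "read_sensor_csv",
    "WaveletMovementClassifier",
]

DEFAULT_WAVELET = "cmor1.5-1.0"  # complex Morlet, center frequency 1.0
DEFAULT_THRESHOLD = 25.0
BAND_HZ = (0.25, 5.0)


@dataclass
class SensorSeries:
    """One force plate: 4 sensor channels of MIDI values plus the sample rate."""

    plate_id: str
    channels: np.ndarray  # shape (n_samples, 4)
    sample_rate: float

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 2 or self.channels.shape[1] != 4:
            raise InvalidInputError("channels must have shape (n_samples, 4)")
        if self.channels.shape[0] == 0:
            raise InvalidInputError("channels must be non-empty")
        if self.channels.min() < 0 or self.channels.max() > 127:
            raise InvalidInputError("sensor values must lie in [0, 127]")
        if not self.sample_rate > 2 * BAND_HZ[1]:
            raise InvalidInputError(
                f"sample_rate must exceed {2 * BAND_HZ[1]:g} Hz (Nyquist for the "
                f"{BAND_HZ[1]:g} Hz band edge)"
            )

    @property
    def n_samples(self) -> int:
        return self.channels.shape[0]


@dataclass
class MovementSummary:
    """Couple-level movement magnitude and the moving/still verdict."""

    plate_magnitudes: tuple[float, float]
    couple_magnitude: float
    moving: bool
    threshold: float
    peak_freqs_hz: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        assert np.isclose(self.couple_magnitude, np.mean(self.plate_magnitudes))
        assert self.moving == (self.couple_magnitude > self.threshold)


def select_max_sensor(plate: SensorSeries) -> int:
    """Index of the channel with the largest peak-to-peak amplitude (ties → lowest)."""
    centered = plate.channels - plate.channels.mean(axis=0)
    p2p = centered.max(axis=0) - centered.min(axis=0)
    return int(np.argmax(p2p))


@lru_cache(maxsize=32)
def _scale_gains(
    wavelet: str, fs: float, freqs_key: tuple[float, ...]
) -> np.ndarray:
    """Per-scale |CWT| response to a unit-amplitude sinusoid at each band frequency."""
    freqs = np.array(freqs_key)
    scales = pywt.frequency2scale(wavelet, freqs / fs)
    n = int(round(fs * max(8.0 / freqs.min(), 16.0)))
    t = np.arange(n) / fs
    gains = np.empty(freqs.size)
    for i, (f, s) in enumerate(zip(freqs, scales)):
        ref = np.sin(2 * np.pi * f * t)
        coef, _ = pywt.cwt(ref, [s], wavelet, sampling_period=1.0 / fs)
        core = coef[0, n // 4 : 3 * n // 4]  # trim cone-of-influence edges
        gains[i] = np.abs(core).mean()
    return gains


def band_magnitude(
    signal: np.ndarray,
    fs: float,
    fmin: float = BAND_HZ[0],
    fmax: float = BAND_HZ[1],
    wavelet: str = DEFAULT_WAVELET,
    n_scales: int = 64,
    normalize: bool = True,
) -> tuple[float, float]:
    """Strongest frequency band in [fmin, fmax] and its average CWT magnitude.

    Scales are log-spaced to cover the band; per band the time-averaged
    |coefficient| is computed and the argmax band returned.  With
    ``normalize`` (default) magnitudes are amplitude-calibrated (see module
    docstring).  The signal must span at least two periods of ``fmin``.
    """
    signal = np.asarray(signal, dtype=float).ravel()
    if signal.size < 2 * fs / fmin:
        raise InsufficientDataError(
            f"signal must span at least two periods of {fmin:g} Hz"
        )
    if not (0 < fmin < fmax):
        raise InvalidInputError("need 0 < fmin < fmax")
    freqs = np.logspace(np.log10(fmin), np.log10(fmax), n_scales)
    scales = pywt.frequency2scale(wavelet, freqs / fs)
    coef, _ = pywt.cwt(signal - signal.mean(), scales, wavelet, sampling_period=1.0 / fs)
    band_mag = np.abs(coef).mean(axis=1)
    if normalize:
        band_mag = band_mag / _scale_gains(wavelet, float(fs), tuple(freqs))
    best = int(np.argmax(band_mag))
    return float(freqs[best]), float(band_mag[best])


def classify_movement(
    magnitudes: tuple[float, float],
    threshold: float = DEFAULT_THRESHOLD,
    peak_freqs: tuple[float, float] | None = None,
) -> MovementSummary:
    """Apply the decision rule: moving iff the couple mean is strictly above threshold."""
    couple = float(np.mean(magnitudes))
    return MovementSummary(
        plate_magnitudes=(float(magnitudes[0]), float(magnitudes[1])),
        couple_magnitude=couple,
        moving=couple > threshold,
        threshold=threshold,
        peak_freqs_hz=peak_freqs,
    )


def assess_couple(
    plate_a: SensorSeries,
    plate_b: SensorSeries,
    threshold: float = DEFAULT_THRESHOLD,
    **band_kwargs,
) -> MovementSummary:
    """Full per-trial assessment: best sensor → band magnitude → couple verdict."""
    mags, freqs = [], []
    for plate in (plate_a, plate_b):
        idx = select_max_sensor(plate)
        f, m = band_magnitude(plate.channels[:, idx], plate.sample_rate, **band_kwargs)
        mags.append(m)
        freqs.append(f)
    return classify_movement((mags[0], mags[1]), threshold, (freqs[0], freqs[1]))


def read_sensor_csv(path: str | Path, sample_rate: float, plate_id: str | None = None) -> SensorSeries:
    """Read a force-plate CSV: 4 columns, one row per sample; fs given explicitly."""
    path = Path(path)
    data = pd.read_csv(path, header=None).to_numpy(dtype=float)
    if data.ndim != 2 or data.shape[1] != 4:
        raise InvalidInputError(f"{path}: expected exactly 4 sensor columns")
    return SensorSeries(plate_id or path.stem, data, sample_rate)


class WaveletMovementClassifier(BaseEstimator, ClassifierMixin):
    """Rule-based moving/still classifier over force-plate pairs.

    ``fit`` only freezes the threshold (``threshold_``); ``predict`` maps a
    list of ``(plate_a, plate_b)`` pairs to booleans, and
    ``summarize(pair)`` returns the full :class:`MovementSummary`.
    """

    def __init__(
        self,
        threshold: float = DEFAULT_THRESHOLD,
        fmin: float = BAND_HZ[0],
        fmax: float = BAND_HZ[1],
        wavelet: str = DEFAULT_WAVELET,
        n_scales: int = 64,
    ) -> None:
        self.threshold = threshold
        self.fmin = fmin
        self.fmax = fmax
        self.wavelet = wavelet
        self.n_scales = n_scales

    def fit(self, X=None, y=None) -> "WaveletMovementClassifier":
        self.threshold_ = float(self.threshold)
        return self

    def summarize(self, pair: tuple[SensorSeries, SensorSeries]) -> MovementSummary:
        if not hasattr(self, "threshold_"):
            self.fit()
        return assess_couple(
            pair[0],
            pair[1],
            threshold=self.threshold_,
            fmin=self.fmin,
            fmax=self.fmax,
            wavelet=self.wavelet,
            n_scales=self.n_scales,
        )

    def predict(self, X) -> np.ndarray:
        """X: iterable of (plate_a, plate_b) pairs → boolean moving verdicts."""
        return np.array([self.summarize(pair).moving for pair in X], dtype=bool)
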