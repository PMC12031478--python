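"""Time- and frequency-domain features of a single-trial signal.

Nine features per channel, the standard surface-EMG descriptor set:

time domain
    mean absolute value (MAV), root mean square (RMS), population variance,
    waveform length (sum of absolute first differences) and zero-crossing
    count (strict sign-product rule: a crossing is counted only where
    ``y[i] * y[i+1] < 0``, so exact-zero samples break crossings).

frequency domain (one-sided DFT magnitude/power, no windowing or detrending)
    dominant frequency (argmax of magnitude, ties to the lowest frequency),
    mean frequency (power-weighted mean), median frequency (smallest
    frequency where cumulative power reaches half the total) and frequency
    centroid (magnitude-weighted mean).  The DC bin is included in all
    spectral weights.

Features are computed over the whole trial as one window.  The full
two-channel vector is the EMG block followed by the PZT block (18 values);
see :data:`FEATURE_NAMES`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .dataset import Trial

TIME_FEATURES = ("mav", "rms", "variance", "waveform_length", "zcr")
FREQ_FEATURES = ("dominant_freq", "mean_freq", "median_freq", "freq_centroid")
CHANNEL_FEATURES: tuple[str, ...] = TIME_FEATURES + FREQ_FEATURES
CHANNELS = ("emg", "pzt")

#: Canonical 18-column order for two-channel extraction: EMG block then PZT.
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{ch}_{f}" for ch in CHANNELS for f in CHANNEL_FEATURES)


@dataclass(frozen=True)
class MagnitudeSpectrum:
    """One-sided DFT magnitude and power of a real signal."""
    freqs: np.ndarray       # Hz, strictly increasing, [0, fs/2]
    magnitudes: np.ndarray  # |Y_k| >= 0
    power: np.ndarray       # |Y_k|^2 >= 0

    @property
    def total_power(self) -> float:
        return float(np.sum(self.power))


def time_features(signal: np.ndarray) -> tuple[float, float, float, float, int]:
    """(mav, rms, variance, waveform_length, zcr) of one signal window.

    mav = (1/N) sum |y_i|;  rms = sqrt((1/N) sum y_i^2);
    variance = (1/N) sum (y_i - mean)^2  (population form);
    waveform_length = sum_{i=1}^{N-1} |y_{i+1} - y_i|;
    zcr = #{i : y_i * y_{i+1} < 0}.
    """
    y = np.asarray(signal, dtype=float)
    if y.ndim != 1 or len(y) < 2:
        raise ValueError("signal must be 1-D with at least 2 samples")
    n = len(y)
    mav = float(np.mean(np.abs(y)))
    rms = float(np.sqrt(np.mean(y ** 2)))
    variance = float(np.mean((y - np.mean(y)) ** 2))
    wl = float(np.sum(np.abs(np.diff(y))))
    zcr = int(np.count_nonzero(y[:-1] * y[1:] < 0))
    return mav, rms, variance, wl, zcr


def magnitude_spectrum(signal: np.ndarray, fs: float) -> MagnitudeSpectrum:
    """One-sided DFT magnitude/power over bins 0..floor(N/2), no windowing."""
    y = np.asarray(signal, dtype=float)
    if y.ndim != 1 or len(y) < 2:
        raise ValueError("signal must be 1-D with at least 2 samples")
    if fs <= 0:
        raise ValueError(f"fs must be > 0, got {fs}")
    spec = np.fft.rfft(y)
    freqs = np.fft.rfftfreq(len(y), d=1.0 / fs)
    mag = np.abs(spec)
    return MagnitudeSpectrum(freqs=freqs, magnitudes=mag, power=mag ** 2)


def freq_features(spec: MagnitudeSpectrum
                  ) -> tuple[float, float, float, float]:
    """(dominant, mean, median, centroid) frequency of a spectrum.

    dominant: argmax magnitude, ties broken toward the lowest frequency;
    mean: sum f_k P_k / sum P_k over the power spectrum;
    median: smallest f_m with cumulative power >= half the total;
    centroid: sum f_k |Y_k| / sum |Y_k| over the magnitude spectrum.
    The DC bin participates in every weight.
    """
    total = spec.total_power
    if total <= 0:
        raise ValueError("all-zero spectrum: frequency features undefined")
    dominant = float(spec.freqs[int(np.argmax(spec.magnitudes))])
    mean = float(np.sum(spec.freqs * spec.power) / total)
    cum = np.cumsum(spec.power)
    median = float(spec.freqs[int(np.searchsorted(cum, 0.5 * total))])
    centroid = float(np.sum(spec.freqs * spec.magnitudes)
                     / np.sum(spec.magnitudes))
    return dominant, mean, median, centroid


def channel_features(signal: np.ndarray, fs: float) -> np.ndarray:
    """All nine features of one channel, in :data:`CHANNEL_FEATURES` order."""
    tf = time_features(signal)
    ff = freq_features(magnitude_spectrum(signal, fs))
    return np.array(tf + ff, dtype=float)


def extract_features(trial: Trial,
                     channels: Sequence[str] = CHANNELS) -> np.ndarray:
    """Feature vector of a trial: 9 values per requested channel.

    For both channels the vector is the EMG block followed by the PZT block
    (18 values), matching :data:`FEATURE_NAMES`.
    """
    for ch in channels:
        if ch not in CHANNELS:
            raise ValueError(f"unknown channel {ch!r}; expected subset of {CHANNELS}")
    blocks = [channel_features(trial.channel(ch), trial.fs) for ch in channels]
    return np.concatenate(blocks)


def feature_names(channels: Sequence[str] = CHANNELS) -> list[str]:
    return [f"{ch}_{f}" for ch in channels for f in CHANNEL_FEATURES]


def feature_table(trials: Iterable[Trial],
                  channels: Sequence[str] = CHANNELS) -> pd.DataFrame:
    """DataFrame of features for many trials, indexed by trial id.

    Columns: ``label`` plus the named feature columns.
    """
    rows = []
    ids = []
    labels = []
    for t in trials:
        rows.append(extract_features(t, channels))
        ids.append(t.trial_id)
        labels.append(t.label)
    df = pd.DataFrame(rows, index=pd.Index(ids, name="trial_id"),
                      columns=feature_names(channels))
    df.insert(0, "label", labels)
    return df


class TrialFeaturizer(BaseEstimator, TransformerMixin):
    """Stateless sklearn transformer: list of trials -> feature matrix.

    Parameters
    ----------
    channels : sequence of {"emg", "pzt"}
        Channels to extract, in output-block order.
    """

    def __init__(self, channels: Sequence[str] = CHANNELS):
        self.channels = channels

    def fit(self, X: Sequence[Trial], y=None) -> "TrialFeaturizer":
        self.feature_names_out_ = feature_names(self.channels)
        return self

    def transform(self, X: Sequence[Trial]) -> np.ndarray:
        return np.vstack([extract_features(t, self.channels) for t in X])

    def get_feature_names_out(self, input_features=None):
        return np.asarray(feature_names(self.channels), dtype=object)
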