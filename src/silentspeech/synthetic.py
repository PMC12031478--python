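"""Synthetic two-channel (EMG + PZT) trial generator.

The generator emulates the qualitative structure of chin-sensor recordings
during silent articulation: the EMG channel is built from enveloped
band-limited Gaussian-noise bursts (muscle activity lives in the tens to
hundreds of Hz), the PZT channel from exponentially decaying low-frequency
sinusoids (skin vibration below ~100 Hz).  Each of the eight letter classes
gets its own template — burst timings, frequency bands, tone frequencies and
decay rates — and trials are noisy, jittered realisations of that template.

Two knobs matter for benchmarking:

``separability``
    Linearly interpolates every class template between a shared *base*
    template (separability 0: all classes alike) and a class-specific one
    (separability 1: maximally distinct).

``channel_coupling_mode``
    ``"independent"``: each class has a distinct motif in *each* channel.
    ``"cross_channel_only"``: the 8 classes are built from 4 EMG motifs x 4
    PZT motifs with every motif reused by exactly two classes, so no single
    channel identifies the class — only the *pair* of motifs does.  This is
    the constructed benchmark for sensor fusion.

All randomness flows from one integer seed; per-trial sample noise comes
from a substream keyed by (class index, trial index), so the dataset is
byte-reproducible and individual trials are reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import signal as sps

from .dataset import LETTERS, Trial

NYQUIST_FRACTION = 0.5


@dataclass(frozen=True)
class EmgBurst:
    """One enveloped band-limited noise burst on the EMG channel."""
    onset: float        # s
    duration: float     # s
    band_low: float     # Hz
    band_high: float    # Hz
    amplitude: float    # mV


@dataclass(frozen=True)
class PztTone:
    """One decaying sinusoid on the PZT channel."""
    onset: float        # s
    frequency: float    # Hz, < 100 (low-frequency skin vibration)
    decay: float        # 1/s
    amplitude: float    # mV


@dataclass(frozen=True)
class ClassTemplate:
    """Deterministic per-class signal recipe for both channels."""
    label: str
    emg_bursts: tuple[EmgBurst, ...]
    pzt_tones: tuple[PztTone, ...]

    def validate(self, fs: float, duration: float) -> None:
        nyq = fs * NYQUIST_FRACTION
        for b in self.emg_bursts:
            if not (0 <= b.onset and b.onset + b.duration <= duration):
                raise ValueError(f"{self.label}: burst outside trial window: {b}")
            if not (0 < b.band_low < b.band_high < nyq):
                raise ValueError(f"{self.label}: bad band [{b.band_low},{b.band_high}]")
        for t in self.pzt_tones:
            if not (0 <= t.onset < duration):
                raise ValueError(f"{self.label}: tone onset outside trial: {t}")
            if not (0 < t.frequency < 100):
                raise ValueError(f"{self.label}: PZT tone must be < 100 Hz: {t}")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the synthetic protocol.

    Defaults mirror the recording protocol: 4096 Hz per channel, 100 trials
    per letter, 8 letters.  Trial duration, jitter and SNR are generator
    choices (the protocol does not pin them); see the methods note.
    """
    fs: float = 4096.0
    duration: float = 1.0
    n_per_class: int = 100
    separability: float = 1.0
    jitter: float = 0.1
    snr_db: float = 20.0
    channel_coupling_mode: Literal["independent", "cross_channel_only"] = "independent"
    seed: int = 0
    labels: tuple[str, ...] = LETTERS

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if self.n_per_class < 1:
            raise ValueError(f"n_per_class must be >= 1, got {self.n_per_class}")
        if not 0.0 <= self.separability <= 1.0:
            raise ValueError("separability must lie in [0, 1]")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")
        if self.channel_coupling_mode not in ("independent", "cross_channel_only"):
            raise ValueError(
                f"unknown channel_coupling_mode {self.channel_coupling_mode!r}")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))


# ---------------------------------------------------------------------------
# template construction
# ---------------------------------------------------------------------------

# Cross-channel pairing: 4 EMG motifs x 4 PZT motifs, every motif in exactly
# two classes, all 8 pairs distinct.  Knowing one channel's motif narrows the
# class to 2 candidates at best (50% ceiling); the pair determines it.
_CROSS_PAIRS: tuple[tuple[int, int], ...] = (
    (0, 0), (0, 1), (1, 1), (1, 2), (2, 2), (2, 3), (3, 3), (3, 0))


def _motif_params(rng: np.random.Generator, duration: float, n_motifs: int,
                  ) -> tuple[list[list[EmgBurst]], list[list[PztTone]]]:
    """Draw n_motifs distinct EMG burst sets and PZT tone sets.

    Motifs are spread deterministically across the parameter ranges so they
    are pairwise distinct by construction; the rng only perturbs within each
    motif's own niche.
    """
    emg_motifs: list[list[EmgBurst]] = []
    pzt_motifs: list[list[PztTone]] = []
    for m in range(n_motifs):
        frac = m / n_motifs
        # two bursts per motif; bands tile 60-460 Hz, onsets tile the trial
        lo = 60.0 + 400.0 * frac
        bursts = [
            EmgBurst(onset=(0.05 + 0.5 * frac) * duration,
                     duration=0.25 * duration,
                     band_low=lo, band_high=lo + 60.0 + 20.0 * rng.uniform(),
                     amplitude=0.8 + 0.4 * rng.uniform()),
            EmgBurst(onset=(0.45 - 0.3 * frac) * duration * 0.5 + 0.3 * duration,
                     duration=0.18 * duration,
                     band_low=40.0 + 150.0 * frac,
                     band_high=40.0 + 150.0 * frac + 45.0,
                     amplitude=0.5 + 0.3 * rng.uniform()),
        ]
        tones = [
            PztTone(onset=(0.05 + 0.6 * frac) * duration * 0.5,
                    frequency=4.0 + 80.0 * frac,
                    decay=3.0 + 4.0 * rng.uniform(),
                    amplitude=1.0 + 0.5 * rng.uniform()),
            PztTone(onset=0.4 * duration + 0.2 * duration * frac,
                    frequency=10.0 + 60.0 * ((frac + 0.37) % 1.0),
                    decay=2.0 + 3.0 * rng.uniform(),
                    amplitude=0.6 + 0.4 * rng.uniform()),
        ]
        emg_motifs.append(bursts)
        pzt_motifs.append(tones)
    return emg_motifs, pzt_motifs


def _blend_burst(base: EmgBurst, target: EmgBurst, s: float) -> EmgBurst:
    lerp = lambda a, b: (1.0 - s) * a + s * b
    return EmgBurst(onset=lerp(base.onset, target.onset),
                    duration=lerp(base.duration, target.duration),
                    band_low=lerp(base.band_low, target.band_low),
                    band_high=lerp(base.band_high, target.band_high),
                    amplitude=lerp(base.amplitude, target.amplitude))


def _blend_tone(base: PztTone, target: PztTone, s: float) -> PztTone:
    lerp = lambda a, b: (1.0 - s) * a + s * b
    return PztTone(onset=lerp(base.onset, target.onset),
                   frequency=lerp(base.frequency, target.frequency),
                   decay=lerp(base.decay, target.decay),
                   amplitude=lerp(base.amplitude, target.amplitude))


def make_templates(config: GeneratorConfig) -> list[ClassTemplate]:
    """Build one :class:`ClassTemplate` per label, deterministic in the seed."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC1A55]))
    n_classes = len(config.labels)
    s = config.separability

    if config.channel_coupling_mode == "independent":
        emg_motifs, pzt_motifs = _motif_params(rng, config.duration, n_classes)
        pairs = [(i, i) for i in range(n_classes)]
    else:
        if n_classes != 8:
            raise ValueError("cross_channel_only mode requires the 8-class protocol")
        emg_motifs, pzt_motifs = _motif_params(rng, config.duration, 4)
        pairs = list(_CROSS_PAIRS)

    # base template = motif 0 of each channel; separability blends toward
    # the class's own motif pair
    base_bursts = emg_motifs[0]
    base_tones = pzt_motifs[0]
    templates = []
    for label, (ei, pi) in zip(config.labels, pairs):
        bursts = tuple(_blend_burst(b0, bt, s)
                       for b0, bt in zip(base_bursts, emg_motifs[ei]))
        tones = tuple(_blend_tone(t0, tt, s)
                      for t0, tt in zip(base_tones, pzt_motifs[pi]))
        tpl = ClassTemplate(label=label, emg_bursts=bursts, pzt_tones=tones)
        tpl.validate(config.fs, config.duration)
        templates.append(tpl)
    return templates


# ---------------------------------------------------------------------------
# trial synthesis
# ---------------------------------------------------------------------------

def _bandpass(x: np.ndarray, lo: float, hi: float, fs: float) -> np.ndarray:
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def _render_clean(template: ClassTemplate, config: GeneratorConfig,
                  rng: np.random.Generator, jitter: float
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Noise-floor-free channel pair for one trial realisation."""
    n = config.n_samples
    t = np.arange(n) / config.fs
    emg = np.zeros(n)
    pzt = np.zeros(n)
    for b in template.emg_bursts:
        amp = b.amplitude * (1.0 + jitter * rng.standard_normal())
        onset = b.onset + jitter * 0.05 * config.duration * rng.standard_normal()
        onset = float(np.clip(onset, 0.0, config.duration - b.duration))
        carrier = _bandpass(rng.standard_normal(n), b.band_low, b.band_high,
                            config.fs)
        carrier /= max(np.std(carrier), 1e-12)
        env = np.zeros(n)
        i0 = int(round(onset * config.fs))
        i1 = min(n, i0 + max(int(round(b.duration * config.fs)), 2))
        env[i0:i1] = np.hanning(i1 - i0)
        emg += amp * env * carrier
    for tone in template.pzt_tones:
        amp = tone.amplitude * (1.0 + jitter * rng.standard_normal())
        onset = tone.onset + jitter * 0.05 * config.duration * rng.standard_normal()
        onset = float(np.clip(onset, 0.0, 0.95 * config.duration))
        tau = t - onset
        active = tau >= 0
        wave = np.zeros(n)
        wave[active] = np.sin(2 * np.pi * tone.frequency * tau[active]) * \
            np.exp(-tone.decay * tau[active])
        pzt += amp * wave
    return emg, pzt


def _trial_rng(config: GeneratorConfig, label: str, trial_index: int
               ) -> np.random.Generator:
    ci = config.labels.index(label)
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, 0x7B1A1, ci, trial_index]))


def render_clean(template: ClassTemplate, config: GeneratorConfig,
                 trial_index: int) -> tuple[np.ndarray, np.ndarray]:
    """The trial's noiseless (pre-noise-floor) channel pair.

    Uses the same per-trial substream as :func:`generate_trial`, so the clean
    component is exactly what the noisy trial is built on.  Useful for
    linearity and SNR audits.
    """
    rng = _trial_rng(config, template.label, trial_index)
    return _render_clean(template, config, rng, config.jitter)


def generate_trial(template: ClassTemplate, config: GeneratorConfig,
                   trial_index: int) -> Trial:
    """Render one noisy trial; deterministic given (seed, label, trial_index)."""
    rng = _trial_rng(config, template.label, trial_index)
    emg, pzt = _render_clean(template, config, rng, config.jitter)
    # additive white noise floor at the configured SNR relative to each
    # channel's clean RMS (falls back to a tiny absolute floor if silent)
    for name, chan in (("emg", emg), ("pzt", pzt)):
        rms = np.sqrt(np.mean(chan ** 2))
        scale = (rms if rms > 0 else 1e-3) * 10 ** (-config.snr_db / 20.0)
        chan += scale * rng.standard_normal(len(chan))
    return Trial(emg=emg, pzt=pzt, fs=config.fs, label=template.label,
                 trial_id=f"{template.label}{trial_index:04d}")


def make_feature_benchmark(n_per_class: int = 100, n_informative: int = 4,
                           n_noise: int = 14, amplitude: float = 6.0,
                           seed: int = 0):
    """Feature-space benchmark with known ground truth for selection tests.

    Eight classes whose centroids are binary codewords over the
    ``n_informative`` leading dimensions, scaled by ``amplitude`` (in noise
    standard deviations); the remaining ``n_noise`` columns are pure noise.
    The codewords are chosen so that *every* informative dimension is
    needed: dropping any one of them makes two classes coincide.  At the
    default 6-sigma separation the informative set is therefore the unique
    optimal subset.

    Returns ``(features_df, labels)`` with columns ``info*`` then ``noise*``.
    """
    import pandas as pd

    codes = np.array([[0, 0, 0, 0], [1, 0, 0, 0], [0, 1, 1, 0], [0, 0, 1, 0],
                      [0, 1, 0, 1], [0, 1, 0, 0], [1, 0, 1, 1], [1, 0, 0, 1]],
                     dtype=float)
    if n_informative != 4:
        raise ValueError("the codeword construction is fixed at 4 informative "
                         "dimensions")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xFEA7]))
    y = np.repeat(np.arange(len(codes)), n_per_class)
    X = np.hstack([
        amplitude * codes[y] + rng.standard_normal((len(y), n_informative)),
        rng.standard_normal((len(y), n_noise)),
    ])
    names = [f"info{i}" for i in range(n_informative)] + \
        [f"noise{i}" for i in range(n_noise)]
    order = rng.permutation(len(y))
    return pd.DataFrame(X[order], columns=names), y[order]


def generate_dataset(config: GeneratorConfig) -> list[Trial]:
    """All trials of the protocol: ``n_per_class`` per label, seed-shuffled."""
    templates = make_templates(config)
    trials = [generate_trial(tpl, config, k)
              for tpl in templates for k in range(config.n_per_class)]
    order = np.random.default_rng(
        np.random.SeedSequence([config.seed, 0x5F0F])).permutation(len(trials))
    return [trials[i] for i in order]
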