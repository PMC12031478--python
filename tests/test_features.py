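"""Feature definitions against hand arithmetic and naive-loop oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from silentspeech.features import (CHANNEL_FEATURES, FEATURE_NAMES,
                                   TrialFeaturizer, channel_features,
                                   extract_features, freq_features,
                                   magnitude_spectrum, time_features)


# ---------------------------------------------------------------------------
# independent oracles: naive loops and a naive DFT, no numpy vectorisation
# ---------------------------------------------------------------------------

def naive_time_features(y):
    n = len(y)
    mav = sum(abs(v) for v in y) / n
    rms = math.sqrt(sum(v * v for v in y) / n)
    mu = sum(y) / n
    var = sum((v - mu) ** 2 for v in y) / n
    wl = sum(abs(y[i + 1] - y[i]) for i in range(n - 1))
    zcr = sum(1 for i in range(n - 1) if y[i] * y[i + 1] < 0)
    return mav, rms, var, wl, zcr


def naive_spectrum(y, fs):
    n = len(y)
    freqs, mags = [], []
    for k in range(n // 2 + 1):
        re = sum(y[i] * math.cos(2 * math.pi * k * i / n) for i in range(n))
        im = -sum(y[i] * math.sin(2 * math.pi * k * i / n) for i in range(n))
        freqs.append(k * fs / n)
        mags.append(math.hypot(re, im))
    return freqs, mags


def naive_freq_features(freqs, mags):
    power = [m * m for m in mags]
    total = sum(power)
    dominant = freqs[max(range(len(mags)), key=lambda k: (mags[k], -k))]
    mean = sum(f * p for f, p in zip(freqs, power)) / total
    acc = 0.0
    median = freqs[-1]
    for f, p in zip(freqs, power):
        acc += p
        if acc >= total / 2:
            median = f
            break
    centroid = sum(f * m for f, m in zip(freqs, mags)) / sum(mags)
    return dominant, mean, median, centroid


# ---------------------------------------------------------------------------
# hand-computed examples
# ---------------------------------------------------------------------------

def test_time_features_hand_example():
    mav, rms, var, wl, zcr = time_features([1, -1, 2, -2])
    assert mav == 1.5
    assert rms == pytest.approx(math.sqrt(2.5))
    assert var == 2.5
    assert wl == 9
    assert zcr == 3


def test_time_features_constant_signal():
    mav, rms, var, wl, zcr = time_features([5.0] * 8)
    assert (mav, rms, var, wl, zcr) == (5.0, 5.0, 0.0, 0.0, 0)


def test_zero_sample_breaks_crossing():
    # products with a zero sample are 0, not < 0: no crossing counted
    assert time_features([1.0, 0.0, -1.0])[4] == 0
    assert time_features([1.0, -1.0])[4] == 1


def test_pure_tone_closed_forms():
    fs, n, f0, amp = 4096.0, 4096, 128.0, 2.0
    t = np.arange(n) / fs
    y = amp * np.sin(2 * np.pi * f0 * t)
    _, rms, *_ = time_features(y)
    assert rms == pytest.approx(amp / math.sqrt(2), rel=1e-9)
    dom, mean, med, cen = freq_features(magnitude_spectrum(y, fs))
    assert dom == pytest.approx(f0)
    assert mean == pytest.approx(f0, rel=1e-6)
    assert med == pytest.approx(f0)
    assert cen == pytest.approx(f0, rel=1e-6)


def test_two_tone_symmetry_and_ties():
    fs, n = 4096.0, 4096
    t = np.arange(n) / fs
    y = np.sin(2 * np.pi * 100 * t) + np.sin(2 * np.pi * 300 * t)
    dom, mean, med, cen = freq_features(magnitude_spectrum(y, fs))
    assert dom == pytest.approx(100.0)     # tie -> lowest frequency
    assert med == pytest.approx(100.0)     # cumulative reaches half there
    assert mean == pytest.approx(200.0, rel=1e-6)
    assert cen == pytest.approx(200.0, rel=1e-6)


def test_constant_signal_energy_at_dc():
    spec = magnitude_spectrum(np.full(64, 3.0), fs=64.0)
    assert spec.magnitudes[0] == pytest.approx(192.0)
    assert np.allclose(spec.magnitudes[1:], 0.0, atol=1e-9)


def test_parseval_identity(rng):
    y = rng.standard_normal(257)  # odd length exercises the bin bookkeeping
    spec = magnitude_spectrum(y, fs=1000.0)
    n = len(y)
    onesided = spec.power[0] + 2 * np.sum(spec.power[1:])
    if n % 2 == 0:
        onesided -= spec.power[-1]  # Nyquist bin is not doubled
    assert np.sum(y ** 2) * n == pytest.approx(onesided, rel=1e-9)


# ---------------------------------------------------------------------------
# oracle sweep
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n", [16, 33, 128])
def test_all_features_match_naive_oracles(rng, n):
    for _ in range(5):
        y = rng.standard_normal(n)
        fs = float(rng.integers(100, 5000))
        got_t = time_features(y)
        want_t = naive_time_features(list(y))
        assert got_t == pytest.approx(want_t, rel=1e-9)
        spec = magnitude_spectrum(y, fs)
        freqs, mags = naive_spectrum(list(y), fs)
        assert spec.freqs == pytest.approx(freqs, rel=1e-9)
        assert list(spec.magnitudes) == pytest.approx(mags, rel=1e-6, abs=1e-8)
        got_f = freq_features(spec)
        want_f = naive_freq_features(freqs, mags)
        assert got_f == pytest.approx(want_f, rel=1e-7)


# ---------------------------------------------------------------------------
# invariants
# ---------------------------------------------------------------------------

@settings(max_examples=50, deadline=None, derandomize=True)
@given(arrays(float, st.integers(2, 200),
              elements=st.floats(-1e6, 1e6, allow_nan=False)))
def test_mav_below_rms_and_variance_identity(y):
    mav, rms, var, _, zcr = time_features(y)
    assert mav <= rms + 1e-9 * max(rms, 1)
    mean = float(np.mean(y))
    # identity up to cancellation error, which scales with rms^2
    assert var == pytest.approx(rms ** 2 - mean ** 2,
                                abs=1e-9 * max(rms ** 2, 1.0))
    assert 0 <= zcr <= len(y) - 1


def test_self_concatenation_behaviour(rng):
    y = rng.standard_normal(256)
    yy = np.concatenate([y, y])
    m1, r1, v1, w1, z1 = time_features(y)
    m2, r2, v2, w2, z2 = time_features(yy)
    assert (m2, r2, v2) == pytest.approx((m1, r1, v1), rel=1e-12)
    # wl and zcr approximately double (one extra seam term/crossing at most)
    assert w1 <= w2 <= 2 * w1 + abs(y[0] - y[-1]) + 1e-9
    assert 2 * z1 <= z2 <= 2 * z1 + 1


# ---------------------------------------------------------------------------
# vector assembly
# ---------------------------------------------------------------------------

def test_extract_feature_vector_layout(small_trials):
    t = small_trials[0]
    both = extract_features(t)
    assert both.shape == (18,)
    emg_only = extract_features(t, ("emg",))
    pzt_only = extract_features(t, ("pzt",))
    assert emg_only.shape == (9,)
    assert np.array_equal(both, np.concatenate([emg_only, pzt_only]))
    assert np.array_equal(emg_only, channel_features(t.emg, t.fs))
    assert len(FEATURE_NAMES) == 18
    assert FEATURE_NAMES[0] == "emg_mav" and FEATURE_NAMES[9] == "pzt_mav"
    with pytest.raises(ValueError, match="unknown channel"):
        extract_features(t, ("emg", "bogus"))


def test_featurizer_transformer(small_trials):
    tf = TrialFeaturizer().fit(small_trials)
    X = tf.transform(small_trials[:5])
    assert X.shape == (5, 18)
    assert list(tf.get_feature_names_out()) == list(FEATURE_NAMES)
    # no randomness: repeated extraction is identical
    assert np.array_equal(X, tf.transform(small_trials[:5]))


def test_degenerate_inputs_rejected():
    with pytest.raises(ValueError):
        time_features([1.0])
    with pytest.raises(ValueError):
        magnitude_spectrum(np.ones(4), fs=0)
    spec = magnitude_spectrum(np.zeros(16), fs=16.0)
    with pytest.raises(ValueError, match="all-zero"):
        freq_features(spec)
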