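"""SMOTE properties and the eight signal operators' contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from silentspeech.augmentation import (GLOBAL_OPERATORS, LOCAL_OPERATORS,
                                       SIGNAL_OPERATORS, AugmentationPlan,
                                       apply_operator, augment_global,
                                       augment_local, augment_signal,
                                       compose, draw_params, make_plan,
                                       smote_oversample)


# ---------------------------------------------------------------------------
# SMOTE
# ---------------------------------------------------------------------------

def test_smote_synthetics_are_convex_combinations(rng):
    X = rng.standard_normal((12, 5))
    y = np.array(["a"] * 6 + ["b"] * 6)
    Xo, yo = smote_oversample(X, y, target_per_class=20, k_neighbors=3, seed=1)
    assert Xo.shape == (40, 5)
    assert np.array_equal(Xo[:12], X)  # originals retained, first
    for xi, yi in zip(Xo[12:], yo[12:]):
        Xc = X[y == yi]
        lo, hi = Xc.min(axis=0), Xc.max(axis=0)
        assert np.all(xi >= lo - 1e-12) and np.all(xi <= hi + 1e-12)


def test_smote_two_point_class_on_segment():
    p, q = np.array([0.0, 0.0]), np.array([2.0, 4.0])
    X = np.vstack([p, q])
    y = np.array(["a", "a"])
    Xo, _ = smote_oversample(X, y, target_per_class=5, k_neighbors=1, seed=3)
    for xi in Xo[2:]:
        lam = xi[0] / 2.0
        assert 0 <= lam <= 1
        assert xi[1] == pytest.approx(4 * lam)


def test_smote_identical_points_reproduce_themselves():
    X = np.tile([1.5, -2.0, 3.0], (6, 1))
    y = np.array(["a"] * 6)
    Xo, _ = smote_oversample(X, y, target_per_class=10, seed=0)
    assert np.allclose(Xo, X[0])


def test_smote_balanced_output_counts(rng):
    X = rng.standard_normal((800, 4))
    y = np.repeat([f"c{i}" for i in range(8)], 100)
    Xo, yo = smote_oversample(X, y, target_per_class=200, seed=2)
    assert len(Xo) == 1600
    vals, counts = np.unique(yo, return_counts=True)
    assert set(counts) == {200}


def test_smote_rejects_tiny_class():
    X = np.zeros((7, 2))
    y = np.array(["a"] * 4 + ["b"] * 3)
    with pytest.raises(ValueError, match="b"):
        smote_oversample(X, y, target_per_class=8, k_neighbors=3)


def test_smote_mean_preserved(rng):
    """Class-conditional mean of synthetic points stays near the original
    class mean (interpolation cannot move mass outside the cloud)."""
    X = rng.standard_normal((50, 3)) + np.array([5.0, -2.0, 0.0])
    y = np.array(["a"] * 50)
    Xo, _ = smote_oversample(X, y, target_per_class=1050, seed=4)
    synth = Xo[50:]
    se = X.std(axis=0) / np.sqrt(len(synth))
    # interpolation shrinks toward the centre; allow a small systematic term
    assert np.all(np.abs(synth.mean(axis=0) - X.mean(axis=0))
                  < 2 * X.std(axis=0) / np.sqrt(50) + 2 * se)


def test_smote_deterministic(rng):
    X = rng.standard_normal((30, 4))
    y = np.repeat(["a", "b", "c"], 10)
    a = smote_oversample(X, y, seed=7)
    b = smote_oversample(X, y, seed=7)
    assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


# ---------------------------------------------------------------------------
# signal operators: explicit examples
# ---------------------------------------------------------------------------

def test_hang_overwrites_run():
    x = np.array([0.0, 1, 2, 3, 4, 5, 6])
    out = apply_operator(x, "hang", {"start": 2, "end": 5})
    assert np.array_equal(out, [0, 1, 2, 2, 2, 5, 6])


def test_gauss_constant_signal_unchanged():
    x = np.full(32, 7.0)
    out = apply_operator(x, "gauss", {"start": 4, "end": 28,
                                      "kernel_width": 9})
    assert np.allclose(out, x)


def test_noise_zero_std_unchanged():
    x = np.full(32, 2.0)
    out = apply_operator(x, "noise",
                         {"start": 3, "end": 20, "draws": np.ones(17)})
    assert np.array_equal(out, x)


def test_downsample_exact_on_linear_ramp():
    x = np.linspace(0.0, 10.0, 64)
    out = apply_operator(x, "downsample",
                         {"start": 8, "end": 56, "fraction": 0.25})
    assert np.allclose(out, x, atol=1e-9)


def test_scale_is_uniform_ratio(rng):
    x = rng.standard_normal(64) + 3.0
    out = augment_global(x, "scale", np.random.default_rng(5))
    ratio = out / x
    assert np.allclose(ratio, ratio[0])
    assert 0.95 <= ratio[0] <= 1.05


def test_shift_x_is_circular():
    x = np.array([0.0, 1, 2, 3, 4, 5])
    out = apply_operator(x, "shift_x", {"shift": 3})
    assert np.array_equal(out, [3, 4, 5, 0, 1, 2])


def test_slope_zero_signal_unchanged():
    x = np.zeros(32)
    out = augment_global(x, "slope", np.random.default_rng(0))
    assert np.array_equal(out, x)


def test_local_global_kind_checks(rng):
    with pytest.raises(ValueError):
        augment_local(np.zeros(32), "scale", rng)
    with pytest.raises(ValueError):
        augment_global(np.zeros(32), "hang", rng)
    with pytest.raises(ValueError, match="too short"):
        augment_local(np.zeros(4), "hang", rng)


# ---------------------------------------------------------------------------
# parameter bounds
# ---------------------------------------------------------------------------

def test_drawn_parameters_respect_bounds(rng):
    """Seeded draw audit at desk scale (the full audit runs in acceptance)."""
    x = rng.standard_normal(200) * 2.0
    n, sd = len(x), np.std(x)
    for _ in range(200):
        for kind in SIGNAL_OPERATORS:
            p = draw_params(kind, rng, x)
            if kind in LOCAL_OPERATORS:
                assert 0 <= p["start"] < p["end"] <= n
                assert p["end"] - p["start"] >= 2
            if kind == "gauss":
                assert 3 <= p["kernel_width"] <= 31 and p["kernel_width"] % 2
            if kind == "noise":
                assert np.all((p["draws"] >= 0) & (p["draws"] < 1))
            if kind == "downsample":
                assert 0.01 <= p["fraction"] <= 0.25
            if kind == "slope":
                assert 0 <= p["rise"] < 10 * sd
            if kind == "shift_x":
                assert abs(p["shift"]) <= 0.05 * n
            if kind == "shift_y":
                assert abs(p["offset"]) <= 0.05 * (x.max() - x.min())
            if kind == "scale":
                assert 0.95 <= p["factor"] <= 1.05


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 10_000), st.sampled_from(SIGNAL_OPERATORS))
def test_every_operator_preserves_length(seed, kind):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(int(rng.integers(8, 300)))
    out = apply_operator(x, kind, draw_params(kind, rng, x))
    assert out.shape == x.shape
    assert np.all(np.isfinite(out))


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def test_empty_plan_is_identity(rng):
    x = rng.standard_normal(64)
    out = compose(x, AugmentationPlan(steps=[], seed=0))
    assert np.array_equal(out, x)


def test_compose_deterministic_and_length_preserving(rng):
    x = rng.standard_normal(128)
    a = augment_signal(x, seed=42)
    b = augment_signal(x, seed=42)
    assert np.array_equal(a, b)
    assert a.shape == x.shape


def test_plan_order_is_seed_shuffled():
    orders = {tuple(make_plan(seed, include_prob=1.0).steps)
              for seed in range(30)}
    assert len(orders) > 1  # order varies with the seed
    assert all(sorted(o) == sorted(SIGNAL_OPERATORS) for o in orders)


def test_composition_varies_across_seeds(rng):
    x = rng.standard_normal(128)
    outs = {augment_signal(x, seed=s).tobytes() for s in range(50)}
    assert len(outs) > 1


def test_plan_rejects_unknown_operator():
    with pytest.raises(ValueError):
        AugmentationPlan(steps=["fliparoo"], seed=0)
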