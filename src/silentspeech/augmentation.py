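"""Training-set augmentation: feature-space SMOTE and raw-signal operators.

Feature-based models are augmented in feature space with SMOTE
(interpolation between a sample and one of its k nearest same-class
neighbours).  Networks trained on raw signals are augmented with eight
signal operators emulating acquisition artefacts — four *local* operators
acting on a random contiguous window (hang, gauss, noise, downsample) and
four *global* ones acting on the whole trace (slope, shift_x, shift_y,
scale).  Operators are composed in a seeded random order, each included
independently with a configurable probability.  Every operator preserves
signal length, and every drawn parameter respects its documented bound:

====== ==============================================================
hang   a random sample value overwrites the following random run
gauss  normalised Gaussian smoothing (odd kernel width in [3, 31]) of
       a random window
noise  additive noise scaled by the signal's standard deviation inside
       a random window (per-sample draws in U(0,1); a zero-centred
       U(-1,1) variant is available)
down   a random window linearly resampled down to 1-25% of its length
       and back up
slope  additive linear ramp, total rise in [0, 10*std)
shift_x circular shift by at most 5% of the length (either direction)
shift_y additive offset, |offset| <= 5% of the signal's range
scale  multiplicative factor in [0.95, 1.05]
====== ==============================================================

Augmentation is applied to the *training* partition only; the experiment
driver audits that validation/test trials are untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

LOCAL_OPERATORS = ("hang", "gauss", "noise", "downsample")
GLOBAL_OPERATORS = ("slope", "shift_x", "shift_y", "scale")
SIGNAL_OPERATORS: tuple[str, ...] = LOCAL_OPERATORS + GLOBAL_OPERATORS

_MIN_LEN = 8


# ---------------------------------------------------------------------------
# feature-space SMOTE
# ---------------------------------------------------------------------------

def smote_oversample(features: np.ndarray | pd.DataFrame,
                     labels: Sequence,
                     target_per_class: int | Mapping | None = None,
                     k_neighbors: int = 5,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Oversample every class to ``target_per_class`` by SMOTE interpolation.

    New points are ``x_i + lam * (x_nn - x_i)`` with ``lam ~ U(0,1)`` and
    ``x_nn`` one of the ``k_neighbors`` nearest same-class neighbours of
    ``x_i``.  Originals are retained and come first in the output.

    Parameters
    ----------
    target_per_class : int, mapping label->count, or None
        None defaults to twice each class's current count.

    Returns
    -------
    (X_out, y_out) with originals followed by synthetic rows.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if len(X) != len(y):
        raise ValueError("features and labels length mismatch")
    rng = np.random.default_rng(seed)
    classes = np.unique(y)
    counts = {c: int(np.sum(y == c)) for c in classes}
    for c in classes:
        if counts[c] < k_neighbors + 1:
            raise ValueError(
                f"class {c!r} has {counts[c]} samples, needs >= {k_neighbors + 1} "
                f"for k_neighbors={k_neighbors}")
    if target_per_class is None:
        targets = {c: 2 * counts[c] for c in classes}
    elif isinstance(target_per_class, Mapping):
        targets = {c: int(target_per_class[c]) for c in classes}
    else:
        t = int(target_per_class)
        if t < max(counts.values()):
            raise ValueError(
                f"target_per_class={t} below the largest class ({max(counts.values())})")
        targets = {c: t for c in classes}

    new_X: list[np.ndarray] = []
    new_y: list = []
    for c in classes:
        idx = np.flatnonzero(y == c)
        n_new = targets[c] - counts[c]
        if n_new <= 0:
            continue
        Xc = X[idx]
        nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(Xc)
        # [:, 1:] drops each point's self-match
        neigh = nn.kneighbors(Xc, return_distance=False)[:, 1:]
        base = rng.integers(0, len(Xc), size=n_new)
        pick = rng.integers(0, k_neighbors, size=n_new)
        lam = rng.uniform(0.0, 1.0, size=n_new)
        xi = Xc[base]
        xn = Xc[neigh[base, pick]]
        new_X.append(xi + lam[:, None] * (xn - xi))
        new_y.extend([c] * n_new)
    if new_X:
        X_out = np.vstack([X] + new_X)
        y_out = np.concatenate([y, np.asarray(new_y, dtype=y.dtype)])
    else:
        X_out, y_out = X.copy(), y.copy()
    return X_out, y_out


class SMOTEOversampler:
    """Estimator-style wrapper around :func:`smote_oversample`.

    sklearn has no resampler mixin; the surface mirrors the common
    ``fit_resample`` convention.
    """

    def __init__(self, target_per_class: int | None = None,
                 k_neighbors: int = 5, seed: int = 0):
        self.target_per_class = target_per_class
        self.k_neighbors = k_neighbors
        self.seed = seed

    def fit_resample(self, X, y):
        return smote_oversample(X, y, self.target_per_class,
                                self.k_neighbors, self.seed)

    def get_params(self, deep=True):
        return {"target_per_class": self.target_per_class,
                "k_neighbors": self.k_neighbors, "seed": self.seed}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self


# ---------------------------------------------------------------------------
# signal-space operators
# ---------------------------------------------------------------------------

def _draw_window(rng: np.random.Generator, n: int) -> tuple[int, int]:
    """Random contiguous window [i, j) with j - i >= 2; redraw degenerates."""
    while True:
        i = int(rng.integers(0, n - 1))
        j = int(rng.integers(i + 1, n + 1))
        if j - i >= 2:
            return i, j


def draw_params(kind: str, rng: np.random.Generator, x: np.ndarray,
                zero_centered_noise: bool = False) -> dict:
    """Draw one parameter set for an operator; bounds are auditable here.

    ``zero_centered_noise`` switches the noise operator's per-sample draws
    from the documented U(0,1) (which adds a positive bias) to U(-1,1).
    """
    n = len(x)
    if kind == "hang":
        i, j = _draw_window(rng, n)
        return {"start": i, "end": j}
    if kind == "gauss":
        i, j = _draw_window(rng, n)
        width = int(2 * rng.integers(1, 16) + 1)  # odd in [3, 31]
        return {"start": i, "end": j, "kernel_width": width}
    if kind == "noise":
        i, j = _draw_window(rng, n)
        lo = -1.0 if zero_centered_noise else 0.0
        return {"start": i, "end": j,
                "draws": rng.uniform(lo, 1.0, size=j - i)}
    if kind == "downsample":
        i, j = _draw_window(rng, n)
        return {"start": i, "end": j,
                "fraction": float(rng.uniform(0.01, 0.25))}
    if kind == "slope":
        return {"rise": float(rng.uniform(0.0, 10.0 * np.std(x)))}
    if kind == "shift_x":
        max_s = int(np.floor(0.05 * n))
        return {"shift": int(rng.integers(-max_s, max_s + 1))}
    if kind == "shift_y":
        span = float(np.max(x) - np.min(x))
        return {"offset": float(rng.uniform(-0.05 * span, 0.05 * span))}
    if kind == "scale":
        return {"factor": float(rng.uniform(0.95, 1.05))}
    raise ValueError(f"unknown operator {kind!r}")


def _gauss_kernel(width: int) -> np.ndarray:
    # width is odd; kernel truncated at 3 sigma and normalised to sum 1
    half = width // 2
    sigma = max(half / 3.0, 1e-12)
    t = np.arange(-half, half + 1)
    k = np.exp(-0.5 * (t / sigma) ** 2)
    return k / k.sum()


def apply_operator(x: np.ndarray, kind: str, params: Mapping) -> np.ndarray:
    """Apply one operator with explicit parameters; length is preserved."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    out = x.copy()
    if kind == "hang":
        i, j = params["start"], params["end"]
        out[i + 1:j] = x[i]
    elif kind == "gauss":
        i, j = params["start"], params["end"]
        k = _gauss_kernel(params["kernel_width"])
        half = len(k) // 2
        window = np.pad(x[i:j], half, mode="edge")
        out[i:j] = np.convolve(window, k, mode="valid")
    elif kind == "noise":
        i, j = params["start"], params["end"]
        draws = np.asarray(params["draws"], dtype=float)
        out[i:j] = x[i:j] + draws * np.std(x)
    elif kind == "downsample":
        i, j = params["start"], params["end"]
        w = j - i
        m = max(2, int(round(params["fraction"] * w)))
        pos = np.linspace(0.0, w - 1.0, m)
        down = np.interp(pos, np.arange(w), x[i:j])
        out[i:j] = np.interp(np.arange(w), pos, down)
    elif kind == "slope":
        out = x + params["rise"] / n * np.arange(n)
    elif kind == "shift_x":
        out = np.roll(x, params["shift"])
    elif kind == "shift_y":
        out = x + params["offset"]
    elif kind == "scale":
        out = x * params["factor"]
    else:
        raise ValueError(f"unknown operator {kind!r}")
    return out


def augment_local(x: np.ndarray, kind: str,
                  rng: np.random.Generator) -> np.ndarray:
    """Apply one windowed operator with freshly drawn parameters."""
    if kind not in LOCAL_OPERATORS:
        raise ValueError(f"{kind!r} is not a local operator {LOCAL_OPERATORS}")
    _check_len(x)
    return apply_operator(x, kind, draw_params(kind, rng, np.asarray(x, float)))


def augment_global(x: np.ndarray, kind: str,
                   rng: np.random.Generator) -> np.ndarray:
    """Apply one whole-signal operator with freshly drawn parameters."""
    if kind not in GLOBAL_OPERATORS:
        raise ValueError(f"{kind!r} is not a global operator {GLOBAL_OPERATORS}")
    _check_len(x)
    return apply_operator(x, kind, draw_params(kind, rng, np.asarray(x, float)))


def _check_len(x) -> None:
    if len(x) < _MIN_LEN:
        raise ValueError(f"signal too short to augment (need >= {_MIN_LEN})")


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

@dataclass
class AugmentationPlan:
    """Seeded record of which operators apply, in which order, with which
    drawn parameters.  Parameters are drawn lazily against each signal (the
    window bounds and std-scaled quantities depend on the signal), but the
    *order* and *inclusion* pattern are fixed by the plan."""
    steps: list[str]
    seed: int
    target: str = "signal-space"

    def __post_init__(self) -> None:
        unknown = [s for s in self.steps if s not in SIGNAL_OPERATORS]
        if unknown:
            raise ValueError(f"unknown operators in plan: {unknown}")


def make_plan(seed: int, operators: Sequence[str] = SIGNAL_OPERATORS,
              include_prob: float = 0.5) -> AugmentationPlan:
    """Draw a composition plan: seeded random order, independent inclusion."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA06]))
    ops = list(operators)
    order = rng.permutation(len(ops))
    included = [ops[i] for i in order if rng.uniform() < include_prob]
    return AugmentationPlan(steps=included, seed=seed)


def compose(x: np.ndarray, plan: AugmentationPlan) -> np.ndarray:
    """Apply the plan's operators sequentially; deterministic given its seed."""
    rng = np.random.default_rng(np.random.SeedSequence([plan.seed, 0xC07]))
    out = np.asarray(x, dtype=float)
    if plan.steps:
        _check_len(out)
    for kind in plan.steps:
        out = apply_operator(out, kind, draw_params(kind, rng, out))
    return out


def augment_signal(x: np.ndarray, seed: int,
                   operators: Sequence[str] = SIGNAL_OPERATORS,
                   include_prob: float = 0.5) -> np.ndarray:
    """One-shot helper: draw a plan for ``seed`` and apply it."""
    return compose(x, make_plan(seed, operators, include_prob))
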