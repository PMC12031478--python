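"""End-to-end scenario driver: the nine input/model training scenarios.

Scenario map (input -> admissible models):

====  ============================  ============
 #    input                          models
====  ============================  ============
 1    EMG features                   svm / rf / dt
 2    PZT features                   svm / rf / dt
 3    EMG + PZT features             svm / rf / dt
 4    optimised EMG features         svm / rf / dt
 5    optimised PZT features         svm / rf / dt
 6    optimised EMG + PZT features   svm / rf / dt
 7    raw EMG                        cnn / snn
 8    raw PZT                        cnn / snn
 9    raw EMG + raw PZT (PMLDF)      cnn / snn
====  ============================  ============

Every scenario performs the same protocol: a per-class stratified 60/20/20
train/validation/test split, augmentation of the *training partition only*
(SMOTE in feature space; the eight signal operators in raw space),
training with validation-driven model selection, and evaluation on the
untouched test partition (accuracy %, macro-F1 %, 8x8 confusion matrix).
"Optimised" scenarios run recursive feature elimination on the training
partition with the subset chosen on validation (or accept a fixed subset).

The driver audits protocol integrity: partition id-sets are disjoint and
test trials are byte-identical before and after training.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import augmentation as aug
from . import classic, dataset, features, selection
from .dataset import DatasetSplit, Trial, stratified_split, split_trials
from .nn import (CNNClassifier, PMLDFClassifier, SiameseClassifier,
                 reduced_fen_spec, PMLDFSpec)

FEATURE_MODELS = ("svm", "rf", "dt")
RAW_MODELS = ("cnn", "snn")

INPUT_MODES: dict[int, str] = {
    1: "emg-features", 2: "pzt-features", 3: "both-features",
    4: "optimized-emg", 5: "optimized-pzt", 6: "optimized-both",
    7: "raw-emg", 8: "raw-pzt", 9: "raw-both-pmldf",
}

_MODE_CHANNELS: dict[str, tuple[str, ...]] = {
    "emg-features": ("emg",), "pzt-features": ("pzt",),
    "both-features": ("emg", "pzt"),
    "optimized-emg": ("emg",), "optimized-pzt": ("pzt",),
    "optimized-both": ("emg", "pzt"),
    "raw-emg": ("emg",), "raw-pzt": ("pzt",),
    "raw-both-pmldf": ("emg", "pzt"),
}


@dataclass
class ScenarioSpec:
    """Configuration of one scenario run.

    The neural defaults are the desk-scale configuration: four FEN blocks,
    at most 100 epochs with patience 15, EMG resampled to 1024 samples and
    PZT to 256 (EMG carries content to ~500 Hz, PZT below ~100 Hz).
    """
    scenario: int
    model: str
    seed: int = 0
    augment: bool = True
    n_augment_copies: int = 1
    smote_target_per_class: int | None = None
    rfe_tolerance: float = 0.005
    fixed_subset: tuple[str, ...] | None = None
    grid: Mapping | None = None
    fen_layers: int = 4
    max_epochs: int = 100
    patience: int = 15
    batch_size: int = 32
    lr: float = 1e-3
    emg_input_length: int = 1024
    pzt_input_length: int = 256
    n_reference: int = 5

    def __post_init__(self) -> None:
        if self.scenario not in INPUT_MODES:
            raise ValueError(f"scenario must be 1..9, got {self.scenario}")
        mode = self.input_mode
        if mode.startswith("raw"):
            if self.model not in RAW_MODELS:
                raise ValueError(
                    f"scenario {self.scenario} ({mode}) requires a raw-signal "
                    f"model {RAW_MODELS}, got {self.model!r}")
        else:
            if self.model not in FEATURE_MODELS:
                raise ValueError(
                    f"scenario {self.scenario} ({mode}) requires a feature "
                    f"model {FEATURE_MODELS}, got {self.model!r}")

    @property
    def input_mode(self) -> str:
        return INPUT_MODES[self.scenario]

    @property
    def channels(self) -> tuple[str, ...]:
        return _MODE_CHANNELS[self.input_mode]


def run_scenario(spec: ScenarioSpec, trials: Sequence[Trial]
                 ) -> classic.ScenarioResult:
    """Run one scenario end-to-end on a trial list; see the module docs."""
    t0 = time.perf_counter()
    counts = {}
    for t in trials:
        counts[t.label] = counts.get(t.label, 0) + 1
    if any(c < 5 for c in counts.values()):
        raise ValueError("need at least 5 trials per class")

    split = stratified_split(trials, seed=spec.seed)
    _assert_disjoint(split)
    train, val, test = split_trials(trials, split)
    test_hashes = [t.content_hash() for t in test]

    if spec.input_mode.startswith("raw"):
        result = _run_raw(spec, train, val, test)
    else:
        result = _run_features(spec, train, val, test)

    if [t.content_hash() for t in test] != test_hashes:
        raise RuntimeError("test trials were modified during training")
    result.config.update({
        "scenario": spec.scenario, "input_mode": spec.input_mode,
        "model": spec.model, "seed": spec.seed, "augment": spec.augment,
        "n_train": len(train), "n_validation": len(val), "n_test": len(test),
        "runtime_s": round(time.perf_counter() - t0, 3),
    })
    return result


def _assert_disjoint(split: DatasetSplit) -> None:
    a, b, c = map(set, (split.train, split.validation, split.test))
    if a & b or a & c or b & c:
        raise RuntimeError("split partitions overlap")


def _run_features(spec: ScenarioSpec, train, val, test
                  ) -> classic.ScenarioResult:
    chans = spec.channels
    ftr = features.feature_table(train, chans)
    fva = features.feature_table(val, chans)
    fte = features.feature_table(test, chans)
    names = features.feature_names(chans)
    Xtr, ytr = ftr[names], ftr["label"].to_numpy()
    Xva, yva = fva[names], fva["label"].to_numpy()
    Xte, yte = fte[names], fte["label"].to_numpy()

    selected: list[str] | None = None
    if spec.input_mode.startswith("optimized"):
        if spec.fixed_subset is not None:
            missing = [f for f in spec.fixed_subset if f not in names]
            if missing:
                raise ValueError(f"fixed subset not in feature set: {missing}")
            selected = list(spec.fixed_subset)
        else:
            ranking = selection.rfe_rank(Xtr, ytr, seed=spec.seed)
            selected = selection.select_subset(
                ranking, Xtr, ytr, Xva, yva,
                tolerance=spec.rfe_tolerance, seed=spec.seed)
        Xtr, Xva, Xte = Xtr[selected], Xva[selected], Xte[selected]

    Xtr_a, ytr_a = Xtr.to_numpy(float), ytr
    if spec.augment:
        Xtr_a, ytr_a = aug.smote_oversample(
            Xtr_a, ytr, target_per_class=spec.smote_target_per_class,
            seed=spec.seed)

    gspec = classic.GridSearchSpec(spec.model, spec.grid, spec.seed)
    model, best_params, trace = classic.grid_search_train(
        Xtr_a, ytr_a, Xva.to_numpy(float), yva, gspec)
    result = classic.evaluate(model, Xte.to_numpy(float), yte,
                              labels=sorted(set(ytr.tolist())))
    result.chosen_params = best_params
    result.config["selected_features"] = selected
    result.config["grid_points"] = len(trace)
    return result


def _raw_matrix(trials: Sequence[Trial], channel: str) -> np.ndarray:
    return np.vstack([t.channel(channel) for t in trials])


def _augment_matrix(X: np.ndarray, seed: int, copies: int) -> np.ndarray:
    """``copies`` augmented variants of each row, seeded per (row, copy)."""
    rows = [X]
    for c in range(copies):
        out = np.empty_like(X)
        for i in range(len(X)):
            plan_seed = int(np.random.SeedSequence(
                [seed, 0xA9, c, i]).generate_state(1)[0] % (2 ** 31))
            out[i] = aug.augment_signal(X[i], plan_seed)
        rows.append(out)
    return np.vstack(rows)


def _run_raw(spec: ScenarioSpec, train, val, test) -> classic.ScenarioResult:
    ytr = np.array([t.label for t in train])
    yva = np.array([t.label for t in val])
    yte = np.array([t.label for t in test])
    lengths = {"emg": spec.emg_input_length, "pzt": spec.pzt_input_length}
    common = dict(lr=spec.lr, batch_size=spec.batch_size,
                  max_epochs=spec.max_epochs, patience=spec.patience,
                  random_state=spec.seed)
    fen = reduced_fen_spec(spec.fen_layers)

    if spec.input_mode == "raw-both-pmldf":
        Xtr = [_raw_matrix(train, ch) for ch in spec.channels]
        Xva = [_raw_matrix(val, ch) for ch in spec.channels]
        Xte = [_raw_matrix(test, ch) for ch in spec.channels]
        if spec.augment:
            n0 = len(ytr)
            Xtr = [_augment_matrix(x, spec.seed + k, spec.n_augment_copies)
                   for k, x in enumerate(Xtr)]
            ytr = np.concatenate([ytr] * (spec.n_augment_copies + 1))
            assert all(len(x) == len(ytr) for x in Xtr) and len(ytr) >= n0
        model = PMLDFClassifier(
            spec=PMLDFSpec(stream_specs=(fen, fen), fusion_spec=fen),
            input_lengths=tuple(lengths[ch] for ch in spec.channels),
            head="softmax" if spec.model == "cnn" else "siamese",
            n_reference=spec.n_reference, **common)
    else:
        ch = spec.channels[0]
        Xtr = _raw_matrix(train, ch)
        Xva = _raw_matrix(val, ch)
        Xte = _raw_matrix(test, ch)
        if spec.augment:
            Xtr = _augment_matrix(Xtr, spec.seed, spec.n_augment_copies)
            ytr = np.concatenate([ytr] * (spec.n_augment_copies + 1))
        cls = CNNClassifier if spec.model == "cnn" else SiameseClassifier
        kwargs = dict(fen_spec=fen, input_length=lengths[ch], **common)
        if spec.model == "snn":
            kwargs["n_reference"] = spec.n_reference
        model = cls(**kwargs)

    model.fit(Xtr, ytr, X_val=Xva, y_val=yva)
    result = classic.evaluate(model, Xte, yte,
                              labels=sorted(set(ytr.tolist())))
    result.config["best_epoch"] = model.history_.best_epoch
    result.config["stopped_epoch"] = model.history_.stopped_epoch
    return result


def run_all(trials: Sequence[Trial], seed: int = 0,
            scenarios: Sequence[int] | None = None,
            spec_overrides: Mapping | None = None) -> pd.DataFrame:
    """Run every (scenario, model) pair and tabulate accuracy and macro-F1.

    Returns a DataFrame with one row per input mode, columns
    ``(metric, model)`` mirroring the comparison-table layout.  Individual
    scenario failures are recorded as NaN and the run continues.
    """
    scenarios = list(scenarios) if scenarios is not None else list(range(1, 10))
    overrides = dict(spec_overrides or {})
    records: dict[str, dict[tuple[str, str], float]] = {}
    errors: dict[tuple[int, str], str] = {}
    for sc in scenarios:
        models = FEATURE_MODELS if INPUT_MODES[sc].split("-")[0] != "raw" \
            else RAW_MODELS
        for model in models:
            spec = ScenarioSpec(scenario=sc, model=model, seed=seed,
                                **overrides)
            row = records.setdefault(INPUT_MODES[sc], {})
            try:
                res = run_scenario(spec, trials)
                row[("accuracy", model)] = res.accuracy
                row[("macro_f1", model)] = res.macro_f1
            except Exception as exc:  # keep going, record the failure
                errors[(sc, model)] = str(exc)
                row[("accuracy", model)] = np.nan
                row[("macro_f1", model)] = np.nan
    table = pd.DataFrame.from_dict(records, orient="index")
    table.columns = pd.MultiIndex.from_tuples(table.columns,
                                              names=["metric", "model"])
    table.index.name = "input"
    table.attrs["errors"] = errors
    return table


def format_table(table: pd.DataFrame) -> str:
    """Aligned text rendering of a :func:`run_all` table."""
    return table.round(2).to_string()
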