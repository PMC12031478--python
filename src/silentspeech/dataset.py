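"""Trial storage and the stratified train/validation/test split.

A *trial* is one labelled two-channel recording: an EMG trace (muscle
activity) and a PZT trace (chin-skin vibration), sampled synchronously.
Trials are stored one per delimited text file with a two-line-per-sample
layout (``emg_mV,pzt_mV`` columns) plus a single manifest file describing
the whole dataset.  All experiments use a per-class stratified 60/20/20
train/validation/test split.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

#: the eight most frequent English letters used as the classification targets
LETTERS: tuple[str, ...] = ("E", "T", "A", "O", "I", "N", "R", "S")

DEFAULT_FRACTIONS: tuple[float, float, float] = (0.6, 0.2, 0.2)


class TrialParseError(ValueError):
    """Raised when a trial file cannot be parsed; message names the line."""


@dataclass
class Trial:
    """One labelled two-channel recording.

    Attributes
    ----------
    emg, pzt : ndarray of float, shape (n_samples,)
        Channel voltages in millivolts.  Equal length, >= 2 samples.
    fs : float
        Sampling rate in Hz (per channel).
    label : str
        One of :data:`LETTERS`.
    trial_id : str
        Unique identifier within a dataset.
    """

    emg: np.ndarray
    pzt: np.ndarray
    fs: float
    label: str
    trial_id: str

    def __post_init__(self) -> None:
        self.emg = np.asarray(self.emg, dtype=float)
        self.pzt = np.asarray(self.pzt, dtype=float)
        if self.emg.ndim != 1 or self.pzt.ndim != 1:
            raise ValueError("trial channels must be 1-D sample arrays")
        if len(self.emg) != len(self.pzt):
            raise ValueError(
                f"channel length mismatch: emg={len(self.emg)} pzt={len(self.pzt)}"
            )
        if len(self.emg) < 2:
            raise ValueError("trial must contain at least 2 samples")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.label not in LETTERS:
            raise ValueError(f"label {self.label!r} not in protocol set {LETTERS}")

    @property
    def n_samples(self) -> int:
        return len(self.emg)

    def channel(self, name: str) -> np.ndarray:
        if name == "emg":
            return self.emg
        if name == "pzt":
            return self.pzt
        raise ValueError(f"unknown channel {name!r}; expected 'emg' or 'pzt'")

    def content_hash(self) -> str:
        """SHA-256 over the raw sample bytes; used for leakage audits."""
        h = hashlib.sha256()
        h.update(self.emg.tobytes())
        h.update(self.pzt.tobytes())
        return h.hexdigest()


@dataclass
class DatasetSplit:
    """Disjoint trial-id lists for the train/validation/test partitions."""

    train: list[str]
    validation: list[str]
    test: list[str]

    def as_dict(self) -> dict[str, list[str]]:
        return {"train": list(self.train), "validation": list(self.validation),
                "test": list(self.test)}

    def partitions(self) -> Iterable[tuple[str, list[str]]]:
        return (("train", self.train), ("validation", self.validation),
                ("test", self.test))


# ---------------------------------------------------------------------------
# per-trial file round-trip
# ---------------------------------------------------------------------------

_HEADER = ["emg_mV", "pzt_mV"]


def write_trial(trial: Trial, path: str | Path) -> None:
    """Write one trial as a two-column CSV with a header line.

    Samples are written with ``repr`` precision so a read round-trips to the
    identical float64 values.
    """
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_HEADER)
        for e, p in zip(trial.emg, trial.pzt):
            w.writerow([repr(float(e)), repr(float(p))])


def read_trial(path: str | Path, *, fs: float, label: str,
               trial_id: str | None = None) -> Trial:
    """Read a two-column trial file written by :func:`write_trial`.

    ``fs`` and ``label`` come from the manifest; the file itself carries only
    samples.  Malformed rows raise :class:`TrialParseError` naming the line.
    """
    path = Path(path)
    emg: list[float] = []
    pzt: list[float] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise TrialParseError(f"{path}: empty file") from None
        if [c.strip() for c in header] != _HEADER:
            raise TrialParseError(
                f"{path}: line 1: expected header {_HEADER}, got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 2:
                raise TrialParseError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(row)}")
            try:
                emg.append(float(row[0]))
                pzt.append(float(row[1]))
            except ValueError:
                raise TrialParseError(
                    f"{path}: line {lineno}: non-numeric value in {row}") from None
    if len(emg) < 2:
        raise TrialParseError(f"{path}: fewer than 2 samples")
    return Trial(emg=np.array(emg), pzt=np.array(pzt), fs=fs, label=label,
                 trial_id=trial_id if trial_id is not None else path.stem)


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

def write_dataset(trials: Sequence[Trial], out_dir: str | Path,
                  manifest_name: str = "manifest.csv") -> Path:
    """Write all trials plus a manifest; returns the manifest path.

    Manifest columns: trial_id, path (relative), label, fs, n_samples.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / manifest_name
    with manifest.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["trial_id", "path", "label", "fs", "n_samples"])
        for t in trials:
            rel = f"{t.trial_id}.csv"
            write_trial(t, out_dir / rel)
            w.writerow([t.trial_id, rel, t.label, repr(float(t.fs)), t.n_samples])
    return manifest


def read_dataset(manifest_path: str | Path) -> list[Trial]:
    """Load every trial listed in a manifest written by :func:`write_dataset`."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    trials: list[Trial] = []
    with manifest_path.open(newline="") as fh:
        for rec in csv.DictReader(fh):
            t = read_trial(base / rec["path"], fs=float(rec["fs"]),
                           label=rec["label"], trial_id=rec["trial_id"])
            if t.n_samples != int(rec["n_samples"]):
                raise TrialParseError(
                    f"{rec['path']}: manifest says {rec['n_samples']} samples, "
                    f"file has {t.n_samples}")
            trials.append(t)
    return trials


# ---------------------------------------------------------------------------
# stratified split
# ---------------------------------------------------------------------------

def stratified_split(trials: Sequence[Trial],
                     fractions: Sequence[float] = DEFAULT_FRACTIONS,
                     seed: int = 0) -> DatasetSplit:
    """Per-class stratified split into train/validation/test id lists.

    Within each class, ids are shuffled by a generator seeded from ``seed``
    and allocated by largest-remainder rounding, so per-class counts match
    the fractions within +/-1.  The split depends only on the id set and the
    seed, not on input ordering.

    Parameters
    ----------
    fractions : (train, validation, test), summing to 1.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f < 0 for f in fractions):
        raise ValueError("fractions must be three non-negative numbers")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")

    by_class: dict[str, list[str]] = {}
    for t in trials:
        by_class.setdefault(t.label, []).append(t.trial_id)
    too_small = [lab for lab, ids in by_class.items() if len(ids) < 5]
    if too_small:
        raise ValueError(
            f"classes with fewer than 5 trials cannot be split: {sorted(too_small)}")

    labels_sorted = sorted(by_class)
    parts: dict[str, list[str]] = {"train": [], "validation": [], "test": []}
    for ci, label in enumerate(labels_sorted):
        ids = sorted(by_class[label])  # order-invariance: canonicalise first
        rng_c = np.random.default_rng(np.random.SeedSequence([seed, ci]))
        perm = rng_c.permutation(len(ids))
        ids = [ids[i] for i in perm]
        counts = _largest_remainder(len(ids), fractions)
        i = 0
        for part, c in zip(("train", "validation", "test"), counts):
            parts[part].extend(ids[i:i + c])
            i += c
    return DatasetSplit(train=parts["train"], validation=parts["validation"],
                        test=parts["test"])


def _largest_remainder(n: int, fractions: tuple[float, ...]) -> list[int]:
    raw = [n * f for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    rem = n - sum(counts)
    order = np.argsort([-(r - np.floor(r)) for r in raw], kind="stable")
    for k in range(rem):
        counts[order[k]] += 1
    return counts


def split_trials(trials: Sequence[Trial], split: DatasetSplit
                 ) -> tuple[list[Trial], list[Trial], list[Trial]]:
    """Materialise the three partitions as trial lists (manifest order)."""
    by_id = {t.trial_id: t for t in trials}
    return ([by_id[i] for i in split.train],
            [by_id[i] for i in split.validation],
            [by_id[i] for i in split.test])


def save_split(split: DatasetSplit, path: str | Path) -> None:
    Path(path).write_text(json.dumps(split.as_dict(), indent=1))


def load_split(path: str | Path) -> DatasetSplit:
    d = json.loads(Path(path).read_text())
    return DatasetSplit(train=d["train"], validation=d["validation"], test=d["test"])
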