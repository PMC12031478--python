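"""sklearn-style estimators around the three network architectures.

All three classifiers share the same surface:

* ``X`` is a 2-D float array of raw single-channel signals, one trial per
  row (for :class:`PMLDFClassifier`, a list/tuple with one such array per
  sensor stream).  Rows are standardised per trial (zero mean, unit
  variance) and Fourier-resampled to the estimator's ``input_length``
  before entering the network.
* ``fit(X, y, X_val=..., y_val=...)`` trains with Adam, the stepped
  exponential learning-rate decay and early stopping on validation
  accuracy; without an explicit validation set, training accuracy drives
  the stopping rule.
* Fitted attributes follow sklearn conventions (``classes_``, ``model_``,
  ``history_``).
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator, ClassifierMixin

from .autograd import Tensor
from .modules import (CNNModel, FENSpec, PMLDF, PMLDFSpec, default_pmldf_spec,
                      reduced_fen_spec)
from .training import (TrainConfig, fit_loop, siamese_cosine_loss)

_EVAL_CHUNK = 256


def prepare_signals(X: np.ndarray, input_length: int | None) -> np.ndarray:
    """Standardise each row (zero mean, unit variance) and resample it.

    Resampling is FFT-based (ideal low-pass), so content above the new
    Nyquist is removed — choose ``input_length`` generously for
    high-frequency channels.  ``None`` keeps the native length.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    X = (X - mu) / np.where(sd > 0, sd, 1.0)
    if input_length is not None and input_length != X.shape[1]:
        X = sps.resample(X, input_length, axis=1)
    return X


class _NeuralBase(BaseEstimator, ClassifierMixin):
    """Shared fit/predict plumbing for the single-stream networks."""

    def _train_config(self) -> TrainConfig:
        return TrainConfig(lr=self.lr, batch_size=self.batch_size,
                           max_epochs=self.max_epochs, patience=self.patience,
                           scheduler_step=self.scheduler_step,
                           scheduler_gamma=self.scheduler_gamma,
                           seed=self.random_state)

    def _encode_labels(self, y) -> np.ndarray:
        self.classes_ = np.array(sorted(set(np.asarray(y).tolist())))
        lookup = {c: i for i, c in enumerate(self.classes_)}
        return np.array([lookup[v] for v in np.asarray(y)])

    def _batched_scores(self, X3: np.ndarray, forward) -> np.ndarray:
        outs = []
        for start in range(0, len(X3), _EVAL_CHUNK):
            outs.append(forward(Tensor(X3[start:start + _EVAL_CHUNK])).data)
        return np.vstack(outs)


class CNNClassifier(_NeuralBase):
    """1D-convolutional classifier: FEN trunk + CN head with softmax.

    Parameters
    ----------
    fen_spec : FENSpec or None
        None selects the full seven-block architecture; pass
        :func:`reduced_fen_spec` for the desk-scale four-block variant.
    input_length : int or None
        Per-trial resampling target before the network (None = native).
    """

    def __init__(self, fen_spec: FENSpec | None = None,
                 input_length: int | None = 256, embed_dim: int = 256,
                 lr: float = 1e-3, batch_size: int = 32,
                 max_epochs: int = 500, patience: int = 150,
                 scheduler_step: int = 10, scheduler_gamma: float = 0.992,
                 random_state: int = 0):
        self.fen_spec = fen_spec
        self.input_length = input_length
        self.embed_dim = embed_dim
        self.lr = lr
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.scheduler_step = scheduler_step
        self.scheduler_gamma = scheduler_gamma
        self.random_state = random_state

    def fit(self, X, y, X_val=None, y_val=None):
        y_idx = self._encode_labels(y)
        Xp = prepare_signals(X, self.input_length)[:, None, :]
        spec = self.fen_spec if self.fen_spec is not None else FENSpec()
        rng = np.random.default_rng(
            np.random.SeedSequence([self.random_state, 0xC44]))
        self.model_ = CNNModel(spec, rng, embed_dim=self.embed_dim,
                               n_classes=len(self.classes_))
        if X_val is not None:
            Xv = prepare_signals(X_val, self.input_length)[:, None, :]
            yv = np.array([list(self.classes_).index(v) for v in y_val])
        else:
            Xv, yv = Xp, y_idx

        from .autograd import softmax_cross_entropy

        def loss_fn(idx):
            logits = self.model_(Tensor(Xp[idx]))
            return softmax_cross_entropy(logits, y_idx[idx])

        def val_fn():
            scores = self._batched_scores(Xv, self.model_)
            return float(np.mean(scores.argmax(axis=1) == yv))

        self.history_ = fit_loop(self.model_, loss_fn, val_fn, len(Xp),
                                 self._train_config())
        return self

    def decision_function(self, X):
        Xp = prepare_signals(X, self.input_length)[:, None, :]
        self.model_.eval()
        return self._batched_scores(Xp, self.model_)

    def predict(self, X):
        return self.classes_[self.decision_function(X).argmax(axis=1)]

    def embed(self, X) -> np.ndarray:
        """256-dim feature vectors from the CN (pre-softmax)."""
        Xp = prepare_signals(X, self.input_length)[:, None, :]
        self.model_.eval()
        return self._batched_scores(Xp, self.model_.embed)


class SiameseClassifier(_NeuralBase):
    """Few-shot Siamese classifier with per-class reference vectors.

    A single shared-weight embedder (FEN + CN) maps trials to 256-dim
    feature vectors.  ``n_reference`` training trials per class serve as
    references; each class's reference vector is the mean embedding of its
    reference trials, recomputed as the embedder trains.  Training
    minimises the contrastive cosine loss; prediction assigns the class
    whose reference vector has the highest cosine similarity (ties go to
    the lexicographically first label).
    """

    def __init__(self, fen_spec: FENSpec | None = None,
                 input_length: int | None = 256, embed_dim: int = 256,
                 n_reference: int = 5, margin: float = 0.0,
                 lr: float = 1e-3, batch_size: int = 32,
                 max_epochs: int = 500, patience: int = 150,
                 scheduler_step: int = 10, scheduler_gamma: float = 0.992,
                 random_state: int = 0):
        self.fen_spec = fen_spec
        self.input_length = input_length
        self.embed_dim = embed_dim
        self.n_reference = n_reference
        self.margin = margin
        self.lr = lr
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.scheduler_step = scheduler_step
        self.scheduler_gamma = scheduler_gamma
        self.random_state = random_state

    def fit(self, X, y, X_val=None, y_val=None):
        y_idx = self._encode_labels(y)
        Xp = prepare_signals(X, self.input_length)[:, None, :]
        C = len(self.classes_)
        rng = np.random.default_rng(
            np.random.SeedSequence([self.random_state, 0x51A]))
        # reference trials: drawn from the training partition only
        ref_rows: list[int] = []
        for ci in range(C):
            rows = np.flatnonzero(y_idx == ci)
            if len(rows) == 0:
                raise ValueError(f"class {self.classes_[ci]!r} missing from "
                                 "training data")
            take = min(self.n_reference, len(rows))
            ref_rows.extend(rng.choice(rows, size=take, replace=False))
        self.reference_rows_ = np.array(ref_rows)
        ref_class = y_idx[self.reference_rows_]
        Xref = Xp[self.reference_rows_]
        onehot_ref = np.zeros((C, len(ref_class)))
        onehot_ref[ref_class, np.arange(len(ref_class))] = 1.0
        ref_weights = onehot_ref / onehot_ref.sum(axis=1, keepdims=True)

        spec = self.fen_spec if self.fen_spec is not None else FENSpec()
        self.model_ = CNNModel(spec, rng, embed_dim=self.embed_dim,
                               n_classes=None)

        def reference_embeddings(with_grad: bool) -> Tensor:
            emb = self.model_.embed(Tensor(Xref))
            refs = Tensor(ref_weights) @ emb  # (C, D) class means
            if not with_grad:
                return Tensor(refs.data)
            return refs

        def loss_fn(idx):
            emb = self.model_.embed(Tensor(Xp[idx]))
            refs = reference_embeddings(with_grad=True)
            return siamese_cosine_loss(emb, refs, y_idx[idx], self.margin)

        if X_val is not None:
            Xv = prepare_signals(X_val, self.input_length)[:, None, :]
            yv = np.array([list(self.classes_).index(v) for v in y_val])
        else:
            Xv, yv = Xp, y_idx

        def val_fn():
            refs = reference_embeddings(with_grad=False).data
            emb = self._batched_scores(Xv, self.model_.embed)
            return float(np.mean(_cosine_argmax(emb, refs) == yv))

        self.history_ = fit_loop(self.model_, loss_fn, val_fn, len(Xp),
                                 self._train_config())
        # final reference feature vectors from the best checkpoint
        self.model_.eval()
        emb = self._batched_scores(Xref, self.model_.embed)
        refs = ref_weights @ emb
        if np.any(np.linalg.norm(refs, axis=1) == 0):
            raise ValueError("zero-norm reference embedding")
        self.reference_vectors_ = refs
        self.embedding_set_ = {
            str(c): refs[i] for i, c in enumerate(self.classes_)}
        return self

    def embed(self, X) -> np.ndarray:
        Xp = prepare_signals(X, self.input_length)[:, None, :]
        self.model_.eval()
        return self._batched_scores(Xp, self.model_.embed)

    def decision_function(self, X):
        emb = self.embed(X)
        return _cosine_matrix(emb, self.reference_vectors_)

    def predict(self, X):
        return self.classes_[self.decision_function(X).argmax(axis=1)]


def _cosine_matrix(emb: np.ndarray, refs: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(emb, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero-norm embedding; cosine similarity undefined")
    f = emb / norms
    r = refs / np.linalg.norm(refs, axis=1, keepdims=True)
    return f @ r.T


def _cosine_argmax(emb: np.ndarray, refs: np.ndarray) -> np.ndarray:
    # argmax takes the first maximum -> lexicographically first class on ties
    return _cosine_matrix(emb, refs).argmax(axis=1)


class PMLDFClassifier(_NeuralBase):
    """Parallel multi-layer fusion classifier over >= 2 sensor streams.

    ``X`` is a list/tuple with one raw-signal matrix per stream (equal row
    counts — rows are paired trials).  Each stream is standardised and
    resampled to its own ``input_lengths`` entry, runs through its own FEN,
    and the fusion stack consumes all streams' block outputs.  ``head``
    selects softmax classification or the Siamese few-shot head.
    """

    def __init__(self, spec: PMLDFSpec | None = None,
                 input_lengths: tuple[int, ...] | None = (256, 256),
                 head: str = "softmax", embed_dim: int = 256,
                 n_reference: int = 5, margin: float = 0.0,
                 lr: float = 1e-3, batch_size: int = 32,
                 max_epochs: int = 500, patience: int = 150,
                 scheduler_step: int = 10, scheduler_gamma: float = 0.992,
                 random_state: int = 0):
        self.spec = spec
        self.input_lengths = input_lengths
        self.head = head
        self.embed_dim = embed_dim
        self.n_reference = n_reference
        self.margin = margin
        self.lr = lr
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.scheduler_step = scheduler_step
        self.scheduler_gamma = scheduler_gamma
        self.random_state = random_state

    def _prepare(self, X) -> list[np.ndarray]:
        if not isinstance(X, (list, tuple)):
            raise ValueError("PMLDFClassifier expects a list/tuple of "
                             "per-stream signal matrices")
        lengths = self.input_lengths or (None,) * len(X)
        if len(lengths) != len(X):
            raise ValueError("input_lengths must match the number of streams")
        mats = [prepare_signals(x, l)[:, None, :] for x, l in zip(X, lengths)]
        if len({m.shape[0] for m in mats}) != 1:
            raise ValueError("streams must have equal numbers of trials")
        return mats

    def fit(self, X, y, X_val=None, y_val=None):
        if self.head not in ("softmax", "siamese"):
            raise ValueError(f"unknown head {self.head!r}")
        mats = self._prepare(X)
        y_idx = self._encode_labels(y)
        C = len(self.classes_)
        spec = self.spec if self.spec is not None \
            else default_pmldf_spec(n_streams=len(mats))
        rng = np.random.default_rng(
            np.random.SeedSequence([self.random_state, 0xF05]))
        n_classes = C if self.head == "softmax" else None
        self.model_ = PMLDF(spec, rng, embed_dim=self.embed_dim,
                            n_classes=n_classes)

        if X_val is not None:
            val_mats = self._prepare(X_val)
            yv = np.array([list(self.classes_).index(v) for v in y_val])
        else:
            val_mats, yv = mats, y_idx

        batched_multi = self._batched_multi

        if self.head == "softmax":
            from .autograd import softmax_cross_entropy

            def loss_fn(idx):
                logits = self.model_([Tensor(m[idx]) for m in mats])
                return softmax_cross_entropy(logits, y_idx[idx])

            def val_fn():
                scores = batched_multi(val_mats, self.model_)
                return float(np.mean(scores.argmax(axis=1) == yv))

            self.history_ = fit_loop(self.model_, loss_fn, val_fn,
                                     mats[0].shape[0], self._train_config())
        else:
            ref_rows: list[int] = []
            for ci in range(C):
                rows = np.flatnonzero(y_idx == ci)
                take = min(self.n_reference, len(rows))
                ref_rows.extend(rng.choice(rows, size=take, replace=False))
            self.reference_rows_ = np.array(ref_rows)
            ref_class = y_idx[self.reference_rows_]
            ref_mats = [m[self.reference_rows_] for m in mats]
            onehot = np.zeros((C, len(ref_class)))
            onehot[ref_class, np.arange(len(ref_class))] = 1.0
            ref_w = onehot / onehot.sum(axis=1, keepdims=True)

            def refs_tensor() -> Tensor:
                emb = self.model_.embed([Tensor(m) for m in ref_mats])
                return Tensor(ref_w) @ emb

            def loss_fn(idx):
                emb = self.model_.embed([Tensor(m[idx]) for m in mats])
                return siamese_cosine_loss(emb, refs_tensor(), y_idx[idx],
                                           self.margin)

            def val_fn():
                refs = refs_tensor().data
                emb = batched_multi(val_mats, self.model_.embed)
                return float(np.mean(_cosine_argmax(emb, refs) == yv))

            self.history_ = fit_loop(self.model_, loss_fn, val_fn,
                                     mats[0].shape[0], self._train_config())
            self.model_.eval()
            emb = batched_multi(ref_mats, self.model_.embed)
            self.reference_vectors_ = ref_w @ emb
        return self

    @staticmethod
    def _batched_multi(mats_in, forward):
        outs = []
        n = mats_in[0].shape[0]
        for start in range(0, n, _EVAL_CHUNK):
            xs = [Tensor(m[start:start + _EVAL_CHUNK]) for m in mats_in]
            outs.append(forward(xs).data)
        return np.vstack(outs)

    def decision_function(self, X):
        mats = self._prepare(X)
        self.model_.eval()
        if self.head == "softmax":
            return self._batched_multi(mats, self.model_)
        emb = self._batched_multi(mats, self.model_.embed)
        return _cosine_matrix(emb, self.reference_vectors_)

    def predict(self, X):
        return self.classes_[self.decision_function(X).argmax(axis=1)]

    def embed(self, X) -> np.ndarray:
        mats = self._prepare(X)
        self.model_.eval()
        return self._batched_multi(mats, self.model_.embed)
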