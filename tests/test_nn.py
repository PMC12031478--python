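"""Autograd correctness, architecture contracts and the training protocol."""

import numpy as np
import pytest

from silentspeech.nn import (Adam, BatchNorm1d, CNNModel, FEN, FENSpec,
                             PMLDF, PMLDFSpec, SiameseClassifier, Tensor,
                             TrainConfig, adaptive_avg_pool1d, concat,
                             conv1d, default_pmldf_spec, fit_loop,
                             reduced_fen_spec, scheduled_lr,
                             siamese_cosine_loss, softmax_cross_entropy,
                             CNNClassifier)
from silentspeech.nn.training import cosine_similarity_matrix


# ---------------------------------------------------------------------------
# numerical gradient checks
# ---------------------------------------------------------------------------

def _num_grad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x[i] += eps
        fp = f()
        x[i] -= 2 * eps
        fm = f()
        x[i] += eps
        g[i] = (fp - fm) / (2 * eps)
    return g


def _assert_close(analytic, numeric, tol=1e-7):
    scale = max(np.abs(numeric).max(), 1.0)
    assert np.abs(analytic - numeric).max() / scale < tol


def test_conv1d_gradients(rng):
    x = Tensor(rng.standard_normal((2, 3, 11)), requires_grad=True)
    w = Tensor(rng.standard_normal((4, 3, 5)) * 0.3, requires_grad=True)
    b = Tensor(rng.standard_normal(4) * 0.1, requires_grad=True)
    out = conv1d(x, w, b, padding=2)
    ((out * out * out).sum()).backward()
    for t in (x, w, b):
        def f(t=t):
            o = conv1d(Tensor(x.data), Tensor(w.data), Tensor(b.data), 2)
            return float((o.data ** 3).sum())
        _assert_close(t.grad, _num_grad(f, t.data))


def test_adaptive_pool_gradients_nondivisible(rng):
    x = Tensor(rng.standard_normal((2, 3, 13)), requires_grad=True)
    (adaptive_avg_pool1d(x, 5) ** 2.0).sum().backward()
    def f():
        return float((adaptive_avg_pool1d(Tensor(x.data), 5).data ** 2).sum())
    _assert_close(x.grad, _num_grad(f, x.data))


def test_batchnorm_training_gradients(rng):
    bn = BatchNorm1d(3)
    x = Tensor(rng.standard_normal((4, 3, 6)), requires_grad=True)
    ((bn(x) ** 3.0).sum()).backward()
    def f():
        bn2 = BatchNorm1d(3)
        return float((bn2(Tensor(x.data)).data ** 3).sum())
    _assert_close(x.grad, _num_grad(f, x.data), tol=1e-5)


def test_softmax_cross_entropy_gradients(rng):
    logits = Tensor(rng.standard_normal((5, 4)), requires_grad=True)
    target = np.array([0, 1, 2, 3, 1])
    softmax_cross_entropy(logits, target).backward()
    def f():
        return float(softmax_cross_entropy(Tensor(logits.data), target).data)
    _assert_close(logits.grad, _num_grad(f, logits.data))


def test_siamese_loss_gradients(rng):
    emb = Tensor(rng.standard_normal((6, 8)), requires_grad=True)
    refs = Tensor(rng.standard_normal((3, 8)), requires_grad=True)
    y = np.array([0, 1, 2, 0, 1, 2])
    siamese_cosine_loss(emb, refs, y, margin=0.1).backward()
    for t in (emb, refs):
        def f():
            return float(siamese_cosine_loss(Tensor(emb.data),
                                             Tensor(refs.data), y, 0.1).data)
        _assert_close(t.grad, _num_grad(f, t.data))


def test_concat_and_broadcast_gradients(rng):
    a = Tensor(rng.standard_normal((2, 3, 4)), requires_grad=True)
    b = Tensor(rng.standard_normal((2, 2, 4)), requires_grad=True)
    c = Tensor(rng.standard_normal((1, 1, 4)), requires_grad=True)
    ((concat([a, b], axis=1) * c) ** 2.0).sum().backward()
    for t in (a, b, c):
        def f():
            out = (concat([Tensor(a.data), Tensor(b.data)], axis=1)
                   * Tensor(c.data)) ** 2.0
            return float(out.data.sum())
        _assert_close(t.grad, _num_grad(f, t.data))


# ---------------------------------------------------------------------------
# loss identities
# ---------------------------------------------------------------------------

def test_siamese_loss_zero_at_perfect_geometry():
    refs = np.eye(3)
    emb = refs[np.array([0, 1, 2])]
    loss = siamese_cosine_loss(Tensor(emb), Tensor(refs),
                               np.array([0, 1, 2]), margin=0.0)
    assert loss.item() == pytest.approx(0.0, abs=1e-9)


def test_siamese_loss_nonnegative(rng):
    for _ in range(20):
        emb = Tensor(rng.standard_normal((5, 7)))
        refs = Tensor(rng.standard_normal((4, 7)))
        y = rng.integers(0, 4, 5)
        assert siamese_cosine_loss(emb, refs, y).item() >= -1e-12


def test_cosine_matrix_values(rng):
    emb = np.array([[1.0, 0.0], [0.0, 2.0]])
    refs = np.array([[2.0, 0.0], [1.0, 1.0]])
    cos = cosine_similarity_matrix(Tensor(emb), Tensor(refs)).data
    assert cos[0, 0] == pytest.approx(1.0, abs=1e-9)
    assert cos[0, 1] == pytest.approx(1 / np.sqrt(2), abs=1e-9)
    assert cos[1, 0] == pytest.approx(0.0, abs=1e-9)


# ---------------------------------------------------------------------------
# architecture contracts
# ---------------------------------------------------------------------------

def test_fen_output_shape_independent_of_input_length(rng):
    fen = FEN(reduced_fen_spec(4), rng)
    shapes = set()
    for L in (4096, 2048, 512):
        outs = fen.forward(Tensor(rng.standard_normal((3, 1, L))))
        assert len(outs) == 4
        shapes.add(tuple(o.shape for o in outs))
    assert len(shapes) == 1
    assert outs[-1].shape == (3, 64, 8)


def test_fen_rejects_too_short_input(rng):
    fen = FEN(reduced_fen_spec(4), rng)
    with pytest.raises(ValueError, match="shorter"):
        fen.forward(Tensor(rng.standard_normal((2, 1, 16))))


def test_zero_input_zero_output_without_bias(rng):
    """conv(0)=0, tanh(0)=0, inference batchnorm with unit statistics keeps
    0, pooling keeps 0: the whole FEN maps zero to zero when biases are off."""
    fen = FEN(reduced_fen_spec(3), rng, bias=False)
    fen.eval()
    outs = fen.forward(Tensor(np.zeros((2, 1, 256))))
    for o in outs:
        assert np.allclose(o.data, 0.0)


def test_fenspec_validation():
    with pytest.raises(ValueError, match="non-increasing"):
        FENSpec(n_layers=2, channels=(8, 8), pooled_lengths=(8, 16))
    with pytest.raises(ValueError):
        FENSpec(n_layers=0)
    spec = FENSpec()
    assert spec.n_layers == 7
    assert spec.pooled_lengths[0] >= spec.pooled_lengths[-1] == 16


def test_pmldf_handles_heterogeneous_lengths_and_scales(rng):
    spec3 = reduced_fen_spec(3)
    pm = PMLDF(PMLDFSpec((spec3, spec3), spec3), rng, n_classes=8)
    out = pm([Tensor(rng.standard_normal((4, 1, 4096))),
              Tensor(rng.standard_normal((4, 1, 2048)))])
    assert out.shape == (4, 8)
    # three streams: same output shape, wider fusion input
    pm3 = PMLDF(PMLDFSpec((spec3,) * 3, spec3), rng, n_classes=8)
    out3 = pm3([Tensor(rng.standard_normal((4, 1, 512)))] * 3)
    assert out3.shape == (4, 8)
    assert pm3.fusion_blocks[0].conv.weight.shape[1] == \
        pm.fusion_blocks[0].conv.weight.shape[1] + spec3.channels[0]


def test_pmldf_rejects_unpaired_batches(rng):
    pm = PMLDF(default_pmldf_spec(2, 2), rng, n_classes=3)
    with pytest.raises(ValueError, match="batch"):
        pm([Tensor(rng.standard_normal((4, 1, 64))),
            Tensor(rng.standard_normal((3, 1, 64)))])
    with pytest.raises(ValueError, match="fusion depth"):
        PMLDFSpec((reduced_fen_spec(2),) * 2, reduced_fen_spec(3))
    with pytest.raises(ValueError, match="2 sensor"):
        PMLDFSpec((reduced_fen_spec(2),), reduced_fen_spec(2))


def test_shared_weight_embedder_is_branch_invariant(rng):
    """The Siamese 'two branches' are one shared-weight network: embedding a
    trial twice (reference branch vs sample branch) is bitwise identical."""
    model = CNNModel(reduced_fen_spec(2), rng)
    model.eval()
    x = rng.standard_normal((3, 1, 64))
    e1 = model.embed(Tensor(x)).data
    e2 = model.embed(Tensor(x.copy())).data
    assert np.array_equal(e1, e2)


# ---------------------------------------------------------------------------
# training protocol
# ---------------------------------------------------------------------------

def test_scheduler_formula_exact():
    lr0 = 1e-3
    for k in range(6):
        assert scheduled_lr(lr0, 10 * k, 10, 0.992) == lr0 * 0.992 ** k
        if k:
            assert scheduled_lr(lr0, 10 * k - 1, 10, 0.992) \
                == lr0 * 0.992 ** (k - 1)


def test_fit_loop_records_scheduled_lr_and_stops_on_patience(rng):
    model = CNNModel(reduced_fen_spec(2), rng, n_classes=2)
    X = rng.standard_normal((8, 1, 64))
    y = np.array([0, 1] * 4)

    def loss_fn(idx):
        return softmax_cross_entropy(model(Tensor(X[idx])), y[idx])

    # frozen training (lr=0) cannot improve after the first epoch
    cfg = TrainConfig(lr=0.0, max_epochs=50, patience=1, batch_size=4, seed=0)
    hist = fit_loop(model, loss_fn, lambda: 0.5, len(X), cfg)
    assert hist.best_epoch == 0
    assert hist.stopped_epoch == 1  # exactly one non-improving epoch

    cfg = TrainConfig(lr=1e-3, max_epochs=25, patience=30, batch_size=4,
                      seed=0)
    model2 = CNNModel(reduced_fen_spec(2), rng, n_classes=2)
    def loss2(idx):
        return softmax_cross_entropy(model2(Tensor(X[idx])), y[idx])
    hist = fit_loop(model2, loss2, lambda: 0.5, len(X), cfg)
    want = [1e-3 * 0.992 ** (e // 10) for e in range(25)]
    assert hist.lr == want
    assert hist.stopped_epoch <= hist.best_epoch + cfg.patience


def test_early_stopping_restores_best_checkpoint(rng):
    model = CNNModel(reduced_fen_spec(2), rng, n_classes=2)
    X = rng.standard_normal((8, 1, 64))
    y = np.array([0, 1] * 4)
    accs = iter([0.3, 0.9, 0.2, 0.1, 0.1, 0.1])
    snapshots = {}

    def loss_fn(idx):
        return softmax_cross_entropy(model(Tensor(X[idx])), y[idx])

    def val_fn():
        acc = next(accs)
        snapshots[acc] = model.get_state()
        return acc

    cfg = TrainConfig(lr=1e-2, max_epochs=6, patience=3, batch_size=4, seed=1)
    hist = fit_loop(model, loss_fn, val_fn, len(X), cfg)
    assert hist.best_epoch == 1
    for a, b in zip(model.get_state(), snapshots[0.9]):
        assert np.array_equal(a, b)


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(scheduler_gamma=0.0)
    with pytest.raises(ValueError):
        TrainConfig(patience=0)


def test_adam_reduces_quadratic_loss():
    w = Tensor(np.array([5.0, -3.0]), requires_grad=True)
    opt = Adam([w], lr=0.2)
    for _ in range(200):
        w.grad = None
        loss = (w ** 2.0).sum()
        loss.backward()
        opt.step()
    assert np.abs(w.data).max() < 1e-2


def test_estimator_determinism(rng):
    X = rng.standard_normal((32, 128))
    y = np.array(["a", "b"] * 16)
    kw = dict(fen_spec=reduced_fen_spec(2), input_length=64, max_epochs=3,
              patience=5, random_state=7)
    p1 = CNNClassifier(**kw).fit(X, y).decision_function(X)
    p2 = CNNClassifier(**kw).fit(X, y).decision_function(X)
    assert np.array_equal(p1, p2)


def test_siamese_predicts_reference_class_exactly(rng):
    """A trial whose embedding coincides with a reference vector gets that
    class; orthogonal embeddings pick the only non-orthogonal reference."""
    clf = SiameseClassifier.__new__(SiameseClassifier)
    clf.classes_ = np.array(["a", "b", "c"])
    clf.reference_vectors_ = np.eye(3)
    clf.input_length = None
    emb = np.array([[0.0, 2.0, 0.0]])
    from silentspeech.nn.estimators import _cosine_matrix
    assert clf.classes_[_cosine_matrix(emb, clf.reference_vectors_)
                        .argmax(axis=1)][0] == "b"
    with pytest.raises(ValueError, match="zero-norm"):
        _cosine_matrix(np.zeros((1, 3)), clf.reference_vectors_)
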