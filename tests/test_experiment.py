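"""Splitting, training dynamics and accuracy metrics."""

import numpy as np
import pytest

import mirepr as m


class _StubModel:
    """Duck-typed predictor for metric tests."""

    def __init__(self, fn):
        self.fn = fn

    def predict(self, x, batch_size=256):
        return self.fn(x)


# ---------------------------------------------------------------------------
# splits

@pytest.mark.parametrize("n,sizes", [(9450, (7560, 945, 945)),
                                     (10, (8, 1, 1)),
                                     (100, (80, 10, 10)),
                                     (17, (15, 1, 1))])
def test_split_sizes_and_conservation(n, sizes):
    tr, va, te = m.split_dataset(n, m.SplitConfig(seed=3))
    assert (len(tr), len(va), len(te)) == sizes
    union = np.concatenate([tr, va, te])
    assert len(union) == n
    assert len(np.unique(union)) == n      # disjoint, covering


def test_split_determinism():
    a = m.split_dataset(1000, m.SplitConfig(seed=9))
    b = m.split_dataset(1000, m.SplitConfig(seed=9))
    c = m.split_dataset(1000, m.SplitConfig(seed=10))
    assert all(np.array_equal(x, y) for x, y in zip(a, b))
    assert not np.array_equal(a[1], c[1])


def test_split_empty_rejected():
    with pytest.raises(ValueError):
        m.split_dataset(0, m.SplitConfig())


def test_subject_unit_keeps_subjects_whole():
    subjects = np.repeat([f"S{i:03d}" for i in range(20)], 30)
    cfg = m.SplitConfig(seed=1, unit="subject")
    tr, va, te = m.split_dataset(len(subjects), cfg, subjects=subjects)
    for split in (tr, va, te):
        for s in np.unique(subjects[split]):
            assert np.isin(np.where(subjects == s)[0], split).all()
    assert len(tr) + len(va) + len(te) == len(subjects)


# ---------------------------------------------------------------------------
# metrics

def test_majority_predictor_accuracy():
    x = np.zeros((100, 4), dtype=np.float32)
    y = np.array([0] * 50 + [1] * 25 + [2] * 25)
    metrics = m.evaluate(_StubModel(lambda x: np.zeros(len(x), dtype=int)),
                         (x, y))
    assert metrics.accuracy == 0.5
    assert metrics.per_class_counts == {"T0": 50, "T1": 25, "T2": 25}


def test_perfect_predictor_diagonal():
    x = np.arange(30, dtype=np.float32).reshape(30, 1)
    y = np.arange(30) % 3
    metrics = m.evaluate(
        _StubModel(lambda x: x[:, 0].astype(int) % 3), (x, y))
    assert metrics.accuracy == 1.0
    assert np.array_equal(metrics.confusion, np.diag([10, 10, 10]))
    assert metrics.confusion.trace() == metrics.confusion.sum()


def test_accuracy_invariant_to_order():
    rng = np.random.default_rng(0)
    x = rng.standard_normal((60, 2)).astype(np.float32)
    y = rng.integers(0, 3, 60)
    stub = _StubModel(lambda v: (v[:, 0] > 0).astype(int))
    a = m.evaluate(stub, (x, y)).accuracy
    perm = rng.permutation(60)
    b = m.evaluate(stub, (x[perm], y[perm])).accuracy
    assert a == b


def test_evaluate_empty_rejected():
    with pytest.raises(ValueError):
        m.evaluate(_StubModel(lambda x: x), (np.empty((0, 2)), np.empty(0)))


def test_untrained_model_near_chance_on_balanced_labels():
    """Permutation-null: random-weight net scores ~1/3 on balanced classes."""
    zoo = m.model_zoo()
    model = m.build_model(zoo["cnn1d-1"], (1, 640), seed=123)
    rng = np.random.default_rng(7)
    x = rng.standard_normal((300, 1, 640)).astype(np.float32)
    y = np.arange(300) % 3
    acc = m.evaluate(model, (x, y)).accuracy
    # 4-sigma binomial band around p = 1/3 at n = 300
    assert abs(acc - 1 / 3) < 4 * np.sqrt((1 / 3) * (2 / 3) / 300)


# ---------------------------------------------------------------------------
# training

def _two_class_memorization_data():
    a = np.zeros((1, 640), dtype=np.float32)
    b = np.zeros((1, 640), dtype=np.float32)
    b[0, ::10] = 5.0
    x = np.stack([a, b] * 20)
    y = np.array([0, 1] * 20)
    return x, y


def test_memorizes_two_distinguishable_samples():
    x, y = _two_class_memorization_data()
    zoo = m.model_zoo()
    model = m.build_model(zoo["cnn1d-1"], (1, 640), seed=0)
    cfg = m.TrainConfig(epochs=30, batch_size=8, seed=0)
    model, history = m.train(model, (x, y), (x, y), cfg)
    assert m.evaluate(model, (x, y)).accuracy == 1.0


def test_training_is_deterministic():
    x, y = _two_class_memorization_data()
    zoo = m.model_zoo()
    histories = []
    for _ in range(2):
        model = m.build_model(zoo["cnn1d-2"], (1, 640), seed=4)
        cfg = m.TrainConfig(epochs=3, batch_size=8, seed=4)
        _, hist = m.train(model, (x, y), (x, y), cfg)
        histories.append(hist)
    assert histories[0] == histories[1]


def test_lr_schedule_monotone_nonincreasing():
    x, y = _two_class_memorization_data()
    zoo = m.model_zoo()
    model = m.build_model(zoo["cnn1d-1"], (1, 640), seed=0)
    # zero LR -> validation accuracy never improves after epoch 0 -> decay
    cfg = m.TrainConfig(learning_rate=1e-12, epochs=8, lr_patience=2,
                        batch_size=8, seed=0)
    _, hist = m.train(model, (x, y), (x, y), cfg)
    lrs = [h["lr"] for h in hist]
    assert all(b <= a for a, b in zip(lrs, lrs[1:]))
    assert lrs[-1] < lrs[0]


def test_divergence_reported_with_epoch():
    x, y = _two_class_memorization_data()
    x = x.copy()
    x[0, 0, 0] = np.nan
    zoo = m.model_zoo()
    model = m.build_model(zoo["cnn1d-1"], (1, 640), seed=0)
    with pytest.raises(m.DivergenceError, match="epoch 0"):
        m.train(model, (x, y), (x, y), m.TrainConfig(epochs=1, seed=0))


def test_shape_mismatch_rejected():
    zoo = m.model_zoo()
    model = m.build_model(zoo["cnn1d-1"], (1, 640), seed=0)
    x = np.zeros((4, 1, 320), dtype=np.float32)
    y = np.zeros(4, dtype=int)
    with pytest.raises(ValueError):
        m.train(model, (x, y), (x, y), m.TrainConfig(epochs=1))


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        m.SplitConfig(fractions=(0.5, 0.2, 0.2))
    with pytest.raises(ValueError):
        m.SplitConfig(unit="run")
    with pytest.raises(ValueError):
        m.TrainConfig(lr_factor=1.5)
    with pytest.raises(ValueError):
        m.TrainConfig(epochs=0)
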