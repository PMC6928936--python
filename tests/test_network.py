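import numpy as np
import pytest

from eegsr.network import (SRConfig, SRNetwork, SplitSpec, apply_sr,
                           build_sr_network, epochs_for_snr, load_model,
                           save_model, split_trials, train_sr)


@pytest.fixture(scope="module")
def net():
    return SRNetwork(SRConfig(seed=0))


# ---------------------------------------------------------------------------
# architecture
# ---------------------------------------------------------------------------

def test_parameter_count_matches_arithmetic(net):
    """Total parameters equal the hand-computed sum of kernel*in*out + bias
    over the eight layers."""
    expected = 0
    specs = [(13, 5, 1, 64), (13, 5, 64, 64), (13, 5, 64, 64),
             (13, 9, 64, 64), (13, 9, 64, 64), (13, 9, 64, 64),
             (13, 5, 64, 64), (7, 1, 64, 1)]
    for kh, kw, cin, cout in specs:
        expected += kh * kw * cin * cout + cout
    assert net.n_parameters == expected


@pytest.mark.parametrize("T", [512, 666, 100, 8])
def test_shape_preservation(net, T):
    x = np.random.default_rng(0).standard_normal((1, T, 64)).astype(np.float32)
    assert net.forward(x).shape == (1, T, 64)


def test_wrong_channel_count_rejected(net):
    with pytest.raises(ValueError, match="64"):
        net.forward(np.zeros((1, 64, 32), dtype=np.float32))
    with pytest.raises(ValueError, match="64-channel"):
        SRNetwork(SRConfig(), n_channels=32)


def test_epoch_schedule():
    assert [epochs_for_snr(s) for s in (100, 50, 10, 5, 1, 0.5, 0.1, 0.05, 0.01)] \
        == [40, 40, 80, 80, 150, 200, 200, 500, 500]
    assert epochs_for_snr(aep=True) == 300
    with pytest.raises(ValueError):
        epochs_for_snr(7)


# ---------------------------------------------------------------------------
# gradients (finite-difference oracle)
# ---------------------------------------------------------------------------

def test_backward_matches_finite_differences():
    rng = np.random.default_rng(5)
    net = SRNetwork(SRConfig(seed=1))
    x = rng.standard_normal((1, 16, 64)).astype(np.float32)
    y = rng.standard_normal((1, 16, 64)).astype(np.float32)

    def loss():
        out = net.forward(x, train=False)
        return float(np.mean((out.astype(np.float64) - y) ** 2))

    out = net.forward(x, train=True)
    net.backward((2.0 / out.size) * (out - y))
    h = 1e-2
    for li in [0, 1, 3, 5, 6, 7]:
        layer = net.layers[li]
        for arr, grad in ((layer.W, layer.dW), (layer.b, layer.db)):
            idx = tuple(rng.integers(0, s) for s in arr.shape)
            orig = arr[idx]
            arr[idx] = orig + h
            lp = loss()
            arr[idx] = orig - h
            lm = loss()
            arr[idx] = orig
            fd = (lp - lm) / (2 * h)
            assert grad[idx] == pytest.approx(fd, rel=2e-2, abs=1e-6), \
                f"layer {li} {'W' if arr is layer.W else 'b'}{idx}"


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n,expected", [(1000, (640, 160, 200)),
                                        (932, (596, 150, 186))])
def test_split_sizes(n, expected):
    for tr, va, te in split_trials(n, SplitSpec(seed=0)):
        assert (len(tr), len(va), len(te)) == expected
        allidx = np.concatenate([tr, va, te])
        assert len(np.unique(allidx)) == n  # disjoint and exhaustive


def test_split_deterministic():
    a = split_trials(100, SplitSpec(seed=42))
    b = split_trials(100, SplitSpec(seed=42))
    for (t1, v1, s1), (t2, v2, s2) in zip(a, b):
        assert np.array_equal(t1, t2) and np.array_equal(v1, v2) and np.array_equal(s1, s2)
    assert len(a) == 5


def test_split_too_few_trials():
    with pytest.raises(ValueError, match="too few"):
        split_trials(3)


# ---------------------------------------------------------------------------
# training and application
# ---------------------------------------------------------------------------

def test_zero_epochs_returns_initial_weights():
    cfg = SRConfig(max_epochs=0, seed=2)
    model = SRNetwork(cfg)
    w0 = model.get_weights()
    x = np.zeros((4, 16, 64), dtype=np.float32)
    _, hist = train_sr(model, x, x, cfg)
    assert hist["train_mse"] == [] and hist["val_mse"] == []
    for (W, b), l in zip(w0, model.layers):
        assert np.array_equal(W, l.W) and np.array_equal(b, l.b)


def test_training_reproducible_from_seed(rng):
    x = rng.standard_normal((6, 32, 64)).astype(np.float32)
    y = rng.standard_normal((6, 32, 64)).astype(np.float32)
    runs = []
    for _ in range(2):
        cfg = SRConfig(max_epochs=2, batch_size=2, seed=7)
        model, hist = train_sr(SRNetwork(cfg), x, y, cfg)
        runs.append((hist["train_mse"], model.get_weights()))
    assert runs[0][0] == runs[1][0]
    for (W1, b1), (W2, b2) in zip(runs[0][1], runs[1][1]):
        assert np.array_equal(W1, W2) and np.array_equal(b1, b2)


def test_identity_task_converges(clean_trials):
    """On the identity task (LR = HR) the training loss must collapse by at
    least 99.9% of its first-epoch value within the 40-epoch budget."""
    rng = np.random.default_rng(0)
    x = np.repeat(clean_trials.data[:, 96:160, :], 2, axis=0).astype(np.float32)
    x *= rng.uniform(0.5, 1.5, (8, 1, 1)).astype(np.float32)
    cfg = SRConfig(max_epochs=40, batch_size=2, seed=3)
    model = SRNetwork(cfg)
    _, hist = train_sr(model, x, x, cfg)
    assert hist["train_mse"][-1] < 1e-3 * hist["train_mse"][0]


def test_shape_mismatch_rejected():
    cfg = SRConfig(max_epochs=1)
    with pytest.raises(ValueError, match="shapes differ"):
        train_sr(SRNetwork(cfg), np.zeros((2, 16, 64), np.float32),
                 np.zeros((2, 32, 64), np.float32), cfg)


def test_apply_zero_final_layer_gives_zero(net, rng):
    model = SRNetwork(SRConfig(seed=0))
    model.layers[-1].W[:] = 0
    model.layers[-1].b[:] = 0
    out = apply_sr(model, rng.standard_normal((1, 32, 64)))
    assert np.all(out.data == 0)


def test_network_linear_with_zero_biases(rng):
    """With biases zeroed the stack of linear-activation layers is a linear
    operator: f(aX + bY) = a f(X) + b f(Y)."""
    model = SRNetwork(SRConfig(seed=4))
    for l in model.layers:
        l.b[:] = 0
    X = rng.standard_normal((1, 48, 64)).astype(np.float32)
    Y = rng.standard_normal((1, 48, 64)).astype(np.float32)
    lhs = model.forward(2 * X - 0.5 * Y)
    rhs = 2 * model.forward(X) - 0.5 * model.forward(Y)
    scale = np.abs(rhs).max()
    assert np.allclose(lhs, rhs, atol=1e-5 * scale)


def test_save_load_roundtrip(tmp_path, rng):
    cfg = SRConfig(max_epochs=1, batch_size=2, seed=9, patch_len=16)
    model = SRNetwork(cfg)
    x = rng.standard_normal((2, 32, 64)).astype(np.float32)
    train_sr(model, x, x, cfg)
    save_model(model, tmp_path / "m.npz")
    back = load_model(tmp_path / "m.npz")
    assert back.config == cfg
    xt = rng.standard_normal((1, 40, 64)).astype(np.float32)
    assert np.array_equal(model.forward(xt), back.forward(xt))


def test_build_sr_network_validates_input_shape():
    net = build_sr_network(SRConfig(), input_shape=(512, 64))
    assert net.n_parameters > 0
    with pytest.raises(ValueError):
        build_sr_network(SRConfig(), input_shape=(4, 64))
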