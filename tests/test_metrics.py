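import numpy as np
import pytest

import eegsr
from eegsr import (EpochArray, ErpComponent, N1_DEFAULT, P2_DEFAULT,
                   amplitude_error, error_source_count, extract_erp, focality,
                   localization_error, mse, pearson, pointwise_ttest,
                   sensor_component_errors)
from eegsr.beamformer import SourceMap, build_source_grid


# ---------------------------------------------------------------------------
# sensor metrics vs brute-force oracles
# ---------------------------------------------------------------------------

def test_mse_trivial_cases(rng):
    x = EpochArray(rng.standard_normal((2, 6, 3)), labels=list("abc"))
    assert np.allclose(mse(x, x), 0)
    shifted = EpochArray(x.data + 1.5, labels=list("abc"))
    assert np.allclose(mse(x, shifted), 1.5**2)


def test_mse_matches_double_loop(rng):
    a = rng.standard_normal((3, 5, 4))
    b = rng.standard_normal((3, 5, 4))
    got = mse(a, b)
    for tr in range(3):
        acc = 0.0
        for t in range(5):
            for c in range(4):
                acc += (a[tr, t, c] - b[tr, t, c]) ** 2
        assert got[tr] == pytest.approx(acc / 20, abs=1e-12)


def test_pearson_trivial_and_bruteforce(rng):
    x = rng.standard_normal((2, 10, 3))
    assert np.allclose(pearson(x, x), 1.0)
    assert np.allclose(pearson(x, -x), -1.0)
    y = rng.standard_normal((2, 10, 3))
    got = pearson(x, y)
    for tr in range(2):
        a, b = x[tr].ravel(), y[tr].ravel()
        cov = np.mean((a - a.mean()) * (b - b.mean()))
        ref = cov / (a.std() * b.std())
        assert got[tr] == pytest.approx(ref, abs=1e-12)
    with pytest.raises(ValueError, match="constant"):
        pearson(np.zeros((1, 4, 2)), y[:1, :4, :2])


# ---------------------------------------------------------------------------
# source metrics
# ---------------------------------------------------------------------------

def _map_with(grid, values):
    power = np.zeros(grid.n_voxels)
    for idx, v in values.items():
        power[idx] = v
    m = SourceMap(grid=grid, power=power)
    from eegsr.beamformer import normalize_threshold_detect
    return normalize_threshold_detect(m, 0.3)


@pytest.fixture(scope="module")
def coarse_grid():
    return build_source_grid(eegsr.HeadModel(), spacing_mm=20.0)


def test_amplitude_error_cases(coarse_grid):
    m1 = _map_with(coarse_grid, {10: 1.0, 40: 0.8})
    assert amplitude_error(m1, m1) == 0.0
    # uniform rescaling is removed by normalization
    m2 = SourceMap(grid=coarse_grid, power=m1.power * 7.0)
    from eegsr.beamformer import normalize_threshold_detect
    m2 = normalize_threshold_detect(m2, 0.3)
    assert amplitude_error(m1, m2) == pytest.approx(0.0, abs=1e-12)
    # hand computation on known maxima
    m3 = _map_with(coarse_grid, {10: 1.0, 40: 0.5})
    expected = (abs(1 - 1) + abs(0.8 - 0.5)) / 2
    assert amplitude_error(m1, m3) == pytest.approx(expected, abs=1e-12)


def test_localization_error_cases(coarse_grid):
    pos = coarse_grid.positions_mm
    m1 = _map_with(coarse_grid, {10: 1.0})
    assert localization_error(m1, m1) == 0.0
    # one lattice step apart
    j = int(np.argmin(np.where(
        np.linalg.norm(pos - pos[10], axis=1) > 0,
        np.linalg.norm(pos - pos[10], axis=1), np.inf)))
    m2 = _map_with(coarse_grid, {j: 1.0})
    assert localization_error(m1, m2) == pytest.approx(20.0)
    # brute-force norm on random peak pairs
    rng = np.random.default_rng(0)
    for _ in range(5):
        a, b = rng.integers(0, coarse_grid.n_voxels, 2)
        ma, mb = _map_with(coarse_grid, {int(a): 1.0}), _map_with(coarse_grid, {int(b): 1.0})
        ref = np.sqrt(np.sum((pos[a] - pos[b]) ** 2))
        assert localization_error(ma, mb) == pytest.approx(ref, abs=1e-12)
    with pytest.raises(ValueError, match="peak"):
        localization_error(m1, SourceMap(grid=coarse_grid, power=np.ones(coarse_grid.n_voxels)))


def test_focality(coarse_grid):
    m1 = _map_with(coarse_grid, {10: 1.0})
    assert focality(m1) == 1.0
    m4 = _map_with(coarse_grid, {10: 1.0, 11: 0.9, 12: 0.9, 13: 0.9})
    assert focality(m4) == 0.25
    raw = SourceMap(grid=coarse_grid, power=np.ones(coarse_grid.n_voxels))
    with pytest.raises(ValueError, match="threshold"):
        focality(raw)


def test_error_source_count(coarse_grid):
    pos = coarse_grid.positions_mm
    A, B = pos[3], pos[30]
    far = [p for p in pos if min(np.linalg.norm(p - A), np.linalg.norm(p - B)) > 40][0]
    assert error_source_count(np.array([A, B]), np.array([A, B])) == 0
    assert error_source_count(np.array([A, B]), np.array([A, far])) == 2
    assert error_source_count(np.array([A]), np.array([A, far])) == 1
    assert error_source_count(np.zeros((0, 3)), np.array([A])) == 1
    # randomized sets vs brute-force symmetric difference with 20mm matching
    rng = np.random.default_rng(1)
    for _ in range(10):
        pa = pos[rng.choice(len(pos), 3, replace=False)]
        pb = pos[rng.choice(len(pos), 3, replace=False)]
        got = error_source_count(pa, pb)
        d = np.linalg.norm(pa[:, None] - pb[None, :], axis=2)
        # brute force: maximum bipartite matching under 20 mm (greedy equals
        # optimal here because lattice spacing is 20 mm)
        match = 0
        used = set()
        for i in np.argsort(d.min(axis=1)):
            cands = [j for j in np.argsort(d[i]) if j not in used and d[i, j] <= 20.0]
            if cands:
                used.add(cands[0])
                match += 1
        assert got == (3 - match) + (3 - match)


# ---------------------------------------------------------------------------
# evoked components
# ---------------------------------------------------------------------------

def _avg_with_peaks(fs=512.0, n=666, t0=-0.3, n1=(-5.0, 0.070), p2=(3.0, 0.140)):
    t = t0 + np.arange(n) / fs
    x = np.zeros((1, n, 2))
    x[0, :, 0] = n1[0] * np.exp(-0.5 * ((t - n1[1]) / 0.01) ** 2) \
        + p2[0] * np.exp(-0.5 * ((t - p2[1]) / 0.02) ** 2)
    return EpochArray(x, fs=fs, t0=t0, labels=["CPz", "other"])


def test_extract_erp_known_peaks():
    avg = _avg_with_peaks()
    amp, lat = extract_erp(avg, N1_DEFAULT, "CPz")
    assert amp == pytest.approx(5.0, rel=1e-2)  # sample quantization
    assert lat == pytest.approx(70.0, abs=2.0)
    amp, lat = extract_erp(avg, P2_DEFAULT, "CPz")
    assert amp == pytest.approx(3.0, rel=1e-2)
    assert lat == pytest.approx(140.0, abs=2.0)


def test_extract_erp_flat_signal_degenerate():
    avg = EpochArray(np.zeros((1, 666, 1)), fs=512.0, t0=-0.3, labels=["CPz"])
    amp, lat = extract_erp(avg, N1_DEFAULT, "CPz")
    assert amp == 0.0
    assert lat == pytest.approx(N1_DEFAULT.window[0] * 1000, abs=2.0)


def test_extract_erp_window_errors():
    avg = _avg_with_peaks()
    with pytest.raises(ValueError, match="window"):
        extract_erp(avg, ErpComponent("N1", (5.0, 6.0), "negative"), "CPz")
    with pytest.raises(ValueError, match="polarity"):
        ErpComponent("N1", (0.04, 0.11), "sideways")


def test_sensor_component_errors():
    hr = {"N1": (5.0, 66.0), "P2": (6.1, 139.0)}
    d = {"N1": (4.5, 70.0), "P2": (4.8, 145.0)}
    amp, lat = sensor_component_errors(hr, d)
    assert amp == pytest.approx(abs(5.0 - 4.5) + abs(6.1 - 4.8))
    assert lat == pytest.approx(4.0 + 6.0)
    with pytest.raises(KeyError):
        sensor_component_errors({"N1": (1, 1)}, d)


# ---------------------------------------------------------------------------
# pointwise t-test
# ---------------------------------------------------------------------------

def test_ttest_identical_inputs_not_significant(rng):
    a = rng.standard_normal((10, 64, 3))
    mask = pointwise_ttest(a, a.copy(), downsample=8, alpha=0.01)
    assert mask.shape == (8, 3)
    assert not mask.any()


def test_ttest_downsample_count():
    a = np.random.default_rng(0).standard_normal((6, 666, 2))
    b = np.random.default_rng(1).standard_normal((6, 666, 2))
    mask = pointwise_ttest(a, b, downsample=8)
    assert mask.shape[0] == 84  # ceil(666 / 8)


def test_ttest_detects_real_difference(rng):
    a = rng.standard_normal((30, 40, 2))
    b = a + 2.0 + 0.1 * rng.standard_normal((30, 40, 2))
    mask = pointwise_ttest(a, b, downsample=1, alpha=0.01)
    assert mask.all()
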