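"""Hand-crafted features against independently coded naive oracles."""

import numpy as np
import pytest
from statsmodels.regression.linear_model import yule_walker

from hcsnet.handcrafted import (
    FeatureConfig,
    ar_coefficients,
    extract_handcrafted_batch,
    feature_names,
    frequency_domain_features,
    time_domain_features,
)
from hcsnet.preprocess import WindowSample
from hcsnet import extract_handcrafted


# ---------------------------------------------------------------- oracles

def oracle_time_domain(x, zc_thr=0.0, ssc_thr=0.0):
    """Naive-loop implementations of the amplitude/count statistics."""
    n = len(x)
    mav = sum(abs(v) for v in x) / n
    ssi = sum(v * v for v in x)
    wl = sum(abs(x[i + 1] - x[i]) for i in range(n - 1))
    rms = (ssi / n) ** 0.5
    zc = 0
    for i in range(n - 1):
        if x[i] * x[i + 1] < 0 and abs(x[i] - x[i + 1]) >= zc_thr:
            zc += 1
    ssc = 0
    for i in range(1, n - 1):
        d1, d2 = x[i] - x[i - 1], x[i] - x[i + 1]
        if d1 * d2 > 0 and max(abs(d1), abs(d2)) >= ssc_thr:
            ssc += 1
    return {"MAV": mav, "SSI": ssi, "WL": wl, "RMS": rms, "ZC": zc, "SSC": ssc}


def oracle_periodogram(x, fs):
    """One-sided periodogram by direct DFT summation (density scaling)."""
    n = len(x)
    n_bins = n // 2 + 1
    freqs = np.array([j * fs / n for j in range(n_bins)])
    p = np.zeros(n_bins)
    for j in range(n_bins):
        re = sum(x[t] * np.cos(2 * np.pi * j * t / n) for t in range(n))
        im = -sum(x[t] * np.sin(2 * np.pi * j * t / n) for t in range(n))
        val = (re * re + im * im) / (fs * n)
        if j not in (0, n // 2) or (j == n // 2 and n % 2 == 1):
            val *= 2.0
        p[j] = val
    return freqs, p


def oracle_fd(x, fs):
    freqs, p = oracle_periodogram(x, fs)
    mnp = p.mean()
    pkf = freqs[int(np.argmax(p))]
    csum = np.cumsum(p)
    mdf = freqs[int(np.argmin(csum < csum[-1] / 2))]
    return {"MNP": mnp, "PKF": pkf, "MDF": mdf}


# ---------------------------------------------------------------- tests

def test_hand_computed_example():
    x = np.array([1.0, -2.0, 3.0, -4.0])
    f = time_domain_features(x)
    assert f["MAV"] == pytest.approx(2.5)
    assert f["SSI"] == pytest.approx(30.0)
    assert f["WL"] == pytest.approx(15.0)
    assert f["RMS"] == pytest.approx(np.sqrt(7.5))
    assert f["ZC"] == 3
    assert f["SSC"] == 2


def test_constant_window_degenerate():
    x = np.full(50, 3.0)
    f = time_domain_features(x)
    assert f["MAV"] == 3.0
    assert f["SSI"] == pytest.approx(50 * 9.0)
    assert f["WL"] == 0.0
    assert f["ZC"] == 0
    assert f["SSC"] == 0


def test_time_domain_matches_loop_oracle(rng):
    for _ in range(10):
        x = rng.standard_normal(300)
        got = time_domain_features(x)
        want = oracle_time_domain(list(x))
        for k in want:
            assert got[k] == pytest.approx(want[k], rel=1e-12), k


def test_ar_zero_variance_convention():
    assert np.allclose(ar_coefficients(np.zeros(300)), 0.0)
    assert np.allclose(ar_coefficients(np.full(300, 2.5)), 0.0)


def test_ar_recovers_ar1_process():
    rng = np.random.default_rng(7)
    x = np.zeros(10_000)
    for t in range(1, len(x)):
        x[t] = 0.9 * x[t - 1] + rng.standard_normal()
    a = ar_coefficients(x)
    assert 0.85 <= a[0] <= 0.95
    assert np.all(np.abs(a[1:]) <= 0.05)


def test_ar_satisfies_normal_equations(rng):
    x = rng.standard_normal(300)
    a = ar_coefficients(x)
    xd = x - x.mean()
    n, p = len(x), 6
    r = np.array([xd[k:] @ xd[: n - k] / n for k in range(p + 1)])
    big_r = r[np.abs(np.subtract.outer(np.arange(p), np.arange(p)))]
    assert np.linalg.norm(big_r @ a - r[1:]) <= 1e-8


def test_ar_matches_statsmodels(rng):
    """Cross-check against an independent Yule-Walker implementation."""
    for _ in range(5):
        x = rng.standard_normal(300)
        a = ar_coefficients(x)
        rho, _ = yule_walker(x, order=6, method="mle", demean=True)
        assert np.allclose(a, rho, atol=1e-8)


def test_fd_single_line():
    t = np.arange(300) / 1500.0
    x = np.sin(2 * np.pi * 100.0 * t)  # on-bin: 100 Hz = 20 * 5 Hz
    f = frequency_domain_features(x, FeatureConfig(fs_hz=1500))
    assert f["PKF"] == pytest.approx(100.0)
    assert f["MDF"] == pytest.approx(100.0)


def test_fd_matches_dft_oracle(rng):
    t = np.arange(300) / 1500.0
    signals = [np.sin(2 * np.pi * 100.0 * t), rng.standard_normal(300)]
    for x in signals:
        got = frequency_domain_features(x, FeatureConfig(fs_hz=1500))
        want = oracle_fd(x, 1500)
        assert got["MNP"] == pytest.approx(want["MNP"], rel=1e-9)
        assert got["PKF"] == want["PKF"]
        assert got["MDF"] == want["MDF"]


def test_fd_tie_breaks_to_lowest_bin():
    t = np.arange(300) / 1500.0
    x = np.sin(2 * np.pi * 50.0 * t) + np.sin(2 * np.pi * 200.0 * t)
    f = frequency_domain_features(x, FeatureConfig(fs_hz=1500))
    assert f["PKF"] == pytest.approx(50.0)
    assert f["MDF"] == pytest.approx(50.0)


def test_block_lengths_and_channel_equivariance(rng):
    w = rng.standard_normal((5, 300))
    cfg = FeatureConfig(fs_hz=1500)
    hv = extract_handcrafted(WindowSample(w, "standing", "S1", 0, 0), cfg)
    assert hv.f_td.shape == (60,)
    assert hv.f_fd.shape == (15,)
    perm = [3, 0, 4, 1, 2]
    hv2 = extract_handcrafted(WindowSample(w[perm], "standing", "S1", 0, 0), cfg)
    assert np.allclose(hv2.f_td.reshape(5, 12), hv.f_td.reshape(5, 12)[perm])
    assert np.allclose(hv2.f_fd.reshape(5, 3), hv.f_fd.reshape(5, 3)[perm])
    # duplicated channel -> duplicated block
    dup = np.vstack([w[:1], w[:1]])
    hv3 = extract_handcrafted(WindowSample(dup, "standing", "S1", 0, 0), cfg)
    assert np.allclose(hv3.f_td[:12], hv3.f_td[12:])


def test_ar_scalar_mode_gives_seven_per_channel(rng):
    w = rng.standard_normal((5, 300))
    td, fd = extract_handcrafted_batch(w[None], FeatureConfig(fs_hz=1500, ar_scalar_mode=True))
    assert td.shape == (1, 35)
    assert fd.shape == (1, 15)
    td_names, _ = feature_names(5, FeatureConfig(ar_scalar_mode=True))
    assert len(td_names) == 35


def test_scale_behaviour(rng):
    x = rng.standard_normal(300)
    cfg = FeatureConfig(fs_hz=1500)
    base_td = time_domain_features(x, cfg)
    base_fd = frequency_domain_features(x, cfg)
    base_ar = ar_coefficients(x, cfg)
    s = 7.5
    td = time_domain_features(s * x, cfg)
    fd = frequency_domain_features(s * x, cfg)
    assert td["MAV"] == pytest.approx(s * base_td["MAV"])
    assert td["WL"] == pytest.approx(s * base_td["WL"])
    assert td["RMS"] == pytest.approx(s * base_td["RMS"])
    assert td["SSI"] == pytest.approx(s**2 * base_td["SSI"])
    assert td["ZC"] == base_td["ZC"] and td["SSC"] == base_td["SSC"]
    assert fd["PKF"] == base_fd["PKF"] and fd["MDF"] == base_fd["MDF"]
    assert fd["MNP"] == pytest.approx(s**2 * base_fd["MNP"])
    assert np.allclose(ar_coefficients(s * x, cfg), base_ar)
    # RMS^2 * N = SSI exactly
    assert td["RMS"] ** 2 * 300 == pytest.approx(td["SSI"], rel=1e-12)


def test_mdf_between_occupied_bins(rng):
    for _ in range(5):
        x = rng.standard_normal(300)
        fd = frequency_domain_features(x, FeatureConfig(fs_hz=1500))
        assert 0.0 <= fd["MDF"] <= 750.0


def test_short_window_errors():
    with pytest.raises(ValueError):
        time_domain_features(np.array([1.0]))
    with pytest.raises(ValueError):
        frequency_domain_features(np.array([1.0, 2.0]))
    with pytest.raises(ValueError):
        ar_coefficients(np.arange(5.0))  # length <= order
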