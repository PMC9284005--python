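"""Hand-crafted time- and frequency-domain sEMG features.

Per channel, the time-domain block holds MAV, SSI, WL, RMS, ZC, SSC and the
six coefficients of an order-6 autoregressive model; the frequency-domain
block holds MNP, PKF and MDF from a one-sided rectangular-window periodogram.
Definitions follow the conventions standard in myoelectric pattern
recognition:

    MAV = (1/N) sum |x_i|                 SSI = sum x_i^2
    WL  = sum |x_{i+1} - x_i|             RMS = sqrt(SSI / N)
    ZC  = #{i : x_i x_{i+1} < 0 and |x_i - x_{i+1}| >= thr_zc}
    SSC = #{i : (x_i - x_{i-1})(x_i - x_{i+1}) > 0
               and max(|x_i - x_{i-1}|, |x_i - x_{i+1}|) >= thr_ssc}

AR coefficients are Yule-Walker estimates (biased autocovariance, demeaned
signal) in the convention ``x_t ~ sum_k a_k x_{t-k}``; a zero-variance window
returns all-zero coefficients. PKF/MDF ties break toward the lowest
frequency bin and the DC bin counts toward total power.

The per-channel time-domain block is 12-dimensional by default. A
``ar_scalar_mode`` flag collapses the AR member to its first coefficient,
giving the 7-features-per-channel layout some of the literature quotes; the
full 6-coefficient block is the default because it keeps information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps

from hcsnet.preprocess import WindowSample

TD_NAMES = ("MAV", "SSI", "WL", "RMS", "ZC", "SSC")
FD_NAMES = ("MNP", "PKF", "MDF")


@dataclass
class FeatureConfig:
    zc_threshold: float = 0.0
    ssc_threshold: float = 0.0
    ar_order: int = 6
    fs_hz: int = 1500
    ar_scalar_mode: bool = False  # collapse AR block to a1 only (7 features/channel)

    def __post_init__(self) -> None:
        if self.zc_threshold < 0 or self.ssc_threshold < 0:
            raise ValueError("thresholds must be >= 0")
        if self.ar_order < 1:
            raise ValueError("ar_order must be >= 1")

    @property
    def n_td(self) -> int:
        return 7 if self.ar_scalar_mode else 6 + self.ar_order

    @property
    def n_fd(self) -> int:
        return 3


@dataclass
class HandcraftedVector:
    """Per-window feature blocks: f_td (C * n_td) and f_fd (C * 3)."""

    f_td: np.ndarray
    f_fd: np.ndarray
    channel_order: Sequence[str] = field(default_factory=list)


def time_domain_features(x: np.ndarray, cfg: FeatureConfig | None = None) -> dict[str, float]:
    """MAV, SSI, WL, RMS, ZC, SSC of a single-channel window."""
    cfg = cfg or FeatureConfig()
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError(f"need a 1-D window of length >= 2, got shape {x.shape}")
    n = x.size
    mav = float(np.mean(np.abs(x)))
    ssi = float(np.sum(x**2))
    wl = float(np.sum(np.abs(np.diff(x))))
    rms = float(np.sqrt(ssi / n))
    d = np.diff(x)
    zc = int(np.sum((x[:-1] * x[1:] < 0) & (np.abs(d) >= cfg.zc_threshold)))
    if n >= 3:
        d1 = x[1:-1] - x[:-2]
        d2 = x[1:-1] - x[2:]
        ssc = int(
            np.sum((d1 * d2 > 0) & (np.maximum(np.abs(d1), np.abs(d2)) >= cfg.ssc_threshold))
        )
    else:
        ssc = 0
    return {"MAV": mav, "SSI": ssi, "WL": wl, "RMS": rms, "ZC": zc, "SSC": ssc}


def _yule_walker_batch(xs: np.ndarray, order: int) -> np.ndarray:
    """Yule-Walker AR fits for a batch of rows (M, N) -> (M, order).

    Biased (1/N) autocovariances of the demeaned rows; zero-variance rows
    yield all-zero coefficients by convention.
    """
    xs = np.asarray(xs, dtype=float)
    m, n = xs.shape
    if n <= order:
        raise ValueError(f"window length {n} must exceed ar_order {order}")
    xd = xs - xs.mean(axis=1, keepdims=True)
    r = np.empty((m, order + 1))
    for k in range(order + 1):
        r[:, k] = np.einsum("ij,ij->i", xd[:, k:], xd[:, : n - k]) / n
    coefs = np.zeros((m, order))
    live = r[:, 0] > 0
    if np.any(live):
        idx = np.abs(np.arange(order)[:, None] - np.arange(order)[None, :])
        big_r = r[live][:, idx]  # (m_live, p, p) Toeplitz
        rhs = r[live][:, 1:]
        try:
            coefs[live] = np.linalg.solve(big_r, rhs[..., None])[..., 0]
        except np.linalg.LinAlgError:
            for i in np.flatnonzero(live):
                coefs[i] = np.linalg.lstsq(r[i][idx], r[i, 1:], rcond=None)[0]
    return coefs


def ar_coefficients(x: np.ndarray, cfg: FeatureConfig | None = None) -> np.ndarray:
    """Order-``ar_order`` Yule-Walker AR coefficients of one window."""
    cfg = cfg or FeatureConfig()
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D window")
    return _yule_walker_batch(x[None, :], cfg.ar_order)[0]


def _periodogram(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    f, p = sps.periodogram(x, fs=fs, window="boxcar", detrend=False, axis=-1)
    return f, p


def frequency_domain_features(x: np.ndarray, cfg: FeatureConfig | None = None) -> dict[str, float]:
    """MNP, PKF, MDF from the one-sided rectangular-window periodogram."""
    cfg = cfg or FeatureConfig()
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise ValueError(f"need a 1-D window of length >= 4, got shape {x.shape}")
    f, p = _periodogram(x, cfg.fs_hz)
    mnp = float(np.mean(p))
    pkf = float(f[int(np.argmax(p))])  # argmax takes the lowest bin on ties
    csum = np.cumsum(p)
    total = csum[-1]
    if total <= 0:
        mdf = 0.0
    else:
        mdf = float(f[int(np.searchsorted(csum, total / 2.0))])
    return {"MNP": mnp, "PKF": pkf, "MDF": mdf}


def feature_names(n_channels: int, cfg: FeatureConfig | None = None) -> tuple[list[str], list[str]]:
    """Column names for the f_td and f_fd blocks, channel-major."""
    cfg = cfg or FeatureConfig()
    if cfg.ar_scalar_mode:
        td = list(TD_NAMES) + ["AR1"]
    else:
        td = list(TD_NAMES) + [f"AR{k + 1}" for k in range(cfg.ar_order)]
    td_names = [f"ch{c + 1}_{name}" for c in range(n_channels) for name in td]
    fd_names = [f"ch{c + 1}_{name}" for c in range(n_channels) for name in FD_NAMES]
    return td_names, fd_names


def extract_handcrafted(w: WindowSample, cfg: FeatureConfig | None = None) -> HandcraftedVector:
    """Assemble per-channel blocks in channel order, then feature order."""
    cfg = cfg or FeatureConfig()
    td, fd = extract_handcrafted_batch(w.window[None, ...], cfg)
    return HandcraftedVector(f_td=td[0], f_fd=fd[0])


def extract_handcrafted_batch(
    windows: np.ndarray, cfg: FeatureConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized extraction over a (M, C, W) stack -> (M, C*n_td), (M, C*3)."""
    cfg = cfg or FeatureConfig()
    windows = np.asarray(windows, dtype=float)
    if windows.ndim != 3:
        raise ValueError(f"expected (M, C, W) stack, got shape {windows.shape}")
    m, c, w = windows.shape
    if w < max(4, cfg.ar_order + 1):
        raise ValueError(f"window length {w} too short for configured features")
    flat = windows.reshape(m * c, w)

    mav = np.mean(np.abs(flat), axis=1)
    ssi = np.sum(flat**2, axis=1)
    wl = np.sum(np.abs(np.diff(flat, axis=1)), axis=1)
    rms = np.sqrt(ssi / w)
    d = np.diff(flat, axis=1)
    zc = np.sum((flat[:, :-1] * flat[:, 1:] < 0) & (np.abs(d) >= cfg.zc_threshold), axis=1)
    d1 = flat[:, 1:-1] - flat[:, :-2]
    d2 = flat[:, 1:-1] - flat[:, 2:]
    ssc = np.sum(
        (d1 * d2 > 0) & (np.maximum(np.abs(d1), np.abs(d2)) >= cfg.ssc_threshold), axis=1
    )
    ar = _yule_walker_batch(flat, cfg.ar_order)
    if cfg.ar_scalar_mode:
        ar = ar[:, :1]
    td = np.column_stack([mav, ssi, wl, rms, zc, ssc, ar])

    f, p = _periodogram(flat, cfg.fs_hz)
    mnp = np.mean(p, axis=1)
    pkf = f[np.argmax(p, axis=1)]
    csum = np.cumsum(p, axis=1)
    total = csum[:, -1]
    half = total / 2.0
    mdf_idx = np.array([int(np.searchsorted(csum[i], half[i])) for i in range(m * c)])
    mdf = np.where(total > 0, f[np.minimum(mdf_idx, len(f) - 1)], 0.0)
    fd = np.column_stack([mnp, pkf, mdf])

    n_td = td.shape[1]
    return td.reshape(m, c * n_td), fd.reshape(m, c * 3)
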