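"""Sliding-window TDAR feature extraction for multichannel EMG.

Per analysis window (100 ms, 60 ms overlap -> 40 ms step) and channel, ten
features are computed: the Hudgins time-domain set — mean absolute value
(MAV), MAV slope (MAVS), zero crossings (ZC), slope sign changes (SSC) — and
the six coefficients of an order-6 autoregressive model adapted by an LMS
linear prediction filter.

At the 1024 Hz working rate the 100 ms window is 102 samples (floored) and
the 40 ms step is 41 samples (rounded); both are fixed here for
reproducibility since neither is integral at the study's rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import EmgRecording

__all__ = [
    "WindowSpec",
    "LmsConfig",
    "FeatureMatrix",
    "FEATURE_NAMES",
    "mav",
    "mavs",
    "zero_crossings",
    "slope_sign_changes",
    "ar_coefficients_lms",
    "extract_features",
    "n_windows",
]

FEATURE_NAMES = ("MAV", "MAVS", "ZC", "SSC", "AR1", "AR2", "AR3", "AR4", "AR5", "AR6")
N_FEATURES_PER_CHANNEL = len(FEATURE_NAMES)


class InstabilityError(RuntimeError):
    """LMS adaptation diverged; try a smaller step size."""


@dataclass(frozen=True)
class WindowSpec:
    """Analysis windowing: 100 ms windows overlapped by 60 ms (40 ms step)."""

    length_ms: float = 100.0
    overlap_ms: float = 60.0

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_ms < self.length_ms:
            raise ValueError("require 0 <= overlap < length")

    def window_samples(self, rate_hz: float) -> int:
        return int(math.floor(self.length_ms * rate_hz / 1000.0))

    def step_samples(self, rate_hz: float) -> int:
        return int(round((self.length_ms - self.overlap_ms) * rate_hz / 1000.0))


@dataclass(frozen=True)
class LmsConfig:
    """LMS linear-prediction settings for the AR feature.

    Windows are normalized to unit variance before adaptation, which makes
    ``step_size`` scale-free; coefficients are adapted from zero over
    ``n_passes`` sweeps of the window. The defaults trade adaptation speed
    for low steady-state misadjustment, so long-window estimates converge
    near the Wiener solution.
    """

    order: int = 6
    step_size: float = 0.002
    n_passes: int = 8
    divergence_bound: float = 1e3


@dataclass
class FeatureMatrix:
    """Per-window feature vectors: ``values`` is (n_windows, n_channels*10)."""

    values: np.ndarray
    window_starts: np.ndarray
    spec: WindowSpec
    rate_hz: float
    column_names: tuple[str, ...] = field(default_factory=tuple)

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]


def n_windows(n_samples: int, win_len: int, step: int) -> int:
    """Window count for full windows: floor((N - win)/step) + 1."""
    if n_samples < win_len:
        return 0
    return (n_samples - win_len) // step + 1


# ---------------------------------------------------------------------------
# Single-window features (batch variants operate on a (W, L) window stack)
# ---------------------------------------------------------------------------


def mav(window: np.ndarray) -> float:
    """Mean absolute value of the window."""
    window = np.asarray(window, dtype=float)
    if window.size == 0:
        raise ValueError("mav: empty window")
    return float(np.mean(np.abs(window)))


def mavs(mav_sequence: np.ndarray) -> np.ndarray:
    """MAV slope: per-window difference MAV(next) - MAV(current).

    The final window carries 0 so the output aligns one-to-one with windows.
    A single window yields ``[0.]`` (degenerate).
    """
    m = np.asarray(mav_sequence, dtype=float)
    if m.ndim != 1 or m.size == 0:
        raise ValueError("mavs: need a 1-D sequence of at least one MAV value")
    out = np.zeros_like(m)
    if m.size >= 2:
        out[:-1] = np.diff(m)
    return out


def zero_crossings(window: np.ndarray, eps_amp: float = 0.0) -> int:
    """Count sign changes between consecutive samples exceeding ``eps_amp``.

    The amplitude dead zone suppresses baseline-noise crossings: a crossing is
    counted only when the two samples have opposite (strict) signs and differ
    by more than ``eps_amp``.
    """
    if eps_amp < 0:
        raise ValueError("eps_amp must be >= 0")
    x = np.asarray(window, dtype=float)
    a, b = x[:-1], x[1:]
    return int(np.count_nonzero((a * b < 0) & (np.abs(a - b) > eps_amp)))


def slope_sign_changes(window: np.ndarray, eps_amp: float = 0.0) -> int:
    """Count interior local extrema whose neighbor steps both exceed ``eps_amp``."""
    if eps_amp < 0:
        raise ValueError("eps_amp must be >= 0")
    x = np.asarray(window, dtype=float)
    if x.size < 3:
        raise ValueError("slope_sign_changes: window length must be >= 3")
    d1 = x[1:-1] - x[:-2]
    d2 = x[1:-1] - x[2:]
    return int(np.count_nonzero((d1 * d2 > 0) & (np.abs(d1) > eps_amp) & (np.abs(d2) > eps_amp)))


def ar_coefficients_lms(window: np.ndarray, config: LmsConfig = LmsConfig()) -> np.ndarray:
    """Order-``config.order`` AR coefficients by LMS adaptive linear prediction.

    Predictor form x_hat[n] = sum_k a_k x[n-k]; coefficients start at zero and
    are adapted over ``n_passes`` sweeps. Returns (a_1..a_order).
    """
    x = np.asarray(window, dtype=float)
    if x.size <= config.order:
        raise ValueError("window too short for the AR order")
    a = _ar_lms_batch(x[None, :], config)
    return a[0]


def _ar_lms_batch(windows: np.ndarray, config: LmsConfig) -> np.ndarray:
    """LMS-AR over a stack of windows (W, L) -> (W, order)."""
    p, mu = config.order, config.step_size
    x = np.asarray(windows, dtype=float)
    std = x.std(axis=1, keepdims=True)
    norm = np.where(std > 0, std, 1.0)
    x = x / norm
    w, n = x.shape
    a = np.zeros((w, p))
    for _ in range(config.n_passes):
        for t in range(p, n):
            past = x[:, t - 1: t - 1 - p: -1] if t - 1 - p >= 0 else x[:, t - 1:: -1][:, :p]
            err = x[:, t] - np.einsum("ij,ij->i", a, past)
            a += mu * err[:, None] * past
        if not np.all(np.isfinite(a)) or np.linalg.norm(a, axis=1).max() > config.divergence_bound:
            raise InstabilityError(
                "LMS adaptation diverged; reduce step_size or pass count"
            )
    return a


# ---------------------------------------------------------------------------
# Full extraction
# ---------------------------------------------------------------------------


def default_eps_amp(samples: np.ndarray, fraction: float = 0.01) -> np.ndarray:
    """Per-channel ZC/SSC dead zone: ``fraction`` x channel RMS."""
    return fraction * np.sqrt(np.mean(np.square(samples), axis=-1))


def extract_features(
    emg: EmgRecording,
    spec: WindowSpec = WindowSpec(),
    eps_amp: float | np.ndarray | None = None,
    lms: LmsConfig = LmsConfig(),
) -> FeatureMatrix:
    """Slide the analysis window over every channel and stack TDAR features.

    Window w covers samples ``[w*step, w*step + win_len)``. Columns are
    grouped by channel: ch1 MAV, MAVS, ZC, SSC, AR1..AR6, then ch2, ...
    ``eps_amp=None`` uses a per-channel dead zone of 1% of the channel RMS.
    """
    x = emg.samples
    if not np.all(np.isfinite(x)):
        raise ValueError("extract_features: non-finite samples")
    win = spec.window_samples(emg.rate_hz)
    step = spec.step_samples(emg.rate_hz)
    n_win = n_windows(emg.n_samples, win, step)
    if n_win < 1:
        raise ValueError(
            f"recording of {emg.n_samples} samples shorter than one "
            f"{win}-sample analysis window"
        )
    if eps_amp is None:
        eps = default_eps_amp(x)
    else:
        eps = np.broadcast_to(np.asarray(eps_amp, dtype=float), (emg.n_channels,))
    starts = np.arange(n_win) * step
    idx = starts[:, None] + np.arange(win)[None, :]

    cols: list[np.ndarray] = []
    names: list[str] = []
    for ch in range(emg.n_channels):
        wnd = x[ch][idx]  # (n_win, win)
        mav_col = np.mean(np.abs(wnd), axis=1)
        mavs_col = mavs(mav_col)
        a, b = wnd[:, :-1], wnd[:, 1:]
        zc_col = np.count_nonzero((a * b < 0) & (np.abs(a - b) > eps[ch]), axis=1)
        d1 = wnd[:, 1:-1] - wnd[:, :-2]
        d2 = wnd[:, 1:-1] - wnd[:, 2:]
        ssc_col = np.count_nonzero(
            (d1 * d2 > 0) & (np.abs(d1) > eps[ch]) & (np.abs(d2) > eps[ch]), axis=1
        )
        ar = _ar_lms_batch(wnd, lms)
        cols.append(
            np.column_stack([mav_col, mavs_col, zc_col, ssc_col, ar])
        )
        cname = emg.channel_names[ch]
        names.extend(f"{cname}.{f}" for f in FEATURE_NAMES)
    values = np.hstack(cols)
    return FeatureMatrix(
        values=values,
        window_starts=starts,
        spec=spec,
        rate_hz=emg.rate_hz,
        column_names=tuple(names),
    )
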