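"""EMG conditioning and cross-stream synchronization.

EMG is band-pass filtered (10-450 Hz, 2nd-order Butterworth) and resampled to
a common 1024 Hz time base; the EMG and motion-capture streams are aligned by
the rising edges of the shared 20 Hz synchronization square wave.

Filtering is forward-only (causal) by default, matching an online-capable
myoelectric control implementation; pass ``zero_phase=True`` for offline
zero-lag filtering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import EmgRecording, SyncTrace

__all__ = [
    "SamplingError",
    "SyncError",
    "AlignedStreams",
    "bandpass_emg",
    "resample_emg",
    "align_by_sync",
    "rising_edges",
]


class SamplingError(ValueError):
    """Sampling rate incompatible with the requested operation."""


class SyncError(RuntimeError):
    """Synchronization signal unusable (no detectable edges)."""


@dataclass
class AlignedStreams:
    """EMG and angle traces on a common time base with equal sample counts."""

    emg: EmgRecording
    angles: "object"  # kinematics.AngleTrace; kept loose to avoid an import cycle
    common_length: int


def _causal_sos_filter(sos: np.ndarray, x: np.ndarray, dc_init: bool = False) -> np.ndarray:
    """Apply an SOS filter causally along the last axis.

    With ``dc_init`` the filter state is initialized to steady state for each
    row's first sample, suppressing the startup transient on signals with a
    nonzero baseline (used for low-pass/anti-alias stages).
    """
    x = np.atleast_2d(x)
    if dc_init:
        zi = signal.sosfilt_zi(sos)  # steady-state response to a unit step
        out = np.empty_like(x)
        for i, row in enumerate(x):
            out[i], _ = signal.sosfilt(sos, row, zi=zi * row[0])
        return out
    return signal.sosfilt(sos, x, axis=-1)


def bandpass_emg(
    emg: EmgRecording,
    low_hz: float = 10.0,
    high_hz: float = 450.0,
    order: int = 2,
    zero_phase: bool = False,
) -> EmgRecording:
    """Band-pass filter EMG (default 10-450 Hz, 2nd-order Butterworth)."""
    if emg.rate_hz <= 2 * high_hz:
        raise SamplingError(
            f"rate {emg.rate_hz} Hz too low for a band-pass up to {high_hz} Hz"
        )
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass",
                        fs=emg.rate_hz, output="sos")
    if zero_phase:
        filtered = signal.sosfiltfilt(sos, emg.samples, axis=-1)
    else:
        filtered = _causal_sos_filter(sos, emg.samples)
    return emg.copy_with(samples=filtered)


def resample_emg(
    emg: EmgRecording, target_hz: float = 1024.0, zero_phase: bool = False
) -> EmgRecording:
    """Resample EMG to ``target_hz`` by anti-alias low-pass + integer decimation.

    Only integer decimation ratios are supported (the study's 2048 -> 1024 Hz
    is a 2:1 decimation); other ratios raise :class:`SamplingError`.
    """
    if target_hz > emg.rate_hz:
        raise SamplingError("resample_emg only downsamples; target above input rate")
    ratio = emg.rate_hz / target_hz
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9 or q < 1:
        raise SamplingError(
            f"unsupported rate ratio {emg.rate_hz}/{target_hz}; integer factors only"
        )
    if q == 1:
        return emg.copy_with(samples=emg.samples.copy())
    # anti-alias low-pass at ~0.9 of the target Nyquist
    cutoff = 0.9 * (target_hz / 2.0)
    sos = signal.butter(6, cutoff, btype="low", fs=emg.rate_hz, output="sos")
    if zero_phase:
        filtered = signal.sosfiltfilt(sos, emg.samples, axis=-1)
    else:
        filtered = _causal_sos_filter(sos, emg.samples, dc_init=True)
    return emg.copy_with(samples=filtered[:, ::q], rate_hz=target_hz)


def rising_edges(trace: SyncTrace, lo_frac: float = 0.3, hi_frac: float = 0.7) -> np.ndarray:
    """Indices of low->high transitions detected by hysteresis thresholding.

    Thresholds sit at fractions of the trace's amplitude range, so detection
    is invariant to amplitude scaling and DC offset.
    """
    x = trace.samples
    lo, hi = x.min(), x.max()
    if hi - lo <= 0 or not np.isfinite(hi - lo):
        raise SyncError("sync trace is constant; no edges detectable")
    t_lo = lo + lo_frac * (hi - lo)
    t_hi = lo + hi_frac * (hi - lo)
    state = x[0] > t_hi  # True once high until dropping below t_lo
    edges = []
    below = ~state
    for i in range(1, x.size):
        if below and x[i] > t_hi:
            edges.append(i)
            below = False
        elif not below and x[i] < t_lo:
            below = True
    if not edges:
        raise SyncError("no rising edges found in sync trace")
    return np.asarray(edges, dtype=int)


def sync_fundamental_hz(trace: SyncTrace) -> float:
    """Median square-wave frequency implied by consecutive rising edges."""
    edges = rising_edges(trace)
    if edges.size < 2:
        raise SyncError("need at least two rising edges to estimate frequency")
    periods = np.diff(edges) / trace.rate_hz
    return float(1.0 / np.median(periods))


def align_by_sync(
    emg_sync: SyncTrace, kin_sync: SyncTrace, min_periods: int = 5
) -> tuple[int, int]:
    """Per-stream start offsets (samples) aligning the first common rising edge.

    Returns ``(offset_emg, offset_kin)``: dropping that many leading samples
    from each stream aligns them. The later-starting stream gets offset 0.
    Identical traces yield ``(0, 0)``.
    """
    e_edges = rising_edges(emg_sync)
    k_edges = rising_edges(kin_sync)
    for name, edges, trace in (("EMG", e_edges, emg_sync), ("kinematic", k_edges, kin_sync)):
        n_periods = edges.size - 1
        if n_periods + 1 < min_periods:
            raise SyncError(
                f"{name} sync trace has only {edges.size} edges; "
                f">= {min_periods} square-wave periods required"
            )
    t_e = e_edges[0] / emg_sync.rate_hz
    t_k = k_edges[0] / kin_sync.rate_hz
    if t_e >= t_k:
        return int(round((t_e - t_k) * emg_sync.rate_hz)), 0
    return 0, int(round((t_k - t_e) * kin_sync.rate_hz))
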