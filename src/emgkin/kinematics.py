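"""Wrist joint angles from 3-D marker trajectories.

A wrist-centered coordinate frame is built per frame from six of the seven
anatomical markers: origin O midway between the radial and ulnar styloids
(STR, STU); z-axis the forearm center axis, positive proximal, pointing from
O to E (midway between the humeral epicondyles MEP, LEP); x-axis the
mediolateral wrist axis (the styloid pair direction orthogonalized against
z); y-axis completing a right-handed frame.

Three DoF angles follow with H the midpoint of the metacarpal markers
(RMC, UMC) and (Hx, Hy, Hz) the components of H - O on the mediolateral,
dorsopalmar, and *distal* forearm axes:

    alpha1 = atan(Hy / Hz)   flexion(+) / extension(-),  range +/-90 deg
    alpha2 = atan(Hx / Hz)   radial(+) / ulnar(-),       range +/-90 deg
    alpha3 = angle(omega, l) with omega = STR - STU, l = LEP - MEP;
             90 deg is prono-supination neutral, >90 pronation.

Mirrored bilateral motion must read out identical angles on both arms, but a
sagittal mirror flips frame handedness; keeping the frame right-handed on
both sides therefore requires one side-aware sign. Here x is lateral on both
sides (the styloid pair itself mirrors) and the palmar direction used for Hy
is s*y with s=+1 (right) / -1 (left).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .features import WindowSpec, n_windows
from .io import MarkerTrajectorySet

__all__ = [
    "GeometryError",
    "WristFrame",
    "AngleTrace",
    "WindowedTargets",
    "build_wrist_frame",
    "compute_angles",
    "condition_angles",
    "window_targets",
    "interpolate_gaps",
]

_DEG = 180.0 / np.pi


class GeometryError(ValueError):
    """Marker configuration degenerate (coincident/collinear sites)."""


class AlignmentError(ValueError):
    """Streams to be combined have mismatched lengths or rates."""


def _side_sign(side: str | None) -> float:
    if side in ("right", None, "intact", "dominant"):
        return 1.0
    if side in ("left", "amputated"):
        return -1.0
    raise ValueError(f"unknown side {side!r}")


@dataclass
class WristFrame:
    """Orthonormal right-handed wrist frame at one motion-capture frame.

    ``palmar_sign`` flips the dorsopalmar read-out axis on the left arm so
    that flexion is positive bilaterally (see module docstring).
    """

    origin: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    palmar_sign: float = 1.0


@dataclass
class AngleTrace:
    """Wrist DoF angles in degrees: ``angles`` is (n_samples, 3)."""

    angles: np.ndarray
    rate_hz: float
    side: str | None = None
    run: int | None = None
    position: str | None = None
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 2 or self.angles.shape[1] != 3:
            raise ValueError("angles must be (n_samples, 3)")
        if self.valid is None:
            self.valid = np.ones(self.angles.shape[0], dtype=bool)

    @property
    def n_samples(self) -> int:
        return self.angles.shape[0]

    def copy_with(self, **kw) -> "AngleTrace":
        return replace(self, **kw)


@dataclass
class WindowedTargets:
    """Per-window mean angles aligned to FeatureMatrix rows: (n_windows, 3)."""

    targets: np.ndarray
    window_starts: np.ndarray
    valid: np.ndarray

    @property
    def n_windows(self) -> int:
        return self.targets.shape[0]


def _unit(v: np.ndarray, what: str, atol: float = 1e-9) -> np.ndarray:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(n < atol):
        raise GeometryError(f"degenerate marker geometry: {what} has near-zero length")
    return v / n


def build_wrist_frame(markers: dict[str, np.ndarray], side: str = "right") -> WristFrame:
    """Wrist frame from one frame's marker positions (dict name -> 3-vector)."""
    stu, strd = np.asarray(markers["STU"], float), np.asarray(markers["STR"], float)
    mep, lep = np.asarray(markers["MEP"], float), np.asarray(markers["LEP"], float)
    rmc, umc = np.asarray(markers["RMC"], float), np.asarray(markers["UMC"], float)
    origin = 0.5 * (strd + stu)
    elbow = 0.5 * (mep + lep)
    z = _unit(elbow - origin, "forearm axis O->E")
    omega = strd - stu
    if np.linalg.norm(omega) < 1e-9:
        raise GeometryError("degenerate marker geometry: STR and STU coincide")
    x_raw = omega - np.dot(omega, z) * z
    x = _unit(x_raw, "mediolateral axis (styloid pair collinear with forearm)")
    y = np.cross(z, x)
    _ = rmc, umc  # hand markers unused by the frame itself
    return WristFrame(origin=origin, x=x, y=y, z=z, palmar_sign=_side_sign(side))


def compute_angles(
    markers: MarkerTrajectorySet,
    side: str | None = None,
    max_gap_s: float = 0.25,
) -> AngleTrace:
    """Per-frame wrist angles (degrees) from a marker trajectory set.

    Gaps up to ``max_gap_s`` are linearly interpolated per marker coordinate;
    frames inside longer gaps are marked invalid in the returned trace (the
    pipeline later drops analysis windows touching them).
    """
    side = side or markers.side or "right"
    s = _side_sign(side)
    coords, valid = interpolate_gaps(markers, max_gap_s=max_gap_s)
    m = {name: coords[:, i, :] for i, name in enumerate(markers.names)}
    origin = 0.5 * (m["STR"] + m["STU"])
    elbow = 0.5 * (m["MEP"] + m["LEP"])
    hand = 0.5 * (m["RMC"] + m["UMC"])

    z = _unit(elbow - origin, "forearm axis O->E")
    omega = m["STR"] - m["STU"]
    x = _unit(omega - np.sum(omega * z, axis=1, keepdims=True) * z,
              "mediolateral axis")
    y = np.cross(z, x)

    h = hand - origin
    hx = np.sum(h * x, axis=1)
    hy = s * np.sum(h * y, axis=1)  # palmar read-out is side-aware
    hz = -np.sum(h * z, axis=1)  # distal component (z is proximal-positive)

    tiny = 1e-12
    singular = hz <= tiny
    hz_safe = np.where(singular, tiny, hz)
    a1 = np.degrees(np.arctan(hy / hz_safe))
    a2 = np.degrees(np.arctan(hx / hz_safe))
    # honor the stated +/-90 deg range at the Hz ~ 0 singularity
    a1 = np.where(singular, np.sign(hy) * 90.0, a1)
    a2 = np.where(singular, np.sign(hx) * 90.0, a2)

    lvec = m["LEP"] - m["MEP"]
    cosang = np.sum(_unit(omega, "STU->STR") * _unit(lvec, "MEP->LEP"), axis=1)
    a3 = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))

    angles = np.column_stack([a1, a2, a3])
    angles[~valid] = np.nan
    return AngleTrace(
        angles=angles, rate_hz=markers.rate_hz, side=side,
        run=markers.run, position=markers.position, valid=valid,
    )


def interpolate_gaps(
    markers: MarkerTrajectorySet, max_gap_s: float = 0.25
) -> tuple[np.ndarray, np.ndarray]:
    """Fill short marker dropouts; flag frames inside long ones.

    Returns ``(coords, valid)`` where coords has interior gaps up to
    ``max_gap_s`` linearly interpolated and ``valid`` marks frames where every
    marker is either observed or so repaired.
    """
    coords = markers.coords.copy()
    gaps = markers.gaps.copy()
    n = markers.n_frames
    max_len = int(round(max_gap_s * markers.rate_hz))
    valid = np.ones(n, dtype=bool)
    t = np.arange(n)
    for mi in range(coords.shape[1]):
        g = gaps[:, mi]
        if not g.any():
            continue
        ok = ~g
        if ok.sum() < 2:
            valid[:] = False
            continue
        # interpolate everything, then re-invalidate long runs and edges
        for c in range(3):
            coords[g, mi, c] = np.interp(t[g], t[ok], coords[ok, mi, c])
        runs = _bool_runs(g)
        for start, stop in runs:
            length = stop - start
            interior = start > 0 and stop < n
            if not interior or length > max_len:
                valid[start:stop] = False
    return coords, valid


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) spans of consecutive True values."""
    idx = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False])).astype(int)))
    return list(zip(idx[0::2], idx[1::2]))


def condition_angles(
    trace: AngleTrace,
    target_hz: float = 1024.0,
    cutoff_hz: float = 6.0,
    order: int = 2,
    zero_phase: bool = False,
) -> AngleTrace:
    """Low-pass (6 Hz, 2nd-order Butterworth) then upsample to 1024 Hz.

    Upsampling uses linear interpolation (the trace is already band-limited
    far below the new Nyquist). The target rate must be an integer multiple
    of the input rate.
    """
    ratio = target_hz / trace.rate_hz
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9 or q < 1:
        raise ValueError(
            f"unsupported rate ratio {target_hz}/{trace.rate_hz}; integer multiples only"
        )
    x = trace.angles.T  # (3, n)
    if np.isnan(x).any():
        raise ValueError("condition_angles: trace contains invalid (NaN) spans; "
                         "drop or repair them first")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=trace.rate_hz, output="sos")
    if zero_phase:
        y = signal.sosfiltfilt(sos, x, axis=-1)
    else:
        zi = signal.sosfilt_zi(sos)
        y = np.empty_like(x)
        for i, row in enumerate(x):
            y[i], _ = signal.sosfilt(sos, row, zi=zi * row[0])
    n = x.shape[1]
    t_in = np.arange(n) / trace.rate_hz
    t_out = np.arange(n * q) / target_hz
    up = np.empty((3, n * q))
    for i in range(3):
        up[i] = np.interp(t_out, t_in, y[i])
    valid_up = np.repeat(trace.valid, q)
    return trace.copy_with(angles=up.T, rate_hz=target_hz, valid=valid_up)


def window_targets(trace: AngleTrace, spec: WindowSpec = WindowSpec()) -> WindowedTargets:
    """Per-window arithmetic means of each angle, aligned to feature windows.

    A window is valid only if every sample it covers is valid.
    """
    win = spec.window_samples(trace.rate_hz)
    step = spec.step_samples(trace.rate_hz)
    nw = n_windows(trace.n_samples, win, step)
    if nw < 1:
        raise AlignmentError("angle trace shorter than one analysis window")
    starts = np.arange(nw) * step
    csum = np.concatenate([np.zeros((1, 3)), np.cumsum(np.nan_to_num(trace.angles), axis=0)])
    sums = csum[starts + win] - csum[starts]
    targets = sums / win
    vcsum = np.concatenate([[0], np.cumsum(trace.valid.astype(int))])
    valid = (vcsum[starts + win] - vcsum[starts]) == win
    return WindowedTargets(targets=targets, window_starts=starts, valid=valid)
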