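"""Synthetic recording sessions: scripted wrist kinematics, forward-modelled
marker trajectories, and angle-driven synthetic EMG with a controllable
arm-position effect.

The generator emulates the study protocol — 3 arm positions x 7 movement
runs of bilateral mirrored wrist articulation, 7-channel EMG at 2048 Hz,
7 markers at 256 Hz, a shared 20 Hz sync square wave — so every pipeline
stage is verifiable without human recordings.

EMG is modelled as amplitude-modulated band-limited (20-350 Hz) Gaussian
noise: each channel's envelope is a noise floor plus a gain-weighted sum of
rectified normalized angular excursions in the six DoF half-directions
(flexion, extension, radial, ulnar, pronation, supination). The arm-position
effect is a per-position multiplicative channel-gain vector plus an additive
baseline shift, mimicking electrode-muscle geometry changes when the limb
pose changes. Motor-unit physiology is out of scope: the pipeline consumes
only windowed features, for which envelope and spectrum realism suffice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from .io import (
    MARKER_NAMES,
    N_EMG_CHANNELS,
    N_RUNS,
    POSITIONS,
    RUN_ACTIVE_DOFS,
    EmgRecording,
    MarkerTrajectorySet,
    RunDescriptor,
    SessionManifest,
    SyncTrace,
    write_emg_tsv,
    write_manifest,
    write_markers_tsv,
    write_sync_tsv,
)
from .kinematics import AngleTrace

__all__ = [
    "ArmGeometry",
    "EmgSynthConfig",
    "MovementScript",
    "script_angles",
    "forward_markers",
    "synthesize_emg",
    "make_sync_pair",
    "generate_session",
]

EMG_RATE_HZ = 2048.0
KIN_RATE_HZ = 256.0
SYNC_HZ = 20.0
NEUTRAL_A3 = 90.0

#: DoF half-direction order used by the gain matrix columns.
DIRECTIONS = ("flex", "ext", "rad", "uln", "pro", "sup")


@dataclass(frozen=True)
class ArmGeometry:
    """Rigid-segment limb geometry (mm) and side for the forward model."""

    upper_arm_mm: float = 300.0
    forearm_mm: float = 260.0
    hand_mm: float = 80.0
    wrist_width_mm: float = 50.0  # STR-STU separation
    elbow_width_mm: float = 70.0  # LEP-MEP separation
    hand_width_mm: float = 70.0  # RMC-UMC separation
    side: str = "right"

    def __post_init__(self) -> None:
        for name in ("upper_arm_mm", "forearm_mm", "hand_mm",
                     "wrist_width_mm", "elbow_width_mm", "hand_width_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _default_gains() -> np.ndarray:
    """7x6 channel x direction gains: one dominant channel per direction with
    moderate cross-talk, channel 7 a mixed extrinsic channel."""
    g = np.full((N_EMG_CHANNELS, len(DIRECTIONS)), 0.2)
    for d in range(len(DIRECTIONS)):
        g[d, d] = 1.0
    g[6, :] = 0.35
    return g


@dataclass
class EmgSynthConfig:
    """Parameters of the synthetic EMG model.

    ``sigma_gain`` scales the log-normal per-position multiplicative channel
    gains; ``sigma_base`` the half-normal additive baseline shift; both zero
    disable the arm-position effect. ``lead_s`` is the head start of the EMG
    stream over the kinematic stream (recovered later via the sync wave).
    """

    gains: np.ndarray = field(default_factory=_default_gains)
    carrier_band_hz: tuple[float, float] = (20.0, 350.0)
    noise_floor: float = 0.05
    sigma_gain: float = 0.0
    sigma_base: float = 0.0
    amplitude_deg: tuple[float, float, float] = (60.0, 60.0, 60.0)
    lead_s: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        self.gains = np.asarray(self.gains, dtype=float)
        if self.gains.shape != (N_EMG_CHANNELS, len(DIRECTIONS)):
            raise ValueError(f"gains must be {N_EMG_CHANNELS}x{len(DIRECTIONS)}")
        if np.any(self.gains < 0):
            raise ValueError("gains must be non-negative")
        if self.noise_floor < 0 or self.sigma_gain < 0 or self.sigma_base < 0:
            raise ValueError("noise_floor and position-effect sigmas must be >= 0")

    def position_effect(self, position: str) -> tuple[np.ndarray, np.ndarray]:
        """Per-position multiplicative channel gains (>0) and baseline shifts.

        The three positions get mutually orthogonal log-gain patterns of a
        randomly oriented but seeded basis, so the perturbation *magnitude*
        between any two positions is deterministic (set by ``sigma_gain``)
        while its direction across channels is random. An i.i.d. draw per
        position would make the effective pairwise effect itself random —
        occasionally near zero — defeating the point of a controllable
        position effect.
        """
        pos_idx = POSITIONS.index(position)
        rng = np.random.default_rng(
            np.random.SeedSequence([int(self.seed) % 2**31, 7919])
        )
        q, _ = np.linalg.qr(rng.normal(size=(N_EMG_CHANNELS, len(POSITIONS))))
        q *= np.where(q[0] >= 0, 1.0, -1.0)  # resolve QR sign ambiguity
        pattern = q[:, pos_idx] * np.sqrt(N_EMG_CHANNELS)
        mult = np.exp(self.sigma_gain * pattern)
        raw_base = rng.normal(size=(N_EMG_CHANNELS, len(POSITIONS)))
        base = self.sigma_base * np.abs(raw_base[:, pos_idx])
        return mult, base


@dataclass(frozen=True)
class MovementScript:
    """Kinematic scripting parameters for one run.

    Articulated DoFs trace neutral -> extreme -> neutral half-cycles of
    sinusoidal shape whose durations are drawn per cycle from
    ``half_period_s``; held DoFs sit at ``hold_fraction`` of the amplitude.
    """

    amplitude_deg: tuple[float, float, float] = (60.0, 60.0, 60.0)
    half_period_s: tuple[float, float] = (1.0, 2.0)
    hold_fraction: float = 0.9


def _hump_train(duration_s: float, rate_hz: float, rng: np.random.Generator,
                half_period_s: tuple[float, float], alternate: bool = True) -> np.ndarray:
    """Unit-amplitude train of sinusoidal humps (neutral->extreme->neutral).

    Each hump lasts T ~ U(half_period_s) and traces sin(pi t / T); hump signs
    alternate so both movement directions are visited.
    """
    n = int(round(duration_s * rate_hz))
    out = np.zeros(n)
    t0 = 0.0
    sign = 1.0
    while t0 < duration_s:
        T = rng.uniform(*half_period_s)
        i0 = int(round(t0 * rate_hz))
        i1 = min(int(round((t0 + T) * rate_hz)), n)
        if i1 <= i0:
            break
        tt = (np.arange(i0, i1) / rate_hz - t0) / T
        out[i0:i1] = sign * np.sin(np.pi * tt)
        if alternate:
            sign = -sign
        t0 += T
    return out


def script_angles(
    run: RunDescriptor,
    script: MovementScript = MovementScript(),
    seed: int = 0,
    rate_hz: float = KIN_RATE_HZ,
) -> tuple[AngleTrace, AngleTrace]:
    """Scripted bilateral mirrored wrist angles for one run (left, right).

    Both sides carry identical (alpha1, alpha2, alpha3) traces — the
    anatomical mirroring lives in the marker forward model and the
    side-aware angle convention. Run semantics: for runs 1-6 the first
    listed DoF is articulated sinusoidally and the second held near maximal
    range; run 7 cycles DoF1 and DoF2 while alternating the direction of
    DoF3.
    """
    run.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, run.run_index,
                                                        POSITIONS.index(run.position)]))
    n = int(round(run.duration_s * rate_hz))
    amp = np.asarray(script.amplitude_deg, dtype=float)
    a = np.zeros((n, 3))
    order = RUN_ACTIVE_DOFS[run.run_index]
    if run.run_index == 7:
        for dof in (1, 2):
            a[:, dof - 1] = amp[dof - 1] * _hump_train(
                run.duration_s, rate_hz, rng, script.half_period_s)
        # DoF3: alternating-direction cyclic movement
        a[:, 2] = amp[2] * _hump_train(run.duration_s, rate_hz, rng,
                                       script.half_period_s)
    else:
        art, held = order
        a[:, art - 1] = amp[art - 1] * _hump_train(
            run.duration_s, rate_hz, rng, script.half_period_s)
        a[:, held - 1] = script.hold_fraction * amp[held - 1]
    a[:, 2] += NEUTRAL_A3  # pronation/supination neutral is 90 deg
    trace_l = AngleTrace(angles=a.copy(), rate_hz=rate_hz, side="left",
                         run=run.run_index, position=run.position)
    trace_r = AngleTrace(angles=a.copy(), rate_hz=rate_hz, side="right",
                         run=run.run_index, position=run.position)
    return trace_l, trace_r


# ---------------------------------------------------------------------------
# Marker forward model
# ---------------------------------------------------------------------------

_POSE_ROTATIONS = {
    # distinct global limb poses; wrist angles are invariant to them
    "POS1": np.eye(3),
    "POS2": None,  # filled below
    "POS3": None,
}


def _rot(axis: str, deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    if axis == "x":
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
    if axis == "y":
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


_POSE_ROTATIONS["POS2"] = _rot("z", 45.0)
_POSE_ROTATIONS["POS3"] = _rot("y", 90.0) @ _rot("z", 10.0)
_POSE_OFFSETS = {
    "POS1": np.array([0.0, 0.0, 0.0]),
    "POS2": np.array([120.0, 40.0, 0.0]),
    "POS3": np.array([250.0, 0.0, 150.0]),
}
_UPPER_ARM_DIR = {
    # direction from the elbow toward the shoulder in the arm-local frame
    "POS1": np.array([0.0, -0.9, 0.436]),
    "POS2": np.array([0.3, -0.85, 0.434]),
    "POS3": np.array([0.0, 0.0, 1.0]),
}


def forward_markers(
    angles: AngleTrace,
    geometry: ArmGeometry = ArmGeometry(),
    position: str = "POS1",
    marker_noise_mm: float = 0.0,
    seed: int = 0,
) -> MarkerTrajectorySet:
    """Rigid-segment forward model placing the 7 markers for an angle trace.

    The wrist DoF angles are embedded so that ``kinematics.compute_angles``
    recovers them exactly in the noiseless case. The arm position changes
    only the global limb pose (a rigid rotation + translation), never the
    scripted wrist angles. Optional isotropic Gaussian marker noise (mm) is
    added per coordinate.
    """
    if position not in POSITIONS:
        raise ValueError(f"unknown position {position!r}")
    side = geometry.side
    s = 1.0 if side == "right" else -1.0
    a = np.radians(angles.angles)
    n = a.shape[0]
    a1, a2, a3 = a[:, 0], a[:, 1], a[:, 2]

    lf, lh = geometry.forearm_mm, geometry.hand_mm
    ww, we, wh = (geometry.wrist_width_mm / 2, geometry.elbow_width_mm / 2,
                  geometry.hand_width_mm / 2)

    # arm-local right-arm construction: O at origin, forearm axis +Z proximal
    zax = np.array([0.0, 0.0, 1.0])
    l_hat = np.tile(np.array([1.0, 0.0, 0.0]), (n, 1))  # MEP->LEP direction
    # pronation rotates the styloid pair about the forearm axis
    omega_hat = np.column_stack([np.cos(a3), -np.sin(a3), np.zeros(n)])

    x_f = omega_hat  # unit, orthogonal to z by construction
    y_f = np.cross(np.tile(zax, (n, 1)), x_f)

    # hand direction: components chosen so atan(Hx/Hz)=a2 and the side-aware
    # palmar read-out gives a1; the left arm is the sagittal mirror of this
    # right-arm construction, and the mirror + side-aware sign cancel exactly
    u = (np.tan(a2)[:, None] * x_f + np.tan(a1)[:, None] * y_f
         - np.tile(zax, (n, 1)))
    u /= np.linalg.norm(u, axis=1, keepdims=True)

    origin = np.zeros((n, 3))
    elbow = np.tile(zax * lf, (n, 1))
    markers = {
        "STR": origin + ww * omega_hat,
        "STU": origin - ww * omega_hat,
        "MEP": elbow - we * l_hat,
        "LEP": elbow + we * l_hat,
    }
    hand_mid = origin + lh * u
    p_hat = np.cross(u, y_f)
    p_norm = np.linalg.norm(p_hat, axis=1, keepdims=True)
    # fall back to the x axis where u is parallel to y (extreme flexion)
    small = (p_norm < 1e-9).ravel()
    p_hat[small] = x_f[small]
    p_hat /= np.linalg.norm(p_hat, axis=1, keepdims=True)
    markers["RMC"] = hand_mid + wh * p_hat
    markers["UMC"] = hand_mid - wh * p_hat
    markers["SHO"] = elbow + geometry.upper_arm_mm * _UPPER_ARM_DIR[position]

    if side == "left":  # sagittal mirror of the right-arm construction
        mirror = np.array([-1.0, 1.0, 1.0])
        markers = {k: v * mirror for k, v in markers.items()}

    rot = _POSE_ROTATIONS[position]
    off = _POSE_OFFSETS[position] + (np.array([180.0, 0.0, 0.0]) * (-s))
    coords = np.stack([markers[name] @ rot.T + off for name in MARKER_NAMES], axis=1)

    if marker_noise_mm > 0:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, 104729]))
        coords = coords + rng.normal(0.0, marker_noise_mm, size=coords.shape)

    return MarkerTrajectorySet(
        coords=coords, rate_hz=angles.rate_hz, names=MARKER_NAMES,
        side=side, run=angles.run, position=angles.position,
    )


# ---------------------------------------------------------------------------
# EMG synthesis
# ---------------------------------------------------------------------------


def _excursions(angles: np.ndarray, amplitude_deg: tuple[float, float, float]) -> np.ndarray:
    """Normalized rectified excursions in the 6 half-directions, in [0, 1]."""
    a1, a2, a3 = angles[:, 0], angles[:, 1], angles[:, 2]
    amp = np.asarray(amplitude_deg, dtype=float)
    e = np.column_stack([
        np.clip(a1, 0, None) / amp[0],
        np.clip(-a1, 0, None) / amp[0],
        np.clip(a2, 0, None) / amp[1],
        np.clip(-a2, 0, None) / amp[1],
        np.clip(a3 - NEUTRAL_A3, 0, None) / amp[2],
        np.clip(NEUTRAL_A3 - a3, 0, None) / amp[2],
    ])
    return np.clip(e, 0.0, 1.0)


def _carrier(n: int, rate_hz: float, band: tuple[float, float],
             rng: np.random.Generator) -> np.ndarray:
    """Unit-variance band-limited Gaussian carrier."""
    white = rng.standard_normal(n)
    sos = signal.butter(4, band, btype="bandpass", fs=rate_hz, output="sos")
    x = signal.sosfilt(sos, white)
    sd = x.std()
    return x / sd if sd > 0 else x


def synthesize_emg(
    angles: AngleTrace,
    config: EmgSynthConfig = EmgSynthConfig(),
    position: str = "POS1",
    seed: int = 0,
    rate_hz: float = EMG_RATE_HZ,
) -> tuple[EmgRecording, SyncTrace, SyncTrace]:
    """Angle-driven synthetic EMG plus the matched sync square-wave pair.

    The EMG stream starts ``config.lead_s`` before the kinematic stream (the
    angles are padded with their first sample over the lead), so the sync
    alignment stage has real work to do. Returns
    ``(emg, emg_sync, kin_sync)``.
    """
    if position not in POSITIONS:
        raise ValueError(f"unknown position {position!r}")
    rng = np.random.default_rng(np.random.SeedSequence(
        [int(seed) % 2**31, 15485863, POSITIONS.index(position)]))
    lead_n_kin = int(round(config.lead_s * angles.rate_hz))
    padded = np.vstack([np.tile(angles.angles[0], (lead_n_kin, 1)), angles.angles])
    # envelope at the kinematic rate, then linear upsample to the EMG rate
    exc = _excursions(padded, config.amplitude_deg)
    mult, base = config.position_effect(position)
    env_kin = (config.noise_floor + exc @ config.gains.T) * mult + base
    n_emg = int(round(padded.shape[0] / angles.rate_hz * rate_hz))
    t_kin = np.arange(padded.shape[0]) / angles.rate_hz
    t_emg = np.arange(n_emg) / rate_hz
    env = np.empty((N_EMG_CHANNELS, n_emg))
    for ch in range(N_EMG_CHANNELS):
        env[ch] = np.interp(t_emg, t_kin, env_kin[:, ch])
    samples = np.empty_like(env)
    for ch in range(N_EMG_CHANNELS):
        samples[ch] = env[ch] * _carrier(n_emg, rate_hz, config.carrier_band_hz, rng)
    emg = EmgRecording(samples=samples, rate_hz=rate_hz, side=angles.side,
                       run=angles.run, position=angles.position)
    emg_sync, kin_sync = make_sync_pair(
        duration_s=angles.angles.shape[0] / angles.rate_hz,
        lead_s=config.lead_s, emg_rate_hz=rate_hz, kin_rate_hz=angles.rate_hz,
    )
    return emg, emg_sync, kin_sync


def make_sync_pair(
    duration_s: float,
    lead_s: float = 0.25,
    emg_rate_hz: float = EMG_RATE_HZ,
    kin_rate_hz: float = KIN_RATE_HZ,
    freq_hz: float = SYNC_HZ,
    amplitude_v: float = 5.0,
) -> tuple[SyncTrace, SyncTrace]:
    """20 Hz +/-5 V square-wave pair with a known inter-stream offset.

    The wave is low before session time zero and starts (low half-period
    first) at t=0; the EMG stream records from t=-lead_s, the kinematic
    stream from t=0. The first rising edge thus appears ``lead_s`` later in
    the EMG trace than in the kinematic trace.
    """

    def wave(t: np.ndarray) -> np.ndarray:
        phase = np.floor(2.0 * freq_hz * t).astype(int)
        w = np.where(phase % 2 == 1, amplitude_v, -amplitude_v)
        return np.where(t < 0, -amplitude_v, w)

    n_emg = int(round((duration_s + lead_s) * emg_rate_hz))
    n_kin = int(round(duration_s * kin_rate_hz))
    t_emg = np.arange(n_emg) / emg_rate_hz - lead_s
    t_kin = np.arange(n_kin) / kin_rate_hz
    return (
        SyncTrace(samples=wave(t_emg), rate_hz=emg_rate_hz, nominal_freq_hz=freq_hz),
        SyncTrace(samples=wave(t_kin), rate_hz=kin_rate_hz, nominal_freq_hz=freq_hz),
    )


# ---------------------------------------------------------------------------
# Full session
# ---------------------------------------------------------------------------


def _amputated_gains(gains: np.ndarray, blur: float = 0.5) -> np.ndarray:
    """Reduced channel specificity for the amputated side: blend each
    channel's gain row toward the across-channel mean."""
    mean_row = gains.mean(axis=0, keepdims=True)
    return (1 - blur) * gains + blur * np.tile(mean_row, (gains.shape[0], 1))


def generate_session(
    out_dir: str | Path,
    subject_id: str = "synth01",
    group: str = "able_bodied",
    duration_s: float = 65.0,
    emg_config: EmgSynthConfig | None = None,
    geometry: ArmGeometry | None = None,
    script: MovementScript | None = None,
    marker_noise_mm: float = 0.5,
    control_side: str = "right",
    master_seed: int = 0,
) -> SessionManifest:
    """Write a complete synthetic session (3 positions x 7 runs x 2 sides).

    Emits 42 EMG files, 42 marker files, 42 sync files (one per stream rate
    per run) and the manifest; per-run seeds derive deterministically from
    ``master_seed``. In ``group="amputee"`` mode the control (amputated)
    side's EMG uses a blurred gain matrix with reduced channel specificity,
    while the regression targets come from the contralateral intact side.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    emg_config = emg_config or EmgSynthConfig()
    script = script or MovementScript(amplitude_deg=emg_config.amplitude_deg)
    geometry = geometry or ArmGeometry()
    manifest = SessionManifest(subject_id=subject_id, group=group,
                               control_side=control_side, root=out_dir)
    base_ss = int(master_seed) % 2**31
    for pos in POSITIONS:
        for run_idx in range(1, N_RUNS + 1):
            rd = RunDescriptor(
                run_index=run_idx, position=pos,
                active_dofs=tuple(sorted(RUN_ACTIVE_DOFS[run_idx])),
                duration_s=duration_s,
            )
            manifest.runs.append(rd)
            run_seed = int(np.random.SeedSequence(
                [base_ss, POSITIONS.index(pos), run_idx]).generate_state(1)[0] % 2**31)
            traces = dict(zip(("left", "right"),
                              script_angles(rd, script, seed=run_seed)))
            tag = f"{pos}_run{run_idx}"
            for side, trace in traces.items():
                geo = ArmGeometry(**{**geometry.__dict__, "side": side})
                markers = forward_markers(
                    trace, geo, position=pos,
                    marker_noise_mm=marker_noise_mm,
                    seed=run_seed + (0 if side == "left" else 1),
                )
                cfg = emg_config
                if group == "amputee" and side == control_side:
                    cfg = EmgSynthConfig(
                        gains=_amputated_gains(emg_config.gains),
                        carrier_band_hz=emg_config.carrier_band_hz,
                        noise_floor=emg_config.noise_floor,
                        sigma_gain=emg_config.sigma_gain,
                        sigma_base=emg_config.sigma_base,
                        amplitude_deg=emg_config.amplitude_deg,
                        lead_s=emg_config.lead_s,
                        seed=emg_config.seed,
                    )
                emg, emg_sync, kin_sync = synthesize_emg(
                    trace, cfg, position=pos,
                    seed=run_seed + (10 if side == "left" else 11),
                )
                emg_path = f"{tag}_{side}_emg.tsv"
                mk_path = f"{tag}_{side}_markers.tsv"
                write_emg_tsv(out_dir / emg_path, emg)
                write_markers_tsv(out_dir / mk_path, markers)
                manifest.files[(run_idx, pos, side, "emg")] = emg_path
                manifest.files[(run_idx, pos, side, "markers")] = mk_path
                if side == "right":  # sync shared by both sides of the run
                    se_path, sk_path = f"{tag}_sync_emg.tsv", f"{tag}_sync_kin.tsv"
                    write_sync_tsv(out_dir / se_path, emg_sync)
                    write_sync_tsv(out_dir / sk_path, kin_sync)
                    manifest.files[(run_idx, pos, "-", "sync_emg")] = se_path
                    manifest.files[(run_idx, pos, "-", "sync_kin")] = sk_path
    manifest_path = out_dir / "manifest.tsv"
    write_manifest(manifest_path, manifest)
    manifest.validate(complete=True)
    return manifest
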