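"""Session I/O: delimited-text EMG, marker, and sync streams plus the session manifest.

All on-disk formats are plain TSV with a small ``KEY\\tvalue`` header block
(rate, channel/marker names, optional labels) followed by one row per sample
or motion-capture frame.  Marker gaps are encoded as empty cells.  Timestamps
are implicit from the sampling rate and the row index.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MARKER_NAMES",
    "N_EMG_CHANNELS",
    "POSITIONS",
    "N_RUNS",
    "RUN_ACTIVE_DOFS",
    "STREAMS",
    "FormatError",
    "ManifestError",
    "EmgRecording",
    "MarkerTrajectorySet",
    "SyncTrace",
    "RunDescriptor",
    "SessionManifest",
    "read_emg_tsv",
    "write_emg_tsv",
    "read_markers_tsv",
    "write_markers_tsv",
    "read_sync_tsv",
    "write_sync_tsv",
    "read_manifest",
    "write_manifest",
]

#: The seven per-arm anatomical marker sites: shoulder (acromion), medial and
#: lateral humeral epicondyles, ulnar and radial styloids, second and fifth
#: metacarpal heads.
MARKER_NAMES = ("SHO", "MEP", "LEP", "STU", "STR", "RMC", "UMC")

N_EMG_CHANNELS = 7
POSITIONS = ("POS1", "POS2", "POS3")
N_RUNS = 7

#: Active wrist DoFs per movement run.  Runs 1-6 combine two DoFs (the first
#: articulated sinusoidally, the second held near maximal range); run 7
#: articulates all three.  DoF1 flexion/extension, DoF2 radial/ulnar
#: deviation, DoF3 pronation/supination.
RUN_ACTIVE_DOFS = {
    1: (1, 2),
    2: (2, 1),
    3: (1, 3),
    4: (3, 1),
    5: (2, 3),
    6: (3, 2),
    7: (1, 2, 3),
}

#: Streams a complete run must provide. ``emg``/``markers`` are per side;
#: the sync traces are shared by both sides of a run (one per stream rate).
STREAMS = ("emg", "markers", "sync_emg", "sync_kin")
SIDES = ("left", "right")

_FMT = "%.10g"  # decimal -> float64 -> decimal round-trips at <= 15 sig. digits


class FormatError(ValueError):
    """A stream file violates the on-disk format contract."""


class ManifestError(ValueError):
    """A session manifest is malformed or incomplete."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass
class EmgRecording:
    """Multichannel surface EMG: ``samples`` is (n_channels, n_samples)."""

    samples: np.ndarray
    rate_hz: float
    side: str | None = None
    run: int | None = None
    position: str | None = None
    channel_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if self.channel_names is None:
            self.channel_names = tuple(
                f"ch{i + 1}" for i in range(self.samples.shape[0])
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    def copy_with(self, **kw) -> "EmgRecording":
        return replace(self, **kw)


@dataclass
class MarkerTrajectorySet:
    """Named 3-D marker trajectories (mm) with a per-sample gap mask.

    ``coords`` is (n_frames, n_markers, 3) ordered as ``names``; ``gaps`` is
    (n_frames, n_markers) boolean, true where the export had empty cells.
    Coordinates are NaN exactly where gapped.
    """

    coords: np.ndarray
    rate_hz: float
    names: tuple[str, ...] = MARKER_NAMES
    gaps: np.ndarray | None = None
    side: str | None = None
    run: int | None = None
    position: str | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must be (n_frames, n_markers, 3)")
        if self.gaps is None:
            self.gaps = np.isnan(self.coords).any(axis=2)
        self.gaps = np.asarray(self.gaps, dtype=bool)
        if set(self.names) != set(MARKER_NAMES) or len(self.names) != len(MARKER_NAMES):
            missing = sorted(set(MARKER_NAMES) - set(self.names))
            extra = sorted(set(self.names) - set(MARKER_NAMES))
            raise FormatError(
                f"marker set must be exactly {MARKER_NAMES}; "
                f"missing={missing} extra={extra}"
            )

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.rate_hz

    def get(self, name: str) -> np.ndarray:
        """(n_frames, 3) trajectory of one marker."""
        return self.coords[:, self.names.index(name), :]


@dataclass
class SyncTrace:
    """Recorded synchronization square wave (nominally 20 Hz, +/-5 V)."""

    samples: np.ndarray
    rate_hz: float
    nominal_freq_hz: float = 20.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()

    @property
    def n_samples(self) -> int:
        return self.samples.size


@dataclass
class RunDescriptor:
    run_index: int
    position: str
    active_dofs: tuple[int, ...]
    duration_s: float

    def validate(self) -> None:
        if not 1 <= self.run_index <= N_RUNS:
            raise ManifestError(f"run_index {self.run_index} outside 1..{N_RUNS}")
        if self.position not in POSITIONS:
            raise ManifestError(f"unknown position {self.position!r}")
        expected = tuple(sorted(RUN_ACTIVE_DOFS[self.run_index]))
        if tuple(sorted(self.active_dofs)) != expected:
            raise ManifestError(
                f"run {self.run_index}: active_dofs {self.active_dofs} "
                f"do not match the run protocol {expected}"
            )
        if not self.duration_s > 0:
            raise ManifestError("duration_s must be positive")


@dataclass
class SessionManifest:
    """Ties runs, positions, sides, and stream files of one session together.

    ``files`` maps ``(run, position, side, stream)`` to a path; the sync
    streams use side ``"-"`` since they are shared by both arms of a run.
    ``control_side`` is the arm whose EMG drives the regression (amputated
    side for amputees, dominant side for able-bodied subjects).
    """

    subject_id: str
    group: str  # {amputee, able_bodied}
    runs: list[RunDescriptor] = field(default_factory=list)
    files: dict[tuple[int, str, str, str], str] = field(default_factory=dict)
    control_side: str = "right"
    root: Path | None = None

    def path(self, run: int, position: str, side: str, stream: str) -> Path:
        side_key = side if stream in ("emg", "markers") else "-"
        p = Path(self.files[(run, position, side_key, stream)])
        return (self.root / p) if (self.root is not None and not p.is_absolute()) else p

    def expected_keys(self) -> set[tuple[int, str, str, str]]:
        keys: set[tuple[int, str, str, str]] = set()
        for pos in POSITIONS:
            for run in range(1, N_RUNS + 1):
                for side in SIDES:
                    keys.add((run, pos, side, "emg"))
                    keys.add((run, pos, side, "markers"))
                keys.add((run, pos, "-", "sync_emg"))
                keys.add((run, pos, "-", "sync_kin"))
        return keys

    def missing_entries(self) -> list[tuple[int, str, str, str]]:
        return sorted(self.expected_keys() - set(self.files))

    def validate(self, complete: bool = True) -> None:
        if self.group not in ("amputee", "able_bodied"):
            raise ManifestError(f"unknown group {self.group!r}")
        if self.control_side not in SIDES:
            raise ManifestError(f"control_side must be one of {SIDES}")
        if not self.runs and not self.files:
            raise ManifestError("empty manifest")
        for rd in self.runs:
            rd.validate()
        unknown = set(self.files) - self.expected_keys()
        if unknown:
            raise ManifestError(f"unexpected file entries: {sorted(unknown)[:5]}")
        if complete:
            missing = self.missing_entries()
            if missing:
                raise ManifestError(
                    f"incomplete session: {len(missing)} missing entries, "
                    f"first: {missing[:5]}"
                )
            run_keys = {(rd.run_index, rd.position) for rd in self.runs}
            want = {(r, p) for p in POSITIONS for r in range(1, N_RUNS + 1)}
            if run_keys != want:
                raise ManifestError(
                    f"run table incomplete: missing {sorted(want - run_keys)[:5]}"
                )


# ---------------------------------------------------------------------------
# TSV readers/writers
# ---------------------------------------------------------------------------


def _read_header(lines: list[str], path: str) -> tuple[dict[str, list[str]], int]:
    """Consume leading KEY\\tvalue... lines; return header dict and body start."""
    header: dict[str, list[str]] = {}
    i = 0
    for i, line in enumerate(lines):
        parts = line.rstrip("\n").split("\t")
        key = parts[0]
        if key and key.upper() == key and not _is_number(key):
            header[key] = parts[1:]
        else:
            return header, i
    return header, i + 1


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def _parse_body(lines: list[str], start: int, n_cols: int, path: str) -> np.ndarray:
    body = "".join(lines[start:])
    if not body.strip():
        return np.empty((0, n_cols))
    try:
        df = pd.read_csv(
            _stdio.StringIO(body), sep="\t", header=None, dtype=float,
            na_values=[""], keep_default_na=True,
        )
    except (ValueError, pd.errors.ParserError):
        # slow path: locate the offending line for the error message
        for off, line in enumerate(lines[start:]):
            if not line.strip():
                continue
            for cell in line.rstrip("\n").split("\t"):
                if cell and not _is_number(cell):
                    raise FormatError(
                        f"{path}: non-numeric cell {cell!r} at line {start + off + 1}"
                    ) from None
        raise FormatError(f"{path}: malformed data body") from None
    if df.shape[1] != n_cols:
        raise FormatError(
            f"{path}: expected {n_cols} data columns, found {df.shape[1]}"
        )
    return df.to_numpy(dtype=float)


def _header_rate(header: dict[str, list[str]], path: str) -> float:
    if "RATE_HZ" not in header:
        raise FormatError(f"{path}: missing RATE_HZ header line")
    try:
        return float(header["RATE_HZ"][0])
    except (IndexError, ValueError):
        raise FormatError(f"{path}: malformed RATE_HZ header") from None


def read_emg_tsv(path: str | Path) -> EmgRecording:
    """Read a multichannel EMG TSV (``RATE_HZ``, ``CHANNELS`` header lines)."""
    path = Path(path)
    lines = path.read_text().splitlines(keepends=True)
    header, start = _read_header(lines, str(path))
    rate = _header_rate(header, str(path))
    if "CHANNELS" not in header:
        raise FormatError(f"{path}: missing CHANNELS header line")
    names = tuple(header["CHANNELS"])
    if len(names) != N_EMG_CHANNELS:
        raise FormatError(
            f"{path}: expected {N_EMG_CHANNELS} channels, header names {len(names)}"
        )
    data = _parse_body(lines, start, len(names), str(path))
    if np.isnan(data).any():
        row = int(np.argwhere(np.isnan(data).any(axis=1))[0, 0])
        raise FormatError(f"{path}: empty/NaN cell in EMG body at data row {row}")
    return EmgRecording(
        samples=data.T,
        rate_hz=rate,
        side=_opt(header, "SIDE"),
        run=_opt_int(header, "RUN"),
        position=_opt(header, "POSITION"),
        channel_names=names,
    )


def write_emg_tsv(path: str | Path, emg: EmgRecording) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write(f"RATE_HZ\t{_FMT % emg.rate_hz}\n")
        fh.write("CHANNELS\t" + "\t".join(emg.channel_names) + "\n")
        _write_labels(fh, emg)
        np.savetxt(fh, emg.samples.T, fmt=_FMT, delimiter="\t")


def read_markers_tsv(path: str | Path) -> MarkerTrajectorySet:
    """Read a marker TSV (``RATE_HZ``, ``MARKERS`` headers; x,y,z per marker)."""
    path = Path(path)
    lines = path.read_text().splitlines(keepends=True)
    header, start = _read_header(lines, str(path))
    rate = _header_rate(header, str(path))
    if "MARKERS" not in header:
        raise FormatError(f"{path}: missing MARKERS header line")
    names = tuple(header["MARKERS"])
    if set(names) != set(MARKER_NAMES) or len(names) != len(MARKER_NAMES):
        missing = sorted(set(MARKER_NAMES) - set(names))
        extra = sorted(set(names) - set(MARKER_NAMES))
        raise FormatError(
            f"{path}: marker names must be exactly the 7-site set; "
            f"missing={missing} extra={extra}"
        )
    data = _parse_body(lines, start, 3 * len(names), str(path))
    coords = data.reshape(-1, len(names), 3)
    # reorder columns into canonical marker order
    order = [names.index(n) for n in MARKER_NAMES]
    coords = coords[:, order, :]
    return MarkerTrajectorySet(
        coords=coords,
        rate_hz=rate,
        names=MARKER_NAMES,
        side=_opt(header, "SIDE"),
        run=_opt_int(header, "RUN"),
        position=_opt(header, "POSITION"),
    )


def write_markers_tsv(path: str | Path, markers: MarkerTrajectorySet) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    flat = markers.coords.reshape(markers.n_frames, -1)
    with path.open("w") as fh:
        fh.write(f"RATE_HZ\t{_FMT % markers.rate_hz}\n")
        fh.write("MARKERS\t" + "\t".join(markers.names) + "\n")
        _write_labels(fh, markers)
        for row in flat:
            fh.write(
                "\t".join("" if np.isnan(v) else _FMT % v for v in row) + "\n"
            )


def read_sync_tsv(path: str | Path) -> SyncTrace:
    path = Path(path)
    lines = path.read_text().splitlines(keepends=True)
    header, start = _read_header(lines, str(path))
    rate = _header_rate(header, str(path))
    nominal = float(header.get("NOMINAL_HZ", ["20"])[0])
    data = _parse_body(lines, start, 1, str(path))
    return SyncTrace(samples=data[:, 0], rate_hz=rate, nominal_freq_hz=nominal)


def write_sync_tsv(path: str | Path, sync: SyncTrace) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write(f"RATE_HZ\t{_FMT % sync.rate_hz}\n")
        fh.write(f"NOMINAL_HZ\t{_FMT % sync.nominal_freq_hz}\n")
        np.savetxt(fh, sync.samples[:, None], fmt=_FMT, delimiter="\t")


def _opt(header: dict[str, list[str]], key: str) -> str | None:
    return header[key][0] if key in header and header[key] else None


def _opt_int(header: dict[str, list[str]], key: str) -> int | None:
    v = _opt(header, key)
    return int(v) if v is not None else None


def _write_labels(fh, rec) -> None:
    if rec.side is not None:
        fh.write(f"SIDE\t{rec.side}\n")
    if rec.run is not None:
        fh.write(f"RUN\t{rec.run}\n")
    if rec.position is not None:
        fh.write(f"POSITION\t{rec.position}\n")


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------


def write_manifest(path: str | Path, manifest: SessionManifest) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write(f"SUBJECT_ID\t{manifest.subject_id}\n")
        fh.write(f"GROUP\t{manifest.group}\n")
        fh.write(f"CONTROL_SIDE\t{manifest.control_side}\n")
        fh.write("[RUNS]\n")
        fh.write("RUN\tPOSITION\tACTIVE_DOFS\tDURATION_S\n")
        for rd in manifest.runs:
            dofs = ",".join(str(d) for d in rd.active_dofs)
            fh.write(f"{rd.run_index}\t{rd.position}\t{dofs}\t{_FMT % rd.duration_s}\n")
        fh.write("[FILES]\n")
        fh.write("RUN\tPOSITION\tSIDE\tSTREAM\tPATH\n")
        for (run, pos, side, stream), p in sorted(manifest.files.items()):
            fh.write(f"{run}\t{pos}\t{side}\t{stream}\t{p}\n")


def read_manifest(path: str | Path) -> SessionManifest:
    path = Path(path)
    manifest = SessionManifest(subject_id="", group="able_bodied", root=path.parent)
    section = None
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        if line in ("[RUNS]", "[FILES]"):
            section = line
            continue
        parts = line.split("\t")
        if section is None:
            if len(parts) != 2:
                raise ManifestError(f"{path}:{lineno}: expected KEY\\tvalue")
            key, value = parts
            if key == "SUBJECT_ID":
                manifest.subject_id = value
            elif key == "GROUP":
                manifest.group = value
            elif key == "CONTROL_SIDE":
                manifest.control_side = value
            else:
                raise ManifestError(f"{path}:{lineno}: unknown key {key!r}")
        elif section == "[RUNS]":
            if parts[0] == "RUN":
                continue
            if len(parts) != 4:
                raise ManifestError(f"{path}:{lineno}: run row needs 4 fields")
            manifest.runs.append(
                RunDescriptor(
                    run_index=int(parts[0]),
                    position=parts[1],
                    active_dofs=tuple(int(d) for d in parts[2].split(",")),
                    duration_s=float(parts[3]),
                )
            )
        else:
            if parts[0] == "RUN":
                continue
            if len(parts) != 5:
                raise ManifestError(f"{path}:{lineno}: file row needs 5 fields")
            run, pos, side, stream, p = parts
            if stream not in STREAMS:
                raise ManifestError(f"{path}:{lineno}: unknown stream {stream!r}")
            manifest.files[(int(run), pos, side, stream)] = p
    if not manifest.subject_id:
        raise ManifestError(f"{path}: missing SUBJECT_ID")
    return manifest
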