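"""EEG recording / event I/O and the 16-channel 10/10 montage geometry.

The recording container holds a channels x samples matrix in microvolts at a
fixed sampling rate (256 Hz in the reference acquisition setup).  The montage
places the 16 electrodes (Fz, FC5, FC1, FCz, FC2, FC6, C3, Cz, C4, CP5, CP1,
CP2, CP6, P3, Pz, P4) on a unit sphere using the standard 10/10 arc
construction, and the distance table derived from it feeds the
inverse-distance Laplacian spatial filter.

Supported on-disk formats:

* EDF (16-bit European Data Format) — read through :mod:`mne`, written by a
  minimal built-in writer (1-second data records).
* Delimited text — one header row of channel labels, one row per sample,
  comma- or tab-separated, microvolts.
* Events — three-column delimited text ``onset_s<TAB>duration_s<TAB>label``.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "EEGRecording",
    "Montage",
    "DistanceTable",
    "Event",
    "EventList",
    "PAPER_CHANNELS",
    "load_recording",
    "save_recording",
    "standard_montage",
    "distances",
    "load_events",
    "save_events",
]

#: The 16 electrodes of the acquisition montage, in amplifier order.
PAPER_CHANNELS: tuple[str, ...] = (
    "Fz", "FC5", "FC1", "FCz", "FC2", "FC6", "C3", "Cz", "C4",
    "CP5", "CP1", "CP2", "CP6", "P3", "Pz", "P4",
)


class FormatError(ValueError):
    """A file could not be interpreted in the requested format."""


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class EEGRecording:
    """Multichannel EEG signal: ``data`` is (n_channels, n_samples) in uV."""

    data: np.ndarray
    fs: float
    labels: list[str]
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (channels x samples) array")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        self.labels = list(self.labels)
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate channel labels")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite samples in recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, data: np.ndarray) -> "EEGRecording":
        """New recording sharing metadata, with replaced sample data."""
        return EEGRecording(data, self.fs, list(self.labels), self.start_time)


@dataclass(frozen=True)
class Montage:
    """Electrode name -> 3-D unit-sphere position, plus reference/ground tags."""

    positions: Mapping[str, np.ndarray]
    reference: str = "right earlobe"
    ground: str = "AFz"

    def __post_init__(self) -> None:
        for name, p in self.positions.items():
            if abs(float(np.linalg.norm(p)) - 1.0) > 1e-6:
                raise ValueError(f"electrode {name} not on the unit sphere")

    @property
    def names(self) -> list[str]:
        return list(self.positions)


@dataclass(frozen=True)
class DistanceTable:
    """Symmetric chord-length distances between all electrode pairs."""

    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, float)
        n = len(self.labels)
        if d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("nonzero self-distance")
        off = d[~np.eye(n, dtype=bool)]
        if np.any(off <= 0):
            raise ValueError("non-positive inter-electrode distance")

    def value(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.d[i, j])


@dataclass(frozen=True)
class Event:
    onset: float
    duration: float
    label: str
    run: int = 0

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass
class EventList:
    """Ordered cue/annotation events; onsets nondecreasing, durations > 0."""

    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        onsets = [e.onset for e in self.events]
        if any(b < a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be nondecreasing")
        if any(e.duration <= 0 for e in self.events):
            raise ValueError("event durations must be positive")

    def __iter__(self):
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)

    def with_label(self, *labels: str) -> list[Event]:
        return [e for e in self.events if e.label in labels]


# --------------------------------------------------------------------------
# montage geometry
# --------------------------------------------------------------------------

# 10/10 arc construction on the unit sphere.  One 10 % step along either
# principal arc (nasion-inion or ear-to-ear, each spanning 180 degrees) is 18
# degrees.  A site is parametrised by its row's midline angle (from the vertex,
# positive toward the nasion) and its lateral rotation about the front-back
# axis (positive toward the right ear).  Odd electrode numbers are left.
_ROW_MIDLINE_DEG = {"F": 36.0, "FC": 18.0, "C": 0.0, "CP": -18.0, "P": -36.0}
_NUMBER_LATERAL_DEG = {0: 0.0, 1: 18.0, 2: 18.0, 3: 36.0, 4: 36.0,
                       5: 54.0, 6: 54.0, 7: 72.0, 8: 72.0}


def _site_position(name: str) -> np.ndarray:
    row = name.rstrip("z0123456789")
    suffix = name[len(row):]
    alpha = math.radians(_ROW_MIDLINE_DEG[row])
    if suffix == "z":
        num, side = 0, 1.0
    else:
        num = int(suffix)
        side = -1.0 if num % 2 else 1.0  # odd = left (-x), even = right (+x)
    beta = side * math.radians(_NUMBER_LATERAL_DEG[num])
    # Midline point (0, sin a, cos a) rotated by beta about the y (front) axis.
    x = math.cos(alpha) * math.sin(beta)
    y = math.sin(alpha)
    z = math.cos(alpha) * math.cos(beta)
    return np.array([x, y, z])


def standard_montage() -> Montage:
    """The 16-electrode 10/10 montage on the unit sphere.

    Axes: +x right, +y nasion (front), +z vertex; Cz is exactly (0, 0, 1).
    Reference is the right-earlobe tag and ground is AFz, matching the
    acquisition setup.
    """
    positions = {name: _site_position(name) for name in PAPER_CHANNELS}
    return Montage(positions=positions, reference="right earlobe", ground="AFz")


def load_montage(path: str | os.PathLike) -> Montage:
    """Read a user montage from ``name x y z`` rows (whitespace/comma split)."""
    positions: dict[str, np.ndarray] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 4:
            raise FormatError(f"montage row needs 4 fields: {line!r}")
        positions[parts[0]] = np.array([float(v) for v in parts[1:]])
    return Montage(positions=positions)


def distances(m: Montage) -> DistanceTable:
    """Chord (straight-line) distances between all electrode pairs."""
    names = tuple(m.names)
    pts = np.array([m.positions[n] for n in names])
    diff = pts[:, None, :] - pts[None, :, :]
    return DistanceTable(labels=names, d=np.linalg.norm(diff, axis=-1))


# --------------------------------------------------------------------------
# recording I/O
# --------------------------------------------------------------------------

def load_recording(path: str | os.PathLike, format: str | None = None) -> EEGRecording:
    """Load an EEG recording from EDF or delimited text.

    ``format`` is ``"edf"`` or ``"delimited"``; when omitted it is inferred
    from the file suffix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if format == "edf":
        return _load_edf(path)
    if format == "delimited":
        return _load_delimited(path)
    raise FormatError(f"unknown format {format!r}")


def save_recording(rec: EEGRecording, path: str | os.PathLike,
                   format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if format == "edf":
        _write_edf(rec, path)
    elif format == "delimited":
        header = "\t".join(rec.labels)
        np.savetxt(path, rec.data.T, fmt="%.6f", delimiter="\t",
                   header=header, comments="")
    else:
        raise FormatError(f"unknown format {format!r}")


def _load_delimited(path: Path) -> EEGRecording:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header:
            raise FormatError(f"{path}: empty file")
        delim = "\t" if "\t" in header else ","
        labels = [h.strip() for h in header.split(delim)]
        if any(_is_number(h) for h in labels):
            raise FormatError(f"{path}: missing channel-label header row")
        data = np.loadtxt(fh, delimiter=delim, ndmin=2)
    if data.shape[1] != len(labels):
        raise FormatError(
            f"{path}: {len(labels)} labels but {data.shape[1]} columns")
    # fs is not encoded in plain text; default to the acquisition rate.
    return EEGRecording(data.T, fs=256.0, labels=labels)


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def _load_edf(path: Path) -> EEGRecording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    labels = list(raw.ch_names)
    data = raw.get_data() * 1e6  # mne uses volts internally
    return EEGRecording(data, fs=fs, labels=labels)


def _write_edf(rec: EEGRecording, path: Path) -> None:
    """Minimal EDF writer: 16-bit samples, 1-second data records.

    Each channel is scaled linearly from its physical range onto the full
    digital range, so the round-trip error is bounded by one 16-bit
    quantisation step of the channel's peak-to-peak range.
    """
    fs = rec.fs
    spr = int(round(fs))  # samples per 1-s record
    if abs(spr - fs) > 1e-9:
        raise FormatError("EDF writer requires an integer sampling rate")
    n_ch = rec.n_channels
    n_rec = int(math.ceil(rec.n_samples / spr))
    total = n_rec * spr
    data = np.zeros((n_ch, total))
    data[:, : rec.n_samples] = rec.data

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    dmin, dmax = -32768, 32767

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii")
        if len(b) > width:
            raise FormatError(f"EDF header field too long: {text!r}")
        return b.ljust(width)

    header = b"".join([
        pad("0", 8), pad("X X X X", 80), pad("Startdate X X X X", 80),
        pad("01.01.00", 8), pad("00.00.00", 8),
        pad(str(256 * (n_ch + 1)), 8), pad("", 44),
        pad(str(n_rec), 8), pad("1", 8), pad(str(n_ch), 4),
    ])
    fields = [
        (16, rec.labels),
        (80, ["" for _ in range(n_ch)]),            # transducer
        (8, ["uV" for _ in range(n_ch)]),           # physical dimension
        (8, [f"{v:.8g}"[:8] for v in pmin]),
        (8, [f"{v:.8g}"[:8] for v in pmax]),
        (8, [str(dmin)] * n_ch),
        (8, [str(dmax)] * n_ch),
        (80, ["" for _ in range(n_ch)]),            # prefiltering
        (8, [str(spr)] * n_ch),
        (32, ["" for _ in range(n_ch)]),            # reserved
    ]
    sig_header = b"".join(
        b"".join(pad(v, width) for v in values) for width, values in fields
    )

    pmin_f = np.array([float(f"{v:.8g}"[:8]) for v in pmin])
    pmax_f = np.array([float(f"{v:.8g}"[:8]) for v in pmax])
    scale = (dmax - dmin) / (pmax_f - pmin_f)
    digital = np.round(
        (data - pmin_f[:, None]) * scale[:, None] + dmin
    ).clip(dmin, dmax).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for r in range(n_rec):
            sl = digital[:, r * spr : (r + 1) * spr]
            fh.write(sl.tobytes())


# --------------------------------------------------------------------------
# event I/O
# --------------------------------------------------------------------------

def load_events(path: str | os.PathLike) -> EventList:
    """Read events from ``onset_s  duration_s  label`` delimited rows."""
    events = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split(",")
        if len(parts) < 3:
            raise FormatError(f"event row needs 3 fields: {line!r}")
        run = int(parts[3]) if len(parts) > 3 else 0
        events.append(Event(float(parts[0]), float(parts[1]),
                            parts[2].strip(), run))
    return EventList(events=events)


def save_events(events: Iterable[Event], path: str | os.PathLike) -> None:
    lines = [f"{e.onset:.6f}\t{e.duration:.6f}\t{e.label}\t{e.run}"
             for e in events]
    Path(path).write_text("\n".join(lines) + "\n")
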