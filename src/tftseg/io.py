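"""Reading and writing multichannel EEG, and the 14-electrode montage.

The study montage is the Emotiv EPOC subset of the 10/20 system:
AF3, F7, F3, FC5, T7, P7, O1, O2, P8, T8, FC6, F4, F8, AF4, sampled at
128 Hz.  Two on-disk formats are supported: 16-bit EDF and a headered CSV
(one ``# rate=<Hz>`` comment line followed by a channel-label header).

All times are 0-based seconds and intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np

#: Channel labels of the 14-electrode study montage, in recording order.
STUDY_CHANNELS = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)

#: Default sampling rate of the study recordings (Hz).
STUDY_RATE = 128.0


@dataclass
class EEGRecording:
    """Channel-labelled sample matrix with sampling rate.

    Parameters
    ----------
    labels : sequence of str
        Unique channel names, one per matrix row.
    rate : float
        Sampling rate in Hz, strictly positive.
    samples : ndarray, shape (n_channels, n_times)
        Signal in microvolts.
    start_time : float
        Offset of the first sample in seconds.
    """

    labels: tuple[str, ...]
    rate: float
    samples: np.ndarray
    start_time: float = 0.0

    def __post_init__(self):
        self.labels = tuple(self.labels)
        self.samples = np.asarray(self.samples, dtype=float)
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.labels):
            raise ValueError(
                f"samples must be (n_channels={len(self.labels)}, n_times); "
                f"got shape {self.samples.shape}"
            )

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_times / self.rate

    def copy(self) -> "EEGRecording":
        return EEGRecording(self.labels, self.rate, self.samples.copy(),
                            self.start_time)


@dataclass
class Montage:
    """2-D scalp positions (head-circle projection) for a set of electrodes.

    Coordinates are unitless, x toward the right ear and y toward the
    nasion, all within the unit circle.  ``anterior`` flags electrodes in
    the front half used by the spatial artifact features.
    """

    positions: dict[str, tuple[float, float]]
    anterior: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self):
        for lab, (x, y) in self.positions.items():
            if np.hypot(x, y) > 1.0 + 1e-9:
                raise ValueError(f"electrode {lab} outside unit circle")

    def coords(self, labels) -> np.ndarray:
        """(n, 2) array of positions for ``labels`` in order."""
        missing = [l for l in labels if l not in self.positions]
        if missing:
            raise KeyError(f"labels absent from montage: {missing}")
        return np.array([self.positions[l] for l in labels], dtype=float)

    def distance(self, a: str, b: str) -> float:
        (xa, ya), (xb, yb) = self.positions[a], self.positions[b]
        return float(np.hypot(xa - xb, ya - yb))


def default_montage() -> Montage:
    """The 14-channel 10/20 subset with projected standard coordinates.

    Positions come from the standard 10/20 template (azimuthal equidistant
    projection onto the unit head circle).  Anterior/posterior is decided
    by nomenclature: AF*, F* and FC* rows are anterior, the rest posterior.
    """
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        std = mne.channels.make_standard_montage("standard_1020")
    pos3d = std.get_positions()["ch_pos"]
    positions: dict[str, tuple[float, float]] = {}
    for lab in STUDY_CHANNELS:
        x, y, z = pos3d[lab]
        v = np.array([x, y, z], dtype=float)
        v /= np.linalg.norm(v)
        theta = np.arccos(np.clip(v[2], -1.0, 1.0))  # inclination from vertex
        rho = min(theta / (np.pi / 2), 1.0)
        az = np.hypot(v[0], v[1])
        if az < 1e-12:
            positions[lab] = (0.0, 0.0)
        else:
            positions[lab] = (rho * v[0] / az, rho * v[1] / az)
    anterior = {lab: lab.startswith(("AF", "F")) for lab in STUDY_CHANNELS}
    return Montage(positions=positions, anterior=anterior)


# ---------------------------------------------------------------------------
# CSV

def _write_csv(rec: EEGRecording, path: Path) -> None:
    header = ",".join(rec.labels)
    with open(path, "w") as fh:
        fh.write(f"# rate={rec.rate:g} start_time={rec.start_time:g}\n")
        fh.write(header + "\n")
        np.savetxt(fh, rec.samples.T, fmt="%.6f", delimiter=",")


def _read_csv(path: Path) -> EEGRecording:
    with open(path) as fh:
        meta = fh.readline().strip()
        if not meta.startswith("#"):
            raise ValueError(f"{path}: missing '# rate=' metadata line")
        fields = dict(
            kv.split("=", 1) for kv in meta.lstrip("# ").split() if "=" in kv
        )
        if "rate" not in fields:
            raise ValueError(f"{path}: no sampling rate in header")
        rate = float(fields["rate"])
        start = float(fields.get("start_time", 0.0))
        labels = [c.strip() for c in fh.readline().strip().split(",")]
        data = np.loadtxt(fh, delimiter=",", ndmin=2)
    return EEGRecording(tuple(labels), rate, data.T, start)


# ---------------------------------------------------------------------------
# EDF (16-bit).  Written by hand; read back through mne.

_EDF_SAMPLES_PER_RECORD_MAX = 9999


def _edf_ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def _write_edf(rec: EEGRecording, path: Path) -> None:
    nchan = rec.n_channels
    n = rec.n_times
    # choose a record layout: one-second records when the sample count
    # divides evenly, otherwise a single record holding everything
    spr = int(round(rec.rate))
    if spr > 0 and n % spr == 0 and spr <= _EDF_SAMPLES_PER_RECORD_MAX:
        n_records, rec_dur = n // spr, spr / rec.rate
    else:
        spr, n_records, rec_dur = n, 1, n / rec.rate
    phys_min = np.floor(rec.samples.min(axis=1))
    phys_max = np.ceil(rec.samples.max(axis=1))
    flat = phys_max - phys_min < 1e-9
    phys_max[flat] = phys_min[flat] + 1.0

    now = datetime(2000, 1, 1)
    hdr = b""
    hdr += _edf_ascii("0", 8)
    hdr += _edf_ascii("X X X X", 80)                      # patient id
    hdr += _edf_ascii("Startdate X X X X", 80)            # recording id
    hdr += _edf_ascii(now.strftime("%d.%m.%y"), 8)
    hdr += _edf_ascii(now.strftime("%H.%M.%S"), 8)
    hdr += _edf_ascii(256 + 256 * nchan, 8)
    hdr += _edf_ascii("", 44)
    hdr += _edf_ascii(n_records, 8)
    hdr += _edf_ascii(f"{rec_dur:.6g}", 8)
    hdr += _edf_ascii(nchan, 4)
    for lab in rec.labels:
        hdr += _edf_ascii(lab, 16)
    hdr += b" " * 80 * nchan                              # transducer
    for _ in range(nchan):
        hdr += _edf_ascii("uV", 8)
    for v in phys_min:
        hdr += _edf_ascii(f"{v:.6g}", 8)
    for v in phys_max:
        hdr += _edf_ascii(f"{v:.6g}", 8)
    for _ in range(nchan):
        hdr += _edf_ascii(-32768, 8)
    for _ in range(nchan):
        hdr += _edf_ascii(32767, 8)
    hdr += b" " * 80 * nchan                              # prefiltering
    for _ in range(nchan):
        hdr += _edf_ascii(spr, 8)
    hdr += b" " * 32 * nchan                              # reserved
    assert len(hdr) == 256 + 256 * nchan

    scale = (phys_max - phys_min) / (32767.0 - (-32768.0))
    digital = np.round(
        (rec.samples - phys_min[:, None]) / scale[:, None] - 32768.0
    ).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_records):
            block = digital[:, r * spr:(r + 1) * spr]
            fh.write(block.tobytes())


def _read_edf(path: Path) -> EEGRecording:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne holds Volts; study units are uV
    return EEGRecording(tuple(raw.ch_names), float(raw.info["sfreq"]), data)


# ---------------------------------------------------------------------------

def read_eeg(path, format: str | None = None) -> EEGRecording:
    """Read an :class:`EEGRecording` from EDF or headered CSV.

    ``format`` is inferred from the suffix when not given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty file")
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "edf":
        return _read_edf(path)
    if fmt == "csv":
        return _read_csv(path)
    raise ValueError(f"unknown EEG format: {fmt!r}")


def write_eeg(rec: EEGRecording, path, format: str | None = None) -> Path:
    """Write a recording as EDF (16-bit) or headered CSV; returns the path."""
    path = Path(path)
    if rec.n_times == 0:
        raise ValueError("refusing to write a zero-length recording")
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "edf":
        _write_edf(rec, path)
    elif fmt == "csv":
        _write_csv(rec, path)
    else:
        raise ValueError(f"unknown EEG format: {fmt!r}")
    return path
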