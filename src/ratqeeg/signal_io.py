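"""Recording and study-metadata I/O.

On-disk data model
------------------
* one EDF file per subject (16-bit records, physical range +/-500 uV);
* a YAML sidecar per recording (``<name>.yaml``) with behavioural markers,
  subject/treatment annotations and the administration time;
* CSV tables for every pipeline output.

The EDF writer is a deliberately small, plain-EDF implementation (no
annotations channel — markers live in the sidecar, because EDF+
annotation support across readers is inconsistent).  Reading goes through
MNE's native EDF reader, which doubles as an independent check on the
writer in the test suite.

All signal values are microvolts end to end; all times are seconds from
recording start.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .montage import ElectrodeLayout, default_layout

__all__ = [
    "Marker",
    "Recording",
    "StudyManifest",
    "SubjectEntry",
    "MARKER_LABELS",
    "write_recording",
    "read_recording",
    "write_results",
]

MARKER_LABELS = ("active", "inactive", "handling", "sleep_suspect", "artifact")

#: EDF physical half-range in uV (the acquisition hardware's dynamic range)
EDF_HALF_RANGE_UV = 500.0


@dataclass(frozen=True)
class Marker:
    start: float
    end: float
    label: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"marker has negative length: {self}")
        if self.label not in MARKER_LABELS:
            raise ValueError(f"unknown marker label {self.label!r}")


@dataclass
class Recording:
    """A multichannel recording in uV with behavioural markers.

    ``data`` is (n_channels, n_samples) in layout order; ``admin_time`` is
    the substance-administration time in seconds from recording start.
    """

    data: np.ndarray
    sfreq: float
    layout: ElectrodeLayout
    markers: list = field(default_factory=list)
    subject_id: str = ""
    group: str = ""
    admin_time: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be (n_channels, n_samples)")
        if self.data.shape[0] != self.layout.n_channels:
            raise ValueError(
                f"{self.data.shape[0]} channels but layout has {self.layout.n_channels}"
            )
        for m in self.markers:
            if m.start < 0 or m.end > self.duration + 1e-9:
                raise ValueError(f"marker {m} outside [0, {self.duration}]")

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.sfreq

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.layout.labels.index(label)]

    def markers_with_label(self, label: str) -> "list[Marker]":
        return [m for m in self.markers if m.label == label]


@dataclass(frozen=True)
class SubjectEntry:
    subject_id: str
    group: str
    path: str = ""


@dataclass
class StudyManifest:
    """Subjects (each recorded once) and the named analysis-epoch windows.

    ``baseline_window`` is absolute seconds; ``post_windows`` are offsets
    from the administration time, so absolute epoch positions are derived
    per recording, never hard-coded.
    """

    subjects: list = field(default_factory=list)
    baseline_window: tuple = (0.0, 600.0)
    post_windows: dict = field(
        default_factory=lambda: {
            "E1": (1200.0, 1800.0),
            "E2": (3000.0, 3600.0),
            "E3": (4200.0, 4800.0),
        }
    )

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(ids) != len(set(ids)):
            raise ValueError("each subject may appear only once in the manifest")
        wins = sorted(self.post_windows.values())
        for (a0, a1), (b0, b1) in zip(wins, wins[1:]):
            if b0 < a1:
                raise ValueError("post-treatment epoch windows overlap")

    def epoch_windows(self, admin_time: float) -> dict:
        """Absolute (start, end) for every epoch of one recording."""
        out = {"baseline": tuple(self.baseline_window)}
        for name, (off0, off1) in self.post_windows.items():
            out[name] = (admin_time + off0, admin_time + off1)
        return out

    @property
    def epoch_names(self) -> list:
        return ["baseline", *self.post_windows]


# ---------------------------------------------------------------------------
# EDF


def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _write_edf(path, data_uv, sfreq, labels, half_range=EDF_HALF_RANGE_UV):
    """Write a plain EDF file: int16 records of 1 s, physical +/-half_range uV."""
    n_ch, n_samples = data_uv.shape
    spr = int(round(sfreq))  # samples per 1-s record
    if abs(sfreq - spr) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_records = int(np.ceil(n_samples / spr))
    padded = np.zeros((n_ch, n_records * spr))
    padded[:, :n_samples] = data_uv

    dig_min, dig_max = -32768, 32767
    phys_min, phys_max = -half_range, half_range
    gain = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.clip(np.round((padded - phys_min) * gain) + dig_min, dig_min, dig_max)
    digital = digital.astype("<i2")

    header = b""
    header += _edf_field("0", 8)  # version
    header += _edf_field("X X X X", 80)  # patient id
    header += _edf_field("Startdate X X X X", 80)  # recording id
    header += _edf_field("01.01.00", 8)
    header += _edf_field("00.00.00", 8)
    header += _edf_field(256 + 256 * n_ch, 8)
    header += _edf_field("", 44)
    header += _edf_field(n_records, 8)
    header += _edf_field(1, 8)  # record duration, s
    header += _edf_field(n_ch, 4)
    for lab in labels:
        header += _edf_field(f"EEG {lab}", 16)
    header += b"".join(_edf_field("AgAgCl screw", 80) for _ in labels)
    header += b"".join(_edf_field("uV", 8) for _ in labels)
    header += b"".join(_edf_field(phys_min, 8) for _ in labels)
    header += b"".join(_edf_field(phys_max, 8) for _ in labels)
    header += b"".join(_edf_field(dig_min, 8) for _ in labels)
    header += b"".join(_edf_field(dig_max, 8) for _ in labels)
    header += b"".join(_edf_field("", 80) for _ in labels)  # prefiltering
    header += b"".join(_edf_field(spr, 8) for _ in labels)
    header += b"".join(_edf_field("", 32) for _ in labels)  # reserved

    with open(path, "wb") as fh:
        fh.write(header)
        # records: per record, per channel, spr int16 samples
        for r in range(n_records):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())


def edf_lsb_uv(half_range: float = EDF_HALF_RANGE_UV) -> float:
    """Physical value of one digital unit in the EDF container."""
    return 2 * half_range / (32767 + 32768)


def write_recording(path, recording: Recording, ground_truth=None) -> None:
    """EDF + YAML sidecar (+ optional ground-truth CSVs for simulations)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    _write_edf(path, recording.data, recording.sfreq, recording.layout.labels)
    sidecar = {
        "subject_id": recording.subject_id,
        "group": recording.group,
        "admin_time": recording.admin_time,
        "sampling_rate": float(recording.sfreq),
        "markers": [
            {"start": float(m.start), "end": float(m.end), "label": m.label}
            for m in recording.markers
        ],
    }
    with open(path.with_suffix(".yaml"), "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=True)
    if ground_truth is not None:
        ground_truth.band_power.to_csv(
            path.with_name(path.stem + "_truth_power.csv"), index=False
        )
        ground_truth.lagged_coherence.to_csv(
            path.with_name(path.stem + "_truth_coherence.csv"), index=False
        )


def read_recording(path, layout: ElectrodeLayout | None = None,
                   expected_sfreq: float | None = None) -> Recording:
    """Read an EDF recording plus its sidecar, normalised to layout order.

    Raises if any layout channel is absent or the sampling rate disagrees
    with the manifest's expectation.
    """
    import mne

    if layout is None:
        layout = default_layout()
    path = Path(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    sfreq = float(raw.info["sfreq"])
    if expected_sfreq is not None and abs(sfreq - expected_sfreq) > 1e-6:
        raise ValueError(
            f"sampling rate {sfreq} Hz in {path.name} does not match the "
            f"manifest's {expected_sfreq} Hz"
        )
    name_map = {}
    for ch in raw.ch_names:
        name_map[ch.removeprefix("EEG ").strip()] = ch
    rows = []
    for lab in layout.labels:
        if lab not in name_map:
            raise ValueError(f"channel {lab!r} missing from {path.name}")
        rows.append(raw.get_data(picks=[name_map[lab]])[0])
    data = np.vstack(rows) * 1e6  # MNE returns volts

    sidecar_path = path.with_suffix(".yaml")
    markers, subject_id, group, admin_time = [], path.stem, "", None
    if sidecar_path.exists():
        with open(sidecar_path) as fh:
            sc = yaml.safe_load(fh)
        subject_id = sc.get("subject_id", subject_id)
        group = sc.get("group", "")
        admin_time = sc.get("admin_time")
        markers = [Marker(m["start"], m["end"], m["label"]) for m in sc.get("markers", [])]
    return Recording(
        data=data, sfreq=sfreq, layout=layout, markers=markers,
        subject_id=subject_id, group=group, admin_time=admin_time,
    )


# ---------------------------------------------------------------------------
# result tables


def write_results(tables: "dict[str, pd.DataFrame]", output_dir) -> "list[Path]":
    """Write pipeline output tables as deterministically formatted CSVs.

    Keys become file names (``<key>.csv``).  Floats are written with
    repr-round-trip precision so a rerun on identical inputs produces
    byte-identical files.
    """
    out = Path(output_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_test"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out} is not writable: {exc}") from exc
    written = []
    for name in sorted(tables):
        df = tables[name]
        dest = out / f"{name}.csv"
        df.to_csv(dest, index=False, lineterminator="\n")
        written.append(dest)
    return written
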