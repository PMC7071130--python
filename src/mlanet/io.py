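"""Containers and I/O for 12-lead ECG records, beats, and reports.

Records travel either as plain CSV matrices (one column per lead, one row
per sample) or as WFDB-style header/signal pairs (``.hea`` + 16-bit ``.dat``),
the layout used by PhysioNet archives.  Segmented beats are stored as a
compressed numpy container next to a CSV manifest carrying labels and
patient IDs, so the label table stays human-diffable.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .leads import LEAD_NAMES, N_LEADS, canonical_lead, FRANK_LEADS

BEAT_LENGTH = 651  # 250 samples before the R peak + the peak + 400 after


class FormatError(ValueError):
    """Raised when a file does not parse as the expected ECG format."""


@dataclasses.dataclass
class EcgRecord:
    """One multichannel ECG record: 12 leads x T samples, in millivolts."""

    signals: np.ndarray
    fs: float = 1000.0
    lead_names: tuple = LEAD_NAMES
    patient_id: str = ""
    record_id: str = ""
    label: str = ""

    def __post_init__(self):
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2 or self.signals.shape[0] != N_LEADS:
            raise ValueError(
                f"record must be {N_LEADS} x T, got {self.signals.shape}")
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")
        self.lead_names = tuple(self.lead_names)

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    def lead(self, name: str) -> np.ndarray:
        return self.signals[LEAD_NAMES.index(canonical_lead(name))]


@dataclasses.dataclass
class BeatSample:
    """One segmented heartbeat: 12 x 651 matrix plus label and patient ID."""

    L: np.ndarray
    label: str
    patient_id: str

    def __post_init__(self):
        self.L = np.asarray(self.L, dtype=float)
        if self.L.shape != (N_LEADS, BEAT_LENGTH):
            raise ValueError(
                f"beat must be {N_LEADS} x {BEAT_LENGTH}, got {self.L.shape}")
        if not np.all(np.isfinite(self.L)):
            raise ValueError("beat contains non-finite values")


@dataclasses.dataclass
class BeatDataset:
    """A labelled collection of beats with per-beat patient provenance."""

    beats: list
    class_names: tuple

    def __post_init__(self):
        self.class_names = tuple(self.class_names)
        for b in self.beats:
            if b.label not in self.class_names:
                raise ValueError(
                    f"beat label {b.label!r} not in class set {self.class_names}")

    def __len__(self) -> int:
        return len(self.beats)

    def to_arrays(self):
        """(N, 12, 651) float array, integer labels, patient-ID array."""
        X = np.stack([b.L for b in self.beats])
        y = np.array([self.class_names.index(b.label) for b in self.beats])
        pids = np.array([b.patient_id for b in self.beats])
        return X, y, pids

    def subset(self, indices) -> "BeatDataset":
        return BeatDataset([self.beats[i] for i in indices], self.class_names)

    @property
    def patient_ids(self):
        return np.array([b.patient_id for b in self.beats])

    @property
    def labels(self):
        return np.array([b.label for b in self.beats])


# -- record I/O ---------------------------------------------------------------

def _reorder_channels(signals: np.ndarray, names: list) -> np.ndarray:
    """Select the 12 canonical leads (by name) in canonical order."""
    canon = {}
    for i, nm in enumerate(names):
        low = str(nm).strip().lower()
        if low in (f.lower() for f in FRANK_LEADS):
            continue
        try:
            canon[canonical_lead(nm)] = i
        except KeyError:
            continue  # unrelated extra channel
    missing = [nm for nm in LEAD_NAMES if nm not in canon]
    if missing:
        raise FormatError(f"record is missing lead(s): {', '.join(missing)}")
    return signals[[canon[nm] for nm in LEAD_NAMES]]


def read_record(path, format: str | None = None, patient_id: str = "",
                record_id: str = "", label: str = "") -> EcgRecord:
    """Read an ECG record from CSV or a WFDB header/signal pair.

    Channels are reordered to the canonical lead order by name; Frank leads
    and other extra channels are dropped.
    """
    path = Path(path)
    if format is None:
        format = "wfdb" if path.suffix == ".hea" else "csv"
    if format == "csv":
        df = pd.read_csv(path)
        if df.shape[1] < N_LEADS:
            raise FormatError(
                f"CSV has {df.shape[1]} channels; {N_LEADS} leads required")
        signals = _reorder_channels(df.to_numpy(dtype=float).T, list(df.columns))
        fs = 1000.0
    elif format == "wfdb":
        signals, fs = _read_wfdb(path)
    else:
        raise ValueError(f"unknown record format: {format!r}")
    return EcgRecord(signals, fs=fs, patient_id=patient_id,
                     record_id=record_id or path.stem, label=label)


def write_record(record: EcgRecord, path, format: str = "csv") -> None:
    path = Path(path)
    if format == "csv":
        df = pd.DataFrame(record.signals.T, columns=list(record.lead_names))
        df.to_csv(path, index=False)
    elif format == "wfdb":
        _write_wfdb(record, path)
    else:
        raise ValueError(f"unknown record format: {format!r}")


_WFDB_GAIN = 8000.0  # ADC units per mV; int16 range then spans ~±4 mV


def _write_wfdb(record: EcgRecord, hea_path: Path) -> None:
    hea_path = Path(hea_path)
    if hea_path.suffix != ".hea":
        hea_path = hea_path.with_suffix(".hea")
    name = hea_path.stem
    dat_name = name + ".dat"
    n_sig, n_samp = record.signals.shape
    lines = [f"{name} {n_sig} {record.fs:g} {n_samp}"]
    adc = np.round(record.signals * _WFDB_GAIN).astype(np.int16)
    for i, lead in enumerate(record.lead_names):
        lines.append(
            f"{dat_name} 16 {_WFDB_GAIN:g}/mV 16 0 {adc[i, 0]} 0 0 {lead}")
    hea_path.write_text("\n".join(lines) + "\n")
    # format 16: samples interleaved across signals, little-endian int16
    adc.T.astype("<i2").tofile(hea_path.parent / dat_name)


def _read_wfdb(hea_path: Path):
    lines = [ln for ln in Path(hea_path).read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    n_sig = int(head[1])
    fs = float(head[2]) if len(head) > 2 else 1000.0
    if n_sig < N_LEADS:
        raise FormatError(
            f"WFDB record has {n_sig} channels; {N_LEADS} leads required")
    sig_lines = lines[1:1 + n_sig]
    names, gains, files = [], [], []
    for ln in sig_lines:
        fields = ln.split()
        files.append(fields[0])
        if fields[1].split("x")[0] != "16":
            raise FormatError(f"unsupported WFDB signal format: {fields[1]}")
        gain_field = fields[2].split("/")[0].split("(")[0] if len(fields) > 2 else "200"
        gains.append(float(gain_field) or 200.0)
        names.append(fields[-1])
    if len(set(files)) != 1:
        raise FormatError("multi-file WFDB records are not supported")
    raw = np.fromfile(Path(hea_path).parent / files[0], dtype="<i2")
    raw = raw.reshape(-1, n_sig).T.astype(float)
    signals = raw / np.asarray(gains)[:, None]
    return _reorder_channels(signals, names), fs


def write_label_table(records, path) -> None:
    """Sidecar CSV mapping record_id -> patient_id, label."""
    pd.DataFrame(
        [(r.record_id, r.patient_id, r.label) for r in records],
        columns=["record_id", "patient_id", "label"],
    ).to_csv(path, index=False)


def read_label_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    required = {"record_id", "patient_id", "label"}
    if not required.issubset(df.columns):
        raise FormatError(f"label table must have columns {sorted(required)}")
    return df


# -- beat container I/O -------------------------------------------------------

def _manifest_path(path: Path) -> Path:
    return path.with_suffix(".manifest.csv")


def write_beats(dataset: BeatDataset, path) -> None:
    """Write beats as compressed arrays plus a CSV manifest of labels/IDs."""
    if len(dataset) == 0:
        raise ValueError("refusing to write an empty beat dataset")
    path = Path(path)
    X, y, pids = dataset.to_arrays()
    np.savez_compressed(path, beats=X.astype(np.float32),
                        class_names=np.array(dataset.class_names))
    pd.DataFrame({
        "beat_index": np.arange(len(dataset)),
        "patient_id": pids,
        "label": dataset.labels,
    }).to_csv(_manifest_path(path), index=False)


def read_beats(path) -> BeatDataset:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    with np.load(path, allow_pickle=False) as z:
        X = z["beats"].astype(float)
        class_names = tuple(str(c) for c in z["class_names"])
    manifest = pd.read_csv(_manifest_path(path), dtype={"patient_id": str})
    if len(manifest) != X.shape[0]:
        raise FormatError(
            f"manifest rows ({len(manifest)}) != beat count ({X.shape[0]})")
    if X.ndim != 3 or X.shape[1:] != (N_LEADS, BEAT_LENGTH):
        raise FormatError(
            f"beat array must be N x {N_LEADS} x {BEAT_LENGTH}, got {X.shape}")
    beats = [BeatSample(X[i], str(manifest.label[i]), str(manifest.patient_id[i]))
             for i in range(X.shape[0])]
    return BeatDataset(beats, class_names)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
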