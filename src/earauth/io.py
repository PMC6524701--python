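"""Reading and writing recordings and corpus manifests.

Two on-disk formats are supported:

* **CSV** — lossless: one header row of channel labels, one sample per
  row, full float precision, with a JSON sidecar (``<file>.json``)
  carrying subject/task/trial identity and the sampling rate.
* **EDF** — the European Data Format, 16-bit: each channel becomes one
  signal with physical unit µV over a configurable physical range
  (default ±1000 µV), so the quantization step is (2 x 1000)/65535 ≈
  0.03 µV, far below signal amplitudes.  EDF files are read back through
  MNE.

A corpus is a directory of recording files plus a flat-table manifest
(CSV) listing path, subject, task, trial, sampling rate and channel
count for every file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .recording import Corpus, Recording

MANIFEST_FORMAT_VERSION = "1"
DEFAULT_PHYSICAL_RANGE_UV = 1000.0
_DIG_MIN, _DIG_MAX = -32768, 32767


@dataclass(frozen=True)
class ManifestEntry:
    path: str
    subject_id: str
    task_name: str
    trial_index: int
    fs: float
    n_channels: int
    format: str


def edf_quantization_step(physical_range_uv: float = DEFAULT_PHYSICAL_RANGE_UV) -> float:
    """Worst-case amplitude resolution of a written EDF file (µV/step)."""
    return 2.0 * physical_range_uv / (_DIG_MAX - _DIG_MIN)


def _edf_field(value: str, width: int) -> bytes:
    b = value.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field {value!r} exceeds {width} ascii bytes")
    return b.ljust(width)


def _write_edf(rec: Recording, path: Path, physical_range_uv: float) -> None:
    """Minimal EDF writer: one data record holding the whole trial."""
    pmin, pmax = -physical_range_uv, physical_range_uv
    if rec.data.min() < pmin or rec.data.max() > pmax:
        raise ValueError(
            f"sample amplitudes exceed the EDF physical range ±{physical_range_uv} µV; "
            "increase physical_range_uv"
        )
    ns = rec.n_channels
    n_samples = rec.n_samples
    record_duration = n_samples / rec.fs

    header = b"".join(
        [
            _edf_field("0", 8),  # version
            _edf_field(f"{rec.subject_id}", 80),
            _edf_field(f"task {rec.task_name} trial {rec.trial_index}", 80),
            _edf_field("01.01.00", 8),
            _edf_field("00.00.00", 8),
            _edf_field(str(256 * (ns + 1)), 8),
            _edf_field("", 44),
            _edf_field("1", 8),  # one data record
            _edf_field(f"{record_duration:g}", 8),
            _edf_field(str(ns), 4),
        ]
    )
    sig = b"".join(
        [
            b"".join(_edf_field(lbl, 16) for lbl in rec.channel_labels),
            b"".join(_edf_field("", 80) for _ in range(ns)),  # transducer
            b"".join(_edf_field("uV", 8) for _ in range(ns)),
            b"".join(_edf_field(f"{pmin:g}", 8) for _ in range(ns)),
            b"".join(_edf_field(f"{pmax:g}", 8) for _ in range(ns)),
            b"".join(_edf_field(str(_DIG_MIN), 8) for _ in range(ns)),
            b"".join(_edf_field(str(_DIG_MAX), 8) for _ in range(ns)),
            b"".join(_edf_field("", 80) for _ in range(ns)),  # prefiltering
            b"".join(_edf_field(str(n_samples), 8) for _ in range(ns)),
            b"".join(_edf_field("", 32) for _ in range(ns)),
        ]
    )
    scale = (pmax - pmin) / (_DIG_MAX - _DIG_MIN)
    digital = np.round((rec.data - pmin) / scale + _DIG_MIN).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        fh.write(digital.tobytes())  # signal-by-signal within the record


def _read_edf(path: Path) -> tuple[np.ndarray, float, tuple[str, ...]]:
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # MNE loads EDF in volts
    return data_uv, float(raw.info["sfreq"]), tuple(raw.ch_names)


def _write_csv(rec: Recording, path: Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(rec.channel_labels) + "\n")
        np.savetxt(fh, rec.data.T, fmt="%.17g", delimiter=",")
    sidecar = {
        "subject_id": rec.subject_id,
        "task_name": rec.task_name,
        "trial_index": rec.trial_index,
        "fs": rec.fs,
        "channel_labels": list(rec.channel_labels),
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1), encoding="utf-8")


def write_recording(
    rec: Recording,
    path: str | Path,
    format: str = "csv",
    physical_range_uv: float = DEFAULT_PHYSICAL_RANGE_UV,
) -> Path:
    """Write one recording as EDF or CSV; returns the written path."""
    path = Path(path)
    fmt = format.lower()
    if fmt == "edf":
        _write_edf(rec, path, physical_range_uv)
    elif fmt == "csv":
        _write_csv(rec, path)
    else:
        raise ValueError(f"unsupported format {format!r}: choose 'edf' or 'csv'")
    return path


def read_recording(
    path: str | Path,
    subject_id: str | None = None,
    task_name: str | None = None,
    trial_index: int | None = None,
    fs: float | None = None,
) -> Recording:
    """Read one EDF or CSV recording, attaching identity labels.

    For CSV the sidecar supplies identity/rate; explicit arguments
    override it.  For EDF, identity must be supplied by the caller (or the
    manifest) since the EDF header stores it only as free text.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"recording file not found: {path}")
    if path.suffix.lower() == ".edf":
        data, fs_read, labels = _read_edf(path)
        return Recording(
            data=data,
            fs=fs if fs is not None else fs_read,
            channel_labels=labels,
            subject_id=subject_id or "unknown",
            task_name=task_name or "unknown",
            trial_index=trial_index if trial_index is not None else 0,
        )
    sidecar_path = Path(str(path) + ".json")
    meta = {}
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text(encoding="utf-8"))
    df = pd.read_csv(path, float_precision="round_trip")
    return Recording(
        data=df.to_numpy(dtype=np.float64).T,
        fs=fs if fs is not None else float(meta.get("fs", 200.0)),
        channel_labels=tuple(df.columns),
        subject_id=subject_id or meta.get("subject_id", "unknown"),
        task_name=task_name or meta.get("task_name", "unknown"),
        trial_index=trial_index if trial_index is not None else int(meta.get("trial_index", 0)),
    )


def write_corpus(
    corpus: Corpus,
    directory: str | Path,
    format: str = "csv",
    physical_range_uv: float = DEFAULT_PHYSICAL_RANGE_UV,
) -> Path:
    """Write every recording plus a manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fmt = format.lower()
    entries = []
    for rec in corpus:
        fname = f"{rec.subject_id}_{rec.task_name}_{rec.trial_index:02d}.{fmt}"
        write_recording(rec, directory / fname, format=fmt, physical_range_uv=physical_range_uv)
        entries.append(
            {
                "path": fname,
                "subject_id": rec.subject_id,
                "task_name": rec.task_name,
                "trial_index": rec.trial_index,
                "fs": rec.fs,
                "n_channels": rec.n_channels,
                "format": fmt,
            }
        )
    manifest = directory / "manifest.csv"
    df = pd.DataFrame(entries)
    df.insert(0, "format_version", MANIFEST_FORMAT_VERSION)
    df.to_csv(manifest, index=False)
    return manifest


def read_corpus(manifest_path: str | Path) -> Corpus:
    """Load a corpus from its manifest.

    Fails if the manifest schema version is unsupported, if any referenced
    file is missing (the error names the entry), or if a
    (subject, task, trial) triple appears twice.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    df = pd.read_csv(manifest_path)
    required = {"path", "subject_id", "task_name", "trial_index", "fs", "n_channels"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"manifest missing columns: {sorted(missing_cols)}")
    versions = set(df.get("format_version", pd.Series([MANIFEST_FORMAT_VERSION])).astype(str))
    if not versions <= {MANIFEST_FORMAT_VERSION}:
        raise ValueError(f"unsupported manifest format_version(s): {sorted(versions)}")

    triples = list(zip(df["subject_id"], df["task_name"], df["trial_index"]))
    if len(set(triples)) != len(triples):
        dupes = sorted({t for t in triples if triples.count(t) > 1})
        raise ValueError(f"duplicate (subject, task, trial) entries in manifest: {dupes}")

    base = manifest_path.parent
    recs = []
    for row in df.itertuples(index=False):
        fpath = base / row.path
        if not fpath.exists():
            raise FileNotFoundError(
                f"manifest entry ({row.subject_id}, {row.task_name}, trial "
                f"{row.trial_index}) refers to missing file {fpath}"
            )
        rec = read_recording(
            fpath,
            subject_id=str(row.subject_id),
            task_name=str(row.task_name),
            trial_index=int(row.trial_index),
            fs=float(row.fs),
        )
        if rec.n_channels != int(row.n_channels):
            raise ValueError(
                f"{fpath}: manifest says {row.n_channels} channels, file has {rec.n_channels}"
            )
        recs.append(rec)
    return Corpus(recordings=recs)
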