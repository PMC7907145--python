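"""Recording I/O: delimited matrices with JSON sidecars, minimal EDF, manifests.

The delimited format is a tab-separated channels x samples matrix plus a
``<name>.json`` sidecar carrying labels, sampling rate, and class label.
The EDF reader/writer covers the plain continuous subset of the format
(one data record, 16-bit samples with per-signal physical scaling), enough
for round-tripping synthetic cohorts and reading simple exports.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Union

import numpy as np

from eegtopo.synth_eeg import Recording

__all__ = [
    "write_recording",
    "read_recording",
    "write_edf",
    "read_edf",
    "write_cohort",
    "read_cohort",
]

PathLike = Union[str, Path]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_recording(rec: Recording, path: PathLike) -> Path:
    """Write a TSV matrix plus JSON sidecar; returns the data path."""
    path = Path(path)
    np.savetxt(path, rec.data, delimiter="\t", fmt="%.10g")
    sidecar = {
        "subject_id": rec.subject_id,
        "label": int(rec.label),
        "channel_labels": list(rec.channel_labels),
        "sampling_rate": float(rec.sampling_rate),
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return path


def _read_delimited(path: Path) -> Recording:
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"missing sidecar {sidecar_path} (expected next to {path})"
        )
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    for key in ("subject_id", "label", "channel_labels", "sampling_rate"):
        if key not in meta:
            raise ValueError(f"sidecar {sidecar_path} missing field {key!r}")
    if meta["sampling_rate"] <= 0:
        raise ValueError(f"sidecar {sidecar_path}: sampling_rate must be > 0")
    try:
        data = np.loadtxt(path, delimiter="\t", ndmin=2)
    except ValueError as exc:
        raise ValueError(f"malformed delimited matrix {path}: {exc}") from exc
    return Recording(
        subject_id=str(meta["subject_id"]),
        label=int(meta["label"]),
        channel_labels=[str(c) for c in meta["channel_labels"]],
        sampling_rate=float(meta["sampling_rate"]),
        data=data,
    )


# -- minimal EDF ----------------------------------------------------------

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: Recording, path: PathLike) -> Path:
    """Single-data-record EDF with per-channel physical scaling."""
    path = Path(path)
    ns = rec.n_channels
    n_samples = rec.n_samples
    duration = rec.duration
    header = b"".join(
        [
            _field(0, 8),
            _field(rec.subject_id, 80),
            _field(f"label={int(rec.label)}", 80),
            _field("01.01.00", 8),
            _field("00.00.00", 8),
            _field(256 + ns * 256, 8),
            _field("", 44),
            _field(1, 8),
            _field(f"{duration:g}", 8),
            _field(ns, 4),
        ]
    )
    pmins = rec.data.min(axis=1)
    pmaxs = rec.data.max(axis=1)
    # widen degenerate ranges so the gain is finite
    flat = pmaxs - pmins <= 0
    pmaxs = np.where(flat, pmins + 1.0, pmaxs)
    sig_fields = []
    for getter, width in (
        (lambda i: rec.channel_labels[i], 16),
        (lambda i: "", 80),
        (lambda i: "uV", 8),
        (lambda i: f"{pmins[i]:.8g}"[:8], 8),
        (lambda i: f"{pmaxs[i]:.8g}"[:8], 8),
        (lambda i: _DIG_MIN, 8),
        (lambda i: _DIG_MAX, 8),
        (lambda i: "", 80),
        (lambda i: n_samples, 8),
        (lambda i: "", 32),
    ):
        sig_fields.append(b"".join(_field(getter(i), width) for i in range(ns)))
    # physical min/max written with limited precision: reparse so scaling is exact
    pmins_w = np.array([float(f"{v:.8g}"[:8]) for v in pmins])
    pmaxs_w = np.array([float(f"{v:.8g}"[:8]) for v in pmaxs])
    gains = (pmaxs_w - pmins_w) / (_DIG_MAX - _DIG_MIN)
    digital = np.round((rec.data - pmins_w[:, None]) / gains[:, None] + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        for block in sig_fields:
            fh.write(block)
        fh.write(digital.tobytes())  # one record: signals back to back
    return path


def read_edf(path: PathLike) -> Recording:
    path = Path(path)
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise ValueError(f"truncated EDF header in {path}")
        subject_id = head[8:88].decode("ascii", "replace").strip()
        recording_field = head[88:168].decode("ascii", "replace").strip()
        n_records = int(head[236:244].decode().strip())
        record_duration = float(head[244:252].decode().strip())
        ns = int(head[252:256].decode().strip())
        if ns <= 0:
            raise ValueError(f"{path}: no signals")
        sig_head = fh.read(ns * 256)
        if len(sig_head) < ns * 256:
            raise ValueError(f"truncated EDF signal headers in {path}")

        def col(offset: int, width: int) -> List[str]:
            base = offset * ns
            return [
                sig_head[base + i * width : base + (i + 1) * width].decode().strip()
                for i in range(ns)
            ]

        labels = col(0, 16)
        pmin = np.array([float(v) for v in col(16 + 80 + 8, 8)])
        pmax = np.array([float(v) for v in col(16 + 80 + 8 + 8, 8)])
        dmin = np.array([float(v) for v in col(16 + 80 + 8 + 16, 8)])
        dmax = np.array([float(v) for v in col(16 + 80 + 8 + 24, 8)])
        spr = np.array([int(v) for v in col(16 + 80 + 8 + 32 + 80, 8)])
        raw = fh.read()
    expected = 2 * int(spr.sum()) * n_records
    if len(raw) < expected:
        raise ValueError(f"{path}: expected {expected} data bytes, found {len(raw)}")
    if record_duration <= 0:
        raise ValueError(f"{path}: non-positive record duration")
    fs = spr / record_duration
    if np.any(np.abs(fs - fs[0]) > 1e-9):
        raise ValueError(f"{path}: signals with mixed sampling rates are not supported")
    values = np.frombuffer(raw[:expected], dtype="<i2").astype(np.float64)
    data = np.empty((ns, int(spr[0]) * n_records))
    per_record = int(spr.sum())
    for rec_i in range(n_records):
        pos = rec_i * per_record
        for si in range(ns):
            data[si, rec_i * spr[si] : (rec_i + 1) * spr[si]] = values[pos : pos + spr[si]]
            pos += spr[si]
    gains = (pmax - pmin) / (dmax - dmin)
    data = (data - dmin[:, None]) * gains[:, None] + pmin[:, None]
    label = 0
    if "label=" in recording_field:
        try:
            label = int(recording_field.split("label=")[1].split()[0])
        except (ValueError, IndexError):
            label = 0
    return Recording(
        subject_id=subject_id or path.stem,
        label=label,
        channel_labels=labels,
        sampling_rate=float(fs[0]),
        data=data,
    )


def read_recording(path: PathLike, format: str = "auto") -> Recording:
    """Read one recording; ``format`` in {'auto', 'edf', 'delimited'}."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if format == "edf":
        return read_edf(path)
    if format == "delimited":
        return _read_delimited(path)
    raise ValueError(f"unknown format {format!r} (expected 'edf' or 'delimited')")


# -- cohort manifests -----------------------------------------------------


def write_cohort(recordings, out_dir: PathLike, format: str = "delimited") -> Path:
    """One file per subject plus a manifest.json; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in recordings:
        if format == "edf":
            fname = f"{rec.subject_id}.edf"
            write_edf(rec, out_dir / fname)
        elif format == "delimited":
            fname = f"{rec.subject_id}.tsv"
            write_recording(rec, out_dir / fname)
        else:
            raise ValueError(f"unknown format {format!r}")
        entries.append(
            {
                "subject_id": rec.subject_id,
                "label": int(rec.label),
                "path": fname,
                "sampling_rate": float(rec.sampling_rate),
            }
        )
    manifest = out_dir / "manifest.json"
    with open(manifest, "w") as fh:
        json.dump({"format": format, "recordings": entries}, fh, indent=1)
    return manifest


def read_cohort(cohort_dir: PathLike) -> List[Recording]:
    cohort_dir = Path(cohort_dir)
    manifest = cohort_dir / "manifest.json"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.json in {cohort_dir}")
    with open(manifest) as fh:
        meta = json.load(fh)
    fmt = meta.get("format", "delimited")
    return [read_recording(cohort_dir / e["path"], fmt) for e in meta["recordings"]]
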