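"""Readers and writers for recordings, templates and result tables.

Two subject formats are supported: EDF (European Data Format, the clinical
interchange format) and a plain delimited matrix (samples x channels TSV
with a header row of electrode labels).  Either carries a structured-text
sidecar (JSON) with sampling rate, epoch boundaries and subject metadata.

The EDF writer here is a minimal single-purpose implementation (16-bit,
per-channel physical scaling, 1 s data records); no EDF-writing library is
part of this package's dependency set, while reading goes through MNE.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import TemplateSet
from .montage import Montage, ifcn25
from .recording import EEGRecording

__all__ = [
    "write_matrix",
    "write_edf",
    "read_recording",
    "write_recording",
    "write_templates",
    "read_templates",
    "write_segmentation",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- sidecar

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _write_sidecar(path: Path, rec: EEGRecording, extra: dict | None = None) -> None:
    meta = {
        "fs_hz": rec.fs_hz,
        "epochs": [[int(a), int(b)] for a, b in rec.epochs],
        "subject_id": rec.subject_id,
        "group": rec.group,
        "migraine": bool(rec.migraine),
    }
    if extra:
        meta.update(extra)
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def _read_sidecar(path: Path) -> dict:
    sc = _sidecar_path(path)
    if sc.exists():
        return json.loads(sc.read_text())
    return {}


# ----------------------------------------------------------- matrix format

def write_matrix(path: str | Path, rec: EEGRecording, extra_meta: dict | None = None) -> Path:
    """Write samples x channels TSV with a header row of electrode labels."""
    path = Path(path)
    header = "\t".join(rec.montage.labels)
    # %.17g preserves doubles exactly, so write->read is bit-identical
    np.savetxt(path, rec.data.T, delimiter="\t", header=header, comments="", fmt="%.17g")
    _write_sidecar(path, rec, extra_meta)
    return path


def _read_matrix(path: Path, montage: Montage | None) -> EEGRecording:
    with open(path) as fh:
        labels = fh.readline().strip().split("\t")
    data = np.loadtxt(path, delimiter="\t", skiprows=1).T
    meta = _read_sidecar(path)
    montage = _resolve_montage(labels, montage)
    return _build_recording(data, montage, meta, default_id=path.stem)


# -------------------------------------------------------------- EDF format

_EDF_DIG_MAX = 32767


def _phys_ascii(v: float) -> str:
    """Positive physical-maximum as <= 7 ASCII chars (leaves room for '-')."""
    for prec in range(6, 0, -1):
        s = f"{v:.{prec}g}"
        if len(s) <= 7:
            return s
    return f"{v:.0e}"


def _ascii(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path: str | Path, rec: EEGRecording, extra_meta: dict | None = None) -> Path:
    """Write a 16-bit EDF file with 1-second data records.

    Each channel gets a symmetric physical range from its own absolute
    maximum, so the quantization step is |data|_max / 32767 per channel.
    Only whole seconds are written; a trailing partial second is dropped
    with a warning.  Epochs and group metadata go to the JSON sidecar.
    """
    path = Path(path)
    fs = rec.fs_hz
    spr = int(round(fs))
    if abs(fs - spr) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_rec = rec.n_samples // spr
    if n_rec * spr != rec.n_samples:
        logger.warning(
            "EDF write %s: dropping %d trailing samples (partial second)",
            path.name, rec.n_samples - n_rec * spr,
        )
    E = rec.n_channels
    data = rec.data[:, : n_rec * spr]
    pmax = np.maximum(np.abs(data).max(axis=1), 1e-6)
    # quantize against the header's truncated ASCII value, so the reader's
    # affine decoding inverts ours exactly
    pmax_str = [_phys_ascii(p) for p in pmax]
    pmax = np.array([float(s) for s in pmax_str])
    scale = _EDF_DIG_MAX / pmax
    digital = np.clip(
        np.round(data * scale[:, None]), -_EDF_DIG_MAX, _EDF_DIG_MAX
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(_ascii("0", 8))
        fh.write(_ascii(rec.subject_id, 80))
        fh.write(_ascii("Startdate 01-JAN-2000", 80))
        fh.write(_ascii("01.01.00", 8))
        fh.write(_ascii("00.00.00", 8))
        fh.write(_ascii(256 * (E + 1), 8))
        fh.write(_ascii("", 44))
        fh.write(_ascii(n_rec, 8))
        fh.write(_ascii(1, 8))
        fh.write(_ascii(E, 4))
        for lab in rec.montage.labels:
            fh.write(_ascii(lab, 16))
        fh.write(b" " * 80 * E)  # transducer
        for _ in range(E):
            fh.write(_ascii("uV", 8))
        for s in pmax_str:
            fh.write(_ascii("-" + s, 8))
        for s in pmax_str:
            fh.write(_ascii(s, 8))
        for _ in range(E):
            fh.write(_ascii(-_EDF_DIG_MAX, 8))
        for _ in range(E):
            fh.write(_ascii(_EDF_DIG_MAX, 8))
        fh.write(b" " * 80 * E)  # prefiltering
        for _ in range(E):
            fh.write(_ascii(spr, 8))
        fh.write(b" " * 32 * E)
        for r in range(n_rec):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())
    T = n_rec * spr
    clipped = rec.with_data(data, epochs=[
        (a, min(b, T)) for a, b in rec.epochs if a < T
    ])
    _write_sidecar(path, clipped, extra_meta)
    return path


def _read_edf(path: Path, montage: Montage | None) -> EEGRecording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE returns volts
    meta = _read_sidecar(path)
    montage = _resolve_montage(list(raw.ch_names), montage)
    if "fs_hz" not in meta:
        meta["fs_hz"] = float(raw.info["sfreq"])
    return _build_recording(data, montage, meta, default_id=path.stem)


# ------------------------------------------------------------------ common

def _resolve_montage(labels: list[str], montage: Montage | None) -> Montage:
    """Match file channel labels against a montage (default: IFCN-25)."""
    ref = montage or ifcn25()
    by_lower = {l.lower(): l for l in labels}
    missing = [l for l in ref.labels if l.lower() not in by_lower]
    if montage is None and len(missing) == len(ref.labels):
        # unfamiliar labels: accept them as an ad-hoc montage
        return Montage(labels=tuple(labels))
    if missing:
        raise ValueError(f"missing channel(s) in file: {', '.join(missing)}")
    return ref


def _build_recording(
    data: np.ndarray, montage: Montage, meta: dict, default_id: str
) -> EEGRecording:
    return EEGRecording(
        data=data,
        fs_hz=float(meta.get("fs_hz", 250.0)),
        montage=montage,
        epochs=[tuple(e) for e in meta.get("epochs", [])],
        subject_id=str(meta.get("subject_id", default_id)),
        group=str(meta.get("group", "")),
        migraine=bool(meta.get("migraine", False)),
    )


def read_recording(path: str | Path, fmt: str | None = None, montage: Montage | None = None) -> EEGRecording:
    """Read a subject recording (EDF or delimited matrix).

    ``fmt`` defaults from the file suffix (.edf -> EDF, otherwise matrix).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "matrix"
    if fmt == "edf":
        return _read_edf(path, montage)
    if fmt == "matrix":
        return _read_matrix(path, montage)
    raise ValueError(f"unknown format {fmt!r}")


def write_recording(path: str | Path, rec: EEGRecording, fmt: str | None = None) -> Path:
    path = Path(path)
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "matrix"
    if fmt == "edf":
        return write_edf(path, rec)
    if fmt == "matrix":
        return write_matrix(path, rec)
    raise ValueError(f"unknown format {fmt!r}")


# -------------------------------------------------------------- templates

def write_templates(path: str | Path, tset: TemplateSet) -> Path:
    """Rows = electrodes, columns = classes; level and GEV in comment lines."""
    path = Path(path)
    lines = [f"# level: {tset.level}"]
    if tset.gev is not None:
        lines.append(f"# gev: {tset.gev:.12g}")
    labels = tset.montage.labels if tset.montage else tuple(
        f"ch{i}" for i in range(tset.n_channels)
    )
    lines.append("electrode\t" + "\t".join(tset.labels))
    for i, lab in enumerate(labels):
        lines.append(lab + "\t" + "\t".join(f"{v:.10g}" for v in tset.maps[:, i]))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_templates(path: str | Path, montage: Montage | None = None) -> TemplateSet:
    path = Path(path)
    level, gev_val = "individual", None
    rows, class_labels, electrodes = [], None, []
    for line in path.read_text().splitlines():
        if line.startswith("# level:"):
            level = line.split(":", 1)[1].strip()
        elif line.startswith("# gev:"):
            gev_val = float(line.split(":", 1)[1])
        elif class_labels is None:
            class_labels = line.split("\t")[1:]
        elif line.strip():
            parts = line.split("\t")
            electrodes.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    maps = np.array(rows).T
    return TemplateSet(
        maps=maps, labels=tuple(class_labels), level=level, gev=gev_val, montage=montage
    )


# ------------------------------------------------------------ segmentation

def write_segmentation(path: str | Path, seg, subject_id: str, class_labels: tuple[str, ...]) -> Path:
    """Segment rows: subject, epoch, start_ms, end_ms, class, truncated, mean_gfp."""
    path = Path(path)
    rows = []
    for s in seg.segments:
        epoch = next(i for i, (a, b) in enumerate(seg.epochs) if a <= s.start < b)
        rows.append(
            {
                "subject": subject_id,
                "epoch": epoch,
                "start_ms": 1000.0 * s.start / seg.fs_hz,
                "end_ms": 1000.0 * s.stop / seg.fs_hz,
                "class": class_labels[s.cls],
                "truncated": s.truncated,
                "mean_gfp": s.mean_gfp,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path
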