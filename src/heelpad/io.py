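"""File formats: stance CSV, pressure-plate XML, cohort manifest.

Three plain-text dialects are supported:

stance CSV
    header ``frame,time_s,thickness_mm,force_N,area_cm2``, one row per
    frame; the complete synchronized recording in one file.
plate XML
    ``<recording frame_rate="50"><frame t="..."><force>..</force>
    <area>..</area></frame>...</recording>`` — a minimal stand-in for a
    pressure plate's XML export (the vendor schema is proprietary, so
    this dialect is defined here and documented as synthetic).
thickness CSV
    header ``frame,thickness_mm``; the fluoroscopy-derived thickness
    series, merged with a plate XML on read.

All writes are atomic (temp file + rename) so re-running a stage with
identical inputs reproduces identical files and a crash never leaves a
half-written output behind.
"""

from __future__ import annotations

import csv
import io as _io
import os
import tempfile
import warnings
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import StanceRecording
from .errors import AlignmentError, HeelpadError, ParameterError

__all__ = [
    "atomic_write_text",
    "write_stance_csv",
    "read_stance_csv",
    "write_plate_xml",
    "read_plate_xml",
    "write_thickness_csv",
    "read_thickness_csv",
    "read_recording",
    "write_recording",
    "write_cohort",
    "read_manifest",
]

DEFAULT_FRAME_RATE = 50.0

STANCE_HEADER = ["frame", "time_s", "thickness_mm", "force_N", "area_cm2"]
THICKNESS_HEADER = ["frame", "thickness_mm"]


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write text via a temporary file and an atomic rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _check_contiguous_frames(frames: np.ndarray, where: str) -> None:
    expected = np.arange(len(frames))
    if not np.array_equal(frames, expected):
        raise HeelpadError(f"{where}: frame indices must run 0..n-1 contiguously")


def write_stance_csv(rec: StanceRecording, path: str | Path) -> None:
    buf = _io.StringIO()
    w = csv.writer(buf)
    w.writerow(STANCE_HEADER)
    for i in range(rec.n_frames):
        w.writerow([
            i,
            repr(float(rec.time[i])),
            repr(float(rec.thickness[i])),
            repr(float(rec.force[i])),
            repr(float(rec.area[i])),
        ])
    atomic_write_text(path, buf.getvalue())


def read_stance_csv(path: str | Path) -> StanceRecording:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as err:
        raise HeelpadError(f"cannot parse stance CSV {path}: {err}") from err
    missing = set(STANCE_HEADER) - set(df.columns)
    if missing:
        raise HeelpadError(f"{path}: missing columns {sorted(missing)}")
    _check_contiguous_frames(df["frame"].to_numpy(), str(path))
    time = df["time_s"].to_numpy(dtype=float)
    if len(time) >= 2:
        frame_rate = 1.0 / float(np.mean(np.diff(time)))
    else:
        frame_rate = DEFAULT_FRAME_RATE
    return StanceRecording(
        time=time,
        thickness=df["thickness_mm"].to_numpy(dtype=float),
        force=df["force_N"].to_numpy(dtype=float),
        area=df["area_cm2"].to_numpy(dtype=float),
        frame_rate=frame_rate,
        meta={"source": str(path), "dialect": "stance_csv"},
    )


def write_plate_xml(rec: StanceRecording, path: str | Path) -> None:
    root = ET.Element("recording", frame_rate=repr(float(rec.frame_rate)))
    for i in range(rec.n_frames):
        frame = ET.SubElement(root, "frame", t=repr(float(rec.time[i])))
        ET.SubElement(frame, "force").text = repr(float(rec.force[i]))
        ET.SubElement(frame, "area").text = repr(float(rec.area[i]))
    ET.indent(root)
    atomic_write_text(path, ET.tostring(root, encoding="unicode") + "\n")


def read_plate_xml(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Parse a plate XML into (time, force, area, frame_rate)."""
    try:
        tree = ET.parse(path)
    except ET.ParseError as err:
        raise HeelpadError(f"malformed plate XML {path}: {err}") from err
    root = tree.getroot()
    if root.tag != "recording":
        raise HeelpadError(f"{path}: root element is <{root.tag}>, expected <recording>")
    fr_attr = root.get("frame_rate")
    if fr_attr is None:
        warnings.warn(
            f"{path}: no frame_rate attribute; assuming the pre-set {DEFAULT_FRAME_RATE:g} Hz",
            stacklevel=2,
        )
        frame_rate = DEFAULT_FRAME_RATE
    else:
        frame_rate = float(fr_attr)
        if frame_rate <= 0:
            raise HeelpadError(f"{path}: frame_rate must be positive")
    times, forces, areas = [], [], []
    for k, frame in enumerate(root.iter("frame")):
        force_el = frame.find("force")
        area_el = frame.find("area")
        if force_el is None or area_el is None:
            raise HeelpadError(f"{path}: frame {k} lacks <force> or <area>")
        t_attr = frame.get("t")
        times.append(float(t_attr) if t_attr is not None else k / frame_rate)
        forces.append(float(force_el.text))
        areas.append(float(area_el.text))
    return (np.asarray(times), np.asarray(forces), np.asarray(areas), frame_rate)


def write_thickness_csv(rec: StanceRecording, path: str | Path) -> None:
    buf = _io.StringIO()
    w = csv.writer(buf)
    w.writerow(THICKNESS_HEADER)
    for i in range(rec.n_frames):
        w.writerow([i, repr(float(rec.thickness[i]))])
    atomic_write_text(path, buf.getvalue())


def read_thickness_csv(path: str | Path) -> np.ndarray:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as err:
        raise HeelpadError(f"cannot parse thickness CSV {path}: {err}") from err
    missing = set(THICKNESS_HEADER) - set(df.columns)
    if missing:
        raise HeelpadError(f"{path}: missing columns {sorted(missing)}")
    _check_contiguous_frames(df["frame"].to_numpy(), str(path))
    return df["thickness_mm"].to_numpy(dtype=float)


def read_recording(
    stance_csv: str | Path | None = None,
    thickness_csv: str | Path | None = None,
    plate_xml: str | Path | None = None,
) -> StanceRecording:
    """Assemble a recording from either a stance CSV or the split
    thickness-CSV + plate-XML pair (which must agree on frame count)."""
    if stance_csv is not None:
        return read_stance_csv(stance_csv)
    if thickness_csv is None or plate_xml is None:
        raise ParameterError(
            "provide either stance_csv or both thickness_csv and plate_xml"
        )
    thickness = read_thickness_csv(thickness_csv)
    time, force, area, frame_rate = read_plate_xml(plate_xml)
    if len(thickness) != len(time):
        raise AlignmentError(
            f"frame counts differ: {thickness_csv} has {len(thickness)}, "
            f"{plate_xml} has {len(time)}"
        )
    return StanceRecording(
        time=time,
        thickness=thickness,
        force=force,
        area=area,
        frame_rate=frame_rate,
        meta={"source": f"{thickness_csv}+{plate_xml}", "dialect": "split"},
    )


def write_recording(rec: StanceRecording, path: str | Path, dialect: str = "stance_csv") -> None:
    if dialect == "stance_csv":
        write_stance_csv(rec, path)
    elif dialect == "plate_xml":
        write_plate_xml(rec, path)
    elif dialect == "thickness_csv":
        write_thickness_csv(rec, path)
    else:
        raise ParameterError(f"unknown dialect '{dialect}'")


MANIFEST_NAME = "manifest.csv"


def write_cohort(dataset, out_dir: str | Path) -> Path:
    """Write every member's stance CSV plus a flat manifest.

    The manifest carries the design keys, relative file paths, the true
    generating parameters (for recovery studies) and the subject
    covariates.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for m in dataset:
        fname = f"{m.subject}_{m.leg}_{m.status}.csv"
        write_stance_csv(m.recording, out_dir / fname)
        row = {
            "subject": m.subject,
            "leg": m.leg,
            "group": m.group,
            "status": m.status,
            "file": fname,
            "true_E_kPa": m.kv.E,
            "true_eta_kPa_s": m.kv.eta,
            "true_h0_mm": m.kv.h0,
            "true_peak_strain": m.peak_strain_target,
        }
        row.update(m.covariates)
        rows.append(row)
    manifest = pd.DataFrame(rows)
    atomic_write_text(out_dir / MANIFEST_NAME, manifest.to_csv(index=False))
    return out_dir / MANIFEST_NAME


def read_manifest(manifest_path: str | Path) -> pd.DataFrame:
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    needed = {"subject", "leg", "group", "status", "file"}
    missing = needed - set(df.columns)
    if missing:
        raise HeelpadError(f"{manifest_path}: manifest lacks columns {sorted(missing)}")
    return df
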