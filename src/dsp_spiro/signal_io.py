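"""Readers/writers for the on-disk session formats.

Conventions: mono 16-bit PCM WAV for audio; CSV with header
``t_s,ax_g,ay_g,az_g`` for the accelerometer; JSON for breath annotations
and the session manifest. All manifest paths are relative to the manifest
file. Readers reject malformed input rather than coercing it.
"""
from __future__ import annotations

import json
import struct
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .errors import AlignmentError, DataError, FormatError
from .types import (AudioRecording, BreathTimeline, ImuRecording, MODES,
                    Session, SubjectProfile)

IMU_COLUMNS = ["t_s", "ax_g", "ay_g", "az_g"]


def write_audio(rec: AudioRecording, path) -> None:
    """Write mono PCM16 WAV; amplitudes clipped to [-1, 1) full scale."""
    scaled = np.clip(rec.samples, -1.0, 32767.0 / 32768.0)
    pcm = np.round(scaled * 32768.0).astype(np.int16)
    wavfile.write(str(path), int(rec.rate), pcm)


def read_audio(path) -> AudioRecording:
    """Read mono PCM16 WAV into a dimensionless-amplitude recording."""
    try:
        rate, data = wavfile.read(str(path))
    except (ValueError, EOFError, struct.error) as exc:
        raise FormatError(f"not a readable WAV file: {path}: {exc}") from exc
    if data.ndim != 1:
        raise FormatError(f"expected mono audio, got {data.shape[1]} channels")
    if data.dtype != np.int16:
        raise FormatError(f"expected 16-bit PCM, got dtype {data.dtype}")
    return AudioRecording(rate=float(rate), samples=data.astype(float) / 32768.0)


def write_imu(rec: ImuRecording, path) -> None:
    df = pd.DataFrame({"t_s": rec.t, "ax_g": rec.ax, "ay_g": rec.ay,
                       "az_g": rec.az})
    df.to_csv(path, index=False, float_format="%.9g")


def read_imu(path) -> ImuRecording:
    """Read the IMU CSV; sampling rate is inferred from the median time step."""
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"unreadable IMU CSV {path}: {exc}") from exc
    missing = [c for c in IMU_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"IMU CSV missing columns {missing}")
    t = df["t_s"].to_numpy(dtype=float)
    if len(t) >= 2 and not np.all(np.diff(t) > 0):
        raise DataError("IMU timestamps are not strictly increasing")
    rate = 1.0 / float(np.median(np.diff(t))) if len(t) >= 2 else 1.0
    return ImuRecording(rate=rate, t=t, ax=df["ax_g"].to_numpy(float),
                        ay=df["ay_g"].to_numpy(float),
                        az=df["az_g"].to_numpy(float))


def write_annotation(timeline: BreathTimeline, subject_id: str, path) -> None:
    doc = {"subject_id": subject_id, "mode": timeline.mode,
           "duration": timeline.duration,
           "closing_insp_start": timeline.closing_insp_start,
           "cycles": [{"insp_start": c[0], "exp_start": c[1], "cycle_end": c[2]}
                      for c in timeline.cycles]}
    Path(path).write_text(json.dumps(doc, indent=1))


def read_annotation(path) -> BreathTimeline:
    try:
        doc = json.loads(Path(path).read_text())
        cycles = tuple((c["insp_start"], c["exp_start"], c["cycle_end"])
                       for c in doc["cycles"])
        return BreathTimeline(cycles=cycles, mode=doc["mode"],
                              duration=doc["duration"],
                              closing_insp_start=doc.get("closing_insp_start"))
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise FormatError(f"unreadable annotation {path}: {exc}") from exc


def write_manifest(path, audio_file: str, imu_file: str,
                   profile: SubjectProfile, mode: str,
                   annotation_file: Optional[str] = None) -> None:
    doc = {"audio": audio_file, "imu": imu_file, "mode": mode,
           "subject": {"subject_id": profile.subject_id, "age": profile.age,
                       "sex": profile.sex, "bmi": profile.bmi,
                       "ethnicity": profile.ethnicity,
                       "fvc_ref": profile.fvc_ref, "fev1_ref": profile.fev1_ref,
                       "pef_ref": profile.pef_ref}}
    if annotation_file is not None:
        doc["annotation"] = annotation_file
    Path(path).write_text(json.dumps(doc, indent=1))


def load_session(manifest_path) -> Session:
    """Assemble a time-aligned Session from a JSON manifest."""
    manifest_path = Path(manifest_path)
    try:
        doc = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"unreadable manifest {manifest_path}: {exc}") from exc
    for key in ("audio", "imu", "mode", "subject"):
        if key not in doc:
            raise FormatError(f"manifest missing key {key!r}")
    if doc["mode"] not in MODES:
        raise FormatError(f"unknown mode {doc['mode']!r} in manifest")
    base = manifest_path.parent
    audio = read_audio(base / doc["audio"])
    imu = read_imu(base / doc["imu"])
    try:
        profile = SubjectProfile(**doc["subject"])
    except TypeError as exc:
        raise FormatError(f"bad subject block in manifest: {exc}") from exc
    annotation = (read_annotation(base / doc["annotation"])
                  if "annotation" in doc else None)
    return Session(subject_id=profile.subject_id, mode=doc["mode"],
                   audio=audio, imu=imu, profile=profile,
                   annotation=annotation)


def save_session(session: Session, out_dir, stem: Optional[str] = None) -> Path:
    """Write audio, IMU, annotation (if present) and a manifest; returns the
    manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = stem or f"{session.subject_id}_{session.mode}"
    write_audio(session.audio, out_dir / f"{stem}.wav")
    write_imu(session.imu, out_dir / f"{stem}_imu.csv")
    annot_file = None
    if session.annotation is not None:
        annot_file = f"{stem}_annotation.json"
        write_annotation(session.annotation, session.subject_id,
                         out_dir / annot_file)
    manifest = out_dir / f"{stem}_manifest.json"
    write_manifest(manifest, f"{stem}.wav", f"{stem}_imu.csv",
                   session.profile, session.mode, annot_file)
    return manifest
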