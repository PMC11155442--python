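"""File formats: exam-recording container, cohort CSV, results JSON.

The recording container is a single file per exam: a JSON metadata header
(probe spec, protocol context, subject id, sector, optional ground truth)
followed by the per-frame timestamp and pressure vectors (float64) and the
frame-major sample matrix as little-endian float32. A plain-text CSV
fallback exists for small fixtures. All readers check an embedded format
version tag.
"""
from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import ExamRecording, Frame, ProbeSpec, TissueModel

MAGIC = b"CMREC\x00"
FORMAT_VERSION = 1


class SchemaError(ValueError):
    """File does not conform to the documented schema."""


def _header_dict(recording: ExamRecording) -> dict:
    header = {
        "format": "cervelast-recording",
        "version": FORMAT_VERSION,
        "subject_id": recording.subject_id,
        "sector": recording.sector,
        "probe": dataclasses.asdict(recording.probe),
        "n_frames": len(recording.frames),
        "n_samples": int(recording.frames[0].samples.shape[0]) if recording.frames else 0,
    }
    if recording.ground_truth is not None:
        header["ground_truth"] = dataclasses.asdict(recording.ground_truth)
    return header


def _recording_from_parts(header: dict, timestamps: np.ndarray,
                          pressures: np.ndarray, samples: np.ndarray) -> ExamRecording:
    for key in ("version", "subject_id", "sector", "probe", "n_frames", "n_samples"):
        if key not in header:
            raise SchemaError(f"recording header missing field '{key}'")
    if header["version"] != FORMAT_VERSION:
        raise SchemaError(
            f"unsupported recording format version {header['version']} "
            f"(expected {FORMAT_VERSION})")
    probe = ProbeSpec(**header["probe"])
    truth = TissueModel(**header["ground_truth"]) if "ground_truth" in header else None
    frames = tuple(
        Frame(timestamp_s=float(t), applied_pressure_kpa=float(p), samples=s)
        for t, p, s in zip(timestamps, pressures, samples)
    )
    return ExamRecording(subject_id=header["subject_id"], sector=header["sector"],
                         probe=probe, frames=frames, ground_truth=truth)


def write_recording(path: str | Path, recording: ExamRecording) -> None:
    """Write the binary container: magic, header length, JSON header, arrays."""
    header = json.dumps(_header_dict(recording)).encode()
    n_frames = len(recording.frames)
    with open(path, "wb") as fh:
        fh.write(MAGIC)
        fh.write(np.uint32(len(header)).tobytes())
        fh.write(header)
        fh.write(recording.timestamps_s().astype("<f8").tobytes())
        fh.write(recording.pressures_kpa().astype("<f8").tobytes())
        if n_frames:
            fh.write(np.ascontiguousarray(recording.sample_matrix(), dtype="<f4").tobytes())


def read_recording(path: str | Path) -> ExamRecording:
    with open(path, "rb") as fh:
        if fh.read(len(MAGIC)) != MAGIC:
            raise SchemaError("bad magic: not a cervelast recording container")
        (header_len,) = np.frombuffer(fh.read(4), dtype=np.uint32)
        try:
            header = json.loads(fh.read(int(header_len)).decode())
        except (UnicodeDecodeError, json.JSONDecodeError) as exc:
            raise SchemaError(f"corrupt recording header: {exc}") from exc
        n_frames, n_samples = header.get("n_frames"), header.get("n_samples")
        if n_frames is None or n_samples is None:
            raise SchemaError("recording header missing field 'n_frames'/'n_samples'")
        timestamps = np.frombuffer(fh.read(8 * n_frames), dtype="<f8")
        pressures = np.frombuffer(fh.read(8 * n_frames), dtype="<f8")
        raw = np.frombuffer(fh.read(4 * n_frames * n_samples), dtype="<f4")
        if raw.size != n_frames * n_samples:
            raise SchemaError("truncated sample matrix")
        samples = raw.astype(float).reshape(n_frames, n_samples)
    return _recording_from_parts(header, timestamps, pressures, samples)


def write_recording_csv(path: str | Path, recording: ExamRecording) -> None:
    """Plain-text fallback: '#'-prefixed JSON header, then one row per frame."""
    header = json.dumps(_header_dict(recording))
    matrix = recording.sample_matrix()
    cols = ["timestamp_s", "pressure_kpa"] + [f"s{i:05d}" for i in range(matrix.shape[1] if matrix.size else 0)]
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        fh.write(",".join(cols) + "\n")
        for t, p, row in zip(recording.timestamps_s(), recording.pressures_kpa(), matrix):
            fh.write(f"{float(t)!r},{float(p)!r},"
                     + ",".join(repr(float(v)) for v in row) + "\n")


def read_recording_csv(path: str | Path) -> ExamRecording:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# "):
            raise SchemaError("missing recording header comment line")
        try:
            header = json.loads(first[2:])
        except json.JSONDecodeError as exc:
            raise SchemaError(f"corrupt recording header: {exc}") from exc
        body = pd.read_csv(fh)
    timestamps = body["timestamp_s"].to_numpy(float)
    pressures = body["pressure_kpa"].to_numpy(float)
    samples = body.drop(columns=["timestamp_s", "pressure_kpa"]).to_numpy(float)
    return _recording_from_parts(header, timestamps, pressures, samples)


# ---------------------------------------------------------------- cohort CSV

REQUIRED_COHORT_COLUMNS = (
    "subject_id", "group", "maternal_age_years", "height_cm", "weight_kg",
    "parity", "prior_ptb", "ga_exam_days", "ga_birth_days",
)


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read a subject table, requiring the core schema columns.

    Unknown extra columns are accepted with a warning (forward
    compatibility); missing required columns are a schema error.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort CSV missing required columns: {missing}")
    known_prefixes = ("true_", "elasticity_", "length_", "r2_", "n_frames_",
                      "valid_", "fit_", "avg_", "comfort", "spontaneous_delivery",
                      "single_sector")
    for col in df.columns:
        if col in REQUIRED_COHORT_COLUMNS:
            continue
        if not col.startswith(known_prefixes):
            warnings.warn(f"cohort CSV has unknown column '{col}' (accepted)",
                          stacklevel=2)
    return df


# ---------------------------------------------------------------- results JSON

def write_results_json(results: dict, path: str | Path) -> None:
    def default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if dataclasses.is_dataclass(obj):
            return dataclasses.asdict(obj)
        raise TypeError(f"not JSON serialisable: {type(obj)}")

    with open(path, "w") as fh:
        json.dump({"format": "cervelast-results", "version": FORMAT_VERSION, **results},
                  fh, indent=2, default=default)
        fh.write("\n")


def read_results_json(path: str | Path) -> dict:
    with open(path) as fh:
        data = json.load(fh)
    if data.get("version") != FORMAT_VERSION:
        raise SchemaError(f"unsupported results version {data.get('version')}")
    return data
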