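"""Session readers/writers.

A session directory holds: ``pupil.csv`` (frame, pupil_mm, gaze_x, gaze_y,
eye_state; blank cell = missing), ``annotations.csv`` (start_frame,
end_frame, label, intensity; 0-based half-open), ``audio.wav`` (float32
mono), ``frames/`` (zero-padded PNGs) and ``session.json`` (ids, rates,
baseline, optional ground truth).  The CSV reader sniffs the delimiter
(comma or semicolon) and decimal convention, since eye-tracker exports
vary.  Frame indices are the canonical clock; audio and video align through
the rates declared in ``session.json``.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .preprocess import EmotionAnnotation, PupilTrace
from .synthgen import SessionBundle
from .windowing import PartitionResult

PathLike = Union[str, Path]


def _sniff_csv(path: Path) -> Dict[str, str]:
    head = path.read_text().splitlines()[0]
    delim = ";" if head.count(";") > head.count(",") else ","
    # semicolon exports commonly pair with decimal commas
    decimal = "," if delim == ";" else "."
    return {"sep": delim, "decimal": decimal}


def read_pupil_csv(path: PathLike, subject_id: str = "unknown",
                   stimulus_id: str = "unknown", sample_rate_hz: float = 60.0,
                   missing_sentinel: Optional[float] = None) -> PupilTrace:
    """Read a gaze-export CSV into a PupilTrace.

    Blank cells become missing; ``missing_sentinel`` additionally maps a
    documented sentinel value (e.g. 0 or -1) to missing.
    """
    path = Path(path)
    dialect = _sniff_csv(path)
    df = pd.read_csv(path, float_precision="round_trip", **dialect)
    required = {"frame", "pupil_mm", "gaze_x", "gaze_y", "eye_state"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    bad = df[df["eye_state"].isna()]
    if len(bad):
        raise ValueError(f"{path}: malformed rows at lines {bad.index[:5].tolist()}")
    diam = df["pupil_mm"].to_numpy(dtype=float)
    if missing_sentinel is not None:
        diam = np.where(diam == missing_sentinel, np.nan, diam)
    gaze = df[["gaze_x", "gaze_y"]].to_numpy(dtype=float)
    return PupilTrace(subject_id, stimulus_id, sample_rate_hz, diam, gaze,
                      df["eye_state"].to_numpy(dtype=object))


def write_pupil_csv(trace: PupilTrace, path: PathLike) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["frame", "pupil_mm", "gaze_x", "gaze_y", "eye_state"])
        for k in range(len(trace)):
            d = trace.diameter_mm[k]
            gx, gy = trace.gaze_px[k]
            w.writerow([
                k,
                "" if np.isnan(d) else repr(float(d)),
                "" if np.isnan(gx) else repr(float(gx)),
                "" if np.isnan(gy) else repr(float(gy)),
                trace.eye_state[k],
            ])


def read_annotation_csv(path: PathLike) -> EmotionAnnotation:
    df = pd.read_csv(Path(path), **_sniff_csv(Path(path)))
    return EmotionAnnotation(
        [(int(r.start_frame), int(r.end_frame)) for r in df.itertuples()],
        [str(r.label) for r in df.itertuples()],
        [int(r.intensity) for r in df.itertuples()],
    )


def write_annotation_csv(annotation: EmotionAnnotation, path: PathLike) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["start_frame", "end_frame", "label", "intensity"])
        for (s, e), lab, inten in zip(annotation.intervals, annotation.labels,
                                      annotation.intensities):
            w.writerow([s, e, lab, inten])


def write_session(bundle: SessionBundle, directory: PathLike) -> Path:
    """Write a session directory (CSV + WAV + PNG stack + JSON manifest)."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_pupil_csv(bundle.pupil, directory / "pupil.csv")
    write_annotation_csv(bundle.annotation, directory / "annotations.csv")
    if bundle.audio is not None:
        wavfile.write(directory / "audio.wav", int(bundle.audio_rate_hz),
                      np.asarray(bundle.audio, dtype=np.float32))
    if bundle.frames is not None:
        fdir = directory / "frames"
        fdir.mkdir(exist_ok=True)
        for k, frame in enumerate(bundle.frames):
            iio.imwrite(fdir / f"frame_{k:06d}.png",
                        np.clip(frame, 0, 255).astype(np.uint8))
    manifest = {
        "subject_id": bundle.pupil.subject_id,
        "stimulus_id": bundle.pupil.stimulus_id,
        "sample_rate_hz": bundle.pupil.sample_rate_hz,
        "audio_rate_hz": bundle.audio_rate_hz,
        "video_rate_hz": bundle.video_rate_hz,
        "baseline_mm": bundle.baseline_mm,
        "truth_boundaries": bundle.truth_boundaries,
        "truth_labels": bundle.truth_labels,
    }
    (directory / "session.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return directory


def read_session(directory: PathLike) -> SessionBundle:
    """Read a session directory written by :func:`write_session`."""
    import imageio.v3 as iio

    directory = Path(directory)
    manifest = json.loads((directory / "session.json").read_text())
    trace = read_pupil_csv(directory / "pupil.csv",
                           subject_id=manifest["subject_id"],
                           stimulus_id=manifest["stimulus_id"],
                           sample_rate_hz=manifest["sample_rate_hz"])
    annotation = read_annotation_csv(directory / "annotations.csv")
    audio = None
    if (directory / "audio.wav").exists():
        _, audio = wavfile.read(directory / "audio.wav")
        audio = np.asarray(audio, dtype=np.float32)
    frames = None
    fdir = directory / "frames"
    if fdir.is_dir():
        paths = sorted(fdir.glob("frame_*.png"))
        if paths:
            frames = np.stack([iio.imread(p) for p in paths]).astype(np.float32)
    n_audio_expected = int(round(len(trace) / trace.sample_rate_hz * manifest["audio_rate_hz"]))
    if audio is not None and abs(len(audio) - n_audio_expected) > manifest["audio_rate_hz"]:
        raise ValueError(
            f"{directory}: audio length {len(audio)} inconsistent with "
            f"{len(trace)} pupil frames"
        )
    return SessionBundle(
        pupil=trace,
        annotation=annotation,
        audio=audio,
        audio_rate_hz=manifest["audio_rate_hz"],
        frames=frames,
        video_rate_hz=manifest["video_rate_hz"],
        truth_boundaries=manifest.get("truth_boundaries"),
        truth_labels=manifest.get("truth_labels"),
        baseline_mm=manifest.get("baseline_mm"),
    )


def write_partition_tsv(result: PartitionResult, session_id: str,
                        path: PathLike) -> None:
    """BED-like 3-column TSV (session_id, start_frame, end_frame)."""
    with Path(path).open("w") as fh:
        fh.write(f"# mode={result.mode} n={result.n}\n")
        for w in result.windows:
            fh.write(f"{session_id}\t{w.start_frame}\t{w.end_frame}\n")


def features_to_tidy_csv(records: List[dict], path: PathLike) -> None:
    """Tidy feature table: session_id, window_start, window_end, modality,
    feature_name, value."""
    cols = ["session_id", "window_start", "window_end", "modality",
            "feature_name", "value"]
    df = pd.DataFrame.from_records(records, columns=cols)
    df.to_csv(Path(path), index=False, float_format="%.12g")
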