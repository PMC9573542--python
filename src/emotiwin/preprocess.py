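"""Pupil-trace preprocessing.

Raw eye-tracker exports lose the pupil signal during blinks and tracking
dropouts, and resting pupil size differs between subjects.  The operations
here (a) fill missing diameter samples by linear interpolation, (b) estimate
a per-subject calm-state baseline and subtract it, and (c) summarise how the
baseline-subtracted diameter distributes over the standard elevation bins
per emotion label — the statistic that motivates treating an emotional
episode as an upper-convex fluctuation cycle bounded by local minima.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np

EYE_STATES = ("fixation", "saccade", "blink", "missing")
EMOTIONS = ("interest", "happy", "confused", "bored")

#: Elevation bins (mm above calm baseline), half-open as printed on the
#: distribution figure: (-inf, 0], (0, 0.5), [0.5, 1), [1, +inf).
DIFF_BIN_LABELS = ("<=0", "(0,0.5)", "[0.5,1)", ">=1")


class UnimputableTraceError(ValueError):
    """Raised when a trace has fewer than two valid diameter samples."""


@dataclass
class PupilTrace:
    """Frame-indexed pupil record for one subject-session.

    ``diameter_mm`` uses NaN as the in-memory missing marker.  All per-frame
    arrays share one length; ``gaze_px`` is ``(n_frames, 2)`` screen-pixel
    coordinates (NaN allowed); ``eye_state`` holds one of
    ``fixation | saccade | blink | missing`` per frame.
    """

    subject_id: str
    stimulus_id: str
    sample_rate_hz: float
    diameter_mm: np.ndarray
    gaze_px: np.ndarray
    eye_state: np.ndarray

    def __post_init__(self) -> None:
        self.diameter_mm = np.asarray(self.diameter_mm, dtype=float)
        self.gaze_px = np.asarray(self.gaze_px, dtype=float)
        self.eye_state = np.asarray(self.eye_state, dtype=object)
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        n = len(self.diameter_mm)
        if self.gaze_px.shape != (n, 2):
            raise ValueError(f"gaze_px must have shape ({n}, 2), got {self.gaze_px.shape}")
        if len(self.eye_state) != n:
            raise ValueError("eye_state length mismatch")
        bad = set(self.eye_state) - set(EYE_STATES)
        if bad:
            raise ValueError(f"unknown eye states: {sorted(bad)}")
        valid = self.diameter_mm[~np.isnan(self.diameter_mm)]
        if np.any(valid <= 0):
            raise ValueError("non-missing diameters must be positive")

    def __len__(self) -> int:
        return len(self.diameter_mm)


@dataclass
class EmotionAnnotation:
    """Labeled half-open frame intervals with 1-5 intensity ratings."""

    intervals: List[Tuple[int, int]]
    labels: List[str]
    intensities: List[int]

    def __post_init__(self) -> None:
        if not (len(self.intervals) == len(self.labels) == len(self.intensities)):
            raise ValueError("intervals, labels and intensities must align")
        for (s, e), lab, inten in zip(self.intervals, self.labels, self.intensities):
            if s < 0 or e <= s:
                raise ValueError(f"bad interval [{s}, {e})")
            if lab not in EMOTIONS:
                raise ValueError(f"unknown label {lab!r}")
            if not 1 <= int(inten) <= 5:
                raise ValueError(f"intensity {inten} outside 1..5")

    def frame_labels(self, n_frames: int) -> np.ndarray:
        """Per-frame label array (object dtype, None where unannotated)."""
        out = np.full(n_frames, None, dtype=object)
        for (s, e), lab in zip(self.intervals, self.labels):
            if e > n_frames:
                raise ValueError(f"interval [{s}, {e}) exceeds trace length {n_frames}")
            out[s:e] = lab
        return out


@dataclass
class BaselineValue:
    subject_id: str
    calm_mean_mm: float

    def __post_init__(self) -> None:
        if not self.calm_mean_mm > 0:
            raise ValueError("calm_mean_mm must be positive")


def _missing_mask(trace: PupilTrace) -> np.ndarray:
    # Blink frames carry no usable pupil size even when the tracker reports one.
    return np.isnan(trace.diameter_mm) | (trace.eye_state == "blink")


def impute_linear(trace: PupilTrace) -> PupilTrace:
    """Fill missing diameter samples by linear interpolation.

    Interior missing runs are interpolated between the nearest valid
    neighbours; leading/trailing runs are clamped to the nearest valid value
    (physiological signals should not be linearly extrapolated).  Frames in
    the ``blink`` eye state are treated as missing diameters; the state
    labels themselves are preserved.  Non-missing samples pass through
    bit-exactly, which also makes the operation idempotent.
    """
    missing = _missing_mask(trace)
    valid_idx = np.flatnonzero(~missing)
    if len(valid_idx) < 2:
        raise UnimputableTraceError(
            f"trace {trace.subject_id}/{trace.stimulus_id}: "
            f"{len(valid_idx)} valid samples, need >= 2"
        )
    if not missing.any():
        return replace(trace, diameter_mm=trace.diameter_mm.copy())
    filled = trace.diameter_mm.copy()
    # np.interp clamps outside the valid range, giving the edge policy for free.
    filled[missing] = np.interp(
        np.flatnonzero(missing), valid_idx, trace.diameter_mm[valid_idx]
    )
    return replace(trace, diameter_mm=filled)


def compute_baseline(calm_trace: PupilTrace) -> BaselineValue:
    """Mean pupil diameter over an imputed calm-state recording."""
    d = calm_trace.diameter_mm
    if len(d) == 0:
        raise ValueError("empty calm trace")
    if np.isnan(d).any():
        raise ValueError("calm trace must be imputed before baseline computation")
    return BaselineValue(calm_trace.subject_id, float(np.mean(d)))


def pooled_baseline(baselines: Sequence[BaselineValue]) -> float:
    """One baseline pooled over subjects (mean of per-subject calm means)."""
    if not baselines:
        raise ValueError("no baselines given")
    return float(np.mean([b.calm_mean_mm for b in baselines]))


def subtract_baseline(trace: PupilTrace, baseline: BaselineValue) -> PupilTrace:
    """Subtract the calm-state mean so traces are comparable across subjects.

    The result is an elevation signal in mm that may be negative.  Validation
    of the positive-diameter invariant is intentionally bypassed for the
    returned object.
    """
    if trace.subject_id != baseline.subject_id:
        raise ValueError(
            f"subject mismatch: trace {trace.subject_id!r} vs baseline {baseline.subject_id!r}"
        )
    if np.isnan(trace.diameter_mm).any():
        raise ValueError("impute the trace before baseline subtraction")
    out = replace(trace, diameter_mm=trace.diameter_mm.copy())
    # Bypass __post_init__ positivity check: elevations are legitimately <= 0.
    object.__setattr__(out, "diameter_mm", trace.diameter_mm - baseline.calm_mean_mm)
    return out


def difference_interval_distribution(
    diff_trace: PupilTrace, annotation: EmotionAnnotation
) -> Dict[str, Dict[str, float]]:
    """Per-label distribution of baseline-subtracted diameter over the bins
    (-inf, 0], (0, 0.5), [0.5, 1), [1, +inf).

    Returns ``{label: {"<=0": f0, "(0,0.5)": f1, "[0.5,1)": f2, ">=1": f3,
    "frac_positive": p}}`` where the four bin fractions sum to 1 over the
    frames carrying that label.
    """
    d = diff_trace.diameter_mm
    labels = annotation.frame_labels(len(d))
    out: Dict[str, Dict[str, float]] = {}
    for lab in sorted(set(annotation.labels)):
        x = d[labels == lab]
        if len(x) == 0:
            raise ValueError(f"label {lab!r} has zero frames; fractions undefined")
        fracs = np.array(
            [
                np.mean(x <= 0),
                np.mean((x > 0) & (x < 0.5)),
                np.mean((x >= 0.5) & (x < 1.0)),
                np.mean(x >= 1.0),
            ]
        )
        out[lab] = dict(zip(DIFF_BIN_LABELS, fracs.tolist()))
        out[lab]["frac_positive"] = float(np.mean(x > 0))
    return out
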