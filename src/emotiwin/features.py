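"""Per-window feature extraction for the eye, audio and video modalities.

Eye windows yield time-domain and waveform (machinery-statistics) features
of the baseline-subtracted pupil diameter and of its first-order difference,
plus eye-event features (saccade/fixation time, gaze displacement).  Audio
windows yield pooled statistics of the MFCC matrix and of its temporal
first difference.  Video windows yield statistics of the inter-frame pixel
change rate.  All statistics use population (1/N) normalisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from . import mfcc as _mfcc
from .windowing import Window

TIME_DOMAIN_NAMES = (
    "max", "min", "mean", "median", "range", "std", "var",
    "energy", "mean_amplitude", "rms",
)
WAVEFORM_NAMES = (
    "crest_factor", "waveform_factor", "skewness_factor",
    "impulse_factor", "clearance_factor", "kurtosis_factor",
)
EYE_EVENT_NAMES = (
    "saccade_time_s", "fixation_time_s", "saccade_count",
    "gaze_diff_x", "gaze_diff_y",
)
#: The seven statistics reported for the audio and video modalities.
SEVEN_STATS = ("max", "min", "mean", "median", "range", "std", "var")


@dataclass
class FeatureVector:
    """Named scalar features for one window and modality."""

    names: List[str]
    values: np.ndarray
    modality: str
    window: Optional[Window] = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != len(self.values):
            raise ValueError("names/values length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate feature names")
        if not self.degenerate and not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature values in a non-degenerate vector")

    def as_dict(self) -> Dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


def time_domain_features(x: Sequence[float], modality: str = "eye",
                         window: Optional[Window] = None,
                         prefix: str = "") -> FeatureVector:
    """Max, min, mean, median, range, std, var, energy (sum of squares),
    mean absolute amplitude and RMS of a sequence (length >= 2)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("time_domain_features needs at least 2 samples")
    vals = np.array([
        x.max(),
        x.min(),
        x.mean(),
        np.median(x),
        x.max() - x.min(),
        x.std(),                # population
        x.var(),
        np.sum(x ** 2),
        np.mean(np.abs(x)),
        np.sqrt(np.mean(x ** 2)),
    ])
    return FeatureVector([prefix + n for n in TIME_DOMAIN_NAMES], vals, modality, window)


def waveform_features(x: Sequence[float], modality: str = "eye",
                      window: Optional[Window] = None,
                      prefix: str = "") -> FeatureVector:
    """Dimensionless waveform shape factors.

    crest = peak/rms, waveform = rms/mean|x|, impulse = peak/mean|x|,
    clearance = peak/(mean sqrt|x|)^2, skewness factor = m3/sigma^3 and
    kurtosis factor = m4/sigma^4 (central moments, population).  A zero-RMS
    or zero-dispersion input cannot support the ratios; such vectors are
    returned flagged degenerate with the affected ratios set to 0.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("waveform_features needs at least 2 samples")
    peak = np.abs(x).max()
    rms = np.sqrt(np.mean(x ** 2))
    mean_amp = np.mean(np.abs(x))
    sq_amp = np.mean(np.sqrt(np.abs(x))) ** 2
    sigma = x.std()
    degenerate = rms == 0 or mean_amp == 0 or sq_amp == 0 or sigma == 0
    if degenerate and sigma == 0 and rms > 0:
        # constant non-zero signal: ratio factors are well-defined (= 1);
        # only the moment factors lose meaning
        crest, wave, imp, clear = peak / rms, rms / mean_amp, peak / mean_amp, peak / sq_amp
        skew = kurt = 0.0
        warnings.warn("zero-variance input: skewness/kurtosis factors set to 0")
    elif degenerate:
        warnings.warn("zero-amplitude input: waveform ratios set to 0")
        crest = wave = imp = clear = skew = kurt = 0.0
    else:
        crest = peak / rms
        wave = rms / mean_amp
        imp = peak / mean_amp
        clear = peak / sq_amp
        skew = np.mean((x - x.mean()) ** 3) / sigma ** 3
        kurt = np.mean((x - x.mean()) ** 4) / sigma ** 4
    vals = np.array([crest, wave, skew, imp, clear, kurt])
    return FeatureVector([prefix + n for n in WAVEFORM_NAMES], vals, modality,
                         window, degenerate=degenerate)


def first_order_difference(x: Sequence[float]) -> np.ndarray:
    """d[k] = x[k+1] - x[k]."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples to difference")
    return np.diff(x)


def eye_event_features(states: Sequence[str], gaze: np.ndarray, rate_hz: float,
                       window: Optional[Window] = None) -> FeatureVector:
    """Saccade/fixation dwell times (s), saccade run count, and mean absolute
    frame-to-frame gaze displacement per axis (pixels).

    Gaze displacement skips frame pairs with missing coordinates; if every
    pair is missing the displacement is 0 and the vector is flagged
    degenerate.
    """
    states = np.asarray(states, dtype=object)
    gaze = np.asarray(gaze, dtype=float)
    if states.size == 0:
        raise ValueError("empty window")
    if gaze.shape != (states.size, 2):
        raise ValueError("gaze must align with states")
    sac = states == "saccade"
    fix = states == "fixation"
    # maximal runs of saccade frames
    padded = np.concatenate([[False], sac, [False]])
    saccade_count = int(np.sum(~padded[:-1] & padded[1:]))
    degenerate = False
    if states.size >= 2:
        d = np.abs(np.diff(gaze, axis=0))
        ok = ~np.isnan(d).any(axis=1)
        if ok.any():
            dx, dy = d[ok].mean(axis=0)
        else:
            dx = dy = 0.0
            degenerate = True
            warnings.warn("all gaze displacements missing; coordinate difference set to 0")
    else:
        dx = dy = 0.0
    vals = np.array([sac.sum() / rate_hz, fix.sum() / rate_hz,
                     saccade_count, dx, dy])
    return FeatureVector(list(EYE_EVENT_NAMES), vals, "eye", window, degenerate=degenerate)


def _seven_stats(x: np.ndarray, prefix: str) -> Tuple[List[str], np.ndarray]:
    vals = np.array([x.max(), x.min(), x.mean(), np.median(x),
                     x.max() - x.min(), x.std(), x.var()])
    return [prefix + n for n in SEVEN_STATS], vals


def mfcc_window_features(
    audio: np.ndarray,
    audio_rate: float,
    window: Window,
    frame_rate_hz: float,
    n_mfcc: int = 13,
    per_coefficient: bool = False,
    **mfcc_kwargs,
) -> FeatureVector:
    """Statistics of the MFCC matrix over the audio span of a frame window.

    The window's frame interval is mapped to audio samples via the rate
    ratio.  By default the seven statistics pool over the whole coefficient
    matrix, and again over its first-order temporal difference (14 features);
    ``per_coefficient=True`` instead emits the statistics for each
    coefficient row separately.
    """
    lo = int(round(window.start_frame / frame_rate_hz * audio_rate))
    hi = int(round(window.end_frame / frame_rate_hz * audio_rate))
    if hi > len(audio):
        raise ValueError("window extends past the audio duration")
    seg = np.asarray(audio, dtype=float)[lo:hi]
    m = _mfcc.mfcc(seg, audio_rate, n_mfcc=n_mfcc, **mfcc_kwargs)
    if m.shape[1] < 2:
        raise ValueError("window too short for an MFCC difference (needs >= 2 frames)")
    dm = np.diff(m, axis=1)
    names: List[str] = []
    vals: List[np.ndarray] = []
    if per_coefficient:
        for c in range(m.shape[0]):
            nm, v = _seven_stats(m[c], f"mfcc{c}_")
            names += nm
            vals.append(v)
            nm, v = _seven_stats(dm[c], f"mfcc{c}_diff_")
            names += nm
            vals.append(v)
    else:
        nm, v = _seven_stats(m.ravel(), "mfcc_")
        names += nm
        vals.append(v)
        nm, v = _seven_stats(dm.ravel(), "mfcc_diff_")
        names += nm
        vals.append(v)
    return FeatureVector(names, np.concatenate(vals), "audio", window)


def to_grayscale(frames: np.ndarray) -> np.ndarray:
    """RGB (or already-gray) frame stack to float grayscale, Rec.601 luma."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 4 and frames.shape[-1] == 3:
        return frames @ np.array([0.299, 0.587, 0.114])
    if frames.ndim == 3:
        return frames
    raise ValueError(f"expected (t, h, w) or (t, h, w, 3) frames, got {frames.shape}")


def pixel_change_rate(frames: np.ndarray, signed: bool = False) -> np.ndarray:
    """Mean per-pixel intensity change between adjacent grayscale frames.

    ``z[t] = sum |X_{t+1} - X_t| / n_pixels`` for each adjacent pair.  The
    absolute value keeps opposite-signed pixel motions from cancelling;
    ``signed=True`` gives the literal signed-sum variant instead.
    """
    g = to_grayscale(frames)
    if g.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    d = np.diff(g, axis=0)
    if not signed:
        d = np.abs(d)
    return d.reshape(d.shape[0], -1).mean(axis=1)


def video_window_features(frames: np.ndarray, window: Window,
                          video_rate_hz: float, frame_rate_hz: float,
                          signed: bool = False) -> FeatureVector:
    """Seven statistics of the pixel-change-rate sequence within a window."""
    lo = int(round(window.start_frame / frame_rate_hz * video_rate_hz))
    hi = int(round(window.end_frame / frame_rate_hz * video_rate_hz))
    sub = np.asarray(frames)[lo:hi]
    if sub.shape[0] < 3:
        raise ValueError("window maps to fewer than 3 video frames")
    z = pixel_change_rate(sub, signed=signed)
    names, vals = _seven_stats(z, "z_")
    return FeatureVector(names, vals, "video", window)


# ---------------------------------------------------------------------------
# Orchestration over a session bundle

def eye_feature_names() -> List[str]:
    names = [f"pd_{n}" for n in TIME_DOMAIN_NAMES]
    names += [f"pd_{n}" for n in WAVEFORM_NAMES]
    names += [f"pd_diff_{n}" for n in TIME_DOMAIN_NAMES]
    names += [f"pd_diff_{n}" for n in WAVEFORM_NAMES]
    names += list(EYE_EVENT_NAMES)
    return names


def audio_feature_names() -> List[str]:
    return [f"mfcc_{n}" for n in SEVEN_STATS] + [f"mfcc_diff_{n}" for n in SEVEN_STATS]


def video_feature_names() -> List[str]:
    return [f"z_{n}" for n in SEVEN_STATS]


def feature_manifest(modalities: Iterable[str] = ("eye", "audio", "video")) -> Dict[str, List[str]]:
    """The stable feature-name manifest per modality."""
    out = {}
    for m in modalities:
        out[m] = {"eye": eye_feature_names,
                  "audio": audio_feature_names,
                  "video": video_feature_names}[m]()
    return out


def feature_groups() -> Dict[str, List[str]]:
    """Feature-group membership used for grouped correlation reporting."""
    return {
        "pupil_time_domain": [f"pd_{n}" for n in TIME_DOMAIN_NAMES] + list(EYE_EVENT_NAMES),
        "pupil_waveform": [f"pd_{n}" for n in WAVEFORM_NAMES],
        "pupil_diff_time_domain": [f"pd_diff_{n}" for n in TIME_DOMAIN_NAMES],
        "pupil_diff_waveform": [f"pd_diff_{n}" for n in WAVEFORM_NAMES],
        "audio_time_domain": [f"mfcc_{n}" for n in SEVEN_STATS],
        "audio_diff_time_domain": [f"mfcc_diff_{n}" for n in SEVEN_STATS],
        "video_time_domain": [f"z_{n}" for n in SEVEN_STATS],
    }


def extract_window_features(bundle, window: Window,
                            modalities: Iterable[str] = ("eye",)) -> Dict[str, FeatureVector]:
    """Extract one FeatureVector per requested modality for one window.

    ``bundle`` is a SessionBundle whose pupil trace is already imputed and
    baseline-subtracted.  Absent modalities are skipped with a warning.
    """
    out: Dict[str, FeatureVector] = {}
    for mod in modalities:
        if mod == "eye":
            x = bundle.pupil.diameter_mm[window.start_frame:window.end_frame]
            d = first_order_difference(x)
            parts = [
                time_domain_features(x, "eye", window, "pd_"),
                waveform_features(x, "eye", window, "pd_"),
                time_domain_features(d, "eye", window, "pd_diff_"),
                waveform_features(d, "eye", window, "pd_diff_"),
                eye_event_features(
                    bundle.pupil.eye_state[window.start_frame:window.end_frame],
                    bundle.pupil.gaze_px[window.start_frame:window.end_frame],
                    bundle.pupil.sample_rate_hz, window),
            ]
            names = [n for p in parts for n in p.names]
            vals = np.concatenate([p.values for p in parts])
            out["eye"] = FeatureVector(names, vals, "eye", window,
                                       degenerate=any(p.degenerate for p in parts))
        elif mod == "audio":
            if bundle.audio is None:
                warnings.warn("audio modality absent; skipped")
                continue
            out["audio"] = mfcc_window_features(
                bundle.audio, bundle.audio_rate_hz, window,
                bundle.pupil.sample_rate_hz)
        elif mod == "video":
            if bundle.frames is None:
                warnings.warn("video modality absent; skipped")
                continue
            out["video"] = video_window_features(
                bundle.frames, window, bundle.video_rate_hz,
                bundle.pupil.sample_rate_hz)
        else:
            raise ValueError(f"unknown modality {mod!r}")
    return out
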