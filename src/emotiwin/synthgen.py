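"""Synthetic learning-session generator.

Emulates the statistical structure the adaptive-window method assumes: the
baseline-subtracted pupil diameter is a concatenation of upper-convex
fluctuation cycles (raised-cosine arches) whose start/end points are local
minima at a zero elevation floor, with one emotion per cycle.

Per-emotion arch recipes (defaults, mm above calm baseline):

* ``interest`` — tall arch (peak ~1.6) with an attention burst (saccade run)
  early in the cycle,
* ``confused`` — tall arch (peak ~1.6) with the attention burst late,
* ``happy``    — medium arch (peak ~0.85),
* ``bored``    — shallow arch (peak ~0.32, low fluctuation).

With these recipes the elevation of interest/confused frames falls mainly at
or above 0.5 mm, happy within (0, 1) mm and bored within (0, 0.5) mm, and
the below-zero share (noise dipping under the zero floor near cycle
boundaries) is largest for bored — the qualitative per-emotion elevation
structure observed in MOOC viewing data.  Interest and confused share one
arch shape and differ only in *when* the attention burst occurs; every
window-aggregate statistic (dwell times, run counts, value distributions) is
identical in expectation between the two, so only the 8-point fine-grained
curves can tell them apart — the property the fine-grained method is
designed to exploit.

Audio is a per-emotion tone/noise mixture and video a moving-pattern scene
whose motion magnitude depends on the emotion, so all three modalities carry
label signal.  Everything is driven by one seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .preprocess import EmotionAnnotation, PupilTrace, EMOTIONS


@dataclass
class ArchRecipe:
    """One emotion's fluctuation-cycle recipe.

    ``attention_phase`` places one saccade burst (an attention shift) inside
    each cycle at a uniform phase within the given range; ``None`` draws the
    phase uniformly over the whole cycle.  A burst early vs late in the
    cycle leaves every window-aggregate statistic unchanged (same dwell
    times, same run count, same displacement), so only the fine-grained
    sub-sample curves can see the difference.
    """

    peak_mm: float            # mean arch amplitude above the calm baseline
    peak_jitter: float        # sd of per-cycle amplitude jitter
    warp_gamma: float = 1.0   # <1 peaks early, >1 peaks late, 1 symmetric
    attention_phase: Optional[Tuple[float, float]] = None
    tone_hz: float = 440.0    # audio recipe: carrier frequency
    tone_amp: float = 0.1
    noise_amp: float = 0.02   # audio recipe: white-noise mixture level
    motion_px: float = 1.0    # video recipe: pattern speed (px/frame)


DEFAULT_RECIPES: Dict[str, ArchRecipe] = {
    "interest": ArchRecipe(1.6, 0.15, attention_phase=(0.05, 0.35), tone_hz=523.0,
                           tone_amp=0.12, noise_amp=0.02, motion_px=2.0),
    "confused": ArchRecipe(1.6, 0.15, attention_phase=(0.65, 0.95), tone_hz=392.0,
                           tone_amp=0.10, noise_amp=0.05, motion_px=1.2),
    "happy": ArchRecipe(0.85, 0.10, tone_hz=659.0, tone_amp=0.12,
                        noise_amp=0.02, motion_px=1.6),
    "bored": ArchRecipe(0.32, 0.05, tone_hz=196.0, tone_amp=0.05,
                        noise_amp=0.08, motion_px=0.1),
}


@dataclass
class GeneratorConfig:
    """Study-condition parameters for one synthetic session."""

    seed: int = 0
    subject_id: str = "synth-000"
    stimulus_id: str = "lesson-0"
    duration_s: float = 60.0
    rate_hz: float = 60.0
    baseline_mm: float = 3.5
    cycle_period_mean: int = 60      # frames; ~2n for the default n = 30
    cycle_period_jitter: int = 15    # uniform +/- jitter, frames
    noise_sd: float = 0.02           # mm additive Gaussian noise
    missing_rate: float = 0.02       # expected fraction of missing frames
    missing_run_mean: float = 4.0    # geometric mean run length, frames
    saccade_rate_hz: float = 0.5     # background saccade onsets per second
    saccade_run_mean: float = 3.0    # geometric mean saccade length, frames
    attention_burst_frames: int = 6  # length of the per-cycle attention burst
    audio_rate_hz: int = 8000
    video_rate_hz: float = 30.0
    frame_size: Tuple[int, int] = (32, 32)
    recipes: Dict[str, ArchRecipe] = field(default_factory=lambda: dict(DEFAULT_RECIPES))
    emotions: Tuple[str, ...] = EMOTIONS
    misaligned_annotation: bool = False  # stress mode: shift labels off cycles

    def __post_init__(self) -> None:
        if self.cycle_period_mean - self.cycle_period_jitter < 4:
            raise ValueError("cycle period can drop below 4 frames; infeasible")
        if self.rate_hz <= 0 or self.audio_rate_hz <= 0 or self.video_rate_hz <= 0:
            raise ValueError("rates must be positive")


@dataclass
class SessionBundle:
    """One synchronized synthetic (or loaded) session."""

    pupil: PupilTrace
    annotation: EmotionAnnotation
    audio: Optional[np.ndarray]
    audio_rate_hz: float
    frames: Optional[np.ndarray]
    video_rate_hz: float
    truth_boundaries: Optional[List[int]] = None  # interior cycle split frames
    truth_labels: Optional[List[str]] = None      # one emotion per cycle
    baseline_mm: Optional[float] = None


def _arch(length: int, peak: float, gamma: float) -> np.ndarray:
    """Warped raised-cosine arch: ``peak * sin(pi * w(k/L))**2``.

    ``w`` is a monotone time warp with ``w(0) = 0`` and ``w(1) = 1``:
    ``gamma > 0`` gives ``w(u) = u**gamma`` (peaks early for gamma < 1);
    ``gamma < 0`` gives ``w(u) = 1 - (1-u)**|gamma|``, the time-reversed
    shape of the ``|gamma|`` arch.  Every arch is exactly zero at its first
    frame and strictly positive elsewhere, so cycle boundaries are strict
    local minima of the noiseless concatenation.
    """
    u = np.arange(length) / length
    g = abs(gamma)
    w = 1.0 - (1.0 - u) ** g if gamma < 0 else u ** g
    return peak * np.sin(np.pi * w) ** 2


def _draw_cycles(rng: np.random.Generator, cfg: GeneratorConfig,
                 n_frames: int) -> Tuple[List[int], List[str], List[float]]:
    """Cycle lengths, labels and amplitudes covering ``n_frames``."""
    lengths: List[int] = []
    labels: List[str] = []
    peaks: List[float] = []
    total = 0
    while total < n_frames:
        p = int(rng.integers(cfg.cycle_period_mean - cfg.cycle_period_jitter,
                             cfg.cycle_period_mean + cfg.cycle_period_jitter + 1))
        p = min(p, n_frames - total)
        if p < 4:  # fold a tiny remainder into the last cycle
            if lengths:
                lengths[-1] += p
            else:
                p = max(p, 4)
                lengths.append(p)
                lab = str(rng.choice(cfg.emotions))
                labels.append(lab)
                peaks.append(max(0.05, rng.normal(cfg.recipes[lab].peak_mm,
                                                  cfg.recipes[lab].peak_jitter)))
            total = n_frames
            break
        lab = str(rng.choice(cfg.emotions))
        rec = cfg.recipes[lab]
        lengths.append(p)
        labels.append(lab)
        peaks.append(max(0.05, rng.normal(rec.peak_mm, rec.peak_jitter)))
        total += p
    return lengths, labels, peaks


def generate_pupil(cfg: GeneratorConfig, rng: Optional[np.random.Generator] = None):
    """Generate the pupil trace, its annotation and the true cycle boundaries.

    Returns ``(trace, annotation, boundaries, labels)`` where ``boundaries``
    are the interior split frames (cycle starts after the first) and
    ``labels`` the per-cycle emotions.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n_frames = int(round(cfg.duration_s * cfg.rate_hz))
    lengths, labels, peaks = _draw_cycles(rng, cfg, n_frames)
    elev = np.concatenate([
        _arch(p, a, cfg.recipes[lab].warp_gamma)
        for p, lab, a in zip(lengths, labels, peaks)
    ])
    diam = cfg.baseline_mm + elev
    if cfg.noise_sd > 0:
        diam = diam + rng.normal(0.0, cfg.noise_sd, n_frames)
    diam = np.maximum(diam, 0.5)  # physiological floor, mm

    # eye states: saccade runs over a fixation background, blink at dropouts
    states = np.full(n_frames, "fixation", dtype=object)
    n_sacc = rng.poisson(cfg.saccade_rate_hz * cfg.duration_s)
    for _ in range(n_sacc):
        s = int(rng.integers(0, n_frames))
        run = 1 + int(rng.geometric(1.0 / cfg.saccade_run_mean))
        states[s:s + run] = "saccade"
    # one attention-shift burst per cycle at an emotion-dependent phase
    starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    for s0, p, lab in zip(starts, lengths, labels):
        lo, hi = cfg.recipes[lab].attention_phase or (0.0, 1.0)
        u = rng.uniform(lo, hi)
        b = int(s0 + u * p)
        states[b : min(b + cfg.attention_burst_frames, n_frames)] = "saccade"

    # gaze: slow drift during fixation, jumps during saccades
    steps = rng.normal(0.0, 1.5, (n_frames, 2))
    steps[states == "saccade"] += rng.normal(0.0, 25.0, (int((states == "saccade").sum()), 2))
    gaze = np.array([960.0, 540.0]) + np.cumsum(steps, axis=0)

    # missing runs: geometric lengths at the requested frame budget
    if cfg.missing_rate > 0:
        budget = cfg.missing_rate * n_frames
        used = 0.0
        while used < budget:
            s = int(rng.integers(0, n_frames))
            run = 1 + int(rng.geometric(1.0 / cfg.missing_run_mean))
            run = min(run, n_frames - s)
            diam[s:s + run] = np.nan
            states[s:s + run] = "blink"
            gaze[s:s + run] = np.nan
            used += run
    # keep the trace imputable
    if np.isnan(diam[~(states == "blink")]).all():
        raise RuntimeError("generator produced an unimputable trace")

    trace = PupilTrace(cfg.subject_id, cfg.stimulus_id, cfg.rate_hz,
                       diam, gaze, states)

    edges = np.cumsum([0] + lengths)
    if int(edges[-1]) != n_frames:
        raise RuntimeError("cycle lengths do not cover the session")
    shift = lengths[0] // 2 if cfg.misaligned_annotation else 0
    intervals: List[Tuple[int, int]] = []
    kept_labels: List[str] = []
    kept_peaks: List[float] = []
    for (a, b), lab, pk in zip(zip(edges[:-1], edges[1:]), labels, peaks):
        s, e = min(a + shift, n_frames), min(b + shift, n_frames)
        if e > s:
            intervals.append((int(s), int(e)))
            kept_labels.append(lab)
            kept_peaks.append(pk)
    if intervals and intervals[-1][1] < n_frames:
        intervals[-1] = (intervals[-1][0], n_frames)
    intensities = [int(np.clip(1 + round(4 * pk / 2.0), 1, 5)) for pk in kept_peaks]
    annotation = EmotionAnnotation(intervals, kept_labels, intensities)
    boundaries = [int(e) for e in edges[1:-1]]
    return trace, annotation, boundaries, labels


def generate_audio(cfg: GeneratorConfig, annotation: EmotionAnnotation,
                   n_frames: int, rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Per-emotion tone + noise mixture aligned to the annotation intervals."""
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    n_samples = int(round(n_frames / cfg.rate_hz * cfg.audio_rate_hz))
    t = np.arange(n_samples) / cfg.audio_rate_hz
    audio = np.zeros(n_samples)
    for (s, e), lab in zip(annotation.intervals, annotation.labels):
        rec = cfg.recipes[lab]
        lo = int(round(s / cfg.rate_hz * cfg.audio_rate_hz))
        hi = min(int(round(e / cfg.rate_hz * cfg.audio_rate_hz)), n_samples)
        seg_t = t[lo:hi]
        audio[lo:hi] = (rec.tone_amp * np.sin(2 * np.pi * rec.tone_hz * seg_t)
                        + rec.noise_amp * rng.normal(0.0, 1.0, hi - lo))
    return audio.astype(np.float32)


def generate_frames(cfg: GeneratorConfig, annotation: EmotionAnnotation,
                    n_frames: int, rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Moving-square scene; per-emotion motion magnitude (bored ~ static)."""
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    h, w = cfg.frame_size
    n_video = int(round(n_frames / cfg.rate_hz * cfg.video_rate_hz))
    labels = annotation.frame_labels(n_frames)
    frames = np.zeros((n_video, h, w), dtype=np.float32)
    x = float(rng.uniform(4, w - 8))
    y = float(rng.uniform(4, h - 8))
    vx, vy = 1.0, 0.7
    for k in range(n_video):
        pupil_frame = min(int(round(k / cfg.video_rate_hz * cfg.rate_hz)), n_frames - 1)
        lab = labels[pupil_frame]
        speed = cfg.recipes[lab].motion_px if lab is not None else 0.5
        x += vx * speed
        y += vy * speed
        if not 0 <= x <= w - 6:
            vx = -vx
            x = float(np.clip(x, 0, w - 6))
        if not 0 <= y <= h - 6:
            vy = -vy
            y = float(np.clip(y, 0, h - 6))
        img = np.full((h, w), 40.0, dtype=np.float32)
        img[int(y):int(y) + 6, int(x):int(x) + 6] = 200.0
        frames[k] = img
    return frames


def generate_session(cfg: GeneratorConfig) -> SessionBundle:
    """Generate a full synchronized session from one seed."""
    trace, annotation, boundaries, labels = generate_pupil(cfg)
    n_frames = len(trace)
    audio = generate_audio(cfg, annotation, n_frames)
    frames = generate_frames(cfg, annotation, n_frames)
    return SessionBundle(
        pupil=trace,
        annotation=annotation,
        audio=audio,
        audio_rate_hz=cfg.audio_rate_hz,
        frames=frames,
        video_rate_hz=cfg.video_rate_hz,
        truth_boundaries=boundaries,
        truth_labels=labels,
        baseline_mm=cfg.baseline_mm,
    )
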