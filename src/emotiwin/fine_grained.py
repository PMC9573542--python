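"""Fine-grained feature curves.

A window is split into 8 contiguous equal-order sub-samples; extracting the
same scalar features from every sub-sample turns each scalar feature into an
8-point curve.  The curve keeps the within-window temporal structure that a
single window-level statistic discards — two windows with identical value
distributions but different temporal ordering produce identical scalar
features yet different curves — and the resulting ``[n_features, 8]``
matrices are the natural input of sequence classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .features import FeatureVector, extract_window_features
from .windowing import Window

N_SUBSAMPLES = 8
MIN_WINDOW_FRAMES = 2 * N_SUBSAMPLES  # every sub-sample needs >= 2 frames


@dataclass
class FineGrainedSample:
    """Feature-curve matrix for one window: row t = curve of feature t."""

    feature_names: List[str]
    curve_matrix: np.ndarray  # (n_features, 8)
    label: Optional[str] = None
    window: Optional[Window] = None
    modality: str = "eye"
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.curve_matrix = np.asarray(self.curve_matrix, dtype=float)
        if self.curve_matrix.shape != (len(self.feature_names), N_SUBSAMPLES):
            raise ValueError(
                f"curve_matrix must be ({len(self.feature_names)}, {N_SUBSAMPLES}), "
                f"got {self.curve_matrix.shape}"
            )
        if not self.degenerate and not np.all(np.isfinite(self.curve_matrix)):
            raise ValueError("non-finite curve values")


def split_eight(window: Window, k: int = N_SUBSAMPLES) -> List[Window]:
    """Split a window into ``k`` contiguous sub-windows of near-equal length.

    The remainder ``r = alen mod k`` is distributed to the first ``r``
    sub-windows, so lengths differ by at most one frame and concatenation
    reconstructs the window exactly.
    """
    alen = window.alen
    if alen < 2 * k:
        raise ValueError(
            f"window [{window.start_frame}, {window.end_frame}) has {alen} frames; "
            f"need >= {2 * k} for {k} sub-samples"
        )
    base, r = divmod(alen, k)
    lengths = [base + 1] * r + [base] * (k - r)
    edges = np.cumsum([window.start_frame] + lengths)
    return [Window(int(a), int(b), window.mode) for a, b in zip(edges, edges[1:])]


def build_feature_curves(bundle, window: Window, modality: str = "eye",
                         label: Optional[str] = None) -> FineGrainedSample:
    """Extract the per-sub-sample feature curves for one window and modality.

    Column ``m`` of the curve matrix equals scalar feature extraction
    applied directly to sub-window ``m``.
    """
    subs = split_eight(window)
    cols: List[FeatureVector] = []
    for sw in subs:
        fv = extract_window_features(bundle, sw, (modality,))[modality]
        cols.append(fv)
    names = cols[0].names
    mat = np.stack([c.values for c in cols], axis=1)
    return FineGrainedSample(list(names), mat, label=label, window=window,
                             modality=modality,
                             degenerate=any(c.degenerate for c in cols))


def to_model_tensor(samples: Sequence[FineGrainedSample]) -> Tuple[np.ndarray, List[Optional[str]]]:
    """Stack samples into a ``[batch, n_features, 8]`` array plus labels."""
    if not samples:
        raise ValueError("no samples to stack")
    names = samples[0].feature_names
    for s in samples[1:]:
        if s.feature_names != names:
            raise ValueError("inconsistent feature manifests across samples")
    X = np.stack([s.curve_matrix for s in samples], axis=0)
    y = [s.label for s in samples]
    return X, y


def from_model_tensor(X: np.ndarray, labels: Sequence[Optional[str]],
                      feature_names: List[str]) -> List[FineGrainedSample]:
    """Inverse of :func:`to_model_tensor` (round-trips losslessly)."""
    return [FineGrainedSample(list(feature_names), X[i], label=labels[i])
            for i in range(X.shape[0])]
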