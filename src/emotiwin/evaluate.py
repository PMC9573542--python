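"""Evaluation machinery: feature-label correlation, the adaptive-vs-static
windowing comparison harness, and classification metrics.

Sample quality is measured two ways.  First, the correlation between window
features and emotion labels: each feature's score is the maximum absolute
point-biserial correlation over the four one-vs-rest label encodings, and
group/overall averages are means of absolute values (signed averages would
cancel).  Second, held-out classification metrics (accuracy, macro-F1,
macro one-vs-rest AUC, confusion matrix) under a subject-wise train/test
split — no subject contributes windows to both sides.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, f1_score, precision_score, recall_score, roc_auc_score

from .features import extract_window_features, feature_groups, feature_manifest
from .fine_grained import build_feature_curves, to_model_tensor
from .models import ClassifierSpec, FittedClassifier, feature_layer_fusion, fit_classifier, fit_reduction
from .preprocess import EMOTIONS, EmotionAnnotation, compute_baseline, impute_linear, subtract_baseline, BaselineValue
from .windowing import PartitionResult, Window, WindowingConfig, adaptive_partition, static_partition
from .synthgen import SessionBundle


# ---------------------------------------------------------------------------
# correlation


@dataclass
class CorrelationReport:
    per_feature: Dict[str, float]
    group_means: Dict[str, float]
    overall_mean: float


def _pointbiserial(x: np.ndarray, ind: np.ndarray) -> float:
    if x.std() == 0 or ind.std() == 0:
        return 0.0
    return float(np.corrcoef(x, ind)[0, 1])


def feature_label_correlation(
    features: np.ndarray,
    labels: Sequence[str],
    feature_names: Sequence[str],
    groups: Optional[Dict[str, List[str]]] = None,
    method: str = "ovr_pointbiserial",
) -> CorrelationReport:
    """Per-feature correlation with a 4-class emotion label.

    ``ovr_pointbiserial`` (default): the maximum |point-biserial r| over the
    one-vs-rest indicator encodings of the label.  ``integer_pearson``:
    plain Pearson r against integer-coded labels (sensitivity analysis).
    Constant features get correlation 0 with a warning.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=object)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    present = sorted(set(y))
    if len(present) < 2:
        raise ValueError("need at least 2 distinct labels")
    if X.shape[1] != len(feature_names):
        raise ValueError("feature_names must match feature columns")
    per: Dict[str, float] = {}
    for j, name in enumerate(feature_names):
        x = X[:, j]
        if x.std() == 0:
            warnings.warn(f"constant feature {name!r}: correlation set to 0")
            per[name] = 0.0
            continue
        if method == "integer_pearson":
            codes = np.array([list(EMOTIONS).index(v) for v in y], dtype=float)
            per[name] = _pointbiserial(x, codes)
        elif method == "ovr_pointbiserial":
            per[name] = max(
                (abs(_pointbiserial(x, (y == lab).astype(float))) for lab in present),
            )
        else:
            raise ValueError(f"unknown method {method!r}")
    group_means: Dict[str, float] = {}
    if groups:
        for gname, members in groups.items():
            vals = [abs(per[m]) for m in members if m in per]
            if vals:
                group_means[gname] = float(np.mean(vals))
    overall = float(np.mean([abs(v) for v in per.values()]))
    return CorrelationReport(per, group_means, overall)


# ---------------------------------------------------------------------------
# classification metrics


@dataclass
class EvalReport:
    accuracy: float
    macro_f1: float
    macro_auc: float
    confusion: np.ndarray          # rows = true class, order = classes
    classes: List[str]
    per_class_precision: Dict[str, float]
    per_class_recall: Dict[str, float]

    def to_dict(self) -> Dict:
        return {
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "macro_auc": self.macro_auc,
            "classes": self.classes,
            "confusion": self.confusion.tolist(),
            "per_class_precision": self.per_class_precision,
            "per_class_recall": self.per_class_recall,
        }


def scores_to_reports(y_true: Sequence[str], y_pred: Sequence[str],
                      scores: Optional[np.ndarray], classes: Sequence[str]) -> EvalReport:
    """Metrics from predictions (+ per-class scores for AUC)."""
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    classes = list(classes)
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    acc = float(np.trace(cm) / cm.sum())
    f1 = float(f1_score(y_true, y_pred, labels=classes, average="macro", zero_division=0))
    absent = [c for c in classes if c not in set(y_true)]
    if absent:
        warnings.warn(f"classes absent from test set: {absent}; their F1 terms are 0")
    auc = np.nan
    if scores is not None:
        aucs = []
        for k, c in enumerate(classes):
            ind = (y_true == c).astype(int)
            if 0 < ind.sum() < len(ind):
                aucs.append(roc_auc_score(ind, scores[:, k]))
        if aucs:
            auc = float(np.mean(aucs))
    prec = precision_score(y_true, y_pred, labels=classes, average=None, zero_division=0)
    rec = recall_score(y_true, y_pred, labels=classes, average=None, zero_division=0)
    return EvalReport(acc, f1, auc, cm, classes,
                      dict(zip(classes, prec.tolist())),
                      dict(zip(classes, rec.tolist())))


def evaluate_classifier(model: FittedClassifier, X_test: np.ndarray,
                        y_test: Sequence[str]) -> EvalReport:
    """Held-out metrics for a fitted classifier."""
    pred = model.predict(X_test)
    scores = model.predict_scores(X_test)
    return scores_to_reports(y_test, pred, scores, model.classes)


# ---------------------------------------------------------------------------
# dataset assembly from session bundles


def prepare_bundle(bundle: SessionBundle,
                   baseline: Optional[float] = None) -> SessionBundle:
    """Impute the pupil trace and subtract the calm baseline in place of it.

    ``baseline`` defaults to the bundle's own recorded calm value; pass a
    measured calm-trace mean for real recordings.
    """
    trace = impute_linear(bundle.pupil)
    base = baseline if baseline is not None else bundle.baseline_mm
    if base is None:
        raise ValueError("no baseline available; supply one")
    diff = subtract_baseline(trace, BaselineValue(trace.subject_id, float(base)))
    out = SessionBundle(**{**bundle.__dict__, "pupil": diff})
    return out


def label_windows(annotation: EmotionAnnotation, windows: Sequence[Window],
                  n_frames: int) -> List[Optional[str]]:
    """Majority-overlap label per window (None if unannotated)."""
    frame_labels = annotation.frame_labels(n_frames)
    out: List[Optional[str]] = []
    for w in windows:
        seg = frame_labels[w.start_frame:w.end_frame]
        labs, counts = np.unique([s for s in seg if s is not None], return_counts=True)
        out.append(str(labs[counts.argmax()]) if len(labs) else None)
    return out


def partition_bundle(bundle: SessionBundle, config: WindowingConfig) -> PartitionResult:
    x = bundle.pupil.diameter_mm
    if config.mode == "adaptive":
        return adaptive_partition(x, config)
    return static_partition(len(x), config)


def build_dataset(
    bundles: Sequence[SessionBundle],
    config: WindowingConfig,
    modalities: Sequence[str] = ("eye",),
    representation: str = "scalar",
    min_alen: Optional[int] = None,
) -> Tuple[Dict[str, np.ndarray], np.ndarray, np.ndarray]:
    """Windows -> per-modality feature arrays, labels and subject ids.

    Returns ``(X_by_modality, y, subjects)`` where each modality maps to a
    2-D array (scalar) or 3-D ``[batch, features, 8]`` array (curves).
    Windows too short for the representation, or without a label, are
    dropped.
    """
    if representation not in ("scalar", "curves"):
        raise ValueError("representation must be 'scalar' or 'curves'")
    if min_alen is None:
        min_alen = 16 if representation == "scalar" else 48
    cols: Dict[str, list] = {m: [] for m in modalities}
    ys: List[str] = []
    subs: List[str] = []
    for bundle in bundles:
        part = partition_bundle(bundle, config)
        labels = label_windows(bundle.annotation, part.windows, len(bundle.pupil))
        for w, lab in zip(part.windows, labels):
            if lab is None or w.alen < min_alen:
                continue
            try:
                if representation == "scalar":
                    fvs = extract_window_features(bundle, w, modalities)
                    row = {m: fvs[m].values for m in modalities if m in fvs}
                else:
                    row = {m: build_feature_curves(bundle, w, m, lab).curve_matrix
                           for m in modalities}
            except ValueError:
                continue  # window unusable for some modality (e.g. too few frames)
            if len(row) != len(modalities):
                continue
            for m in modalities:
                cols[m].append(row[m])
            ys.append(lab)
            subs.append(bundle.pupil.subject_id)
    if not ys:
        raise ValueError("no usable windows; check the partition configuration")
    X = {m: np.stack(cols[m], axis=0) for m in modalities}
    return X, np.array(ys, dtype=object), np.array(subs, dtype=object)


def subject_split(subjects: np.ndarray, test_fraction: float = 0.25,
                  seed: int = 0) -> Tuple[np.ndarray, np.ndarray]:
    """Boolean train/test masks with no subject on both sides."""
    uniq = np.unique(subjects)
    if len(uniq) < 2:
        raise ValueError("need at least 2 subjects for a subject-wise split")
    rng = np.random.default_rng(seed)
    n_test = max(1, int(round(test_fraction * len(uniq))))
    test_subjects = set(rng.choice(uniq, size=n_test, replace=False).tolist())
    test_mask = np.array([s in test_subjects for s in subjects])
    return ~test_mask, test_mask


def pipeline_evaluate(
    bundles: Sequence[SessionBundle],
    config: WindowingConfig,
    classifier: ClassifierSpec,
    modalities: Sequence[str] = ("eye",),
    representation: str = "scalar",
    test_fraction: float = 0.25,
    split_seed: int = 0,
    reduce: bool = True,
    shuffle_labels: bool = False,
) -> EvalReport:
    """End-to-end: partition, featurize, reduce (train-fit), fuse, classify.

    Per-modality features are z-scored and PCA-reduced with statistics
    fitted on the training subjects only, fused by feature-layer
    concatenation, and scored on the held-out subjects.
    ``shuffle_labels=True`` permutes labels (seeded) as a chance-level
    control.
    """
    X, y, subs = build_dataset(bundles, config, modalities, representation)
    if shuffle_labels:
        y = np.random.default_rng(split_seed).permutation(y)
    tr, te = subject_split(subs, test_fraction, split_seed)
    blocks_tr, blocks_te = [], []
    for m in modalities:
        if reduce:
            red = fit_reduction(X[m][tr])
            if X[m].ndim == 3:
                blocks_tr.append(red.transform_curves(X[m][tr]))
                blocks_te.append(red.transform_curves(X[m][te]))
            else:
                blocks_tr.append(red.transform(X[m][tr]))
                blocks_te.append(red.transform(X[m][te]))
        else:
            blocks_tr.append(X[m][tr])
            blocks_te.append(X[m][te])
    Xtr = feature_layer_fusion(blocks_tr)
    Xte = feature_layer_fusion(blocks_te)
    model = fit_classifier(classifier, Xtr, y[tr])
    return evaluate_classifier(model, Xte, y[te])


def compare_windowing(
    bundles: Sequence[SessionBundle],
    n_values: Sequence[int] = (30,),
    static_factor: int = 2,
    modalities: Sequence[str] = ("eye",),
    classifier: Optional[ClassifierSpec] = None,
    test_fraction: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Adaptive-vs-static comparison under identical downstream processing.

    Each minimum half-length ``n`` is paired with the static length
    ``static_factor * n`` (1 s static <-> n = 30 at 60 Hz).  For every
    (n, mode, modality) cell the table reports the mean absolute
    feature-label correlation and, when a classifier spec is given, held-out
    accuracy/macro-F1/AUC.  Cells with fewer than 2 windows per present
    class are marked unevaluable (NaN metrics).
    """
    classifier = classifier or ClassifierSpec("knn")
    rows = []
    for n in n_values:
        configs = {
            "adaptive": WindowingConfig(n=n, mode="adaptive"),
            "static": WindowingConfig(mode="static", static_len=static_factor * n),
        }
        for mode, cfg in configs.items():
            for modality in modalities:
                row = {"n": n, "mode": mode, "modality": modality,
                       "static_len": static_factor * n if mode == "static" else None}
                try:
                    X, y, subs = build_dataset(bundles, cfg, (modality,), "scalar")
                except ValueError:
                    rows.append({**row, "mean_abs_corr": np.nan, "accuracy": np.nan,
                                 "macro_f1": np.nan, "macro_auc": np.nan,
                                 "n_windows": 0, "evaluable": False})
                    continue
                names = feature_manifest((modality,))[modality]
                rep = feature_label_correlation(X[modality], y, names, feature_groups())
                row.update(mean_abs_corr=rep.overall_mean, n_windows=len(y))
                counts = pd.Series(y).value_counts()
                evaluable = bool((counts >= 2).all() and len(np.unique(subs)) >= 2)
                row["evaluable"] = evaluable
                if evaluable:
                    er = pipeline_evaluate(bundles, cfg, classifier, (modality,),
                                           "scalar", test_fraction, seed)
                    row.update(accuracy=er.accuracy, macro_f1=er.macro_f1,
                               macro_auc=er.macro_auc)
                else:
                    row.update(accuracy=np.nan, macro_f1=np.nan, macro_auc=np.nan)
                rows.append(row)
    return pd.DataFrame(rows)
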