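"""Multiclass evaluation: confusion-matrix metrics, one-vs-rest ROC/AUC,
Cohen's kappa inter-rater agreement, and Grad-CAM heatmaps.

Per-class binary counts come from the one-vs-rest reduction of the 4x4
confusion matrix (fixed class order ERD, Healthy, RRD, TRD).  From TP/TN/
FP/FN the standard indicators follow:

    sensitivity = TP/(TP+FN)          specificity = TN/(TN+FP)
    accuracy    = (TP+TN)/total       precision   = TP/(TP+FP)
    F1          = 2 PR / (P+R)        MCC = (TP*TN - FP*FN)/sqrt(...)

Zero denominators are reported as 0 together with an ``undefined`` flag so
batch evaluation never aborts.  AUC uses the rank (Mann-Whitney) statistic
with midranks for ties, which is exact and monotone-invariant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from skimage.transform import resize

CLASS_ORDER = ("ERD", "Healthy", "RRD", "TRD")


def confusion_matrix(y_true, y_pred, labels=CLASS_ORDER) -> np.ndarray:
    """Counts[i, j] = number of samples with true label i predicted as j."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    index = {lab: i for i, lab in enumerate(labels)}
    cm = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(y_true, y_pred):
        if t not in index or p not in index:
            raise ValueError(f"unknown label in ({t!r}, {p!r}); expected one of {labels}")
        cm[index[t], index[p]] += 1
    return cm


def one_vs_rest_counts(cm: np.ndarray, k: int) -> tuple[int, int, int, int]:
    """(TP, TN, FP, FN) for class ``k`` from a multiclass confusion matrix."""
    cm = np.asarray(cm)
    tp = int(cm[k, k])
    fn = int(cm[k].sum() - tp)
    fp = int(cm[:, k].sum() - tp)
    tn = int(cm.sum() - tp - fn - fp)
    return tp, tn, fp, fn


@dataclass(frozen=True)
class ClassMetrics:
    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    precision: float
    f1: float
    mcc: float
    undefined: tuple[str, ...] = ()


def _safe_div(num: float, den: float, flag: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(flag)
        return 0.0
    return num / den


def classification_metrics(tp: int, tn: int, fp: int, fn: int) -> ClassMetrics:
    """All per-class indicators from the binary counts.

    Undefined ratios (zero denominators) are reported as 0 and listed in the
    ``undefined`` field.
    """
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    flags: list[str] = []
    sens = _safe_div(tp, tp + fn, "sensitivity", flags)
    spec = _safe_div(tn, tn + fp, "specificity", flags)
    acc = _safe_div(tp + tn, tp + tn + fp + fn, "accuracy", flags)
    prec = _safe_div(tp, tp + fp, "precision", flags)
    f1 = _safe_div(2 * prec * sens, prec + sens, "f1", flags)
    mcc_den = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _safe_div(tp * tn - fp * fn, mcc_den, "mcc", flags)
    return ClassMetrics(tp, tn, fp, fn, sens, spec, acc, prec, f1, mcc, tuple(flags))


def roc_auc(scores: np.ndarray, y_true, k, labels=CLASS_ORDER) -> float:
    """One-vs-rest AUC for class ``k`` via the rank statistic (midranks on
    ties).  ``scores`` is (n, n_classes); ``k`` may be a label or an index."""
    scores = np.asarray(scores, dtype=np.float64)
    if isinstance(k, str):
        k = labels.index(k)
    y = np.array([1 if t == labels[k] else 0 for t in y_true])
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError(f"class {labels[k]!r} absent (or exhaustive) in y_true; AUC undefined")
    ranks = rankdata(scores[:, k])
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    p_o: float
    p_e: float
    degenerate: bool = False  # both raters constant and identical (p_e == 1)


def cohens_kappa(labels_a, labels_b) -> KappaResult:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    p_o is the fraction of exact agreements; p_e the product-of-marginals
    chance agreement.  When both raters are constant and identical (p_e = 1),
    kappa is 1 by convention and the result is flagged degenerate.
    """
    a = list(labels_a)
    b = list(labels_b)
    if len(a) != len(b):
        raise ValueError("label sequences must have equal length")
    if not a:
        raise ValueError("empty label sequences")
    n = len(a)
    p_o = sum(x == y for x, y in zip(a, b)) / n
    cats = sorted(set(a) | set(b), key=str)
    p_e = sum((a.count(c) / n) * (b.count(c) / n) for c in cats)
    if p_e >= 1.0:
        return KappaResult(kappa=1.0, p_o=p_o, p_e=p_e, degenerate=True)
    return KappaResult(kappa=(p_o - p_e) / (1.0 - p_e), p_o=p_o, p_e=p_e)


@dataclass(frozen=True)
class MetricsReport:
    """Per-class indicators plus macro averages and overall accuracy.

    ``macro`` averages each indicator over classes (one-vs-rest accuracy
    included); ``overall_accuracy`` is the plain multiclass trace/total,
    which in general differs from macro one-vs-rest accuracy — both are
    reported, neither is forced to match the other.
    """

    confusion: np.ndarray
    per_class: dict[str, ClassMetrics]
    auc: dict[str, float]
    macro: dict[str, float]
    overall_accuracy: float


def metrics_report(y_true, y_pred, scores: np.ndarray | None = None,
                   labels=CLASS_ORDER) -> MetricsReport:
    """Full evaluation report from labels (and optionally probability scores
    for per-class AUC)."""
    cm = confusion_matrix(y_true, y_pred, labels)
    per_class = {}
    auc = {}
    for i, lab in enumerate(labels):
        per_class[lab] = classification_metrics(*one_vs_rest_counts(cm, i))
        if scores is not None:
            try:
                auc[lab] = roc_auc(scores, y_true, i, labels)
            except ValueError:
                auc[lab] = float("nan")
    fields = ("sensitivity", "specificity", "accuracy", "precision", "f1", "mcc")
    macro = {f: float(np.mean([getattr(m, f) for m in per_class.values()])) for f in fields}
    if auc:
        macro["auc"] = float(np.nanmean(list(auc.values())))
    total = cm.sum()
    overall = float(np.trace(cm) / total) if total else 0.0
    return MetricsReport(cm, per_class, auc, macro, overall)


def report_as_percent(report: MetricsReport) -> dict:
    """JSON-friendly rendering with rates as percentages (2 decimals)."""
    pct = lambda v: round(100.0 * v, 2)
    out = {
        "confusion_matrix": report.confusion.tolist(),
        "overall_accuracy_pct": pct(report.overall_accuracy),
        "per_class": {},
        "macro": {k: (round(v, 4) if k in ("mcc", "auc") else pct(v))
                  for k, v in report.macro.items()},
    }
    for lab, m in report.per_class.items():
        out["per_class"][lab] = {
            "TP": m.tp, "TN": m.tn, "FP": m.fp, "FN": m.fn,
            "sensitivity_pct": pct(m.sensitivity), "specificity_pct": pct(m.specificity),
            "accuracy_pct": pct(m.accuracy), "precision_pct": pct(m.precision),
            "f1_pct": pct(m.f1), "mcc": round(m.mcc, 4),
            "undefined": list(m.undefined),
        }
        if lab in report.auc:
            out["per_class"][lab]["auc"] = round(report.auc[lab], 4)
    return out


# ---------------------------------------------------------------------------
# Grad-CAM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GradCamMap:
    heatmap: np.ndarray  # H x W in [0, 1]
    target_class: int
    layer: str


def grad_cam(net, img: np.ndarray, target_class: int, layer: str = "relu5") -> GradCamMap:
    """Gradient-weighted class-activation map.

    The gradient of the target-class logit is backpropagated to the chosen
    convolutional activation (the fifth block's post-ReLU maps by default),
    spatially averaged into channel weights, and the rectified weighted sum
    of the activation channels is bilinearly upsampled to the input size and
    max-normalized.
    """
    idx = net.layer_index(layer)
    activations = net.forward_collect(img[None].astype(np.float64))
    act = activations[idx]
    if act.ndim != 4:
        raise ValueError(f"layer {layer!r} has no spatial feature maps")
    logits = activations[-1]
    dlogits = np.zeros_like(logits)
    dlogits[0, target_class] = 1.0
    dact = net.backward(dlogits, stop_at=idx + 1)
    weights = dact[0].mean(axis=(0, 1))            # one weight per channel
    cam = np.maximum((act[0] * weights).sum(axis=-1), 0.0)
    h, w = img.shape[:2]
    cam = resize(cam, (h, w), order=1, mode="edge", anti_aliasing=False)
    cam = np.maximum(cam, 0.0)
    if cam.max() > 0:
        cam = cam / cam.max()
    return GradCamMap(heatmap=cam, target_class=target_class, layer=layer)
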