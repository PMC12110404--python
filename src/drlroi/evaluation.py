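"""Patient-level evaluation: score aggregation, ACC/sensitivity/specificity,
ROC/AUC with a DeLong-variance confidence interval, and the paired DeLong
test for correlated AUCs.

Slice probabilities are averaged per patient ("the mean slice probability is
the patient probability"); patient-level figures are the headline metrics,
slice-level ones are reported alongside.  AUC follows the Mann-Whitney
convention (ties credited 1/2), which is what the trapezoidal ROC area
equals; the DeLong machinery is written out here because no installed
statistics package exposes it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.metrics import roc_curve

from .backbone import Backbone, class_activation_map
from .phantom import Cohort


class DegenerateVarianceError(RuntimeError):
    """The variance of the AUC difference is zero but the AUCs differ."""


@dataclass
class PatientScore:
    patient_id: str
    probability: float      # mean positive-class probability over slices
    label: int

    def __post_init__(self):
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must lie in [0, 1]")


@dataclass
class EvalReport:
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    auc_ci: tuple[float, float]
    roc: np.ndarray                  # (n_points, 2) of (FPR, TPR)
    confusion: np.ndarray            # [[TN, FP], [FN, TP]]
    slice_auc: float = float("nan")
    slice_accuracy: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "roc": self.roc.tolist(),
            "confusion": self.confusion.tolist(),
            "slice_auc": self.slice_auc,
            "slice_accuracy": self.slice_accuracy,
        }


def patient_probability(slice_probs) -> float:
    """Arithmetic mean of a patient's slice probabilities."""
    probs = np.asarray(list(slice_probs), dtype=np.float64)
    if probs.size == 0:
        raise ValueError("patient has no slices")
    return float(probs.mean())


def aggregate_patients(slice_probs: np.ndarray, labels: np.ndarray,
                       groups: np.ndarray) -> list[PatientScore]:
    """Collapse slice-level probabilities to one PatientScore per patient."""
    df = pd.DataFrame({"p": slice_probs, "y": labels, "g": groups})
    out = []
    for pid, sub in df.groupby("g", sort=False):
        if sub["y"].nunique() != 1:
            raise ValueError(f"patient {pid} has inconsistent labels")
        out.append(PatientScore(patient_id=str(pid),
                                probability=patient_probability(sub["p"]),
                                label=int(sub["y"].iloc[0])))
    return out


def confusion_metrics(scores: list[PatientScore], threshold: float = 0.5):
    """Accuracy, sensitivity, specificity and the 2x2 confusion matrix.

    A patient is called positive when probability > threshold.
    """
    labels = np.array([s.label for s in scores])
    preds = np.array([s.probability > threshold for s in scores], dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    tp = int(((preds == 1) & (labels == 1)).sum())
    tn = int(((preds == 0) & (labels == 0)).sum())
    fp = int(((preds == 1) & (labels == 0)).sum())
    fn = int(((preds == 0) & (labels == 1)).sum())
    accuracy = (tp + tn) / len(labels)
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp)
    confusion = np.array([[tn, fp], [fn, tp]])
    return accuracy, sensitivity, specificity, confusion


def roc_auc(scores: np.ndarray, labels: np.ndarray):
    """ROC step curve and its area (= the Mann-Whitney statistic).

    Returns ``(roc_points, auc)`` where ``roc_points`` is an ordered
    (FPR, TPR) array starting at (0, 0) and ending at (1, 1).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return points, auc


# ---------------------------------------------------------------------------
# DeLong machinery
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    """Midranks (1-based), averaging over ties."""
    order = np.argsort(x, kind="mergesort")
    sorted_x = x[order]
    n = len(x)
    ranks = np.empty(n, dtype=np.float64)
    i = 0
    while i < n:
        j = i
        while j < n and sorted_x[j] == sorted_x[i]:
            j += 1
        ranks[i:j] = 0.5 * (i + j - 1) + 1.0
        i = j
    out = np.empty(n, dtype=np.float64)
    out[order] = ranks
    return out


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """Structural components V10 (per positive) and V01 (per negative),
    plus the AUC, for one score vector."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    all_scores = np.concatenate([pos, neg])
    rank_all = _midrank(all_scores)
    rank_pos = _midrank(pos)
    rank_neg = _midrank(neg)
    auc = (rank_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (rank_all[:m] - rank_pos) / n
    v01 = 1.0 - (rank_all[m:] - rank_neg) / m
    return auc, v10, v01


def delong_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(AUC, DeLong variance of the AUC estimate)."""
    auc, v10, v01 = _delong_components(np.asarray(scores, float),
                                       np.asarray(labels, int))
    m, n = len(v10), len(v01)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def auc_ci(scores: np.ndarray, labels: np.ndarray, level: float = 0.95,
           method: str = "delong", n_boot: int = 2000,
           seed: int = 0) -> tuple[float, float]:
    """Confidence interval for the AUC, truncated to [0, 1].

    ``method='delong'`` uses the DeLong-variance normal interval;
    ``method='bootstrap'`` resamples patients with replacement.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    auc, var = delong_variance(scores, labels)
    if method == "delong":
        if var <= 0.0:
            # degenerate (e.g. perfect separation): widest defensible interval
            import warnings

            warnings.warn("degenerate DeLong variance; returning [0, 1]",
                          RuntimeWarning, stacklevel=2)
            return (0.0, 1.0)
        z = norm.ppf(0.5 + level / 2.0)
        half = z * np.sqrt(var)
        return (float(max(auc - half, 0.0)), float(min(auc + half, 1.0)))
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        n = len(scores)
        aucs = []
        while len(aucs) < n_boot:
            idx = rng.integers(0, n, size=n)
            if len(np.unique(labels[idx])) < 2:
                continue
            _, a = roc_auc(scores[idx], labels[idx])
            aucs.append(a)
        lo, hi = np.quantile(aucs, [0.5 - level / 2.0, 0.5 + level / 2.0])
        return (float(max(lo, 0.0)), float(min(hi, 1.0)))
    raise ValueError(f"unknown method {method!r}")


def delong_test(scores_a: np.ndarray, scores_b: np.ndarray,
                labels: np.ndarray) -> tuple[float, float]:
    """Paired DeLong test for two correlated AUCs on the same subjects.

    Returns ``(z, p)`` with a two-sided normal p-value; ``z`` is
    antisymmetric under swapping the two score vectors.  Identical scores
    give (0, 1); a zero-variance nonzero difference raises
    :class:`DegenerateVarianceError`.
    """
    scores_a = np.asarray(scores_a, dtype=np.float64)
    scores_b = np.asarray(scores_b, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    auc_a, v10_a, v01_a = _delong_components(scores_a, labels)
    auc_b, v10_b, v01_b = _delong_components(scores_b, labels)
    m, n = len(v10_a), len(v01_a)
    dauc = auc_a - auc_b
    if m > 1:
        s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    else:
        s10 = np.zeros((2, 2))
    if n > 1:
        s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    else:
        s01 = np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    if var <= 0.0:
        if abs(dauc) < 1e-12:
            return 0.0, 1.0
        raise DegenerateVarianceError(
            "zero variance of the AUC difference with nonzero difference")
    z = dauc / np.sqrt(var)
    p = 2.0 * norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


# ---------------------------------------------------------------------------
# Model-level reports
# ---------------------------------------------------------------------------

def evaluate_scores(slice_probs: np.ndarray, labels: np.ndarray,
                    groups: np.ndarray, threshold: float = 0.5,
                    ci_level: float = 0.95) -> EvalReport:
    """Full report from slice probabilities; headline figures are patient-level."""
    patients = aggregate_patients(slice_probs, labels, groups)
    p_scores = np.array([s.probability for s in patients])
    p_labels = np.array([s.label for s in patients])
    accuracy, sensitivity, specificity, confusion = confusion_metrics(patients,
                                                                      threshold)
    roc_points, auc = roc_auc(p_scores, p_labels)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ci = auc_ci(p_scores, p_labels, level=ci_level)
    _, slice_auc_val = roc_auc(slice_probs, labels)
    slice_acc = float(((slice_probs > threshold).astype(int) == labels).mean())
    return EvalReport(accuracy=accuracy, sensitivity=sensitivity,
                      specificity=specificity, auc=auc, auc_ci=ci,
                      roc=roc_points, confusion=confusion,
                      slice_auc=slice_auc_val, slice_accuracy=slice_acc)


def cam_roi_fractions(backbone: Backbone, slice_probs: np.ndarray,
                      cohort: Cohort, threshold: float = 0.5,
                      batch_size: int = 64, policy=None,
                      action_mode: str = "spatial") -> dict[str, float]:
    """Fraction of slices whose CAM argmax falls inside the ROI mask,
    separately for correctly and incorrectly classified slices.

    When a ``policy`` is given, its deterministic gate is applied to the
    feature map first, so the CAM shows the evidence the gated model
    actually pools — the learned ROI weighting included."""
    backbone.eval()
    images = cohort.images()
    labels = cohort.labels()
    masks = cohort.masks()
    head_w = backbone.head.W.data      # (C, n_classes)
    inside_correct, n_correct, inside_wrong, n_wrong = 0, 0, 0, 0
    for start in range(0, len(images), batch_size):
        sl = slice(start, start + batch_size)
        fmaps = backbone.features(images[sl])
        if policy is not None:
            from .rl import act, apply_action

            actions, _, _ = act(fmaps.mean(axis=(2, 3)), policy,
                                mode="deterministic")
            fmaps = apply_action(fmaps, actions, mode=action_mode)
        for i in range(fmaps.shape[0]):
            k = start + i
            pred = int(slice_probs[k] > threshold)
            cam = class_activation_map(fmaps[i], head_w, pred,
                                       output_size=masks.shape[1])
            ay, ax = np.unravel_index(int(np.argmax(cam)), cam.shape)
            inside = bool(masks[k][ay, ax])
            if pred == labels[k]:
                n_correct += 1
                inside_correct += inside
            else:
                n_wrong += 1
                inside_wrong += inside
    return {
        "correct_in_roi": inside_correct / n_correct if n_correct else float("nan"),
        "incorrect_in_roi": inside_wrong / n_wrong if n_wrong else float("nan"),
        "n_correct": n_correct,
        "n_incorrect": n_wrong,
    }
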