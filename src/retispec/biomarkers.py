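"""Peak-based biomarker extraction and diagnostic statistics.

The injury "barcode" is six peak intensities (1266, 1452, 1660, 2850, 2880,
2930 cm^-1 by default) plus the 2930/2850 intensity ratio, the headline
discriminant between injured and control retinae.  Supporting statistics:
box-plot summaries with 1.5xIQR whiskers, a nonparametric ROC curve whose
area is computed both by threshold-sweep trapezoid integration and by the
Mann–Whitney U statistic (the two must agree), and sensitivity /
specificity / accuracy from a 2x2 confusion table.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.stats import rankdata

from .spectra import Spectrum

__all__ = [
    "BARCODE_BANDS",
    "BarcodeFeatures",
    "BoxplotSummary",
    "ROCResult",
    "peak_intensity",
    "barcode",
    "boxplot_summary",
    "roc_auc",
    "confusion_metrics",
]

#: default barcode feature bands (cm^-1); 2955 is a supported alternate
BARCODE_BANDS: tuple[float, ...] = (1266.0, 1452.0, 1660.0, 2850.0, 2880.0, 2930.0)


@dataclass
class BarcodeFeatures:
    bands: tuple
    intensities: np.ndarray  # aligned with `bands`
    ratio: float  # I(2930) / I(2850)

    def as_dict(self) -> dict:
        d = {f"I{int(b)}": float(v) for b, v in zip(self.bands, self.intensities)}
        d["ratio_2930_2850"] = self.ratio
        return d


@dataclass
class BoxplotSummary:
    median: float
    q1: float
    q3: float
    iqr: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float  # Mann-Whitney U based, ties counted 1/2
    auc_trapezoid: float  # threshold-sweep integral; equals `auc` by construction
    n_pos: int
    n_neg: int


def peak_intensity(spectrum: Spectrum, center: float, half_window: float = 10.0
                   ) -> float:
    """Maximum intensity within +-half_window of `center`.

    Ties go to the lower wavenumber.  Intended for baseline-corrected spectra.
    """
    sel = np.abs(spectrum.axis - center) <= half_window
    if not sel.any():
        raise ValueError(f"no channels within {half_window} cm^-1 of {center}")
    return float(np.max(spectrum.intensity[sel]))


def barcode(spectrum: Spectrum, bands: tuple[float, ...] = BARCODE_BANDS,
            half_window: float = 10.0) -> BarcodeFeatures:
    """All barcode peak intensities plus the 2930/2850 ratio."""
    missing = [b for b in bands
               if not np.any(np.abs(spectrum.axis - b) <= half_window)]
    for b in (2850.0, 2930.0):
        if not np.any(np.abs(spectrum.axis - b) <= half_window) and b not in missing:
            missing.append(b)
    if missing:
        raise ValueError(f"spectrum does not cover barcode bands: {sorted(missing)}")
    vals = np.array([peak_intensity(spectrum, b, half_window) for b in bands])
    i2850 = peak_intensity(spectrum, 2850.0, half_window)
    i2930 = peak_intensity(spectrum, 2930.0, half_window)
    if i2850 <= 0:
        raise ValueError("2850 cm^-1 peak intensity is nonpositive; "
                         "the 2930/2850 ratio is undefined")
    return BarcodeFeatures(tuple(bands), vals, float(i2930 / i2850))


def boxplot_summary(values) -> BoxplotSummary:
    """Quartiles by linear interpolation of order statistics (type-7);
    whiskers at Q1 - 1.5*IQR and Q3 + 1.5*IQR clipped to the data extremes;
    outliers strictly beyond the whiskers."""
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("boxplot summary needs >= 4 values")
    q1, med, q3 = np.percentile(v, [25.0, 50.0, 75.0])
    iqr = q3 - q1
    lo = max(float(v.min()), q1 - 1.5 * iqr)
    hi = min(float(v.max()), q3 + 1.5 * iqr)
    out = v[(v < lo) | (v > hi)]
    return BoxplotSummary(float(med), float(q1), float(q3), float(iqr),
                          lo, hi, out)


def roc_auc(scores, labels, positive_label=None) -> ROCResult:
    """Nonparametric ROC over all score thresholds.

    The AUC is computed two ways — trapezoidal integration of the swept
    (1-specificity, sensitivity) curve, and the Mann–Whitney U statistic
    U / (n_pos * n_neg) with ties contributing 1/2 — and the call fails if
    the two disagree beyond 1e-10 (they are mathematically identical).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if positive_label is None:
        if classes.size != 2:
            raise ValueError("positive_label required for non-binary labels")
        lowered = [str(c).lower() for c in classes]
        positive_label = (classes[lowered.index("tbi")] if "tbi" in lowered
                          else classes.max())
    is_pos = labels == positive_label
    n_pos, n_neg = int(is_pos.sum()), int((~is_pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both a positive and a negative class are required")
    pos, neg = scores[is_pos], scores[~is_pos]

    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    tpr = np.array([(pos >= t).mean() for t in thresholds])
    fpr = np.array([(neg >= t).mean() for t in thresholds])
    auc_trap = float(np.trapezoid(tpr, fpr))

    ranks = rankdata(scores)  # average ranks on ties -> 1/2 credit per tie
    u = ranks[is_pos].sum() - n_pos * (n_pos + 1) / 2.0
    auc_u = float(u / (n_pos * n_neg))
    if abs(auc_trap - auc_u) > 1e-10:
        raise RuntimeError(
            f"ROC self-check failed: trapezoid {auc_trap!r} vs U {auc_u!r}")
    return ROCResult(thresholds, tpr, 1.0 - fpr, auc_u, auc_trap, n_pos, n_neg)


@dataclass
class ConfusionMetrics:
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    undefined: tuple


def confusion_metrics(counts) -> ConfusionMetrics:
    """sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
    accuracy = (TP+TN)/total, from a 2x2 table counts[true][pred] with the
    positive class first.  Zero denominators are flagged as undefined rather
    than propagated as NaN.  Exact rational arithmetic for integer counts."""
    c = np.asarray(counts)
    if c.shape != (2, 2) or np.any(c < 0):
        raise ValueError("a nonnegative 2x2 count table is required")
    exact = np.issubdtype(c.dtype, np.integer) or np.all(c == np.round(c))
    num = (lambda v: Fraction(int(v))) if exact else Fraction
    tp, fn = num(c[0, 0]), num(c[0, 1])
    fp, tn = num(c[1, 0]), num(c[1, 1])
    undefined = []

    def ratio(n, d, name):
        if d == 0:
            undefined.append(name)
            return None
        return float(n / d)

    sens = ratio(tp, tp + fn, "sensitivity")
    spec = ratio(tn, tn + fp, "specificity")
    acc = ratio(tp + tn, tp + tn + fp + fn, "accuracy")
    return ConfusionMetrics(sens, spec, acc, tuple(undefined))
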