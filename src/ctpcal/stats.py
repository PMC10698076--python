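"""Agreement statistics: Bland-Altman, Cohen's kappa, 2x2 metrics, Pearson."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "BlandAltman",
    "KappaResult",
    "ClassificationMetrics",
    "bland_altman",
    "cohens_kappa",
    "classification_metrics",
    "pearson_r",
]

KAPPA_BANDS = (
    (0.00, "no agreement"),
    (0.21, "slight"),
    (0.41, "fair"),
    (0.61, "moderate"),
    (0.81, "substantial"),
    (np.inf, "excellent"),
)


@dataclass(frozen=True)
class BlandAltman:
    mean_diff: float
    loa_low: float
    loa_high: float
    n: int


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    ci_low: float
    ci_high: float
    category: str


@dataclass(frozen=True)
class ClassificationMetrics:
    sensitivity: float | None
    specificity: float | None
    accuracy: float
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    def counts(self) -> dict:
        """Table-style 'k/n' count strings for each metric."""
        pos, neg = self.tp + self.fn, self.tn + self.fp
        return {
            "sensitivity": f"{self.tp}/{pos}",
            "specificity": f"{self.tn}/{neg}",
            "accuracy": f"{self.tp + self.tn}/{self.n}",
        }


def bland_altman(ref, cmp) -> BlandAltman:
    """Limits of agreement for differences `ref - cmp` (reference first)."""
    ref = np.asarray(ref, dtype=float)
    cmp = np.asarray(cmp, dtype=float)
    if ref.shape != cmp.shape or ref.ndim != 1:
        raise ValueError("ref and cmp must be equal-length 1-D arrays")
    if len(ref) < 2:
        raise ValueError("need at least two paired values")
    diffs = ref - cmp
    mean = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    return BlandAltman(mean, mean - 1.96 * sd, mean + 1.96 * sd, len(ref))


def kappa_category(kappa: float) -> str:
    for upper, name in KAPPA_BANDS:
        if kappa < upper:
            return name
    return KAPPA_BANDS[-1][1]


def cohens_kappa(labels_a, labels_b) -> KappaResult:
    """Cohen's kappa for two binary raters, with asymptotic 95% CI.

    If both raters agree perfectly and chance agreement is 1 (a single
    observed class), kappa is defined as 1 by convention.
    """
    a = np.asarray(labels_a).astype(bool)
    b = np.asarray(labels_b).astype(bool)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("labels must be equal-length 1-D arrays, n >= 2")
    n = len(a)
    p_o = float(np.mean(a == b))
    p_a, p_b = float(np.mean(a)), float(np.mean(b))
    p_e = p_a * p_b + (1 - p_a) * (1 - p_b)
    if p_e >= 1.0:
        kappa = 1.0 if p_o == 1.0 else 0.0
        return KappaResult(kappa, kappa, kappa, kappa_category(kappa))
    kappa = (p_o - p_e) / (1 - p_e)
    se = np.sqrt(p_o * (1 - p_o) / (n * (1 - p_e) ** 2))
    lo = kappa - 1.96 * se
    hi = min(kappa + 1.96 * se, 1.0)
    return KappaResult(float(kappa), float(lo), float(hi), kappa_category(kappa))


def classification_metrics(reference, predicted) -> ClassificationMetrics:
    """Sensitivity/specificity/accuracy of `predicted` against `reference`.

    Undefined metrics (no positives or no negatives in the reference) are
    reported as None rather than silently zero.
    """
    ref = np.asarray(reference).astype(bool)
    pred = np.asarray(predicted).astype(bool)
    if ref.shape != pred.shape or ref.ndim != 1:
        raise ValueError("reference and predicted must be equal-length 1-D arrays")
    tp = int(np.sum(ref & pred))
    fn = int(np.sum(ref & ~pred))
    tn = int(np.sum(~ref & ~pred))
    fp = int(np.sum(~ref & pred))
    pos, neg = tp + fn, tn + fp
    return ClassificationMetrics(
        sensitivity=tp / pos if pos else None,
        specificity=tn / neg if neg else None,
        accuracy=(tp + tn) / len(ref),
        tp=tp,
        fn=fn,
        tn=tn,
        fp=fp,
    )


def pearson_r(x, y) -> float:
    """Product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-D arrays, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    return float(sps.pearsonr(x, y).statistic)
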