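"""Agreement and classification metrics for predicted vs observed severity.

The comparison of a claims-based severity prediction with a self-reported
reference is summarised in a k x k confusion matrix (rows = predicted,
columns = observed). For the dichotomous severe / non-severe comparison
the 2 x 2 special case yields

* sensitivity  = TP / (TP + FN),
* specificity  = TN / (TN + FP),
* proportion correctly predicted = trace / n,
* Matthews correlation coefficient
  MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

and chance-corrected agreement via Cohen's kappa. On the three-level
ordinal comparison a *weighted* kappa (linear weights by default) credits
near-misses, and Spearman's rho measures rank correlation, with a 95% CI
from the Fisher z-transform. Verbal interpretation bands follow the
conventional scales (kappa: poor/fair/moderate/substantial/almost perfect;
rho: weak/modest/moderate/strong/very strong; MCC: very weak/fair/
moderately strong/very strong).

Kappa and its large-sample variance are delegated to
:func:`statsmodels.stats.inter_rater.cohens_kappa`; MCC and the
proportion metrics are computed directly from the table. Degenerate
margins (an empty predicted or observed class) yield MCC 0 with a warning
rather than an exception so that stochastic simulations never crash.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.inter_rater import cohens_kappa as _sm_kappa


@dataclass(frozen=True)
class ConfusionMatrix:
    """k x k cross-tabulation; rows are predicted, columns observed."""

    labels: tuple
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        k = len(self.labels)
        if k < 2:
            raise ValueError("need at least two categories")
        if counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def k(self) -> int:
        return len(self.labels)

    @classmethod
    def from_binary_counts(cls, tp: int, fp: int, fn: int, tn: int) -> "ConfusionMatrix":
        """2x2 matrix with label order (severe, non-severe): row/column 0 is
        the positive (severe) class, so counts = [[TP, FP], [FN, TN]]."""
        return cls(("severe", "non_severe"), np.array([[tp, fp], [fn, tn]]))

    def binary_cells(self) -> tuple[int, int, int, int]:
        if self.k != 2:
            raise ValueError("binary cells require a 2x2 matrix")
        (tp, fp), (fn, tn) = self.counts
        return int(tp), int(fp), int(fn), int(tn)


def build_confusion(
    predicted: Sequence, observed: Sequence, labels: Sequence
) -> ConfusionMatrix:
    """Cross-tabulate paired predicted/observed values over ``labels``."""
    predicted = list(predicted)
    observed = list(observed)
    if len(predicted) != len(observed):
        raise ValueError("predicted and observed must have equal length")
    if not predicted:
        raise ValueError("cannot build a confusion matrix from empty lists")
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for p, o in zip(predicted, observed):
        if p not in index or o not in index:
            raise ValueError(f"value outside label set: {(p, o)!r}")
        counts[index[p], index[o]] += 1
    return ConfusionMatrix(tuple(labels), counts)


def sensitivity(m: ConfusionMatrix) -> float:
    """TP / (TP + FN): the share of observed severe cases predicted severe."""
    tp, _, fn, _ = m.binary_cells()
    if tp + fn == 0:
        raise ZeroDivisionError("no observed positive cases")
    return tp / (tp + fn)


def specificity(m: ConfusionMatrix) -> float:
    """TN / (TN + FP): the share of observed non-severe cases predicted so."""
    _, fp, _, tn = m.binary_cells()
    if tn + fp == 0:
        raise ZeroDivisionError("no observed negative cases")
    return tn / (tn + fp)


def proportion_correct(m: ConfusionMatrix) -> float:
    """trace / n over any k x k matrix."""
    if m.n == 0:
        raise ZeroDivisionError("empty confusion matrix")
    return float(np.trace(m.counts)) / m.n


def mcc(m: ConfusionMatrix) -> float:
    """Matthews correlation coefficient of a 2x2 matrix.

    Returns 0.0 with a warning when any margin is empty (the coefficient
    is undefined there; 0 is the no-association convention).
    """
    tp, fp, fn, tn = (float(c) for c in m.binary_cells())
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        warnings.warn("degenerate margin: MCC undefined, returning 0", stacklevel=2)
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def kappa_weights(k: int, weights: str | None) -> np.ndarray:
    """Agreement-weight matrix: 1 on the diagonal, decreasing off it."""
    if weights not in (None, "none", "linear", "quadratic"):
        raise ValueError(f"unknown weighting {weights!r}")
    i, j = np.indices((k, k))
    if weights in (None, "none"):
        return (i == j).astype(float)
    d = np.abs(i - j) / (k - 1)
    return 1.0 - (d if weights == "linear" else d**2)


def cohen_kappa(
    m: ConfusionMatrix, weights: str | None = "linear", alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """Cohen's (weighted) kappa with a large-sample Wald confidence interval.

    For a 2x2 table every weighting coincides with unweighted kappa, so the
    2-level severe/non-severe comparison is weighting-invariant. The CI is
    point +/- z * SE with the asymptotic (Fleiss-Cohen-Everitt) standard
    error.
    """
    if m.n == 0:
        raise ZeroDivisionError("empty confusion matrix")
    table = m.counts.astype(float)
    w = kappa_weights(m.k, weights)
    p = table / m.n
    pe = float((np.outer(p.sum(axis=1), p.sum(axis=0)) * w).sum())
    if pe >= 1.0 - 1e-12:
        raise ZeroDivisionError("expected agreement is 1: kappa undefined")
    wt = None if weights in (None, "none") else weights
    res = _sm_kappa(table, wt=wt, return_results=True)
    kappa = float(res.kappa)
    se = float(np.sqrt(res.var_kappa))
    z = stats.norm.ppf(1 - alpha / 2)
    return kappa, (kappa - z * se, kappa + z * se)


def spearman_rho(
    x: Sequence, y: Sequence, alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """Spearman rank correlation (average ranks for ties) with a Fisher-z CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d sequences")
    n = len(x)
    if n < 4:
        raise ValueError("need at least four pairs")
    rho = float(stats.spearmanr(x, y).statistic)
    z = stats.norm.ppf(1 - alpha / 2)
    if abs(rho) >= 1.0:
        return rho, (rho, rho)
    fz = np.arctanh(rho)
    half = z / math.sqrt(n - 3)
    return rho, (float(np.tanh(fz - half)), float(np.tanh(fz + half)))


# ---------------------------------------------------------------------------
# verbal interpretation bands

_BANDS = {
    # (lower edge inclusive, label), checked from the top
    "rho": ((0.8, "very strong"), (0.51, "strong"), (0.31, "moderate"),
            (0.1, "modest"), (float("-inf"), "weak")),
    "kappa": ((0.81, "almost perfect"), (0.61, "substantial"), (0.41, "moderate"),
              (0.21, "fair"), (float("-inf"), "poor")),
    "mcc": ((0.8, "very strong"), (0.6, "moderately strong"), (0.3, "fair"),
            (0.01, "very weak"), (float("-inf"), "negligible")),
}


def interpret(metric_name: str, value: float) -> str:
    """Verbal strength band for rho, kappa or MCC, lower edges inclusive.

    The rho scale's top band is open ("> 0.8"), so exactly 0.8 is "strong";
    all other edges are inclusive at the lower edge of their interval.
    """
    name = metric_name.lower()
    if name not in _BANDS:
        raise ValueError(f"no interpretation scale for {metric_name!r}")
    if name == "rho" and value == 0.8:
        return "strong"
    for low, label in _BANDS[name]:
        if value >= low:
            return label
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# report assembly


@dataclass
class MetricReport:
    """Headline metrics of one predicted-vs-observed comparison."""

    matrix: ConfusionMatrix
    sensitivity: float | None = None
    specificity: float | None = None
    correct: float | None = None
    mcc: float | None = None
    kappa: float | None = None
    kappa_ci: tuple[float, float] | None = None
    rho: float | None = None
    rho_ci: tuple[float, float] | None = None
    bands: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "labels": list(self.matrix.labels),
            "counts": self.matrix.counts.tolist(),
            "n": self.matrix.n,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "correct": self.correct,
            "mcc": self.mcc,
            "kappa": self.kappa,
            "kappa_ci": list(self.kappa_ci) if self.kappa_ci else None,
            "rho": self.rho,
            "rho_ci": list(self.rho_ci) if self.rho_ci else None,
            "bands": self.bands,
        }


def evaluate_binary(m: ConfusionMatrix) -> MetricReport:
    """Full 2x2 report: sensitivity, specificity, proportion correct, MCC
    and (weighting-invariant) kappa with CI."""
    kappa, ci = cohen_kappa(m, weights="linear")
    report = MetricReport(
        matrix=m,
        sensitivity=sensitivity(m),
        specificity=specificity(m),
        correct=proportion_correct(m),
        mcc=mcc(m),
        kappa=kappa,
        kappa_ci=ci,
    )
    report.bands = {
        "mcc": interpret("mcc", report.mcc),
        "kappa": interpret("kappa", report.kappa),
    }
    return report


def evaluate_ordinal(
    predicted: Sequence[int], observed: Sequence[int], labels: Sequence = (1, 2, 3)
) -> MetricReport:
    """k-level report: proportion correct, weighted kappa and Spearman rho."""
    m = build_confusion(predicted, observed, labels)
    kappa, kci = cohen_kappa(m, weights="linear")
    rho, rci = spearman_rho(list(predicted), list(observed))
    report = MetricReport(
        matrix=m,
        correct=proportion_correct(m),
        kappa=kappa,
        kappa_ci=kci,
        rho=rho,
        rho_ci=rci,
    )
    report.bands = {
        "kappa": interpret("kappa", kappa),
        "rho": interpret("rho", rho),
    }
    return report


def tally_equals_matrix(
    predicted: Sequence, observed: Sequence, m: ConfusionMatrix
) -> bool:
    """Brute-force per-pair tally check used as an internal consistency oracle."""
    index = {lab: i for i, lab in enumerate(m.labels)}
    tally = np.zeros_like(m.counts)
    for p, o in zip(predicted, observed):
        tally[index[p], index[o]] += 1
    return bool((tally == m.counts).all())
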