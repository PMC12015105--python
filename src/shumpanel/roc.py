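"""Empirical ROC machinery: AUC, curves, Youden cut-points, MCC, DeLong tests.

Conventions (fixed throughout the package):

* higher score => more likely positive (PR) class;
* ties get half credit in the AUC (Mann-Whitney estimator) and appear as
  diagonal segments in the curve;
* classification at threshold tau is ``score > tau``;
* curve thresholds are +inf, the midpoints between adjacent distinct scores
  in descending order, then -inf, so the curve runs (0,0) -> (1,1);
* Youden ties break toward the lowest threshold (highest sensitivity);
* MCC with a zero denominator factor is defined as 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

__all__ = [
    "ScoreSet",
    "ROCCurve",
    "OperatingPoint",
    "empirical_auc",
    "roc_curve",
    "youden_optimal",
    "operating_point_at",
    "mcc_at",
    "delong_auc_variance",
    "compare_auc",
    "compare_auc_paired",
    "bootstrap_auc_variance",
    "correlation_matrix",
    "marker_scores",
]


def _validate_scores(positives, negatives) -> tuple[np.ndarray, np.ndarray]:
    pos = np.asarray(positives, dtype=float).ravel()
    neg = np.asarray(negatives, dtype=float).ravel()
    if pos.size == 0:
        raise ValueError("positive class is empty")
    if neg.size == 0:
        raise ValueError("negative class is empty")
    if not (np.isfinite(pos).all() and np.isfinite(neg).all()):
        raise ValueError("scores must be finite")
    return pos, neg


@dataclass(frozen=True)
class ScoreSet:
    """Scores split by true class, optionally carrying sample ids for pairing."""

    positives: np.ndarray
    negatives: np.ndarray
    positive_ids: tuple[str, ...] | None = None
    negative_ids: tuple[str, ...] | None = None

    def __post_init__(self):
        pos, neg = _validate_scores(self.positives, self.negatives)
        object.__setattr__(self, "positives", pos)
        object.__setattr__(self, "negatives", neg)


def empirical_auc(positives, negatives) -> float:
    """Mann-Whitney AUC: P(X > Y) + 0.5 P(X = Y) for random positive X, negative Y.

    Computed from midranks; equals the trapezoidal area of the tie-corrected
    empirical ROC.
    """
    pos, neg = _validate_scores(positives, negatives)
    n1, n0 = pos.size, neg.size
    r = rankdata(np.concatenate([pos, neg]))
    return float((r[:n1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


@dataclass(frozen=True)
class ROCCurve:
    """Empirical ROC: descending thresholds with the (fpr, tpr) they induce."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_curve(positives, negatives) -> ROCCurve:
    """Tie-corrected empirical ROC.

    Thresholds are +inf, midpoints between adjacent distinct pooled scores
    (descending), then -inf; the curve therefore starts at (0, 0) and ends at
    (1, 1), and its trapezoidal area equals :func:`empirical_auc`.
    """
    pos, neg = _validate_scores(positives, negatives)
    uniq = np.unique(np.concatenate([pos, neg]))  # ascending
    mids = (uniq[1:] + uniq[:-1]) / 2.0
    # adjacent scores ~1 ulp apart can round their midpoint up to the larger
    # value; a valid cut for `score > tau` needs tau in [lower, upper)
    mids = np.where(mids >= uniq[1:], uniq[:-1], mids)
    thr = np.concatenate([[np.inf], mids[::-1], [-np.inf]])
    tpr = (pos[:, None] > thr[None, :]).mean(axis=0)
    fpr = (neg[:, None] > thr[None, :]).mean(axis=0)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc)


@dataclass(frozen=True)
class OperatingPoint:
    """One threshold with its classification metrics.

    confusion is (TP, FP, TN, FN) at decision rule ``score > threshold``.
    """

    threshold: float
    tpr: float
    fpr: float
    youden_j: float
    mcc: float
    confusion: tuple[int, int, int, int]


def mcc_at(tp: int, fp: int, tn: int, fn: int) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    if tp + fp + tn + fn == 0:
        raise ValueError("empty confusion table")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / math.sqrt(denom))


def operating_point_at(positives, negatives, threshold: float) -> OperatingPoint:
    """Metrics of the rule ``score > threshold`` on the given scores."""
    pos, neg = _validate_scores(positives, negatives)
    tp = int((pos > threshold).sum())
    fn = pos.size - tp
    fp = int((neg > threshold).sum())
    tn = neg.size - fp
    tpr = tp / pos.size
    fpr = fp / neg.size
    return OperatingPoint(
        threshold=float(threshold),
        tpr=tpr,
        fpr=fpr,
        youden_j=tpr - fpr,
        mcc=mcc_at(tp, fp, tn, fn),
        confusion=(tp, fp, tn, fn),
    )


def youden_optimal(positives, negatives) -> OperatingPoint:
    """Operating point maximizing Youden's J = TPR - FPR.

    Ties are broken toward the lowest threshold (highest sensitivity).  On a
    degenerate single-valued score the diagonal point (J = 0) is returned
    with a warning.
    """
    pos, neg = _validate_scores(positives, negatives)
    curve = roc_curve(pos, neg)
    j = curve.tpr - curve.fpr
    if np.all(j <= 0) and curve.thresholds.size <= 2:
        warnings.warn("degenerate ROC: single threshold, returning J = 0 point")
    best = len(j) - 1 - int(np.argmax(j[::-1]))  # last argmax = lowest threshold
    return operating_point_at(pos, neg, curve.thresholds[best])


# ---------------------------------------------------------------------------
# DeLong machinery for AUC variances and comparisons
# ---------------------------------------------------------------------------


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus the DeLong structural components V10 (per positive) and V01
    (per negative), computed from midranks."""
    m, n = pos.size, neg.size
    rx = rankdata(pos)
    ry = rankdata(neg)
    rz = rankdata(np.concatenate([pos, neg]))
    v10 = (rz[:m] - rx) / n
    v01 = 1.0 - (rz[m:] - ry) / m
    auc = float(v10.mean())
    return auc, v10, v01


def delong_auc_variance(positives, negatives) -> float:
    """DeLong variance estimate of a single empirical AUC."""
    pos, neg = _validate_scores(positives, negatives)
    _, v10, v01 = _placements(pos, neg)
    m, n = pos.size, neg.size
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


def bootstrap_auc_variance(positives, negatives, n_boot: int = 2000, seed: int = 0) -> float:
    """Class-stratified bootstrap variance of the empirical AUC (DeLong alternative)."""
    pos, neg = _validate_scores(positives, negatives)
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        aucs[b] = empirical_auc(
            rng.choice(pos, size=pos.size, replace=True),
            rng.choice(neg, size=neg.size, replace=True),
        )
    return float(aucs.var(ddof=1))


def compare_auc(
    scores_a: ScoreSet,
    scores_b: ScoreSet,
    paired: bool = True,
) -> tuple[float, float, float]:
    """DeLong z-test for a difference between two empirical AUCs.

    paired=True assumes the same subjects underlie both score sets (e.g. one
    assay read in two matrices) and uses the structural-components covariance;
    ids, when present on both sets, must then match.  paired=False sums the
    two independent DeLong variances.

    Returns (delta_auc = AUC_A - AUC_B, z, two-sided p).
    """
    pa, na = scores_a.positives, scores_a.negatives
    pb, nb = scores_b.positives, scores_b.negatives
    if paired:
        if pa.size != pb.size or na.size != nb.size:
            raise ValueError("paired comparison requires equal class sizes in A and B")
        for ids_a, ids_b, which in (
            (scores_a.positive_ids, scores_b.positive_ids, "positive"),
            (scores_a.negative_ids, scores_b.negative_ids, "negative"),
        ):
            if ids_a is not None and ids_b is not None and ids_a != ids_b:
                raise ValueError(f"paired comparison with mismatched {which} sample ids")
        auc_a, v10a, v01a = _placements(pa, na)
        auc_b, v10b, v01b = _placements(pb, nb)
        m, n = pa.size, na.size
        s10 = np.cov(v10a, v10b, ddof=1) if m > 1 else np.zeros((2, 2))
        s01 = np.cov(v01a, v01b, ddof=1) if n > 1 else np.zeros((2, 2))
        var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
            s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
        ) / n
    else:
        auc_a = empirical_auc(pa, na)
        auc_b = empirical_auc(pb, nb)
        var = delong_auc_variance(pa, na) + delong_auc_variance(pb, nb)
    delta = auc_a - auc_b
    if var <= 0:
        # identical scores (or degenerate variance): no evidence of a difference
        return float(delta), 0.0, 1.0 if delta == 0 else float("nan")
    z = delta / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(delta), float(z), float(p)


def compare_auc_paired(scores_a: ScoreSet, scores_b: ScoreSet) -> tuple[float, float, float]:
    return compare_auc(scores_a, scores_b, paired=True)


# ---------------------------------------------------------------------------
# Panel-level helpers
# ---------------------------------------------------------------------------


def marker_scores(
    panel: pd.DataFrame,
    marker: str,
    positive_class: str = "PR",
    negative_class: str = "PS",
    matrix_label: str | None = None,
) -> ScoreSet:
    """Extract one marker's scores from a panel table as a ScoreSet."""
    df = panel
    if matrix_label is not None:
        df = df[df["matrix_label"] == matrix_label]
    if marker not in df.columns:
        raise KeyError(f"marker {marker!r} not in panel")
    pos = df[df["class_label"] == positive_class]
    neg = df[df["class_label"] == negative_class]
    return ScoreSet(
        positives=pos[marker].to_numpy(),
        negatives=neg[marker].to_numpy(),
        positive_ids=tuple(pos["sample_id"]),
        negative_ids=tuple(neg["sample_id"]),
    )


def plot_roc(curves: dict[str, ROCCurve], path=None):
    """Plot one or more labelled ROC curves (requires matplotlib); returns the
    Axes, saving to ``path`` when given."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for label, c in curves.items():
        ax.plot(c.fpr, c.tpr, label=f"{label} (AUC {c.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right", fontsize=8)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return ax


def correlation_matrix(panel: pd.DataFrame, markers: list[str] | None = None) -> pd.DataFrame:
    """Pearson correlation of marker concentrations across all samples
    (classes pooled).  Zero-variance markers yield NaN rows/columns."""
    from .synthetic import panel_markers

    if markers is None:
        markers = panel_markers(panel)
    if len(panel) < 3:
        raise ValueError("need at least 3 samples for a correlation matrix")
    return panel[markers].corr(method="pearson")
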