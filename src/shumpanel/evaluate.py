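"""Out-of-sample and uncertainty machinery around the SHUM combiner.

* leave-one-out (LOO) evaluation of the combined panel or of single markers,
  with the standardization, coefficients and Youden cut-off all refit inside
  each fold so no held-out label ever reaches the model that scores it;
* class-stratified bootstrap standard errors of the unit-norm coefficients
  (draws sign-aligned to the full-data fit before taking SDs);
* the deployable diagnostic rule (combination vector + cut-off, score above
  the cut-off => positive/PR call);
* an end-to-end report bundling per-marker ROC/AUC in each assay matrix,
  paired AUC comparisons between matrices, the marker correlation matrix,
  the combined fit, the LOO table, bootstrap SEs and the rule.

All randomness flows from a single seed through independent spawned streams,
so each stage is reproducible in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import roc
from .roc import (
    ScoreSet,
    empirical_auc,
    marker_scores,
    mcc_at,
    operating_point_at,
    youden_optimal,
)
from .shum import CombinationVector, SHUMConfig, SHUMFit, combined_score, optimize_shum
from .synthetic import panel_markers

__all__ = [
    "LOOResult",
    "BootstrapResult",
    "DiagnosticRule",
    "loo_evaluate",
    "bootstrap_se",
    "build_rule",
    "apply_rule",
    "report",
    "report_to_json",
]

POSITIVE, NEGATIVE = "PR", "PS"


def _derive_seed(seed: int, stream: int) -> int:
    """Independent child seed (< 2**31) for a named sub-stream."""
    return int(np.random.SeedSequence(seed).spawn(stream + 1)[stream].generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Leave-one-out
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LOOResult:
    """Held-out scores and decisions per sample plus pooled confusion metrics."""

    per_sample: pd.DataFrame  # sample_id, true, score, threshold, predicted
    tpr: float
    fpr: float
    mcc: float
    confusion: tuple[int, int, int, int]  # TP, FP, TN, FN
    n_unclassifiable: int = 0


def _fit_fold(
    train: pd.DataFrame,
    markers: list[str],
    config: SHUMConfig,
    marker: str | None,
) -> CombinationVector:
    """Refit the scoring function on one training fold.

    Full-panel mode refits the SHUM combination; single-marker mode fixes a
    one-hot beta (only the standardization and cut-off are refit)."""
    if marker is None:
        return optimize_shum(train, markers, config).beta
    x = train.loc[train["class_label"].isin((NEGATIVE, POSITIVE)), marker].to_numpy(float)
    center, scale = x.mean(), x.std(ddof=1)
    if scale <= 0:
        raise ValueError(f"zero-variance marker {marker!r} in fold")
    return CombinationVector(
        markers=(marker,), coefficients=np.ones(1), center=np.array([center]), scale=np.array([scale])
    )


def loo_evaluate(
    panel: pd.DataFrame,
    markers: list[str],
    config: SHUMConfig | None = None,
    marker: str | None = None,
    fixed_threshold: float | None = None,
) -> LOOResult:
    """Leave-one-out evaluation of the combined panel (default) or one marker.

    For each sample the standardization, combination and Youden cut-off are
    refit on the other n-1 samples, then the held-out sample is scored and
    classified (score > cut-off => PR).  ``fixed_threshold`` bypasses the
    per-fold Youden cut-off with a fixed clinical threshold on the *raw*
    single-marker scale.  A fold whose training remainder loses an entire
    class is counted unclassifiable.
    """
    if config is None:
        config = SHUMConfig()
    df = panel[panel["class_label"].isin((NEGATIVE, POSITIVE))].reset_index(drop=True)
    if len(df) < 4:
        raise ValueError("LOO needs at least 4 samples")
    for cls in (NEGATIVE, POSITIVE):
        if (df["class_label"] == cls).sum() < 2:
            raise ValueError(f"LOO needs >= 2 samples of class {cls!r}")

    rows = []
    n_unclass = 0
    for i in range(len(df)):
        train = df.drop(index=i)
        held = df.iloc[[i]]
        if train["class_label"].nunique() < 2:
            n_unclass += 1
            continue
        if fixed_threshold is not None and marker is not None:
            score = float(held[marker].iloc[0])
            tau = float(fixed_threshold)
        else:
            beta = _fit_fold(train, markers, config, marker)
            tr_scores = combined_score(beta, train)
            pos = tr_scores[train["class_label"].to_numpy() == POSITIVE].to_numpy()
            neg = tr_scores[train["class_label"].to_numpy() == NEGATIVE].to_numpy()
            tau = youden_optimal(pos, neg).threshold
            score = float(combined_score(beta, held).iloc[0])
        rows.append(
            {
                "sample_id": held["sample_id"].iloc[0],
                "true": held["class_label"].iloc[0],
                "score": score,
                "threshold": tau,
                "predicted": POSITIVE if score > tau else NEGATIVE,
            }
        )
    per = pd.DataFrame(rows)
    tp = int(((per["true"] == POSITIVE) & (per["predicted"] == POSITIVE)).sum())
    fn = int(((per["true"] == POSITIVE) & (per["predicted"] == NEGATIVE)).sum())
    fp = int(((per["true"] == NEGATIVE) & (per["predicted"] == POSITIVE)).sum())
    tn = int(((per["true"] == NEGATIVE) & (per["predicted"] == NEGATIVE)).sum())
    tpr = tp / (tp + fn) if tp + fn else 0.0
    fpr = fp / (fp + tn) if fp + tn else 0.0
    return LOOResult(
        per_sample=per,
        tpr=tpr,
        fpr=fpr,
        mcc=mcc_at(tp, fp, tn, fn),
        confusion=(tp, fp, tn, fn),
        n_unclassifiable=n_unclass,
    )


# ---------------------------------------------------------------------------
# Bootstrap coefficient standard errors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BootstrapResult:
    """Sign-aligned bootstrap draws of the unit-norm coefficients and their SDs."""

    markers: tuple[str, ...]
    draws: np.ndarray  # (B, k), each row unit norm
    se: np.ndarray  # (k,)
    B: int


def bootstrap_se(
    panel: pd.DataFrame,
    markers: list[str],
    config: SHUMConfig | None = None,
    B: int = 500,
    max_retries: int = 100,
) -> BootstrapResult:
    """Class-stratified bootstrap SEs of the SHUM coefficients.

    Each resample redraws samples with replacement within class (preserving
    the cohort sizes), refits, and is sign-aligned to the full-data fit (flip
    when the dot product is negative) before per-coefficient SDs are taken.
    Degenerate resamples in which a class collapses to a single unique row
    are redrawn, up to ``max_retries`` per draw.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    if config is None:
        config = SHUMConfig()
    df = panel[panel["class_label"].isin((NEGATIVE, POSITIVE))].reset_index(drop=True)
    full = optimize_shum(df, markers, config)
    rng = np.random.default_rng(_derive_seed(config.seed, 1))
    groups = {cls: df[df["class_label"] == cls] for cls in (NEGATIVE, POSITIVE)}
    draws = np.empty((B, len(markers)))
    for b in range(B):
        for attempt in range(max_retries + 1):
            parts = []
            for cls, g in groups.items():
                idx = rng.integers(0, len(g), size=len(g))
                parts.append(g.iloc[idx])
            samp = pd.concat(parts, ignore_index=True)
            degenerate = any(
                samp.loc[samp["class_label"] == cls, markers].drop_duplicates().shape[0] < 2
                for cls in groups
            )
            if not degenerate:
                break
        else:
            raise RuntimeError(f"bootstrap draw {b}: degenerate resample after {max_retries} retries")
        fit = optimize_shum(samp, markers, replace(config, seed=_derive_seed(config.seed, 2 + b)))
        beta = fit.beta.coefficients
        if beta @ full.beta.coefficients < 0:
            beta = -beta
        draws[b] = beta
    return BootstrapResult(
        markers=tuple(markers), draws=draws, se=draws.std(axis=0, ddof=1), B=B
    )


# ---------------------------------------------------------------------------
# Diagnostic rule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiagnosticRule:
    """Deployable classifier: combined score above ``cutoff`` => PR call."""

    beta: CombinationVector
    cutoff: float

    def to_dict(self) -> dict:
        return {"beta": self.beta.to_dict(), "cutoff": self.cutoff}

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "DiagnosticRule":
        return cls(beta=CombinationVector.from_dict(d["beta"]), cutoff=float(d["cutoff"]))

    @classmethod
    def from_json(cls, text: str) -> "DiagnosticRule":
        return cls.from_dict(json.loads(text))


def build_rule(
    panel: pd.DataFrame, markers: list[str], config: SHUMConfig | None = None
) -> tuple[DiagnosticRule, SHUMFit]:
    """Fit the combination on the panel and set the cut-off at the Youden
    optimum of the training combined scores."""
    if config is None:
        config = SHUMConfig()
    df = panel[panel["class_label"].isin((NEGATIVE, POSITIVE))]
    fit = optimize_shum(df, markers, config)
    scores = combined_score(fit.beta, df)
    pos = scores[df["class_label"].to_numpy() == POSITIVE].to_numpy()
    neg = scores[df["class_label"].to_numpy() == NEGATIVE].to_numpy()
    op = youden_optimal(pos, neg)
    return DiagnosticRule(beta=fit.beta, cutoff=op.threshold), fit


def apply_rule(rule: DiagnosticRule, panel: pd.DataFrame) -> pd.DataFrame:
    """Score a panel with a fitted rule; returns sample_id, score, predicted."""
    scores = combined_score(rule.beta, panel)
    return pd.DataFrame(
        {
            "sample_id": panel["sample_id"].to_numpy(),
            "score": scores.to_numpy(),
            "predicted": np.where(scores.to_numpy() > rule.cutoff, POSITIVE, NEGATIVE),
        }
    )


# ---------------------------------------------------------------------------
# End-to-end report
# ---------------------------------------------------------------------------


def _round(obj, nd=4):
    """Round floats recursively at serialization time only."""
    if isinstance(obj, float):
        return round(obj, nd)
    if isinstance(obj, dict):
        return {k: _round(v, nd) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round(v, nd) for v in obj]
    if isinstance(obj, np.ndarray):
        return _round(obj.tolist(), nd)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return round(float(obj), nd)
    return obj


def report(
    panel: pd.DataFrame,
    markers: list[str] | None = None,
    config: SHUMConfig | None = None,
    B: int = 500,
    loo: bool = True,
) -> dict:
    """Full analysis report on one panel table (may hold EV and serum rows).

    Sections: per-marker AUC/operating point per assay matrix, paired DeLong
    comparison of matrices where sample ids match, the pooled marker
    correlation matrix, the combined SHUM fit with bootstrap coefficient SEs,
    LOO confusion metrics for the combination and each marker, and the
    deployable diagnostic rule.  Deterministic given ``config.seed``.
    """
    if config is None:
        config = SHUMConfig()
    if markers is None:
        markers = panel_markers(panel)
    out: dict = {"markers": list(markers), "seed": config.seed, "n": int(len(panel))}

    matrices = sorted(panel["matrix_label"].unique())
    per_marker: dict = {}
    for mk in markers:
        entry: dict = {}
        for mat in matrices:
            ss = marker_scores(panel, mk, matrix_label=mat)
            auc = empirical_auc(ss.positives, ss.negatives)
            flipped = auc < 0.5
            pos, neg = ss.positives, ss.negatives
            if flipped:  # auto-orient: lower values indicate PR for this marker
                pos, neg = -pos, -neg
                auc = 1.0 - auc
            op = youden_optimal(pos, neg)
            entry[mat] = {
                "auc": auc,
                "orientation_flipped": bool(flipped),
                "youden": {
                    "threshold": op.threshold,
                    "tpr": op.tpr,
                    "fpr": op.fpr,
                    "youden_j": op.youden_j,
                    "mcc": op.mcc,
                },
            }
        if {"EV", "serum"} <= set(matrices):
            a = marker_scores(panel, mk, matrix_label="EV")
            b = marker_scores(panel, mk, matrix_label="serum")
            paired = a.positive_ids == b.positive_ids and a.negative_ids == b.negative_ids
            delta, z, p = roc.compare_auc(a, b, paired=paired)
            entry["ev_vs_serum"] = {"delta_auc": delta, "z": z, "p": p, "paired": bool(paired)}
        per_marker[mk] = entry
    out["per_marker"] = per_marker

    if markers:
        fit_matrix = "EV" if "EV" in matrices else matrices[0]
        fit_panel = panel[panel["matrix_label"] == fit_matrix]
        out["correlation"] = {
            "markers": list(markers),
            "matrix": roc.correlation_matrix(fit_panel, list(markers)).to_numpy().tolist(),
        }
        rule, fit = build_rule(fit_panel, list(markers), config)
        scores = combined_score(fit.beta, fit_panel)
        lab = fit_panel["class_label"].to_numpy()
        op = operating_point_at(
            scores[lab == POSITIVE].to_numpy(), scores[lab == NEGATIVE].to_numpy(), rule.cutoff
        )
        boot = bootstrap_se(fit_panel, list(markers), config, B=B)
        out["combined"] = {
            "fit_matrix": fit_matrix,
            "coefficients": dict(zip(fit.beta.markers, fit.beta.coefficients.tolist())),
            "bootstrap_se": dict(zip(boot.markers, boot.se.tolist())),
            "bootstrap_B": boot.B,
            "shum": fit.shum,
            "auc": fit.hum,
            "cutoff": rule.cutoff,
            "tpr": op.tpr,
            "fpr": op.fpr,
            "youden_j": op.youden_j,
            "mcc": op.mcc,
        }
        out["rule"] = rule.to_dict()
        if loo:
            loo_all = loo_evaluate(fit_panel, list(markers), config)
            loo_section = {
                "combined": {
                    "tpr": loo_all.tpr,
                    "fpr": loo_all.fpr,
                    "mcc": loo_all.mcc,
                    "confusion": list(loo_all.confusion),
                }
            }
            for mk in markers:
                r = loo_evaluate(fit_panel, [mk], config, marker=mk)
                loo_section[mk] = {
                    "tpr": r.tpr,
                    "fpr": r.fpr,
                    "mcc": r.mcc,
                    "confusion": list(r.confusion),
                }
            out["loo"] = loo_section
    return out


def report_to_json(rep: dict, nd: int = 4) -> str:
    """Serialize a report with floats rounded to ``nd`` decimals (values are
    never rounded internally, only here)."""
    return json.dumps(_round(rep, nd), indent=2, sort_keys=True)
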