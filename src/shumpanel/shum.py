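"""Optimal linear biomarker combination by smoothed HUM maximization.

The hypervolume under the ROC manifold (HUM) of a score generalizes the AUC
to ordered classes: for two classes it is the proportion of (positive,
negative) pairs ranked correctly (AUC); for three ordered classes it is the
proportion of correctly ordered triplets.  For a linear combination
score = beta' x the empirical HUM is a step function of beta, so we maximize
a smoothed surrogate (SHUM) in which the order indicator is replaced by a
logistic kernel s(t) = 1 / (1 + exp(-t)) at bandwidth h:

    SHUM_h(beta) = (1 / n1 n0) sum_ij s((beta'x_i - beta'y_j) / h)     (2-class)

which converges to the empirical HUM as h -> 0+.  beta is constrained to the
unit Euclidean sphere for identifiability (the score is scale-free).

Optimization is projected gradient ascent on the sphere with a coarse-to-fine
bandwidth annealing schedule and multi-start (random unit vectors plus the
pooled-covariance Fisher/LDA direction as a warm start).  Markers are
z-standardized on the fitting data before combination, so the unit-norm
coefficients are comparable across markers with different units; the fitted
standardization travels with the coefficient vector.  The sign is fixed so
the mean combined score of the positive (PR) class exceeds that of the
negative (PS) class.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .roc import empirical_auc

__all__ = [
    "SHUMConfig",
    "CombinationVector",
    "SHUMFit",
    "shum_objective",
    "empirical_hum",
    "optimize_shum",
    "combined_score",
    "fisher_direction",
]

_DEFAULT_BANDWIDTHS = tuple(float(h) for h in np.geomspace(1.0, 0.05, 8))


@dataclass(frozen=True)
class SHUMConfig:
    """Optimization contract for the SHUM maximizer.

    bandwidth_schedule is in units of the pooled within-class SD of the
    current combined score (coarse-to-fine annealing, geometric 1 -> 0.05 by
    default).  restarts counts random unit-vector starts; the Fisher/LDA warm
    start is always added on top.  Deterministic given seed.
    """

    bandwidth_schedule: tuple[float, ...] = _DEFAULT_BANDWIDTHS
    restarts: int = 20
    max_iter: int = 100
    tol: float = 1e-8
    seed: int = 0

    def __post_init__(self):
        hs = tuple(float(h) for h in self.bandwidth_schedule)
        if not hs or any(h <= 0 for h in hs):
            raise ValueError("bandwidths must be positive")
        if any(b <= a for a, b in zip(hs, hs[1:])):
            pass  # enforced decreasing below
        if list(hs) != sorted(hs, reverse=True) or len(set(hs)) != len(hs):
            raise ValueError("bandwidth_schedule must be strictly decreasing")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        object.__setattr__(self, "bandwidth_schedule", hs)


@dataclass(frozen=True)
class CombinationVector:
    """Unit-norm linear combination over named markers, with the per-marker
    (center, scale) standardization learned on the fitting data."""

    markers: tuple[str, ...]
    coefficients: np.ndarray
    center: np.ndarray
    scale: np.ndarray

    def __post_init__(self):
        beta = np.asarray(self.coefficients, dtype=float)
        if abs(np.linalg.norm(beta) - 1.0) > 1e-10:
            raise ValueError(f"coefficient norm must be 1, got {np.linalg.norm(beta):.12f}")
        if np.any(np.asarray(self.scale) <= 0):
            raise ValueError("standardization scales must be > 0")
        object.__setattr__(self, "markers", tuple(self.markers))
        object.__setattr__(self, "coefficients", beta)
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        object.__setattr__(self, "scale", np.asarray(self.scale, dtype=float))

    def to_dict(self) -> dict:
        return {
            "markers": list(self.markers),
            "coefficients": self.coefficients.tolist(),
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CombinationVector":
        return cls(
            markers=tuple(d["markers"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            center=np.asarray(d["center"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
        )


def combined_score(beta: CombinationVector, panel: pd.DataFrame) -> pd.Series:
    """Per-sample combined score sum_k beta_k (x_k - center_k) / scale_k,
    using the standardization stored at fit time."""
    missing = [m for m in beta.markers if m not in panel.columns]
    if missing:
        raise KeyError(f"panel missing marker columns: {missing}")
    x = panel[list(beta.markers)].to_numpy(dtype=float)
    z = (x - beta.center) / beta.scale
    return pd.Series(z @ beta.coefficients, index=panel.index, name="combined_score")


# ---------------------------------------------------------------------------
# Objective and gradients (standardized design matrices, ordered class list)
# ---------------------------------------------------------------------------


def _class_matrices(
    panel: pd.DataFrame, markers: list[str], classes: tuple[str, ...]
) -> list[np.ndarray]:
    out = []
    for cls in classes:
        sub = panel[panel["class_label"] == cls]
        if len(sub) < 2:
            raise ValueError(f"class {cls!r} needs >= 2 samples, found {len(sub)}")
        out.append(sub[markers].to_numpy(dtype=float))
    return out


def shum_objective(scores_by_class: list[np.ndarray], h: float) -> float:
    """Smoothed empirical HUM of pre-computed scores, classes ordered low->high.

    Two classes [neg, pos]: mean_ij s((pos_i - neg_j)/h).  Three ordered
    classes [low, mid, high]: mean_ijk s((high_i - mid_j)/h) s((mid_j - low_k)/h).
    Converges to the empirical HUM as h -> 0+.
    """
    if h <= 0:
        raise ValueError(f"bandwidth h must be > 0, got {h}")
    if len(scores_by_class) == 2:
        neg, pos = scores_by_class
        return float(expit((pos[:, None] - neg[None, :]) / h).mean())
    if len(scores_by_class) == 3:
        low, mid, high = scores_by_class
        a = expit((high[:, None] - mid[None, :]) / h)  # (n_high, n_mid)
        b = expit((mid[:, None] - low[None, :]) / h)  # (n_mid, n_low)
        return float(a.sum(axis=0) @ b.sum(axis=1) / (high.size * mid.size * low.size))
    raise ValueError("2 or 3 ordered classes supported")


def empirical_hum(scores_by_class: list[np.ndarray]) -> float:
    """Unsmoothed empirical HUM (ties get half credit per order indicator)."""
    if len(scores_by_class) == 2:
        neg, pos = scores_by_class
        return empirical_auc(pos, neg)
    if len(scores_by_class) == 3:
        low, mid, high = scores_by_class

        def ind(d):
            return (d > 0) + 0.5 * (d == 0)

        a = ind(high[:, None] - mid[None, :])
        b = ind(mid[:, None] - low[None, :])
        return float(a.sum(axis=0) @ b.sum(axis=1) / (high.size * mid.size * low.size))
    raise ValueError("2 or 3 ordered classes supported")


def _obj_grad(xs: list[np.ndarray], beta: np.ndarray, h: float) -> tuple[float, np.ndarray]:
    """SHUM objective and its gradient wrt beta on standardized matrices."""
    if len(xs) == 2:
        xn, xp = xs
        u = xp @ beta
        v = xn @ beta
        t = (u[:, None] - v[None, :]) / h
        p = expit(t)
        w = p * (1.0 - p)
        n = u.size * v.size
        obj = float(p.mean())
        grad = (xp.T @ w.sum(axis=1) - xn.T @ w.sum(axis=0)) / (n * h)
        return obj, grad
    xl, xm, xh = xs
    tl, tm, th = xl @ beta, xm @ beta, xh @ beta
    a = expit((th[:, None] - tm[None, :]) / h)  # high vs mid
    b = expit((tm[:, None] - tl[None, :]) / h)  # mid vs low
    ap = a * (1.0 - a)
    bp = b * (1.0 - b)
    asum0 = a.sum(axis=0)  # per mid
    bsum1 = b.sum(axis=1)  # per mid
    n = th.size * tm.size * tl.size
    obj = float(asum0 @ bsum1 / n)
    # d/dbeta mean_ijk a_ij b_jk
    term1 = xh.T @ (ap @ bsum1) - xm.T @ (ap.sum(axis=0) * bsum1)
    term2 = xm.T @ (asum0 * bp.sum(axis=1)) - xl.T @ (bp.T @ asum0)
    grad = (term1 + term2) / (n * h)
    return obj, grad


def _pooled_sd(scores_by_class: list[np.ndarray]) -> float:
    num = sum((s.size - 1) * s.var(ddof=1) for s in scores_by_class)
    den = sum(s.size - 1 for s in scores_by_class)
    return math.sqrt(num / den) if den > 0 else 1.0


def fisher_direction(xs: list[np.ndarray]) -> np.ndarray:
    """Pooled-covariance Fisher/LDA direction between the extreme classes,
    normalized to unit length; falls back to the mean difference when the
    pooled covariance is singular."""
    lo, hi = xs[0], xs[-1]
    d = hi.mean(axis=0) - lo.mean(axis=0)
    cov = sum((x.shape[0] - 1) * np.cov(x, rowvar=False) for x in xs) / sum(
        x.shape[0] - 1 for x in xs
    )
    cov = np.atleast_2d(cov)
    try:
        w = np.linalg.solve(cov + 1e-10 * np.eye(cov.shape[0]), d)
    except np.linalg.LinAlgError:
        w = d
    nrm = np.linalg.norm(w)
    if nrm == 0 or not np.isfinite(nrm):
        w = np.ones(lo.shape[1])
        nrm = np.linalg.norm(w)
    return w / nrm


def _ascend(
    xs: list[np.ndarray], beta0: np.ndarray, config: SHUMConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Projected gradient ascent over the annealing schedule from one start.

    Returns (final beta, best iterate).  The empirical HUM is a step function
    of beta while the ascent follows its smoothed surrogate, so the iterate
    with the highest *unsmoothed* HUM along the trajectory is remembered and
    returned alongside the smoothed optimum.
    """
    beta = beta0 / np.linalg.norm(beta0)
    best_beta = beta
    best_hum = empirical_hum([x @ beta for x in xs])
    for h_rel in config.bandwidth_schedule:
        scale = _pooled_sd([x @ beta for x in xs])
        h = max(h_rel * scale, 1e-9)
        lr = 1.0
        obj, grad = _obj_grad(xs, beta, h)
        for _ in range(config.max_iter):
            if not np.all(np.isfinite(grad)):
                raise FloatingPointError(f"non-finite SHUM gradient at bandwidth h={h:g}")
            gt = grad - (grad @ beta) * beta  # tangent projection
            gn = np.linalg.norm(gt)
            if gn < 1e-14:
                break
            accepted = False
            for _ in range(25):
                cand = beta + lr * gt
                cand /= np.linalg.norm(cand)
                cobj, cgrad = _obj_grad(xs, cand, h)
                if cobj > obj:
                    accepted = True
                    break
                lr *= 0.5
            if not accepted:
                break
            improved = cobj - obj
            beta, obj, grad = cand, cobj, cgrad
            hum = empirical_hum([x @ beta for x in xs])
            if hum > best_hum:
                best_hum, best_beta = hum, beta
            lr = min(lr * 1.5, 1e3)
            if improved < config.tol:
                break
    return beta, best_beta


def _polish(xs: list[np.ndarray], beta: np.ndarray, max_steps: int = 60, n_cand: int = 8) -> np.ndarray:
    """Discrete pair-flip refinement of the empirical HUM.

    The empirical HUM changes only when beta crosses a hyperplane
    (x_i - y_j)' beta = 0 for some cross-class pair, so its maximizer can sit
    on a sliver of the sphere too narrow for smoothed ascent to land on.
    From the current beta, try the minimal rotation that flips each of the
    nearest mis-ranked adjacent-class pairs (reflect the component of beta
    along the pair difference, with a small overshoot) and accept whichever
    move improves the unsmoothed HUM; repeat until no move helps.
    """
    best = empirical_hum([x @ beta for x in xs])
    for _ in range(max_steps):
        cands = []
        for low_x, high_x in zip(xs[:-1], xs[1:]):
            margin = (high_x @ beta)[:, None] - (low_x @ beta)[None, :]
            bad = margin <= 0
            idx = np.argwhere(bad)
            if idx.size == 0:
                continue
            order = np.argsort(-margin[bad])[:n_cand]  # smallest violation first
            for t in order:
                i, j = idx[t]
                d = high_x[i] - low_x[j]
                nd = np.linalg.norm(d)
                if nd < 1e-12:
                    continue
                dhat = d / nd
                cand = beta - 1.002 * (beta @ dhat) * dhat
                ncand = np.linalg.norm(cand)
                if ncand > 1e-9:
                    cands.append(cand / ncand)
        improved = False
        for cand in cands:
            h = empirical_hum([x @ cand for x in xs])
            if h > best:
                beta, best, improved = cand, h, True
                break
        if not improved:
            break
    return beta


@dataclass(frozen=True)
class SHUMFit:
    """Result of :func:`optimize_shum`: the fitted combination plus its
    smoothed objective (at the smallest bandwidth) and unsmoothed HUM."""

    beta: CombinationVector
    shum: float
    hum: float
    classes: tuple[str, ...]
    config: SHUMConfig

    def to_dict(self) -> dict:
        return {
            "beta": self.beta.to_dict(),
            "shum": self.shum,
            "hum": self.hum,
            "classes": list(self.classes),
            "config": {
                "bandwidth_schedule": list(self.config.bandwidth_schedule),
                "restarts": self.config.restarts,
                "max_iter": self.config.max_iter,
                "tol": self.config.tol,
                "seed": self.config.seed,
            },
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def optimize_shum(
    panel: pd.DataFrame,
    markers: list[str],
    config: SHUMConfig | None = None,
    classes: tuple[str, ...] = ("PS", "PR"),
) -> SHUMFit:
    """Fit the unit-norm linear combination maximizing the smoothed HUM.

    ``classes`` lists the class labels in increasing score order (default
    two-class PS < PR; pass ("control", "PS", "PR") for the ordered
    three-class HUM).  Markers are z-standardized on the fitting rows; the
    best of ``restarts`` random starts plus the Fisher/LDA warm start wins by
    unsmoothed empirical HUM, ties broken by the smoothed objective.
    """
    if config is None:
        config = SHUMConfig()
    if len(markers) < 1:
        raise ValueError("at least one marker required")
    fit_rows = panel[panel["class_label"].isin(classes)]
    raw = _class_matrices(fit_rows, list(markers), classes)
    allx = np.vstack(raw)
    center = allx.mean(axis=0)
    scale = allx.std(axis=0, ddof=1)
    if np.any(scale <= 0):
        bad = [m for m, s in zip(markers, scale) if s <= 0]
        raise ValueError(f"zero-variance markers cannot be standardized: {bad}")
    xs = [(x - center) / scale for x in raw]
    k = len(markers)

    rng = np.random.default_rng(config.seed)
    starts = [fisher_direction(xs)]
    for _ in range(config.restarts):
        v = rng.standard_normal(k)
        starts.append(v / np.linalg.norm(v))

    best = None  # (hum, shum, beta)
    h_final_rel = config.bandwidth_schedule[-1]
    for b0 in starts:
        final, best_iter = _ascend(xs, b0, config)
        for beta in (final, best_iter):
            scores = [x @ beta for x in xs]
            hum = empirical_hum(scores)
            h_final = max(h_final_rel * _pooled_sd(scores), 1e-9)
            shum = shum_objective(scores, h_final)
            if best is None or (hum, shum) > (best[0], best[1]):
                best = (hum, shum, beta)

    _, _, beta = best
    beta = _polish(xs, beta)
    scores = [x @ beta for x in xs]
    hum = empirical_hum(scores)
    shum = shum_objective(scores, max(h_final_rel * _pooled_sd(scores), 1e-9))
    # orient: positive (last) class scores higher on average
    lo_mean = (xs[0] @ beta).mean()
    hi_mean = (xs[-1] @ beta).mean()
    if hi_mean < lo_mean:
        beta = -beta
        scores = [x @ beta for x in xs]
        hum = empirical_hum(scores)
        shum = shum_objective(scores, max(h_final_rel * _pooled_sd(scores), 1e-9))

    cv = CombinationVector(
        markers=tuple(markers), coefficients=beta, center=center, scale=scale
    )
    return SHUMFit(beta=cv, shum=shum, hum=hum, classes=tuple(classes), config=config)
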