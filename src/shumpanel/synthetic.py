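"""Seeded generation of synthetic ELISA biomarker panel tables.

The generator emulates serum / extracellular-vesicle (EV) protein panels from
a two-cohort case-control design: platinum-sensitive (PS) and
platinum-resistant (PR) ovarian-cancer patients, optionally with a healthy
control group.  Marker concentrations are lognormal — Gaussian on the log
scale — which is the natural model when between-group differences are stated
as fold-changes and within-group noise as a coefficient of variation (CV).
For CV c the log-scale standard deviation is sqrt(ln(1 + c^2)).

Markers are correlated on the log scale through a user-supplied correlation
matrix.  A per-marker ``serum_attenuation`` factor in [0, 1] shrinks the
log-scale class effect when the assay matrix is whole serum instead of EVs,
emulating the empirical finding that EV-borne candidate proteins separate the
classes while the same proteins in whole serum do not.

Fold-changes can be calibrated to hit a target single-marker AUC through the
equal-variance binormal identity AUC = Phi(ln(fold) / (sigma_log * sqrt(2))).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

__all__ = [
    "MarkerSpec",
    "PanelDesign",
    "sd_log_from_cv",
    "calibrate_fold_from_auc",
    "binormal_auc",
    "generate_panel",
    "generate_paired_panels",
    "study_markers",
    "study_design",
    "DEFAULT_MARKER_AUCS",
]

#: Target single-marker AUCs (PR vs PS, EV matrix) used for the default
#: study-like panel.  CFH/TMEM205/CA125/HE4 are calibrated to the observed
#: discrimination of those assays; CD1B, FAS and mesothelin are set to modest
#: values consistent with "no significant single-marker difference" at n=44/44.
DEFAULT_MARKER_AUCS: dict[str, float] = {
    "CFH": 0.95,
    "TMEM205": 0.84,
    "CD1B": 0.60,
    "FAS": 0.55,
    "CA125": 0.53,
    "HE4": 0.55,
    "Mesothelin": 0.58,
}

#: Candidate EV markers whose class effect is attenuated in whole serum.
_CANDIDATE_MARKERS = frozenset({"CFH", "TMEM205", "CD1B", "FAS"})

_CLASSES = ("PS", "PR", "control")


def sd_log_from_cv(cv: float) -> float:
    """Log-scale standard deviation of a lognormal with coefficient of variation ``cv``."""
    if cv < 0:
        raise ValueError(f"cv must be >= 0, got {cv}")
    return math.sqrt(math.log1p(cv * cv))


def binormal_auc(fold_change: float, cv: float) -> float:
    """Single-marker AUC implied by the equal-variance binormal model on the log scale."""
    if fold_change <= 0:
        raise ValueError(f"fold_change must be > 0, got {fold_change}")
    s = sd_log_from_cv(cv)
    if s == 0:
        return 1.0 if fold_change > 1 else (0.0 if fold_change < 1 else 0.5)
    return float(ndtr(math.log(fold_change) / (s * math.sqrt(2.0))))


def calibrate_fold_from_auc(target_auc: float, cv: float) -> float:
    """Fold-change whose binormal single-marker AUC equals ``target_auc``.

    Inverts AUC = Phi(ln(fold) / (sigma_log * sqrt(2))) with
    sigma_log = sqrt(ln(1 + cv^2)); round-trips with :func:`generate_panel`
    at large n.
    """
    if not 0.0 < target_auc < 1.0:
        raise ValueError(f"target_auc must lie in (0, 1), got {target_auc}")
    return float(math.exp(ndtri(target_auc) * sd_log_from_cv(cv) * math.sqrt(2.0)))


@dataclass(frozen=True)
class MarkerSpec:
    """One biomarker's generative parameters.

    fold_change: PR mean / PS mean on the natural scale (EV matrix).
    cv: within-class coefficient of variation (SD/mean, natural scale).
    serum_attenuation: factor in [0, 1] multiplying the log-scale class
        effect when the assay matrix is whole serum.
    """

    name: str
    fold_change: float
    cv: float = 0.6
    serum_attenuation: float = 1.0

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError(f"{self.name}: fold_change must be > 0")
        if self.cv <= 0:
            raise ValueError(f"{self.name}: cv must be > 0")
        if not 0.0 <= self.serum_attenuation <= 1.0:
            raise ValueError(f"{self.name}: serum_attenuation must lie in [0, 1]")

    @property
    def sd_log(self) -> float:
        return sd_log_from_cv(self.cv)


@dataclass
class PanelDesign:
    """Full generative design of a panel table.

    correlation is the log-scale inter-marker correlation matrix (unit
    diagonal, positive definite).  n_per_class maps class labels from
    {PS, PR, control} to cohort sizes.
    """

    markers: list[MarkerSpec]
    n_per_class: dict[str, int]
    correlation: np.ndarray | None = None
    seed: int = 0
    baseline: float = 100.0  # PS geometric-mean concentration, arbitrary ELISA units

    def __post_init__(self) -> None:
        if not self.markers:
            raise ValueError("at least one marker required")
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise ValueError("duplicate marker names")
        for cls, n in self.n_per_class.items():
            if cls not in _CLASSES:
                raise ValueError(f"unknown class label {cls!r}; expected one of {_CLASSES}")
            if n < 2:
                raise ValueError(f"class {cls!r} needs n >= 2, got {n}")
        k = len(self.markers)
        if self.correlation is None:
            self.correlation = np.eye(k)
        self.correlation = np.asarray(self.correlation, dtype=float)
        if self.correlation.shape != (k, k):
            raise ValueError(f"correlation must be {k}x{k}")
        if not np.allclose(self.correlation, self.correlation.T):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.correlation), 1.0):
            raise ValueError("correlation matrix must have a unit diagonal")
        w = np.linalg.eigvalsh(self.correlation)
        if w[0] <= 0:
            raise ValueError(
                f"correlation matrix is not positive definite: smallest eigenvalue {w[0]:.6g}"
            )

    @property
    def marker_names(self) -> list[str]:
        return [m.name for m in self.markers]

    def to_json(self) -> str:
        return json.dumps(
            {
                "markers": [
                    {
                        "name": m.name,
                        "fold_change": m.fold_change,
                        "cv": m.cv,
                        "serum_attenuation": m.serum_attenuation,
                    }
                    for m in self.markers
                ],
                "n_per_class": self.n_per_class,
                "correlation": self.correlation.tolist(),
                "seed": self.seed,
                "baseline": self.baseline,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "PanelDesign":
        d = json.loads(text)
        return cls(
            markers=[MarkerSpec(**m) for m in d["markers"]],
            n_per_class={k: int(v) for k, v in d["n_per_class"].items()},
            correlation=np.asarray(d["correlation"], dtype=float)
            if d.get("correlation") is not None
            else None,
            seed=int(d.get("seed", 0)),
            baseline=float(d.get("baseline", 100.0)),
        )


def _log_means(design: PanelDesign, cls: str, matrix_label: str) -> np.ndarray:
    """Per-marker log-scale means for one class in one assay matrix."""
    mu0 = math.log(design.baseline)
    out = np.full(len(design.markers), mu0)
    if cls == "PR":
        for j, m in enumerate(design.markers):
            atten = m.serum_attenuation if matrix_label == "serum" else 1.0
            out[j] += atten * math.log(m.fold_change)
    # PS and control share the PS baseline distribution (fold 1 vs PS).
    return out


def _cov_log(design: PanelDesign) -> np.ndarray:
    sd = np.array([m.sd_log for m in design.markers])
    return design.correlation * np.outer(sd, sd)


def generate_panel(
    design: PanelDesign,
    matrix_label: str = "EV",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw one seeded panel table.

    Returns a DataFrame with columns ``sample_id, class_label, matrix_label``
    followed by one positive concentration column per marker.  Deterministic
    given ``design.seed`` (or an explicit ``rng``).
    """
    if matrix_label not in ("EV", "serum"):
        raise ValueError(f"matrix_label must be 'EV' or 'serum', got {matrix_label!r}")
    if rng is None:
        rng = np.random.default_rng(design.seed)
    cov = _cov_log(design)
    chol = np.linalg.cholesky(cov)
    frames = []
    for cls in _CLASSES:
        if cls not in design.n_per_class:
            continue
        n = design.n_per_class[cls]
        z = rng.standard_normal((n, len(design.markers)))
        logx = _log_means(design, cls, matrix_label) + z @ chol.T
        df = pd.DataFrame(np.exp(logx), columns=design.marker_names)
        df.insert(0, "matrix_label", matrix_label)
        df.insert(0, "class_label", cls)
        df.insert(0, "sample_id", [f"{matrix_label}-{cls}-{i:04d}" for i in range(n)])
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def generate_paired_panels(design: PanelDesign) -> tuple[pd.DataFrame, pd.DataFrame]:
    """EV and whole-serum panels for the *same* patients.

    Each patient's latent log-scale noise vector is shared between matrices,
    so the serum table differs from the EV table only through the attenuated
    class effect — the idealisation of assaying one serum draw two ways.
    Sample ids match across the two tables (prefix-free patient ids).
    """
    rng = np.random.default_rng(design.seed)
    cov = _cov_log(design)
    chol = np.linalg.cholesky(cov)
    ev_frames, serum_frames = [], []
    for cls in _CLASSES:
        if cls not in design.n_per_class:
            continue
        n = design.n_per_class[cls]
        z = rng.standard_normal((n, len(design.markers)))
        noise = z @ chol.T
        ids = [f"{cls}-{i:04d}" for i in range(n)]
        for label, frames in (("EV", ev_frames), ("serum", serum_frames)):
            logx = _log_means(design, cls, label) + noise
            df = pd.DataFrame(np.exp(logx), columns=design.marker_names)
            df.insert(0, "matrix_label", label)
            df.insert(0, "class_label", cls)
            df.insert(0, "sample_id", ids)
            frames.append(df)
    return pd.concat(ev_frames, ignore_index=True), pd.concat(serum_frames, ignore_index=True)


def study_markers(
    target_aucs: dict[str, float] | None = None,
    cv: float = 0.6,
    serum_attenuation: float = 0.2,
) -> list[MarkerSpec]:
    """Marker specs calibrated so each marker's binormal AUC hits its target.

    Candidate EV markers (CFH, TMEM205, CD1B, FAS) get the attenuated serum
    effect; established serum markers (CA125, HE4, mesothelin) behave the same
    in both matrices.
    """
    if target_aucs is None:
        target_aucs = DEFAULT_MARKER_AUCS
    specs = []
    for name, auc in target_aucs.items():
        specs.append(
            MarkerSpec(
                name=name,
                fold_change=calibrate_fold_from_auc(auc, cv),
                cv=cv,
                serum_attenuation=serum_attenuation if name in _CANDIDATE_MARKERS else 1.0,
            )
        )
    return specs


def study_design(
    markers: list[MarkerSpec] | None = None,
    n_per_class: dict[str, int] | None = None,
    rho: float = 0.1,
    seed: int = 0,
) -> PanelDesign:
    """The default study-like design: 44 PS + 44 PR, weak exchangeable
    inter-marker correlation (rho = 0.1), CV 60%, marker AUCs per
    :data:`DEFAULT_MARKER_AUCS`."""
    if markers is None:
        markers = study_markers()
    if n_per_class is None:
        n_per_class = {"PS": 44, "PR": 44}
    k = len(markers)
    corr = np.full((k, k), rho)
    np.fill_diagonal(corr, 1.0)
    return PanelDesign(markers=markers, n_per_class=n_per_class, correlation=corr, seed=seed)


def read_panel(path) -> pd.DataFrame:
    """Read a panel table from CSV (schema: sample_id,class_label,matrix_label,markers...)."""
    df = pd.read_csv(path)
    required = {"sample_id", "class_label", "matrix_label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"panel CSV missing columns: {sorted(missing)}")
    return df


def panel_markers(panel: pd.DataFrame) -> list[str]:
    """Marker columns of a panel table (everything after the three id columns)."""
    return [c for c in panel.columns if c not in ("sample_id", "class_label", "matrix_label")]
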