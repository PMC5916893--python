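"""Equilibrium binding-isotherm model for gel-shift (EMSA) titrations.

The unbound-band intensity of a labelled RNA or ssDNA ligand R titrated
with protein P follows the exact 1:1 equilibrium ("quadratic") isotherm

    FI = m - (m - b) * [ (R + P + Kd - sqrt((R + P + Kd)^2 - 4 R P)) / (2 R) ]

where m is the maximum intensity (no protein), b the basal intensity at
saturation, and the bracket is the bound fraction of ligand.  This module
evaluates the model and fits (Kd, m, b) to titration data by least
squares, fitting Kd on a log scale for stability across the nM-to-uM
affinity range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "BindingDataset",
    "BindingFitResult",
    "predict_unbound_intensity",
    "fit_binding",
    "kd_ratio",
    "average_kd",
    "read_titration_csv",
    "write_fit_json",
]


def predict_unbound_intensity(P, R: float, kd: float, m: float, b: float):
    """Unbound-band intensity at protein concentration P (scalar or array).

    All concentrations in nM; requires R > 0, kd >= 0, P >= 0, b <= m.
    The bound fraction always lies in [0, 1].
    """
    P = np.asarray(P, dtype=float)
    if R <= 0:
        raise ValueError("ligand concentration R must be positive")
    if kd < 0 or np.any(P < 0):
        raise ValueError("kd and P must be non-negative")
    if b > m:
        raise ValueError("basal intensity b cannot exceed maximum m")
    s = R + P + kd
    disc = s * s - 4.0 * R * P
    # the discriminant equals (R - P + kd)^2 + 4*kd*P >= 0; clip rounding dust
    disc = np.maximum(disc, 0.0)
    bound_frac = (s - np.sqrt(disc)) / (2.0 * R)
    bound_frac = np.clip(bound_frac, 0.0, 1.0)
    out = m - (m - b) * bound_frac
    return out if out.ndim else float(out)


@dataclass
class BindingDataset:
    """One titration series: fixed ligand R, varying protein P."""

    ligand_conc_nM: float
    protein_conc_nM: np.ndarray
    intensity: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.protein_conc_nM = np.asarray(self.protein_conc_nM, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ligand_conc_nM <= 0:
            raise ValueError("ligand concentration must be positive")
        if np.any(self.protein_conc_nM < 0):
            raise ValueError("protein concentrations must be non-negative")
        if len(np.unique(self.protein_conc_nM)) != self.protein_conc_nM.size:
            raise ValueError("protein concentrations must be distinct")
        if self.protein_conc_nM.size < 5:
            raise ValueError("need at least 5 titration points to fit")
        if self.protein_conc_nM.size != self.intensity.size:
            raise ValueError("P and FI must have equal length")


@dataclass
class BindingFitResult:
    kd_nM: float
    kd_se_nM: float
    m: float
    b: float
    rss: float
    converged: bool
    label: str = ""

    def to_dict(self) -> dict:
        return {
            "label": self.label, "kd_nM": self.kd_nM, "kd_se_nM": self.kd_se_nM,
            "m": self.m, "b": self.b, "rss": self.rss, "converged": self.converged,
        }


def _default_init(data: BindingDataset) -> tuple[float, float, float]:
    m0 = float(np.max(data.intensity))
    b0 = float(np.min(data.intensity))
    half = 0.5 * (m0 + b0)
    order = np.argsort(data.protein_conc_nM)
    P, FI = data.protein_conc_nM[order], data.intensity[order]
    idx = int(np.argmin(np.abs(FI - half)))
    kd0 = float(P[idx]) if P[idx] > 0 else float(np.median(P[P > 0]))
    return kd0, m0, b0


def fit_binding(data: BindingDataset, init=None) -> BindingFitResult:
    """Least-squares fit of (Kd, m, b) to one titration.

    Kd is fitted as log(Kd) to enforce positivity; b <= m is enforced by
    the parameterization b = m - delta^2.  The Kd standard error comes
    from the curvature of the fit (delta method on log Kd).  Degenerate
    data (constant intensity) is rejected; non-convergence is reported in
    the ``converged`` flag, never silently.
    """
    if np.ptp(data.intensity) == 0:
        raise ValueError("degenerate titration: constant intensity")
    kd0, m0, b0 = init if init is not None else _default_init(data)
    if kd0 <= 0:
        raise ValueError("initial kd must be positive")
    R = data.ligand_conc_nM
    P, FI = data.protein_conc_nM, data.intensity

    def residuals(x):
        log_kd, m, delta = x
        b = m - delta * delta
        return predict_unbound_intensity(P, R, math.exp(log_kd), m, b) - FI

    x0 = np.array([math.log(kd0), m0, math.sqrt(max(m0 - b0, 1e-12))])
    res = least_squares(residuals, x0, method="lm", max_nfev=20000)
    log_kd, m, delta = res.x
    kd = math.exp(log_kd)
    b = m - delta * delta
    rss = float(np.sum(res.fun ** 2))
    dof = max(P.size - 3, 1)
    kd_se = math.inf
    converged = bool(res.success)
    try:
        jtj = res.jac.T @ res.jac
        cov = np.linalg.inv(jtj) * (rss / dof)
        se_log_kd = math.sqrt(max(cov[0, 0], 0.0))
        kd_se = kd * se_log_kd
    except np.linalg.LinAlgError:
        converged = False
    if not math.isfinite(kd_se):
        kd_se = math.inf
    return BindingFitResult(kd, kd_se, float(m), float(b), rss, converged,
                            label=data.label)


def kd_ratio(a: BindingFitResult, b: BindingFitResult) -> tuple[float, float]:
    """Ratio a.kd / b.kd with first-order propagated standard error."""
    if not (a.converged and b.converged):
        raise ValueError("both fits must have converged")
    ratio = a.kd_nM / b.kd_nM
    rel = 0.0
    for f in (a, b):
        if math.isfinite(f.kd_se_nM):
            rel += (f.kd_se_nM / f.kd_nM) ** 2
    return ratio, ratio * math.sqrt(rel)


def average_kd(fits: list[BindingFitResult]) -> tuple[float, float]:
    """Mean and SD of Kd over replicate fits (day-to-day replicates)."""
    kds = np.array([f.kd_nM for f in fits if f.converged])
    if kds.size == 0:
        raise ValueError("no converged fits")
    sd = float(np.std(kds, ddof=1)) if kds.size > 1 else 0.0
    return float(np.mean(kds)), sd


def read_titration_csv(path, ligand_conc_nM: float | None = None,
                       label: str = "") -> BindingDataset:
    """Read a titration table with columns P_nM and FI.

    The ligand concentration may be given as a column R_nM (constant) or
    passed explicitly.
    """
    df = pd.read_csv(path)
    if "P_nM" not in df or "FI" not in df:
        raise ValueError(f"{path}: expected columns P_nM and FI")
    if ligand_conc_nM is None:
        if "R_nM" not in df:
            raise ValueError(f"{path}: no R_nM column and no ligand_conc_nM given")
        ligand_conc_nM = float(df["R_nM"].iloc[0])
    return BindingDataset(ligand_conc_nM, df["P_nM"].to_numpy(),
                          df["FI"].to_numpy(), label=label or str(path))


def write_fit_json(path, fits: list[BindingFitResult]) -> None:
    import json

    payload = [f.to_dict() for f in fits]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
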