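"""Synthetic data with planted ground truth.

Generates the two kinds of input the analysis pipeline consumes, without
any experimental data: (i) two-channel single-cell fluorescence
trajectories mimicking the 15-min / 300-min time-lapse protocol —
heterogeneous ON/OFF induction, stochastic onset times, a cel lag behind
cea, lognormal amplitude variation and additive measurement noise; and
(ii) EMSA titration series drawn from the equilibrium isotherm with
multiplicative intensity noise.  Every planted quantity is recorded so
recovery can be audited.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .binding import BindingDataset, predict_unbound_intensity
from .simulate import CellTrajectory, Ensemble

__all__ = [
    "TrajectoryRecipe",
    "TitrationRecipe",
    "GroundTruth",
    "generate_trajectories",
    "generate_titration",
]


@dataclass(frozen=True)
class TrajectoryRecipe:
    """Recipe for a planted-truth trajectory ensemble.

    The waveform per ON channel is a saturating ramp: zero until the
    planted onset, linear rise over ``rise_time_min`` to a lognormal
    amplitude, then plateau; additive Gaussian noise with SD equal to
    ``noise_sd`` times the cell's amplitude is applied on the sampling
    grid.  ``onset_offset_min``/``onset_mean_min`` parameterize the
    shifted-exponential cea onset distribution; the cel onset is the cea
    onset plus a normal planted delay.
    """

    n_cells: int = 200
    p_on_cea: float = 0.75
    p_on_cel_given_cea: float = 0.8
    onset_offset_min: float = 30.0
    onset_mean_min: float = 40.0        # mean of the exponential part
    delay_mean_min: float = 75.0
    delay_sd_min: float = 20.0
    amplitude_median: float = 1000.0
    amplitude_gsd: float = 1.5          # geometric SD of the lognormal
    rise_time_min: float = 15.0
    noise_sd: float = 0.05              # fraction of the cell's amplitude
    sample_interval_min: float = 15.0
    horizon_min: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_on_cea, self.p_on_cel_given_cea):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.horizon_min <= 0 or self.sample_interval_min <= 0:
            raise ValueError("horizon and sample interval must be positive")
        n = self.horizon_min / self.sample_interval_min
        if abs(n - round(n)) > 1e-9:
            raise ValueError("sample_interval_min must divide horizon_min")
        if self.amplitude_gsd < 1.0:
            raise ValueError("amplitude_gsd must be >= 1")


@dataclass
class GroundTruth:
    """Everything planted into a synthetic ensemble, for audit."""

    recipe: TrajectoryRecipe
    on_cea: np.ndarray
    on_cel: np.ndarray
    onset_cea_min: np.ndarray      # nan where OFF
    onset_cel_min: np.ndarray
    delay_min: np.ndarray
    amplitude_cea: np.ndarray
    amplitude_cel: np.ndarray

    def to_json(self, path) -> None:
        payload = {
            "recipe": self.recipe.__dict__,
            "on_cea": self.on_cea.astype(bool).tolist(),
            "on_cel": self.on_cel.astype(bool).tolist(),
            "onset_cea_min": self.onset_cea_min.tolist(),
            "onset_cel_min": self.onset_cel_min.tolist(),
            "delay_min": self.delay_min.tolist(),
            "amplitude_cea": self.amplitude_cea.tolist(),
            "amplitude_cel": self.amplitude_cel.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _ramp(times: np.ndarray, onset: float, rise: float, amp: float) -> np.ndarray:
    out = np.zeros_like(times)
    if rise <= 0:
        out[times >= onset] = amp
        return out
    frac = np.clip((times - onset) / rise, 0.0, 1.0)
    return amp * frac


def generate_trajectories(recipe: TrajectoryRecipe) -> tuple[Ensemble, GroundTruth]:
    """Deterministic-given-seed synthetic ensemble plus its ground truth."""
    rng = np.random.default_rng(recipe.seed)
    n = recipe.n_cells
    times = np.arange(0.0, recipe.horizon_min + 1e-9, recipe.sample_interval_min)

    on_cea = rng.random(n) < recipe.p_on_cea
    on_cel = on_cea & (rng.random(n) < recipe.p_on_cel_given_cea)
    onset_cea = np.where(
        on_cea,
        recipe.onset_offset_min + rng.exponential(recipe.onset_mean_min, n),
        np.nan,
    )
    delay = rng.normal(recipe.delay_mean_min, recipe.delay_sd_min, n)
    onset_cel = np.where(on_cel, onset_cea + delay, np.nan)
    delay = np.where(on_cel, delay, np.nan)
    sigma_log = np.log(recipe.amplitude_gsd)
    amp_cea = np.where(
        on_cea,
        recipe.amplitude_median * np.exp(rng.normal(0.0, sigma_log, n)), 0.0
    )
    amp_cel = np.where(
        on_cel,
        recipe.amplitude_median * np.exp(rng.normal(0.0, sigma_log, n)), 0.0
    )

    cells = []
    for i in range(n):
        cea = (
            _ramp(times, onset_cea[i], recipe.rise_time_min, amp_cea[i])
            if on_cea[i] else np.zeros_like(times)
        )
        cel = (
            _ramp(times, onset_cel[i], recipe.rise_time_min, amp_cel[i])
            if on_cel[i] else np.zeros_like(times)
        )
        if recipe.noise_sd > 0:
            if on_cea[i]:
                cea = cea + rng.normal(0.0, recipe.noise_sd * amp_cea[i], times.size)
            if on_cel[i]:
                cel = cel + rng.normal(0.0, recipe.noise_sd * amp_cel[i], times.size)
        cells.append(
            CellTrajectory(
                cell_id=i, times=times,
                cea_signal=np.maximum(cea, 0.0),
                cel_signal=np.maximum(cel, 0.0),
            )
        )
    ens = Ensemble(cells=cells, strain_name="synthetic", seed=recipe.seed)
    truth = GroundTruth(
        recipe=recipe, on_cea=on_cea, on_cel=on_cel,
        onset_cea_min=onset_cea, onset_cel_min=onset_cel, delay_min=delay,
        amplitude_cea=amp_cea, amplitude_cel=amp_cel,
    )
    return ens, truth


@dataclass(frozen=True)
class TitrationRecipe:
    """Serial-dilution EMSA titration drawn from the printed isotherm.

    Defaults mirror the RNA gel-shift protocol: 2-fold dilutions from a
    6600 nM protein stock, 14 points, with multiplicative Gaussian
    intensity noise (band intensities scale with exposure).
    """

    kd_true_nM: float = 22.0
    m_true: float = 1000.0
    b_true: float = 100.0
    R_nM: float = 10.0
    stock_nM: float = 6600.0
    dilution_fold: float = 2.0
    n_points: int = 14
    noise_sd_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.kd_true_nM, self.R_nM, self.stock_nM) <= 0:
            raise ValueError("concentrations must be positive")
        if self.n_points < 5:
            raise ValueError("need at least 5 points")
        if self.dilution_fold <= 1:
            raise ValueError("dilution fold must exceed 1")
        if self.b_true > self.m_true:
            raise ValueError("b_true cannot exceed m_true")


def generate_titration(recipe: TitrationRecipe) -> BindingDataset:
    """Titration points on the serial-dilution grid, noise applied multiplicatively."""
    rng = np.random.default_rng(recipe.seed)
    P = recipe.stock_nM / recipe.dilution_fold ** np.arange(recipe.n_points)
    fi = predict_unbound_intensity(
        P, recipe.R_nM, recipe.kd_true_nM, recipe.m_true, recipe.b_true
    )
    if recipe.noise_sd_fraction > 0:
        fi = fi * (1.0 + rng.normal(0.0, recipe.noise_sd_fraction, P.size))
    return BindingDataset(
        ligand_conc_nM=recipe.R_nM, protein_conc_nM=P, intensity=fi,
        label=f"synthetic_kd{recipe.kd_true_nM:g}",
    )
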