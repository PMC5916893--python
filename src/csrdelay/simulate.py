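"""Exact stochastic simulation of the CsrA titration network.

Single cells are propagated with the direct Gillespie method over the
imaging window (300 min, sampled every 15 min, mirroring the time-lapse
protocol), using a self-contained xorshift64* random stream per cell so
that a (network, spec, seed) triple is reproducible bit for bit across
platforms and thread counts.  Per-cell seeds of an ensemble are derived as
``spec.seed + cell_index``.

Lysis is absorbing: once the Cel protein count reaches the lysis threshold
the cell is marked and its signals are frozen for the remaining samples.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit

from .network import I_CSRA, I_PCEA, I_PCEL, ReactionNetwork

__all__ = [
    "SimulationSpec",
    "CellTrajectory",
    "Ensemble",
    "simulate_cell",
    "simulate_ensemble",
    "stationary_free_csra",
    "write_ensemble_csv",
    "read_ensemble_csv",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Sampling protocol and ensemble size."""

    horizon_min: float = 300.0
    sample_interval_min: float = 15.0
    n_cells: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.horizon_min <= 0:
            raise ValueError("horizon_min must be positive")
        n = self.horizon_min / self.sample_interval_min
        if abs(n - round(n)) > 1e-9:
            raise ValueError("sample_interval_min must divide horizon_min")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")

    @property
    def times(self) -> np.ndarray:
        n = int(round(self.horizon_min / self.sample_interval_min))
        return np.linspace(0.0, self.horizon_min, n + 1)


@dataclass
class CellTrajectory:
    """Two-channel sampled time series of one simulated (or synthetic) cell."""

    cell_id: int
    times: np.ndarray
    cea_signal: np.ndarray
    cel_signal: np.ndarray
    lysed_at: float | None = None
    rng_seed: int | None = None
    species_counts: np.ndarray | None = None  # (n_times, n_species) if recorded

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.asarray(self.cea_signal) < 0) or np.any(
            np.asarray(self.cel_signal) < 0
        ):
            raise ValueError("signals must be non-negative")


@dataclass
class Ensemble:
    """Cells sharing one time grid, plus provenance for reproducibility."""

    cells: list[CellTrajectory]
    strain_name: str = ""
    parameter_hash: str = ""
    seed: int | None = None
    lysis_on_cel: bool = False

    def __post_init__(self) -> None:
        if self.cells:
            t0 = self.cells[0].times
            for c in self.cells[1:]:
                if not np.array_equal(c.times, t0):
                    raise ValueError("all trajectories must share one time grid")

    @property
    def times(self) -> np.ndarray:
        return self.cells[0].times

    def __len__(self) -> int:
        return len(self.cells)


# ---------------------------------------------------------------------------
# SSA kernel
# ---------------------------------------------------------------------------

_U64 = np.uint64
_INV_2_53 = 1.0 / 9007199254740992.0


@njit(cache=True)
def _xorshift_next(state):
    s = state
    s ^= s >> _U64(12)
    s ^= s << _U64(25)
    s ^= s >> _U64(27)
    return s


@njit(cache=True)
def _uniform(state):
    s = _xorshift_next(state)
    x = (s * _U64(0x2545F4914F6CDD1D)) >> _U64(11)
    u = float(x) * _INV_2_53
    if u <= 0.0:
        u = _INV_2_53
    return s, u


@njit(cache=True)
def _ssa_core(counts, rates, re1, re2, stoich, gated, onset, t_grid,
              lysis_threshold, seed):
    """Direct-method SSA with an induction gate and optional absorbing lysis.

    Returns (samples, lysed_at) with lysed_at = -1.0 when no lysis occurred.
    """
    n_r = rates.shape[0]
    n_t = t_grid.shape[0]
    n_s = counts.shape[0]
    samples = np.zeros((n_t, n_s), dtype=np.int64)
    props = np.zeros(n_r, dtype=np.float64)
    horizon = t_grid[n_t - 1]

    # seed mixing (splitmix-style) so adjacent cell seeds give distinct streams
    z = _U64(seed) + _U64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> _U64(27))) * _U64(0x94D049BB133111EB)
    state = z ^ (z >> _U64(31))
    if state == _U64(0):
        state = _U64(0x853C49E6748FEA9B)

    t = 0.0
    si = 0
    induced = onset <= 0.0
    lysed_at = -1.0
    while True:
        a0 = 0.0
        for j in range(n_r):
            if gated[j] and not induced:
                props[j] = 0.0
                continue
            a = rates[j]
            if re1[j] >= 0:
                a *= counts[re1[j]]
            if re2[j] >= 0:
                a *= counts[re2[j]]
            props[j] = a
            a0 += a
        if a0 <= 0.0:
            if not induced and onset < horizon:
                # advance silently to the induction gate
                while si < n_t and t_grid[si] < onset:
                    for k in range(n_s):
                        samples[si, k] = counts[k]
                    si += 1
                t = onset
                induced = True
                continue
            break
        state, u1 = _uniform(state)
        tau = -math.log(u1) / a0
        t_next = t + tau
        if not induced and t_next > onset:
            while si < n_t and t_grid[si] < onset:
                for k in range(n_s):
                    samples[si, k] = counts[k]
                si += 1
            t = onset
            induced = True
            continue
        # record grid points passed while the state was constant
        while si < n_t and t_grid[si] < t_next:
            for k in range(n_s):
                samples[si, k] = counts[k]
            si += 1
        if t_next > horizon or si >= n_t:
            break
        t = t_next
        # choose reaction
        state, u2 = _uniform(state)
        target = u2 * a0
        acc = 0.0
        rj = n_r - 1
        for j in range(n_r):
            acc += props[j]
            if acc >= target:
                rj = j
                break
        for k in range(n_s):
            counts[k] += stoich[rj, k]
            if counts[k] < 0:
                # negative copy number signals an inconsistent propensity
                raise RuntimeError("negative species count during SSA")
        if lysis_threshold >= 0 and counts[I_PCEL] >= lysis_threshold:
            lysed_at = t
            break
    # remaining samples: frozen (lysis) or final (exhausted) state
    while si < n_t:
        for k in range(n_s):
            samples[si, k] = counts[k]
        si += 1
    return samples, lysed_at


@njit(cache=True)
def _time_average_core(counts, rates, re1, re2, stoich, horizon, burnin,
                       species_idx, seed):
    """Time-weighted average of one species over [burnin, horizon]."""
    n_r = rates.shape[0]
    n_s = counts.shape[0]
    z = _U64(seed) + _U64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> _U64(27))) * _U64(0x94D049BB133111EB)
    state = z ^ (z >> _U64(31))
    if state == _U64(0):
        state = _U64(0x853C49E6748FEA9B)
    t = 0.0
    acc = 0.0
    props = np.zeros(n_r, dtype=np.float64)
    while t < horizon:
        a0 = 0.0
        for j in range(n_r):
            a = rates[j]
            if re1[j] >= 0:
                a *= counts[re1[j]]
            if re2[j] >= 0:
                a *= counts[re2[j]]
            props[j] = a
            a0 += a
        if a0 <= 0.0:
            t_next = horizon
        else:
            state, u1 = _uniform(state)
            t_next = t - math.log(u1) / a0
        lo = max(t, burnin)
        hi = min(t_next, horizon)
        if hi > lo:
            acc += counts[species_idx] * (hi - lo)
        if t_next >= horizon or a0 <= 0.0:
            break
        t = t_next
        state, u2 = _uniform(state)
        target = u2 * a0
        s = 0.0
        rj = n_r - 1
        for j in range(n_r):
            s += props[j]
            if s >= target:
                rj = j
                break
        for k in range(n_s):
            counts[k] += stoich[rj, k]
    return acc / (horizon - burnin)


# ---------------------------------------------------------------------------
# public simulation API
# ---------------------------------------------------------------------------

def _parameter_hash(net: ReactionNetwork) -> str:
    payload = json.dumps(
        {
            "strain": net.strain.__dict__,
            "params": net.params.__dict__,
            "reactions": [(r.name, r.rate, r.reactants, r.stoich, r.gated)
                          for r in net.reactions],
        },
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def simulate_cell(net: ReactionNetwork, spec: SimulationSpec, seed: int) -> CellTrajectory:
    """Simulate one cell exactly; identical inputs give identical output."""
    rng = np.random.default_rng(seed)
    cell = net.realize_cell(rng)
    rates_base, re1, re2, stoich, gated = net.to_arrays()
    lysis = net.params.lysis_threshold if net.strain.lysis_on_cel else -1
    t_grid = spec.times
    samples, lysed_at = _ssa_core(
        cell.initial_counts.copy(), cell.rates, re1, re2, stoich, gated,
        cell.onset_min, t_grid, lysis, seed & 0x7FFFFFFFFFFFFFFF,
    )
    return CellTrajectory(
        cell_id=seed,
        times=t_grid,
        cea_signal=samples[:, I_PCEA].astype(float),
        cel_signal=samples[:, I_PCEL].astype(float),
        lysed_at=None if lysed_at < 0 else float(lysed_at),
        rng_seed=seed,
        species_counts=samples,
    )


def simulate_ensemble(net: ReactionNetwork, spec: SimulationSpec) -> Ensemble:
    """n_cells independent cells; per-cell seed = spec.seed + cell index."""
    cells = []
    for i in range(spec.n_cells):
        traj = simulate_cell(net, spec, spec.seed + i)
        traj.cell_id = i
        cells.append(traj)
    return Ensemble(
        cells=cells,
        strain_name=net.strain.name,
        parameter_hash=_parameter_hash(net),
        seed=spec.seed,
        lysis_on_cel=net.strain.lysis_on_cel,
    )


def stationary_free_csra(net: ReactionNetwork, spec: SimulationSpec,
                         burnin_fraction: float = 0.2) -> float:
    """Long-run time average of free CsrA for a binding-only network.

    Rejects networks containing reactions that change any molecule total
    (production or decay), since those admit no binding-only stationary
    state.  Compare against :func:`csrdelay.network.free_csra_equilibrium`.
    """
    for r in net.reactions:
        if len(r.reactants) == 0:
            raise ValueError(
                f"reaction {r.name!r} is a production source; "
                "no binding-only stationary state exists"
            )
        if all(d <= 0 for _, d in r.stoich):
            raise ValueError(
                f"reaction {r.name!r} destroys molecules; "
                "no binding-only stationary state exists"
            )
    init = getattr(net, "binding_only_init", None)
    if init is None:
        raise ValueError("network lacks a binding-only initial state")
    rates, re1, re2, stoich, _ = net.to_arrays()
    return float(
        _time_average_core(
            init.copy().astype(np.int64), rates, re1, re2, stoich,
            float(spec.horizon_min), burnin_fraction * float(spec.horizon_min),
            I_CSRA, (spec.seed or 0) & 0x7FFFFFFFFFFFFFFF,
        )
    )


# ---------------------------------------------------------------------------
# tidy CSV + provenance sidecar
# ---------------------------------------------------------------------------

def write_ensemble_csv(ens: Ensemble, csv_path, sidecar_path=None) -> None:
    rows = []
    for c in ens.cells:
        for k, t in enumerate(c.times):
            rows.append(
                (c.cell_id, float(t), float(c.cea_signal[k]),
                 float(c.cel_signal[k]),
                 bool(c.lysed_at is not None and t >= c.lysed_at))
            )
    df = pd.DataFrame(rows, columns=["cell_id", "time_min", "cea", "cel", "lysed"])
    df.to_csv(csv_path, index=False)
    sidecar = Path(sidecar_path) if sidecar_path else Path(csv_path).with_suffix(".json")
    meta = {
        "strain_name": ens.strain_name,
        "parameter_hash": ens.parameter_hash,
        "seed": ens.seed,
        "lysis_on_cel": ens.lysis_on_cel,
        "lysed_at": {str(c.cell_id): c.lysed_at for c in ens.cells
                     if c.lysed_at is not None},
    }
    sidecar.write_text(json.dumps(meta, indent=1))


def read_ensemble_csv(csv_path, sidecar_path=None) -> Ensemble:
    df = pd.read_csv(csv_path)
    sidecar = Path(sidecar_path) if sidecar_path else Path(csv_path).with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    lysed_at = {int(k): v for k, v in meta.get("lysed_at", {}).items()}
    cells = []
    for cid, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("time_min")
        cells.append(
            CellTrajectory(
                cell_id=int(cid),
                times=grp["time_min"].to_numpy(float),
                cea_signal=grp["cea"].to_numpy(float),
                cel_signal=grp["cel"].to_numpy(float),
                lysed_at=lysed_at.get(int(cid)),
            )
        )
    return Ensemble(
        cells=cells,
        strain_name=meta.get("strain_name", ""),
        parameter_hash=meta.get("parameter_hash", ""),
        seed=meta.get("seed"),
        lysis_on_cel=bool(meta.get("lysis_on_cel", False)),
    )
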