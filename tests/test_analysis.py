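"""Onset calling and delay statistics."""

import numpy as np
import pytest

from csrdelay.analysis import (
    DEFAULT_THRESHOLD,
    call_onset,
    delay_curve_vs_copy_number,
    summarize,
    suggest_threshold,
)
from csrdelay.network import RateParameters
from csrdelay.simulate import CellTrajectory, Ensemble, SimulationSpec
from csrdelay.synthetic import TrajectoryRecipe, generate_trajectories

GRID = np.arange(0.0, 301.0, 15.0)


def _cell(cell_id, onset_cea=None, onset_cel=None, amp=100.0, lysed_at=None):
    """Step-function cell: channel jumps to `amp` at its onset."""
    cea = np.where(GRID >= onset_cea, amp, 0.0) if onset_cea is not None else np.zeros_like(GRID)
    cel = np.where(GRID >= onset_cel, amp, 0.0) if onset_cel is not None else np.zeros_like(GRID)
    return CellTrajectory(cell_id=cell_id, times=GRID, cea_signal=cea,
                          cel_signal=cel, lysed_at=lysed_at)


class TestCallOnset:
    def test_silent_cell_is_off(self):
        call = call_onset(_cell(0), "cea", 10.0)
        assert not call.is_on and call.t_on_min is None

    def test_first_strict_crossing(self):
        traj = CellTrajectory(
            cell_id=0, times=np.array([0.0, 15.0, 30.0, 45.0]),
            cea_signal=np.array([0.0, 5.0, 12.0, 30.0]),
            cel_signal=np.zeros(4),
        )
        assert call_onset(traj, "cea", 10.0).t_on_min == 30.0

    def test_crossing_at_final_sample_is_the_horizon(self):
        traj = CellTrajectory(
            cell_id=0, times=np.array([0.0, 15.0, 30.0]),
            cea_signal=np.array([0.0, 0.0, 50.0]),
            cel_signal=np.zeros(3),
        )
        assert call_onset(traj, "cea", 10.0).t_on_min == 30.0

    def test_threshold_is_strict(self):
        traj = CellTrajectory(
            cell_id=0, times=np.array([0.0, 15.0]),
            cea_signal=np.array([10.0, 10.0]), cel_signal=np.zeros(2),
        )
        assert not call_onset(traj, "cea", 10.0).is_on

    def test_unknown_channel(self):
        with pytest.raises(ValueError, match="channel"):
            call_onset(_cell(0), "yfp", 10.0)


class TestSummarize:
    def test_mean_delay_arithmetic(self):
        ens = Ensemble(cells=[
            _cell(0, onset_cea=30.0, onset_cel=90.0),
            _cell(1, onset_cea=45.0, onset_cel=120.0),
        ])
        stats = summarize(ens, 10.0, 10.0)
        assert stats.n_both_on == 2
        assert stats.mean_delay_min == pytest.approx(67.5)
        # SEM = sd / sqrt(n_both_on)
        assert stats.sem_min == pytest.approx(np.std([60.0, 75.0], ddof=1) / np.sqrt(2))

    def test_identical_channels_give_zero_delay(self):
        ens = Ensemble(cells=[
            _cell(i, onset_cea=t, onset_cel=t) for i, t in enumerate([30.0, 60.0])
        ])
        assert summarize(ens, 10.0, 10.0).mean_delay_min == 0.0

    def test_negative_delays_enter_the_plain_mean(self):
        ens = Ensemble(cells=[
            _cell(0, onset_cea=60.0, onset_cel=30.0),
            _cell(1, onset_cea=30.0, onset_cel=90.0),
        ])
        stats = summarize(ens, 10.0, 10.0)
        assert stats.mean_delay_min == pytest.approx((-30.0 + 60.0) / 2)
        assert stats.n_negative_delays == 1

    def test_frac_not_lysing_counts_cells_without_lysis(self):
        cells = [_cell(i, onset_cea=30.0, onset_cel=60.0, lysed_at=75.0)
                 for i in range(6)]
        cells += [_cell(6 + i, onset_cea=30.0) for i in range(3)]
        ens = Ensemble(cells=cells, lysis_on_cel=True)
        stats = summarize(ens, 10.0, 10.0)
        assert stats.frac_not_lysing == pytest.approx(1.0 / 3.0)

    def test_no_both_on_cells_flagged_not_nan(self):
        ens = Ensemble(cells=[_cell(0, onset_cea=30.0), _cell(1)])
        stats = summarize(ens, 10.0, 10.0)
        assert stats.n_both_on == 0
        assert stats.mean_delay_min is None
        assert stats.n_censored == 1
        assert stats.mean_delay_lower_bound_min == pytest.approx(300.0 - 30.0)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            summarize(Ensemble(cells=[]), 10.0, 10.0)

    def test_permutation_invariance(self, small_s_rep1_ensemble):
        ens = small_s_rep1_ensemble
        rng = np.random.default_rng(0)
        shuffled = Ensemble(
            cells=[ens.cells[i] for i in rng.permutation(len(ens))],
            strain_name=ens.strain_name, lysis_on_cel=ens.lysis_on_cel,
        )
        a = summarize(ens)
        b = summarize(shuffled)
        assert a.mean_delay_min == pytest.approx(b.mean_delay_min)
        assert a.pct_on_cel == b.pct_on_cel
        assert a.n_both_on == b.n_both_on

    def test_raising_cel_threshold_never_shortens_the_delay(self, small_s_rep1_ensemble):
        prev = -np.inf
        for thr in (20.0, 40.0, 80.0):
            stats = summarize(small_s_rep1_ensemble, DEFAULT_THRESHOLD, thr)
            if stats.mean_delay_min is None:
                break
            assert stats.mean_delay_min >= prev - 1e-9
            prev = stats.mean_delay_min

    def test_fi_max_only_over_on_cells(self):
        ens = Ensemble(cells=[
            _cell(0, onset_cea=30.0, amp=100.0),
            _cell(1),  # OFF cell must not dilute FI_max
        ])
        stats = summarize(ens, 10.0, 10.0)
        assert stats.fi_max_cea == pytest.approx(100.0)
        assert stats.pct_on_cea == 0.5


class TestPlantedOnsetRecovery:
    def test_low_noise_recovery_within_one_frame(self):
        recipe = TrajectoryRecipe(n_cells=80, p_on_cea=1.0, p_on_cel_given_cea=1.0,
                                  noise_sd=0.05, amplitude_gsd=1.0, seed=5)
        ens, truth = generate_trajectories(recipe)
        interval = recipe.sample_interval_min
        for i, cell in enumerate(ens.cells):
            call = call_onset(cell, "cea", 0.2 * truth.amplitude_cea[i])
            assert call.is_on
            planted_grid = np.ceil(truth.onset_cea_min[i] / interval) * interval
            assert abs(call.t_on_min - planted_grid) <= interval


class TestDelayCurve:
    def test_copy_number_and_ssdna_orderings(self, params):
        spec = SimulationSpec(n_cells=40, seed=21)
        s_curve = delay_curve_vs_copy_number(params, [13, 55], ssdna=False, spec=spec)
        assert list(s_curve["copy_number"]) == [13, 55]
        # 13 copies: essentially nobody expresses cel, the delay is censored-long
        lb13 = s_curve.loc[s_curve.copy_number == 13, "mean_delay_lower_bound_min"].item()
        d55 = s_curve.loc[s_curve.copy_number == 55, "mean_delay_min"].item()
        assert lb13 > d55
        c_curve = delay_curve_vs_copy_number(params, [55], ssdna=True, spec=spec)
        assert c_curve["mean_delay_min"].item() < d55

    def test_single_copy_cannot_release(self, params):
        spec = SimulationSpec(n_cells=25, seed=8)
        curve = delay_curve_vs_copy_number(params, [1], ssdna=False, spec=spec)
        assert curve["frac_not_lysing"].item() > 0.95

    def test_empty_copy_numbers_rejected(self, params):
        with pytest.raises(ValueError):
            delay_curve_vs_copy_number(
                params, [], ssdna=False, spec=SimulationSpec(n_cells=1, seed=0)
            )


class TestSuggestThreshold:
    def test_noise_floor_guard(self, small_s_rep1_ensemble):
        # noise-free simulated counts have a zero baseline: the floor applies
        assert suggest_threshold(small_s_rep1_ensemble, "cea") == 1.0

    def test_scales_with_baseline(self):
        rng = np.random.default_rng(0)
        cells = []
        for i in range(30):
            base = np.abs(rng.normal(0.0, 10.0, GRID.size))
            cells.append(CellTrajectory(cell_id=i, times=GRID,
                                        cea_signal=base, cel_signal=base))
        ens = Ensemble(cells=cells)
        thr = suggest_threshold(ens, "cea")
        p95 = np.percentile([c.cea_signal[0] for c in cells], 95)
        assert thr == pytest.approx(5.0 * p95)
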