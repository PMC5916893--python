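"""Equilibrium isotherm evaluation and Kd fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csrdelay.binding import (
    BindingDataset,
    average_kd,
    fit_binding,
    kd_ratio,
    predict_unbound_intensity,
)
from csrdelay.synthetic import TitrationRecipe, generate_titration


def _quadratic_oracle(P, R, kd):
    """Bound ligand fraction from the raw equilibrium quadratic.

    [RP]^2 - (R + P + kd) [RP] + R P = 0, physical root [RP] <= min(R, P).
    """
    roots = np.roots([1.0, -(R + P + kd), R * P])
    phys = [r.real for r in roots if abs(r.imag) < 1e-9 and -1e-9 <= r.real <= min(R, P) + 1e-9]
    assert phys, "no physical root"
    return min(phys) / R


class TestPredict:
    def test_no_protein_gives_maximum_intensity(self):
        assert predict_unbound_intensity(0.0, 10.0, 22.0, 1000.0, 100.0) == 1000.0

    def test_infinite_affinity_saturates_to_basal(self):
        fi = predict_unbound_intensity(50.0, 10.0, 0.0, 1000.0, 100.0)
        assert fi == pytest.approx(100.0)

    def test_against_independent_quadratic_root(self):
        P, R, kd, m, b = 22.0, 10.0, 22.0, 1000.0, 100.0
        frac = _quadratic_oracle(P, R, kd)
        expected = m - (m - b) * frac
        assert expected == pytest.approx(600.49, abs=0.01)
        assert predict_unbound_intensity(P, R, kd, m, b) == pytest.approx(expected, rel=1e-12)

    def test_rejects_zero_ligand(self):
        with pytest.raises(ValueError):
            predict_unbound_intensity(1.0, 0.0, 22.0, 1.0, 0.0)

    def test_rejects_basal_above_maximum(self):
        with pytest.raises(ValueError):
            predict_unbound_intensity(1.0, 10.0, 22.0, 100.0, 200.0)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        R=st.floats(0.1, 1e3),
        kd=st.floats(0.0, 1e4),
        p1=st.floats(0.0, 1e5),
        dp=st.floats(0.0, 1e4),
        dk=st.floats(0.0, 1e4),
    )
    def test_monotonic_and_bounded(self, R, kd, p1, dp, dk):
        m, b = 1000.0, 50.0
        f1 = predict_unbound_intensity(p1, R, kd, m, b)
        f2 = predict_unbound_intensity(p1 + dp, R, kd, m, b)
        f3 = predict_unbound_intensity(p1, R, kd + dk, m, b)
        assert f2 <= f1 + 1e-6          # non-increasing in P
        assert f3 + 1e-6 >= f1          # non-decreasing in kd
        assert b - 1e-9 <= f1 <= m + 1e-9


def _grid_search_kd(data, n_grid=2048):
    """Independent oracle: profile (m, b) by linear least squares on a log-kd
    grid, refined once around the best point."""
    def rss_for(kd):
        g = (data.ligand_conc_nM + data.protein_conc_nM + kd
             - np.sqrt((data.ligand_conc_nM + data.protein_conc_nM + kd) ** 2
                       - 4 * data.ligand_conc_nM * data.protein_conc_nM)) / (
            2 * data.ligand_conc_nM)
        # FI = m (1 - g) + b g is linear in (m, b)
        A = np.column_stack([1.0 - g, g])
        coef, *_ = np.linalg.lstsq(A, data.intensity, rcond=None)
        resid = data.intensity - A @ coef
        return float(resid @ resid)

    lo, hi = math.log(1e-3), math.log(1e6)
    for _ in range(2):
        grid = np.exp(np.linspace(lo, hi, n_grid))
        rss = np.array([rss_for(k) for k in grid])
        i = int(np.argmin(rss))
        lo = math.log(grid[max(i - 1, 0)])
        hi = math.log(grid[min(i + 1, n_grid - 1)])
    return float(np.exp(0.5 * (lo + hi)))


class TestFit:
    @pytest.mark.parametrize(
        "kd_true,stock,R",
        [(22.0, 6600.0, 10.0), (991.0, 33300.0, 50.0)],
    )
    def test_noise_free_recovery_to_four_significant_figures(self, kd_true, stock, R):
        data = generate_titration(TitrationRecipe(
            kd_true_nM=kd_true, stock_nM=stock, R_nM=R, noise_sd_fraction=0.0,
        ))
        fit = fit_binding(data)
        assert fit.converged
        assert fit.kd_nM == pytest.approx(kd_true, rel=5e-4)
        assert fit.m == pytest.approx(1000.0, rel=1e-3)
        assert fit.b == pytest.approx(100.0, rel=1e-2)

    def test_monte_carlo_recovery_under_two_percent_noise(self):
        errors = []
        for rep in range(200):
            data = generate_titration(TitrationRecipe(
                kd_true_nM=22.0, noise_sd_fraction=0.02, seed=1000 + rep,
            ))
            fit = fit_binding(data)
            if fit.converged:
                errors.append(abs(fit.kd_nM - 22.0) / 22.0)
        assert len(errors) > 180
        assert np.median(errors) < 0.15

    def test_agrees_with_grid_search_oracle(self):
        data = generate_titration(TitrationRecipe(
            kd_true_nM=22.0, noise_sd_fraction=0.02, seed=77,
        ))
        fit = fit_binding(data)
        oracle = _grid_search_kd(data)
        # within the (refined) grid resolution
        assert fit.kd_nM == pytest.approx(oracle, rel=0.02)

    def test_point_order_invariance(self):
        data = generate_titration(TitrationRecipe(noise_sd_fraction=0.02, seed=3))
        rng = np.random.default_rng(0)
        perm = rng.permutation(data.protein_conc_nM.size)
        shuffled = BindingDataset(
            data.ligand_conc_nM, data.protein_conc_nM[perm], data.intensity[perm]
        )
        assert fit_binding(data).kd_nM == pytest.approx(
            fit_binding(shuffled).kd_nM, rel=1e-6
        )

    def test_intensity_rescaling_leaves_kd_invariant(self):
        data = generate_titration(TitrationRecipe(noise_sd_fraction=0.02, seed=4))
        scaled = BindingDataset(
            data.ligand_conc_nM, data.protein_conc_nM, 3.7 * data.intensity
        )
        fa, fb = fit_binding(data), fit_binding(scaled)
        assert fb.kd_nM == pytest.approx(fa.kd_nM, rel=1e-5)
        assert fb.m == pytest.approx(3.7 * fa.m, rel=1e-5)
        assert fb.b == pytest.approx(3.7 * fa.b, rel=1e-3)

    def test_degenerate_constant_intensity_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_binding(BindingDataset(10.0, np.arange(1.0, 8.0), np.full(7, 5.0)))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="5"):
            BindingDataset(10.0, np.array([1.0, 2.0, 4.0]), np.array([3.0, 2.0, 1.0]))


class TestKdRatio:
    def _fit(self, kd, stock, R, seed=0):
        return fit_binding(generate_titration(TitrationRecipe(
            kd_true_nM=kd, stock_nM=stock, R_nM=R, noise_sd_fraction=0.0, seed=seed,
        )))

    def test_ssdna_to_rna_ratio_is_45(self):
        rna = self._fit(22.0, 6600.0, 10.0)
        ssdna = self._fit(991.0, 33300.0, 50.0)
        ratio, se = kd_ratio(ssdna, rna)
        assert ratio == pytest.approx(991.0 / 22.0, rel=1e-3)
        assert se >= 0.0

    def test_identical_fits_give_unity(self):
        f = self._fit(22.0, 6600.0, 10.0)
        ratio, _ = kd_ratio(f, f)
        assert ratio == pytest.approx(1.0)

    def test_reciprocal_product_is_one(self):
        a = self._fit(22.0, 6600.0, 10.0)
        b = self._fit(991.0, 33300.0, 50.0)
        r1, _ = kd_ratio(a, b)
        r2, _ = kd_ratio(b, a)
        assert r1 * r2 == pytest.approx(1.0, rel=1e-12)

    def test_average_kd_over_replicates(self):
        fits = [
            fit_binding(generate_titration(TitrationRecipe(
                kd_true_nM=22.0, noise_sd_fraction=0.02, seed=s,
            )))
            for s in range(3)
        ]
        mean, sd = average_kd(fits)
        assert mean == pytest.approx(22.0, rel=0.2)
        assert sd >= 0.0
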