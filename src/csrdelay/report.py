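"""Headline numbers of the model: strain delays, lysis fractions, Kd fits.

One entry point recomputes, from scratch, the quantities the model is
judged by: the S_REP1 mean cea-cel delay (the calibration anchor), the
C_REP1 copy-number cross-prediction (ssDNA disabled), the wild-type delay
and its dispersion with ssDNA present, the lysed fractions with and
without ssDNA, and the RNA/ssDNA dissociation constants recovered from
synthetic gel-shift titrations.
"""

from __future__ import annotations

import numpy as np

from .analysis import DEFAULT_THRESHOLD, summarize
from .binding import fit_binding, kd_ratio
from .network import RateParameters, StrainConfig, build_network, strain_presets
from .simulate import Ensemble, SimulationSpec, simulate_ensemble
from .synthetic import TitrationRecipe, generate_titration

__all__ = ["headline_numbers"]


def _delay_stats(strain: StrainConfig, params: RateParameters, n_cells: int,
                 seed: int):
    net = build_network(strain, params)
    spec = SimulationSpec(n_cells=n_cells, seed=seed)
    ens = simulate_ensemble(net, spec)
    return ens, summarize(ens, DEFAULT_THRESHOLD, DEFAULT_THRESHOLD)


def headline_numbers(seed: int = 1, n_cells: int = 500) -> dict:
    """Recompute the model's headline quantities.

    Returns a mapping of short names to ``{"value": float, "n": int}``.
    Delays are in minutes; fractions in [0, 1]; Kd's in nM.
    """
    params = RateParameters()
    presets = strain_presets()
    results: dict[str, dict] = {}

    # S_REP1: 55 reporter plasmids, no ssDNA — the calibration anchor
    _, s1 = _delay_stats(presets["S_REP1"], params, n_cells, seed)
    results["s_rep1_mean_delay_min"] = {
        "value": float(s1.mean_delay_min), "n": s1.n_both_on,
    }

    # C_REP1 cross-prediction: only the plasmid configuration changes
    # (55 reporter + 20 pColE2-P9), ssDNA disabled
    c_rep1_no_ssdna = StrainConfig("C_REP1_no_ssdna", 20, 55, False)
    _, c1 = _delay_stats(c_rep1_no_ssdna, params, n_cells, seed + 1_000_000)
    results["c_rep1_mean_delay_min"] = {
        "value": float(c1.mean_delay_min), "n": c1.n_both_on,
    }

    # C_WT with ssDNA (alpha_D = 7): delay over lysing cells, breadth, lysis
    ens_wt, wt = _delay_stats(presets["C_WT"], params, n_cells, seed + 2_000_000)
    lysing = Ensemble(
        cells=[c for c in ens_wt.cells if c.lysed_at is not None],
        strain_name="C_WT_lysing", lysis_on_cel=True,
    )
    wt_lysing = summarize(lysing, DEFAULT_THRESHOLD, DEFAULT_THRESHOLD)
    delays = wt_lysing.delays
    results["c_wt_mean_delay_min"] = {
        "value": float(wt_lysing.mean_delay_min), "n": wt_lysing.n_both_on,
    }
    results["c_wt_delay_cv"] = {
        "value": float(np.std(delays, ddof=1) / np.mean(delays)),
        "n": delays.size,
    }
    results["c_wt_frac_lysed_with_ssdna"] = {
        "value": 1.0 - wt.frac_not_lysing, "n": wt.n_cells,
    }

    # C_WT without ssDNA: unable to lyse within the imaging window
    c_wt_no = StrainConfig("C_WT_no_ssdna", 20, 0, False, lysis_on_cel=True)
    ens_no, wt_no = _delay_stats(c_wt_no, params, n_cells, seed + 3_000_000)
    results["c_wt_frac_lysed_without_ssdna"] = {
        "value": 1.0 - wt_no.frac_not_lysing, "n": wt_no.n_cells,
    }

    # gel-shift Kd recovery from the printed dilution protocols (2% noise)
    rna = generate_titration(TitrationRecipe(
        kd_true_nM=22.0, R_nM=10.0, stock_nM=6600.0, n_points=14,
        noise_sd_fraction=0.02, seed=seed + 4_000_000,
    ))
    ssdna = generate_titration(TitrationRecipe(
        kd_true_nM=991.0, R_nM=50.0, stock_nM=33300.0, n_points=14,
        noise_sd_fraction=0.02, seed=seed + 5_000_000,
    ))
    fit_rna = fit_binding(rna)
    fit_ssdna = fit_binding(ssdna)
    ratio, _ = kd_ratio(fit_ssdna, fit_rna)
    results["kd_rna_nm"] = {"value": fit_rna.kd_nM, "n": rna.protein_conc_nM.size}
    results["kd_ssdna_nm"] = {
        "value": fit_ssdna.kd_nM, "n": ssdna.protein_conc_nM.size,
    }
    results["kd_ratio_ssdna_to_rna"] = {
        "value": ratio,
        "n": rna.protein_conc_nM.size + ssdna.protein_conc_nM.size,
    }
    return results
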