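# Methods

## Model overview

`csrdelay` models the post-transcriptional control of ColicinE2 release as
a discrete stochastic reaction network per cell. The central quantity is
the free pool of the RNA-binding protein CsrA: translation of the lysis
gene *cel* requires a long mRNA whose Shine-Dalgarno region is free of
CsrA, and the delay between toxin (*cea*) and lysis (*cel*) expression is
the time the cell's CsrA-sequestering elements need to drain that pool.

Species (per cell): short mRNA (*cea-cei*), long mRNA (*cea-cei-cel*) in
three site-occupancy states (0, 1 or 2 CsrA bound), free CsrA, CsrA bound
to CsrB sites, to CsrC sites and to ssDNA, free CsrB/CsrC sites, free
ssDNA, and the two protein read-outs P_cea and P_cel. LexA is represented
by the per-cell induction gate (below) rather than as an explicit
molecule.

Reactions:

* **SOS-gated transcription.** After the cell's stochastic SOS onset,
  transcripts initiate at `transcription_rate × total plasmids ×
  induction_rate_scale`; each initiation yields the long mRNA with
  probability `p_long` (terminator readthrough) and the short mRNA
  otherwise.
* **Two-site CsrA repression.** The *cel* leader carries two CsrA hairpin
  sites. Binding is sequential mass action with statistical factors
  (2·k_on onto the free mRNA, k_on onto the singly bound one; off-rates
  k_off and 2·k_off). *cel* is translated only from the fully unbound
  long mRNA; *cea* is translated from every transcript.
* **sRNA buffering.** CsrB and CsrC are constitutive pools of independent
  1:1 CsrA sites (18 sites × 6 CsrB molecules, 9 × 6 CsrC) with
  production/decay balanced at the pool size; a site that decays while
  occupied returns its CsrA to the free pool.
* **ssDNA sink.** Strains carrying pColE2-P9 produce ssDNA at
  `alpha_D × ssdna_production_rate × n_colE2_plasmids` per min,
  independent of the SOS response, with first-order decay; CsrA binds it
  reversibly with the weak ssDNA affinity. At t = 0 the ssDNA pool starts
  at its stationary level and CsrA is pre-partitioned among the
  constitutive sinks using the deterministic equilibrium solver.
* **Turnover.** First-order decay of all mRNAs, sRNA sites, ssDNA and
  proteins; decay of any CsrA-carrying complex releases the CsrA. The
  total CsrA pool is strictly conserved (no synthesis or degradation of
  CsrA itself) — every reaction preserves
  free + mRNA-bound + sRNA-bound + ssDNA-bound.
* **Lysis.** In strains where *cel* encodes the real lysis protein
  (wild type C_WT), the cell lyses when P_cel reaches `lysis_threshold`;
  lysis is absorbing — signals are frozen at their current values for the
  remaining samples.

### Why two binding sites

The *cel* leader's CsrA-binding region is a double hairpin, and the
binding-site mutants (CsrA1/CsrA2) target the second site. A single-site
version of this network was tried first and cannot reproduce the observed
copy-number sensitivity: with one site per transcript the titration
transition is too soft, and the 55-plasmid vs 75-plasmid delays come out
in a ~2:1 ratio instead of the required ~3:1. Requiring both sites free
for translation makes the repression quadratic in the free-site fraction
and doubles each transcript's sequestration capacity, which sharpens the
switch to the observed sensitivity.

### How k_M enters

The association constant k_M (baseline 0.007; 0.0125 for the
stronger-binding CsrA1 site, 0.0018 for the weaker CsrA2 site) is treated
as dimensionless and converted to a per-molecule per-minute on-rate by
`binding_rate_scale` (default 10). The dissociation rate is a fixed
property of the protein-nucleic acid contact, chosen so that at the
baseline k_M the equilibrium K_d equals the measured 22 nM. A strain's
k_M therefore shifts the effective K_d (K_d_eff = k_off / (k_M · scale)),
which matches the gel-shift observation that the site mutations change
affinity, and produces the delay ordering CsrA2 < wild-type site < CsrA1.
With `binding_rate_scale = 1` binding would be so slow that a newborn
long mRNA translates *cel* for 2–3 min before the first CsrA arrives,
which destroys the titration delay; the scale of 10 puts site
equilibration well inside the 6-min mRNA lifetime while leaving the
equilibrium untouched.

## Parameters

All rates per minute, all K_d's in nM (converted at 0.6022 molecules/nM
for the 1-fL cell volume), defaults in `RateParameters`:

| parameter | default | meaning / basis |
|---|---|---|
| `k_M_baseline` | 0.007 | association constant, wild-type site |
| `binding_rate_scale` | 10 | converts k_M to a per-molecule on-rate |
| `kd_rna_nM` | 22 | measured CsrA–RNA site affinity |
| `kd_ssdna_nM` | 991 | measured CsrA–ssDNA affinity (45× weaker) |
| `kd_srna_nM` | 30 | CsrB/CsrC site affinity (tight, literature scale) |
| `csrA_total` | 300 | free-equivalent CsrA pool ("a few hundred") |
| `srna_sites_B/C`, `csrB/C_molecules` | 18×6, 9×6 | sized so CsrB holds ≈32% of the pool at baseline, CsrC half that |
| `transcription_rate` | 2.7 | initiations/plasmid/min at full induction (calibrated) |
| `p_long` | 0.1 | terminator readthrough |
| `translation_rate` | 0.07 | proteins/mRNA/min (calibrated) |
| `mrna_halflife_min` | 6 | typical bacterial mRNA |
| `protein_halflife_min` | 35 | effective loss incl. dilution (calibrated) |
| `srna_halflife_min` | 30 | sRNA turnover |
| `ssdna_halflife_min` | 60 | ssDNA turnover |
| `alpha_D` | 7 | ssDNA production scale |
| `ssdna_production_rate` | 0.8 | per pColE2-P9 plasmid per min (calibrated) |
| `lysis_threshold` | 40 | Cel molecules triggering lysis |
| `induction_offset_min` / `induction_exp_mean_min` | 30 / 30 | shifted-exponential SOS onset per cell |

`alpha_D` scales ssDNA **production**; whether it should instead scale
abundance or site count is not settled, but for a linear birth-death pool
the stationary abundance is proportional to production, so the choices
coincide at steady state.

Per-cell heterogeneity: plasmid copy numbers are Poisson around the
strain means, the CsrA pool is Poisson around `csrA_total`, and the SOS
onset is offset + Exponential. The copy-number spread is the main source
of the broad delay distributions and of the non-expressing subpopulations
in low-copy strains.

### Calibration

Expression and turnover defaults were set by calibrating the model to the
S_REP1 anchor (mean delay 67 min at 55 reporter plasmids), first on a
deterministic quasi-equilibrium mean-field skeleton of the same network,
then verified on the stochastic simulator. The copy-number prediction
(C_REP1 ≈ 24 min), the wild-type ssDNA prediction (≈ 1 h, CV > 0.3,
majority lysing) and the qualitative behaviour of the low-copy and
ssDNA-free strains (majority non-expressing / unable to lyse) then follow
from the same single parameter set without further adjustment.

## Simulation and analysis conventions

* Exact direct-method SSA; no tau-leaping (copy numbers are hundreds at
  most). The induction gate is handled exactly via the memorylessness of
  the exponential waiting time.
* RNG: a self-contained xorshift64* stream per cell, seeded by splitmix
  mixing of `spec.seed + cell_index`, so ensembles are bit-reproducible
  across platforms and independent of execution order. Initial-condition
  sampling uses a numpy PCG64 generator with the same per-cell seed.
* Sampled signals are raw molecule counts on the 15-min grid; observation
  noise exists only in the synthetic generator, keeping the simulator
  deterministic given its seed.
* Onset calling: first grid time with signal **strictly** above the
  threshold, reported on the grid (no interpolation). Default threshold
  30 molecules for simulated counts; for noisy data `suggest_threshold`
  gives 5× the 95th percentile of the pre-induction baseline.
* The mean delay is the plain mean of t_ONcel − t_ONcea over cells ON in
  both channels; negative differences are included and counted
  separately. SEM uses n_both_on. Cells ON in *cea* that never cross the
  *cel* threshold are reported via a right-censored lower-bound mean
  (delay ≥ horizon − t_ONcea), the form in which delays of mostly
  non-expressing strains are quoted.
* The free-CsrA coupled-equilibrium solver uses bisection to relative
  tolerance 1e−10; it is the oracle against which the SSA's stationary
  free-CsrA time average is tested (agreement within 3 SE on binding-only
  networks).
* Binding fits run in log(K_d) with b ≤ m enforced by parameterization
  (b = m − δ²); initial values m = max FI, b = min FI, K_d = P at
  half-range. Non-convergence is flagged, never silent; the K_d standard
  error is the curvature (delta-method) estimate, and replicate fits can
  additionally be averaged with their SD.

## What the synthetic generator does and does not emulate

The trajectory generator plants ON/OFF induction, shifted-exponential
onsets, a normal cea→cel delay, lognormal amplitudes, a linear rise to
plateau (standing in for fluorophore maturation/accumulation) and
additive Gaussian noise. It does **not** emulate photobleaching, focus
drift, segmentation errors, cell growth/division or day-to-day gain
changes; tests that pass on it validate the estimator logic (threshold
crossing, censoring, averaging), not robustness to those imaging
artefacts. The titration generator draws points exactly on the
equilibrium isotherm of the stated serial-dilution protocols with
multiplicative noise; it does not model band smearing or gel-to-gel
background.

## Problem sizes

The test suite and the acceptance script use 500-cell ensembles for the
three headline strains and 300-cell ensembles for the mutant-ordering and
lysis properties; binding-recovery Monte Carlo uses 200 replicate
titrations. At these sizes the SEM of a strain's mean delay is ~2 min,
well inside the quoted tolerances.

## Known limitations

* The reaction scheme is a concrete stand-in constrained by the published
  interaction topology and observables, not a transcription of any
  specific published equation set.
* LexA/AsnC transcriptional timing is reduced to a single
  `induction_rate_scale` knob on the gated transcription rate; the sRNA
  knockouts therefore show the naive prediction (longer delay when the
  buffer is removed), not the experimentally observed premature
  induction, which involves transcription-level feedback outside this
  model's scope.
* No cell growth, division or lineage tracking; dilution is folded into
  the first-order protein loss. No spatial effects.
* CsrA acts as a single binding unit per site; explicit dimerization and
  inter-site cooperativity are not modelled.
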