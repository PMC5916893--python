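# csrdelay

Stochastic modelling and single-cell analysis of the timing of ColicinE2
release in *Escherichia coli*.

## The problem

ColicinE2 is a plasmid-encoded DNase bacteriocin. Its operon carries three
genes — *cea* (the toxin), *cei* (immunity) and *cel* (a lysis protein
whose expression releases the toxin by killing the producer cell). Upon
DNA damage the SOS response derepresses the operon, and two transcripts
are made: a short *cea-cei* mRNA and, by terminator readthrough, a long
*cea-cei-cel* mRNA. Translation of *cel* from the long mRNA is blocked by
the carbon-storage regulator CsrA, which binds two GGA hairpin motifs
overlapping the *cel* Shine-Dalgarno sequence. The cell therefore produces
toxin first and releases it only later — and the delay between *cea* and
*cel* onset is set by how fast the free CsrA pool is drained by its
sequestering elements:

* the sRNAs CsrB and CsrC (constitutive, many CsrA sites each),
* the long mRNA itself, whose abundance scales with plasmid copy number,
* ssDNA generated by rolling-circle replication of the natural pColE2-P9
  plasmid, a weak (K_d ≈ 45× that of the mRNA site) but very abundant
  CsrA sink.

`csrdelay` implements this molecular-titration clock as a discrete
stochastic reaction network: an exact Gillespie simulator produces
two-channel single-cell trajectories on the 15-min / 300-min imaging grid;
an analysis layer reproduces the single-cell quantification (switching
threshold, t_ON, FI_max, %ON, mean cea-cel delay ± SEM, non-lysing
fraction); a fitting layer implements the equilibrium ("quadratic")
binding isotherm used for gel-shift titrations,

    FI = m − (m − b) · [ (R + P + K_d − √((R + P + K_d)² − 4 R P)) / (2R) ],

and a synthetic-data module generates trajectory ensembles and titrations
with planted ground truth so the whole pipeline is testable without any
experimental data.

## Worked example

```python
from csrdelay import (RateParameters, SimulationSpec, build_network,
                      free_csra_equilibrium, simulate_ensemble,
                      strain_presets, summarize)

params = RateParameters()                    # calibrated defaults
net = build_network(strain_presets()["S_REP1"], params)
ens = simulate_ensemble(net, SimulationSpec(n_cells=200, seed=1))
st = summarize(ens)
print(f"S_REP1: n={st.n_cells} both_on={st.n_both_on} "
      f"pct_on_cel={st.pct_on_cel:.2f} "
      f"delay={st.mean_delay_min:.1f}+/-{st.sem_min:.1f} min")

f = free_csra_equilibrium(300, {"mRNA": 260, "sRNA": 162},
                          {"mRNA": 13.2, "sRNA": 18.1})
print(f"free CsrA at S_REP1-like steady state: {f:.1f} molecules")
```

prints

```
S_REP1: n=200 both_on=188 pct_on_cel=0.94 delay=64.9+/-2.9 min
free CsrA at S_REP1-like steady state: 27.3 molecules
```

The reporter strain S_REP1 (55 reporter plasmids, no ssDNA) expresses the
toxin channel within minutes of its SOS onset, but the lysis channel only
turns on ~65 min later, once the accumulating long mRNA (together with the
sRNA buffer) has titrated the ~300-molecule free-CsrA pool down to the
K_d scale — the solver shows only ~27 molecules remain free at steady
state. Adding the 20 pColE2-P9 copies (C_REP1) shortens the delay to
~29 min through the extra mRNA alone, and the ssDNA they shed suppresses
it almost completely; conversely the wild type C_WT (20 plasmids, no
reporter) lyses within the 300-min window only because of its ssDNA.

A command-line interface wraps the same pipeline:

```bash
csrdelay simulate --strain S_REP1 --strain C_WT --n-cells 200 --seed 1 --out run/
csrdelay analyze run/S_REP1.csv run/C_WT.csv --out run/stats.json
csrdelay fit-binding rna.csv ssdna.csv --out fits.json
```

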