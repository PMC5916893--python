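"""Reaction network for the ColicinE2 release-timing circuit.

The ColicinE2 operon (*cea-cei-cel*) sits behind an SOS promoter.  After
LexA cleavage two transcripts are made: a short *cea-cei* mRNA and, by
terminator readthrough, a long *cea-cei-cel* mRNA.  Translation of *cel*
(the lysis gene) is blocked by the carbon-storage regulator CsrA, which
binds two GGA hairpin sites overlapping the *cel* Shine-Dalgarno sequence.
The free CsrA pool is itself titrated by the sRNAs CsrB/CsrC, by the long
mRNA, and — in strains carrying the natural pColE2-P9 plasmid — by ssDNA
produced during rolling-circle plasmid replication.  The delay between
*cea* and *cel* onset is therefore a molecular-titration clock: *cel* only
switches on once the sequestering sinks have drained the free CsrA pool.

This module defines the strain configurations, the kinetic parameters, the
discrete reaction network handed to the stochastic simulator, and a
deterministic coupled-equilibrium solver for free CsrA used as an
independent oracle for the simulator.
"""

from __future__ import annotations

import configparser
import dataclasses
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "NM_TO_MOLECULES_PER_FL",
    "StrainConfig",
    "RateParameters",
    "NetworkState",
    "Reaction",
    "ReactionNetwork",
    "CellRealization",
    "strain_presets",
    "build_network",
    "binding_only_network",
    "free_csra_equilibrium",
    "save_config",
    "load_config",
]

# 1 nM in molecules per femtolitre: 6.022e23 * 1e-9 mol/L * 1e-18 L/fL * 1e3
NM_TO_MOLECULES_PER_FL = 0.6022

# ---------------------------------------------------------------------------
# species indexing (shared with the simulator kernel)
# ---------------------------------------------------------------------------

SPECIES = (
    "mRNA_short",        # 0  cea-cei transcript
    "mRNA_long_free",    # 1  cea-cei-cel transcript, both CsrA sites free
    "mRNA_long_csrA1",   # 2  long transcript with one CsrA bound
    "mRNA_long_csrA2",   # 3  long transcript with both CsrA sites bound
    "CsrA_free",         # 4
    "CsrA_on_srnaB",     # 5
    "CsrA_on_srnaC",     # 6
    "sRNA_B_free_sites", # 7
    "sRNA_C_free_sites", # 8
    "ssDNA_free",        # 9
    "ssDNA_csrA",        # 10
    "P_cea",             # 11 toxin / YFP proxy
    "P_cel",             # 12 lysis protein / CFP proxy
)
S_IDX = {name: i for i, name in enumerate(SPECIES)}
N_SPECIES = len(SPECIES)

I_MS = S_IDX["mRNA_short"]
I_ML0 = S_IDX["mRNA_long_free"]
I_ML1 = S_IDX["mRNA_long_csrA1"]
I_ML2 = S_IDX["mRNA_long_csrA2"]
I_CSRA = S_IDX["CsrA_free"]
I_CB = S_IDX["CsrA_on_srnaB"]
I_CC = S_IDX["CsrA_on_srnaC"]
I_SB = S_IDX["sRNA_B_free_sites"]
I_SC = S_IDX["sRNA_C_free_sites"]
I_D = S_IDX["ssDNA_free"]
I_DC = S_IDX["ssDNA_csrA"]
I_PCEA = S_IDX["P_cea"]
I_PCEL = S_IDX["P_cel"]

# how many CsrA molecules each species holds (conservation bookkeeping)
CSRA_WEIGHT = np.zeros(N_SPECIES, dtype=np.int64)
CSRA_WEIGHT[I_CSRA] = 1
CSRA_WEIGHT[I_ML1] = 1
CSRA_WEIGHT[I_ML2] = 2
CSRA_WEIGHT[I_CB] = 1
CSRA_WEIGHT[I_CC] = 1
CSRA_WEIGHT[I_DC] = 1


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StrainConfig:
    """A named plasmid / ssDNA / binding-site configuration.

    ``k_M`` is the per-molecule association rate constant of CsrA for one
    hairpin site on the long mRNA; the binding-site mutants CsrA1/CsrA2 are
    represented purely through this knob (the dissociation rate is a fixed
    property of the CsrA protein, so changing ``k_M`` shifts the effective
    equilibrium constant, mirroring the stronger/weaker affinities measured
    for the mutated sites).
    """

    name: str
    n_colE2_plasmids: int
    n_reporter_plasmids: int
    ssdna_present: bool
    k_M: float = 0.007
    csrB_present: bool = True
    csrC_present: bool = True
    induction_rate_scale: float = 1.0
    lysis_on_cel: bool = False

    def __post_init__(self) -> None:
        if self.n_colE2_plasmids < 0 or self.n_reporter_plasmids < 0:
            raise ValueError("plasmid copy numbers must be non-negative")
        if self.ssdna_present and self.n_colE2_plasmids == 0:
            raise ValueError(
                "ssdna_present requires pColE2-P9 copies: ssDNA derives from "
                "rolling-circle replication of that plasmid"
            )
        if self.k_M <= 0:
            raise ValueError("k_M must be positive")
        if self.induction_rate_scale < 0:
            raise ValueError("induction_rate_scale must be >= 0")

    @property
    def total_plasmids(self) -> int:
        return self.n_colE2_plasmids + self.n_reporter_plasmids


@dataclass
class RateParameters:
    """Kinetic and equilibrium constants of the network (model units).

    Rates are per minute; bimolecular rate constants are per molecule per
    minute; dissociation constants are in nM and converted to molecule
    units through ``cell_volume_fL``.  The defaults are the package's
    calibrated parameter set (see docs/methods.md for the calibration
    rationale); they are the single versioned source of defaults.
    """

    # CsrA <-> long-mRNA hairpin site.  k_M is the dimensionless association
    # constant varied between strains; binding_rate_scale converts it to a
    # per-molecule per-minute on-rate.  The dissociation rate is a fixed
    # property of the protein-RNA contact, set so that at the baseline
    # k_M = 0.007 the equilibrium K_d equals the measured 22 nM.
    k_M_baseline: float = 0.007
    binding_rate_scale: float = 10.0
    kd_rna_nM: float = 22.0             # measured site affinity at baseline k_M
    # CsrA <-> ssDNA
    kd_ssdna_nM: float = 991.0
    k_on_ssdna: float = 0.001
    alpha_D: float = 7.0                # ssDNA production scale
    ssdna_production_rate: float = 0.8  # per pColE2-P9 plasmid per min (x alpha_D)
    # CsrA <-> sRNA sites
    kd_srna_nM: float = 30.0
    k_on_srna: float = 0.007
    srna_sites_B: int = 18              # CsrA sites per CsrB molecule
    srna_sites_C: int = 9               # CsrA sites per CsrC molecule
    csrB_molecules: int = 6
    csrC_molecules: int = 6
    # pools and expression
    csrA_total: int = 300               # free-equivalent CsrA pool per cell
    transcription_rate: float = 2.7     # initiations per plasmid per min, full induction
    p_long: float = 0.1                 # terminator T1 readthrough probability
    translation_rate: float = 0.07      # proteins per mRNA per min
    # turnover (minutes)
    mrna_halflife_min: float = 6.0
    protein_halflife_min: float = 35.0
    srna_halflife_min: float = 30.0
    ssdna_halflife_min: float = 60.0
    # lysis and geometry
    lysis_threshold: int = 40           # Cel molecules triggering lysis
    cell_volume_fL: float = 1.0
    # per-cell SOS onset-time distribution: offset + Exponential(mean)
    induction_offset_min: float = 30.0
    induction_exp_mean_min: float = 30.0

    def validate(self) -> None:
        positives = [
            self.k_M_baseline, self.binding_rate_scale, self.kd_rna_nM,
            self.kd_ssdna_nM,
            self.kd_srna_nM, self.k_on_ssdna, self.k_on_srna,
            self.transcription_rate, self.translation_rate,
            self.mrna_halflife_min, self.protein_halflife_min,
            self.srna_halflife_min, self.ssdna_halflife_min,
            self.cell_volume_fL,
        ]
        if any(v < 0 for v in positives):
            raise ValueError("rates, half-lives and Kd's must be non-negative")
        if not 0.0 <= self.p_long <= 1.0:
            raise ValueError("p_long must lie in [0, 1]")
        if self.csrA_total < 0 or self.lysis_threshold < 0:
            raise ValueError("pool sizes must be non-negative")
        if self.alpha_D < 0 or self.ssdna_production_rate < 0:
            raise ValueError("ssDNA production must be non-negative")

    # -- unit conversions ---------------------------------------------------

    def nm_to_molecules(self, nm: float) -> float:
        return nm * NM_TO_MOLECULES_PER_FL * self.cell_volume_fL

    @property
    def kd_rna_molecules(self) -> float:
        """Site K_d in molecule units at the baseline k_M."""
        return self.nm_to_molecules(self.kd_rna_nM)

    @property
    def kd_ssdna_molecules(self) -> float:
        return self.nm_to_molecules(self.kd_ssdna_nM)

    @property
    def kd_srna_molecules(self) -> float:
        return self.nm_to_molecules(self.kd_srna_nM)

    @property
    def rna_off_rate(self) -> float:
        """Fixed CsrA-mRNA dissociation rate (per min)."""
        return self.k_M_baseline * self.binding_rate_scale * self.kd_rna_molecules

    def rna_on_rate(self, k_M: float) -> float:
        """Per-site association rate (per molecule per min) for a strain's k_M."""
        return k_M * self.binding_rate_scale

    def kd_rna_effective(self, k_M: float) -> float:
        """Effective mRNA-site K_d (molecules) for a strain's k_M.

        The dissociation rate is a property of the protein-RNA contact and
        is held fixed; binding-site mutations act on the association rate,
        so K_d_eff = rna_off_rate / (k_M * binding_rate_scale).  At the
        baseline k_M this equals the measured 22 nM.
        """
        return self.rna_off_rate / self.rna_on_rate(k_M)

    @property
    def srna_sites_total_B(self) -> int:
        return self.srna_sites_B * self.csrB_molecules

    @property
    def srna_sites_total_C(self) -> int:
        return self.srna_sites_C * self.csrC_molecules


@dataclass
class NetworkState:
    """Molecule counts of one cell at one instant.

    ``lexA_active`` mirrors the SOS induction gate: the simulator represents
    LexA cleavage as the per-cell stochastic onset time after which
    transcription reactions become active.
    """

    counts: np.ndarray           # length N_SPECIES, non-negative integers
    lexA_active: bool
    lysed: bool

    def csra_total(self) -> int:
        """CsrA summed over free and all bound forms."""
        return int(np.dot(CSRA_WEIGHT, self.counts))


# ---------------------------------------------------------------------------
# strain presets (wild type and mutant panel)
# ---------------------------------------------------------------------------

def strain_presets() -> dict[str, StrainConfig]:
    """The strain panel: wild type, reporter strains and mutants.

    C strains carry ~20 copies of the natural pColE2-P9 plasmid (and hence
    accumulate ssDNA); S strains carry only the reporter plasmid.  REP1
    strains carry ~55 reporter copies, REP2 strains ~13.  CsrA1/CsrA2 alter
    the CsrA binding site (stronger / weaker); CsrB/CsrC/CsrBC are sRNA
    knockouts; LexA1/LexA2 alter the SOS box (stronger / weaker induction).
    """
    presets = {
        "C_WT": StrainConfig("C_WT", 20, 0, True, lysis_on_cel=True),
        "C_REP1": StrainConfig("C_REP1", 20, 55, True),
        "S_REP1": StrainConfig("S_REP1", 0, 55, False),
        "C_REP2": StrainConfig("C_REP2", 20, 13, True),
        "S_REP2": StrainConfig("S_REP2", 0, 13, False),
        "CsrA1": StrainConfig("CsrA1", 0, 55, False, k_M=0.0125),
        "CsrA2": StrainConfig("CsrA2", 0, 55, False, k_M=0.0018),
        "CsrB": StrainConfig("CsrB", 0, 55, False, csrB_present=False),
        "CsrC": StrainConfig("CsrC", 0, 55, False, csrC_present=False),
        "CsrBC": StrainConfig(
            "CsrBC", 0, 55, False, csrB_present=False, csrC_present=False
        ),
        "LexA1": StrainConfig("LexA1", 0, 55, False, induction_rate_scale=0.6),
        "LexA2": StrainConfig("LexA2", 0, 55, False, induction_rate_scale=1.4),
    }
    return presets


# ---------------------------------------------------------------------------
# free-CsrA coupled-equilibrium solver (oracle)
# ---------------------------------------------------------------------------

def free_csra_equilibrium(
    csra_total: float,
    site_totals: dict[str, float],
    kds: dict[str, float],
    rtol: float = 1e-10,
) -> float:
    """Free CsrA at equilibrium against independent 1:1 binding sites.

    Solves F + sum_s S_s * F / (F + K_s) = csra_total for the unique root
    F in [0, csra_total] by bisection.  All quantities in molecule units.
    """
    if csra_total < 0:
        raise ValueError("csra_total must be non-negative")
    if set(site_totals) != set(kds):
        raise ValueError("site_totals and kds must share keys")
    sinks = [(float(site_totals[k]), float(kds[k])) for k in site_totals]
    if any(s < 0 or k < 0 for s, k in sinks):
        raise ValueError("site totals and kds must be non-negative")
    if csra_total == 0:
        return 0.0

    def excess(f: float) -> float:
        tot = f
        for s, k in sinks:
            if f + k > 0:
                tot += s * f / (f + k)
            elif s > 0:  # k == 0 and f == 0: infinitely tight sink
                tot += 0.0
        return tot - csra_total

    lo, hi = 0.0, float(csra_total)
    # excess(0) <= 0 and excess(csra_total) >= 0; excess strictly increasing
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if excess(mid) > 0.0:
            hi = mid
        else:
            lo = mid
        if hi - lo <= rtol * max(hi, 1e-300):
            break
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# reaction network
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Reaction:
    """One elementary reaction: mass action of order 0, 1 or 2.

    ``rate`` multiplies the product of the reactant counts.  ``gated`` marks
    reactions that only fire after the cell's SOS onset (transcription).
    """

    name: str
    rate: float
    reactants: tuple[int, ...]       # species indices entering the propensity
    stoich: tuple[tuple[int, int], ...]  # (species index, delta)
    gated: bool = False

    def propensity(self, counts: np.ndarray, induced: bool) -> float:
        if self.gated and not induced:
            return 0.0
        a = self.rate
        for idx in self.reactants:
            a *= counts[idx]
        return a

    def csra_delta(self) -> int:
        return sum(CSRA_WEIGHT[i] * d for i, d in self.stoich)


@dataclass
class CellRealization:
    """Per-cell randomized initial condition handed to the SSA kernel."""

    initial_counts: np.ndarray
    rates: np.ndarray              # per-cell reaction rate constants
    onset_min: float               # SOS onset (LexA cleavage) time
    n_colE2: int
    n_reporter: int
    csra_total: int


@dataclass
class ReactionNetwork:
    """Concrete reaction list for one strain under one parameter set."""

    strain: StrainConfig
    params: RateParameters
    reactions: list[Reaction]

    @property
    def species(self) -> tuple[str, ...]:
        return SPECIES

    # -- array form for the simulator kernel --------------------------------

    def to_arrays(self):
        n_r = len(self.reactions)
        rates = np.array([r.rate for r in self.reactions], dtype=np.float64)
        re1 = np.full(n_r, -1, dtype=np.int64)
        re2 = np.full(n_r, -1, dtype=np.int64)
        for j, r in enumerate(self.reactions):
            if len(r.reactants) > 2:
                raise ValueError(f"reaction {r.name}: order > 2 unsupported")
            if len(r.reactants) >= 1:
                re1[j] = r.reactants[0]
            if len(r.reactants) == 2:
                re2[j] = r.reactants[1]
        stoich = np.zeros((n_r, N_SPECIES), dtype=np.int64)
        for j, r in enumerate(self.reactions):
            for i, d in r.stoich:
                stoich[j, i] += d
        gated = np.array([r.gated for r in self.reactions], dtype=np.bool_)
        return rates, re1, re2, stoich, gated

    # -- per-cell randomization ---------------------------------------------

    def realize_cell(self, rng: np.random.Generator) -> CellRealization:
        """Sample one cell: SOS onset, plasmid numbers, CsrA pool, and the
        pre-induction steady state of the constitutive species.

        Plasmid copy numbers are Poisson around the strain means; the CsrA
        pool is Poisson around ``csrA_total``.  ssDNA (produced continuously,
        independent of the SOS response) starts at its stationary pool, and
        CsrA is pre-partitioned between sRNA sites and ssDNA with the
        deterministic coupled-equilibrium solver.
        """
        p = self.params
        st = self.strain
        n_cole2 = int(rng.poisson(st.n_colE2_plasmids)) if st.n_colE2_plasmids else 0
        n_rep = int(rng.poisson(st.n_reporter_plasmids)) if st.n_reporter_plasmids else 0
        if st.ssdna_present and n_cole2 == 0:
            n_cole2 = 1  # keep the strain invariant under Poisson sampling
        csra_tot = int(rng.poisson(p.csrA_total))
        onset = p.induction_offset_min + rng.exponential(p.induction_exp_mean_min)

        # rescale per-cell copy-number dependent rate constants
        rates = np.array([r.rate for r in self.reactions], dtype=np.float64)
        mean_tot = max(st.total_plasmids, 1)
        tot = n_cole2 + n_rep
        for j, r in enumerate(self.reactions):
            if r.name.startswith("tx_"):
                rates[j] = r.rate * tot / mean_tot
            elif r.name == "ssdna_production" and st.n_colE2_plasmids > 0:
                rates[j] = r.rate * n_cole2 / st.n_colE2_plasmids

        counts = np.zeros(N_SPECIES, dtype=np.int64)
        sb = p.srna_sites_total_B if st.csrB_present else 0
        sc = p.srna_sites_total_C if st.csrC_present else 0
        d_tot = 0.0
        if st.ssdna_present:
            delta_d = math.log(2.0) / p.ssdna_halflife_min
            d_tot = p.alpha_D * p.ssdna_production_rate * n_cole2 / delta_d
        free = free_csra_equilibrium(
            csra_tot,
            {"B": sb, "C": sc, "D": d_tot},
            {"B": p.kd_srna_molecules, "C": p.kd_srna_molecules,
             "D": p.kd_ssdna_molecules},
        )
        bound_b = int(round(sb * free / (free + p.kd_srna_molecules))) if sb else 0
        bound_c = int(round(sc * free / (free + p.kd_srna_molecules))) if sc else 0
        bound_d = int(round(d_tot * free / (free + p.kd_ssdna_molecules))) if d_tot else 0
        bound_b = min(bound_b, csra_tot)
        bound_c = min(bound_c, max(csra_tot - bound_b, 0))
        bound_d = min(bound_d, max(csra_tot - bound_b - bound_c, 0))
        counts[I_CB] = bound_b
        counts[I_CC] = bound_c
        counts[I_DC] = bound_d
        counts[I_CSRA] = csra_tot - bound_b - bound_c - bound_d
        counts[I_SB] = max(sb - bound_b, 0)
        counts[I_SC] = max(sc - bound_c, 0)
        counts[I_D] = max(int(round(d_tot)) - bound_d, 0)
        return CellRealization(counts, rates, onset, n_cole2, n_rep, csra_tot)


def build_network(strain: StrainConfig, params: RateParameters) -> ReactionNetwork:
    """Assemble the reaction list for one strain.

    Raises on a non-runnable strain (zero total plasmids) or invalid
    parameters.  The ssDNA branch is included only when the strain carries
    pColE2-P9 and its production propensity is non-zero only when
    ``alpha_D > 0`` — with ``alpha_D = 0`` the production rate is exactly
    zero and the network behaves as the ssDNA-free one.
    """
    params.validate()
    if strain.total_plasmids <= 0:
        raise ValueError("total plasmid count must be positive for a runnable strain")

    p = params
    dm = math.log(2.0) / p.mrna_halflife_min
    dp = math.log(2.0) / p.protein_halflife_min
    ds = math.log(2.0) / p.srna_halflife_min
    dd = math.log(2.0) / p.ssdna_halflife_min
    tx_total = p.transcription_rate * strain.total_plasmids * strain.induction_rate_scale
    k_on = p.rna_on_rate(strain.k_M)
    k_off = p.rna_off_rate

    rxns: list[Reaction] = [
        # SOS-gated transcription (LexA cleavage opens the promoter)
        Reaction("tx_short", (1.0 - p.p_long) * tx_total, (), ((I_MS, +1),), gated=True),
        Reaction("tx_long", p.p_long * tx_total, (), ((I_ML0, +1),), gated=True),
        # mRNA turnover; CsrA returns to the free pool when its carrier decays
        Reaction("decay_m_short", dm, (I_MS,), ((I_MS, -1),)),
        Reaction("decay_m_long0", dm, (I_ML0,), ((I_ML0, -1),)),
        Reaction("decay_m_long1", dm, (I_ML1,), ((I_ML1, -1), (I_CSRA, +1))),
        Reaction("decay_m_long2", dm, (I_ML2,), ((I_ML2, -1), (I_CSRA, +2))),
        # CsrA on the two hairpin sites of the cel leader
        Reaction("rna_bind1", 2.0 * k_on, (I_CSRA, I_ML0),
                 ((I_CSRA, -1), (I_ML0, -1), (I_ML1, +1))),
        Reaction("rna_unbind1", k_off, (I_ML1,),
                 ((I_ML1, -1), (I_ML0, +1), (I_CSRA, +1))),
        Reaction("rna_bind2", k_on, (I_CSRA, I_ML1),
                 ((I_CSRA, -1), (I_ML1, -1), (I_ML2, +1))),
        Reaction("rna_unbind2", 2.0 * k_off, (I_ML2,),
                 ((I_ML2, -1), (I_ML1, +1), (I_CSRA, +1))),
        # translation: cea from every transcript, cel only from fully free long mRNA
        Reaction("tl_cea_short", p.translation_rate, (I_MS,), ((I_PCEA, +1),)),
        Reaction("tl_cea_long0", p.translation_rate, (I_ML0,), ((I_PCEA, +1),)),
        Reaction("tl_cea_long1", p.translation_rate, (I_ML1,), ((I_PCEA, +1),)),
        Reaction("tl_cea_long2", p.translation_rate, (I_ML2,), ((I_PCEA, +1),)),
        Reaction("tl_cel", p.translation_rate, (I_ML0,), ((I_PCEL, +1),)),
        # protein turnover / dilution
        Reaction("decay_p_cea", dp, (I_PCEA,), ((I_PCEA, -1),)),
        Reaction("decay_p_cel", dp, (I_PCEL,), ((I_PCEL, -1),)),
    ]

    for present, si, ci, tot_sites, tag in (
        (strain.csrB_present, I_SB, I_CB, p.srna_sites_total_B, "B"),
        (strain.csrC_present, I_SC, I_CC, p.srna_sites_total_C, "C"),
    ):
        if not present:
            continue
        rxns += [
            Reaction(f"srna{tag}_bind", p.k_on_srna, (I_CSRA, si),
                     ((I_CSRA, -1), (si, -1), (ci, +1))),
            Reaction(f"srna{tag}_unbind", p.k_on_srna * p.kd_srna_molecules,
                     (ci,), ((ci, -1), (I_CSRA, +1), (si, +1))),
            Reaction(f"srna{tag}_production", tot_sites * ds, (), ((si, +1),)),
            Reaction(f"srna{tag}_decay_free", ds, (si,), ((si, -1),)),
            Reaction(f"srna{tag}_decay_bound", ds, (ci,),
                     ((ci, -1), (I_CSRA, +1),)),
        ]

    prod = p.alpha_D * p.ssdna_production_rate * strain.n_colE2_plasmids
    if strain.ssdna_present and prod > 0:
        # with alpha_D = 0 the production propensity vanishes and the whole
        # branch is dropped: the network is then identical to the ssDNA-free one
        rxns += [
            Reaction("ssdna_production", prod, (), ((I_D, +1),)),
            Reaction("ssdna_decay_free", dd, (I_D,), ((I_D, -1),)),
            Reaction("ssdna_bind", p.k_on_ssdna, (I_CSRA, I_D),
                     ((I_CSRA, -1), (I_D, -1), (I_DC, +1))),
            Reaction("ssdna_unbind", p.k_on_ssdna * p.kd_ssdna_molecules,
                     (I_DC,), ((I_DC, -1), (I_CSRA, +1), (I_D, +1))),
            Reaction("ssdna_decay_bound", dd, (I_DC,),
                     ((I_DC, -1), (I_CSRA, +1))),
        ]

    net = ReactionNetwork(strain, params, rxns)
    for r in rxns:
        if r.csra_delta() != 0:
            raise AssertionError(f"reaction {r.name} breaks CsrA conservation")
        if r.rate < 0:
            raise ValueError(f"reaction {r.name} has negative rate")
    return net


def binding_only_network(
    csra_total: int,
    site_totals: dict[str, float],
    kds: dict[str, float],
    on_rates: dict[str, float] | None = None,
) -> ReactionNetwork:
    """A network containing nothing but reversible CsrA-site binding.

    Used to compare the simulator's stationary free-CsrA average against
    the analytic coupled-equilibrium solver.  Sinks are mapped onto unused
    sink species slots (sRNA-B, sRNA-C, ssDNA) — at most three sinks.
    """
    if len(site_totals) > 3:
        raise ValueError("at most three sinks supported")
    slots = [(I_SB, I_CB), (I_SC, I_CC), (I_D, I_DC)]
    params = RateParameters()
    strain = StrainConfig("binding_only", 0, 1, False)
    rxns = []
    init = np.zeros(N_SPECIES, dtype=np.int64)
    init[I_CSRA] = csra_total
    for (name, sites), (si, ci) in zip(sorted(site_totals.items()), slots):
        kon = (on_rates or {}).get(name, 0.007)
        kd = kds[name]
        rxns += [
            Reaction(f"bind_{name}", kon, (I_CSRA, si),
                     ((I_CSRA, -1), (si, -1), (ci, +1))),
            Reaction(f"unbind_{name}", kon * kd, (ci,),
                     ((ci, -1), (I_CSRA, +1), (si, +1))),
        ]
        init[si] = int(round(sites))
    net = ReactionNetwork(strain, params, rxns)
    net.binding_only_init = init  # type: ignore[attr-defined]
    return net


# ---------------------------------------------------------------------------
# structured-text configuration files
# ---------------------------------------------------------------------------

_STRAIN_FIELDS = [f.name for f in dataclasses.fields(StrainConfig)]


def save_config(
    path, params: RateParameters, strains: dict[str, StrainConfig] | None = None
) -> None:
    """Write parameters (and optional strain overrides) as flat key = value text."""
    cp = configparser.ConfigParser()
    cp.optionxform = str  # keep case: k_M etc.
    cp["parameters"] = {
        f.name: repr(getattr(params, f.name))
        for f in dataclasses.fields(RateParameters)
    }
    for name, st in (strains or {}).items():
        cp[f"strain:{name}"] = {
            k: repr(getattr(st, k)) for k in _STRAIN_FIELDS if k != "name"
        }
    with open(path, "w") as fh:
        cp.write(fh)


def load_config(path) -> tuple[RateParameters, dict[str, StrainConfig]]:
    """Read a config written by :func:`save_config`; round-trip is lossless."""
    cp = configparser.ConfigParser()
    cp.optionxform = str
    read = cp.read(path)
    if not read:
        raise FileNotFoundError(path)
    kwargs = {}
    if cp.has_section("parameters"):
        field_types = {f.name: f.type for f in dataclasses.fields(RateParameters)}
        for key, raw in cp["parameters"].items():
            if key not in field_types:
                raise ValueError(f"unknown parameter {key!r} in {path}")
            kwargs[key] = _parse_scalar(raw)
    params = RateParameters(**kwargs)
    params.validate()
    strains = {}
    for section in cp.sections():
        if not section.startswith("strain:"):
            continue
        name = section.split(":", 1)[1]
        skw = {k: _parse_scalar(v) for k, v in cp[section].items()}
        strains[name] = StrainConfig(name=name, **skw)
    return params, strains


def _parse_scalar(raw: str):
    raw = raw.strip()
    if raw in ("True", "False"):
        return raw == "True"
    try:
        return int(raw)
    except ValueError:
        pass
    try:
        return float(raw)
    except ValueError:
        return raw.strip("'\"")
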