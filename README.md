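# pexkit — residue-level proton exchange for particle simulations

Classical force fields cannot break or form bonds, so a conventional
molecular dynamics simulation of a *protic ionic liquid* — a salt whose
Brønsted acid and base exchange a proton, `HA + B ⇌ A⁻ + BH⁺` — freezes
every molecule in one protonation state and misses the part of the
charge transport that protons carry.  `pexkit` is a Python toolkit for
people who want to put that reaction back into a particle simulation
without a reactive force field, and to analyse the resulting
trajectories correctly.

It provides four things:

1. **Single-topology dual-state residue templates.**  Each exchangeable
   residue carries two complete non-bonded parameter sets (protonated /
   deprotonated) over one shared atom list, mapped one-to-one; the
   transferable hydrogen survives deprotonation as a zero-charge *dummy
   atom*.  A packaged configuration describes the
   1-methylimidazolium/acetate pair (IM1H/IM1, HOAC/OAC) together with
   Drude-oscillator utilities: the spring relation `k = C q_δ²/α` linking
   Drude charge and polarizability, the self-polarization energy
   `U = Σ k d²`, and the polarizability-dependent Lennard-Jones scaling
   `ε = ε₀ (Δα + s·α_max)/(s·Δα + α_max)`.

2. **A feedback-controlled exchange engine.**  At fixed intervals the
   dynamics is paused; donor-H/acceptor contacts closer than `r_max`
   (minimum image) become transfer candidates, overlaps are resolved by
   shortest-distance-first matching, and each pair reacts with its
   channel's current probability.  That probability is steered by a cubic
   count feedback,

       p = p_ref + c · (n_now / n_ref − 1)³   (clamped to [0, 1]),

   which holds the charged:neutral partitioning at its reference value
   (here 30%:70%) even when the sampled contact statistics would
   otherwise drift it away.

3. **A toy Brownian engine** (soft-sphere + screened-Coulomb beads,
   overdamped dynamics, periodic box) so that the whole
   pipeline — build, run, exchange, analyse — works at desk scale in
   seconds to minutes, with no external MD package.

4. **Transfer-aware analyses.**  Diffusion coefficients by the Einstein
   relation `D = slope⟨Δr²⟩/6`, with each residue's time series *cut at
   its transfer events* so charged and neutral mobility never mix; and
   the static conductivity from the collective translational dipole
   `M_J = Σ qᵢrᵢ`,

       σ(0) = slope⟨ΔM_J²⟩ / (6 V k_B T),

   where each transfer's artificial box-scale jump in the unfolded series
   is replaced by its physical minimum-image contribution
   `δM_J = Δq_j · e · r_ij` (eight admissible charge-transition cases).
   Shell-resolved potentials of mean force,
   `PMF_kl = −k_B T ln(c_l(shell)/c_l)`, and ΔPMF matrices between runs
   round out the structure analysis.

## Worked example

`examples/02_build_and_exchange.py` builds a 200-residue bead box at the
30%:70% partitioning and runs 80 exchange cycles over Brownian dynamics:

```
Residues: 200, update cycles: 80, transfer events: 125

Composition (first/last update):
 time_ps  IM1H  IM1  OAC  HOAC
     0.5    29   71   29    71
    40.0    27   73   27    73

Charged fraction of imidazole-type residues: start 30.0%, mean over run 28.0%

Events per transfer channel:
  HOAC+OAC->OAC+HOAC       61
  IM1+HOAC->IM1H+OAC       20
  IM1H+IM1->IM1+IM1H       21
  IM1H+OAC->IM1+HOAC       23

First event: t=0.5 ps, residues 13->107, charges (+1,+0) -> (+0,+1), |r_ij|=3.75 A
```

The composition stays pinned near the 30% reference by the cubic
feedback; every event conserves charge exactly (a proton hop swaps one
+1/0 or 0/−1 label pair).  `examples/03_transport_analysis.py` continues
into the transport analysis and shows why the dipole correction matters:
on a 29 Å box the raw unfolded dipole picks up ~58 e·Å artifacts per
transfer and overestimates σ(0) by a factor of ~5 relative to the
event-corrected series.

The other examples cover the template/Drude layer (`01`), and the
RDF-derived first-shell PMF matrices and replica ΔPMF (`04`).  A thin
CLI wraps the same calls: `pexkit build`, `pexkit run`,
`pexkit analyze transport`, `pexkit analyze structure`.

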