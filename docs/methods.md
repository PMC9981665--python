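# Methods

## The model

`pexkit` implements residue-level proton exchange as a Monte-Carlo-style
move layered over particle dynamics.  Each exchangeable residue is a
*single topology* with two discrete parameter states — protonated and
deprotonated — related by a bijective atom mapping; a state switch
rewrites the residue's per-atom charges and (optionally) Lennard-Jones
parameters, and a proton absent in the current state persists as a dummy
atom (zero charge, negligible LJ well, zero polarizability).  The four
transfer channels of the packaged imidazolium/acetate chemistry are

| reactants | products | r_max [Å] | p_ref | c |
|---|---|---|---|---|
| IM1H + OAC | IM1 + HOAC | 1.55 | 0.994 | 300 |
| IM1 + HOAC | IM1H + OAC | 1.55 | 0.098 | 300 |
| IM1H + IM1 | IM1 + IM1H | 1.55 | 0.201 | 300 |
| HOAC + OAC | OAC + HOAC | 1.55 | 0.684 | 300 |

Probabilities are stored as fractions; configuration files may give them
in percent.  The donor in any channel is the reactant currently in its
template's protonated state; the first two channels change the number of
charged molecules, the last two only shuttle the proton (swap channels).

An update step is: (1) collect all donor-H/acceptor-site pairs with
minimum-image distance strictly below the channel's `r_max`; for
multi-site acceptors (both carboxylate oxygens) the closest site is
recorded; (2) reduce overlapping candidates to a disjoint set by greedy
shortest-distance-first matching, ties broken by residue ids — the
shortest contact is the most reaction-prone, and a residue transfers at
most once per update; (3) refresh each channel's probability from the
*current* composition (before any acceptance draw) with the cubic
feedback `p = p_ref + c (n_now/n_ref − 1)³`, clamped to [0, 1], where
`n` counts the channel's first reactant (the species it consumes);
(4) accept each pair by an independent Bernoulli draw from a dedicated
seeded RNG stream; (5) switch donor to deprotonated and acceptor to
protonated, either instantaneously or along a linear charge
interpolation (`n_lambda_steps` intermediate states, with a dynamics
hook between increments; the endpoint is identical to the instantaneous
swap).  Each executed transfer is logged with integer charges before and
after and the minimum-image displacement `r_ij = mimage(r_j − r_i)` of
the two residue centers at event time — the geometry the conductivity
correction needs later.

Two deliberate interpretations where the rule leaves room: the feedback
acts only on the composition-changing channels; swap channels keep
`p = p_ref` because they cannot steer the composition, which is the
feedback's sole purpose.  And out-of-range feedback values are clamped
to [0, 1] rather than rejected.

## Units and constants

CHARMM-style internal units throughout: Å, kcal/mol, elementary charge,
ps, amu, K; Coulomb prefactor 332.0716 kcal·Å/(mol·e²), k_B =
0.0019872041 kcal/(mol·K).  Conversions (m²/s for D, mS/cm for σ) are
derived from CODATA constants in `pexkit.units` and verified
dimensionally in the tests.

The LJ-scaling formula `ε = ε₀ (Δα + s·α_max)/(s·Δα + α_max)`
(Δα = α_max − α) is stated with the only operator grouping that
satisfies both limits ε(0) = ε₀ and ε(α_max) = s·ε₀; typeset versions of
this expression are ambiguous about the grouping, so the limits, not the
typography, fix the implementation.

## The toy engine and the packaged demonstration conditions

The Brownian engine exists to exercise the exchange machinery and the
analyses at desk scale; it deliberately replaces polarizable MD.  Beads
interact through WCA repulsion (ε, σ) plus Yukawa-screened Coulomb
`C q_i q_j exp(−r/λ_s)/r`, truncated and shifted to zero at the cutoff,
and move by the overdamped update `x += (D₀/kT) F dt + √(2 D₀ dt) ξ`
with `D₀ = kT/(m γ)` — free beads diffuse with exactly `D₀`, the anchor
for validating the transport estimators.

The packaged demonstration (`DemoConditions`) is a 1,000-residue
single-bead box, 150 cation/anion pairs + 350 neutral pairs (the
30%:70% reference), σ = 4 Å beads in a 43 Å box (liquid-like packing
fraction ~0.8), T = 300 K, friction 20 ps⁻¹, mass 100 amu
(D₀ ≈ 0.12 Å²/ps, a liquid-like mobility), dt = 0.02 ps, updates every
0.5 ps for 250 cycles after 500 equilibration steps.  Two parameters
depart from naive expectations and matter:

* **Screening length 0.5 Å** (the formal Debye length of a dense ionic
  melt).  With weak screening the bare ±1 bead charges bind cation/anion
  contact pairs by tens of kT: every cation sits in a permanent ion
  pair, the near-unity discharge channel fires for all 150 of them at
  every update, and the composition bangs between the feedback rails
  (~10–45% charged) instead of fluctuating around the reference.  Strong
  screening keeps charge ordering qualitative while leaving pair
  lifetimes finite.
* **Transfer cutoff 0.95 σ**, just inside the soft-sphere contact
  distance.  An atomistic H-bond criterion (1.55 Å) is a rare
  configuration on the scale of a coordination shell; the equivalent
  rarity at bead resolution requires the cutoff to sit in the steep part
  of the repulsive wall.  At 0.95 σ a 1,000-residue box produces ~5–10
  transfer opportunities per update (a few thousand events per run),
  the sparse regime in which the feedback is mean-reverting.

With these conditions the time-averaged charged fraction settles at
~27–28%, slightly below the 30% reference: the bead contact statistics
weight the discharge channel (p_ref = 0.994) more heavily than the
recharge channel (p_ref = 0.098), and the cubic feedback — which is flat
near n = n_ref and only reaches full strength at ~15% deviation, where
the discharge probability clamps to zero — balances the rates a few
percentage points under the reference.  The same under-shoot mechanism
exists in the atomistic system; the toy merely makes it visible.

What the toy does *not* emulate: polarizable (Drude) dynamics and the
energetic smoothing it provides during state swaps, Ewald electrostatics,
molecular shape and hydrogen-bond directionality, barostats, and
quantitative transport magnitudes.  Passing tests therefore validate the
*bookkeeping and estimators* (charge conservation, candidate detection,
series cutting, dipole corrections, unit conversions), not the physics
of any real ionic liquid.

## Transport analysis

Residue-center trajectories are stored folded; analyses unfold them by
accumulating minimum-image frame-to-frame displacements (exact as long
as no residue moves half a box length between frames; such frames are
reported as aliasing errors).

*Diffusion.*  Each residue's unfolded series is cut at its transfer
events; segments shorter than a configurable minimum (default 50% of the
run, mirroring a 25-ns-of-50-ns criterion at production scale) are
discarded, the rest are labeled with the species held during the
segment.  MSDs are averaged over multiple time origins (stride
configurable) and over segments, weighted by sample count, and `D` is
the least-squares slope over a stated lag window divided by 6.  Default
windows scale a 2–6 ns production prescription down to 10–30% of the run
length.  Pooled template-level coefficients (IM1H/IM1 and OAC/HOAC
combined) are also emitted.

*Conductivity.*  `M_J(t) = Σ qᵢ(t) rᵢ(t)` uses integer molecular charges
and unfolded centers; charges change at the frame bearing the event's
time stamp.  A transfer executed under the minimum image appears in the
unfolded series as a charge hop of order the box length; the raw jump
`Δq_i rᵢ + Δq_j rⱼ` (unfolded coordinates at the event frame) is
removed and the physical contribution `δM_J = Δq_j e · r_ij`
(minimum-image displacement from the event log) added, as a cumulative
additive correction series — the raw data stay auditable, and with no
events corrected ≡ raw.  The eight admissible charge transitions
(four channels × two (i,j) labelings) and their ±e·r_ij coefficients are
enumerated programmatically and checked against the direct dipole
difference.  The sign convention `r_ij = r_j − r_i` is fixed by requiring
the (+1,−1)→(0,0) case to reproduce `M_J^b = −e·r_ij`.  σ(0) is the MSD
slope of (corrected) `M_J` over the fit window divided by `6 V k_B T`.

## Structure analysis

First shells are defined by per-species-pair radial cutoffs (default:
the first minimum of the pair RDF, computed by a bundled helper), with
shell volume `V = 4/3 π r_cut³`.  This replaces a radical-Voronoi
construction: absolute PMFs therefore carry a pair-wise offset relative
to tessellation-based volumes, but the offset cancels in run-to-run
differences (ΔPMF), which is the quantity of interest.  `PMF_kl =
−k_B T ln((N_kl/V_k)/(N_l/V))`, frames equally weighted; entries whose
shell was never populated are flagged `+inf` (a depletion floor) and
written as text, never as a numeric infinity.  ΔPMF is the entrywise
difference of two matrices over identical species sets.

## Numerical choices and degenerate inputs

- Candidate distances are strict (`< r_max`); `r_max` must be below half
  the smallest box edge (geometry error otherwise).
- Neighbor searches use periodic KD-trees; both the candidate search and
  the shell assignment are tested against O(N²) brute-force oracles on
  100 random configurations.
- Coincident beads (r < 10⁻⁶ Å) raise a singularity error; non-finite
  positions after an integrator step raise a blow-up error advising a
  smaller timestep.
- Residue ids are 0-based in memory and 1-based in PSF files; the PSF
  dialect covers title/atom/bond sections only (segment, residue id and
  name, atom name/type, charge, mass) — enough for state bookkeeping,
  and readable by MDAnalysis, which the tests use as an independent
  read-back check.
- All randomness flows through explicit seeds: packing, dynamics noise
  and acceptance draws use separate seeded streams, so a (seed, config)
  pair reproduces an identical event log bit for bit.
- Writing then re-reading a template configuration reproduces every
  field bit-exactly (YAML float round-trip via `repr`).

## Known limitations

- The acetate parameter block in the packaged configuration is a
  synthetic stand-in (flagged in the file): values consistent with the
  0/−1 charge states and CGenFF-like magnitudes, not a published
  parameterisation.  The imidazolium/imidazole block is transcribed from
  a published Drude-force-field-style table.
- Single-bead residues have no orientational gate for transfers; contact
  distance is the only criterion, so channel selectivity differs from
  atomistic H-bond statistics.
- The toy conductivities and diffusivities are internally consistent but
  not comparable in magnitude to experimental ionic-liquid values; the
  engine exists to validate estimators, not to predict transport.
- Distance-dependent (Fermi-function) transfer probabilities and
  multi-proton species are not implemented.
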