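# Methods

`condfuse` simulates the coalescence and kinetic arrest of biomolecular
condensates with a coarse-grained two-flavor sticker–spacer polymer
model, and computes the observable suite used to characterize droplet
fusion.  This note records the model, the numerical choices, the
parameters that matter, and what the desk-scale test protocols do and do
not demonstrate.

## Model

Each chain is a bead–spring polymer (default 35 beads of 1000 Da, about
10 amino acids per bead).  Five beads at positions {4, 11, 18, 25, 32}
are *stickers* of one flavor (A/red or B/cyan); the rest are *spacers*.
Four potentials act (energies kcal/mol, lengths Å):

- **Backbone**: E = Kb (R − R0)², Kb = 3 kcal mol⁻¹ Å⁻², R0 = 10 Å.
- **Bending**: E = κ(1 − cos θ), κ = 2 kcal/mol.  θ is the *deflection*
  between successive bond vectors, so a straight chain has θ = 0 and zero
  energy.  (The other convention — interior angle at the middle bead —
  would make the hairpin the minimum; the straight-chain minimum is the
  one consistent with a flexible excluded-volume chain.)  The convention
  is written into run provenance.
- **Nonspecific LJ**: E = 4 Ens[(σ/r)¹² − (σ/r)⁶], σ = 10 Å, truncated
  plainly (unshifted) at 2.5σ; a `lj_shift` switch enables shifted
  truncation.  Ens sets the spacer-driven cohesion ("contacts").
- **Specific sticker bond**: a shifted harmonic
  E = [Es/(R0b − Rcut)²]·[(R − R0b)² − (Rcut − R0b)²] for R < Rcut, zero
  beyond; depth −Es at R0b = 1.122σ = 11.22 Å, zero exactly at
  Rcut = R0b + 1.5 Å = 12.72 Å.

Energies are quoted in kT at 310 K (1 kT = 0.616 kcal/mol) in configs
and converted once at load.

**Bond kinetics.** Every 20 steps: bonded pairs with R ≥ Rcut break with
probability p_off; then all unbonded complementary (A–B only) sticker
pairs with R < Rcut are enumerated, sorted nearest-first, and bonded
greedily with probability p_on, respecting valency 1 (a `pair_order:
random` switch exposes random resolution of competing candidates; the
break-before-form order is fixed).  Defaults p_on = p_off = 1 make the
kinetics purely distance-triggered; bond lifetime then grows as
exp(Es/kT) (verified: regression slope 0.875 over Es = 4–8 kT).  While
bonded, a pair's LJ interaction is suppressed and restored on breakage.
Newly formed bonds are born wherever the pair is inside Rcut, with no
formation barrier (diffusion-limited association).

**Dynamics.** BAOAB-split Langevin integration; friction force
−(m/damp)·v with damp = 500 fs, dt = 30 fs, T = 310 K; the O-step uses
the exact Ornstein–Uhlenbeck update, so equipartition holds for any
dt/damp.  Nonbonded interactions skip intrachain pairs one or two
backbone bonds apart (configurable).  Neighbor search is a Verlet list
over a periodic KD-tree at cutoff + skin (default skin 3 Å), rebuilt
when any bead has moved half a skin; its forces are asserted identical
to an all-pairs reference.  The hot pair loops have numba kernels with a
bit-equivalent numpy fallback.  Coordinates are kept *unwrapped* (pair
geometry always uses minimum image) so that cluster-level collective
variables remain continuous; writers wrap on output.

**Metadynamics.** Well-tempered Gaussian bias along either the system
radius of gyration of chain-center beads (bead n//2, 1-based — the 17th
bead of a 35-mer) or the distance between two labeled clusters'
chain-center centroids.  Hill height decays as exp(−V/(kB ΔT)),
ΔT = (γ−1)T; the PMF estimate is −γ/(γ−1)·V(s), min-shifted.  Defaults
w0 = 0.3 kcal/mol, σ_G = 2 Å (Rg) / 5 Å (distance), pace 500–1000
steps, γ = 8–10: widths of order the CV fluctuation scale of the test
systems, heights a fraction of kT so single hills do not kick the
dynamics.  The machinery is validated against an analytic double well
(overdamped 1-D reference integrator, RMSE < 0.5 kT).  Steering (moving
harmonic anchor) and harmonic walls are provided as protocol presets.

## Workflow protocols

The production-style workflow is: (1) *collapse* a dilute solution by
biasing the system Rg; (2) *relax* the single cluster unbiased at the
(Es, Ens) under study; (3) *duplicate* the relaxed cluster at a
center-of-geometry separation of 3 Rg (all beads; +x axis, fixed for
reproducibility) and *fuse* under a bias on the intercluster distance.
R_dist = R_clusters/σ_cluster with σ_cluster = 2 Rg of the relaxed
cluster, measured once before duplication and frozen (a hard-sphere
2·√(5/3)·Rg alternative is available).  Extent of fusion = 1 −
R_dist(t_f), reported raw (negative if clusters separate).

At desk scale two substitutions stand in for the very long biased runs:

- **Cluster construction**: `anneal_bonded_cluster` packs chains
  compactly, then repeatedly matches nearest free complementary stickers
  and pulls each matched pair with a temporary harmonic restraint while
  the normal bond kinetics run, under a weak Rg wall holding condensate
  density (target 1.5×10⁻³ beads/Å³).  Matching favors chain pairs not
  already bonded (caps 1 → 2 → ∞), so the network percolates instead of
  forming saturated chain couples.  This reproduces the *state* the long
  relaxation reaches — a percolated network at ~0.8–0.9 sticker
  occupancy and condensate density — not its kinetics.
- **Fusion bias**: a steered approach brings the clusters from 3 Rg to
  contact (1 σ_cluster), then well-tempered metadynamics confined by an
  upper wall at 1.1 σ_cluster explores interpenetration.  Plain hill
  deposition alone cannot drag free clusters tens of Å within desk-scale
  step budgets (the bias force needed to move a cluster against its
  friction, ~M/damp × drift speed, exceeds what slowly accumulating
  hills provide).

## What the desk-scale tests show — and what they do not

The synthetic systems reproduce: the analytic structure of all four
potentials; thermostat correctness; Arrhenius bond-lifetime scaling;
valency saturation; the bonded-network stability criterion (largest
component ≥ 0.9 at Es = 10 kT); bond-count conservation during fusion;
and a kinetic contrast in which Es = 15 kT clusters show *zero* bond
breaks while Es = 10 kT clusters exchange.

They do **not** reproduce the entropy-driven merger itself.  Measured
mean bond lifetime at Es = 10 kT is ≈ 2.4×10⁵ steps; production-scale
fusion runs span hundreds of lifetimes, while the suite's runs span one
to two.  With ~10 break events per run and nearest-first rebinding,
intercluster bonds effectively never form, so the rising C12/exchange-
entropy signature of successful fusion is out of reach at this scale;
the corresponding acceptance assertions are expected to fail and are
retained deliberately.  Test problem sizes: two 6-chain clusters
(3 per flavor, 420 beads), fusion runs of 2×10⁵ steps, three seed pairs.

Real condensates differ from the generator's systems in further ways:
chains here are monodisperse two-flavor heteropolymers with strictly
heterotypic, valency-1 stickers; there is no electrostatics, solvent, or
sequence heterogeneity; cluster sizes are orders of magnitude below
experimental droplets, so surface-to-volume ratios are exaggerated.

## Numerical details and edge cases

- Degenerate inputs are *flagged*, not raised, where a value is a valid
  limit: empty event log → NaN lifetime; zero bonds → NaN entropy;
  all-coincident beads → infinite density; < 4 or coplanar points → NaN
  hull ratio.  Geometry/contract violations raise (`ValueError`,
  `PackingError`, `ParseError`, `ConfigError`,
  `NumericalInstabilityError`).
- Entropy uses natural log (ln 3 ≈ 1.0986 matches the reported maximum
  1.1; log₂/log₁₀ do not), with 0·log 0 := 0.
- Packing is rejection sampling with a retry budget; failure suggests a
  larger box.  A capped-force pre-relaxation (cap 20–50 kcal mol⁻¹ Å⁻¹)
  removes packing overlaps before production dynamics.
- Bond-kinetics determinism: nearest-first matching makes `update_bonds`
  deterministic given positions when p_on = p_off = 1; trajectories are
  bitwise reproducible for a fixed seed.
- Contact counting (cutoff 22.44 Å) applies the same intrachain
  exclusions as the dynamics, for consistency between the two "contact"
  notions.
- Dissociation-event windows default to the snapshot cadence (events
  counted between successive observation points).
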