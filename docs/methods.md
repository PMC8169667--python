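# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `stunbh`.  Nothing here reports an empirical number that the
test suite or `scripts/acceptance.py` does not itself compute.

## Force field

Beads interact through harmonic bonds `0.5 k_b (r − r0)²`, harmonic angles
`0.5 k_a (θ − θ0)²`, and nonbonded 12-6 Lennard-Jones plus screened Coulomb
`k_e q_i q_j / (ε_r r)` terms.  Units are Å, fs, kJ/mol, amu, e and K;
`k_e = 1389.35 kJ mol⁻¹ Å e⁻²`; the relative dielectric defaults to 15, the
value appropriate for MARTINI-style CG electrostatics in water.

**Switching.**  Shifted CG force fields specify the *behaviour* (the
nonbonded potential goes smoothly to zero between an onset radius and the
cutoff) but not one canonical formula.  Each nonbonded pair term is
multiplied by the quintic polynomial `S(t) = 1 − 10t³ + 15t⁴ − 6t⁵`,
`t = (r − r_on)/(r_cut − r_on)`, which has `S = 1, S′ = S″ = 0` at the onset
and `S = 0, S′ = S″ = 0` at the cutoff.  Defaults: LJ onset 9 Å, Coulomb
onset 0.5 Å, cutoff 12 Å.  Energies and forces are therefore continuous
everywhere and exactly zero beyond the cutoff, which the tests verify
directly.

**Exclusions.**  Directly bonded (1-2) and angle-end (1-3) pairs are
excluded from nonbonded interactions — standard CG practice.

**Combination rules.**  Per-type σ/ε with Lorentz–Berthelot mixing; an
explicit pair table overrides individual type pairs (used by the pocket
fixture to make the groove lining attractive to nucleobase beads).

**Periodicity.**  Orthorhombic minimum-image convention for nonbonded
terms; bonded terms are never wrapped (molecules are kept whole).

**DMD scaling.**  The search's "discrete molecular dynamics" proposal mode
multiplies every nonbonded pair energy (LJ and Coulomb alike) by exactly
0.01, leaving bonded terms untouched.  No unscaled hard core is retained by
default: an optional repulsive floor was considered and rejected because
the uniform scaling is itself the documented move, and the subsequent
relaxation on the physical surface removes any overlaps it creates.

**Binding energy.**  The fixed-geometry decomposition evaluates four
single-point energies at identical coordinates — the full system, the
system without the receptor, the system without the ligand, and the
solvent/ion environment alone — and returns
`G_BE = G_complex − G_no_receptor − G_no_ligand + G_environment`.
The environment term cancels the solvent–solvent energy that the two
middle terms both contain; for a pairwise-additive potential the result
equals the ligand–receptor cross-pair sum *exactly*, which is the identity
the test suite enforces at 1e-8 kJ/mol.  This cross-group interaction
energy — not any re-solvated free energy — is also the search objective,
matching the method's definition of f(x); desolvation work is therefore
deliberately outside the objective (the solvent still shapes the dynamics
of every proposal move).

## Dynamics

Velocity Verlet with Berendsen velocity rescaling
`λ = sqrt(1 + (dt/τ)(T_target/T_inst − 1))`; τ defaults to 100 fs (the
coupling constant is not prescribed by the method, so it is a package
default exposed in the config).  Instantaneous temperature uses 3N − 3
degrees of freedom because the centre-of-mass momentum is removed at
velocity initialisation.  `τ = ∞` gives NVE, used by the energy-conservation
tests (drift < 1e-3 kJ/mol over 1 ps at dt = 1 fs for a dimer, with the
expected O(dt²) scaling).  The only unit conversion in the integrator is
exact: 1 amu (Å/fs)² = 1e4 kJ/mol.

Proposal moves resample Maxwell–Boltzmann velocities every iteration:
local minimization between iterations destroys any meaningful velocity
history, so carrying velocities over would only launder the previous
move's direction.

## Local minimization

FIRE is the default descent engine (dimensionless dt with unit
pseudo-masses, dt ∈ [0.01, 0.25], per-bead step capped at 0.4 Å); a scipy
conjugate-gradient option is provided, and a scipy L-BFGS-B option
(`method="lbfgs"`) is recommended for systems that mix stiff receptor
bonds with soft intermolecular modes — on such landscapes first-order
descent needs thousands of iterations where quasi-Newton needs hundreds.
All methods guarantee the returned energy never exceeds the input energy
and report a converged flag against a max-per-bead-force tolerance
(default 1e-2 kJ mol⁻¹ Å⁻¹).

## The STUN-BH-DMD search

* Transform: `E_STUN = asinh(f − f₀)`, with f₀ the best objective value so
  far.  New minima are accepted unconditionally and recentre the transform
  (`E_STUN(f₀, f₀) = 0`).
* Metropolis on the transformed surface: accept if `E_STUN ≤ STUN_last`,
  else accept iff `exp[(STUN_last − E_STUN)/kT] > u`.
* kT lives on the dimensionless transformed scale, so `kT₀ = 1` (an O(1)
  scale for a transform whose range is compressed to O(1)); the method
  prescribes the 20-step adaptation *goal* (50 % acceptance) but not the
  update rule, so the controller multiplies/divides by 1.2, clamped to
  [1e-6, 1e6].  The acceptance-targets script measures what this controller
  actually achieves on a 2000-iteration cluster search.
* Moves alternate MD and DMD parameters; relaxation and the objective
  always use the physical parameters — the DMD surface is a proposal
  distortion, not the potential of record.
* Multi-start: each start re-orients the receptor by a uniform random
  rotation about its mass centre (ligand and solvent untouched).  For
  receptor-free systems (cluster benchmarks) a Gaussian coordinate kick of
  configurable width substitutes for the rotation.
* Seeds: a master `SeedSequence` spawns one child per start; each child
  drives that chain's velocity draws and Metropolis decisions, so runs are
  exactly reproducible and individual starts replayable.

**Cluster benchmark settings.**  The published 600 K / 300-step move is
tuned to the MARTINI energy scale (ε ~ 2–5 kJ/mol).  A Lennard-Jones
benchmark cluster with ε = 1 kJ/mol needs a matched move temperature:
`cluster_move_settings` uses kB·T = 0.7 ε and 100-step moves, plus a
flat-bottom spherical restraint (k = 2 kJ mol⁻¹ Å⁻², radius
σ(0.5 + 0.45 n^⅓) about the instantaneous centre) that only acts outside
the radius — without it an open-boundary cluster simply evaporates during
hot moves.  With these settings the search recovers the analytic LJ3/LJ4
minima and the LJ7 multi-start-oracle minimum from ≥ 90 % of seeds within
a 60-iteration budget (the suite runs 20 seeds).

## Pathways

`pull_path` generates an initial chain by steering the ligand–receptor
COM distance outward under a harmonic restraint (default
k = 50 kJ mol⁻¹ Å⁻², 0.01 Å per 10 fs step, low-temperature dynamics
between snapshots) and minimizing each snapshot with the restraint held at
its image distance.  `neb_relax` then applies the nudged elastic band with
the improved-tangent formulation: perpendicular true force plus a spring
force (default 10 kJ mol⁻¹ Å⁻²) along the tangent, endpoints frozen, FIRE
descent on all interior images jointly; a climbing-image variant is
available behind a flag but off by default.  Only ligand and receptor
coordinates enter the band metric — solvent beads feel the plain true
force — so solvent permutation cannot distort the path.  On the quartic
double well `(x² − 1)²` with 16 images the relaxed band recovers the unit
barrier within 1 % and a profile symmetric to machine precision, and
refining 8 → 16 → 32 images approaches the analytic barrier monotonically.
The barrier is reported as max(total energy) − reactant energy together
with the transition-state image and the binding-onset image (first image
whose ligand–receptor energy drops below zero).

## Trajectory analyses

* RMSD: mass-unweighted, optional Kabsch superposition.
* Radius of gyration: mass-weighted and normalised by total mass,
  `Rg = sqrt(Σ mᵢ|rᵢ − r_COM|²/Σ mᵢ)`.  A `literal_unnormalized` variant
  (no division by total mass) is kept for compatibility with the
  unnormalised form sometimes printed for this monitor; it is
  dimensionally amu^½·Å and useful only as a relative stability signal.
* RMSF: frames superposed on the receptor beads to the window-mean
  structure (two fixed-point passes), per-bead RMS fluctuation, averaged
  within each ligand nucleobase (a per-bead mode is available; whether the
  per-nucleobase figure should average beads or use nucleobase COMs is a
  convention choice — bead averaging is the default here).
* COM distance traces: per frame, minimum-image, optionally split per
  nucleobase.
* Interaction map: the time-mean ligand–receptor cross-pair energy binned
  by (receptor residue, ligand nucleobase).  Column sums are definitionally
  the per-nucleobase histogram and the matrix total equals the time-mean
  total interaction energy — identities the tests check at 1e-8.  The
  highlight threshold defaults to −8.4 kJ/mol, the level conventionally
  used to flag persistent CG contacts.
* Solvent shells: strict `distance < cutoff` semantics, KD-tree
  implementation cross-checked against an O(N²) minimum-image scan.

## Synthetic systems

The fixture generator emulates the *structure* of an aptamer/protein
search problem, not its chemistry:

* LJ clusters — benchmark surfaces with analytically known global minima.
* A pocket receptor — a U-shaped groove with walls on a 5 Å lattice and a
  floor on a half-spacing (2.5 Å) sub-lattice, held near-rigid by harmonic
  bonds between lattice neighbours rather than frozen, so minimization and
  MD treat all beads uniformly.  The dense floor matters: with bead
  spacing well below σ the surface presents no site-registration wells, so
  the bound pose's energy is smooth under translation instead of jumping
  between lattice registrations.  Only the pocket-lining floor strip
  attracts the ligand's nucleobase beads (pair-table ε = 3 kJ/mol);
  backbone-floor attraction is an order of magnitude weaker and the walls
  are essentially steric (ε = 0.05), so exactly one contact topology —
  bases down on the pocket strip — dominates, rather than a family of
  corner- and side-contact poses within a few percent of each other.  The
  ligand is a chain of backbone beads (5 Å rest bonds) each carrying one
  pendant nucleobase bead, with angle terms keeping the comb shape
  defined; stiffness is adjustable (defaults k_b = 300 kJ mol⁻¹ Å⁻²,
  k_a = 200 kJ mol⁻¹ rad⁻²).  In the bound optimum the bases press into
  the compliant dense surface, which yields locally (receptor
  k = 400 kJ mol⁻¹ Å⁻²) until contact saturates; because the surface
  response is the same wherever the ligand binds on the strip, that
  optimum is sharply reproducible, which is what makes an
  optimizer-vs-optimizer energy comparison at the percent level
  well-posed.  The pose-recovery tests use a reduced variant (5×4 floor
  cells, 3-residue ligand stiffened to k_b = 2000 / k_a = 1500, 5 Å
  walls): a near-rigid ligand is required for a rigid-pose orientation
  grid to be a valid independent ground truth, and the shallow wall lets
  rigidly placed poses enter the groove without clashing.
* Solvation — water beads (72 amu ≈ 4 waters, σ = 4.7 Å, ε = 5 kJ/mol,
  neutral) inserted by batched rejection sampling to a target mass density
  (default 1 g/cm³), at least 5 Å from any solute bead and 4 Å from other
  waters (pure hard-core insertion at 5 Å water–water would jam below the
  target density).  Counterions convert randomly chosen water beads in
  place until the total charge is zero, conserving the bead count.

What passing tests on these fixtures show: the search machinery,
bookkeeping, controller and analyses behave as specified on systems whose
ground truth is known.  What they do not show: fidelity to any real
protein/aptamer complex — the fixtures have no sequence specificity, no
real MARTINI parameter set, no antifreeze particles (an ordinary bead type
here), and far fewer solvent beads than a production system.

## Problem sizes and budgets

The shipped tests and the acceptance script run on deliberately small
systems — LJ clusters of 3–13 beads, a 41–104-bead pocket complex, toy
solvated boxes of ≤ 1000 beads, 2000-iteration single-chain searches —
sizes chosen so the full suite completes on one CPU in minutes while still
exercising every code path at meaningful statistics.  The production-scale
operating point (tens of thousands of solvent beads, 4000 starts × 100
iterations) is reachable through the same API but is not what the tests
measure.

## Known limitations

* No neighbour lists: energies/forces are O(N²) per evaluation, fine for
  the intended 10²–10⁴ bead range, not for much larger systems.
* Berendsen rescaling does not sample a strict canonical ensemble; it is
  used here (as in the source method) as a robust relaxation thermostat.
* The fixed-geometry binding energy excludes desolvation/entropic terms by
  design; it is a pose-ranking objective, not a free energy.
* Plain NEB without climbing image locates the barrier to the resolution
  of the image spacing (≈ 1 % at 16 images on the toy surface).
* PDB round trips quantise coordinates to 3 decimals (format limit);
  in-memory coordinates are never rounded.
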