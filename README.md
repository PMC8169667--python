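# stunbh

Global-minimum search and pathway analysis for coarse-grained (CG)
ligand/receptor bead complexes in explicit bead solvent, built around the
stochastic tunnelling–basin hopping–discrete molecular dynamics
(STUN-BH-DMD) method.

## Who this is for

Molecular modellers who want to locate low-lying binding poses of a
flexible ligand (e.g. a ssDNA aptamer in a MARTINI-style representation)
on a receptor protein in water without running brute-force MD, and then
characterise the result: minimum-energy adsorption pathways (NEB),
per-residue interaction maps, and standard trajectory observables.

## The method

The objective is the ligand–receptor interaction energy
f(x) = Σ cross-group pairs [LJ + screened Coulomb], evaluated on relaxed
structures.  The search walks on basin minima:

1. **Move** — a short burst of hot NVT dynamics (default 300 × 10 fs at
   600 K), alternating between the physical potential (MD) and one whose
   nonbonded strengths are uniformly reduced to 1/100 (DMD), which lets
   trapped ligand fragments rearrange freely.
2. **Relax** — local minimization (FIRE, conjugate-gradient, or L-BFGS)
   on the physical surface maps the move to its basin minimum.
3. **Tunnel** — the objective is transformed through

   E_STUN(x) = ln( (f(x) − f₀) + √((f(x) − f₀)² + 1) ) = asinh(f(x) − f₀),

   where f₀ is the lowest binding energy found so far.  The transform
   compresses the landscape above f₀ so Metropolis dynamics can cross
   high barriers.
4. **Accept** — a new minimum (f < f₀) is always accepted and resets f₀;
   otherwise the step is accepted iff
   exp[(STUN_last − E_STUN)/kT] exceeds a uniform random number.  kT is
   re-tuned every 20 steps (×/÷ 1.2) toward 50 % acceptance.
5. **Multi-start** — the receptor is rigidly re-oriented uniformly at
   random about its mass centre for each independent start.

Around the search the package provides the full toolchain: a shifted
MARTINI-style bead force field (quintic switching to exactly zero at the
cutoff), velocity-Verlet NVT dynamics with Berendsen rescaling,
solvation/counterion fixture generators, steered-pulling + nudged-elastic-band
pathways with barrier reports, and analyses (RMSD, radius of gyration,
per-nucleobase RMSF and COM distances, residue×nucleobase interaction-energy
maps with the −8.4 kJ/mol contact threshold, solvent-shell counts).

## Worked example

Find the global minimum of a 4-bead Lennard-Jones cluster (the analytic
answer is a regular tetrahedron with all six pairs at the pair-minimum
distance, E = −6 ε):

```python
from stunbh.stun_search import run_search
from stunbh.synthetic import cluster_move_settings, lj_forcefield, make_lj_cluster

ff = lj_forcefield(sigma=4.7, epsilon=1.0)          # kJ/mol, Angstrom
topo, conf = make_lj_cluster(4, seed=2)
res = run_search(conf, topo, ff, n_starts=2, iters_per_start=15, seed=0,
                 move=cluster_move_settings(4), objective="total",
                 start_perturbation=2.0)
print(f"best energy: {res.best_f:.6f} kJ/mol")
print(f"acceptance:  {res.log.loc[res.log['mode'] != 'init', 'accepted'].mean():.2f}")
```

prints

```
best energy: -5.999990 kJ/mol
acceptance:  1.00
```

i.e. the search reaches the tetrahedral global minimum (−6 ε, here
ε = 1 kJ/mol) to the minimizer tolerance; the acceptance column of the
per-iteration log shows how often proposals were kept.  The same call with
`objective="binding"` on a solvated ligand/receptor system returns the
lowest ligand–receptor interaction energy and the pose that achieves it.

The command-line interface wraps the same functions:

```bash
stunbh synth pocket --out pocket --seed 1
stunbh search --system pocket --out run --starts 4 --iters 25 --seed 1
stunbh neb --system run/best --out mep --images 16
stunbh analyze imap --system pocket --traj traj.xyz --out imap.tsv
```

Every run writes a reproducibility manifest (config hash, seed, versions)
next to its outputs.

## Units

Angstrom, femtosecond, kJ/mol, amu, elementary charge, Kelvin throughout;
Coulomb prefactor 1389.35 kJ mol⁻¹ Å e⁻² divided by the relative
dielectric (default 15).  See `docs/methods.md` for the model details,
parameter defaults and their rationale, and known limitations.
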