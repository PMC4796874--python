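# Methods

This note documents the models, numerical choices, and limitations behind
focuswalk, in the order the pipeline runs them.

## Physical model and units

Both bodies are rigid: fixed internal geometry and fixed partial charges.
Lengths are in Å, charges in elementary charge e, energies in kcal/mol,
temperatures in K. Potentials are carried internally in kT/e at the problem
temperature and converted with 1 kT = 0.0019872·T kcal/mol; the Coulomb
constant is 332.0637 kcal·Å/(mol·e²). These constants are fixed in
`constants.py` so every conversion is bit-reproducible.

The solvent is implicit: a two-dielectric model (solute ε_in = 2 inside the
van der Waals union of atom spheres, solvent ε_out = 80 outside) with
linearized mobile-ion screening at ionic strength I (default 150 mM 1:1 salt)
wherever ions can reach — screening is switched off within radius + Stern
layer (default 2 Å) of any atom. The Debye constant follows from
ε_s κ² = 8π C(T) n with n the ion density; at 150 mM, 298 K this gives a
Debye length of ≈7.9 Å.

The van der Waals surface (not a solvent-probe reentrant surface) defines the
dielectric boundary. This is the simplest surface that is exactly testable by
a brute-force midpoint oracle; it under-fills reentrant crevices relative to a
molecular-surface definition, which mostly affects absolute solvation energies
of multi-atom solutes, not the landscape differences the Monte Carlo engine
consumes.

## Finite-difference PB solver

The linearized PB equation is discretized on a cubic grid (node (i,j,k) at
origin + h·(i,j,k), 0-based) with the standard 7-point stencil:

* charges spread to the 8 surrounding nodes by trilinear weights (total grid
  charge equals total atomic charge exactly);
* dielectrics sampled at edge midpoints (edge-centered arrays, one shorter
  along their axis);
* the screening coefficient ε_s κ² = 8π C n applied on ion-accessible nodes.

The system is solved by checkerboard (red-black) successive over-relaxation
with ω = 2/(1 + sin(π/N)), N the largest grid dimension — the asymptotically
optimal ω for the uniform-coefficient problem and a good default for the
mildly heterogeneous ones here. Convergence is declared on the relative
residual ‖Aφ − b‖₂/‖b‖₂ over interior nodes (b includes source and
boundary inflow), default tolerance 1e-6, default iteration cap 10,000;
non-convergence raises an error carrying the residual history. A scipy sparse
direct solve of the identical system is the independent oracle in the test
suite (agreement to 1e-6 relative on a 9³ grid).

Boundary conditions: `zero`, `coulombic_debye` (the default parent condition:
the sum of per-charge Debye-screened Coulomb potentials, the standard
far-field closure), or `focused` (all boundary nodes fixed by trilinear
interpolation from a parent potential). Grid self-energy is never reported:
every energy is a difference of solves on identical grids, so the
grid-dependent self-term cancels exactly.

A resolution of 2 grids/Å is the reference fine resolution throughout; at that
spacing the solver reproduces Coulomb 1/r scaling to <1%, Debye–Hückel
screening to ~3% at 5–12 Å, and the analytic Born solvation energy of a
q = 1 e, R = 2 Å ion (−82.0 kcal/mol) to ~5%.

## Computational focusing

A child run rebuilds charge, dielectric, and ion maps on its own (finer) grid
from the same structures, fixes every boundary node to the interpolated parent
potential, and re-solves. Children may sit anywhere strictly inside the
parent, need not align with parent nodes, and may nest (each level increments
`level`). Atoms within 1.5 nodes of the child boundary are not charge-spread
on the child grid (their spreading would touch fixed boundary nodes); they
enter through the boundary condition instead, exactly as atoms outside the
child box do.

Validation: for a single charge in uniform ε = 80, a 32 Å child at 2 grids/Å
inside a 64 Å parent at 1 grid/Å matches a direct global 129³ fine solve to
0.03% max relative deviation over interior nodes >4 Å from the charge, and the
deviation decreases monotonically as the parent box grows (48 → 64 → 80 Å).

## Pose lattice and rigid transforms

Poses are (x, y, z, φ, θ, Ψ): mass-center station plus intrinsic Z-Y-Z Euler
angles (the classical convention; it determines rotamer identity, so it is
fixed and documented). Stations discretize each geometry coordinate
inclusively (both range ends are stations: −88…88 Å at 4 Å gives 45).
Cylindrical geometry uses (longitudinal, radial-from-axis, lateral-angle)
coordinates; longitudinal is the axial coordinate used for directionality.
"N rotamers" selects N deterministic low-discrepancy orientations (body axis
on a Fibonacci spiral, Ψ = 0); an explicit rotamer list or a structured
per-angle grid (with wrap-around adjacency for full-circle φ/Ψ grids) may be
supplied instead. The lattice is fully deterministic — no RNG anywhere in
sampling.

`apply_pose` rotates about the body's geometric center then translates the
center to the station; being orthogonal, it preserves internal distances to
<1e-9 Å (machine precision in practice).

## Energy module

E_total = E_coul + E_solv + E_vdw per pose, all soft-clamped: distances below
1 Å (configurable) are reset to 1 Å in both the Coulomb and Lennard-Jones
sums, making the landscape finite and continuous through small rigid-body
clashes. LJ parameters combine by Lorentz–Berthelot (σ arithmetic mean,
ε geometric mean).

Two electrostatic routes:

* `pairwise` — closed-form soft Coulomb in uniform solvent dielectric,
  E_solv = 0. No screening; fast and exactly linear in the charges. This is
  the route used for desk-scale landscape statistics.
* `field` — the screened interaction Σ qᵢ φ_receptor(rᵢ) from a focused child
  solve around the pose region (children cached per station region; exactly
  one parent solve per table, verified by the test suite). The three-term
  report keeps E_coul as the uniform-dielectric Coulomb value and stores the
  (screened − Coulomb) difference in E_solv, so the decomposition always sums
  to the physical total while the split remains explicitly diagnostic: how a
  screened single-field interaction should be split between "Coulomb" and
  "solvation" is a modeling convention, not an observable.

Pose-independent desolvation of the rigid bodies is omitted: the Monte Carlo
engine only consumes energy differences between poses, in which such terms
cancel. The ligand is treated as a set of test charges in the field route
(its own dielectric cavity does not perturb the receptor field); this is the
price of reusing one receptor field for every pose, and it is consistent with
the rigid-landscape approximation.

Tables are deterministic for fixed inputs and byte-identical for any worker
count (poses are computed independently and written back by index).

## Monte Carlo pathway engine

The walker proposes one move per step, drawn uniformly from the ±1
single-coordinate move set over non-singleton lattice dimensions; a move that
would leave the lattice is a null proposal, counted as a rejected attempt.
This kernel is symmetric everywhere — including boundaries, where
"uniform among current neighbors" would not be — so plain Metropolis
acceptance (accept if ΔE ≤ 0, else with probability exp(−ΔE/kT)) has
exp(−E/kT)/Z as its exact stationary distribution. Rejected attempts
re-record the current state, so occupancy histograms weight states by
Boltzmann dwell time. A long non-terminating run on a 3-state (0, kT, 2kT)
table reproduces 1 : e⁻¹ : e⁻² occupancy to <1%.

Pathways start at a user-set lattice index and terminate when the axial
displacement of the mass center reaches the termination distance (80 Å by
default — one filament repeat), recording `plus_end` or `minus_end` by sign;
a `max_steps` cap (default 10⁷) guards non-terminating walks. The default
temperature, 500 K, is deliberately above physiological: the extra thermal
energy stands in for external (e.g. ATP-derived) energy that pulls a motor
out of its binding funnel, so finite runs can escape ~kcal/mol wells.

RNG: numpy PCG64. Draw order is documented and fixed — one integer draw per
proposal, one uniform draw per Metropolis test with ΔE > 0 — consumed from
two independent buffers refilled in blocks of 8192, so a pathway is
byte-reproducible from its seed. Ensembles give pathway i the i-th spawn of
the ensemble seed. For small lattices, `absorption_probability` builds the
full one-step transition matrix of this exact kernel and solves the absorbing
linear system, providing an exact reference for directional probabilities
(simulated minus exact ≈ 0.003 at 1000 pathways on a 45-station ramp).

## Synthetic fixtures and what they do (and do not) show

All fixtures are pseudo-atom constructions, bit-reproducible from their
parameters and seed.

* **Born ion** — single charged sphere; closed-form solvation oracle.
* **Nanoparticle** — n sites quasi-uniform on a sphere (Fibonacci spiral,
  tangential jitter from the seed), each carrying net_charge/n. Default
  +32 e, radius 10 Å, 64 sites: a uniformly charged control ligand with
  near-zero dipole, whose pathways should show no directional preference.
* **Toy filament** — negative charge sites every `repeat` Å (default 80 Å,
  the tubulin-dimer scale) along `n_protofilaments` axial lines (default 3)
  on a 30 Å cylinder, 320 Å long. The default site charge (−0.25 e) keeps the
  control-ligand landscape corrugation at a few kT at the 500 K walk
  temperature, so walkers diffuse along the filament instead of freezing into
  one well — the regime the ensemble statistics probe.
* **Tilted filament** — site charges scaled linearly in z so successive
  binding wells of the control landscape deepen toward +z by a stated
  kcal/mol per repeat. Because the landscape is linear in the site charges,
  the realized bias can be calibrated exactly: the generator decomposes the
  contact-line profile as E₀(z) + s·D(z) and fixes the slope s by a short
  fixed-point iteration so the mean well-to-well drop matches the request
  (finite-filament edge effects included). Scale factors clamp at zero so no
  site changes sign.

Default study conditions for the directionality statistics mirror the
cylindrical production geometry: longitudinal −88…88 Å at 4 Å (45 stations),
surface offsets 0–20 Å (axis distances 40–60 Å for the default fixture pair),
lateral ±28° at 4°, termination 80 Å, T = 500 K, 1000 pathways. On these
conditions the symmetric control gives p_plus = 0.50 within sampling error
and a 2 kcal/mol-per-repeat tilt gives p_plus ≈ 0.78.

What passing these tests does *not* show: the fixtures have no conformational
flexibility, no protonation changes, no reentrant surface chemistry, and
pairwise-route landscapes have no salt screening; quantitative agreement with
experiments on real motor/filament systems requires the atomistic structures
and the field route at production scale, which is outside the desk-scale test
envelope.

## Numerical and engineering choices

* Grids are cubic with odd dims (a center node exists); `make_grid` caps dims
  and points the user to focusing when the cap would be exceeded.
* Trilinear interpolation everywhere a field is evaluated off-node (site
  potentials, child boundaries, reaction-field probes), order-preserving.
* Energy tables persist as CSV (full 6D index + terms); potential maps as
  OpenDX text (interoperable with APBS/PyMOL/VMD tooling, ~6 significant
  digits) or a numpy .npz container with grid metadata that round-trips
  bit-exactly.
* The pipeline manifest records a sha256 per artifact and the config hash;
  reruns skip stages whose inputs and outputs both verify.
* Problem sizes in the test suite (≤129³ parents, ≤4050-pose tables,
  10⁶-step equilibrium runs, 1000-pathway ensembles) were chosen so the full
  suite and the acceptance script each complete in a few minutes on one CPU.

## Known limitations

Linearized PB only (no nonlinear option); vdW dielectric surface; rigid
bodies with fixed charges; no kinetics mapping of MC steps to time; no
periodic boundaries or membrane slab dielectrics; single-node parallelism
only (worker threads over poses). The pairwise route ignores screening and
desolvation by construction; the field route treats the ligand as test
charges. These are deliberate scope boundaries, not accidental gaps.
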