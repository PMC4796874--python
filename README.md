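# focuswalk

Multiscale implicit-solvent electrostatics for rigid-body binding of a small
ligand to a very large receptor — the regime of a kinesin motor domain walking
along a complete microtubule, an antibody approaching a virus capsid, or a
charged nanoparticle diffusing on a filament. Before physical docking, binding
in these systems is steered mostly by long-range electrostatics, and truncating
the receptor to make the calculation affordable silently removes the forces of
interest. focuswalk keeps the whole receptor in the calculation and spends
resolution only where it matters.

## What it computes

**1. Electrostatic potential, with computational focusing.** The linearized
Poisson–Boltzmann (PB) equation

```
∇·(ε ∇φ) − ε_s κ² φ = −4π C Σᵢ qᵢ δ(r − rᵢ)
```

is solved by finite differences (7-point stencil, edge-centered dielectrics,
red-black SOR) on a regular grid, with φ in kT/e. A coarse *parent* run covers
the entire system; *child* runs re-solve any interior sub-box at higher
resolution using the trilinearly interpolated parent potential as a Dirichlet
boundary condition, and can be nested to any depth. Many child runs share one
parent run, so a full landscape costs one global solve plus cheap local solves.

**2. Pose energies.** Ligand placements form a discrete 6D lattice
(x, y, z, φ, θ, Ψ): mass-center stations in cuboidal, spherical, or
cylindrical geometry crossed with a rotamer set. Each pose gets a three-term
energy

```
E_total = E_coul + E_solv + E_vdw
```

with soft-clamped Coulomb and Lennard-Jones sums (any interatomic distance
below 1 Å is reset to 1 Å, so small rigid-body clashes stay finite) and, in
the `field` method, the screened electrostatic term Σᵢ qᵢ φ(rᵢ) from a focused
child solve. Energies are stored in a pose → energy lookup table.

**3. Binding pathways.** A Metropolis Monte Carlo walker moves on the pose
lattice using the lookup table: a random ±1 single-coordinate move is accepted
when ΔE ≤ 0 and with probability exp(−ΔE/kT) otherwise. Pathways terminate
when the ligand has drifted a set distance along the lattice axis (plus or
minus end), and ensembles of pathways yield directional probabilities
(p_plus with binomial standard error) and station occupancy histograms.

Synthetic fixtures with known ground truth — Born ions, a uniformly charged
+32 e nanoparticle control, and periodic charged filaments with an optional
axial energy tilt — make every layer testable on one CPU with no downloads.

## Worked example

A uniformly charged nanoparticle on a mirror-symmetric toy filament has no
reason to drift either way; on a filament whose binding wells deepen by
~2 kcal/mol per 80 Å repeat it should drift toward the plus end:

```python
import focuswalk as fw

lattice = fw.generate_lattice(
    "cylindrical",
    ranges={"longitudinal": (-88, 88), "radial": (40, 60), "lateral": (-28, 28)},
    steps={"longitudinal": 4.0, "radial": 4.0, "lateral": 4.0},
)
config = fw.MCConfig(start_index=(22, 0, 7, 0, 0, 0), temperature=500.0,
                     termination_distance=80.0, seed=11)

for name, receptor in [("symmetric", fw.make_toy_filament()),
                       ("tilted", fw.make_tilted_filament(gradient=2.0))]:
    table = fw.build_energy_table(receptor, fw.make_nanoparticle(), lattice)
    stats = fw.ensemble_stats(fw.run_ensemble(table, config, 1000), lattice)
    print(f"{name:9s} p_plus = {stats.p_plus:.3f} +/- {stats.se_p_plus:.3f}")
```

prints (seed 11):

```
symmetric p_plus = 0.514 +/- 0.016
tilted    p_plus = 0.798 +/- 0.013
```

i.e. the symmetric control is statistically indistinguishable from 0.5, while
a 2 kcal/mol-per-repeat charge asymmetry alone biases three out of four
pathways toward the plus end. The same stages run from a single YAML config
via the CLI: `focuswalk run --config run.yaml` (stages: parameterize → sample
→ energize → walk → stats, with a checksummed resume manifest).

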