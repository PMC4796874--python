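"""Deterministic synthetic structures with known ground truth.

These generators make the whole pipeline testable without any download:

* Born ions -- single charged spheres with a closed-form solvation energy;
* uniformly charged spherical nanoparticles (the +32 e control ligand: a
  ligand with no charge asymmetry, hence no directional preference);
* toy periodic charged filaments -- a cylinder with negative charge sites
  every ``repeat`` Å along each protofilament line, emulating the periodic
  electrostatic potential valleys of a microtubule (tubulin-dimer repeat
  ~80 Å);
* tilted filaments -- the same filament with site charges scaled linearly
  along the axis so binding wells deepen toward the plus end by a stated
  energy per repeat, giving the directionality machinery a ground-truth bias.

Fixtures are built from pseudo-atoms (charge sites): the method operates on
atoms-with-parameters and is indifferent to chemistry.  Everything is
bit-reproducible from (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .structures import (
    ParameterizedStructure,
    fibonacci_sphere,
    from_arrays,
    write_parameter_table,
    write_pdb,
)

#: pseudo-atom defaults: site radius Å, LJ parameters
SITE_RADIUS = 2.0
SITE_LJ_EPSILON = 0.05
SITE_LJ_SIGMA = 3.0


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative fixture description (used by the CLI and the pipeline)."""

    kind: str  # born_ion | nanoparticle | toy_filament | tilted_filament | point_charge
    params: tuple = ()  # sorted (key, value) pairs
    seed: int = 0

    @staticmethod
    def make(kind: str, seed: int = 0, **params) -> "FixtureSpec":
        return FixtureSpec(kind=kind, params=tuple(sorted(params.items())), seed=seed)


def build_fixture(spec: FixtureSpec) -> ParameterizedStructure:
    params = dict(spec.params)
    if spec.kind in ("born_ion", "point_charge"):
        return make_born_ion(**params)
    if spec.kind == "nanoparticle":
        return make_nanoparticle(seed=spec.seed, **params)
    if spec.kind == "toy_filament":
        return make_toy_filament(**params)
    if spec.kind == "tilted_filament":
        return make_tilted_filament(**params)
    raise ValueError(f"unknown fixture kind {spec.kind!r}")


def make_born_ion(q: float = 1.0, radius: float = 2.0) -> ParameterizedStructure:
    """A single charged sphere at the origin; LJ parameters zeroed."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    return from_arrays(
        coords=[[0.0, 0.0, 0.0]],
        charges=[q],
        radii=[radius],
        lj_epsilon=[0.0],
        lj_sigma=[1.0],
        names=["QB"],
        residues=["ION"],
        label="born_ion",
    )


def make_nanoparticle(
    radius: float = 10.0,
    net_charge: float = 32.0,
    n_sites: int = 64,
    seed: int = 0,
    jitter: float = 0.02,
) -> ParameterizedStructure:
    """A uniformly charged spherical nanoparticle.

    ``n_sites`` pseudo-atoms sit quasi-uniformly on the sphere (Fibonacci
    spiral, tangentially jittered by up to ``jitter`` rad from the seed), each
    carrying net_charge/n_sites.  The default +32 e matches experimentally
    studied nanoparticles and serves as the uniform-charge control: its lack
    of charge asymmetry should produce no directional preference.
    """
    if n_sites < 4:
        raise ValueError("n_sites must be >= 4")
    dirs = fibonacci_sphere(n_sites)
    if jitter > 0:
        rng = np.random.Generator(np.random.PCG64(seed))
        pert = rng.normal(scale=jitter, size=(n_sites, 3))
        pert -= dirs * np.sum(pert * dirs, axis=1, keepdims=True)  # tangential
        dirs = dirs + pert
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    q = net_charge / n_sites
    return from_arrays(
        coords=radius * dirs,
        charges=np.full(n_sites, q),
        radii=np.full(n_sites, SITE_RADIUS),
        lj_epsilon=np.full(n_sites, SITE_LJ_EPSILON),
        lj_sigma=np.full(n_sites, SITE_LJ_SIGMA),
        names=["QN"] * n_sites,
        residues=["NPA"] * n_sites,
        label="nanoparticle",
    )


def make_toy_filament(
    length: float = 320.0,
    repeat: float = 80.0,
    radius: float = 30.0,
    site_charge: float = -0.25,
    n_protofilaments: int = 3,
) -> ParameterizedStructure:
    """A periodic charged filament along +z, centered at the origin.

    Negative charge sites are placed every ``repeat`` Å from -length/2 to
    +length/2 on each of ``n_protofilaments`` equally spaced axial lines at
    the cylinder radius (the first line at lateral angle 0).  The default
    site charge (-0.25 e) keeps the control-ligand landscape corrugation at a
    few kT at the elevated Monte Carlo temperature, so walkers diffuse along
    the filament rather than freezing into one well -- the regime the
    pathway statistics probe.
    """
    if repeat > length:
        raise ValueError("repeat must be <= length")
    if n_protofilaments < 1:
        raise ValueError("n_protofilaments must be >= 1")
    zs = np.arange(-length / 2.0, length / 2.0 + 1e-9, repeat)
    coords = []
    for k in range(n_protofilaments):
        alpha = 2.0 * math.pi * k / n_protofilaments
        x, y = radius * math.cos(alpha), radius * math.sin(alpha)
        for z in zs:
            coords.append((x, y, z))
    n = len(coords)
    return from_arrays(
        coords=np.asarray(coords),
        charges=np.full(n, site_charge),
        radii=np.full(n, SITE_RADIUS),
        lj_epsilon=np.full(n, SITE_LJ_EPSILON),
        lj_sigma=np.full(n, SITE_LJ_SIGMA),
        names=["QS"] * n,
        residues=["FIL"] * n,
        label="toy_filament",
    )


def make_tilted_filament(
    gradient: float = 2.0,
    length: float = 320.0,
    repeat: float = 80.0,
    radius: float = 30.0,
    site_charge: float = -0.25,
    n_protofilaments: int = 3,
    reference_well_depth: Optional[float] = None,
) -> ParameterizedStructure:
    """A toy filament whose binding wells deepen toward +z.

    Site charges are scaled linearly along the axis so that successive wells
    of the control-ligand landscape deepen toward the plus end by
    approximately ``gradient`` kcal/mol per repeat.  Because the landscape is
    linear in the site charges, scaling the sites near z by f(z) scales the
    local well minimum by f(z); the calibration reference is therefore the
    well depth of the default +32 e nanoparticle in surface contact with the
    base filament (pairwise soft-Coulomb route); pass ``reference_well_depth``
    to override.  Scale factors are clamped at zero so no site changes sign.
    """
    base = make_toy_filament(length, repeat, radius, site_charge, n_protofilaments)
    if gradient == 0.0:
        return base
    if reference_well_depth is not None:
        if reference_well_depth <= 0:
            raise ValueError("reference_well_depth must be > 0")
        slope = gradient / reference_well_depth
    else:
        slope = math.copysign(
            _calibrate_tilt_slope(base, repeat, radius, abs(gradient)), gradient
        )
    z = base.coords[:, 2]
    scale = np.maximum(0.0, 1.0 + slope * z / repeat)
    out = base.copy()
    out.charges = base.charges * scale
    # distinct charges need distinct parameter-table identities
    out.names = [f"Q{i + 1}" for i in range(out.n_atoms)]
    out.label = "tilted_filament"
    return out


def _calibrate_tilt_slope(
    filament: ParameterizedStructure, repeat: float, radius: float, gradient: float
) -> float:
    """Per-repeat charge-scale slope realizing ``gradient`` kcal/mol per repeat.

    Scaling site charges by f(z) = 1 + s z/repeat changes the control-ligand
    Coulomb landscape linearly in s, so the profile along a surface-contact
    line decomposes as E_s(z) = E0(z) + s D(z).  The realized bias is the mean
    difference between successive well minima (windows one repeat wide around
    the three central wells); a short fixed-point iteration on s matches it to
    the requested gradient, absorbing finite-length edge effects that a naive
    well-depth estimate misses.
    """
    from .energies import soft_coulomb

    nano = make_nanoparticle()
    contact_r = radius + 10.0  # filament radius + nanoparticle radius, contact
    zline = np.arange(-1.5 * repeat, 1.5 * repeat + 1e-9, repeat / 20.0)
    site_w = filament.coords[:, 2] / repeat
    e0 = np.empty(len(zline))
    d = np.empty(len(zline))
    for i, zc in enumerate(zline):
        coords = nano.coords + np.array([contact_r, 0.0, zc])
        e0[i] = soft_coulomb(
            coords, nano.charges, filament.coords, filament.charges, eps=80.0
        )
        d[i] = soft_coulomb(
            coords, nano.charges, filament.coords, filament.charges * site_w, eps=80.0
        )
    if e0.min() >= 0:
        raise ValueError("filament landscape has no attractive binding well")

    windows = [np.abs(zline - k * repeat) <= repeat / 2.0 for k in (-1, 0, 1)]

    def realized(s: float) -> float:
        prof = e0 + s * d
        mins = [prof[w].min() for w in windows]
        return 0.5 * ((mins[0] - mins[1]) + (mins[1] - mins[2]))

    s = gradient / max(1e-12, -float(e0.min()))
    for _ in range(8):
        r = realized(s)
        if r <= 0:
            s *= 2.0
            continue
        s *= gradient / r
    return s


def parameter_table_for(structure: ParameterizedStructure) -> dict:
    """A parameter table reproducing the structure's per-atom parameters.

    Requires (residue, atom-name) pairs to identify parameters uniquely,
    which the fixture generators guarantee.
    """
    table = {}
    for i in range(structure.n_atoms):
        key = (structure.residues[i], structure.names[i])
        entry = {
            "charge": float(structure.charges[i]),
            "radius": float(structure.radii[i]),
            "lj_epsilon": float(structure.lj_epsilon[i]),
            "lj_sigma": float(structure.lj_sigma[i]),
        }
        if key in table and table[key] != entry:
            raise ValueError(f"atoms {key} have inconsistent parameters")
        table[key] = entry
    return table


def emit_fixture(structure: ParameterizedStructure, outdir, stem: Optional[str] = None):
    """Write a fixture as PDB + bespoke parameter table; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = stem or (structure.label or "fixture")
    pdb_path = outdir / f"{stem}.pdb"
    ff_path = outdir / f"{stem}.ff"
    write_pdb(structure, pdb_path)
    write_parameter_table(parameter_table_for(structure), ff_path)
    return pdb_path, ff_path
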