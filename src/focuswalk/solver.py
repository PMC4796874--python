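"""Finite-difference linearized Poisson-Boltzmann solver with focusing.

The linearized PB equation

    div(eps grad phi) - eps_s kappa^2 phi = -4 pi C sum_i q_i delta(r - r_i)

is discretized on the 7-point stencil with edge-centered dielectrics and
solved by checkerboard (red-black) successive over-relaxation.  Potentials are
carried in kT/e at the problem temperature; C is the Coulomb constant in those
units, so a point charge q in uniform dielectric eps gives phi = C q/(eps r).

Computational focusing: a coarse parent run covers the whole system; child
runs re-solve a sub-box at higher resolution with every child boundary node
fixed to the trilinearly interpolated parent potential.  Child boxes may sit
anywhere inside the parent and nest to any depth.  All energies are computed
as differences between solves on identical grids so the (unphysical,
grid-dependent) self-energy cancels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np

from . import constants
from .errors import ConvergenceError, FocusingError, OutOfGridError
from .grids import (
    GridSpec,
    ScalarField,
    map_dielectric,
    map_ion_accessibility,
    make_grid,
    spread_charges,
    trilinear_interpolate,
    uniform_dielectric,
)
from .structures import ParameterizedStructure


@dataclass(frozen=True)
class PBPhysics:
    """Implicit-solvent settings shared by parent and child solves.

    Defaults are the conventional two-dielectric implicit-solvent values:
    solute dielectric 2, water 80, 150 mM 1:1 salt, 2 Å Stern (ion-exclusion)
    layer.
    """

    eps_in: float = 2.0
    eps_out: float = 80.0
    ionic_strength: float = 0.150  # mol/L
    temperature: float = 298.15  # K
    stern: float = 2.0  # Å

    def __post_init__(self):
        if self.eps_in <= 0 or self.eps_out <= 0:
            raise ValueError("dielectric constants must be > 0")
        if self.ionic_strength < 0:
            raise ValueError("ionic strength must be >= 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")

    @property
    def kappa(self) -> float:
        return constants.debye_kappa(
            self.ionic_strength, self.temperature, self.eps_out
        )


@dataclass
class PBProblem:
    """A fully gridded linearized-PB problem ready for the solver."""

    charge: ScalarField  # e per node
    dielectric: Tuple[ScalarField, ScalarField, ScalarField]
    ion_mask: ScalarField
    ionic_strength: float
    temperature: float
    boundary: str = "coulombic_debye"  # zero | coulombic_debye | focused
    #: point charges used for the analytic far-field boundary condition
    source_coords: Optional[np.ndarray] = None
    source_charges: Optional[np.ndarray] = None
    #: solvent dielectric entering the far-field boundary condition
    eps_boundary: float = 80.0
    #: full-shape array whose boundary faces hold fixed values (focused mode)
    boundary_phi: Optional[np.ndarray] = None

    def __post_init__(self):
        g = self.charge.grid
        for f in (*self.dielectric, self.ion_mask):
            if f.grid != g:
                raise ValueError("all problem fields must share one GridSpec")
        if self.ionic_strength < 0 or self.temperature <= 0:
            raise ValueError("ionic_strength >= 0 and temperature > 0 required")
        if self.boundary not in ("zero", "coulombic_debye", "focused"):
            raise ValueError(f"unknown boundary mode {self.boundary!r}")
        if self.boundary == "focused" and self.boundary_phi is None:
            raise ValueError("focused boundary requires boundary_phi")

    @property
    def grid(self) -> GridSpec:
        return self.charge.grid


@dataclass
class PotentialField:
    """A solved potential map (kT/e) with its provenance."""

    field: ScalarField
    residual: float
    level: int = 0
    temperature: float = 298.15
    iterations: int = 0

    @property
    def grid(self) -> GridSpec:
        return self.field.grid

    @property
    def values(self) -> np.ndarray:
        return self.field.values


def build_problem(
    structure: ParameterizedStructure,
    grid: GridSpec,
    physics: PBPhysics = PBPhysics(),
    boundary: str = "coulombic_debye",
    uniform_eps: Optional[float] = None,
) -> PBProblem:
    """Grid a structure into a PBProblem.

    ``uniform_eps`` replaces the two-dielectric map with a homogeneous one
    (reference solves and analytic test systems).
    """
    charge = spread_charges(structure, grid)
    if uniform_eps is not None:
        dielectric = uniform_dielectric(grid, uniform_eps)
        eps_b = uniform_eps
    else:
        dielectric = map_dielectric(structure, grid, physics.eps_in, physics.eps_out)
        eps_b = physics.eps_out
    ion_mask = map_ion_accessibility(structure, grid, physics.stern)
    return PBProblem(
        charge=charge,
        dielectric=dielectric,
        ion_mask=ion_mask,
        ionic_strength=physics.ionic_strength,
        temperature=physics.temperature,
        boundary=boundary,
        source_coords=structure.coords.copy(),
        source_charges=structure.charges.copy(),
        eps_boundary=eps_b,
    )


def _boundary_mask(dims) -> np.ndarray:
    m = np.zeros(dims, dtype=bool)
    m[0, :, :] = m[-1, :, :] = True
    m[:, 0, :] = m[:, -1, :] = True
    m[:, :, 0] = m[:, :, -1] = True
    return m


def _debye_coulomb_values(
    points: np.ndarray,
    source_coords: np.ndarray,
    source_charges: np.ndarray,
    eps: float,
    kappa: float,
    temperature: float,
    min_r: float,
) -> np.ndarray:
    """Sum of per-charge Debye-screened Coulomb potentials, kT/e."""
    c = constants.coulomb_kt(temperature)
    out = np.zeros(len(points))
    # chunk over sources to bound memory for large structures
    for lo in range(0, len(source_coords), 256):
        sc = source_coords[lo : lo + 256]
        sq = source_charges[lo : lo + 256]
        d = np.linalg.norm(points[:, None, :] - sc[None, :, :], axis=2)
        d = np.maximum(d, min_r)
        out += (c / eps) * np.sum(sq[None, :] * np.exp(-kappa * d) / d, axis=1)
    return out


def _apply_boundary(problem: PBProblem, phi: np.ndarray) -> None:
    dims = problem.grid.dims
    if problem.boundary == "zero":
        return
    mask = _boundary_mask(dims)
    if problem.boundary == "focused":
        phi[mask] = problem.boundary_phi[mask]
        return
    idx = np.argwhere(mask)
    pts = problem.grid.grid_to_world(idx)
    kappa = constants.debye_kappa(
        problem.ionic_strength, problem.temperature, problem.eps_boundary
    )
    vals = _debye_coulomb_values(
        pts,
        problem.source_coords,
        problem.source_charges,
        problem.eps_boundary,
        kappa,
        problem.temperature,
        min_r=0.5 * problem.grid.spacing,
    )
    phi[mask] = vals


def solve_linear_pb(
    problem: PBProblem,
    tol: float = 1e-6,
    max_iter: int = 10000,
    omega: Optional[float] = None,
    level: int = 0,
    check_every: int = 5,
) -> PotentialField:
    """Solve the gridded linearized PB problem by red-black SOR.

    Convergence is declared when the relative residual ||A phi - b|| / ||b||
    (2-norms over interior nodes; b includes source and boundary
    contributions) drops to ``tol``.  Raises :class:`ConvergenceError`
    carrying the residual history otherwise.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    grid = problem.grid
    h = grid.spacing
    dims = grid.dims
    nmax = max(dims)
    if omega is None:
        omega = 2.0 / (1.0 + math.sin(math.pi / nmax))

    c = constants.coulomb_kt(problem.temperature)
    n_ions = problem.ionic_strength * constants.MOLAR_TO_PER_A3
    # screening coefficient eps_s*kappa^2 = 8 pi C n, applied on ion-accessible nodes
    k2 = 8.0 * math.pi * c * n_ions * problem.ion_mask.values[1:-1, 1:-1, 1:-1]

    ex, ey, ez = (f.values for f in problem.dielectric)
    I = (slice(1, -1), slice(1, -1), slice(1, -1))
    e_xp = ex[1:, 1:-1, 1:-1]
    e_xm = ex[:-1, 1:-1, 1:-1]
    e_yp = ey[1:-1, 1:, 1:-1]
    e_ym = ey[1:-1, :-1, 1:-1]
    e_zp = ez[1:-1, 1:-1, 1:]
    e_zm = ez[1:-1, 1:-1, :-1]
    denom = e_xp + e_xm + e_yp + e_ym + e_zp + e_zm + k2 * h * h
    source = 4.0 * math.pi * c * problem.charge.values[I] / h

    phi = np.zeros(dims)
    _apply_boundary(problem, phi)

    def neighbor_sum() -> np.ndarray:
        return (
            e_xp * phi[2:, 1:-1, 1:-1]
            + e_xm * phi[:-2, 1:-1, 1:-1]
            + e_yp * phi[1:-1, 2:, 1:-1]
            + e_ym * phi[1:-1, :-2, 1:-1]
            + e_zp * phi[1:-1, 1:-1, 2:]
            + e_zm * phi[1:-1, 1:-1, :-2]
        )

    # ||b||: residual of the zero-interior state (source + boundary inflow)
    b_norm = float(np.linalg.norm(neighbor_sum() + source))
    if b_norm == 0.0:
        # homogeneous problem with zero boundary: phi == 0 exactly
        return PotentialField(
            field=ScalarField(grid, phi, "potential"),
            residual=0.0,
            level=level,
            temperature=problem.temperature,
        )

    ii, jj, kk = np.indices(denom.shape)
    red = (ii + jj + kk) % 2 == 0
    black = ~red
    phi_int = phi[I]

    history = []
    for it in range(1, max_iter + 1):
        for colour in (red, black):
            gs = (neighbor_sum() + source) / denom
            phi_int[colour] += omega * (gs[colour] - phi_int[colour])
        if it % check_every == 0 or it == max_iter:
            r = neighbor_sum() + source - denom * phi_int
            rel = float(np.linalg.norm(r)) / b_norm
            history.append(rel)
            if rel <= tol:
                return PotentialField(
                    field=ScalarField(grid, phi, "potential"),
                    residual=rel,
                    level=level,
                    temperature=problem.temperature,
                    iterations=it,
                )
    raise ConvergenceError(
        f"SOR did not reach tol {tol} in {max_iter} iterations "
        f"(last residual {history[-1]:.3e})",
        residual_history=history,
    )


def focus(
    parent: PotentialField,
    structure: ParameterizedStructure,
    physics: PBPhysics,
    child_center: Sequence[float],
    child_edge: float,
    child_resolution: float,
    tol: float = 1e-6,
    max_iter: int = 10000,
    uniform_eps: Optional[float] = None,
) -> PotentialField:
    """Child run: re-solve a sub-box at higher resolution.

    Charge, dielectric, and ion maps are rebuilt on the child grid from the
    same structure; every child boundary node is fixed to the trilinear
    interpolation of the parent potential.  The result can serve as the parent
    of a further (nested) call.  Atoms too close to the child boundary for
    charge spreading enter only through the boundary condition.
    """
    pgrid = parent.grid
    if child_resolution < pgrid.resolution - 1e-9:
        raise FocusingError(
            f"child resolution {child_resolution} is coarser than parent "
            f"{pgrid.resolution}"
        )
    spacing = 1.0 / child_resolution
    n = int(round(child_edge * child_resolution)) + 1
    if n % 2 == 0:
        n += 1
    n = max(n, 5)
    center = np.asarray(child_center, float)
    half = 0.5 * (n - 1) * spacing
    cgrid = GridSpec(origin=tuple(center - half), spacing=spacing, dims=(n, n, n))

    lo_ok = np.all(np.asarray(cgrid.origin) >= np.asarray(pgrid.origin) - 1e-9)
    hi_ok = np.all(cgrid.upper_corner <= pgrid.upper_corner + 1e-9)
    if not (lo_ok and hi_ok):
        raise FocusingError(
            f"child box {cgrid.origin}..{tuple(cgrid.upper_corner)} extends "
            f"past parent {pgrid.origin}..{tuple(pgrid.upper_corner)}"
        )

    inside = cgrid.contains_points(structure.coords, margin_nodes=1.5)
    if np.any(inside):
        sub = _subset(structure, inside)
    else:
        sub = None

    from .grids import ScalarField as SF  # local alias

    charge = (
        spread_charges(sub, cgrid)
        if sub is not None
        else SF(cgrid, np.zeros(cgrid.dims), "charge")
    )
    if uniform_eps is not None:
        dielectric = uniform_dielectric(cgrid, uniform_eps)
    else:
        dielectric = map_dielectric(structure, cgrid, physics.eps_in, physics.eps_out)
    ion_mask = map_ion_accessibility(structure, cgrid, physics.stern)

    bphi = np.zeros(cgrid.dims)
    bmask = _boundary_mask(cgrid.dims)
    idx = np.argwhere(bmask)
    pts = cgrid.grid_to_world(idx)
    bphi[bmask] = trilinear_interpolate(pgrid, parent.values, pts)

    problem = PBProblem(
        charge=charge,
        dielectric=dielectric,
        ion_mask=ion_mask,
        ionic_strength=physics.ionic_strength,
        temperature=physics.temperature,
        boundary="focused",
        boundary_phi=bphi,
        eps_boundary=uniform_eps if uniform_eps is not None else physics.eps_out,
    )
    return solve_linear_pb(
        problem, tol=tol, max_iter=max_iter, level=parent.level + 1
    )


def _subset(structure: ParameterizedStructure, mask: np.ndarray) -> ParameterizedStructure:
    idx = np.flatnonzero(mask)
    return ParameterizedStructure(
        serials=structure.serials[idx],
        names=[structure.names[i] for i in idx],
        residues=[structure.residues[i] for i in idx],
        chains=[structure.chains[i] for i in idx],
        coords=structure.coords[idx],
        charges=structure.charges[idx],
        radii=structure.radii[idx],
        lj_epsilon=structure.lj_epsilon[idx],
        lj_sigma=structure.lj_sigma[idx],
        label=structure.label,
        parameterized=structure.parameterized,
    )


def site_potentials(field: PotentialField, points: np.ndarray) -> np.ndarray:
    """Trilinearly interpolated potential (kT/e) at each point, in order."""
    return trilinear_interpolate(field.grid, field.values, np.atleast_2d(points))


def reaction_field_energy(
    structure: ParameterizedStructure,
    physics: PBPhysics = PBPhysics(),
    reference_eps: Optional[float] = None,
    resolution: float = 2.0,
    edge: Optional[float] = None,
    fill_fraction: float = 0.5,
    dims_cap: int = 193,
    tol: float = 1e-6,
    max_iter: int = 20000,
) -> float:
    """Electrostatic solvation energy, kcal/mol.

    dG_solv = 1/2 sum_i q_i [phi_solvated(r_i) - phi_reference(r_i)], where
    the reference solve uses a uniform dielectric (``reference_eps``, default
    eps_in) and no salt.  Both solves share one grid and one charge spreading,
    so the grid self-energy cancels exactly.
    """
    grid = make_grid(
        structure, resolution, fill_fraction=fill_fraction, dims_cap=dims_cap, edge=edge
    )
    ref_eps = physics.eps_in if reference_eps is None else reference_eps

    solv = solve_linear_pb(
        build_problem(structure, grid, physics, boundary="coulombic_debye"),
        tol=tol,
        max_iter=max_iter,
    )
    ref_physics = replace(physics, ionic_strength=0.0)
    ref = solve_linear_pb(
        build_problem(
            structure, grid, ref_physics, boundary="coulombic_debye",
            uniform_eps=ref_eps,
        ),
        tol=tol,
        max_iter=max_iter,
    )
    phi_s = site_potentials(solv, structure.coords)
    phi_r = site_potentials(ref, structure.coords)
    kt = constants.kt_kcal(physics.temperature)
    return float(0.5 * np.sum(structure.charges * (phi_s - phi_r)) * kt)


def interaction_energy_from_field(
    field: PotentialField,
    coords: np.ndarray,
    charges: np.ndarray,
) -> float:
    """Screened receptor-ligand electrostatic energy sum_i q_i phi(r_i), kcal/mol.

    ``field`` is the receptor's (possibly focused) potential; the ligand
    enters as test charges and must lie inside the field's grid.
    """
    coords = np.atleast_2d(coords)
    try:
        phi = site_potentials(field, coords)
    except OutOfGridError as exc:
        raise OutOfGridError(f"ligand atom outside receptor field: {exc}") from exc
    return float(np.sum(np.asarray(charges) * phi) * constants.kt_kcal(field.temperature))
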