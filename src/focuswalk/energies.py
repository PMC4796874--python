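"""Per-pose binding energies and the pose -> energy lookup table.

E_total = E_coul + E_solv + E_vdw per pose.  Coulomb and Lennard-Jones sums
are "soft": any inter-atomic distance below the clamp (1 Å by default) is
reset to the clamp, so small rigid-body clashes give large-but-finite
energies and the landscape stays continuous.

Two electrostatics routes are supported:

* ``pairwise`` -- closed-form soft Coulomb in a uniform solvent dielectric;
  E_solv is 0 (fast screening-free approximation for landscape work);
* ``field``   -- the screened interaction sum_i q_i phi_receptor(r_i) from a
  focused PB child solve around the pose region, with one parent solve shared
  by every pose.  E_coul is still reported as the uniform-dielectric Coulomb
  value and E_solv as the (screened - Coulomb) difference, so the three-term
  decomposition always sums to the physical total.

Desolvation penalties of the rigid bodies are pose-independent here and are
omitted: the Monte Carlo engine only ever consumes energy *differences*
between poses.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .constants import COULOMB_K
from .errors import FocuswalkError, LatticeError
from .grids import make_grid
from .sampling import Pose, PoseLattice, apply_pose
from .solver import (
    PBPhysics,
    PotentialField,
    build_problem,
    focus,
    interaction_energy_from_field,
    solve_linear_pb,
)
from .structures import ParameterizedStructure


def soft_coulomb(
    coords_a: np.ndarray,
    charges_a: np.ndarray,
    coords_b: np.ndarray,
    charges_b: np.ndarray,
    eps: float = 80.0,
    clamp: float = 1.0,
) -> float:
    """Soft-clamped inter-body Coulomb energy, kcal/mol.

    sum_ij 332.0637 q_i q_j / (eps * max(r_ij, clamp)).
    """
    if eps <= 0 or clamp <= 0:
        raise ValueError("eps and clamp must be > 0")
    r = np.maximum(cdist(np.atleast_2d(coords_a), np.atleast_2d(coords_b)), clamp)
    return float(
        (COULOMB_K / eps)
        * np.sum(np.outer(np.asarray(charges_a), np.asarray(charges_b)) / r)
    )


def soft_lennard_jones(
    coords_a: np.ndarray,
    eps_a: np.ndarray,
    sigma_a: np.ndarray,
    coords_b: np.ndarray,
    eps_b: np.ndarray,
    sigma_b: np.ndarray,
    clamp: float = 1.0,
) -> float:
    """Soft-clamped inter-body Lennard-Jones energy, kcal/mol.

    sum_ij 4 eps_ij [(sigma_ij/r'_ij)^12 - (sigma_ij/r'_ij)^6] with
    r' = max(r, clamp) and Lorentz-Berthelot combining rules
    (sigma arithmetic mean, eps geometric mean).
    """
    if clamp <= 0:
        raise ValueError("clamp must be > 0")
    r = np.maximum(cdist(np.atleast_2d(coords_a), np.atleast_2d(coords_b)), clamp)
    eps_ij = np.sqrt(np.outer(np.asarray(eps_a), np.asarray(eps_b)))
    sigma_ij = 0.5 * (np.asarray(sigma_a)[:, None] + np.asarray(sigma_b)[None, :])
    s6 = (sigma_ij / r) ** 6
    return float(np.sum(4.0 * eps_ij * (s6 * s6 - s6)))


@dataclass
class EnergyRecord:
    """Energy decomposition of one pose, kcal/mol."""

    pose_index: tuple
    e_coul: float
    e_solv: float
    e_vdw: float

    @property
    def e_total(self) -> float:
        return self.e_coul + self.e_solv + self.e_vdw


@dataclass
class EnergyContext:
    """Shared settings (and cached PB solves) for per-pose energies."""

    physics: PBPhysics = dc_field(default_factory=PBPhysics)
    clamp: float = 1.0  # Å; soft-core reset distance
    eps_coulomb: Optional[float] = None  # defaults to physics.eps_out
    #: parent-run settings (field method)
    parent_resolution: float = 0.5  # grids/Å
    parent_edge: Optional[float] = None  # Å; auto-sized when None
    parent_dims_cap: int = 193
    #: child-run settings (field method)
    child_resolution: float = 2.0
    child_margin: float = 6.0  # Å of padding around the posed ligand
    child_dims_cap: int = 129
    tol: float = 1e-6
    max_iter: int = 20000
    #: homogeneous-dielectric override for analytic test systems
    uniform_eps: Optional[float] = None

    _parent: Optional[PotentialField] = dc_field(default=None, repr=False)
    _parent_solves: int = 0
    _child_cache: dict = dc_field(default_factory=dict, repr=False)

    @property
    def coulomb_eps(self) -> float:
        if self.eps_coulomb is not None:
            return self.eps_coulomb
        return self.uniform_eps if self.uniform_eps is not None else self.physics.eps_out

    def parent_field(
        self, receptor: ParameterizedStructure, extent_radius: float
    ) -> PotentialField:
        """The (single, cached) parent PB solve covering the sampling region."""
        if self._parent is None:
            edge = self.parent_edge
            if edge is None:
                edge = 2.0 * (extent_radius + 4.0 / self.parent_resolution)
            grid = make_grid(
                receptor,
                self.parent_resolution,
                dims_cap=self.parent_dims_cap,
                edge=edge,
            )
            problem = build_problem(
                receptor,
                grid,
                self.physics,
                boundary="coulombic_debye",
                uniform_eps=self.uniform_eps,
            )
            self._parent = solve_linear_pb(
                problem, tol=self.tol, max_iter=self.max_iter
            )
            self._parent_solves += 1
        return self._parent

    def child_field(
        self,
        receptor: ParameterizedStructure,
        center: np.ndarray,
        edge: float,
        extent_radius: float,
    ) -> PotentialField:
        """Focused child solve around a pose region, cached per region."""
        key = (tuple(np.round(center, 6)), round(edge, 6))
        if key not in self._child_cache:
            parent = self.parent_field(receptor, extent_radius)
            self._child_cache[key] = focus(
                parent,
                receptor,
                self.physics,
                child_center=center,
                child_edge=edge,
                child_resolution=self.child_resolution,
                tol=self.tol,
                max_iter=self.max_iter,
                uniform_eps=self.uniform_eps,
            )
        return self._child_cache[key]


@dataclass
class EnergyTable:
    """One energy record per lattice pose, in lexicographic pose order."""

    lattice: PoseLattice
    e_coul: np.ndarray
    e_solv: np.ndarray
    e_vdw: np.ndarray
    metadata: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        n = self.lattice.n_poses
        for name in ("e_coul", "e_solv", "e_vdw"):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per pose ({n})")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite energies")
            setattr(self, name, arr)

    @property
    def e_total(self) -> np.ndarray:
        return self.e_coul + self.e_solv + self.e_vdw

    def record(self, index) -> EnergyRecord:
        flat = self.lattice.flat_index(index)
        return EnergyRecord(
            pose_index=self.lattice.unflat_index(flat),
            e_coul=float(self.e_coul[flat]),
            e_solv=float(self.e_solv[flat]),
            e_vdw=float(self.e_vdw[flat]),
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = self.lattice.to_dataframe()
        df["e_coul"] = self.e_coul
        df["e_solv"] = self.e_solv
        df["e_vdw"] = self.e_vdw
        df["e_total"] = self.e_total
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.10g")


def load_energy_csv(lattice: PoseLattice, path, metadata=None) -> EnergyTable:
    df = pd.read_csv(path)
    if len(df) != lattice.n_poses:
        raise FocuswalkError(
            f"energy table has {len(df)} rows but lattice has {lattice.n_poses} poses"
        )
    return EnergyTable(
        lattice=lattice,
        e_coul=df["e_coul"].to_numpy(),
        e_solv=df["e_solv"].to_numpy(),
        e_vdw=df["e_vdw"].to_numpy(),
        metadata=dict(metadata or {}),
    )


def pose_energy(
    receptor: ParameterizedStructure,
    ligand: ParameterizedStructure,
    pose: Pose,
    method: str = "pairwise",
    context: Optional[EnergyContext] = None,
    extent_radius: Optional[float] = None,
) -> EnergyRecord:
    """Three-term energy of one pose (kcal/mol)."""
    context = context or EnergyContext()
    coords = apply_pose(ligand, pose)
    e_vdw = soft_lennard_jones(
        coords,
        ligand.lj_epsilon,
        ligand.lj_sigma,
        receptor.coords,
        receptor.lj_epsilon,
        receptor.lj_sigma,
        clamp=context.clamp,
    )
    e_coul = soft_coulomb(
        coords,
        ligand.charges,
        receptor.coords,
        receptor.charges,
        eps=context.coulomb_eps,
        clamp=context.clamp,
    )
    if method == "pairwise":
        e_solv = 0.0
    elif method == "field":
        if extent_radius is None:
            extent_radius = float(
                np.linalg.norm(pose.position - receptor.centroid)
            ) + ligand.bounding_radius()
        edge = 2.0 * (ligand.bounding_radius() + context.child_margin)
        child = context.child_field(receptor, pose.position, edge, extent_radius)
        e_screen = interaction_energy_from_field(child, coords, ligand.charges)
        e_solv = e_screen - e_coul
    else:
        raise ValueError(f"unknown energy method {method!r}")
    return EnergyRecord(
        pose_index=tuple(pose.index), e_coul=e_coul, e_solv=e_solv, e_vdw=e_vdw
    )


def _lattice_extent_radius(
    receptor: ParameterizedStructure,
    ligand: ParameterizedStructure,
    lattice: PoseLattice,
) -> float:
    center = receptor.centroid
    rmax = receptor.bounding_radius()
    shape = lattice.shape
    for i1 in (0, shape[0] - 1):
        for i2 in (0, shape[1] - 1):
            for i3 in (0, shape[2] - 1):
                p = lattice.station_position(i1, i2, i3)
                rmax = max(rmax, float(np.linalg.norm(p - center)))
    return rmax + ligand.bounding_radius()


def build_energy_table(
    receptor: ParameterizedStructure,
    ligand: ParameterizedStructure,
    lattice: PoseLattice,
    method: str = "pairwise",
    context: Optional[EnergyContext] = None,
    workers: int = 1,
) -> EnergyTable:
    """Energy record for every lattice pose.

    With the ``field`` method exactly one parent PB solve is performed and
    shared by all focused child solves (children are cached per station
    region).  The table is deterministic for fixed inputs and identical for
    any ``workers`` count: poses are partitioned into index-ordered chunks
    whose results are written back by position.
    """
    if lattice.n_poses == 0:
        raise LatticeError("empty pose lattice")
    context = context or EnergyContext()
    extent = _lattice_extent_radius(receptor, ligand, lattice)
    if method == "field":
        context.parent_field(receptor, extent)  # the one shared parent solve
        if context._parent_solves != 1:
            raise FocuswalkError("internal error: parent PB run must be solved once")

    n = lattice.n_poses
    e_coul = np.empty(n)
    e_solv = np.empty(n)
    e_vdw = np.empty(n)

    def compute(flat: int) -> None:
        pose = lattice.pose(lattice.unflat_index(flat))
        try:
            rec = pose_energy(
                receptor, ligand, pose, method=method, context=context,
                extent_radius=extent,
            )
        except FocuswalkError as exc:
            raise FocuswalkError(f"pose {pose.index} (flat {flat}): {exc}") from exc
        e_coul[flat] = rec.e_coul
        e_solv[flat] = rec.e_solv
        e_vdw[flat] = rec.e_vdw

    if workers <= 1 or method == "field":
        # field children share one in-process cache; keep them sequential
        for flat in range(n):
            compute(flat)
    else:
        from concurrent.futures import ThreadPoolExecutor

        with ThreadPoolExecutor(max_workers=workers) as pool:
            list(pool.map(compute, range(n)))

    return EnergyTable(
        lattice=lattice,
        e_coul=e_coul,
        e_solv=e_solv,
        e_vdw=e_vdw,
        metadata={
            "method": method,
            "clamp": context.clamp,
            "eps_coulomb": context.coulomb_eps,
            "temperature": context.physics.temperature,
            "eps_in": context.physics.eps_in,
            "eps_out": context.physics.eps_out,
            "ionic_strength": context.physics.ionic_strength,
        },
    )
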