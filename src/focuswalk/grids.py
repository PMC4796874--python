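"""Regular 3D grids and the mapping of structures onto them.

The finite-difference PB discretization lives on a cubic lattice of nodes;
node (i, j, k) sits at ``origin + spacing * (i, j, k)`` in world coordinates
(0-based indices).  Three gridded inputs feed the solver:

* charge: atomic partial charges spread to the 8 surrounding nodes by
  trilinear (cloud-in-cell) weights, stored in e per node;
* dielectric: edge-centered, sampled at edge midpoints against the
  van der Waals union-of-spheres surface (eps_in inside any atom sphere);
* ion accessibility: node-centered 0/1 mask, 0 within radius + Stern layer of
  any atom, suppressing mobile-ion screening there.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .errors import GridSizeError, OutOfGridError
from .structures import ParameterizedStructure


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular cubic-lattice grid."""

    origin: tuple  # world position of node (0, 0, 0), Å
    spacing: float  # Å per grid interval
    dims: tuple  # nodes per axis

    def __post_init__(self):
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "dims", tuple(int(v) for v in self.dims))
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if any(d < 5 for d in self.dims):
            raise ValueError("each dim must be >= 5 (stencil needs interior nodes)")

    @property
    def resolution(self) -> float:
        """Grids per Å."""
        return 1.0 / self.spacing

    @property
    def edge_lengths(self) -> np.ndarray:
        return (np.asarray(self.dims) - 1) * self.spacing

    @property
    def upper_corner(self) -> np.ndarray:
        return np.asarray(self.origin) + self.edge_lengths

    @property
    def center(self) -> np.ndarray:
        return np.asarray(self.origin) + 0.5 * self.edge_lengths

    def world_to_grid(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(np.asarray(points, float)) - np.asarray(self.origin)) / self.spacing

    def grid_to_world(self, indices: np.ndarray) -> np.ndarray:
        return np.asarray(self.origin) + np.atleast_2d(np.asarray(indices, float)) * self.spacing

    def axes(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of the node planes along each axis."""
        return tuple(
            self.origin[a] + self.spacing * np.arange(self.dims[a]) for a in range(3)
        )

    def contains_points(self, points: np.ndarray, margin_nodes: float = 0.0) -> np.ndarray:
        g = self.world_to_grid(points)
        lo = margin_nodes
        hi = np.asarray(self.dims) - 1 - margin_nodes
        return np.all((g >= lo) & (g <= hi), axis=1)


@dataclass
class ScalarField:
    """A scalar quantity sampled on (or on the edges of) a grid."""

    grid: GridSpec
    values: np.ndarray
    quantity: str  # charge | dielectric_x|y|z | ion_mask | potential

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        expected = list(self.grid.dims)
        axis = {"dielectric_x": 0, "dielectric_y": 1, "dielectric_z": 2}.get(self.quantity)
        if axis is not None:
            expected[axis] -= 1
        if list(self.values.shape) != expected:
            raise ValueError(
                f"{self.quantity} shape {self.values.shape} != expected {tuple(expected)}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.quantity} field contains non-finite values")


def make_grid(
    structure: ParameterizedStructure,
    resolution: float = 2.0,
    fill_fraction: float = 0.9,
    dims_cap: int = 193,
    edge: float | None = None,
) -> GridSpec:
    """A cubic grid centered on the structure's geometric center.

    The edge is chosen so the structure's bounding sphere spans
    ``fill_fraction`` of it, unless an explicit ``edge`` (Å) is requested.
    Dims are forced odd (a center node exists) and capped at ``dims_cap``.
    """
    if not 0 < fill_fraction <= 1:
        raise ValueError("fill_fraction must be in (0, 1]")
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    if edge is None:
        edge = 2.0 * structure.bounding_radius() / fill_fraction
    n = int(round(edge * resolution)) + 1
    if n % 2 == 0:
        n += 1
    n = max(n, 5)
    if n > dims_cap:
        raise GridSizeError(
            f"grid would need {n} nodes per axis (cap {dims_cap}); "
            "reduce resolution or use a focused child run for the region of interest"
        )
    spacing = 1.0 / resolution
    half = 0.5 * (n - 1) * spacing
    center = structure.centroid
    return GridSpec(origin=tuple(center - half), spacing=spacing, dims=(n, n, n))


def spread_charges(structure: ParameterizedStructure, grid: GridSpec) -> ScalarField:
    """Distribute atomic charges to nodes by trilinear weights (e per node).

    Total grid charge equals total atomic charge exactly (weights sum to 1).
    Atoms must lie strictly inside the interior so all 8 receiving nodes are
    interior nodes.
    """
    q = np.zeros(grid.dims)
    g = grid.world_to_grid(structure.coords)
    base = np.floor(g).astype(int)
    frac = g - base
    dims = np.asarray(grid.dims)
    ok = np.all((base >= 1) & (base + 1 <= dims - 2), axis=1)
    if not np.all(ok):
        bad = int(np.flatnonzero(~ok)[0])
        raise OutOfGridError(
            f"atom {structure.serials[bad]} ({structure.names[bad]}) at "
            f"{structure.coords[bad]} lies outside the grid interior"
        )
    for dx in (0, 1):
        wx = np.where(dx, frac[:, 0], 1 - frac[:, 0])
        for dy in (0, 1):
            wy = np.where(dy, frac[:, 1], 1 - frac[:, 1])
            for dz in (0, 1):
                wz = np.where(dz, frac[:, 2], 1 - frac[:, 2])
                np.add.at(
                    q,
                    (base[:, 0] + dx, base[:, 1] + dy, base[:, 2] + dz),
                    structure.charges * wx * wy * wz,
                )
    return ScalarField(grid, q, "charge")


def _mark_spheres(grid: GridSpec, centers, radii, shape, offset_vec, inside_cb):
    """Apply ``inside_cb(slices, mask)`` for sample points within each sphere.

    Sample point (i,j,k) sits at origin + spacing*(ijk + offset_vec); only the
    local bounding box of each sphere is examined.
    """
    h = grid.spacing
    origin = np.asarray(grid.origin)
    for c, r in zip(centers, radii):
        if r <= 0:
            continue
        gc = (c - origin) / h - np.asarray(offset_vec)
        lo = np.maximum(np.ceil(gc - r / h).astype(int), 0)
        hi = np.minimum(np.floor(gc + r / h).astype(int), np.asarray(shape) - 1)
        if np.any(lo > hi):
            continue
        ii, jj, kk = np.meshgrid(
            *(np.arange(lo[a], hi[a] + 1) for a in range(3)), indexing="ij"
        )
        d2 = (
            (ii - gc[0]) ** 2 + (jj - gc[1]) ** 2 + (kk - gc[2]) ** 2
        ) * h * h
        mask = d2 < r * r
        sl = tuple(slice(lo[a], hi[a] + 1) for a in range(3))
        inside_cb(sl, mask)


def map_dielectric(
    structure: ParameterizedStructure,
    grid: GridSpec,
    eps_in: float = 2.0,
    eps_out: float = 80.0,
) -> Tuple[ScalarField, ScalarField, ScalarField]:
    """Edge-centered two-dielectric maps against the vdW union of spheres.

    An edge midpoint strictly inside any atom sphere takes eps_in, else
    eps_out.  Returns (eps_x, eps_y, eps_z) with the edge axis one shorter.
    """
    if eps_in <= 0 or eps_out <= 0:
        raise ValueError("dielectric constants must be > 0")
    fields = []
    for axis, name in enumerate(("dielectric_x", "dielectric_y", "dielectric_z")):
        shape = list(grid.dims)
        shape[axis] -= 1
        values = np.full(shape, eps_out, dtype=np.float64)
        offset = [0.0, 0.0, 0.0]
        offset[axis] = 0.5
        def cb(sl, mask, values=values):
            values[sl][mask] = eps_in
        _mark_spheres(grid, structure.coords, structure.radii, shape, offset, cb)
        fields.append(ScalarField(grid, values, name))
    return tuple(fields)


def map_ion_accessibility(
    structure: ParameterizedStructure, grid: GridSpec, stern: float = 2.0
) -> ScalarField:
    """Node mask: 0 within (radius + stern) of any atom center, else 1."""
    if stern < 0:
        raise ValueError("stern must be >= 0")
    values = np.ones(grid.dims, dtype=np.float64)
    def cb(sl, mask):
        values[sl][mask] = 0.0
    _mark_spheres(
        grid,
        structure.coords,
        structure.radii + stern,
        grid.dims,
        (0.0, 0.0, 0.0),
        cb,
    )
    return ScalarField(grid, values, "ion_mask")


def uniform_dielectric(grid: GridSpec, eps: float) -> Tuple[ScalarField, ScalarField, ScalarField]:
    """Uniform dielectric maps (reference solves, homogeneous test systems)."""
    out = []
    for axis, name in enumerate(("dielectric_x", "dielectric_y", "dielectric_z")):
        shape = list(grid.dims)
        shape[axis] -= 1
        out.append(ScalarField(grid, np.full(shape, float(eps)), name))
    return tuple(out)


def trilinear_interpolate(grid: GridSpec, values: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of node values at world-coordinate points."""
    g = grid.world_to_grid(points)
    dims = np.asarray(grid.dims)
    eps = 1e-9
    if np.any(g < -eps) or np.any(g > dims - 1 + eps):
        bad = int(
            np.flatnonzero(np.any((g < -eps) | (g > dims - 1 + eps), axis=1))[0]
        )
        raise OutOfGridError(f"point index {bad} at {np.atleast_2d(points)[bad]} is outside the grid")
    g = np.clip(g, 0.0, dims - 1)
    base = np.minimum(np.floor(g).astype(int), dims - 2)
    frac = g - base
    out = np.zeros(len(g))
    for dx in (0, 1):
        wx = np.where(dx, frac[:, 0], 1 - frac[:, 0])
        for dy in (0, 1):
            wy = np.where(dy, frac[:, 1], 1 - frac[:, 1])
            for dz in (0, 1):
                wz = np.where(dz, frac[:, 2], 1 - frac[:, 2])
                out += values[base[:, 0] + dx, base[:, 1] + dy, base[:, 2] + dz] * wx * wy * wz
    return out
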