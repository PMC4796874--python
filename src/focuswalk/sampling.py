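"""Discrete 6D rigid-body pose lattices and pose transforms.

A pose is a mass-center translation plus an intrinsic Z-Y-Z Euler rotation
(phi, theta, psi) of the ligand.  The lattice crosses a set of mass-center
stations -- laid out in cuboidal, spherical, or cylindrical geometry around
the receptor -- with a set of rotamers, giving pose count = stations x
rotamers.  Everything here is deterministic: no RNG, lexicographic index
ordering.

Translation coordinates per geometry (ranges/steps dict keys):

* cuboidal:    ``x, y, z`` (Å along the frame axes; axial = z)
* spherical:   ``r`` (Å), ``polar``, ``azimuth`` (degrees; axial = r)
* cylindrical: ``longitudinal`` (Å along the frame's third axis, the axial
  coordinate), ``radial`` (Å from the axis), ``lateral`` (degrees around the
  axis)

Angular coordinates are stored in radians in [0, 2pi) (theta in [0, pi]).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import LatticeError
from .structures import ParameterizedStructure, fibonacci_sphere

_TWO_PI = 2.0 * math.pi

GEOMETRY_COORDS = {
    "cuboidal": ("x", "y", "z"),
    "spherical": ("r", "polar", "azimuth"),
    "cylindrical": ("longitudinal", "radial", "lateral"),
}

#: which translation coordinate carries directional (axial) displacement
AXIAL_DIM = {"cuboidal": 2, "spherical": 0, "cylindrical": 0}


@dataclass(frozen=True)
class LatticeFrame:
    """Origin and orthonormal axis triad defining the sampling frame.

    ``axes[2]`` is the principal axis: the cylinder axis for cylindrical
    sampling, the polar axis for spherical sampling.
    """

    origin: tuple = (0.0, 0.0, 0.0)
    axes: tuple = ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))

    def __post_init__(self):
        a = np.asarray(self.axes, float)
        if a.shape != (3, 3) or not np.allclose(a @ a.T, np.eye(3), atol=1e-8):
            raise LatticeError("frame axes must be an orthonormal 3x3 triad")

    @property
    def matrix(self) -> np.ndarray:
        return np.asarray(self.axes, float)


@dataclass
class Pose:
    """One rigid-body placement: mass-center position + Euler angles."""

    x: float
    y: float
    z: float
    phi: float
    theta: float
    psi: float
    index: tuple

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])

    @property
    def angles(self) -> tuple:
        return (self.phi, self.theta, self.psi)


def _inclusive_steps(lo: float, hi: float, step: float, name: str) -> np.ndarray:
    if step <= 0:
        raise LatticeError(f"{name}: step must be > 0")
    if hi < lo:
        raise LatticeError(f"{name}: range is reversed ({lo} > {hi})")
    n = int(math.floor((hi - lo) / step + 1e-9)) + 1
    return lo + step * np.arange(n)


def _wrap_angle(a: float) -> float:
    return a % _TWO_PI


def rotation_matrix(phi: float, theta: float, psi: float) -> np.ndarray:
    """Intrinsic Z-Y-Z Euler rotation: R = Rz(phi) @ Ry(theta) @ Rz(psi)."""
    cf, sf = math.cos(phi), math.sin(phi)
    ct, st = math.cos(theta), math.sin(theta)
    cp, sp = math.cos(psi), math.sin(psi)
    rz_phi = np.array([[cf, -sf, 0], [sf, cf, 0], [0, 0, 1.0]])
    ry = np.array([[ct, 0, st], [0, 1.0, 0], [-st, 0, ct]])
    rz_psi = np.array([[cp, -sp, 0], [sp, cp, 0], [0, 0, 1.0]])
    return rz_phi @ ry @ rz_psi


def fibonacci_rotamers(n: int) -> List[tuple]:
    """n deterministic low-discrepancy orientations.

    The rotated body z-axis is spread over the sphere by a Fibonacci spiral
    (phi = azimuth, theta = polar angle); psi is 0 throughout.
    """
    if n < 1:
        raise LatticeError("rotamer count must be >= 1")
    if n == 1:
        return [(0.0, 0.0, 0.0)]
    dirs = fibonacci_sphere(n)
    out = []
    for d in dirs:
        theta = math.acos(max(-1.0, min(1.0, d[2])))
        phi = _wrap_angle(math.atan2(d[1], d[0]))
        out.append((phi, theta, 0.0))
    return out


@dataclass
class PoseLattice:
    """The full 6D pose lattice: translation stations x rotamers.

    ``shape`` is the 6-tuple of index extents (3 translational + 3 angular);
    an explicit rotamer list occupies the 4th index with singleton 5th/6th.
    ``periodic`` marks index dimensions with wrap-around adjacency (full-circle
    angular grids).
    """

    geometry: str
    frame: LatticeFrame
    coord_values: tuple  # 3 arrays of translation-coordinate values
    angle_values: Optional[tuple]  # 3 arrays (structured) or None
    rotamer_list: Optional[list]  # list of (phi, theta, psi) or None
    periodic: tuple = (False,) * 6

    def __post_init__(self):
        if self.geometry not in GEOMETRY_COORDS:
            raise LatticeError(f"unknown geometry {self.geometry!r}")
        if self.n_poses == 0:
            raise LatticeError("empty pose lattice")

    # -- shape -------------------------------------------------------------
    @property
    def shape(self) -> tuple:
        trans = tuple(len(v) for v in self.coord_values)
        if self.angle_values is not None:
            return trans + tuple(len(v) for v in self.angle_values)
        return trans + (len(self.rotamer_list), 1, 1)

    @property
    def n_stations(self) -> int:
        return int(np.prod([len(v) for v in self.coord_values]))

    @property
    def n_rotamers(self) -> int:
        if self.angle_values is not None:
            return int(np.prod([len(v) for v in self.angle_values]))
        return len(self.rotamer_list)

    @property
    def n_poses(self) -> int:
        return self.n_stations * self.n_rotamers

    @property
    def axial_dim(self) -> int:
        return AXIAL_DIM[self.geometry]

    # -- index handling ----------------------------------------------------
    def check_index(self, index) -> tuple:
        index = tuple(int(v) for v in index)
        if len(index) != 6:
            raise LatticeError(f"index must have 6 components, got {len(index)}")
        for d, (i, n) in enumerate(zip(index, self.shape)):
            if not 0 <= i < n:
                raise LatticeError(f"index {index} out of bounds in dim {d} (size {n})")
        return index

    def flat_index(self, index) -> int:
        return int(np.ravel_multi_index(self.check_index(index), self.shape))

    def unflat_index(self, flat: int) -> tuple:
        return tuple(int(v) for v in np.unravel_index(flat, self.shape))

    # -- geometry ----------------------------------------------------------
    def station_position(self, i1: int, i2: int, i3: int) -> np.ndarray:
        """World position of a mass-center station."""
        c1 = self.coord_values[0][i1]
        c2 = self.coord_values[1][i2]
        c3 = self.coord_values[2][i3]
        e1, e2, e3 = self.frame.matrix
        o = np.asarray(self.frame.origin, float)
        if self.geometry == "cuboidal":
            return o + c1 * e1 + c2 * e2 + c3 * e3
        if self.geometry == "spherical":
            r, polar, azimuth = c1, math.radians(c2), math.radians(c3)
            return o + r * (
                math.sin(polar) * math.cos(azimuth) * e1
                + math.sin(polar) * math.sin(azimuth) * e2
                + math.cos(polar) * e3
            )
        # cylindrical: c1 longitudinal, c2 radial, c3 lateral (deg)
        alpha = math.radians(c3)
        return o + c1 * e3 + c2 * (math.cos(alpha) * e1 + math.sin(alpha) * e2)

    def rotamer(self, m1: int, m2: int, m3: int) -> tuple:
        if self.angle_values is not None:
            return (
                _wrap_angle(self.angle_values[0][m1]),
                float(self.angle_values[1][m2]),
                _wrap_angle(self.angle_values[2][m3]),
            )
        return self.rotamer_list[m1]

    def pose(self, index) -> Pose:
        i1, i2, i3, m1, m2, m3 = self.check_index(index)
        pos = self.station_position(i1, i2, i3)
        phi, theta, psi = self.rotamer(m1, m2, m3)
        return Pose(
            x=float(pos[0]),
            y=float(pos[1]),
            z=float(pos[2]),
            phi=phi,
            theta=theta,
            psi=psi,
            index=(i1, i2, i3, m1, m2, m3),
        )

    def poses(self):
        """All poses in lexicographic index order."""
        for flat in range(self.n_poses):
            yield self.pose(self.unflat_index(flat))

    def axial_value(self, index) -> float:
        """The axial (directional) translation coordinate of a pose, Å."""
        index = self.check_index(index)
        d = self.axial_dim
        return float(self.coord_values[d][index[d]])

    def station_flat_index(self, index) -> int:
        """Flat station (translation-only) index, for occupancy histograms."""
        i1, i2, i3 = self.check_index(index)[:3]
        trans_shape = tuple(len(v) for v in self.coord_values)
        return int(np.ravel_multi_index((i1, i2, i3), trans_shape))

    # -- adjacency ---------------------------------------------------------
    @property
    def moves(self) -> List[tuple]:
        """The +-1 single-coordinate move set over non-singleton dimensions."""
        out = []
        for d, n in enumerate(self.shape):
            if n > 1:
                out.append((d, -1))
                out.append((d, +1))
        return out

    def apply_move(self, index, move) -> Optional[tuple]:
        """Index after a move, or None if it leaves the lattice."""
        d, delta = move
        idx = list(self.check_index(index))
        n = self.shape[d]
        i = idx[d] + delta
        if self.periodic[d]:
            i %= n
        elif not 0 <= i < n:
            return None
        idx[d] = i
        return tuple(idx)

    def neighbors(self, index) -> List[tuple]:
        """All lattice points differing by +-1 in exactly one index dim."""
        index = self.check_index(index)
        out = []
        for move in self.moves:
            nb = self.apply_move(index, move)
            if nb is not None and nb != index:
                out.append(nb)
        # a periodic dim of size 2 reaches the same neighbor both ways
        return list(dict.fromkeys(out))

    # -- serialization -----------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for p in self.poses():
            rows.append(
                (*p.index, p.x, p.y, p.z, p.phi, p.theta, p.psi)
            )
        return pd.DataFrame(
            rows,
            columns=["i0", "i1", "i2", "i3", "i4", "i5", "x", "y", "z", "phi", "theta", "psi"],
        )


def generate_lattice(
    geometry: str,
    frame: Optional[LatticeFrame] = None,
    ranges: Optional[Dict[str, tuple]] = None,
    steps: Optional[Dict[str, float]] = None,
    rotamers=1,
) -> PoseLattice:
    """Build a pose lattice.

    ``ranges`` maps each geometry coordinate to an inclusive (lo, hi) pair
    (a single value may be given for a degenerate coordinate); ``steps`` gives
    the per-coordinate resolution.  ``rotamers`` is an integer (deterministic
    Fibonacci orientations), an explicit list of (phi, theta, psi) triples, or
    a dict with per-angle ``ranges``/``steps`` (radians) building a structured
    angular grid; full-circle phi/psi grids get periodic adjacency.
    """
    frame = frame or LatticeFrame()
    ranges = dict(ranges or {})
    steps = dict(steps or {})
    coord_names = GEOMETRY_COORDS.get(geometry)
    if coord_names is None:
        raise LatticeError(f"unknown geometry {geometry!r}")

    coord_values = []
    for name in coord_names:
        rng = ranges.get(name, (0.0, 0.0))
        if np.isscalar(rng):
            rng = (float(rng), float(rng))
        lo, hi = float(rng[0]), float(rng[1])
        if lo == hi:
            coord_values.append(np.array([lo]))
        else:
            step = steps.get(name)
            if step is None:
                raise LatticeError(f"no step given for coordinate {name!r}")
            coord_values.append(_inclusive_steps(lo, hi, float(step), name))

    periodic = [False, False, False]
    angle_values = None
    rotamer_list = None
    if isinstance(rotamers, int):
        rotamer_list = fibonacci_rotamers(rotamers)
        periodic += [False, False, False]
    elif isinstance(rotamers, dict):
        angle_values = []
        for name in ("phi", "theta", "psi"):
            rng = rotamers.get("ranges", {}).get(name, (0.0, 0.0))
            if np.isscalar(rng):
                rng = (float(rng), float(rng))
            lo, hi = float(rng[0]), float(rng[1])
            if lo == hi:
                vals = np.array([lo])
                step = None
            else:
                step = rotamers.get("steps", {}).get(name)
                if step is None:
                    raise LatticeError(f"no step given for angle {name!r}")
                vals = _inclusive_steps(lo, hi, float(step), name)
            angle_values.append(vals)
            full_circle = (
                name in ("phi", "psi")
                and step is not None
                and abs((hi - lo) + step - _TWO_PI) < 1e-9
            )
            periodic.append(full_circle)
        angle_values = tuple(angle_values)
    else:
        rotamer_list = [tuple(float(a) for a in r) for r in rotamers]
        if not rotamer_list:
            raise LatticeError("empty rotamer list")
        periodic += [False, False, False]

    lattice = PoseLattice(
        geometry=geometry,
        frame=frame,
        coord_values=tuple(coord_values),
        angle_values=angle_values,
        rotamer_list=rotamer_list,
        periodic=tuple(periodic),
    )
    _check_geometry(lattice, ranges)
    return lattice


def _check_geometry(lattice: PoseLattice, ranges) -> None:
    if lattice.geometry == "cylindrical" and "radial" in ranges:
        rng = ranges["radial"]
        lo, hi = (rng, rng) if np.isscalar(rng) else rng
        e3 = lattice.frame.matrix[2]
        o = np.asarray(lattice.frame.origin)
        for i2, r in enumerate(lattice.coord_values[1]):
            p = lattice.station_position(0, i2, 0)
            v = p - o
            radial = math.sqrt(max(0.0, float(v @ v - (v @ e3) ** 2)))
            if not (lo - 1e-9 <= radial <= hi + 1e-9):
                raise LatticeError(
                    f"station radial distance {radial} outside [{lo}, {hi}]"
                )


def apply_pose(ligand: ParameterizedStructure, pose: Pose) -> np.ndarray:
    """Coordinates of the ligand placed at a pose.

    The body is rotated about its mass center by the Z-Y-Z Euler rotation and
    the mass center is translated to the pose position.  Internal geometry is
    preserved exactly (orthogonal transform).
    """
    center = ligand.centroid
    r = rotation_matrix(pose.phi, pose.theta, pose.psi)
    return (ligand.coords - center) @ r.T + pose.position


def invert_pose_transform(coords: np.ndarray, ligand: ParameterizedStructure, pose: Pose) -> np.ndarray:
    """Undo :func:`apply_pose` (testing helper)."""
    r = rotation_matrix(pose.phi, pose.theta, pose.psi)
    return (np.asarray(coords) - pose.position) @ r + ligand.centroid
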