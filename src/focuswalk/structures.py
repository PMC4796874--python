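"""Atomic structures with per-atom physical parameters.

A :class:`ParameterizedStructure` is the rigid body the rest of the toolkit
operates on: coordinates plus per-atom partial charge, radius, and
Lennard-Jones parameters.  Structures are read from standard PDB files
(coordinates only) and parameterized from a plain-text force-field table.

The parameter table is whitespace-delimited with one row per (residue,
atom-name) pair::

    # residue  atom  charge(e)  radius(A)  epsilon(kcal/mol)  sigma(A)
    LIG        C1    0.500      1.700      0.1094             3.400
    *          NA    1.000      1.868      0.0028             3.328

A residue of ``*`` matches any residue (exact residue matches win).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np

from .errors import EmptyStructureError, ParameterizationError, PDBParseError

logger = logging.getLogger(__name__)

#: Fallback parameters for atoms missing from the table (opt-in).
DEFAULT_PARAMS = {"charge": 0.0, "radius": 1.5, "lj_epsilon": 0.05, "lj_sigma": 3.0}


@dataclass
class AtomRecord:
    """One atom: identity, position (Å), charge (e), radius (Å), LJ parameters."""

    serial: int
    name: str
    residue: str
    chain: str
    position: np.ndarray
    charge: float = 0.0
    radius: float = 0.0
    lj_epsilon: float = 0.0
    lj_sigma: float = 0.0


@dataclass
class ParameterizedStructure:
    """An ordered collection of atoms treated as one rigid body.

    Per-atom data is stored columnar (numpy arrays) so grid mapping and
    pairwise energies vectorize; :meth:`atoms` yields row views for callers
    that want records.
    """

    serials: np.ndarray
    names: list
    residues: list
    chains: list
    coords: np.ndarray  # (n, 3) float64, Å
    charges: np.ndarray
    radii: np.ndarray
    lj_epsilon: np.ndarray
    lj_sigma: np.ndarray
    label: str = ""
    parameterized: bool = False

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)
        n = len(self.coords)
        if n == 0:
            raise EmptyStructureError(f"structure {self.label!r} has no atoms")
        if not np.all(np.isfinite(self.coords)):
            raise PDBParseError(f"structure {self.label!r} has non-finite coordinates")
        for attr in ("serials", "charges", "radii", "lj_epsilon", "lj_sigma"):
            setattr(self, attr, np.asarray(getattr(self, attr)))
            if len(getattr(self, attr)) != n:
                raise ValueError(f"{attr} length does not match coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def net_charge(self) -> float:
        """Sum of atomic partial charges, e."""
        return float(np.sum(self.charges))

    @property
    def centroid(self) -> np.ndarray:
        """Geometric center (unit-mass mass center), Å."""
        return self.coords.mean(axis=0)

    def bounding_radius(self, inflate: float = 0.0) -> float:
        """Radius of the centroid-centered sphere containing all atom spheres."""
        d = np.linalg.norm(self.coords - self.centroid, axis=1)
        radii = np.where(np.isfinite(self.radii), self.radii, 0.0)
        return float(np.max(d + radii + inflate))

    def atoms(self) -> Iterator[AtomRecord]:
        for i in range(self.n_atoms):
            yield AtomRecord(
                serial=int(self.serials[i]),
                name=self.names[i],
                residue=self.residues[i],
                chain=self.chains[i],
                position=self.coords[i].copy(),
                charge=float(self.charges[i]),
                radius=float(self.radii[i]),
                lj_epsilon=float(self.lj_epsilon[i]),
                lj_sigma=float(self.lj_sigma[i]),
            )

    def copy(self) -> "ParameterizedStructure":
        return ParameterizedStructure(
            serials=self.serials.copy(),
            names=list(self.names),
            residues=list(self.residues),
            chains=list(self.chains),
            coords=self.coords.copy(),
            charges=self.charges.copy(),
            radii=self.radii.copy(),
            lj_epsilon=self.lj_epsilon.copy(),
            lj_sigma=self.lj_sigma.copy(),
            label=self.label,
            parameterized=self.parameterized,
        )

    def with_coords(self, coords: np.ndarray) -> "ParameterizedStructure":
        out = self.copy()
        out.coords = np.asarray(coords, dtype=np.float64).reshape(-1, 3)
        if len(out.coords) != self.n_atoms:
            raise ValueError("coordinate array has wrong length")
        return out


def from_arrays(
    coords: np.ndarray,
    charges: Sequence[float] | None = None,
    radii: Sequence[float] | None = None,
    lj_epsilon: Sequence[float] | None = None,
    lj_sigma: Sequence[float] | None = None,
    names: Sequence[str] | None = None,
    residues: Sequence[str] | None = None,
    label: str = "",
) -> ParameterizedStructure:
    """Build a structure directly from arrays (used by the fixture generators)."""
    coords = np.asarray(coords, dtype=np.float64).reshape(-1, 3)
    n = len(coords)
    zeros = np.zeros(n)
    return ParameterizedStructure(
        serials=np.arange(1, n + 1),
        names=list(names) if names is not None else [f"Q{i + 1}" for i in range(n)],
        residues=list(residues) if residues is not None else ["SIT"] * n,
        chains=["A"] * n,
        coords=coords,
        charges=np.asarray(charges, float) if charges is not None else zeros.copy(),
        radii=np.asarray(radii, float) if radii is not None else np.full(n, 1.5),
        lj_epsilon=np.asarray(lj_epsilon, float) if lj_epsilon is not None else zeros.copy(),
        lj_sigma=np.asarray(lj_sigma, float) if lj_sigma is not None else np.full(n, 3.0),
        label=label,
        parameterized=charges is not None,
    )


# ---------------------------------------------------------------------------
# PDB input/output (biotite-backed)
# ---------------------------------------------------------------------------


def read_pdb(path) -> ParameterizedStructure:
    """Read ATOM/HETATM records from a PDB file; parameters are left unset.

    Raises :class:`PDBParseError` for malformed records (naming the offending
    line) and :class:`EmptyStructureError` when no atoms are present.
    """
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise PDBParseError(f"cannot read {path}: {exc}") from exc

    n_records = sum(
        1 for line in text.splitlines() if line.startswith(("ATOM", "HETATM"))
    )
    if n_records == 0:
        raise EmptyStructureError(f"{path} contains no ATOM/HETATM records")

    try:
        import warnings

        with warnings.catch_warnings():
            # pseudo-atom fixtures have no inferable element; irrelevant here
            warnings.filterwarnings("ignore", message=".*element.*")
            pdb = PDBFile.read(str(path))
            arr = pdb.get_structure(model=1)
    except Exception as exc:
        _locate_bad_record(text, path)  # raises with a line number if found
        raise PDBParseError(f"cannot parse {path}: {exc}") from exc

    n = arr.array_length()
    serials = (
        arr.get_annotation("atom_id")
        if "atom_id" in arr.get_annotation_categories()
        else np.arange(1, n + 1)
    )
    return ParameterizedStructure(
        serials=np.asarray(serials, dtype=int),
        names=[str(s) for s in arr.atom_name],
        residues=[str(s) for s in arr.res_name],
        chains=[str(s) for s in arr.chain_id],
        coords=np.asarray(arr.coord, dtype=np.float64),
        charges=np.zeros(n),
        radii=np.zeros(n),
        lj_epsilon=np.zeros(n),
        lj_sigma=np.zeros(n),
        label=path.stem,
        parameterized=False,
    )


def _locate_bad_record(text: str, path) -> None:
    """Scan ATOM/HETATM lines for an unparsable coordinate field."""
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        for lo, hi in ((30, 38), (38, 46), (46, 54)):
            try:
                float(line[lo:hi])
            except ValueError:
                raise PDBParseError(
                    f"{path}: malformed coordinate field on line {lineno}: {line!r}"
                ) from None


def write_pdb(structure: ParameterizedStructure, path) -> None:
    """Write the structure as a standard PDB file (coordinates only)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = structure.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = structure.coords.astype(np.float32)
    arr.set_annotation("atom_name", np.asarray(structure.names, dtype="U6"))
    arr.set_annotation("res_name", np.asarray(structure.residues, dtype="U5"))
    arr.set_annotation("chain_id", np.asarray(structure.chains, dtype="U4"))
    arr.set_annotation("res_id", np.arange(1, n + 1))
    arr.set_annotation("element", np.asarray([""] * n, dtype="U2"))
    arr.set_annotation("hetero", np.asarray([True] * n))
    pdb = PDBFile()
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*element.*")
        pdb.set_structure(arr)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Force-field parameter tables
# ---------------------------------------------------------------------------


def read_parameter_table(path) -> dict:
    """Parse the whitespace-delimited parameter table into a lookup dict.

    Keys are (residue, atom-name); residue ``*`` is a wildcard.
    """
    table = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 6:
            raise ParameterizationError(
                f"{path}: line {lineno}: expected 6 fields "
                "(residue atom charge radius epsilon sigma), got "
                f"{len(parts)}"
            )
        res, name = parts[0], parts[1]
        try:
            charge, radius, eps, sigma = (float(v) for v in parts[2:])
        except ValueError:
            raise ParameterizationError(
                f"{path}: line {lineno}: non-numeric parameter value"
            ) from None
        table[(res, name)] = {
            "charge": charge,
            "radius": radius,
            "lj_epsilon": eps,
            "lj_sigma": sigma,
        }
    return table


def write_parameter_table(table: Mapping, path) -> None:
    lines = ["# residue  atom  charge(e)  radius(A)  epsilon(kcal/mol)  sigma(A)"]
    for (res, name), p in table.items():
        lines.append(
            f"{res:<8s} {name:<6s} {p['charge']: .9g} {p['radius']:.6g} "
            f"{p['lj_epsilon']:.6g} {p['lj_sigma']:.6g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def assign_parameters(
    structure: ParameterizedStructure,
    forcefield,
    allow_defaults: bool = False,
    defaults: Mapping | None = None,
) -> ParameterizedStructure:
    """Assign charge/radius/LJ parameters from a table to every atom.

    ``forcefield`` may be a path to a table file or an already-parsed dict.
    Lookup is exact (residue, atom) first, then wildcard (``*``, atom).
    Unmatched atoms raise :class:`ParameterizationError` unless
    ``allow_defaults`` is set, in which case they receive ``defaults``
    (:data:`DEFAULT_PARAMS` unless overridden) with a logged warning.
    """
    table = forcefield if isinstance(forcefield, Mapping) else read_parameter_table(forcefield)
    defaults = dict(DEFAULT_PARAMS, **(defaults or {}))

    out = structure.copy()
    missing = []
    defaulted = []
    for i in range(out.n_atoms):
        key = (out.residues[i], out.names[i])
        params = table.get(key) or table.get(("*", out.names[i]))
        if params is None:
            if allow_defaults:
                params = defaults
                defaulted.append(key)
            else:
                missing.append(key)
                continue
        out.charges[i] = params["charge"]
        out.radii[i] = params["radius"]
        out.lj_epsilon[i] = params["lj_epsilon"]
        out.lj_sigma[i] = params["lj_sigma"]

    if missing:
        raise ParameterizationError(
            "no parameters for atoms: "
            + ", ".join(f"{r}/{n}" for r, n in sorted(set(missing)))
        )
    if defaulted:
        logger.warning(
            "assigned default parameters to %d atoms (%s)",
            len(defaulted),
            ", ".join(f"{r}/{n}" for r, n in sorted(set(defaulted))[:5]),
        )
    bad = np.flatnonzero(out.radii <= 0)
    if bad.size:
        raise ParameterizationError(
            f"non-positive radius for atoms at indices {bad[:5].tolist()}"
        )
    out.parameterized = True
    return out


# ---------------------------------------------------------------------------
# Surface probe points
# ---------------------------------------------------------------------------


def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (golden-spiral construction), deterministic."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    golden = math.pi * (3.0 - math.sqrt(5.0))
    az = golden * np.arange(n)
    return np.column_stack([rho * np.cos(az), rho * np.sin(az), z])


def surface_probe_points(
    structure: ParameterizedStructure,
    offset: float = 2.0,
    spacing: float = 1.0,
    tol: float = 0.1,
) -> np.ndarray:
    """Points ``offset`` Å outside the union-of-spheres molecular surface.

    Each atom contributes a Fibonacci point cloud on the sphere of radius
    (atom radius + offset); points buried inside any other inflated atom
    sphere (by more than ``tol``) are pruned.  Point density targets one point
    per ``spacing``² of inflated surface area.
    """
    if offset < 0 or spacing <= 0:
        raise ValueError("offset must be >= 0 and spacing > 0")
    if not structure.parameterized:
        raise ParameterizationError("structure has no radii; assign parameters first")

    centers = structure.coords
    inflated = structure.radii + offset
    points = []
    for i in range(structure.n_atoms):
        r = inflated[i]
        n = max(1, int(round(4.0 * math.pi * r * r / (spacing * spacing))))
        cloud = centers[i] + r * fibonacci_sphere(n)
        # prune points buried inside any other inflated sphere
        keep = np.ones(len(cloud), dtype=bool)
        for j in range(structure.n_atoms):
            if j == i:
                continue
            d = np.linalg.norm(cloud - centers[j], axis=1)
            keep &= d >= inflated[j] - tol
        points.append(cloud[keep])
    return np.concatenate(points, axis=0)


def write_xyz_points(points: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(points), fmt="%.6f")
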