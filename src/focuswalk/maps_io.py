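"""Potential-map persistence: OpenDX text format and a binary container.

OpenDX regular scalar grids are the lingua franca of implicit-solvent tools
(APBS, PyMOL, VMD all read them).  The text format carries ~6 significant
digits; the .npz container round-trips bit-exactly and keeps grid metadata.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .grids import GridSpec, ScalarField
from .solver import PotentialField


def write_dx(field: PotentialField, path) -> None:
    g = field.grid
    nx, ny, nz = g.dims
    values = field.values.ravel(order="C")  # x fastest-varying last, per DX spec
    lines = [
        "# OpenDX scalar map written by focuswalk",
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        "origin {:.6e} {:.6e} {:.6e}".format(*g.origin),
        f"delta {g.spacing:.6e} 0.000000e+00 0.000000e+00",
        f"delta 0.000000e+00 {g.spacing:.6e} 0.000000e+00",
        f"delta 0.000000e+00 0.000000e+00 {g.spacing:.6e}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {values.size} data follows",
    ]
    body = [
        " ".join(f"{v:.9e}" for v in values[i : i + 3])
        for i in range(0, values.size, 3)
    ]
    lines.extend(body)
    lines.append('attribute "dep" string "positions"')
    lines.append('object "regular positions regular connections" class field')
    Path(path).write_text("\n".join(lines) + "\n")


def read_dx(path) -> PotentialField:
    dims = None
    origin = None
    deltas = []
    data = []
    in_data = False
    n_items = 0
    for line in Path(path).read_text().splitlines():
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        if in_data:
            if s.startswith(("attribute", "object")):
                in_data = False
                continue
            data.extend(float(v) for v in s.split())
            continue
        if s.startswith("object 1"):
            dims = tuple(int(v) for v in s.split()[-3:])
        elif s.startswith("origin"):
            origin = tuple(float(v) for v in s.split()[1:4])
        elif s.startswith("delta"):
            deltas.append([float(v) for v in s.split()[1:4]])
        elif "data follows" in s:
            n_items = int(s.split("items")[1].split()[0])
            in_data = True
    if dims is None or origin is None or len(deltas) != 3:
        raise ValueError(f"{path}: not a regular OpenDX scalar grid")
    spacing = deltas[0][0]
    if not (
        np.allclose(deltas, np.diag([spacing] * 3))
    ):
        raise ValueError(f"{path}: only axis-aligned cubic grids are supported")
    values = np.asarray(data[:n_items]).reshape(dims, order="C")
    grid = GridSpec(origin=origin, spacing=spacing, dims=dims)
    return PotentialField(
        field=ScalarField(grid, values, "potential"), residual=float("nan")
    )


def save_field(field: PotentialField, path) -> None:
    """Bit-exact binary container (numpy .npz) with grid metadata."""
    np.savez(
        path,
        values=field.values,
        origin=np.asarray(field.grid.origin),
        spacing=np.asarray(field.grid.spacing),
        dims=np.asarray(field.grid.dims),
        residual=np.asarray(field.residual),
        level=np.asarray(field.level),
        temperature=np.asarray(field.temperature),
    )


def load_field(path) -> PotentialField:
    with np.load(path) as z:
        grid = GridSpec(
            origin=tuple(z["origin"]),
            spacing=float(z["spacing"]),
            dims=tuple(int(v) for v in z["dims"]),
        )
        return PotentialField(
            field=ScalarField(grid, z["values"], "potential"),
            residual=float(z["residual"]),
            level=int(z["level"]),
            temperature=float(z["temperature"]),
        )
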