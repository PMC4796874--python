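"""Metropolis Monte Carlo binding pathways over an energy lookup table.

The walker lives on the pose lattice.  Each step draws one move uniformly
from the +-1 single-coordinate move set (a symmetric proposal kernel: a move
that would leave the lattice is a null proposal and counts as rejected, so
detailed balance with respect to exp(-E/kT) holds everywhere, including at
lattice boundaries).  Moves are accepted by the Metropolis criterion: always
when dE <= 0, else with probability exp(-dE/kT).  On rejection the walker
re-records its current state, so occupancy histograms weight states by
Boltzmann dwell time.

A pathway terminates when the axial displacement of the mass center from the
start exceeds the termination distance (outcome ``plus_end`` or ``minus_end``
by sign) or at ``max_steps``.

Reproducibility: the RNG is numpy's PCG64 seeded from the config.  Draws are
consumed in a fixed documented order -- one integer draw per proposal, one
uniform draw per Metropolis test with dE > 0 -- from two independent buffers
refilled in blocks of 8192.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .constants import kt_kcal
from .energies import EnergyTable
from .errors import FocuswalkError, LatticeError
from .sampling import PoseLattice

_BLOCK = 8192


@dataclass(frozen=True)
class MCConfig:
    """Monte Carlo run settings.

    The default temperature (500 K) is deliberately above physiological: the
    extra thermal energy stands in for the external (ATP-derived) energy that
    pulls a motor out of its binding funnel, letting finite-length runs escape
    deep wells.
    """

    start_index: tuple
    temperature: float = 500.0  # K
    termination_distance: float = 80.0  # Å along the lattice's axial coordinate
    max_steps: int = 10_000_000
    seed: int = 0

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.termination_distance <= 0:
            raise ValueError("termination_distance must be > 0")


@dataclass
class Pathway:
    """An accepted-state sequence S_0..S_N (flat pose indices, repeats kept)."""

    states: np.ndarray
    outcome: str  # plus_end | minus_end | max_steps
    accepted: int
    attempted: int

    @property
    def length(self) -> int:
        return len(self.states)


@dataclass
class EnsembleStats:
    """Aggregate directionality and occupancy over an ensemble of pathways."""

    n_pathways: int
    n_plus: int
    n_minus: int
    n_max_steps: int
    occupancy: np.ndarray  # visits per translation station (repeats counted)
    mean_length: float

    @property
    def p_plus(self) -> float:
        return self.n_plus / (self.n_plus + self.n_minus)

    @property
    def se_p_plus(self) -> float:
        """Binomial standard error of p_plus."""
        n = self.n_plus + self.n_minus
        p = self.p_plus
        return math.sqrt(p * (1.0 - p) / n)

    def to_dict(self) -> dict:
        return {
            "n_pathways": self.n_pathways,
            "n_plus": self.n_plus,
            "n_minus": self.n_minus,
            "n_max_steps": self.n_max_steps,
            "p_plus": self.p_plus,
            "se_p_plus": self.se_p_plus,
            "mean_length": self.mean_length,
        }


class _Draws:
    """Buffered, order-stable draws from one PCG64 generator."""

    def __init__(self, rng: np.random.Generator, n_moves: int):
        self._rng = rng
        self._n_moves = n_moves
        self._ints: list = []
        self._floats: list = []

    def next_move(self) -> int:
        if not self._ints:
            self._ints = self._rng.integers(0, self._n_moves, size=_BLOCK).tolist()
            self._ints.reverse()
        return self._ints.pop()

    def next_uniform(self) -> float:
        if not self._floats:
            self._floats = self._rng.random(size=_BLOCK).tolist()
            self._floats.reverse()
        return self._floats.pop()


def metropolis_accept(delta_e: float, temperature: float, rng: np.random.Generator) -> bool:
    """Metropolis criterion: accept if dE <= 0, else with prob exp(-dE/kT).

    Consumes exactly one RNG draw when dE > 0 and none otherwise.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    if delta_e <= 0:
        return True
    return float(rng.random()) < math.exp(-delta_e / kt_kcal(temperature))


def propose_move(lattice: PoseLattice, index, rng: np.random.Generator) -> Optional[tuple]:
    """Draw one +-1 single-coordinate move uniformly; one RNG draw.

    Returns the candidate index, or None when the drawn move leaves the
    lattice (a null proposal; the caller treats it as rejected).  Raises for
    a lattice with no moves (isolated state).
    """
    moves = lattice.moves
    if not moves:
        raise LatticeError("lattice has no non-singleton dimensions to move in")
    move = moves[int(rng.integers(0, len(moves)))]
    return lattice.apply_move(lattice.check_index(index), move)


def _neighbor_table(lattice: PoseLattice) -> np.ndarray:
    """(n_poses, n_moves) flat-index transition table; -1 = null move."""
    shape = lattice.shape
    moves = lattice.moves
    n = lattice.n_poses
    idx = np.stack(np.unravel_index(np.arange(n), shape), axis=1)
    out = np.full((n, len(moves)), -1, dtype=np.int64)
    for m, (d, delta) in enumerate(moves):
        cand = idx.copy()
        cand[:, d] += delta
        if lattice.periodic[d]:
            cand[:, d] %= shape[d]
            ok = np.ones(n, dtype=bool)
        else:
            ok = (cand[:, d] >= 0) & (cand[:, d] < shape[d])
        flat = np.ravel_multi_index(
            tuple(np.clip(cand[:, a], 0, shape[a] - 1) for a in range(6)), shape
        )
        out[ok, m] = flat[ok]
    return out


def _axial_by_flat(lattice: PoseLattice) -> np.ndarray:
    d = lattice.axial_dim
    comp = np.unravel_index(np.arange(lattice.n_poses), lattice.shape)[d]
    return lattice.coord_values[d][comp]


def generate_pathway(
    table: EnergyTable,
    config: MCConfig,
    rng: Optional[np.random.Generator] = None,
) -> Pathway:
    """One Metropolis pathway, fully reproducible from the config seed."""
    lattice = table.lattice
    start = lattice.flat_index(config.start_index)
    energies = table.e_total
    nbr = _neighbor_table(lattice)
    axial = _axial_by_flat(lattice)
    if not lattice.moves:
        raise LatticeError("lattice has no non-singleton dimensions to move in")

    if rng is None:
        rng = np.random.Generator(np.random.PCG64(config.seed))
    draws = _Draws(rng, nbr.shape[1])

    beta = 1.0 / kt_kcal(config.temperature)
    term = config.termination_distance
    start_axial = axial[start]

    cur = start
    states = [cur]
    accepted = 0
    attempted = 0
    outcome = "max_steps"
    e_cur = energies[cur]
    for _ in range(config.max_steps):
        attempted += 1
        cand = nbr[cur, draws.next_move()]
        if cand >= 0:
            de = energies[cand] - e_cur
            if de <= 0 or draws.next_uniform() < math.exp(-beta * de):
                cur = cand
                e_cur = energies[cand]
                accepted += 1
        states.append(cur)
        disp = axial[cur] - start_axial
        if abs(disp) >= term - 1e-9:
            outcome = "plus_end" if disp > 0 else "minus_end"
            break
    return Pathway(
        states=np.asarray(states, dtype=np.int64),
        outcome=outcome,
        accepted=accepted,
        attempted=attempted,
    )


def run_ensemble(
    table: EnergyTable,
    config: MCConfig,
    n_pathways: int,
) -> List[Pathway]:
    """n independent pathways; pathway i uses the i-th spawn of the seed."""
    children = np.random.SeedSequence(config.seed).spawn(n_pathways)
    return [
        generate_pathway(table, config, rng=np.random.Generator(np.random.PCG64(ss)))
        for ss in children
    ]


def ensemble_stats(pathways: Sequence[Pathway], lattice: PoseLattice) -> EnsembleStats:
    """Directional probability and station occupancy for an ensemble."""
    n_plus = sum(1 for p in pathways if p.outcome == "plus_end")
    n_minus = sum(1 for p in pathways if p.outcome == "minus_end")
    n_max = sum(1 for p in pathways if p.outcome == "max_steps")
    if n_plus + n_minus == 0:
        raise FocuswalkError("no terminated pathways in the ensemble")
    n_rot = lattice.n_rotamers
    occ = np.zeros(lattice.n_stations, dtype=np.int64)
    total_len = 0
    for p in pathways:
        occ += np.bincount(p.states // n_rot, minlength=lattice.n_stations)
        total_len += p.length
    return EnsembleStats(
        n_pathways=len(pathways),
        n_plus=n_plus,
        n_minus=n_minus,
        n_max_steps=n_max,
        occupancy=occ,
        mean_length=total_len / len(pathways),
    )


def pathway_to_dataframe(pathway: Pathway, table: EnergyTable):
    """Per-step export: step, flat/lattice index, pose coordinates, e_total.

    Ensembles are summarized rather than dumped wholesale; this is for
    inspecting individual trajectories.
    """
    import pandas as pd

    lattice = table.lattice
    rows = []
    prev = None
    for step, flat in enumerate(pathway.states):
        pose = lattice.pose(lattice.unflat_index(int(flat)))
        rows.append((step, int(flat), *pose.index, pose.x, pose.y, pose.z,
                     pose.phi, pose.theta, pose.psi,
                     float(table.e_total[int(flat)]),
                     prev is None or flat != prev))
        prev = flat
    return pd.DataFrame(rows, columns=[
        "step", "flat_index", "i0", "i1", "i2", "i3", "i4", "i5",
        "x", "y", "z", "phi", "theta", "psi", "e_total", "moved"])


def absorption_probability(table: EnergyTable, config: MCConfig) -> float:
    """Exact plus-end absorption probability of the Metropolis chain.

    Builds the full one-step transition matrix of the implemented kernel
    (uniform move draw, null moves at boundaries, Metropolis acceptance),
    marks every state at axial displacement >= termination_distance as
    absorbing, and solves the linear system for the probability of absorbing
    on the plus side.  Intended as an independent reference for small
    lattices (dense solve).
    """
    lattice = table.lattice
    n = lattice.n_poses
    if n > 20000:
        raise FocuswalkError("exact absorption solve is limited to small lattices")
    energies = table.e_total
    nbr = _neighbor_table(lattice)
    axial = _axial_by_flat(lattice)
    start = lattice.flat_index(config.start_index)
    disp = axial - axial[start]
    plus = disp >= config.termination_distance - 1e-9
    minus = disp <= -config.termination_distance + 1e-9
    interior = ~(plus | minus)

    beta = 1.0 / kt_kcal(config.temperature)
    n_moves = nbr.shape[1]
    p_move = 1.0 / n_moves

    P = np.zeros((n, n))
    for s in range(n):
        if not interior[s]:
            continue
        stay = 0.0
        for m in range(n_moves):
            t = nbr[s, m]
            if t < 0:
                stay += p_move
                continue
            de = energies[t] - energies[s]
            acc = 1.0 if de <= 0 else math.exp(-beta * de)
            P[s, t] += p_move * acc
            stay += p_move * (1.0 - acc)
        P[s, s] += stay

    # u = P_interior u + P_to_plus; solve (I - Q) u = r
    idx_int = np.flatnonzero(interior)
    Q = P[np.ix_(idx_int, idx_int)]
    r = P[np.ix_(idx_int, np.flatnonzero(plus))].sum(axis=1)
    u = np.linalg.solve(np.eye(len(idx_int)) - Q, r)
    pos = {s: i for i, s in enumerate(idx_int)}
    if start not in pos:
        return 1.0 if plus[start] else 0.0
    return float(u[pos[start]])
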