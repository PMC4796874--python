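"""Metropolis engine: acceptance rule, proposals, pathways, ensembles."""

import math

import numpy as np
import pytest

import focuswalk as fw
from focuswalk.errors import FocuswalkError, LatticeError


def _table_1d(energies):
    n = len(energies)
    lat = fw.generate_lattice("cuboidal", ranges={"z": (0, float(n - 1))},
                              steps={"z": 1.0}, rotamers=1)
    z = np.zeros(n)
    return fw.EnergyTable(lattice=lat, e_coul=np.asarray(energies, float),
                          e_solv=z.copy(), e_vdw=z.copy())


class TestMetropolisAccept:
    def test_downhill_moves_are_always_accepted(self, rng):
        assert all(fw.metropolis_accept(-1.0, 300.0, rng) for _ in range(1000))

    def test_zero_delta_is_always_accepted(self, rng):
        assert all(fw.metropolis_accept(0.0, 300.0, rng) for _ in range(1000))

    def test_acceptance_at_kT_is_one_over_e(self):
        rng = np.random.Generator(np.random.PCG64(42))
        kt = fw.kt_kcal(298.15)
        n = 100_000
        acc = sum(fw.metropolis_accept(kt, 298.15, rng) for _ in range(n)) / n
        assert acc == pytest.approx(math.exp(-1), abs=0.005)

    def test_uphill_acceptance_consumes_exactly_one_draw(self):
        rng_a = np.random.Generator(np.random.PCG64(7))
        rng_b = np.random.Generator(np.random.PCG64(7))
        fw.metropolis_accept(1.0, 300.0, rng_a)
        rng_b.random()
        assert rng_a.random() == rng_b.random()


class TestProposeMove:
    def test_interior_state_proposals_are_uniform(self):
        lat = fw.generate_lattice(
            "cuboidal",
            ranges={"x": (0, 2), "y": (0, 2), "z": (0, 2)},
            steps={"x": 1.0, "y": 1.0, "z": 1.0},
            rotamers={
                "ranges": {"phi": (0, 1.0), "theta": (0.1, 1.1), "psi": (0, 1.0)},
                "steps": {"phi": 0.5, "theta": 0.5, "psi": 0.5},
            },
        )
        rng = np.random.Generator(np.random.PCG64(5))
        idx = (1, 1, 1, 1, 1, 1)
        counts = {}
        n = 60_000
        for _ in range(n):
            cand = fw.propose_move(lat, idx, rng)
            counts[cand] = counts.get(cand, 0) + 1
        # all 12 neighbors, each with frequency 1/12 +- 0.01
        assert set(counts) == set(lat.neighbors(idx))
        for c in counts.values():
            assert c / n == pytest.approx(1 / 12, abs=0.01)

    def test_boundary_moves_become_null_proposals(self):
        lat = _table_1d([0.0, 0.0]).lattice
        rng = np.random.Generator(np.random.PCG64(0))
        seen = {fw.propose_move(lat, (0, 0, 0, 0, 0, 0), rng) for _ in range(200)}
        assert seen == {None, (0, 0, 1, 0, 0, 0)}

    def test_invalid_index_raises(self, tiny_lattice):
        rng = np.random.Generator(np.random.PCG64(0))
        with pytest.raises(LatticeError):
            fw.propose_move(tiny_lattice, (99, 0, 0, 0, 0, 0), rng)


class TestGeneratePathway:
    def test_trapped_walker_never_leaves_start(self):
        energies = np.full(11, 1e6)
        energies[5] = 0.0
        table = _table_1d(energies)
        config = fw.MCConfig(start_index=(0, 0, 5, 0, 0, 0), temperature=300.0,
                             termination_distance=3.0, max_steps=2000, seed=1)
        p = fw.generate_pathway(table, config)
        assert p.outcome == "max_steps"
        assert set(p.states) == {table.lattice.flat_index((0, 0, 5, 0, 0, 0))}

    def test_flat_symmetric_table_is_unbiased(self, flat_1d_table):
        config = fw.MCConfig(start_index=(0, 0, 20, 0, 0, 0), temperature=500.0,
                             termination_distance=40.0, max_steps=100_000, seed=2)
        stats = fw.ensemble_stats(
            fw.run_ensemble(flat_1d_table, config, 400), flat_1d_table.lattice)
        assert abs(stats.p_plus - 0.5) <= 3 * stats.se_p_plus

    def test_ramp_matches_exact_markov_absorption(self):
        kt = fw.kt_kcal(500.0)
        energies = -0.25 * kt * np.arange(41)
        table = _table_1d(energies)
        config = fw.MCConfig(start_index=(0, 0, 20, 0, 0, 0), temperature=500.0,
                             termination_distance=10.0, max_steps=100_000, seed=3)
        exact = fw.absorption_probability(table, config)
        stats = fw.ensemble_stats(
            fw.run_ensemble(table, config, 600), table.lattice)
        assert abs(stats.p_plus - exact) <= 3 * stats.se_p_plus + 1e-9

    def test_same_seed_gives_identical_pathway(self, flat_1d_table):
        config = fw.MCConfig(start_index=(0, 0, 20, 0, 0, 0), temperature=400.0,
                             termination_distance=20.0, max_steps=100_000, seed=9)
        p1 = fw.generate_pathway(flat_1d_table, config)
        p2 = fw.generate_pathway(flat_1d_table, config)
        assert np.array_equal(p1.states, p2.states)
        assert (p1.outcome, p1.accepted, p1.attempted) == (
            p2.outcome, p2.accepted, p2.attempted)

    def test_consecutive_distinct_states_are_lattice_neighbors(self):
        rng_e = np.random.Generator(np.random.PCG64(4))
        kt = fw.kt_kcal(500.0)
        table = _table_1d(rng_e.uniform(0, 2 * kt, size=21))
        config = fw.MCConfig(start_index=(0, 0, 10, 0, 0, 0), temperature=500.0,
                             termination_distance=8.0, max_steps=50_000, seed=5)
        p = fw.generate_pathway(table, config)
        lat = table.lattice
        for a, b in zip(p.states[:-1], p.states[1:]):
            if a != b:
                assert lat.unflat_index(b) in lat.neighbors(lat.unflat_index(a))

    def test_terminated_pathway_reached_the_termination_distance(self):
        config = fw.MCConfig(start_index=(0, 0, 20, 0, 0, 0), temperature=500.0,
                             termination_distance=12.0, max_steps=100_000, seed=6)
        table = _table_1d(np.zeros(41))
        p = fw.generate_pathway(table, config)
        assert p.outcome in ("plus_end", "minus_end")
        lat = table.lattice
        z0 = lat.axial_value((0, 0, 20, 0, 0, 0))
        zf = lat.axial_value(lat.unflat_index(int(p.states[-1])))
        assert abs(zf - z0) >= 12.0

    def test_mirrored_energy_table_mirrors_directionality(self):
        kt = fw.kt_kcal(500.0)
        rng_e = np.random.Generator(np.random.PCG64(11))
        energies = rng_e.uniform(0, 1.5 * kt, size=41) - 0.1 * kt * np.arange(41)
        fwd = _table_1d(energies)
        rev = _table_1d(energies[::-1])
        config = fw.MCConfig(start_index=(0, 0, 20, 0, 0, 0), temperature=500.0,
                             termination_distance=20.0, max_steps=100_000, seed=12)
        s_fwd = fw.ensemble_stats(fw.run_ensemble(fwd, config, 400), fwd.lattice)
        s_rev = fw.ensemble_stats(fw.run_ensemble(rev, config, 400), rev.lattice)
        assert abs(s_fwd.p_plus - (1 - s_rev.p_plus)) <= 3 * (
            s_fwd.se_p_plus + s_rev.se_p_plus)


class TestEnsembleStats:
    def test_directional_probability_is_plus_fraction(self, flat_1d_table):
        paths = [fw.Pathway(states=np.array([0]), outcome="plus_end", accepted=0,
                            attempted=0) for _ in range(860)]
        paths += [fw.Pathway(states=np.array([0]), outcome="minus_end", accepted=0,
                             attempted=0) for _ in range(140)]
        stats = fw.ensemble_stats(paths, flat_1d_table.lattice)
        assert stats.p_plus == 0.86

    def test_identical_pathways_scale_the_occupancy_histogram(self, flat_1d_table):
        states = np.array([20, 21, 21, 22])
        one = fw.Pathway(states=states, outcome="plus_end", accepted=3, attempted=4)
        stats1 = fw.ensemble_stats([one], flat_1d_table.lattice)
        stats5 = fw.ensemble_stats([one] * 5, flat_1d_table.lattice)
        np.testing.assert_array_equal(stats5.occupancy, 5 * stats1.occupancy)

    def test_occupancy_counts_every_recorded_visit(self, flat_1d_table):
        states = np.array([20, 20, 20, 21])  # rejections re-record the state
        p = fw.Pathway(states=states, outcome="plus_end", accepted=1, attempted=3)
        stats = fw.ensemble_stats([p], flat_1d_table.lattice)
        assert stats.occupancy[20] == 3
        assert stats.occupancy.sum() == 4

    def test_three_state_equilibrium_occupancy_is_boltzmann(self):
        """Long non-terminating run: occupancy ratios 1 : e^-1 : e^-2."""
        kt = fw.kt_kcal(298.15)
        table = _table_1d([0.0, kt, 2 * kt])
        config = fw.MCConfig(start_index=(0, 0, 0, 0, 0, 0), temperature=298.15,
                             termination_distance=1e9, max_steps=400_000, seed=21)
        p = fw.generate_pathway(table, config)
        occ = np.bincount(p.states, minlength=3) / len(p.states)
        expected = np.exp([0, -1, -2]) / np.exp([0, -1, -2]).sum()
        np.testing.assert_allclose(occ, expected, rtol=0.02)

    def test_pathway_per_step_export_tracks_states_and_energies(self, flat_1d_table):
        config = fw.MCConfig(start_index=(0, 0, 20, 0, 0, 0), temperature=500.0,
                             termination_distance=12.0, max_steps=10_000, seed=13)
        p = fw.generate_pathway(flat_1d_table, config)
        df = fw.pathway_to_dataframe(p, flat_1d_table)
        assert len(df) == p.length
        assert list(df["flat_index"]) == list(p.states)
        assert df["moved"].iloc[0]

    def test_no_terminated_pathways_raises(self, flat_1d_table):
        p = fw.Pathway(states=np.array([0]), outcome="max_steps", accepted=0,
                       attempted=1)
        with pytest.raises(FocuswalkError):
            fw.ensemble_stats([p], flat_1d_table.lattice)
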