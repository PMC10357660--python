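"""CPM engine: energy bookkeeping, Metropolis rule, growth, division."""

import numpy as np
import pytest
from dataclasses import replace

from evocpm import _kernel
from evocpm.adhesion import genome_for_gamma
from evocpm.cpm import Simulation, accept_probability
from evocpm.environment import build_gradient
from evocpm.grn import Behaviour
from evocpm.io_config import (GenomeBundle, SimulationConfig,
                              make_fixture_genome)
from evocpm.seasons import block_sites
from conftest import small_config, uniform_field

FWD = [(0, 1), (1, -1), (1, 0), (1, 1)]  # each Moore pair counted once


def full_hamiltonian(spins, J, At, lam):
    """Independent oracle: the total energy computed from scratch with
    plain loops (adhesion over all heterotypic Moore pairs + the area
    constraint of every cell)."""
    L = spins.shape[0]
    H = 0.0
    for x in range(L):
        for y in range(L):
            for dx, dy in FWD:
                xn, yn = x + dx, y + dy
                if 0 <= xn < L and 0 <= yn < L:
                    a, b = spins[x, y], spins[xn, yn]
                    if a != b:
                        H += J[a, b]
    areas = np.bincount(spins.ravel(), minlength=At.size)
    for s in range(1, At.size):
        if areas[s] > 0 or At[s] > 0:
            H += lam * (areas[s] - At[s]) ** 2
    return H


def random_configuration(rng, L, n_cells):
    """A random multi-cell lattice with consistent bookkeeping."""
    spins = rng.integers(0, n_cells + 1, (L, L)).astype(np.int32)
    J = rng.uniform(1, 30, (n_cells + 1, n_cells + 1))
    J = (J + J.T) / 2
    np.fill_diagonal(J, 0.0)
    area = np.bincount(spins.ravel(), minlength=n_cells + 1).astype(
        np.int64)
    area[0] = 0
    At = rng.integers(1, 60, n_cells + 1).astype(np.int64)
    At[0] = 0
    return spins, J, area, At


class TestDeltaHOracle:
    def test_incremental_matches_full_recomputation(self):
        # the spec-level equivalence: incremental dH == H_after - H_before
        rng = np.random.default_rng(42)
        lam = 4.0
        for trial in range(100):
            L = int(rng.integers(8, 31))
            spins, J, area, At = random_configuration(rng, L,
                                                      int(rng.integers(2, 6)))
            # pick a site with a differing neighbour and propose a copy
            for _ in range(200):
                x, y = rng.integers(0, L, 2)
                nbrs = [(x + dx, y + dy) for dx, dy in _kernel.MOORE
                        if 0 <= x + dx < L and 0 <= y + dy < L]
                cand = [spins[p] for p in nbrs if spins[p] != spins[x, y]]
                if cand:
                    ss = int(cand[int(rng.integers(len(cand)))])
                    break
            else:
                continue
            field = np.ones((L, L), dtype=np.int32)
            got = _kernel.copy_delta_h(spins, field, J, area, At, lam,
                                       int(x), int(y), ss)
            h_before = full_hamiltonian(spins, J, At, lam)
            after = spins.copy()
            after[x, y] = ss
            h_after = full_hamiltonian(after, J, At, lam)
            assert got == pytest.approx(h_after - h_before, abs=1e-9)


class TestAcceptProbability:
    def test_dissipative_copy_always_accepted(self):
        assert accept_probability(-5.0, 16.0) == 1.0

    def test_zero_energy_change_accepted(self):
        assert accept_probability(0.0, 16.0) == 1.0

    def test_boltzmann_tail(self):
        assert accept_probability(16.0, 16.0) == pytest.approx(
            np.exp(-1), rel=1e-12)

    def test_temperature_must_be_positive(self):
        with pytest.raises(ValueError):
            accept_probability(1.0, 0.0)


def single_cell_sim(cfg, seed=3, fixture="constitutive_migrator",
                    gamma=0, flat_field=True, at=(None, None)):
    f = (uniform_field(cfg.L) if flat_field
         else build_gradient(cfg.L, "up", cfg.k_chi,
                             np.random.default_rng(seed)))
    sim = Simulation(cfg, f, seed)
    bundle = make_fixture_genome(fixture)
    top = cfg.L // 2 - 4 if at[0] is None else at[0]
    left = cfg.L // 2 - 4 if at[1] is None else at[1]
    rows, cols = block_sites(top, left, cfg.A_T)
    s = sim.add_cell(rows, cols, genome_for_gamma(gamma), bundle.grn)
    return sim, s


class TestMonteCarloStep:
    def test_pure_medium_is_inert(self):
        cfg = small_config(L=20)
        sim = Simulation(cfg, uniform_field(20), 1)
        before = sim.spins.copy()
        sim.run(50)
        assert np.array_equal(sim.spins, before)

    def test_site_conservation_and_bookkeeping(self):
        cfg = small_config(L=40)
        sim, s = single_cell_sim(cfg)
        for _ in range(5):
            sim.run(100)
            sim.audit()   # incremental state equals recomputation
            areas = np.bincount(sim.spins.ravel(),
                                minlength=sim.capacity + 1)
            assert areas.sum() == 40 * 40

    def test_area_fluctuates_around_target(self):
        # equilibrium of the area constraint over 5000 MCS
        cfg = small_config(L=40)
        sim, s = single_cell_sim(cfg)
        sim.run(500)
        samples = []
        for _ in range(90):
            sim.run(50)
            samples.append(sim.area[s])
        mean_area = np.mean(samples)
        assert abs(mean_area - cfg.A_T) / cfg.A_T < 0.10

    def test_acceptance_rate_matches_boltzmann(self):
        # instrumented counters, work terms disabled so dH is integer
        cfg = small_config(L=30, mu_p=0.0, mu_chi=0.0)
        sim, s = single_cell_sim(cfg)
        sim.enable_stats()
        sim.run(3000)
        attempts, accepts = sim.stats
        checked = 0
        for k in range(1, 64):
            n = attempts[k]
            if n < 500:
                continue
            p = np.exp(-k / cfg.T)
            se = np.sqrt(p * (1 - p) / n)
            assert abs(accepts[k] / n - p) < 3 * se + 1e-9
            checked += 1
        assert checked >= 2


class TestPersistence:
    def _arrays(self, cap=3):
        z = lambda dt: np.zeros(cap, dtype=dt)
        return dict(
            alive=z(np.uint8), behav=z(np.int8), area=z(np.int64),
            At=z(np.int64), sx=z(np.int64), sy=z(np.int64),
            chs=z(np.int64), px=z(np.float64), py=z(np.float64),
            ref_comx=z(np.float64), ref_comy=z(np.float64),
            w_in=np.zeros((cap, 2, 3)), w_reg=np.zeros((cap, 3, 3)),
            w_out=np.zeros((cap, 3)), rho_reg=np.ones((cap, 3)),
            rho_out=np.ones(cap), phi=np.zeros((cap, 2)),
            reg_state=np.zeros((cap, 3), dtype=np.int8),
            out_state=z(np.int8), streak=z(np.int32), ndiv=z(np.int32),
            grn_phase=z(np.int32), p_phase=z(np.int32),
            next_size_mcs=z(np.int64), divide_flag=z(np.uint8),
            cull_flag=z(np.uint8))

    def _tick(self, a, mcs=0):
        _kernel.update_cells(
            mcs, 1, a["alive"], a["behav"], a["area"], a["At"], a["sx"],
            a["sy"], a["chs"], a["px"], a["py"], a["ref_comx"],
            a["ref_comy"], a["w_in"], a["w_reg"], a["w_out"],
            a["rho_reg"], a["rho_out"], a["phi"], a["reg_state"],
            a["out_state"], a["streak"], a["ndiv"], a["grn_phase"],
            a["p_phase"], a["next_size_mcs"], a["divide_flag"],
            a["cull_flag"], 20, 50, 10000, 3, 50, 400)

    def test_displacement_is_normalized(self):
        a = self._arrays()
        a["alive"][1] = 1
        a["behav"][1] = 1
        a["area"][1] = 50
        a["At"][1] = 50
        a["chs"][1] = 50
        a["sx"][1] = 50 * 30
        a["sy"][1] = 50 * 40
        a["ref_comx"][1] = 27.0    # displacement (3, 4) since last update
        a["ref_comy"][1] = 36.0
        a["grn_phase"][1] = 5      # avoid a GRN tick at mcs 0
        self._tick(a)
        assert (a["px"][1], a["py"][1]) == (0.6, 0.8)
        assert (a["ref_comx"][1], a["ref_comy"][1]) == (30.0, 40.0)

    def test_zero_displacement_retains_previous_direction(self):
        a = self._arrays()
        a["alive"][1] = 1
        a["behav"][1] = 1
        a["area"][1] = 50
        a["At"][1] = 50
        a["chs"][1] = 50
        a["sx"][1] = 50 * 30
        a["sy"][1] = 50 * 40
        a["ref_comx"][1], a["ref_comy"][1] = 30.0, 40.0
        a["px"][1], a["py"][1] = 1.0, 0.0
        a["grn_phase"][1] = 5
        self._tick(a)
        assert (a["px"][1], a["py"][1]) == (1.0, 0.0)


class TestGrowthAndDivision:
    def make_divider_sim(self, L=40, tau_s=40000):
        cfg = small_config(L=L, tau_s=tau_s)
        sim, s = single_cell_sim(cfg, fixture="constitutive_divider")
        return cfg, sim, s

    def test_growth_schedule_doubles_target_area(self):
        cfg, sim, s = self.make_divider_sim()
        # eta_init wait (10000 MCS) then 1 site per eta_grow/A_T MCS
        sim.run(10000 + 30)
        assert sim.behav[s] == int(Behaviour.GROWING)
        assert sim.At[s] == cfg.A_T
        sim.run(10000)
        assert cfg.A_T + 20 <= sim.At[s] <= cfg.A_T + 27
        sim.run(11000)
        events = sim.division_events
        assert len(events) == 1 and events[0]["divisions_done"] == 1

    def test_division_partitions_sites_evenly(self, rng):
        cfg = small_config(L=40)
        sim, s = single_cell_sim(cfg)
        sim.remove_cell(s)
        rows, cols = np.meshgrid(range(10, 20), range(12, 22),
                                 indexing="ij")
        bundle = make_fixture_genome("constitutive_migrator")
        s = sim.add_cell(rows.ravel(), cols.ravel(), genome_for_gamma(0),
                         bundle.grn)   # 100-site cell
        d = sim.divide_cell(s)
        assert d is not None
        assert abs(sim.area[s] - sim.area[d]) <= 10  # within 10% of 100
        assert sim.area[s] + sim.area[d] == 100
        sim.audit()

    def test_daughters_inherit_and_reset(self):
        cfg = small_config(L=40)
        sim, s = single_cell_sim(cfg)
        sim.mutations_enabled = False
        sim.ndiv[s] = 1
        sim.streak[s] = 77
        d = sim.divide_cell(s)
        for c in (s, d):
            assert sim.ndiv[c] == 2
            assert sim.streak[c] == 0
            assert not sim.reg_state[c].any()
            assert sim.At[c] == cfg.A_T
            assert sim.behav[c] == int(Behaviour.MIGRATORY)
        assert sim.adh_genomes[d] == sim.adh_genomes[s]
        assert sim.grn_genomes[d] == sim.grn_genomes[s]

    def test_mutation_hits_exactly_one_daughter(self):
        cfg = small_config(L=40, mu_RI=1.0, mu_omega=1.0, sigma=0.1)
        sim, s = single_cell_sim(cfg)
        parent_adh = sim.adh_genomes[s].copy()
        parent_grn = sim.grn_genomes[s].copy()
        d = sim.divide_cell(s)
        changed = [c for c in (s, d)
                   if sim.adh_genomes[c] != parent_adh
                   or sim.grn_genomes[c] != parent_grn]
        unchanged = [c for c in (s, d) if c not in changed]
        assert len(changed) == 1 and len(unchanged) == 1
        u = unchanged[0]
        assert sim.adh_genomes[u] == parent_adh
        assert sim.grn_genomes[u] == parent_grn
        # with certain flips the mutant's bitstrings are complements
        m = changed[0]
        assert np.array_equal(sim.adh_genomes[m].receptor,
                              1 - parent_adh.receptor)

    def test_single_site_cell_division_deferred(self):
        cfg = small_config(L=20)
        sim = Simulation(cfg, uniform_field(20), 1)
        bundle = make_fixture_genome("constitutive_migrator")
        s = sim.add_cell([5], [5], genome_for_gamma(0), bundle.grn)
        assert sim.divide_cell(s) is None

    def test_debris_is_culled(self):
        cfg = small_config(L=20)
        sim = Simulation(cfg, uniform_field(20), 1)
        bundle = make_fixture_genome("constitutive_migrator")
        s = sim.add_cell([5, 5], [5, 6], genome_for_gamma(0), bundle.grn)
        sim.At[s] = 2   # no growth pressure: the fragment stays debris
        sim.run(1)
        assert sim.alive[s] == 0
        assert (sim.spins == 0).all()
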