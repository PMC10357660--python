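"""Cellular Potts engine: lattice state, cells, Monte Carlo updates,
growth, division and removal.

The hot loops live in :mod:`evocpm._kernel`; this module owns the
bookkeeping that is cheap but fiddly: spin allocation, the interfacial
energy matrix J, genome inheritance and mutation at division, and the
audit that incremental state matches recomputation.

Cells are identified by positive integer spins; spin 0 is the medium.
Per-cell quantities are flat arrays indexed by spin.  Areas, coordinate
sums and chemoattractant-weighted sums are maintained incrementally by
the kernel and can be audited against a from-scratch recomputation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernel, adhesion, grn
from .environment import GradientField
from .grn import Behaviour, GRNGenome

#: realized-area fraction of 2*A_T required (with a full target area)
#: before a cell may divide
DIVISION_AREA_FRACTION = 0.9


@dataclass
class EnergyParams:
    """Global CPM energetics (arbitrary units of energy, AUE)."""
    T: float = 16.0        # Boltzmann temperature
    lam: float = 4.0       # area stiffness lambda
    mu_p: float = 3.0      # persistence strength (migratory cells)
    tau_p: int = 50        # persistence refresh period, MCS
    mu_chi: float = 1.0    # chemotaxis strength (migratory cells)

    def __post_init__(self):
        if self.T <= 0:
            raise ValueError("temperature must be positive")
        if min(self.lam, self.mu_p, self.mu_chi) < 0:
            raise ValueError("energy strengths must be non-negative")


def accept_probability(delta: float, T: float) -> float:
    """Metropolis acceptance: 1 if dH + Y < 0, else exp(-(dH+Y)/T)."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    if delta < 0:
        return 1.0
    return float(np.exp(-delta / T))


@dataclass
class CellView:
    """Read-only snapshot of one cell's record."""
    spin: int
    area: int
    target_area: int
    divisions_done: int
    behaviour: Behaviour
    persistence: np.ndarray
    com: np.ndarray
    adhesion: adhesion.AdhesionGenome | None
    grn_genome: GRNGenome | None
    grn_state: grn.GRNState
    group: int


class Simulation:
    """Lattice + cells + field under one parameterization.

    Parameters
    ----------
    config : SimulationConfig
        Full parameterization (see :mod:`evocpm.io_config`).
    field : GradientField
        The season's chemoattractant field.
    seed_seq : np.random.SeedSequence | int
        Master entropy; substreams are derived deterministically per
        subsystem (kernel, mutation, placement, ...) so adding a
        subsystem never perturbs existing streams.
    fixed_j : tuple (J_cc, J_cm) or None
        When set, interfacial energies ignore the genomes (the
        "adhesion cannot evolve" regime, canonically (36, 14)).
    """

    def __init__(self, config, field: GradientField, seed_seq,
                 fixed_j: tuple[float, float] | None = None):
        from .io_config import SimulationConfig  # avoid cycle
        if not isinstance(config, SimulationConfig):
            raise TypeError("config must be a SimulationConfig")
        self.config = config
        self.params = EnergyParams(T=config.T, lam=config.lam,
                                   mu_p=config.mu_p, tau_p=config.tau_p,
                                   mu_chi=config.mu_chi)
        self.L = field.L
        self.field = field
        self.fixed_j = fixed_j
        if not isinstance(seed_seq, np.random.SeedSequence):
            seed_seq = np.random.SeedSequence(seed_seq)
        self.seed_seq = seed_seq
        kernel_ss, py_ss, mut_ss, env_ss, cull_ss = seed_seq.spawn(5)
        self.kernel_state = np.array(
            [_kernel.seed_state(kernel_ss.generate_state(1)[0] or 1)],
            dtype=np.uint64)
        self.rng = np.random.Generator(np.random.PCG64(py_ss))
        self.mut_rng = np.random.Generator(np.random.PCG64(mut_ss))
        #: season-level streams: gradient construction and end-of-season
        #: culling draws (kept separate so adding draws to one subsystem
        #: never perturbs another)
        self.env_rng = np.random.Generator(np.random.PCG64(env_ss))
        self.cull_rng = np.random.Generator(np.random.PCG64(cull_ss))

        self.spins = np.zeros((self.L, self.L), dtype=np.int32)
        self.mcs = 0          # season-local time
        self.season = 0
        self.n_spins = 0      # highest spin id ever allocated this season
        self.division_events: list[dict] = []
        self.mutations_enabled = True
        self._stats = None
        self._alloc(max(64, config.init_population * 8 + 8))

    # ---------------------------------------------------------- storage

    def _alloc(self, cap: int) -> None:
        z = lambda dt: np.zeros(cap + 1, dtype=dt)
        self.area = z(np.int64)
        self.At = z(np.int64)
        self.sx = z(np.int64)
        self.sy = z(np.int64)
        self.chs = z(np.int64)
        self.chx = z(np.int64)
        self.chy = z(np.int64)
        self.px = z(np.float64)
        self.py = z(np.float64)
        self.behav = z(np.int8)
        self.alive = z(np.uint8)
        self.ref_comx = z(np.float64)
        self.ref_comy = z(np.float64)
        self.w_in = np.zeros((cap + 1, 2, 3))
        self.w_reg = np.zeros((cap + 1, 3, 3))
        self.w_out = np.zeros((cap + 1, 3))
        self.rho_reg = np.zeros((cap + 1, 3))
        self.rho_out = z(np.float64)
        self.phi = np.zeros((cap + 1, 2))
        self.reg_state = np.zeros((cap + 1, 3), dtype=np.int8)
        self.out_state = z(np.int8)
        self.streak = z(np.int32)
        self.ndiv = z(np.int32)
        self.grn_phase = z(np.int32)
        self.p_phase = z(np.int32)
        self.next_size_mcs = z(np.int64)
        self.divide_flag = z(np.uint8)
        self.cull_flag = z(np.uint8)
        self.group = z(np.int32)
        self.J = np.zeros((cap + 1, cap + 1))
        self.adh_genomes: list = [None] * (cap + 1)
        self.grn_genomes: list = [None] * (cap + 1)
        self.capacity = cap

    def _grow_capacity(self, cap: int) -> None:
        old = self.__dict__.copy()
        old_cap = self.capacity
        self._alloc(cap)
        for name in ("area", "At", "sx", "sy", "chs", "chx", "chy", "px",
                     "py", "behav", "alive", "ref_comx", "ref_comy",
                     "w_in", "w_reg", "w_out", "rho_reg", "rho_out", "phi",
                     "reg_state", "out_state", "streak", "ndiv",
                     "grn_phase", "p_phase", "next_size_mcs",
                     "divide_flag", "cull_flag", "group"):
            getattr(self, name)[:old_cap + 1] = old[name]
        self.J[:old_cap + 1, :old_cap + 1] = old["J"]
        self.adh_genomes[:old_cap + 1] = old["adh_genomes"]
        self.grn_genomes[:old_cap + 1] = old["grn_genomes"]

    # ------------------------------------------------------------ cells

    def add_cell(self, rows, cols, adh_genome, grn_genome, group: int = 0,
                 divisions_done: int = 0) -> int:
        """Place a new cell on currently-medium sites; returns its spin."""
        rows = np.asarray(rows, dtype=np.int64)
        cols = np.asarray(cols, dtype=np.int64)
        if rows.size == 0:
            raise ValueError("a cell needs at least one site")
        if np.any(self.spins[rows, cols] != 0):
            raise ValueError("target sites are not all medium")
        if self.n_spins + 1 > self.capacity:
            self._grow_capacity(self.capacity * 2)
        s = self.n_spins + 1
        self.n_spins = s
        self.spins[rows, cols] = s
        self.alive[s] = 1
        self.group[s] = group
        self.adh_genomes[s] = adh_genome.copy()
        self.grn_genomes[s] = grn_genome.copy()
        self._load_grn_arrays(s)
        self.area[s] = rows.size
        self.At[s] = self.config.A_T
        self.sx[s] = rows.sum()
        self.sy[s] = cols.sum()
        f = self.field.values[rows, cols].astype(np.int64)
        self.chs[s] = f.sum()
        self.chx[s] = (f * rows).sum()
        self.chy[s] = (f * cols).sum()
        self.behav[s] = int(Behaviour.MIGRATORY)
        self.ndiv[s] = divisions_done
        self.px[s] = self.py[s] = 0.0
        self.ref_comx[s] = self.sx[s] / self.area[s]
        self.ref_comy[s] = self.sy[s] / self.area[s]
        self.grn_phase[s] = int(self.rng.integers(0, grn.GRN_PERIOD))
        self.p_phase[s] = int(self.rng.integers(0, self.params.tau_p))
        self.reg_state[s] = 0
        self.out_state[s] = 0
        self.streak[s] = 0
        self._set_j_for(s)
        return s

    def _load_grn_arrays(self, s: int) -> None:
        g = self.grn_genomes[s]
        self.w_in[s] = g.w_in
        self.w_reg[s] = g.w_reg
        self.w_out[s] = g.w_out
        self.rho_reg[s] = g.rho_reg
        self.rho_out[s] = g.rho_out
        self.phi[s] = g.phi

    def _set_j_for(self, s: int) -> None:
        """(Re)compute row/column s of the interfacial energy matrix."""
        if self.fixed_j is not None:
            j_cc, j_cm = self.fixed_j
            self.J[s, 0] = self.J[0, s] = j_cm
            for o in range(1, self.n_spins + 1):
                if o != s and self.alive[o]:
                    self.J[s, o] = self.J[o, s] = j_cc
            return
        a = self.adh_genomes[s]
        self.J[s, 0] = self.J[0, s] = adhesion.j_cell_medium(a)
        for o in range(1, self.n_spins + 1):
            if o != s and self.alive[o]:
                j = adhesion.j_cell_cell(a, self.adh_genomes[o])
                self.J[s, o] = self.J[o, s] = j

    def rebuild_J(self) -> None:
        """Vectorized rebuild of the full interfacial-energy matrix."""
        self.J[:] = 0.0
        spins = self.cell_spins()
        if spins.size == 0:
            return
        if self.fixed_j is not None:
            j_cc, j_cm = self.fixed_j
            self.J[np.ix_(spins, spins)] = j_cc
            self.J[spins, spins] = 0.0
            self.J[spins, 0] = self.J[0, spins] = j_cm
            return
        R = np.stack([self.adh_genomes[s].receptor for s in spins])
        I = np.stack([self.adh_genomes[s].ligand for s in spins])
        D = (R[:, None, :] != I[None, :, :]).sum(axis=2)
        jcc = adhesion.J_ALPHA + 2 * adhesion.NU - D - D.T
        self.J[np.ix_(spins, spins)] = jcc
        self.J[spins, spins] = 0.0
        jcm = (adhesion.J_ALPHA_PRIME
               + I[:, :adhesion.NU_PRIME] @ adhesion.F_MEDIUM)
        self.J[spins, 0] = self.J[0, spins] = jcm

    def cell_spins(self) -> np.ndarray:
        return np.flatnonzero(self.alive[:self.n_spins + 1]).astype(int)

    def com(self, s: int) -> np.ndarray:
        return np.array([self.sx[s], self.sy[s]]) / self.area[s]

    def perceived_concentration(self, s: int) -> float:
        return float(self.chs[s] / self.area[s])

    def gamma(self, s: int) -> float:
        """Homotypic surface tension of cell s (fixed-energy regime
        aware)."""
        if self.fixed_j is not None:
            j_cc, j_cm = self.fixed_j
            return adhesion.surface_tension(j_cm, j_cc)
        return adhesion.gamma_of(self.adh_genomes[s])

    def cell_view(self, s: int) -> CellView:
        state = grn.GRNState(self.reg_state[s].copy(),
                             int(self.out_state[s]), int(self.streak[s]))
        return CellView(spin=s, area=int(self.area[s]),
                        target_area=int(self.At[s]),
                        divisions_done=int(self.ndiv[s]),
                        behaviour=Behaviour(int(self.behav[s])),
                        persistence=np.array([self.px[s], self.py[s]]),
                        com=self.com(s),
                        adhesion=self.adh_genomes[s],
                        grn_genome=self.grn_genomes[s],
                        grn_state=state, group=int(self.group[s]))

    # ------------------------------------------------------------ field

    def set_field(self, field: GradientField) -> None:
        if field.L != self.L:
            raise ValueError("field size does not match lattice")
        self.field = field
        _kernel.accumulate_chi(self.spins, field.values, self.chs,
                               self.chx, self.chy)

    # ---------------------------------------------------------- running

    def enable_stats(self, n_bins: int = 64) -> None:
        """Collect per-integer-energy attempt/accept counters (only
        meaningful when the work terms are zero so dH + Y is integer)."""
        self._stats = (np.zeros(n_bins, dtype=np.int64),
                       np.zeros(n_bins, dtype=np.int64))

    @property
    def stats(self):
        return self._stats

    def step(self) -> None:
        """One MCS: L*L copy attempts, then cell maintenance."""
        if self._stats is None:
            sa = sc = np.zeros(1, dtype=np.int64)
            collect = False
        else:
            sa, sc = self._stats
            collect = True
        p = self.params
        _kernel.run_mcs(self.spins, self.field.values, self.J, self.area,
                        self.At, self.sx, self.sy, self.chs, self.chx,
                        self.chy, self.px, self.py, self.behav,
                        p.lam, p.T, p.mu_p, p.mu_chi, self.kernel_state,
                        sa, sc, collect)
        flagged = _kernel.update_cells(
            self.mcs, self.n_spins, self.alive, self.behav, self.area,
            self.At, self.sx, self.sy, self.chs, self.px, self.py,
            self.ref_comx, self.ref_comy,
            self.w_in, self.w_reg, self.w_out, self.rho_reg, self.rho_out,
            self.phi, self.reg_state, self.out_state, self.streak,
            self.ndiv, self.grn_phase, self.p_phase, self.next_size_mcs,
            self.divide_flag, self.cull_flag,
            grn.GRN_PERIOD, p.tau_p, self.config.eta_init,
            self.config.max_divisions, self.config.A_T,
            self.config.eta_grow // self.config.A_T)
        if flagged:
            self._handle_flags()
        self.mcs += 1

    def _handle_flags(self) -> None:
        if self.cull_flag.any():
            for s in np.flatnonzero(self.cull_flag):
                self.remove_cell(int(s))
                self.cull_flag[s] = 0
        if self.divide_flag.any():
            for s in np.flatnonzero(self.divide_flag):
                self.divide_flag[s] = 0
                if self.alive[s]:
                    self.divide_cell(int(s))

    def run(self, n_mcs: int) -> None:
        """Advance ``n_mcs`` Monte Carlo steps.

        Equivalent to ``n_mcs`` calls of :meth:`step` but batched inside
        the compiled kernel; the batch returns to Python only when a
        division or debris event needs handling.
        """
        if self._stats is None:
            sa = sc = np.zeros(1, dtype=np.int64)
            collect = False
        else:
            sa, sc = self._stats
            collect = True
        p = self.params
        remaining = n_mcs
        while remaining > 0:
            done = _kernel.run_block(
                remaining, self.mcs, self.spins, self.field.values,
                self.J, self.area, self.At, self.sx, self.sy, self.chs,
                self.chx, self.chy, self.px, self.py, self.behav,
                p.lam, p.T, p.mu_p, p.mu_chi, self.kernel_state,
                sa, sc, collect,
                self.n_spins, self.alive, self.ref_comx, self.ref_comy,
                self.w_in, self.w_reg, self.w_out, self.rho_reg,
                self.rho_out, self.phi, self.reg_state, self.out_state,
                self.streak, self.ndiv, self.grn_phase, self.p_phase,
                self.next_size_mcs, self.divide_flag, self.cull_flag,
                grn.GRN_PERIOD, p.tau_p, self.config.eta_init,
                self.config.max_divisions, self.config.A_T,
                self.config.eta_grow // self.config.A_T)
            self.mcs += done
            remaining -= done
            self._handle_flags()

    # --------------------------------------------------------- division

    def divide_cell(self, s: int) -> int | None:
        """Split cell s through a plane perpendicular to its long axis.

        Both daughters: target area back to A_T, GRN states reset,
        division counter incremented.  Exactly one daughter (chosen at
        random) receives GRN-parameter and, when adhesion evolves,
        bitstring mutations.  Returns the new spin, or None when the
        cell has fewer than 2 sites (division deferred).
        """
        sites = np.argwhere(self.spins == s)
        if sites.shape[0] < 2:
            return None
        conc_at_division = self.perceived_concentration(s)
        centered = sites - sites.mean(axis=0)
        cov = centered.T @ centered
        evals, evecs = np.linalg.eigh(cov)
        axis = evecs[:, int(np.argmax(evals))]
        proj = centered @ axis
        # median split perpendicular to the long axis; random jitter
        # breaks projection ties so equal halves are possible
        proj = proj + self.rng.normal(0.0, 1e-9, proj.shape)
        order = np.argsort(proj)
        half = sites.shape[0] // 2
        keep, give = sites[order[:half]], sites[order[half:]]
        if self.rng.random() < 0.5:
            keep, give = give, keep

        if self.n_spins + 1 > self.capacity:
            self._grow_capacity(self.capacity * 2)
        d = self.n_spins + 1
        self.n_spins = d
        self.spins[give[:, 0], give[:, 1]] = d
        self.alive[d] = 1
        self.group[d] = self.group[s]

        new_ndiv = int(self.ndiv[s]) + 1
        adh_parent = self.adh_genomes[s]
        grn_parent = self.grn_genomes[s]
        self.adh_genomes[d] = adh_parent.copy()
        self.grn_genomes[d] = grn_parent.copy()
        mutated = None
        if self.mutations_enabled:
            mutated = s if self.mut_rng.random() < 0.5 else d
            cfg = self.config
            self.grn_genomes[mutated] = grn.mutate_grn(
                self.grn_genomes[mutated], cfg.mu_omega, cfg.sigma,
                self.mut_rng)
            if cfg.adhesion_evolvable:
                self.adh_genomes[mutated] = adhesion.mutate_bitstrings(
                    self.adh_genomes[mutated], cfg.mu_RI, self.mut_rng)

        for spin, cell_sites in ((s, keep), (d, give)):
            rows, cols = cell_sites[:, 0], cell_sites[:, 1]
            self.area[spin] = rows.size
            self.sx[spin] = rows.sum()
            self.sy[spin] = cols.sum()
            f = self.field.values[rows, cols].astype(np.int64)
            self.chs[spin] = f.sum()
            self.chx[spin] = (f * rows).sum()
            self.chy[spin] = (f * cols).sum()
            self.At[spin] = self.config.A_T
            self.behav[spin] = int(Behaviour.MIGRATORY)
            self.ndiv[spin] = new_ndiv
            self.reg_state[spin] = 0
            self.out_state[spin] = 0
            self.streak[spin] = 0
            self.ref_comx[spin] = self.sx[spin] / self.area[spin]
            self.ref_comy[spin] = self.sy[spin] / self.area[spin]
            self._load_grn_arrays(spin)
        # daughter inherits the persistence direction; phases are drawn
        # fresh for the new spin (not inherited)
        self.px[d], self.py[d] = self.px[s], self.py[s]
        self.grn_phase[d] = int(self.rng.integers(0, grn.GRN_PERIOD))
        self.p_phase[d] = int(self.rng.integers(0, self.params.tau_p))
        self._set_j_for(d)
        if mutated == s:
            self._set_j_for(s)
        self.division_events.append(dict(
            season=self.season, mcs=self.mcs, parent=s, child=d,
            divisions_done=new_ndiv, concentration=conc_at_division,
            group=int(self.group[s])))
        return d

    def remove_cell(self, s: int) -> None:
        """Return a cell's sites to medium and drop its record."""
        sites = np.argwhere(self.spins == s)
        self.spins[sites[:, 0], sites[:, 1]] = 0
        self.alive[s] = 0
        self.behav[s] = 0
        for name in ("area", "sx", "sy", "chs", "chx", "chy"):
            getattr(self, name)[s] = 0
        self.adh_genomes[s] = None
        self.grn_genomes[s] = None

    # ------------------------------------------------------------ audit

    def audit(self) -> None:
        """Verify incremental bookkeeping against recomputation."""
        cap = self.capacity
        area = np.zeros(cap + 1, dtype=np.int64)
        sx = np.zeros(cap + 1, dtype=np.int64)
        sy = np.zeros(cap + 1, dtype=np.int64)
        _kernel.accumulate_geometry(self.spins, area, sx, sy)
        chs = np.zeros(cap + 1, dtype=np.int64)
        chx = np.zeros(cap + 1, dtype=np.int64)
        chy = np.zeros(cap + 1, dtype=np.int64)
        _kernel.accumulate_chi(self.spins, self.field.values, chs, chx, chy)
        ok = (np.array_equal(area, self.area)
              and np.array_equal(sx, self.sx)
              and np.array_equal(sy, self.sy)
              and np.array_equal(chs, self.chs)
              and np.array_equal(chx, self.chx)
              and np.array_equal(chy, self.chy))
        if not ok:
            raise RuntimeError(
                "incremental cell bookkeeping diverged from recomputation")
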