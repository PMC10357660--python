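"""Seasonal evolutionary loop.

A season is ``tau_s`` MCS of cell dynamics followed by distance-
dependent culling, a per-season state reset (division counters, GRN
states) and a random relocation of the chemoattractant peak.  Cells
closer to the peak at the end of the season survive more often:

    P_death(d) = p_min + (p_max - p_min) * d^3 / (d_scale^3 + d^3),

a Hill curve rising from ``p_min`` at the peak toward ``p_max`` far
away, half-way between the two at ``d = d_scale``.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np

from .cpm import Simulation
from .environment import build_gradient, relocate_peak
from .grn import Behaviour
from .io_config import GenomeBundle, SimulationConfig


def death_probability(d_c, cfg: SimulationConfig) -> np.ndarray | float:
    """Probability that a cell at distance ``d_c`` from the peak dies at
    the season boundary."""
    d = np.asarray(d_c, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance to peak cannot be negative")
    p = cfg.p_min + (cfg.p_max - cfg.p_min) * d**3 / (cfg.d_scale**3 + d**3)
    return float(p) if np.isscalar(d_c) else p


def survival_mask(distances, cfg: SimulationConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Independent survival draws, one per cell, in the given order."""
    d = np.atleast_1d(np.asarray(distances, dtype=float))
    return rng.random(d.size) >= death_probability(d, cfg)


@dataclass
class SeasonRecord:
    """Per-season observables."""
    season: int
    population_start: int
    population_end: int       # before culling
    survivors: int            # after culling
    deaths: int
    median_gamma: float
    #: per-order median division time (MCS within the season), NaN when
    #: no division of that order happened
    median_division_times: tuple[float, float, float] = (np.nan,) * 3
    #: distances to the peak at season end (before culling)
    end_distances: np.ndarray = dfield(default_factory=lambda: np.array([]))
    #: (mcs, median distance) trace sampled through the season
    distance_trace: list = dfield(default_factory=list)
    extinct: bool = False
    #: division events of this season (copies of the simulation log)
    division_events: list = dfield(default_factory=list)


def _median_division_times(events, max_divisions: int):
    out = []
    for order in range(1, max_divisions + 1):
        times = [e["mcs"] for e in events if e["divisions_done"] == order]
        out.append(float(np.median(times)) if times else np.nan)
    return tuple(out)


def population_gammas(sim: Simulation) -> np.ndarray:
    return np.array([sim.gamma(int(s)) for s in sim.cell_spins()])


def run_season(sim: Simulation, trace_samples: int = 20) -> SeasonRecord:
    """Run ``tau_s`` MCS of cell dynamics and collect observables.

    Does not cull or roll over; callers follow with
    :func:`apply_culling` and :func:`season_rollover`.  Terminates early
    (record marked extinct) if every cell disappears mid-season.
    """
    cfg = sim.config
    n_events_before = len(sim.division_events)
    start = len(sim.cell_spins())
    record = SeasonRecord(season=sim.season, population_start=start,
                          population_end=0, survivors=0, deaths=0,
                          median_gamma=np.nan)
    sample_every = max(1, cfg.tau_s // trace_samples)
    while sim.mcs < cfg.tau_s:
        chunk = min(sample_every - sim.mcs % sample_every,
                    cfg.tau_s - sim.mcs)
        sim.run(chunk)
        if sim.mcs % sample_every == 0 or sim.mcs == cfg.tau_s:
            spins = sim.cell_spins()
            if spins.size == 0:
                record.extinct = True
                break
            d = np.array([sim.field.distance_to_peak(*sim.com(int(s)))
                          for s in spins])
            record.distance_trace.append((sim.mcs, float(np.median(d))))
    spins = sim.cell_spins()
    record.population_end = spins.size
    record.extinct = spins.size == 0
    record.division_events = [e for e in sim.division_events[n_events_before:]]
    record.median_division_times = _median_division_times(
        record.division_events, cfg.max_divisions)
    if spins.size:
        record.end_distances = np.array(
            [sim.field.distance_to_peak(*sim.com(int(s))) for s in spins])
        record.median_gamma = float(np.median(population_gammas(sim)))
    return record


def apply_culling(sim: Simulation, record: SeasonRecord | None = None
                  ) -> int:
    """Remove each cell independently with P_death of its end-of-season
    centre-of-mass distance to the peak; returns the death count.

    Draws are made in cell-id order from the simulation's dedicated
    culling stream, so outcomes are reproducible under a fixed seed.
    """
    spins = sim.cell_spins()
    if spins.size == 0:
        if record is not None:
            record.extinct = True
        return 0
    d = np.array([sim.field.distance_to_peak(*sim.com(int(s)))
                  for s in spins])
    keep = survival_mask(d, sim.config, sim.cull_rng)
    for s in spins[~keep]:
        sim.remove_cell(int(s))
    deaths = int((~keep).sum())
    if record is not None:
        record.deaths = deaths
        record.survivors = int(keep.sum())
        record.extinct = record.survivors == 0
    return deaths


def season_rollover(sim: Simulation) -> None:
    """Start the next season: compact spin ids, reset division counters
    and GRN states of the survivors, relocate the peak and rebuild the
    gradient.  Genomes, positions and persistence vectors carry over."""
    _compact(sim)
    spins = sim.cell_spins()
    sim.ndiv[spins] = 0
    sim.reg_state[spins] = 0
    sim.out_state[spins] = 0
    sim.streak[spins] = 0
    sim.behav[spins] = int(Behaviour.MIGRATORY)
    sim.season += 1
    sim.mcs = 0
    # stale growth schedules would fire immediately at MCS 0
    sim.next_size_mcs[spins] = sim.config.eta_grow // sim.config.A_T
    side = relocate_peak(sim.env_rng)
    field = build_gradient(sim.L, side, sim.config.k_chi, sim.env_rng)
    sim.set_field(field)


def _compact(sim: Simulation) -> None:
    """Relabel surviving cells to contiguous spins 1..n."""
    spins = sim.cell_spins()
    mapping = np.zeros(sim.n_spins + 1, dtype=np.int32)
    mapping[spins] = np.arange(1, spins.size + 1, dtype=np.int32)
    sim.spins = mapping[sim.spins]
    order = spins  # old ids in ascending order -> new ids 1..n
    for name in ("area", "At", "sx", "sy", "chs", "chx", "chy", "px",
                 "py", "behav", "out_state", "streak", "ndiv",
                 "grn_phase", "p_phase", "next_size_mcs", "group",
                 "ref_comx", "ref_comy"):
        arr = getattr(sim, name)
        arr[1:spins.size + 1] = arr[order]
        arr[spins.size + 1:] = 0
    sim.reg_state[1:spins.size + 1] = sim.reg_state[order]
    sim.reg_state[spins.size + 1:] = 0
    for name in ("w_in", "w_reg", "w_out", "rho_reg", "rho_out", "phi"):
        arr = getattr(sim, name)
        arr[1:spins.size + 1] = arr[order]
    genomes_a = [sim.adh_genomes[s] for s in order]
    genomes_g = [sim.grn_genomes[s] for s in order]
    sim.adh_genomes = [None] + genomes_a + [None] * (sim.capacity
                                                     - spins.size)
    sim.grn_genomes = [None] + genomes_g + [None] * (sim.capacity
                                                     - spins.size)
    sim.alive[:] = 0
    sim.alive[1:spins.size + 1] = 1
    sim.n_spins = spins.size
    if sim.n_spins * 8 > sim.capacity:
        sim._grow_capacity(sim.n_spins * 8 + 8)
    sim.rebuild_J()


# ------------------------------------------------------------- seeding

def block_sites(top: int, left: int, n_sites: int):
    """A compact, near-square block of exactly ``n_sites`` sites."""
    w = int(np.ceil(np.sqrt(n_sites)))
    rows, cols = [], []
    for k in range(n_sites):
        rows.append(top + k // w)
        cols.append(left + k % w)
    return np.array(rows), np.array(cols)


def seed_population(sim: Simulation, bundles: list[GenomeBundle],
                    rng: np.random.Generator, groups=None) -> None:
    """Place one cell per bundle at random non-overlapping positions,
    each planted as a compact block of A_T sites."""
    cfg = sim.config
    w = int(np.ceil(np.sqrt(cfg.A_T)))
    pitch = w + 2
    slots = [(r, c) for r in range(1, sim.L - w - 1, pitch)
             for c in range(1, sim.L - w - 1, pitch)]
    if len(slots) < len(bundles):
        raise ValueError("lattice too small for the requested population")
    idx = rng.permutation(len(slots))[:len(bundles)]
    for k, (b, slot) in enumerate(zip(bundles, (slots[i] for i in idx))):
        rows, cols = block_sites(slot[0], slot[1], cfg.A_T)
        group = 0 if groups is None else groups[k]
        sim.add_cell(rows, cols, b.adhesion, b.grn, group=group)


def random_bundles(n: int, rng: np.random.Generator) -> list[GenomeBundle]:
    """Random GRN parameters (uniform in [-1, 1]) and random bitstrings:
    the canonical starting population for evolutionary runs."""
    from .grn import GRNGenome
    from .adhesion import AdhesionGenome
    return [GenomeBundle(GRNGenome.random(rng), AdhesionGenome.random(rng))
            for _ in range(n)]
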