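"""The three experiment protocols and their analysis metrics.

* Evolutionary runs: a population seeded with random (or supplied)
  genomes evolves over many seasons, with or without evolvable
  adhesion; without it, every interface uses the fixed non-adhesive
  energies (J_cc = 36, J_cm = 14, gamma = -4).
* Regime-switch continuations: a clonal population founded from one
  ancestor evolves under the opposite adhesion regime.
* Competition experiments: two mutation-free groups of 16 cells placed
  side by side at the lattice end opposite the peak, run until one
  group goes extinct.
* Clonal-cluster development: one season of 50 genetically identical
  adhering cells, sampled frame by frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import adhesion, seasons
from .cpm import Simulation
from .environment import (GradientField, build_gradient, peak_coordinate,
                          relocate_peak)
from .io_config import GenomeBundle, SimulationConfig
from .seasons import (SeasonRecord, apply_culling, block_sites,
                      random_bundles, run_season, season_rollover,
                      seed_population)

#: the fixed-energy regime used when adhesion cannot evolve
FIXED_NONADHESIVE = (adhesion.J_CC_FIXED, adhesion.J_CM_FIXED)


@dataclass
class RunLog:
    """Outcome of a multi-season run."""
    config: SimulationConfig
    records: list[SeasonRecord]
    extinct: bool
    sim: Simulation

    @property
    def division_events(self) -> list[dict]:
        return [e for r in self.records for e in r.division_events]

    def gamma_series(self) -> np.ndarray:
        return np.array([r.median_gamma for r in self.records])


def new_simulation(cfg: SimulationConfig, seed=None,
                   fixed_j=None) -> Simulation:
    """Build a simulation with its first-season gradient drawn from the
    run's own environment stream."""
    L = cfg.L
    placeholder = GradientField(values=np.ones((L, L), dtype=np.int32),
                                peak_side="up",
                                peak=peak_coordinate(L, "up"),
                                k_chi=cfg.k_chi, d_max=1.0)
    sim = Simulation(cfg, placeholder, cfg.seed if seed is None else seed,
                     fixed_j=fixed_j)
    side = relocate_peak(sim.env_rng)
    sim.set_field(build_gradient(L, side, cfg.k_chi, sim.env_rng))
    return sim


def run_evolution(cfg: SimulationConfig, adhesion_evolvable: bool | None
                  = None, seed=None, seed_bundles=None, n_seasons=None,
                  stop_when=None, on_season=None) -> RunLog:
    """The evolutionary protocol: seasons of dynamics + culling +
    rollover until ``n_seasons`` (default ``cfg.seasons``), extinction,
    or ``stop_when(record)`` is satisfied."""
    if adhesion_evolvable is None:
        adhesion_evolvable = cfg.adhesion_evolvable
    from dataclasses import replace
    cfg = replace(cfg, adhesion_evolvable=adhesion_evolvable)
    fixed_j = None if adhesion_evolvable else FIXED_NONADHESIVE
    sim = new_simulation(cfg, seed=seed, fixed_j=fixed_j)
    if seed_bundles is None:
        bundles = random_bundles(cfg.init_population, sim.rng)
    else:
        bundles = [seed_bundles[i % len(seed_bundles)].copy()
                   for i in range(cfg.init_population)]
    seed_population(sim, bundles, sim.rng)
    n_seasons = cfg.seasons if n_seasons is None else n_seasons
    records: list[SeasonRecord] = []
    for _ in range(n_seasons):
        record = run_season(sim)
        if not record.extinct:
            apply_culling(sim, record)
        records.append(record)
        if on_season is not None:
            on_season(sim, record)
        if record.extinct:
            return RunLog(cfg, records, True, sim)
        if stop_when is not None and stop_when(record):
            break
        season_rollover(sim)
    return RunLog(cfg, records, False, sim)


def run_switch_experiment(ancestor: GenomeBundle,
                          adhesion_evolvable: bool,
                          cfg: SimulationConfig, seed=None,
                          n_seasons=None, stop_when=None) -> RunLog:
    """Continuation under the flipped adhesion regime: the population is
    founded clonally from one ancestor (season-1 genomes identical) and
    evolves with mutation under the new regime."""
    bundles = [ancestor.copy() for _ in range(cfg.init_population)]
    return run_evolution(cfg, adhesion_evolvable=adhesion_evolvable,
                         seed=seed, seed_bundles=bundles,
                         n_seasons=n_seasons, stop_when=stop_when)


# -------------------------------------------------------- competition

@dataclass
class CompetitionSetup:
    """Two mutation-free groups of equal size."""
    bundle_a: GenomeBundle
    bundle_b: GenomeBundle
    n_per_group: int = 16


@dataclass
class CompetitionResult:
    #: 'a', 'b' for a win, 'draw' on simultaneous extinction, None if
    #: the season cap was hit first
    winner: str | None
    seasons_run: int
    #: per-season rows: dict(season, size_a, size_b, dist_pct_a, dist_pct_b)
    season_trace: list
    #: within-season samples of (mcs, group, size, distance_pct),
    #: first season only
    first_season_trace: list
    sim: Simulation


def _group_stats(sim: Simulation):
    spins = sim.cell_spins()
    out = {}
    for g in (0, 1):
        sel = [int(s) for s in spins if sim.group[s] == g]
        if sel:
            d = np.array([sim.field.distance_to_peak(*sim.com(s))
                          for s in sel])
            out[g] = (len(sel), float(np.median(d)))
        else:
            out[g] = (0, np.nan)
    return out


def distance_percent(d, d_max) -> np.ndarray | float:
    """0% = maximum distance from the peak, 100% = at the peak."""
    return 100.0 * (1.0 - np.asarray(d, dtype=float) / d_max)


def place_competition_groups(sim: Simulation, setup: CompetitionSetup
                             ) -> None:
    """Two adjacent rectangular blocks of cells centred on the boundary
    opposite the gradient peak."""
    cfg = sim.config
    w = int(np.ceil(np.sqrt(cfg.A_T)))
    pitch = w + 1
    per_row = int(np.ceil(np.sqrt(setup.n_per_group)))
    n_rows = int(np.ceil(setup.n_per_group / per_row))
    block_w = per_row * pitch
    block_h = n_rows * pitch
    L = sim.L
    # local frame: peak at the top, groups side by side at the bottom
    top = L - 2 - block_h
    left_a = L // 2 - block_w
    coords = []
    for g, left in ((0, left_a), (1, left_a + block_w)):
        k = 0
        for r in range(n_rows):
            for c in range(per_row):
                if k >= setup.n_per_group:
                    break
                coords.append((g, top + r * pitch, left + c * pitch))
                k += 1
    side = sim.field.peak_side

    def transform(row, col):
        if side == "up":
            return row, col
        if side == "down":
            return L - 1 - row, col
        if side == "left":
            return col, row
        return col, L - 1 - row   # right

    for g, r0, c0 in coords:
        rows, cols = block_sites(0, 0, cfg.A_T)
        rr, cc = zip(*(transform(r0 + int(a), c0 + int(b))
                       for a, b in zip(rows, cols)))
        bundle = setup.bundle_a if g == 0 else setup.bundle_b
        sim.add_cell(np.array(rr), np.array(cc), bundle.adhesion,
                     bundle.grn, group=g)


def run_competition(setup: CompetitionSetup, cfg: SimulationConfig,
                    seed=None, max_seasons: int = 50,
                    trace_samples: int = 12) -> CompetitionResult:
    """Iterate seasons without mutation until one group is extinct."""
    sim = new_simulation(cfg, seed=seed)
    sim.mutations_enabled = False
    place_competition_groups(sim, setup)
    d_max = sim.field.d_max
    season_trace = []
    first_trace = []
    winner = None
    n_run = 0
    for season in range(max_seasons):
        sample_every = max(1, cfg.tau_s // trace_samples)
        while sim.mcs < cfg.tau_s:
            chunk = min(sample_every - sim.mcs % sample_every,
                        cfg.tau_s - sim.mcs)
            sim.run(chunk)
            if season == 0 and sim.mcs % sample_every == 0:
                stats = _group_stats(sim)
                for g in (0, 1):
                    size, dmed = stats[g]
                    first_trace.append(dict(
                        mcs=sim.mcs, group="ab"[g], size=size,
                        distance_pct=distance_percent(dmed, d_max)
                        if size else np.nan))
        apply_culling(sim)
        stats = _group_stats(sim)
        season_trace.append(dict(
            season=season, size_a=stats[0][0], size_b=stats[1][0],
            dist_pct_a=distance_percent(stats[0][1], d_max)
            if stats[0][0] else np.nan,
            dist_pct_b=distance_percent(stats[1][1], d_max)
            if stats[1][0] else np.nan))
        n_run = season + 1
        if stats[0][0] == 0 and stats[1][0] == 0:
            winner = "draw"
            break
        if stats[1][0] == 0:
            winner = "a"
            break
        if stats[0][0] == 0:
            winner = "b"
            break
        season_rollover(sim)
        d_max = sim.field.d_max
    return CompetitionResult(winner=winner, seasons_run=n_run,
                             season_trace=season_trace,
                             first_season_trace=first_trace, sim=sim)


# -------------------------------------------------- clonal development

@dataclass
class DevelopmentFrame:
    mcs: int
    #: per-cell rows: (spin, com_row, com_col, behaviour, divisions_done)
    cells: list
    cluster_com: tuple


def run_clonal_development(bundle: GenomeBundle, cfg: SimulationConfig,
                           n_cells: int = 50, seed=None,
                           sample_every: int = 2000
                           ) -> tuple[list[DevelopmentFrame], Simulation]:
    """One season of a genetically homogeneous cluster, sampled at a
    fixed MCS interval; mutations never occur.  Returns the frame series
    and the end-of-season simulation."""
    sim = new_simulation(cfg, seed=seed)
    sim.mutations_enabled = False
    # a compact cluster on the side opposite the peak
    per_row = int(np.ceil(np.sqrt(n_cells)))
    w = int(np.ceil(np.sqrt(cfg.A_T)))
    pitch = w + 1
    L = sim.L
    side = sim.field.peak_side
    block = per_row * pitch
    top, left = L - 2 - block, (L - block) // 2

    def transform(row, col):
        if side == "up":
            return row, col
        if side == "down":
            return L - 1 - row, col
        if side == "left":
            return col, row
        return col, L - 1 - row

    k = 0
    for r in range(per_row):
        for c in range(per_row):
            if k >= n_cells:
                break
            rows, cols = block_sites(0, 0, cfg.A_T)
            rr, cc = zip(*(transform(top + r * pitch + int(a),
                                     left + c * pitch + int(b))
                           for a, b in zip(rows, cols)))
            sim.add_cell(np.array(rr), np.array(cc), bundle.adhesion,
                         bundle.grn)
            k += 1
    frames = []

    def snap():
        spins = sim.cell_spins()
        cells = [(int(s), *sim.com(int(s)).tolist(),
                  int(sim.behav[s]), int(sim.ndiv[s])) for s in spins]
        coms = np.array([c[1:3] for c in cells])
        frames.append(DevelopmentFrame(
            mcs=sim.mcs, cells=cells,
            cluster_com=tuple(coms.mean(axis=0)) if len(cells) else
            (np.nan, np.nan)))

    snap()
    while sim.mcs < cfg.tau_s:
        chunk = min(sample_every - sim.mcs % sample_every,
                    cfg.tau_s - sim.mcs)
        sim.run(chunk)
        if sim.mcs % sample_every == 0:
            snap()
    return frames, sim


# ------------------------------------------------------------- metrics

@dataclass
class StrategyMetrics:
    """Division-timing summary of an evolved strategy."""
    #: pooled medians of 1st/2nd/3rd division times (MCS within season)
    median_division_times: tuple
    #: number of seasons pooled
    seasons_pooled: int
    #: per-season median gamma over the pooled window
    median_gamma: float


def compute_strategy_metrics(records: list[SeasonRecord],
                             last_n: int = 10,
                             max_divisions: int = 3) -> StrategyMetrics:
    """Pool division timestamps over the last ``last_n`` completed
    seasons and report per-order medians (the canonical strategy
    readout)."""
    if not records:
        raise ValueError("no season records")
    if len(records) < last_n:
        import warnings
        warnings.warn(f"only {len(records)} seasons available; pooling "
                      f"all of them", stacklevel=2)
    window = records[-last_n:]
    events = [e for r in window for e in r.division_events]
    medians = []
    for order in range(1, max_divisions + 1):
        t = [e["mcs"] for e in events if e["divisions_done"] == order]
        medians.append(float(np.median(t)) if t else np.nan)
    gammas = [r.median_gamma for r in window
              if not np.isnan(r.median_gamma)]
    return StrategyMetrics(
        median_division_times=tuple(medians),
        seasons_pooled=len(window),
        median_gamma=float(np.median(gammas)) if gammas else np.nan)
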