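"""Evolvable Boolean gene regulatory network and the behaviour state machine.

The network has a fixed architecture of N = 6 nodes: 2 sensory nodes
(local chemoattractant concentration; divisions already done), 3 Boolean
regulatory nodes (fully connected among themselves, including self-loops)
and one Boolean output node fed by the regulatory nodes.  The 24 real
parameters (18 weights, 4 thresholds, 2 input scalings) evolve by rare
additive Gaussian mutation; the wiring never changes.

All nodes update synchronously: new states are computed from the old
states only.  A regulatory or output node switches on iff its weighted
input strictly exceeds its threshold (ties give 0).  Sensory node j
contributes its (real-valued) input times the evolvable scaling phi_j.

The output node drives the cell's behaviour: 0 means migratory; a
sustained 1 (eta_init consecutive MCS, i.e. eta_init / GRN_PERIOD
consecutive network updates) switches the cell to growth and division,
unless the per-season division cap is exhausted, in which case the cell
is quiescent (neither migrating nor dividing).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

N_SENSORY = 2
N_REG = 3
#: MCS between successive network updates of one cell
GRN_PERIOD = 20
#: number of evolvable real parameters (6 + 9 + 3 weights, 4 thresholds,
#: 2 scalings)
N_PARAMS = 24


class Behaviour(enum.IntEnum):
    """Cell behaviour driven by the GRN output node."""
    MIGRATORY = 1   # persistent random walk + chemotaxis
    GROWING = 2     # target area inflating toward division; mu_p = mu_chi = 0
    QUIESCENT = 3   # output is 1 but division cap reached; immobile


@dataclass
class GRNGenome:
    """The 24 evolvable parameters of the fixed-architecture network."""

    #: weights sensory j -> regulatory i, shape (2, 3)
    w_in: np.ndarray = field(
        default_factory=lambda: np.zeros((N_SENSORY, N_REG)))
    #: weights regulatory k -> regulatory i (self-loops included), shape (3, 3)
    w_reg: np.ndarray = field(
        default_factory=lambda: np.zeros((N_REG, N_REG)))
    #: weights regulatory k -> output, shape (3,)
    w_out: np.ndarray = field(default_factory=lambda: np.zeros(N_REG))
    #: activation thresholds rho for the 3 regulatory nodes
    rho_reg: np.ndarray = field(default_factory=lambda: np.zeros(N_REG))
    #: activation threshold of the output node
    rho_out: float = 0.0
    #: input scalings phi for the 2 sensory nodes
    phi: np.ndarray = field(default_factory=lambda: np.zeros(N_SENSORY))

    def __post_init__(self) -> None:
        self.w_in = np.asarray(self.w_in, dtype=float).reshape(N_SENSORY, N_REG)
        self.w_reg = np.asarray(self.w_reg, dtype=float).reshape(N_REG, N_REG)
        self.w_out = np.asarray(self.w_out, dtype=float).reshape(N_REG)
        self.rho_reg = np.asarray(self.rho_reg, dtype=float).reshape(N_REG)
        self.rho_out = float(self.rho_out)
        self.phi = np.asarray(self.phi, dtype=float).reshape(N_SENSORY)

    @classmethod
    def random(cls, rng: np.random.Generator,
               low: float = -1.0, high: float = 1.0) -> "GRNGenome":
        """Uniform random parameters, used to seed evolutionary runs."""
        u = lambda *shape: rng.uniform(low, high, shape)
        return cls(w_in=u(N_SENSORY, N_REG), w_reg=u(N_REG, N_REG),
                   w_out=u(N_REG), rho_reg=u(N_REG),
                   rho_out=float(rng.uniform(low, high)), phi=u(N_SENSORY))

    def to_vector(self) -> np.ndarray:
        """Flatten to the canonical 24-vector (w_in, w_reg, w_out,
        rho_reg, rho_out, phi)."""
        return np.concatenate([self.w_in.ravel(), self.w_reg.ravel(),
                               self.w_out, self.rho_reg, [self.rho_out],
                               self.phi])

    @classmethod
    def from_vector(cls, v) -> "GRNGenome":
        v = np.asarray(v, dtype=float)
        if v.size != N_PARAMS:
            raise ValueError(f"expected {N_PARAMS} parameters, got {v.size}")
        return cls(w_in=v[0:6].reshape(N_SENSORY, N_REG),
                   w_reg=v[6:15].reshape(N_REG, N_REG),
                   w_out=v[15:18], rho_reg=v[18:21], rho_out=v[21],
                   phi=v[22:24])

    def copy(self) -> "GRNGenome":
        return GRNGenome.from_vector(self.to_vector())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GRNGenome):
            return NotImplemented
        return np.array_equal(self.to_vector(), other.to_vector())


@dataclass
class GRNState:
    """Boolean node states plus the output-1 streak counter."""
    regulatory: np.ndarray = field(
        default_factory=lambda: np.zeros(N_REG, dtype=np.int8))
    output: int = 0
    #: consecutive network updates with output 1
    output_one_streak: int = 0

    def copy(self) -> "GRNState":
        return GRNState(self.regulatory.copy(), self.output,
                        self.output_one_streak)


@dataclass
class SensoryInput:
    """What one cell senses at a network update."""
    chemoattractant: float   # average field value over the cell's sites
    divisions_done: int      # in [0, max_divisions]


def grn_step(genome: GRNGenome, state: GRNState,
             inp: SensoryInput) -> GRNState:
    """One synchronous network update.

    r_i(t+1) = sum_j w_{j->i} S_j(t), with S_j = phi_j * input_j for
    sensory nodes; S_i(t+1) = 1 iff r_i > rho_i.  The output node reads
    the *old* regulatory states (synchronous update).  The streak counter
    is maintained by :func:`behaviour_update`, not here.
    """
    s_in = genome.phi * np.array([inp.chemoattractant,
                                  float(inp.divisions_done)])
    old = state.regulatory.astype(float)
    r_reg = s_in @ genome.w_in + old @ genome.w_reg
    r_out = genome.w_out @ old
    new = GRNState(regulatory=(r_reg > genome.rho_reg).astype(np.int8),
                   output=int(r_out > genome.rho_out),
                   output_one_streak=state.output_one_streak)
    return new


def reset_grn(state: GRNState) -> GRNState:
    """All Boolean states and the streak back to 0 (idempotent)."""
    state.regulatory[:] = 0
    state.output = 0
    state.output_one_streak = 0
    return state


def behaviour_update(behaviour: Behaviour, state: GRNState,
                     divisions_done: int, max_divisions: int,
                     eta_init: int, grn_period: int = GRN_PERIOD) -> Behaviour:
    """Advance the migrate/divide/quiescent state machine one network tick.

    Mutates ``state.output_one_streak``.  Output 0 makes the cell
    migratory and resets the streak (an interrupted growth phase restarts
    the eta_init wait from scratch).  Output 1 sustained for eta_init MCS
    commits the cell to growth, or to quiescence if the division cap is
    already spent.
    """
    if state.output == 0:
        state.output_one_streak = 0
        return Behaviour.MIGRATORY
    state.output_one_streak += 1
    committed = state.output_one_streak * grn_period >= eta_init
    if divisions_done >= max_divisions:
        # the division cap is spent: growth is never an option
        if committed or behaviour == Behaviour.GROWING:
            return Behaviour.QUIESCENT
        return behaviour
    if committed:
        return Behaviour.GROWING
    # still accumulating the eta_init wait
    return behaviour


def mutate_grn(genome: GRNGenome, per_param_probability: float, sd: float,
               rng: np.random.Generator) -> GRNGenome:
    """Each of the 24 parameters independently gains N(0, sd) noise with
    the given probability; untouched parameters are bit-identical."""
    v = genome.to_vector()
    hit = rng.random(N_PARAMS) < per_param_probability
    if hit.any():
        v = v.copy()
        v[hit] += rng.normal(0.0, sd, int(hit.sum()))
    return GRNGenome.from_vector(v)


def steady_state_output(genome: GRNGenome, chemoattractant: float,
                        divisions_done: int, max_steps: int = 64) -> int:
    """Output state reached from the all-zero state under constant input.

    Iterates the synchronous update until the regulatory state revisits a
    previous configuration (the 3-bit state space guarantees a cycle
    within 8 steps); returns the output on the attractor (majority over
    the cycle, ties toward 1).  Used to read a genome's response profile
    over the (concentration x divisions) input grid.
    """
    inp = SensoryInput(chemoattractant, divisions_done)
    state = GRNState()
    seen: dict[tuple, int] = {}
    history: list[tuple] = []
    for step in range(max_steps):
        key = tuple(state.regulatory.tolist())
        if key in seen:
            cycle = history[seen[key]:]
            outs = [o for (_, o) in cycle]
            return int(sum(outs) * 2 >= len(outs))
        seen[key] = step
        state = grn_step(genome, state, inp)
        history.append((key, state.output))
    return state.output


def response_profile(genome: GRNGenome, concentrations,
                     divisions) -> np.ndarray:
    """Steady-state output over an input grid, shape
    (len(concentrations), len(divisions))."""
    return np.array([[steady_state_output(genome, c, n) for n in divisions]
                     for c in concentrations], dtype=np.int8)
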