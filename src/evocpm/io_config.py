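"""Configuration, seed-genome files, fixtures and checkpoints.

The configuration file is a flat YAML mapping whose keys are the model's
canonical parameter names (``L``, ``T``, ``lambda``, ``A_T``, ...).
Missing keys take the model defaults; unknown keys and out-of-range
values are rejected with the offending key named.

Seed-genome files are human-diffable plain text: one ``key: value`` pair
per line, genomes separated by blank lines.  Bitstrings are written as
literal 0/1 character strings, most-significant position first; GRN
parameters carry stable field names (``w_in0_reg0`` ... ``phi_in1``) at
full decimal precision.

Checkpoints are JSON with run-length-encoded lattices and the full RNG
state of every stream, so a resumed run is bit-identical to an
uninterrupted one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace

import numpy as np
import yaml

from . import adhesion, grn
from .adhesion import AdhesionGenome
from .environment import GradientField
from .grn import GRNGenome

CHECKPOINT_VERSION = 1

#: mapping config-file key -> dataclass attribute (only where they differ)
_KEY_TO_ATTR = {"lambda": "lam"}
_ATTR_TO_KEY = {v: k for k, v in _KEY_TO_ATTR.items()}


@dataclass
class SimulationConfig:
    """Full parameterization of a run.

    Defaults are the model's canonical values; the architecture
    constants (bitstring lengths, minimum J values) are fixed by the
    adhesion scheme and validated rather than tunable.
    """

    L: int = 500                 # lattice side, sites
    T: float = 16.0              # Boltzmann temperature, AUE
    lam: float = 4.0             # cell stiffness lambda, AUE/site^2
    A_T: int = 50                # base target area, sites
    J_alpha: int = 4             # minimum cell-cell J, AUE/site length
    J_alpha_prime: int = 8       # minimum cell-medium J
    nu: int = 24                 # receptor/ligand bitstring length
    nu_prime: int = 6            # medium-facing ligand prefix length
    mu_p: float = 3.0            # persistence strength, AUE
    tau_p: int = 50              # persistence period, MCS
    mu_chi: float = 1.0          # chemotaxis strength, AUE
    k_chi: float = 5.0           # gradient scaling, molecules/site length
    eta_init: int = 10000        # MCS of sustained output 1 before growth
    eta_grow: int = 20000        # MCS to double the target area
    tau_s: int = 180000          # season duration, MCS
    p_min: float = 0.05          # death probability at the peak
    p_max: float = 1.0           # death probability far from the peak
    d_scale: float = 40.0        # half-maximal death distance, site lengths
    mu_RI: float = 0.01          # bit flip probability per bit
    mu_omega: float = 0.02       # GRN parameter mutation probability
    sigma: float = 0.05          # GRN mutation step s.d.
    # experiment-level fields
    seed: int = 1
    seasons: int = 100
    init_population: int = 50
    adhesion_evolvable: bool = True
    max_divisions: int = 3
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.L < 2:
            raise ValueError("L must be at least 2")
        if self.T <= 0:
            raise ValueError("T must be positive")
        for key in ("lam", "mu_p", "mu_chi", "k_chi", "d_scale", "scale"):
            if getattr(self, key) <= 0 and key in ("k_chi", "d_scale",
                                                   "scale"):
                raise ValueError(f"{_ATTR_TO_KEY.get(key, key)} must be "
                                 "positive")
            if getattr(self, key) < 0:
                raise ValueError(f"{_ATTR_TO_KEY.get(key, key)} must be "
                                 "non-negative")
        for key in ("p_min", "p_max", "mu_RI", "mu_omega"):
            v = getattr(self, key)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{key} must lie in [0, 1], got {v}")
        if self.p_min > self.p_max:
            raise ValueError("p_min must not exceed p_max")
        for key in ("A_T", "tau_p", "eta_init", "eta_grow", "tau_s",
                    "seasons", "init_population", "max_divisions"):
            if getattr(self, key) <= 0:
                raise ValueError(f"{key} must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        fixed = dict(J_alpha=adhesion.J_ALPHA,
                     J_alpha_prime=adhesion.J_ALPHA_PRIME,
                     nu=adhesion.NU, nu_prime=adhesion.NU_PRIME)
        for key, want in fixed.items():
            if getattr(self, key) != want:
                raise ValueError(
                    f"{key} is fixed at {want} by the adhesion scheme")

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            out[_ATTR_TO_KEY.get(f.name, f.name)] = getattr(self, f.name)
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        known = {f.name for f in fields(cls)}
        kwargs = {}
        for key, value in data.items():
            attr = _KEY_TO_ATTR.get(key, key)
            if attr not in known:
                raise ValueError(f"unknown configuration key: {key!r}")
            kwargs[attr] = value
        try:
            return cls(**kwargs)
        except TypeError as exc:  # wrong value type for a key
            raise ValueError(str(exc)) from exc

    def scaled(self) -> "SimulationConfig":
        """Apply the linear ``scale`` factor to the lattice side and the
        death-distance scale (the quantities with units of length)."""
        if self.scale == 1.0:
            return self
        return replace(self, L=max(2, round(self.L * self.scale)),
                       d_scale=self.d_scale * self.scale, scale=1.0)


def load_config(path) -> SimulationConfig:
    """Parse and validate a flat YAML configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError("configuration file must be a flat mapping")
    return SimulationConfig.from_dict(data)


def save_config(cfg: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


# --------------------------------------------------------------- genomes

@dataclass
class GenomeBundle:
    """A heritable unit: regulatory network + adhesion bitstrings."""
    grn: GRNGenome
    adhesion: AdhesionGenome

    def copy(self) -> "GenomeBundle":
        return GenomeBundle(self.grn.copy(), self.adhesion.copy())


def _grn_field_names() -> list[str]:
    names = [f"w_in{j}_reg{i}" for j in range(2) for i in range(3)]
    names += [f"w_reg{k}_reg{i}" for k in range(3) for i in range(3)]
    names += [f"w_reg{k}_out" for k in range(3)]
    names += [f"rho_reg{i}" for i in range(3)]
    names += ["rho_out", "phi_in0", "phi_in1"]
    return names


GRN_FIELD_NAMES = _grn_field_names()


def write_seed_genomes(bundles, path) -> None:
    """Serialize genome bundles to a plain-text key-value file."""
    with open(path, "w") as fh:
        for n, b in enumerate(bundles):
            if n:
                fh.write("\n")
            r, i = b.adhesion.to_strings()
            fh.write(f"receptor: {r}\n")
            fh.write(f"ligand: {i}\n")
            for name, value in zip(GRN_FIELD_NAMES, b.grn.to_vector()):
                fh.write(f"{name}: {float(value)!r}\n")


def read_seed_genomes(path) -> list[GenomeBundle]:
    """Parse a seed-genome file; raises ValueError with the offending
    line number on malformed input."""
    records: list[dict] = []
    current: dict = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                if current:
                    records.append(current)
                    current = {}
                continue
            if ":" not in line:
                raise ValueError(
                    f"{path}:{lineno}: expected 'key: value', got {line!r}")
            key, _, value = line.partition(":")
            current[key.strip()] = (value.strip(), lineno)
    if current:
        records.append(current)
    bundles = []
    for rec in records:
        for need in ("receptor", "ligand", *GRN_FIELD_NAMES):
            if need not in rec:
                raise ValueError(f"{path}: genome record is missing "
                                 f"field {need!r}")
        for bits_key in ("receptor", "ligand"):
            value, lineno = rec[bits_key]
            if len(value) != adhesion.NU or set(value) - {"0", "1"}:
                raise ValueError(
                    f"{path}:{lineno}: {bits_key} must be a "
                    f"{adhesion.NU}-character 0/1 string")
        adh = AdhesionGenome.from_strings(rec["receptor"][0],
                                          rec["ligand"][0])
        try:
            vec = [float(rec[name][0]) for name in GRN_FIELD_NAMES]
        except ValueError as exc:
            raise ValueError(f"{path}: bad numeric value: {exc}") from exc
        bundles.append(GenomeBundle(GRNGenome.from_vector(vec), adh))
    return bundles


FIXTURE_KINDS = ("division_early_counter", "division_late_threshold",
                 "constitutive_divider", "constitutive_migrator")


def make_fixture_genome(kind: str, threshold_concentration: float = 10.0,
                        max_divisions: int = 3) -> GenomeBundle:
    """Handcrafted strategy genomes with known truth-table responses.

    ``division_early_counter``
        Output 1 (divide) while divisions_done < max_divisions, 0 after
        the last division: the network counts divisions and then
        switches permanently to migration.
    ``division_late_threshold``
        Output 1 iff the perceived concentration is at least the given
        threshold: the cell migrates up-gradient and divides only once
        the chemoattractant is high enough.
    ``constitutive_divider`` / ``constitutive_migrator``
        Output pinned to 1 / 0 regardless of input (test scaffolding
        for the division cap and for pure migration).

    All bundles carry a neutral (gamma = 0) adhesion genome.
    """
    g = GRNGenome()
    # unused regulatory nodes keep a positive threshold on zero input
    g.rho_reg[:] = 1.0
    if kind == "division_early_counter":
        g.phi[:] = (0.0, 1.0)
        g.w_in[1, 0] = -1.0
        g.rho_reg[0] = -(max_divisions - 0.5)
        g.w_out[0] = 1.0
        g.rho_out = 0.5
    elif kind == "division_late_threshold":
        g.phi[:] = (1.0, 0.0)
        g.w_in[0, 0] = 1.0
        g.rho_reg[0] = threshold_concentration - 1e-9
        g.w_out[0] = 1.0
        g.rho_out = 0.5
    elif kind == "constitutive_divider":
        g.rho_out = -1.0
    elif kind == "constitutive_migrator":
        g.rho_out = 1.0
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; expected one "
                         f"of {FIXTURE_KINDS}")
    return GenomeBundle(g, adhesion.genome_for_gamma(0))


# ------------------------------------------------------------ checkpoint

def _rle_encode(arr: np.ndarray) -> list:
    flat = np.asarray(arr).ravel()
    if flat.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(flat)) + 1
    starts = np.concatenate([[0], breaks])
    ends = np.concatenate([breaks, [flat.size]])
    return [[int(flat[s]), int(e - s)] for s, e in zip(starts, ends)]


def _rle_decode(runs: list, shape, dtype) -> np.ndarray:
    if not runs:
        return np.zeros(shape, dtype=dtype)
    out = np.concatenate([np.full(count, value, dtype=dtype)
                          for value, count in runs])
    return out.reshape(shape)


_CELL_SCALARS = ("area", "At", "sx", "sy", "chs", "chx", "chy", "px",
                 "py", "behav", "out_state", "streak", "ndiv", "grn_phase",
                 "p_phase", "next_size_mcs", "group", "ref_comx",
                 "ref_comy")


def write_checkpoint(sim, path) -> None:
    """Dump the complete simulation state as structured text."""
    spins = sim.cell_spins()
    cells = []
    for s in spins:
        rec = {"spin": int(s)}
        for name in _CELL_SCALARS:
            rec[name] = getattr(sim, name)[s].item()
        rec["reg_state"] = sim.reg_state[s].tolist()
        r, i = sim.adh_genomes[s].to_strings()
        rec["receptor"], rec["ligand"] = r, i
        rec["grn"] = sim.grn_genomes[s].to_vector().tolist()
        cells.append(rec)
    state = {
        "version": CHECKPOINT_VERSION,
        "config": sim.config.to_dict(),
        "season": sim.season,
        "mcs": sim.mcs,
        "n_spins": int(sim.n_spins),
        "mutations_enabled": sim.mutations_enabled,
        "fixed_j": list(sim.fixed_j) if sim.fixed_j else None,
        "field": {
            "peak_side": sim.field.peak_side,
            "values": _rle_encode(sim.field.values),
        },
        "spins": _rle_encode(sim.spins),
        "cells": cells,
        "rng": {
            "kernel": int(sim.kernel_state[0]),
            "py": sim.rng.bit_generator.state,
            "mut": sim.mut_rng.bit_generator.state,
            "env": sim.env_rng.bit_generator.state,
            "cull": sim.cull_rng.bit_generator.state,
        },
        "division_events": sim.division_events,
    }
    with open(path, "w") as fh:
        json.dump(state, fh)


def read_checkpoint(path):
    """Reconstruct a :class:`~evocpm.cpm.Simulation` exactly."""
    from .cpm import Simulation
    from .environment import peak_coordinate

    with open(path) as fh:
        try:
            state = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"corrupt checkpoint {path}: {exc}") from exc
    if state.get("version") != CHECKPOINT_VERSION:
        raise ValueError(
            f"checkpoint version mismatch: file has "
            f"{state.get('version')!r}, expected {CHECKPOINT_VERSION}")
    cfg = SimulationConfig.from_dict(state["config"])
    L = cfg.L
    values = _rle_decode(state["field"]["values"], (L, L), np.int32)
    peak_side = state["field"]["peak_side"]
    rows, cols = np.indices((L, L))
    peak = peak_coordinate(L, peak_side)
    d_max = float(np.hypot(rows - peak[0], cols - peak[1]).max())
    field_obj = GradientField(values=values, peak_side=peak_side,
                              peak=peak, k_chi=cfg.k_chi, d_max=d_max)
    fixed_j = tuple(state["fixed_j"]) if state["fixed_j"] else None
    sim = Simulation(cfg, field_obj, cfg.seed, fixed_j=fixed_j)
    sim.season = state["season"]
    sim.mcs = state["mcs"]
    sim.n_spins = state["n_spins"]
    sim.mutations_enabled = state["mutations_enabled"]
    if sim.n_spins > sim.capacity:
        sim._grow_capacity(sim.n_spins + 8)
    sim.spins = _rle_decode(state["spins"], (L, L), np.int32)
    for rec in state["cells"]:
        s = rec["spin"]
        sim.alive[s] = 1
        for name in _CELL_SCALARS:
            getattr(sim, name)[s] = rec[name]
        sim.reg_state[s] = rec["reg_state"]
        sim.adh_genomes[s] = AdhesionGenome.from_strings(rec["receptor"],
                                                         rec["ligand"])
        sim.grn_genomes[s] = GRNGenome.from_vector(rec["grn"])
        sim._load_grn_arrays(s)
    sim.rebuild_J()
    sim.kernel_state[0] = np.uint64(state["rng"]["kernel"])
    sim.rng.bit_generator.state = state["rng"]["py"]
    sim.mut_rng.bit_generator.state = state["rng"]["mut"]
    sim.env_rng.bit_generator.state = state["rng"]["env"]
    sim.cull_rng.bit_generator.state = state["rng"]["cull"]
    sim.division_events = state["division_events"]
    sim.audit()
    return sim
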