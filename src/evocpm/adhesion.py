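"""Receptor/ligand bitstring adhesion energetics.

Each cell carries two binary strings of length ``NU`` (default 24): a
*receptor* ``R`` and a *ligand* ``I``.  The interfacial energy between two
cells decreases (adhesion strengthens) with the complementarity of each
cell's receptor to the other cell's ligand, measured by the Hamming
distance ``D(R, I)``.  Adhesion to the inert medium depends only on a
short prefix of the ligand, weighted by a fixed lookup table.

Energies are in arbitrary units of energy (AUE) per unit boundary length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: bitstring length of receptor and ligand
NU = 24
#: length of the ligand prefix facing the medium
NU_PRIME = 6
#: minimum cell-cell J
J_ALPHA = 4
#: minimum cell-medium J
J_ALPHA_PRIME = 8
#: per-bit weight of the medium-facing ligand prefix, F(i) for i=1..6
F_MEDIUM = np.array([4, 3, 2, 1, 1, 1], dtype=np.int64)
#: the medium is inert: medium-medium contact costs nothing
J_MEDIUM_MEDIUM = 0.0


def _as_bits(seq, name: str) -> np.ndarray:
    arr = np.asarray(seq, dtype=np.uint8)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be a 1-D bit sequence")
    if not np.all((arr == 0) | (arr == 1)):
        raise ValueError(f"{name} must contain only 0/1 values")
    return arr


@dataclass
class AdhesionGenome:
    """Receptor and ligand bitstrings of one cell.

    Both strings have exactly :data:`NU` elements, each 0 or 1.  Position 1
    of the medium-weight lookup F(i) maps to index 0 of the ligand (the
    canonical orientation used throughout the package).
    """

    receptor: np.ndarray = field(
        default_factory=lambda: np.zeros(NU, dtype=np.uint8))
    ligand: np.ndarray = field(
        default_factory=lambda: np.zeros(NU, dtype=np.uint8))

    def __post_init__(self) -> None:
        self.receptor = _as_bits(self.receptor, "receptor")
        self.ligand = _as_bits(self.ligand, "ligand")
        if self.receptor.shape != (NU,) or self.ligand.shape != (NU,):
            raise ValueError(
                f"receptor and ligand must have length {NU}, got "
                f"{self.receptor.size} and {self.ligand.size}")

    @classmethod
    def random(cls, rng: np.random.Generator) -> "AdhesionGenome":
        return cls(receptor=rng.integers(0, 2, NU).astype(np.uint8),
                   ligand=rng.integers(0, 2, NU).astype(np.uint8))

    @classmethod
    def from_strings(cls, receptor: str, ligand: str) -> "AdhesionGenome":
        return cls(receptor=np.frombuffer(receptor.encode(), np.uint8) - ord("0"),
                   ligand=np.frombuffer(ligand.encode(), np.uint8) - ord("0"))

    def to_strings(self) -> tuple[str, str]:
        return ("".join(map(str, self.receptor.tolist())),
                "".join(map(str, self.ligand.tolist())))

    def copy(self) -> "AdhesionGenome":
        return AdhesionGenome(self.receptor.copy(), self.ligand.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AdhesionGenome):
            return NotImplemented
        return (np.array_equal(self.receptor, other.receptor)
                and np.array_equal(self.ligand, other.ligand))


def hamming_mismatch(receptor, ligand) -> int:
    """Number of positions where receptor and ligand bits differ.

    D(R, I) = sum_i (1 - delta(R_i, I_i)); larger D means stronger
    complementarity and hence stronger adhesion.
    """
    r = np.asarray(receptor)
    i = np.asarray(ligand)
    if r.shape != i.shape:
        raise ValueError(
            f"receptor and ligand lengths differ: {r.size} != {i.size}")
    return int(np.count_nonzero(r != i))


def j_cell_cell(a: AdhesionGenome, b: AdhesionGenome) -> float:
    """Interfacial energy between two cells.

    J = J_alpha + 2*nu - D(R_a, I_b) - D(R_b, I_a), symmetric in (a, b)
    and bounded in [J_alpha, J_alpha + 2*nu] = [4, 52].
    """
    return float(J_ALPHA + 2 * NU
                 - hamming_mismatch(a.receptor, b.ligand)
                 - hamming_mismatch(b.receptor, a.ligand))


def j_cell_medium(a: AdhesionGenome) -> float:
    """Interfacial energy between a cell and the medium.

    J = J_alpha' + sum_{i=1..nu'} F(i) * I_i over the first ``NU_PRIME``
    ligand bits; bounded in [8, 20].  Receptor bits and ligand bits beyond
    the prefix play no role.
    """
    prefix = a.ligand[:NU_PRIME].astype(np.int64)
    return float(J_ALPHA_PRIME + int(F_MEDIUM @ prefix))


def surface_tension(j_cm: float, j_cc: float) -> float:
    """Cell-medium surface tension gamma = J_cm - J_cc / 2.

    Cells adhere to each other when gamma > 0 and prefer the medium
    (do not adhere) when gamma < 0.
    """
    return j_cm - j_cc / 2.0


def gamma_of(a: AdhesionGenome, b: AdhesionGenome | None = None) -> float:
    """Surface tension of a (homotypic by default) cell pair."""
    other = a if b is None else b
    return surface_tension(j_cell_medium(a), j_cell_cell(a, other))


def mutate_bitstrings(a: AdhesionGenome, flip_probability: float,
                      rng: np.random.Generator) -> AdhesionGenome:
    """Return a mutated copy: each of the 2*nu bits flips independently."""
    if not 0.0 <= flip_probability <= 1.0:
        raise ValueError("flip_probability must lie in [0, 1]")
    flips_r = rng.random(NU) < flip_probability
    flips_i = rng.random(NU) < flip_probability
    return AdhesionGenome(receptor=a.receptor ^ flips_r,
                          ligand=a.ligand ^ flips_i)


#: fixed interfacial energies used when adhesion cannot evolve
J_CC_FIXED = 36.0
J_CM_FIXED = 14.0


def nonadhesive_genome() -> AdhesionGenome:
    """Representative genome realizing the fixed non-adhesive energies
    (homotypic J_cc = 36, J_cm = 14, gamma = -4)."""
    ligand = np.zeros(NU, dtype=np.uint8)
    ligand[[0, 2]] = 1                       # F(1)+F(3) = 6 -> J_cm = 14
    ligand[NU_PRIME:NU_PRIME + 6] = 1        # 8 mismatches vs zero receptor
    g = AdhesionGenome(receptor=np.zeros(NU, dtype=np.uint8), ligand=ligand)
    assert j_cell_cell(g, g) == J_CC_FIXED and j_cell_medium(g) == J_CM_FIXED
    return g


def genome_for_gamma(gamma: int) -> AdhesionGenome:
    """Construct a representative genome whose homotypic pair realizes
    the requested integer surface tension.

    Greedy assignment: pick the smallest feasible cell-medium J, derive
    the required cell-cell J = 2*(J_cm - gamma), build the ligand prefix
    greedily against the F(i) weights, put the remaining required
    receptor/ligand mismatches in the ligand tail (receptor all zeros).
    Used by competition experiments where groups are specified only by a
    target gamma.
    """
    for j_cm in range(J_ALPHA_PRIME, J_ALPHA_PRIME + int(F_MEDIUM.sum()) + 1):
        j_cc = 2 * (j_cm - gamma)
        if not J_ALPHA <= j_cc <= J_ALPHA + 2 * NU:
            continue
        mismatches = (J_ALPHA + 2 * NU - j_cc) // 2  # per R/I pair
        prefix_sum = j_cm - J_ALPHA_PRIME
        # greedy prefix achieving the required weighted sum
        prefix = np.zeros(NU_PRIME, dtype=np.uint8)
        remaining = prefix_sum
        for i in np.argsort(-F_MEDIUM, kind="stable"):
            if F_MEDIUM[i] <= remaining:
                prefix[i] = 1
                remaining -= F_MEDIUM[i]
        if remaining != 0:
            continue
        ones_prefix = int(prefix.sum())
        extra = mismatches - ones_prefix
        if extra < 0 or extra > NU - NU_PRIME:
            continue
        ligand = np.zeros(NU, dtype=np.uint8)
        ligand[:NU_PRIME] = prefix
        ligand[NU_PRIME:NU_PRIME + extra] = 1
        genome = AdhesionGenome(receptor=np.zeros(NU, dtype=np.uint8),
                                ligand=ligand)
        assert gamma_of(genome) == gamma
        return genome
    raise ValueError(f"surface tension {gamma} is not realizable")
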