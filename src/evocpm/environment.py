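"""Chemoattractant gradient lattice.

A second lattice of the same dimensions as the cell lattice holds an
integer amount of chemoattractant per site, constant within a season.
The peak sits at the centre of one lattice boundary and the amount
decays linearly with Euclidean distance d from the peak,

    chi(d) = 1 + (k_chi * d_max / 100) * (1 - d / d_max),

where d_max is the largest peak-to-site distance (the far corner).
Non-integer chi is stochastically rounded, up with probability equal to
its fractional part, so the stored integer is an unbiased sample of chi.
Every stored value is at least 1 (chi(d_max) = 1 exactly).

Cells perceive only the field under their own sites: their sensory input
is the arithmetic mean, and their chemotaxis direction points from the
cell's centre of mass to the chi-weighted centre of mass of those sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SIDES = ("up", "down", "left", "right")


def peak_coordinate(L: int, peak_side: str) -> tuple[int, int]:
    """Midpoint lattice site of the chosen boundary, 0-based (row, col)."""
    mid = L // 2
    if peak_side == "up":
        return (0, mid)
    if peak_side == "down":
        return (L - 1, mid)
    if peak_side == "left":
        return (mid, 0)
    if peak_side == "right":
        return (mid, L - 1)
    raise ValueError(f"unknown side {peak_side!r}; expected one of {SIDES}")


@dataclass
class GradientField:
    """Integer chemoattractant lattice with a seasonal peak location."""
    values: np.ndarray          # int32 (L, L), every entry >= 1
    peak_side: str
    peak: tuple[int, int]       # (row, col) of the peak site
    k_chi: float
    d_max: float

    @property
    def L(self) -> int:
        return self.values.shape[0]

    def chi_analytic(self, d) -> np.ndarray:
        """Pre-rounding chi(d)."""
        d = np.asarray(d, dtype=float)
        return 1.0 + (self.k_chi * self.d_max / 100.0) * (1.0 - d / self.d_max)

    def distance_to_peak(self, row, col) -> np.ndarray:
        return np.hypot(np.asarray(row, float) - self.peak[0],
                        np.asarray(col, float) - self.peak[1])


def build_gradient(L: int, peak_side: str, k_chi: float,
                   rng: np.random.Generator) -> GradientField:
    """Build the season's field with stochastic integer rounding."""
    if L < 2:
        raise ValueError("lattice size must be at least 2")
    if k_chi <= 0:
        raise ValueError("k_chi must be positive")
    peak = peak_coordinate(L, peak_side)
    rows, cols = np.indices((L, L))
    d = np.hypot(rows - peak[0], cols - peak[1])
    d_max = float(d.max())
    chi = 1.0 + (k_chi * d_max / 100.0) * (1.0 - d / d_max)
    floor = np.floor(chi)
    frac = chi - floor
    values = (floor + (rng.random((L, L)) < frac)).astype(np.int32)
    return GradientField(values=values, peak_side=peak_side, peak=peak,
                         k_chi=k_chi, d_max=d_max)


def relocate_peak(rng: np.random.Generator) -> str:
    """Uniformly random boundary side for the new season (may repeat)."""
    return SIDES[int(rng.integers(0, 4))]


def perceived_concentration(rows, cols, field: GradientField) -> float:
    """Average field value over the given cell sites."""
    rows = np.asarray(rows)
    if rows.size == 0:
        raise ValueError("cell has no lattice sites")
    return float(np.mean(field.values[rows, np.asarray(cols)]))


def chemotaxis_vector(rows, cols, field: GradientField) -> np.ndarray:
    """Vector from the cell's centre of mass to the chi-weighted centre
    of mass of its own sites; the zero vector when the perceived field is
    locally flat."""
    rows = np.asarray(rows, dtype=float)
    cols = np.asarray(cols, dtype=float)
    if rows.size == 0:
        raise ValueError("cell has no lattice sites")
    w = field.values[rows.astype(int), cols.astype(int)].astype(float)
    com = np.array([rows.mean(), cols.mean()])
    weighted = np.array([(w * rows).sum(), (w * cols).sum()]) / w.sum()
    return weighted - com
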