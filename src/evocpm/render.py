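"""Raster snapshot export.

Cells are colour-coded by behaviour (dividing in blues, migrating in
warm colours, quiescent grey) with lighter shades for higher division
counts; in competition mode the two groups are coloured green and
purple instead.  The medium is white.
"""

from __future__ import annotations

import numpy as np
from PIL import Image

from .grn import Behaviour

_MIG = np.array([200, 40, 30])
_GROW = np.array([40, 60, 200])
_QUI = np.array([120, 120, 120])
_GROUPS = {0: np.array([40, 160, 60]), 1: np.array([140, 60, 180])}


def snapshot_array(sim, by_group: bool = False) -> np.ndarray:
    """RGB uint8 array (L, L, 3) of the current lattice."""
    L = sim.L
    img = np.full((L, L, 3), 255, dtype=np.uint8)
    max_div = max(1, sim.config.max_divisions)
    for s in sim.cell_spins():
        s = int(s)
        if by_group:
            base = _GROUPS.get(int(sim.group[s]), _QUI).astype(float)
            if sim.behav[s] == int(Behaviour.GROWING):
                base = base + (255 - base) * 0.45
        else:
            b = int(sim.behav[s])
            base = {int(Behaviour.MIGRATORY): _MIG,
                    int(Behaviour.GROWING): _GROW,
                    int(Behaviour.QUIESCENT): _QUI}.get(b, _QUI).astype(
                        float)
            base = base + (255 - base) * (0.5 * sim.ndiv[s] / max_div)
        img[sim.spins == s] = base.astype(np.uint8)
    return img


def save_snapshot(sim, path, by_group: bool = False,
                  upscale: int = 1) -> None:
    arr = snapshot_array(sim, by_group=by_group)
    im = Image.fromarray(arr)
    if upscale > 1:
        im = im.resize((arr.shape[1] * upscale, arr.shape[0] * upscale),
                       Image.NEAREST)
    im.save(path)
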