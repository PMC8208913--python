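"""Equidistant ring montage.

The recording cap places 61 sintered Ag/AgCl electrodes on five concentric
rings spaced equidistantly around the vertex electrode Cz.  Exact cap
coordinates are not published, so the layout is reconstructed geometrically:
ring ``k`` (1-based) sits at radius ``k / 5`` of the head radius and carries
``4 * k + 4`` electrodes at equal angular spacing (4 + 8 + 12 + 16 + 20 = 60
plus Cz = 61).  Only the *relative* 2-D positions matter downstream - they
drive the spatial weighting of simulated components, the spatial noise
correlation, and topography plots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Montage", "ring_montage"]

RING_COUNTS = (4, 8, 12, 16, 20)


@dataclass(frozen=True)
class Montage:
    ch_names: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 2), head radius 1, +y anterior

    @property
    def n_channels(self) -> int:
        return len(self.ch_names)

    def index(self, name: str) -> int:
        return self.ch_names.index(name)


def ring_montage(ring_counts: tuple[int, ...] = RING_COUNTS) -> Montage:
    """Build the concentric-ring montage (default: 61 channels).

    Channel naming: ``Cz`` at the vertex; ring ``k`` electrode ``j`` is
    ``R{k}C{j:02d}``, numbered clockwise from the anterior midline.  Each
    ring is rotated by half an electrode spacing relative to the previous
    one so no non-vertex electrode sits exactly on the midline axis.
    """
    names = ["Cz"]
    pos = [(0.0, 0.0)]
    n_rings = len(ring_counts)
    for k, count in enumerate(ring_counts, start=1):
        radius = k / n_rings
        offset = np.pi / count  # half-spacing stagger keeps midline clear
        for j in range(count):
            theta = offset + 2 * np.pi * j / count
            # theta measured from anterior midline, clockwise
            names.append(f"R{k}C{j + 1:02d}")
            pos.append((radius * np.sin(theta), radius * np.cos(theta)))
    return Montage(ch_names=tuple(names), positions=np.array(pos))


def gaussian_topography(montage: Montage, center: tuple[float, float],
                        width: float) -> np.ndarray:
    """Spatial weights exp(-d^2 / (2 width^2)) from ``center``, peak 1."""
    d2 = np.sum((montage.positions - np.asarray(center)) ** 2, axis=1)
    w = np.exp(-d2 / (2.0 * width**2))
    return w / w.max()
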