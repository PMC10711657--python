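"""Axial-coordinate hexagonal lattice geometry (pointy-top orientation).

The micropattern arrays are hexagonal lattices of circular adhesive patches.
Sites are addressed by axial coordinates (q, r); the six nearest neighbours
of a site are at fixed axial offsets.  Cartesian positions place neighbours
at the centre-to-centre spacing ``d`` in a pointy-top layout.
"""

from __future__ import annotations

import math

import numpy as np

#: Axial offsets of the six nearest neighbours of any site.
AXIAL_NEIGHBOURS: tuple[tuple[int, int], ...] = (
    (1, 0),
    (1, -1),
    (0, -1),
    (-1, 0),
    (-1, 1),
    (0, 1),
)


def axial_to_xy(q, r, spacing: float):
    """Cartesian (x, y) of axial site(s) for nearest-neighbour spacing ``d``.

    Pointy-top convention: x = d*(q + r/2), y = d*(sqrt(3)/2)*r.  All six
    neighbours of the origin then lie exactly at distance ``d``.
    """
    q = np.asarray(q, dtype=float)
    r = np.asarray(r, dtype=float)
    x = spacing * (q + r / 2.0)
    y = spacing * (math.sqrt(3.0) / 2.0) * r
    return x, y


def are_neighbours(a: tuple[int, int], b: tuple[int, int]) -> bool:
    dq, dr = b[0] - a[0], b[1] - a[1]
    return (dq, dr) in AXIAL_NEIGHBOURS


def neighbour_offsets_xy(spacing: float) -> np.ndarray:
    """(6, 2) array of Cartesian offsets to the six neighbouring centres."""
    qs = np.array([o[0] for o in AXIAL_NEIGHBOURS])
    rs = np.array([o[1] for o in AXIAL_NEIGHBOURS])
    x, y = axial_to_xy(qs, rs, spacing)
    return np.column_stack([x, y])


def lattice_sites(rows: int, cols: int) -> list[tuple[int, int]]:
    """Axial sites of a rows x cols parallelogram block."""
    return [(q, r) for r in range(rows) for q in range(cols)]
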