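"""TNT connectivity statistics on micropatterned cell arrays.

The headline statistic is the percentage of TNT-connected micropatterns.
Its denominator deliberately excludes isolated occupied patterns: a cell
whose nearest-neighbour patterns are all unoccupied cannot possibly be
TNT-connected across patterns, so it is not an informative trial.  The
module also counts rare inter-pattern translocation events in cell
trajectories (a control that connections are not formed by cells migrating
between patterns) and summarizes TNT lifetimes observed under a fixed
observation cap (300 min in the study), treating capped records as
right-censored.

TNT edges consumed here are annotation products: a connection counts as a
TNT when it is thin (diameter < 800 nm), membranous and F-actin positive,
substrate-detached, and continuous between the two cell bodies.  Those
criteria are applied upstream (by a human annotator or detector); this
module only consumes the resulting edge table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hexgrid import AXIAL_NEIGHBOURS, are_neighbours, neighbour_offsets_xy
from .pattern_qc import PatternGeometry

Site = tuple[int, int]


class EmptyDenominatorError(ValueError):
    """No occupied site has an occupied nearest neighbour."""


@dataclass
class LatticeState:
    """Hexagonal lattice with per-site occupancy and TNT edges.

    ``sites`` are axial coordinates; ``occupied`` the subset carrying a
    cell; ``edges`` unordered occupied nearest-neighbour pairs connected
    by a TNT (one cell per pattern is assumed, matching the single-cell
    patterning design, so "TNT-connected pattern" and "TNT-connected cell"
    coincide).
    """

    sites: list[Site]
    occupied: set[Site]
    edges: set[frozenset] = field(default_factory=set)

    def __post_init__(self):
        self.sites = [tuple(s) for s in self.sites]
        site_set = set(self.sites)
        self.occupied = {tuple(s) for s in self.occupied}
        if not self.occupied <= site_set:
            raise ValueError("occupied sites must be lattice sites")
        norm_edges = set()
        for e in self.edges:
            pair = [tuple(p) for p in e]
            if len(set(pair)) != 2:
                raise ValueError("self-edges are not allowed")
            a, b = pair
            if a not in self.occupied or b not in self.occupied:
                raise ValueError(f"edge {a}-{b} joins an unoccupied site")
            if not are_neighbours(a, b):
                raise ValueError(f"edge {a}-{b} joins non-neighbouring sites")
            norm_edges.add(frozenset((a, b)))
        self.edges = norm_edges


def eligible_denominator(lattice: LatticeState) -> set[Site]:
    """Occupied sites with at least one occupied nearest neighbour.

    These form the denominator of the connected percentage; isolated
    occupied sites are excluded because no inter-pattern TNT can reach them.
    """
    occ = lattice.occupied
    return {
        s
        for s in occ
        if any((s[0] + dq, s[1] + dr) in occ for dq, dr in AXIAL_NEIGHBOURS)
    }


def percent_tnt_connected(lattice: LatticeState) -> float:
    """100 * |sites incident to >= 1 TNT edge| / |eligible sites|.

    A site connected by two TNTs counts once (site incidence).  Raises
    :class:`EmptyDenominatorError` when no site is eligible — the statistic
    is undefined then, not zero.
    """
    eligible = eligible_denominator(lattice)
    if not eligible:
        raise EmptyDenominatorError("no occupied site has an occupied neighbour")
    connected = {s for e in lattice.edges for s in e}
    return 100.0 * len(connected) / len(eligible)


@dataclass
class Trajectory:
    """Cell position over time relative to its home-pattern centre (um)."""

    time_min: np.ndarray
    position_um: np.ndarray
    geometry: PatternGeometry

    def __post_init__(self):
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.position_um = np.asarray(self.position_um, dtype=float)
        if np.any(np.diff(self.time_min) <= 0):
            raise ValueError("time must be increasing")
        if self.position_um.shape != (self.time_min.size, 2):
            raise ValueError("positions must be (n, 2)")
        if not np.all(np.isfinite(self.position_um)):
            raise ValueError("positions must be finite")


def translocation_events(
    trajectories: list[Trajectory],
    min_dwell_samples: int = 2,
) -> tuple[int, list[bool]]:
    """Count inter-pattern translocations across trajectories.

    A translocation is scored when a trajectory leaves its home circle and
    subsequently sits inside a neighbouring pattern circle (distance to a
    neighbour centre < circle radius) for at least ``min_dwell_samples``
    consecutive samples.  Returns the total event count and a per-trajectory
    flag.  Positions are relative to the home centre, so the measure is
    invariant under rigid translation of trajectory and centres together.
    """
    flags = []
    total = 0
    for traj in trajectories:
        geom = traj.geometry
        radius = geom.diameter_um / 2.0
        centres = neighbour_offsets_xy(geom.spacing_um)
        pos = traj.position_um
        left_home = np.linalg.norm(pos, axis=1) >= radius
        d_neigh = np.linalg.norm(pos[:, None, :] - centres[None, :, :], axis=2)
        in_neigh = (d_neigh < radius).any(axis=1)

        events = 0
        has_left = False
        run = 0
        counted_run = False
        for k in range(pos.shape[0]):
            if left_home[k]:
                has_left = True
            if in_neigh[k] and has_left:
                run += 1
                if run >= min_dwell_samples and not counted_run:
                    events += 1
                    counted_run = True
            else:
                run = 0
                counted_run = False
        flags.append(events > 0)
        total += events
    return total, flags


@dataclass
class DurationRecord:
    """One observed TNT lifetime; censored records sit exactly at the cap."""

    duration_min: float
    censored: bool = False

    def __post_init__(self):
        if self.duration_min <= 0:
            raise ValueError("duration must be > 0")


@dataclass
class DurationSummary:
    median_min: float
    n: int
    n_censored: int
    unreliable: bool


def duration_summary(records: list[DurationRecord], cap_min: float = 300.0) -> DurationSummary:
    """Median TNT duration with censored values held at the observation cap.

    Censored records must equal the cap.  The median is computed over all
    values; when half or more of the records are censored the median itself
    is determined by the cap and the summary is flagged unreliable.
    """
    if not records:
        raise ValueError("at least one duration record is required")
    values = []
    n_cens = 0
    for rec in records:
        if rec.censored:
            if abs(rec.duration_min - cap_min) > 1e-9:
                raise ValueError("censored records must sit at the cap")
            n_cens += 1
        values.append(min(rec.duration_min, cap_min))
    frac_cens = n_cens / len(records)
    return DurationSummary(
        median_min=float(np.median(values)),
        n=len(records),
        n_censored=n_cens,
        unreliable=frac_cens >= 0.5,
    )
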