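"""Optical-tweezer force-trace analysis.

Force on the trapped bead follows the harmonic relation F = kappa * dx,
with the trap stiffness kappa calibrated by the viscous-drag method using
Faxen's correction for a sphere dragged parallel to a nearby surface.
Traces are presented with a 10-point centred moving average, and force
peaks (dF) — events where retrograde actin flow outcompetes polymerization
and yanks the bead toward the cell body — are extracted as prominent local
maxima above their preceding local baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal


class CalibrationError(ValueError):
    """Degenerate calibration design (e.g. a single distinct velocity)."""


@dataclass
class ForceTrace:
    """Uniformly sampled bead-displacement series with trap stiffness.

    ``displacement_um`` is the bead offset from its pre-pull reference
    position; ``kappa_pn_per_um`` converts it to force.
    """

    time_s: np.ndarray
    displacement_um: np.ndarray
    kappa_pn_per_um: float

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.displacement_um = np.asarray(self.displacement_um, dtype=float)
        if self.time_s.size != self.displacement_um.size:
            raise ValueError("time and displacement must have equal length")
        if self.kappa_pn_per_um <= 0:
            raise ValueError("trap stiffness must be > 0")
        if self.time_s.size >= 2:
            dt = np.diff(self.time_s)
            if np.any(dt <= 0):
                raise ValueError("time must be strictly increasing")
            if np.ptp(dt) > 1e-9 * max(1.0, abs(dt[0])):
                raise ValueError("sampling must be uniform")

    @property
    def rate_hz(self) -> float:
        return 1.0 / float(self.time_s[1] - self.time_s[0])


@dataclass
class ForcePeak:
    """One retraction event: onset, apex and magnitude dF above baseline."""

    onset_time_s: float
    apex_time_s: float
    magnitude_pn: float
    baseline_pn: float

    def __post_init__(self):
        if self.magnitude_pn <= 0:
            raise ValueError("dF must be > 0")
        if not self.onset_time_s < self.apex_time_s:
            raise ValueError("onset must precede apex")


def faxen_drag(radius_um: float, viscosity_pa_s: float, height_um: float) -> float:
    """Drag coefficient (pN*s/um) of a sphere near a wall, Faxen-corrected.

    gamma = 6*pi*eta*r / (1 - (9/16)s + (1/8)s^3 - (45/256)s^4 - (1/16)s^5)
    with s = r/h, the standard fifth-order series for motion parallel to a
    plane wall; h is the sphere-centre height above the surface.  In these
    units the free-space value is simply 6*pi*eta*r (1 Pa*s * um equals
    1 pN*s/um).
    """
    if radius_um <= 0 or viscosity_pa_s <= 0:
        raise ValueError("radius and viscosity must be > 0")
    if height_um <= radius_um:
        raise ValueError("bead centre height must exceed the bead radius")
    s = radius_um / height_um
    correction = 1.0 - (9.0 / 16.0) * s + (1.0 / 8.0) * s**3 - (45.0 / 256.0) * s**4 - (1.0 / 16.0) * s**5
    return 6.0 * math.pi * viscosity_pa_s * radius_um / correction


@dataclass
class StiffnessCalibration:
    """Trap stiffness from a velocity sweep, with fit diagnostics."""

    kappa_pn_per_um: float
    residual_rms_pn: float
    r_squared: float
    warning: bool


def calibrate_stiffness(sweep, drag_pn_s_per_um: float) -> StiffnessCalibration:
    """kappa from the viscous-drag method: gamma*v = kappa * offset.

    ``sweep`` is a sequence of (stage velocity um/s, mean bead offset um)
    pairs.  kappa is the least-squares slope of gamma*v against offset
    through the origin.  Offsets poorly proportional to velocity
    (R^2 < 0.9) set the ``warning`` flag.
    """
    sweep = np.asarray(sweep, dtype=float)
    if sweep.ndim != 2 or sweep.shape[1] != 2:
        raise ValueError("sweep must be pairs of (velocity, offset)")
    v, x = sweep[:, 0], sweep[:, 1]
    if np.unique(v).size < 2:
        raise CalibrationError("at least 2 distinct stage velocities are required")
    force = drag_pn_s_per_um * v
    denom = float(np.dot(x, x))
    if denom == 0:
        raise CalibrationError("all bead offsets are zero")
    kappa = float(np.dot(x, force)) / denom
    resid = force - kappa * x
    ss_tot = float(np.sum((force - force.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return StiffnessCalibration(
        kappa_pn_per_um=kappa,
        residual_rms_pn=float(np.sqrt(np.mean(resid**2))),
        r_squared=r2,
        warning=r2 < 0.9,
    )


def moving_average(series: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average; edge windows truncate to available samples."""
    series = np.asarray(series, dtype=float)
    if window < 1 or window > series.size:
        raise ValueError("window must be in [1, len(series)]")
    kernel = np.ones(window)
    num = np.convolve(series, kernel, mode="same")
    den = np.convolve(np.ones_like(series), kernel, mode="same")
    return num / den


def force_series(trace: ForceTrace, smooth_window: int = 10):
    """Raw force kappa*dx and its centred moving average (default 10 points).

    Returns ``(raw_pn, smoothed_pn)``; the raw series is always retained.
    """
    raw = trace.kappa_pn_per_um * trace.displacement_um
    return raw, moving_average(raw, smooth_window)


def detect_force_peaks(
    force_pn: np.ndarray,
    time_s: np.ndarray,
    min_prominence_pn: float = 2.0,
    min_separation_s: float = 5.0,
) -> list[ForcePeak]:
    """Extract dF peaks from a (smoothed) force series.

    Peaks are local maxima with prominence >= ``min_prominence_pn`` and
    pairwise separation >= ``min_separation_s``.  dF is measured from the
    apex down to the preceding local baseline, taken over the segment
    between the previous accepted peak (or the trace start) and the apex.
    The baseline *level* is the median of that segment excluding the final
    approach window before the apex (the raw segment minimum is biased low
    by the expected extreme of the smoothed noise over long segments); the
    segment trough marks the reported onset.  The result is invariant to
    adding any constant to the whole series.
    """
    force_pn = np.asarray(force_pn, dtype=float)
    time_s = np.asarray(time_s, dtype=float)
    if force_pn.size < 2:
        return []
    dt = float(time_s[1] - time_s[0])
    distance = max(1, int(round(min_separation_s / dt)))
    apexes, _ = signal.find_peaks(force_pn, prominence=min_prominence_pn, distance=distance)
    peaks: list[ForcePeak] = []
    prev = 0
    for apex in apexes:
        segment = force_pn[prev : apex + 1]
        base_idx = prev + int(np.argmin(segment))
        plateau = force_pn[prev : max(prev + 1, apex - distance)]
        if plateau.size:
            baseline = float(np.median(plateau))
        else:
            baseline = float(force_pn[base_idx])
        magnitude = float(force_pn[apex] - baseline)
        if magnitude <= 0 or base_idx >= apex:
            continue
        peaks.append(
            ForcePeak(
                onset_time_s=float(time_s[base_idx]),
                apex_time_s=float(time_s[apex]),
                magnitude_pn=magnitude,
                baseline_pn=baseline,
            )
        )
        prev = apex
    return peaks
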