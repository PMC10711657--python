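"""Actin-intensity quantification in pulled membrane nanotubes.

Pipeline mirroring the study's nanotube analysis: the tube cross-section in
the membrane channel is fit to a Gaussian to set the band half-width (2*sigma);
the actin channel is background-subtracted, band-averaged along the tube
axis, and normalized by the mean cytosolic signal; the origin X = 0 is the
position of the maximum membrane intensity within the plasma-membrane rim
near the tube base; an exponential I(X) = baseline + (I0-baseline)*exp(-X/l)
is fit and the characteristic decay length reported as 2l — the distance at
which the origin intensity has fallen to 1/e^2 of its initial value.
Profiles are finally categorized by how far the actin signal stays
distinguishable from background (5-um bins, >= 20 um top bin).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize


class FitError(RuntimeError):
    """A least-squares fit failed or was degenerate."""


class OriginError(RuntimeError):
    """No membrane-rim maximum found within the proximal search window."""


@dataclass
class TubeImage:
    """Two-channel nanotube image with axis and reference regions.

    ``axis_xy`` is a polyline in pixel coordinates (x=column, y=row) running
    from inside the cell body outward along the tube.  ``cytosol_mask`` marks
    pixels inside the cell body used for normalization; ``background_mask``
    marks pixels outside cell and tube used for background subtraction.
    """

    membrane: np.ndarray
    actin: np.ndarray
    pixel_size_um: float
    axis_xy: np.ndarray
    cytosol_mask: np.ndarray
    background_mask: np.ndarray

    def __post_init__(self):
        self.membrane = np.asarray(self.membrane, dtype=float)
        self.actin = np.asarray(self.actin, dtype=float)
        self.axis_xy = np.asarray(self.axis_xy, dtype=float)
        self.cytosol_mask = np.asarray(self.cytosol_mask, dtype=bool)
        self.background_mask = np.asarray(self.background_mask, dtype=bool)
        if self.membrane.shape != self.actin.shape:
            raise ValueError("membrane and actin channels must share a shape")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be > 0")
        if self.axis_xy.ndim != 2 or self.axis_xy.shape[0] < 2 or self.axis_xy.shape[1] != 2:
            raise ValueError("axis must be a polyline of >= 2 (x, y) vertices")
        if not self.cytosol_mask.any() or not self.background_mask.any():
            raise ValueError("cytosol and background regions must be non-empty")
        if (self.cytosol_mask & self.background_mask).any():
            raise ValueError("cytosol and background regions must be disjoint")


@dataclass
class GaussianFit:
    """Gaussian cross-section fit of the membrane ridge.

    ``sigma_um`` is the median fitted width over the sampled axial
    positions; the band half-width used downstream is w = 2*sigma.
    """

    centre_um: float
    sigma_um: float
    amplitude: float
    offset: float

    def __post_init__(self):
        if self.sigma_um <= 0:
            raise ValueError("sigma must be > 0")

    @property
    def half_width_um(self) -> float:
        return 2.0 * self.sigma_um


@dataclass
class ActinProfile:
    """Normalized actin intensity along the tube, X = 0 at the membrane rim.

    Intensities are background-subtracted and expressed in units of the mean
    cytosolic signal (cytosol = 1).  ``background_level`` / ``background_spread``
    are the mean and standard deviation of the normalized background region.
    """

    x_um: np.ndarray
    intensity: np.ndarray
    background_level: float
    background_spread: float

    def __post_init__(self):
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.x_um.size != self.intensity.size:
            raise ValueError("x and intensity must have equal length")
        if self.x_um.size and (self.x_um[0] != 0.0 or np.any(np.diff(self.x_um) <= 0)):
            raise ValueError("X must start at 0 and be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")

    @property
    def span_um(self) -> float:
        return float(self.x_um[-1] - self.x_um[0]) if self.x_um.size else 0.0


@dataclass
class DecayFit:
    """Exponential fit I(X) = baseline + (I0 - baseline) * exp(-X / l).

    ``two_ell_um`` is the reported characteristic decay length 2l, at which
    the model value above baseline has fallen to 1/e^2 of (I0 - baseline).
    """

    i0: float
    ell_um: float
    baseline: float
    residual_rms: float
    converged: bool
    two_ell_um: float = field(init=False)

    def __post_init__(self):
        if self.ell_um <= 0:
            raise ValueError("ell must be > 0")
        self.two_ell_um = 2.0 * self.ell_um

    def model(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.baseline + (self.i0 - self.baseline) * np.exp(-x / self.ell_um)


INFILTRATION_BINS = ((0.0, 5.0), (5.0, 10.0), (10.0, 15.0), (15.0, 20.0))


@dataclass
class InfiltrationResult:
    """Distance over which actin stays above background, and its 5-um bin."""

    extent_um: float
    category: str
    censored: bool


# ---------------------------------------------------------------------------
# geometry helpers


def _bilinear(channel: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Bilinear interpolation at float pixel coordinates (x=col, y=row)."""
    ny, nx = channel.shape
    x = np.clip(x, 0.0, nx - 1.0)
    y = np.clip(y, 0.0, ny - 1.0)
    x0 = np.clip(np.floor(x).astype(int), 0, nx - 2)
    y0 = np.clip(np.floor(y).astype(int), 0, ny - 2)
    dx = x - x0
    dy = y - y0
    c00 = channel[y0, x0]
    c01 = channel[y0, x0 + 1]
    c10 = channel[y0 + 1, x0]
    c11 = channel[y0 + 1, x0 + 1]
    return (
        c00 * (1 - dx) * (1 - dy)
        + c01 * dx * (1 - dy)
        + c10 * (1 - dx) * dy
        + c11 * dx * dy
    )


def _axis_arclength_px(axis_xy: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(axis_xy, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _point_and_normal(axis_xy: np.ndarray, s_px: np.ndarray):
    """Points on the polyline at arc lengths ``s_px`` and unit normals there."""
    cum = _axis_arclength_px(axis_xy)
    pts = np.empty((s_px.size, 2))
    normals = np.empty((s_px.size, 2))
    seg_idx = np.clip(np.searchsorted(cum, s_px, side="right") - 1, 0, len(cum) - 2)
    for i, (s, j) in enumerate(zip(s_px, seg_idx)):
        p0, p1 = axis_xy[j], axis_xy[j + 1]
        seg_len = cum[j + 1] - cum[j]
        t = 0.0 if seg_len == 0 else (s - cum[j]) / seg_len
        pts[i] = p0 + t * (p1 - p0)
        tangent = (p1 - p0) / (seg_len if seg_len else 1.0)
        normals[i] = (-tangent[1], tangent[0])
    return pts, normals


def band_profile(
    channel: np.ndarray,
    axis_xy: np.ndarray,
    s_px: np.ndarray,
    half_width_px: float,
    perp_step_px: float = 0.5,
) -> np.ndarray:
    """Mean intensity across a perpendicular band at each axial position.

    Perpendicular offsets are sampled at ``perp_step_px`` (default 0.5 pixel)
    with bilinear interpolation, emulating a wide-line intensity profile.
    """
    pts, normals = _point_and_normal(axis_xy, s_px)
    offsets = np.arange(-half_width_px, half_width_px + 1e-9, perp_step_px)
    xs = pts[:, 0][:, None] + normals[:, 0][:, None] * offsets[None, :]
    ys = pts[:, 1][:, None] + normals[:, 1][:, None] * offsets[None, :]
    return _bilinear(channel, xs, ys).mean(axis=1)


# ---------------------------------------------------------------------------
# operations


def _fit_gaussian_1d(r_um: np.ndarray, values: np.ndarray):
    """Single Gaussian + offset least squares; returns params or None."""

    def model(r, amp, centre, sigma, offset):
        return amp * np.exp(-((r - centre) ** 2) / (2.0 * sigma**2)) + offset

    vmin, vmax = float(values.min()), float(values.max())
    span = r_um[-1] - r_um[0]
    p0 = [vmax - vmin, float(r_um[np.argmax(values)]), span / 8.0, vmin]
    try:
        popt, _ = optimize.curve_fit(
            model,
            r_um,
            values,
            p0=p0,
            bounds=([0.0, r_um[0], 1e-6, -np.inf], [np.inf, r_um[-1], span, np.inf]),
            maxfev=5000,
        )
    except (RuntimeError, ValueError):
        return None
    amp, centre, sigma, offset = popt
    resid = values - model(r_um, *popt)
    noise = float(np.std(resid))
    # degenerate "fits": no real ridge, or sigma pinned at the window size
    scale = max(abs(vmax), abs(vmin), 1e-12)
    if amp < max(3.0 * noise, 1e-6 * scale) or sigma >= 0.95 * span:
        return None
    return amp, centre, sigma, offset


def fit_cross_section(
    image: TubeImage,
    positions_um,
    half_width_um: float | None = None,
) -> GaussianFit:
    """Fit the membrane ridge cross-section to a Gaussian at each position.

    ``positions_um`` are arc-length positions along the tube axis (distal to
    the cell body).  sigma is the median over positions; the returned fit
    carries w = 2*sigma.  Raises :class:`FitError` when the fit fails at
    more than half the positions (e.g. a flat membrane channel).
    """
    positions_um = np.asarray(positions_um, dtype=float)
    if positions_um.size == 0:
        raise ValueError("at least one axial position is required")
    px = image.pixel_size_um
    if half_width_um is None:
        half_width_um = max(1.5, 8.0 * px)
    half_width_px = half_width_um / px

    pts, normals = _point_and_normal(image.axis_xy, positions_um / px)
    offsets_px = np.arange(-half_width_px, half_width_px + 1e-9, 0.5)
    r_um = offsets_px * px
    fits = []
    for p, nvec in zip(pts, normals):
        xs = p[0] + nvec[0] * offsets_px
        ys = p[1] + nvec[1] * offsets_px
        values = _bilinear(image.membrane, xs, ys)
        res = _fit_gaussian_1d(r_um, values)
        if res is not None:
            fits.append(res)
    if len(fits) <= len(positions_um) / 2.0:
        raise FitError(
            f"Gaussian cross-section fit failed at {len(positions_um) - len(fits)} "
            f"of {len(positions_um)} positions (no detectable ridge?)"
        )
    amps, centres, sigmas, offs = (np.array([f[i] for f in fits]) for i in range(4))
    return GaussianFit(
        centre_um=float(np.median(centres)),
        sigma_um=float(np.median(sigmas)),
        amplitude=float(np.median(amps)),
        offset=float(np.median(offs)),
    )


def extract_actin_profile(
    image: TubeImage,
    fit: GaussianFit,
    proximal_fraction: float = 0.25,
) -> ActinProfile:
    """Background-subtract, band-average, normalize, and set the X=0 origin.

    The actin channel is averaged across a perpendicular band of half-width
    2*sigma at pixel-pitch steps along the axis, background-subtracted using
    the mean of the background region and normalized by the (equally
    background-subtracted) cytosol mean.  X = 0 is placed at the arc-length
    position of the maximum membrane band intensity within the proximal
    ``proximal_fraction`` of the axis; ties break toward the cell body
    (smallest arc length).  Samples distal to the origin are returned.
    """
    px = image.pixel_size_um
    cum = _axis_arclength_px(image.axis_xy)
    total_px = cum[-1]
    s_px = np.arange(0.0, total_px + 1e-9, 1.0)
    half_width_px = fit.half_width_um / px

    mem_band = band_profile(image.membrane, image.axis_xy, s_px, half_width_px)
    act_band = band_profile(image.actin, image.axis_xy, s_px, half_width_px)

    n_prox = int(math.floor(proximal_fraction * s_px.size))
    if n_prox < 1:
        raise OriginError("proximal search window contains no samples")
    window = mem_band[:n_prox]
    # ties (within numerical tolerance) break toward the cell body
    wmax = float(window.max())
    tol = 1e-9 * max(1.0, abs(wmax))
    origin_idx = int(np.argmax(window >= wmax - tol))

    bg = float(image.actin[image.background_mask].mean())
    cyto = float(image.actin[image.cytosol_mask].mean()) - bg
    if cyto <= 0:
        raise ValueError("cytosol mean does not exceed background; cannot normalize")

    norm = (act_band[origin_idx:] - bg) / cyto
    x_um = (s_px[origin_idx:] - s_px[origin_idx]) * px
    bg_norm = (image.actin[image.background_mask] - bg) / cyto
    return ActinProfile(
        x_um=x_um,
        intensity=norm,
        background_level=float(bg_norm.mean()),
        background_spread=float(bg_norm.std()),
    )


def fit_decay(
    profile: ActinProfile,
    pin_baseline_zero: bool = False,
    min_samples: int = 8,
    min_span_um: float = 2.0,
) -> DecayFit:
    """Least-squares exponential decay fit, reporting 2l.

    The model is I(X) = baseline + (I0 - baseline) * exp(-X / l) with
    l in (0, 10*span] and baseline >= 0.  With ``pin_baseline_zero`` the
    stricter pure-exponential model is fit.  Non-convergence or l at a
    bound is flagged via ``converged=False`` rather than silently returned.
    """
    x, y = profile.x_um, profile.intensity
    if x.size < min_samples:
        raise ValueError(f"profile must have >= {min_samples} samples")
    span = profile.span_um
    if span < min_span_um:
        raise ValueError(f"profile must span >= {min_span_um} um")

    ell_hi = 10.0 * span
    i0_guess = max(float(y[0]), 1e-6)
    if pin_baseline_zero:

        def model(xv, i0, ell):
            return i0 * np.exp(-xv / ell)

        p0 = [i0_guess, span / 4.0]
        bounds = ([0.0, 1e-9], [np.inf, ell_hi])
    else:

        def model(xv, i0, ell, base):
            return base + (i0 - base) * np.exp(-xv / ell)

        base_guess = max(float(y.min()), 0.0)
        p0 = [i0_guess, span / 4.0, base_guess]
        bounds = ([0.0, 1e-9, 0.0], [np.inf, ell_hi, np.inf])

    converged = True
    try:
        popt, _ = optimize.curve_fit(model, x, y, p0=p0, bounds=bounds, maxfev=10000)
    except (RuntimeError, ValueError):
        popt = np.asarray(p0, dtype=float)
        converged = False

    i0, ell = float(popt[0]), float(popt[1])
    base = 0.0 if pin_baseline_zero else float(popt[2])
    if not (1e-8 < ell < 0.999 * ell_hi):
        converged = False
        ell = min(max(ell, 1e-8), ell_hi)
    resid = y - model(x, *popt)
    return DecayFit(
        i0=i0,
        ell_um=ell,
        baseline=base,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        converged=converged,
    )


def infiltration_extent(profile: ActinProfile, k: int = 5) -> InfiltrationResult:
    """Distance at which the profile becomes indistinguishable from background.

    The extent is the smallest X at which ``k`` consecutive samples satisfy
    I <= background level + 2 * background spread.  Profiles that never meet
    the criterion are censored at the profile span.  The category is the
    5-um bin containing the extent ([0-5), [5-10), [10-15), [15-20), >=20).
    """
    thr = profile.background_level + 2.0 * profile.background_spread
    below = profile.intensity <= thr
    extent = None
    if below.size >= k:
        run = np.convolve(below.astype(int), np.ones(k, dtype=int), mode="valid")
        hits = np.nonzero(run == k)[0]
        if hits.size:
            extent = float(profile.x_um[hits[0]])
    censored = extent is None
    if censored:
        extent = profile.span_um
    for lo, hi in INFILTRATION_BINS:
        if lo <= extent < hi:
            category = f"[{lo:g}-{hi:g})"
            break
    else:
        category = ">=20"
    return InfiltrationResult(extent_um=extent, category=category, censored=censored)
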