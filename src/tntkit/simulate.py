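"""Synthetic-data generators with recorded ground truth.

Every downstream analysis stage has a generator here that emulates its
input and returns it together with a :class:`~tntkit.truth.TruthRecord`
holding the quantities a recovery test needs.  All randomness flows through
one seeded :class:`numpy.random.Generator` per call, so identical
(seed, parameters) reproduce outputs bit-for-bit.

Generated inputs:

* hexagonal micropattern images (filled circles, diameter 31 um by default,
  at centre spacing d = diameter + D),
* two-channel nanotube images whose actin channel decays exponentially
  along the tube from a cytosolic plateau,
* harmonic-trap bead traces with scheduled retraction peaks (dF),
* hexagonal lattices with stochastic occupancy and TNT edges,
* donor/acceptor transfer outcomes with separate contact and secretion
  routes,
* log-normal peptide intensity tables with a known differential fraction
  and condition-dependent missingness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, special

from .connectivity import LatticeState
from .force_trace import ForceTrace
from .hexgrid import AXIAL_NEIGHBOURS, axial_to_xy, lattice_sites
from .pattern_qc import PatternGeometry, PatternImage
from .proteomics import PeptideTable
from .transfer_assay import FlowCounts, TransferTable
from .truth import TruthRecord
from .tube_profile import TubeImage

# fraction of the Gaussian ridge peak that survives band-averaging over
# +/- 2 sigma: mean of exp(-r^2 / 2 sigma^2) over the 4 sigma wide band
_BAND_MEAN_FACTOR = math.sqrt(2.0 * math.pi) * special.erf(math.sqrt(2.0)) / 4.0


# ---------------------------------------------------------------------------
# micropattern images


def gen_pattern_image(
    geometry: PatternGeometry,
    canvas_px: tuple[int, int] = (512, 512),
    noise_sd: float = 0.0,
    seed: int = 0,
    foreground: float = 1000.0,
    orientation_deg: float = 0.0,
) -> tuple[PatternImage, TruthRecord]:
    """Hexagonal array of filled circles of the stated diameter.

    Circle centres sit on a (possibly rotated) hexagonal lattice with
    centre-to-centre spacing d = diameter + D; additive Gaussian noise of
    ``noise_sd`` counts is applied.  The canvas must contain at least three
    lattice periods along each axis.
    """
    ny, nx = canvas_px
    px = geometry.pixel_size_um
    d = geometry.spacing_um
    width_um, height_um = nx * px, ny * px
    row_period = d * math.sqrt(3.0) / 2.0
    if width_um < 3 * d or height_um < 3 * row_period:
        raise ValueError(
            f"canvas ({width_um:g} x {height_um:g} um) must span >= 3 lattice "
            f"periods ({3 * d:g} x {3 * row_period:g} um)"
        )

    theta = math.radians(orientation_deg)
    rot = np.array(
        [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
    )
    # enough axial indices to cover the canvas after rotation
    n_q = int(math.ceil(max(width_um, height_um) / d)) + 3
    n_r = int(math.ceil(max(width_um, height_um) / row_period)) + 3
    centres = []
    radius = geometry.diameter_um / 2.0
    for r in range(-n_r, n_r + 1):
        for q in range(-n_q, n_q + 1):
            x, y = axial_to_xy(q, r, d)
            cx, cy = rot @ np.array([float(x), float(y)])
            cx += width_um / 2.0
            cy += height_um / 2.0
            if -radius <= cx <= width_um + radius and -radius <= cy <= height_um + radius:
                centres.append((cx, cy))

    img = np.zeros((ny, nx), dtype=float)
    xs = (np.arange(nx) + 0.5) * px
    ys = (np.arange(ny) + 0.5) * px
    r_px = radius / px
    for cx, cy in centres:
        j0 = max(0, int((cx - radius) / px) - 1)
        j1 = min(nx, int((cx + radius) / px) + 2)
        i0 = max(0, int((cy - radius) / px) - 1)
        i1 = min(ny, int((cy + radius) / px) + 2)
        if j0 >= j1 or i0 >= i1:
            continue
        sub_x = xs[j0:j1] - cx
        sub_y = ys[i0:i1] - cy
        mask = sub_x[None, :] ** 2 + sub_y[:, None] ** 2 <= radius**2
        img[i0:i1, j0:j1][mask] = foreground

    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
        img = np.clip(img, 0.0, None)

    truth = TruthRecord(
        generator="gen_pattern_image",
        seed=seed,
        parameters={
            "diameter_um": geometry.diameter_um,
            "separation_um": geometry.separation_um,
            "spacing_um": d,
            "orientation_deg": orientation_deg,
            "pixel_size_um": px,
            "foreground": foreground,
            "noise_sd": noise_sd,
            "n_circles": len(centres),
            "centres_um": centres,
        },
    )
    return PatternImage(pixels=img, pixel_size_um=px), truth


# ---------------------------------------------------------------------------
# nanotube images


@dataclass(frozen=True)
class TubeSimParams:
    """Parameters of the two-channel synthetic nanotube image.

    ``i0`` is the band-averaged (over +/- 2 sigma_m) actin intensity above
    background at the tube base, so the extracted profile starts near
    i0/cytosol after normalization.  ``blur_um`` is a Gaussian convolution
    standing in for the microscope PSF; noise is Poisson on expected counts
    by default, with a Gaussian option for closed-form checks.
    """

    tube_length_um: float = 15.0
    ell_um: float = 3.0
    i0: float = 50.0
    sigma_m_um: float = 0.4
    cytosol_level: float = 50.0
    background: float = 2.0
    blur_um: float = 0.2
    noise: str = "poisson"  # "poisson" | "gaussian" | "none"
    noise_sd: float = 0.0
    pixel_size_um: float = 0.1
    cell_width_um: float = 8.0
    membrane_cell_level: float = 60.0
    membrane_rim_amp: float = 200.0
    membrane_tube_amp: float = 80.0

    def __post_init__(self):
        if self.ell_um <= 0:
            raise ValueError("decay length ell must be > 0")
        for name in ("tube_length_um", "sigma_m_um", "pixel_size_um", "blur_um"):
            if getattr(self, name) < 0 or (name != "blur_um" and getattr(self, name) == 0):
                raise ValueError(f"{name} must be > 0")
        if self.tube_length_um < 5 * self.pixel_size_um:
            raise ValueError("tube length must be >= 5 pixels")
        if self.noise not in ("poisson", "gaussian", "none"):
            raise ValueError("noise must be 'poisson', 'gaussian' or 'none'")


def _tube_expected_channels(params: TubeSimParams):
    """Noise-free expected-count images plus geometry (pixel coordinates)."""
    px = params.pixel_size_um
    margin_um = 3.0
    width_um = params.cell_width_um + params.tube_length_um + margin_um
    height_um = 2.0 * max(4.0, 10.0 * params.sigma_m_um + 2.0)
    nx = int(round(width_um / px))
    ny = int(round(height_um / px))
    x_um = (np.arange(nx) + 0.5) * px
    y_um = (np.arange(ny) + 0.5) * px
    y_c = height_um / 2.0
    x_edge = params.cell_width_um

    cell = (x_um <= x_edge).astype(float)
    ridge_perp = np.exp(-((y_um - y_c) ** 2) / (2.0 * params.sigma_m_um**2))[:, None]
    in_tube = (x_um > x_edge) & (x_um <= x_edge + params.tube_length_um)

    membrane = np.zeros((ny, nx))
    membrane += params.membrane_cell_level * cell[None, :]
    membrane += params.membrane_rim_amp * np.exp(
        -((x_um - x_edge) ** 2) / (2.0 * params.sigma_m_um**2)
    )[None, :]
    membrane += params.membrane_tube_amp * ridge_perp * in_tube[None, :]
    membrane += params.background

    actin = np.zeros((ny, nx))
    actin += params.cytosol_level * cell[None, :]
    amp_axial = np.where(
        in_tube,
        (params.i0 / _BAND_MEAN_FACTOR) * np.exp(-(x_um - x_edge) / params.ell_um),
        0.0,
    )
    actin = actin + amp_axial[None, :] * ridge_perp
    actin += params.background

    geom = {
        "x_edge_um": x_edge,
        "y_c_um": y_c,
        "nx": nx,
        "ny": ny,
        "x_um": x_um,
        "y_um": y_um,
    }
    return membrane, actin, geom


def gen_tube_image(params: TubeSimParams, seed: int = 0) -> tuple[TubeImage, TruthRecord]:
    """Two-channel nanotube image with a known actin decay length.

    The membrane channel holds the cell body, a bright rim at the cell edge
    (whose maximum defines the X = 0 origin) and a Gaussian-cross-section
    tube ridge of width sigma_m.  The actin channel holds a cytosolic
    plateau and, along the tube, a band-averaged intensity
    i0 * exp(-X / ell) above background.  Both channels are blurred then
    noised.  The axis polyline, cytosol and background masks are attached.
    """
    membrane, actin, geom = _tube_expected_channels(params)
    px = params.pixel_size_um
    if params.blur_um > 0:
        sig = params.blur_um / px
        membrane = ndimage.gaussian_filter(membrane, sig)
        actin = ndimage.gaussian_filter(actin, sig)

    rng = np.random.default_rng(seed)
    if params.noise == "poisson":
        membrane = rng.poisson(np.clip(membrane, 0, None)).astype(float)
        actin = rng.poisson(np.clip(actin, 0, None)).astype(float)
    elif params.noise == "gaussian" and params.noise_sd > 0:
        membrane = membrane + rng.normal(0, params.noise_sd, membrane.shape)
        actin = actin + rng.normal(0, params.noise_sd, actin.shape)

    x_edge_px = geom["x_edge_um"] / px - 0.5
    y_c_px = geom["y_c_um"] / px - 0.5
    start_x = max(0.0, x_edge_px - 3.0 / px)  # start 3 um inside the cell
    end_x = min(geom["nx"] - 1.0, x_edge_px + params.tube_length_um / px)
    axis = np.array([[start_x, y_c_px], [end_x, y_c_px]])

    yy, xx = np.mgrid[0 : geom["ny"], 0 : geom["nx"]]
    cyto = (xx * px < geom["x_edge_um"] - 1.0) & (
        np.abs(yy - y_c_px) * px < geom["y_c_um"] - 1.5
    )
    bg = (xx * px > geom["x_edge_um"] + 1.0) & (
        np.abs(yy - y_c_px) * px > 8.0 * params.sigma_m_um + 0.5
    )

    image = TubeImage(
        membrane=membrane,
        actin=actin,
        pixel_size_um=px,
        axis_xy=axis,
        cytosol_mask=cyto,
        background_mask=bg,
    )
    truth = TruthRecord(
        generator="gen_tube_image",
        seed=seed,
        parameters={
            "ell_um": params.ell_um,
            "two_ell_um": 2.0 * params.ell_um,
            "i0": params.i0,
            "sigma_m_um": params.sigma_m_um,
            "cytosol_level": params.cytosol_level,
            "background": params.background,
            "tube_length_um": params.tube_length_um,
            "pixel_size_um": px,
            "tube_base_px": [x_edge_px, y_c_px],
            "axis_px": axis,
            "noise": params.noise,
        },
    )
    return image, truth


# ---------------------------------------------------------------------------
# force traces


def gen_force_trace(
    kappa_true: float,
    peak_schedule,
    noise_sd: float = 0.0,
    duration_s: float = 300.0,
    rate_hz: float = 20.0,
    seed: int = 0,
    baseline_pn: float = 5.0,
) -> tuple[ForceTrace, TruthRecord]:
    """Harmonic-trap bead trace with scheduled retraction peaks.

    ``peak_schedule`` is a list of (apex time s, dF pN, rise s, relax s);
    each peak rises linearly to dF at its apex and relaxes linearly back.
    The displacement series is (baseline + sum of peaks + noise) / kappa.
    Peaks whose shapes overlap (apex gap < relax + next rise) set an
    ``overlap_warning`` flag in the truth record.
    """
    if rate_hz <= 0:
        raise ValueError("sampling rate must be > 0")
    schedule = [tuple(float(v) for v in p) for p in peak_schedule]
    for t_apex, d_f, rise, relax in schedule:
        if d_f <= 0 or rise <= 0 or relax <= 0:
            raise ValueError("peak dF, rise and relax must be > 0")
        if t_apex - rise < 0 or t_apex + relax > duration_s:
            raise ValueError(f"peak at {t_apex} s does not fit within the trace")
    schedule.sort(key=lambda p: p[0])
    overlap = any(
        schedule[i + 1][0] - schedule[i][0] < schedule[i][3] + schedule[i + 1][2]
        for i in range(len(schedule) - 1)
    )

    t = np.arange(0.0, duration_s, 1.0 / rate_hz)
    force = np.full_like(t, baseline_pn)
    for t_apex, d_f, rise, relax in schedule:
        up = (t >= t_apex - rise) & (t <= t_apex)
        down = (t > t_apex) & (t <= t_apex + relax)
        force[up] += d_f * (t[up] - (t_apex - rise)) / rise
        force[down] += d_f * (1.0 - (t[down] - t_apex) / relax)

    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        force = force + rng.normal(0.0, noise_sd, force.shape)

    trace = ForceTrace(time_s=t, displacement_um=force / kappa_true, kappa_pn_per_um=kappa_true)
    truth = TruthRecord(
        generator="gen_force_trace",
        seed=seed,
        parameters={
            "kappa_true_pn_per_um": kappa_true,
            "baseline_pn": baseline_pn,
            "noise_sd_pn": noise_sd,
            "rate_hz": rate_hz,
            "duration_s": duration_s,
            "peak_times_s": [p[0] for p in schedule],
            "peak_magnitudes_pn": [p[1] for p in schedule],
            "peak_rise_s": [p[2] for p in schedule],
            "peak_relax_s": [p[3] for p in schedule],
            "overlap_warning": overlap,
        },
    )
    return trace, truth


# ---------------------------------------------------------------------------
# lattices


def gen_lattice(
    rows: int,
    cols: int,
    p_occupied: float,
    p_tnt: float,
    seed: int = 0,
) -> tuple[LatticeState, TruthRecord]:
    """Hexagonal lattice with independent occupancy and TNT edges.

    Each site is occupied with probability ``p_occupied``; each occupied
    nearest-neighbour pair carries a TNT edge independently with
    probability ``p_tnt``.
    """
    for name, p in (("p_occupied", p_occupied), ("p_tnt", p_tnt)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    sites = lattice_sites(rows, cols)
    occupied = {s for s in sites if rng.random() < p_occupied}
    site_set = set(sites)
    pairs = []
    for s in sites:
        for dq, dr in AXIAL_NEIGHBOURS[:3]:  # half the offsets -> each pair once
            nb = (s[0] + dq, s[1] + dr)
            if nb in site_set:
                pairs.append((s, nb))
    edges = {
        frozenset(pair)
        for pair in pairs
        if pair[0] in occupied and pair[1] in occupied and rng.random() < p_tnt
    }
    lattice = LatticeState(sites=sites, occupied=occupied, edges=edges)
    truth = TruthRecord(
        generator="gen_lattice",
        seed=seed,
        parameters={
            "rows": rows,
            "cols": cols,
            "p_occupied": p_occupied,
            "p_tnt": p_tnt,
            "occupied": sorted(occupied),
            "edges": sorted(tuple(sorted(e)) for e in edges),
            "n_neighbour_pairs": len(pairs),
        },
    )
    return lattice, truth


# ---------------------------------------------------------------------------
# transfer experiments


def gen_transfer_experiment(
    n_acceptors: int,
    p_contact: float,
    p_secretion: float,
    seed: int = 0,
) -> tuple[TransferTable, TransferTable, FlowCounts, TruthRecord]:
    """Co-culture + secretion-control transfer outcome with known routes.

    Co-culture acceptors are positive with probability p_contact +
    p_secretion (the two routes act on disjoint cells); the conditioned-
    medium control sees only p_secretion.  The flow-cytometry counts mirror
    the co-culture table exactly (Q1 = acceptors, Q2 = positives).
    """
    if n_acceptors <= 0:
        raise ValueError("n_acceptors must be > 0")
    for name, p in (("p_contact", p_contact), ("p_secretion", p_secretion)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    if p_contact + p_secretion > 1.0:
        raise ValueError("p_contact + p_secretion must be <= 1")
    rng = np.random.default_rng(seed)
    pos_cc = int(rng.binomial(n_acceptors, p_contact + p_secretion))
    pos_sec = int(rng.binomial(n_acceptors, p_secretion))
    coculture = TransferTable(n_total=n_acceptors, n_positive=pos_cc, route="coculture")
    control = TransferTable(
        n_total=n_acceptors, n_positive=pos_sec, route="secretion-control"
    )
    flow = FlowCounts(q1=n_acceptors, q2=pos_cc)
    truth = TruthRecord(
        generator="gen_transfer_experiment",
        seed=seed,
        parameters={
            "n_acceptors": n_acceptors,
            "p_contact": p_contact,
            "p_secretion": p_secretion,
            "positives_coculture": pos_cc,
            "positives_secretion": pos_sec,
        },
    )
    return coculture, control, flow, truth


# ---------------------------------------------------------------------------
# proteomics


def gen_proteomics(
    n_proteins: int = 2000,
    n_per_condition: int = 3,
    frac_differential: float = 0.1,
    effect: float = 2.0,
    var_prior: tuple[float, float] = (4.0, 0.09),
    missing_rates: tuple[float, float] = (0.0, 0.0),
    seed: int = 0,
    base_mean: float = 25.0,
    base_sd: float = 2.0,
    peptides_per_protein: tuple[int, int] = (3, 8),
) -> tuple[PeptideTable, TruthRecord]:
    """Log-normal peptide intensity table with known differential proteins.

    Per-protein log2 variances are drawn from a scaled inverse-chi-square
    prior (d0, s0^2); a ``frac_differential`` subset is shifted by +/-
    ``effect`` log2 units in condition A.  ``missing_rates`` gives the
    (random, condition-exclusive) missingness: random dropout is applied
    cell-wise (always leaving >= 1 observed value per condition so the
    matrix stays testable), and an exclusive fraction of proteins is made
    all-missing in one condition.  Peptide rows carry fixed per-peptide
    fractions of each protein's linear intensity, so protein-level sums
    reproduce the intended values exactly.
    """
    if n_per_condition < 2:
        raise ValueError("need >= 2 samples per condition")
    if not 0.0 <= frac_differential <= 1.0:
        raise ValueError("frac_differential must lie in [0, 1]")
    d0, s0_sq = var_prior
    rate_random, rate_exclusive = missing_rates
    rng = np.random.default_rng(seed)

    proteins = [f"P{i:05d}" for i in range(n_proteins)]
    samples = [f"A{j + 1}" for j in range(n_per_condition)] + [
        f"B{j + 1}" for j in range(n_per_condition)
    ]
    condition_of = {s: s[0] for s in samples}
    n_samp = len(samples)
    cond_a = np.array([condition_of[s] == "A" for s in samples])

    mu = rng.normal(base_mean, base_sd, n_proteins)
    sigma2 = d0 * s0_sq / rng.chisquare(d0, n_proteins)

    n_diff = int(round(frac_differential * n_proteins))
    diff_idx = rng.choice(n_proteins, size=n_diff, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_diff)
    shift = np.zeros(n_proteins)
    shift[diff_idx] = signs * effect

    log2_vals = (
        mu[:, None]
        + shift[:, None] * cond_a[None, :]
        + rng.standard_normal((n_proteins, n_samp)) * np.sqrt(sigma2)[:, None]
    )

    missing = np.zeros((n_proteins, n_samp), dtype=bool)
    if rate_random > 0:
        missing = rng.random((n_proteins, n_samp)) < rate_random
        # keep every protein testable: at least one observed value per condition
        for cond_mask in (cond_a, ~cond_a):
            cols = np.nonzero(cond_mask)[0]
            all_gone = missing[:, cols].all(axis=1)
            if all_gone.any():
                keep = rng.integers(0, cols.size, size=int(all_gone.sum()))
                missing[np.nonzero(all_gone)[0], cols[keep]] = False

    n_excl = int(round(rate_exclusive * n_proteins))
    candidates = np.setdiff1d(np.arange(n_proteins), diff_idx)
    n_excl = min(n_excl, candidates.size)
    excl_idx = rng.choice(candidates, size=n_excl, replace=False) if n_excl else np.array([], int)
    excl_in_a = rng.random(n_excl) < 0.5  # True: present only in A (missing in B)
    for i, only_a in zip(excl_idx, excl_in_a):
        missing[i, ~cond_a if only_a else cond_a] = True
        missing[i, cond_a if only_a else ~cond_a] = False

    lo, hi = peptides_per_protein
    n_pep = rng.integers(lo, hi + 1, n_proteins)
    rows = []
    for i, prot in enumerate(proteins):
        k = int(n_pep[i])
        weights = rng.dirichlet(np.ones(k))
        uniq = rng.random(k) < 0.8
        uniq[0] = True  # the filter needs >= 1 unique peptide
        linear = np.where(missing[i], np.nan, 2.0 ** log2_vals[i])
        n_observable = k + int(rng.integers(0, 4))
        for j in range(k):
            row = {
                "protein": prot,
                "peptide": f"{prot}_pep{j}",
                "unique": bool(uniq[j]),
                "n_observable": n_observable,
            }
            for s_idx, s in enumerate(samples):
                row[s] = weights[j] * linear[s_idx]
            rows.append(row)
    df = pd.DataFrame(rows)

    truth = TruthRecord(
        generator="gen_proteomics",
        seed=seed,
        parameters={
            "n_proteins": n_proteins,
            "n_per_condition": n_per_condition,
            "effect_log2": effect,
            "d0": d0,
            "s0_sq": s0_sq,
            "missing_rate_random": rate_random,
            "missing_rate_exclusive": rate_exclusive,
            "differential": {proteins[i]: float(shift[i]) for i in diff_idx},
            "exclusive_to_A": sorted(
                proteins[i] for i, only_a in zip(excl_idx, excl_in_a) if only_a
            ),
            "exclusive_to_B": sorted(
                proteins[i] for i, only_a in zip(excl_idx, excl_in_a) if not only_a
            ),
        },
    )
    return PeptideTable(df=df, condition_of=condition_of), truth
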