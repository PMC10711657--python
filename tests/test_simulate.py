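"""Generator contracts: determinism, closed-form construction, truth records."""

import numpy as np
import pandas as pd
import pytest

from tntkit import pattern_qc, simulate
from tntkit.hexgrid import AXIAL_NEIGHBOURS
from tntkit.truth import TruthRecord


def _pattern(seed):
    geom = pattern_qc.PatternGeometry(31.0, 15.0, 1.0)
    img, tr = simulate.gen_pattern_image(geom, (256, 256), noise_sd=3.0, seed=seed)
    return img.pixels, tr


def _tube(seed):
    img, tr = simulate.gen_tube_image(simulate.TubeSimParams(), seed=seed)
    return np.stack([img.membrane, img.actin]), tr


def _trace(seed):
    trace, tr = simulate.gen_force_trace(
        60.0, [(50, 10, 3, 5)], noise_sd=1.0, duration_s=120, rate_hz=20, seed=seed
    )
    return trace.displacement_um, tr


def _lattice(seed):
    lat, tr = simulate.gen_lattice(8, 8, 0.6, 0.3, seed=seed)
    return (tuple(sorted(lat.occupied)), tuple(sorted(map(tuple, map(sorted, lat.edges))))), tr


def _transfer(seed):
    cc, ctrl, flow, tr = simulate.gen_transfer_experiment(500, 0.2, 0.05, seed=seed)
    return (cc.n_positive, ctrl.n_positive, flow.q2), tr


def _proteome(seed):
    pep, tr = simulate.gen_proteomics(n_proteins=40, seed=seed, missing_rates=(0.1, 0.05))
    return pep.df, tr


GENERATORS = {
    "pattern": _pattern,
    "tube": _tube,
    "trace": _trace,
    "lattice": _lattice,
    "transfer": _transfer,
    "proteome": _proteome,
}


@pytest.mark.parametrize("name", sorted(GENERATORS))
def test_same_seed_reproduces_bit_for_bit(name):
    out1, _ = GENERATORS[name](seed=13)
    out2, _ = GENERATORS[name](seed=13)
    if isinstance(out1, np.ndarray):
        assert np.array_equal(out1, out2)
    elif isinstance(out1, pd.DataFrame):
        pd.testing.assert_frame_equal(out1, out2)
    else:
        assert out1 == out2


@pytest.mark.parametrize("name", sorted(GENERATORS))
def test_truth_record_attached_and_serializable(name, tmp_path):
    _, truth = GENERATORS[name](seed=3)
    assert isinstance(truth, TruthRecord)
    assert truth.seed == 3
    path = tmp_path / "x.truth.json"
    truth.to_json(path)
    loaded = TruthRecord.from_json(path)
    assert loaded.generator == truth.generator


TRUTH_KEYS = {
    "pattern": {"spacing_um", "orientation_deg", "centres_um"},
    "tube": {"ell_um", "two_ell_um", "i0", "background", "axis_px"},
    "trace": {"kappa_true_pn_per_um", "peak_times_s", "peak_magnitudes_pn"},
    "lattice": {"edges", "occupied", "p_tnt"},
    "transfer": {"p_contact", "p_secretion", "positives_coculture"},
    "proteome": {"differential", "exclusive_to_A", "exclusive_to_B", "d0", "s0_sq"},
}


@pytest.mark.parametrize("name", sorted(TRUTH_KEYS))
def test_truth_holds_quantities_needed_for_recovery(name):
    _, truth = GENERATORS[name](seed=1)
    assert TRUTH_KEYS[name] <= set(truth.parameters)


# ---------------------------------------------------------------------------
# pattern images


def test_noiseless_pattern_matches_bruteforce_disk_rasterization():
    """Noiseless output equals an independent distance-based reconstruction."""
    geom = pattern_qc.PatternGeometry(31.0, 15.0, 1.0)
    img, truth = simulate.gen_pattern_image(geom, (256, 256), noise_sd=0.0, seed=0)
    centres = np.asarray(truth.parameters["centres_um"], dtype=float)
    fg = truth.parameters["foreground"]
    ny, nx = img.pixels.shape
    xs = (np.arange(nx) + 0.5) * 1.0
    ys = (np.arange(ny) + 0.5) * 1.0
    xx, yy = np.meshgrid(xs, ys)
    expected = np.zeros((ny, nx))
    r = geom.diameter_um / 2.0
    for cx, cy in centres:
        expected[(xx - cx) ** 2 + (yy - cy) ** 2 <= r**2] = fg
    assert np.allclose(img.pixels, expected, rtol=1e-9, atol=0)


def test_noiseless_pattern_is_binary_with_foreground_max():
    geom = pattern_qc.PatternGeometry(31.0, 15.0, 1.0)
    img, _ = simulate.gen_pattern_image(geom, (256, 256), noise_sd=0.0, seed=0)
    assert set(np.unique(img.pixels)) == {0.0, 1000.0}


def test_pattern_canvas_must_hold_three_periods():
    geom = pattern_qc.PatternGeometry(31.0, 15.0, 1.0)  # d = 46 um
    with pytest.raises(ValueError, match="3 lattice periods"):
        simulate.gen_pattern_image(geom, (100, 100), seed=0)


# ---------------------------------------------------------------------------
# tube images


def test_zero_amplitude_tube_actin_is_background(noiseless_tube):
    params = simulate.TubeSimParams(i0=0.0, noise="poisson")
    img, truth = simulate.gen_tube_image(params, seed=21)
    px = params.pixel_size_um
    # sample the tube band well away from the cell edge
    y_c = int(round(img.axis_xy[0, 1]))
    x0 = int(round(img.axis_xy[0, 0] + (3.0 + 2.0) / px))
    x1 = int(round(img.axis_xy[1, 0]))
    band = img.actin[y_c - 2 : y_c + 3, x0:x1]
    bg = img.actin[img.background_mask]
    se = np.sqrt(bg.var() / band.size + bg.var() / bg.size)
    assert abs(band.mean() - bg.mean()) < 3.0 * se


def test_noiseless_tube_decays_to_inverse_e_at_ell(noiseless_tube):
    """Band-averaged actin at X = ell over X = 0 equals 1/e analytically."""
    img, truth, params = noiseless_tube
    px = params.pixel_size_um
    y_c = img.axis_xy[0, 1]
    base_x = truth.parameters["tube_base_px"][0]
    offsets = np.arange(-2 * params.sigma_m_um, 2 * params.sigma_m_um + 1e-9, px / 2)

    def band_mean(x_px):
        rows = np.clip(np.round(y_c + offsets / px).astype(int), 0, img.actin.shape[0] - 1)
        col = int(round(x_px))
        return img.actin[rows, col].mean() - params.background

    eps = 2.0  # just distal to the base, in pixels
    i_start = band_mean(base_x + eps)
    i_ell = band_mean(base_x + eps + params.ell_um / px)
    assert i_ell / i_start == pytest.approx(np.exp(-1.0), abs=1e-3)


def test_tube_rejects_nonpositive_decay_length():
    with pytest.raises(ValueError, match="ell"):
        simulate.TubeSimParams(ell_um=0.0)


# ---------------------------------------------------------------------------
# force traces


def test_empty_schedule_noiseless_trace_is_flat():
    trace, _ = simulate.gen_force_trace(60.0, [], noise_sd=0.0, duration_s=60, seed=0)
    force = trace.kappa_pn_per_um * trace.displacement_um
    assert np.ptp(force) == 0.0


def test_single_peak_height_matches_schedule():
    trace, truth = simulate.gen_force_trace(
        60.0, [(30.0, 10.0, 3.0, 5.0)], noise_sd=0.0, duration_s=60, seed=0
    )
    force = trace.kappa_pn_per_um * trace.displacement_um
    baseline = truth.parameters["baseline_pn"]
    assert force.max() - baseline == pytest.approx(10.0, rel=0.01)


def test_overlapping_peaks_raise_warning_flag():
    _, truth = simulate.gen_force_trace(
        60.0, [(30.0, 10.0, 3.0, 5.0), (34.0, 8.0, 3.0, 5.0)], duration_s=60, seed=0
    )
    assert truth.parameters["overlap_warning"] is True
    _, truth_ok = simulate.gen_force_trace(
        60.0, [(30.0, 10.0, 3.0, 5.0), (50.0, 8.0, 3.0, 5.0)], duration_s=60, seed=0
    )
    assert truth_ok.parameters["overlap_warning"] is False


def test_peak_outside_duration_rejected():
    with pytest.raises(ValueError, match="does not fit"):
        simulate.gen_force_trace(60.0, [(59.0, 10.0, 3.0, 5.0)], duration_s=60, seed=0)


# ---------------------------------------------------------------------------
# lattices


def test_empty_and_saturated_lattices():
    empty, _ = simulate.gen_lattice(4, 4, p_occupied=0.0, p_tnt=1.0, seed=0)
    assert not empty.occupied and not empty.edges
    full, _ = simulate.gen_lattice(2, 2, p_occupied=1.0, p_tnt=1.0, seed=0)
    site_set = set(full.sites)
    expected_pairs = {
        frozenset((s, (s[0] + dq, s[1] + dr)))
        for s in full.sites
        for dq, dr in AXIAL_NEIGHBOURS
        if (s[0] + dq, s[1] + dr) in site_set
    }
    assert full.edges == expected_pairs


def test_edge_frequency_matches_p_tnt():
    """Monte-Carlo: edge rate among occupied neighbour pairs ~ Binomial(p)."""
    p_tnt = 0.3
    n_pairs = 0
    n_edges = 0
    for seed in range(1, 51):
        lat, _ = simulate.gen_lattice(10, 10, 0.7, p_tnt, seed=seed)
        occ = lat.occupied
        for s in lat.sites:
            for dq, dr in AXIAL_NEIGHBOURS[:3]:
                nb = (s[0] + dq, s[1] + dr)
                if nb in occ and s in occ and nb in set(lat.sites):
                    n_pairs += 1
                    if frozenset((s, nb)) in lat.edges:
                        n_edges += 1
    rate = n_edges / n_pairs
    se = np.sqrt(p_tnt * (1 - p_tnt) / n_pairs)
    assert abs(rate - p_tnt) < 3.0 * se


# ---------------------------------------------------------------------------
# transfer


def test_zero_probability_transfer_all_negative():
    cc, ctrl, flow, _ = simulate.gen_transfer_experiment(100, 0.0, 0.0, seed=0)
    assert cc.n_positive == 0 and ctrl.n_positive == 0 and flow.q2 == 0


def test_route_probabilities_must_be_feasible():
    with pytest.raises(ValueError):
        simulate.gen_transfer_experiment(100, 0.7, 0.5, seed=0)


# ---------------------------------------------------------------------------
# proteomics generator


def test_no_exclusive_rate_yields_no_exclusive_truth():
    _, truth = simulate.gen_proteomics(n_proteins=50, seed=5, missing_rates=(0.1, 0.0))
    assert truth.parameters["exclusive_to_A"] == []
    assert truth.parameters["exclusive_to_B"] == []


def test_peptide_sums_reproduce_intended_protein_intensity():
    """Per-protein linear sums across peptides land back on one value."""
    pep, _ = simulate.gen_proteomics(n_proteins=20, seed=8)
    df = pep.df
    sums = df.groupby("protein")[pep.sample_columns].sum(min_count=1)
    # every protein has a strictly positive total in every sample (no missingness)
    assert (sums > 0).all().all()
    # peptide weights are fixed per peptide: ratio to the protein total is
    # identical across samples
    for prot, grp in df.groupby("protein"):
        frac = grp[pep.sample_columns].to_numpy() / sums.loc[prot].to_numpy()
        assert np.allclose(frac, frac[:, :1], rtol=1e-9)
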