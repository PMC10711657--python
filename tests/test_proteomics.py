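"""Peptide filtering, iBAQ, normalization, imputation, moderated testing,
adaptive BH and fold enrichment."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from tntkit import proteomics, simulate
from tntkit.proteomics import IntensityMatrix, PeptideTable

COND = {"A1": "A", "A2": "A", "A3": "A", "B1": "B", "B2": "B", "B3": "B"}


def _table(rows):
    return PeptideTable(df=pd.DataFrame(rows), condition_of=dict(COND))


def _row(protein, peptide, unique, values, n_observable=10):
    row = {"protein": protein, "peptide": peptide, "unique": unique, "n_observable": n_observable}
    row.update(dict(zip(COND, values)))
    return row


# ---------------------------------------------------------------------------
# filtering and quantification


def test_two_peptides_one_unique_retained_without_unique_dropped():
    table = _table(
        [
            _row("kept", "p1", True, [100] * 6),
            _row("kept", "p2", False, [200] * 6),
            _row("dropped", "q1", False, [100] * 6),
            _row("dropped", "q2", False, [100] * 6),
            _row("dropped", "q3", False, [100] * 6),
            _row("single", "r1", True, [100] * 6),
        ]
    )
    matrix = proteomics.protein_filter_quant(table)
    assert list(matrix.data.index) == ["kept"]
    assert np.allclose(matrix.data.loc["kept"], np.log2(300.0))


def test_protein_sums_match_bruteforce_on_random_table():
    rng = np.random.default_rng(3)
    rows = []
    for i in range(30):
        k = int(rng.integers(2, 6))
        for j in range(k):
            vals = np.where(rng.random(6) < 0.2, np.nan, rng.lognormal(10, 1, 6))
            rows.append(_row(f"P{i}", f"P{i}_pep{j}", j == 0, vals))
    table = _table(rows)
    matrix = proteomics.protein_filter_quant(table)
    df = table.df
    for prot in matrix.data.index:
        sub = df[df["protein"] == prot]
        for s in COND:
            vals = sub[s].dropna()
            expected = math.log2(vals.sum()) if len(vals) else np.nan
            got = matrix.data.loc[prot, s]
            assert (np.isnan(expected) and np.isnan(got)) or got == pytest.approx(expected)


def test_ibaq_definition_and_homogeneity():
    table = _table([
        _row("P", "p1", True, [100] * 6),
        _row("P", "p2", False, [200] * 6),
        _row("P", "p3", False, [300] * 6),
    ])
    vals = proteomics.ibaq(table)
    assert np.allclose(vals.loc["P"], 60.0)  # (100+200+300)/10
    doubled = _table([
        _row("P", "p1", True, [200] * 6),
        _row("P", "p2", False, [400] * 6),
        _row("P", "p3", False, [600] * 6),
    ])
    assert np.allclose(proteomics.ibaq(doubled).loc["P"], 120.0)


def test_ibaq_matches_bruteforce_on_random_table():
    rng = np.random.default_rng(9)
    rows = []
    for i in range(20):
        n_obs = int(rng.integers(5, 20))
        for j in range(3):
            rows.append(_row(f"P{i}", f"P{i}_{j}", True, rng.lognormal(8, 1, 6), n_obs))
    table = _table(rows)
    got = proteomics.ibaq(table)
    df = table.df
    for prot in got.index:
        sub = df[df["protein"] == prot]
        for s in COND:
            assert got.loc[prot, s] == pytest.approx(
                sub[s].sum() / sub["n_observable"].iloc[0]
            )


def test_ibaq_requires_positive_observable_count():
    table = _table([_row("P", "p1", True, [100] * 6, n_observable=0),
                    _row("P", "p2", True, [100] * 6, n_observable=0)])
    with pytest.raises(ValueError):
        proteomics.ibaq(table)


# ---------------------------------------------------------------------------
# median centering


def _matrix(values, index=None):
    data = pd.DataFrame(values, columns=list(COND), index=index)
    return IntensityMatrix(data=data, condition_of=dict(COND))


def test_median_center_equalizes_sample_medians_and_is_idempotent():
    rng = np.random.default_rng(0)
    vals = rng.normal(20, 2, size=(40, 6)) + rng.normal(0, 1, size=(1, 6))
    vals[rng.random(vals.shape) < 0.1] = np.nan
    m = _matrix(vals)
    centred = proteomics.median_center(m)
    for cond in ("A", "B"):
        meds = [centred.data[s].median() for s in centred.samples_of(cond)]
        assert np.allclose(meds, meds[0], atol=1e-9)
    twice = proteomics.median_center(centred)
    assert np.allclose(twice.data.to_numpy(), centred.data.to_numpy(), equal_nan=True, atol=1e-12)


def test_median_center_preserves_within_sample_differences():
    rng = np.random.default_rng(1)
    vals = rng.normal(20, 2, size=(30, 6))
    m = _matrix(vals)
    centred = proteomics.median_center(m)
    for s in COND:
        assert np.allclose(np.diff(centred.data[s]), np.diff(m.data[s]), atol=1e-12)


def test_median_center_rejects_empty_sample():
    vals = np.full((5, 6), 20.0)
    vals[:, 0] = np.nan
    with pytest.raises(ValueError):
        proteomics.median_center(_matrix(vals))


# ---------------------------------------------------------------------------
# presence split and imputation


def test_split_presence_examples():
    vals = np.array(
        [
            [20, 21, 20, np.nan, np.nan, np.nan],  # exclusive to A
            [np.nan, np.nan, np.nan, 18, 18, 19],  # exclusive to B
            [20, 21, 20, 18, 18, 19],  # testable
            [20, np.nan, 20, np.nan, 18, 19],  # testable with holes
        ]
    )
    m = _matrix(vals, index=["pa", "pb", "full", "holes"])
    excl_a, excl_b, testable = proteomics.split_presence(m)
    assert excl_a == ["pa"] and excl_b == ["pb"]
    assert list(testable.data.index) == ["full", "holes"]


def test_split_presence_recovers_generator_truth():
    pep, truth = simulate.gen_proteomics(n_proteins=200, seed=4, missing_rates=(0.05, 0.1))
    matrix = proteomics.protein_filter_quant(pep)
    excl_a, excl_b, _ = proteomics.split_presence(matrix)
    assert sorted(excl_a) == truth.parameters["exclusive_to_A"]
    assert sorted(excl_b) == truth.parameters["exclusive_to_B"]


def test_impute_identity_without_missing():
    vals = np.random.default_rng(0).normal(20, 1, size=(10, 6))
    m = _matrix(vals)
    out = proteomics.impute_missing(m, seed=0)
    assert np.array_equal(out.data.to_numpy(), m.data.to_numpy())
    assert not out.imputed.to_numpy().any()


def test_impute_fills_conditional_mean_and_flags():
    vals = np.array([[5.0, 7.0, np.nan, 10.0, 10.0, 10.0]])
    m = _matrix(vals, index=["P"])
    out = proteomics.impute_missing(m, seed=0)
    assert out.data.loc["P", "A3"] == pytest.approx(6.0)
    assert out.imputed.loc["P", "A3"]
    # observed cells untouched
    assert out.data.loc["P", "A1"] == 5.0 and not out.imputed.loc["P", "A1"]


def test_impute_requires_one_observation_per_condition():
    vals = np.array([[5.0, 7.0, 6.0, np.nan, np.nan, np.nan]])
    with pytest.raises(ValueError):
        proteomics.impute_missing(_matrix(vals, index=["P"]), seed=0)


def test_impute_recovers_complete_data_condition_means():
    """10% random dropout, within-protein scatter at the generator's default
    scale (sd ~ 0.3 log2 units): imputed condition means track the
    complete-data means to ~0.1 log2 units on average."""
    rng = np.random.default_rng(8)
    mu = rng.normal(20, 2, size=(1000, 1))
    complete = mu + rng.normal(0, 0.3, size=(1000, 6))
    holes = complete.copy()
    mask = rng.random(holes.shape) < 0.1
    # keep at least one observation per condition
    mask[:, 0] = False
    mask[:, 3] = False
    holes[mask] = np.nan
    out = proteomics.impute_missing(_matrix(holes), seed=0)
    for cols in ([0, 1, 2], [3, 4, 5]):
        got = out.data.iloc[:, cols].mean(axis=1)
        want = complete[:, cols].mean(axis=1)
        assert np.abs(got - want).mean() < 0.1


# ---------------------------------------------------------------------------
# moderated test


def _complete_matrix(n=200, seed=0, effect=0.0, n_diff=0):
    rng = np.random.default_rng(seed)
    vals = rng.normal(20, 0.5, size=(n, 6))
    vals[:n_diff, :3] += effect
    return _matrix(vals, index=[f"P{i}" for i in range(n)])


def test_d0_zero_equals_ordinary_pooled_t():
    m = _complete_matrix(n=50, seed=1)
    res = proteomics.moderated_test(m, d0=0)
    a = m.data[["A1", "A2", "A3"]].to_numpy()
    b = m.data[["B1", "B2", "B3"]].to_numpy()
    t_ref, p_ref = stats.ttest_ind(a, b, axis=1)
    assert np.allclose(res["t"], t_ref, rtol=1e-9)
    assert np.allclose(res["p"], p_ref, rtol=1e-9)


def test_identical_variances_collapse_to_known_variance_test():
    """All proteins sharing one s^2 -> complete shrinkage onto that value
    and normal-reference (infinite-df) p-values."""
    rng = np.random.default_rng(2)
    base = rng.normal(20, 1, size=(30, 1))
    # construct equal within-group scatter for every protein
    pattern = np.array([-1.0, 0.0, 1.0])
    vals = np.hstack([base + pattern, base + 0.5 + pattern])
    m = _matrix(vals, index=[f"P{i}" for i in range(30)])
    res = proteomics.moderated_test(m)
    s2 = res["s2"].to_numpy()
    assert np.allclose(s2, s2[0])
    assert math.isinf(res.attrs["df_total"])
    se = np.sqrt(s2[0] * (2 / 3))
    p_ref = 2 * stats.norm.sf(np.abs(res["log2FC"] / se))
    assert np.allclose(res["p"], p_ref, rtol=1e-9)


def test_null_p_values_are_uniform():
    pep, _ = simulate.gen_proteomics(
        n_proteins=2000, frac_differential=0.0, effect=0.0, seed=5
    )
    matrix = proteomics.median_center(proteomics.protein_filter_quant(pep))
    res = proteomics.moderated_test(matrix)
    ks = stats.kstest(res["p"], "uniform")
    assert ks.pvalue > 0.01


def test_p_monotone_in_absolute_t():
    m = _complete_matrix(n=100, seed=3, effect=1.0, n_diff=30)
    res = proteomics.moderated_test(m)
    order = np.argsort(np.abs(res["t"].to_numpy()))
    assert np.all(np.diff(res["p"].to_numpy()[order]) <= 1e-15)


def test_variance_prior_recovered_from_its_own_model():
    rng = np.random.default_rng(6)
    d0_true, s0_true, df = 5.0, 0.04, 4
    sigma2 = d0_true * s0_true / rng.chisquare(d0_true, 20_000)
    s2 = sigma2 * rng.chisquare(df, 20_000) / df
    d0_hat, s0_hat = proteomics.estimate_variance_prior(s2, df)
    assert d0_hat == pytest.approx(d0_true, rel=0.15)
    assert s0_hat == pytest.approx(s0_true, rel=0.05)


# ---------------------------------------------------------------------------
# adaptive BH


def test_bh_with_pi0_one_matches_statsmodels_exactly():
    rng = np.random.default_rng(7)
    for _ in range(100):
        p = rng.random(rng.integers(5, 200))
        adj, pi0 = proteomics.adjust_adaptive_bh(p, pi0=1.0)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.array_equal(adj, ref)
        assert pi0 == 1.0


def test_all_ones_yield_no_calls():
    adj, _ = proteomics.adjust_adaptive_bh(np.ones(50), pi0=1.0)
    assert np.all(adj == 1.0)


def test_pi0_estimator_near_one_under_uniform_nulls():
    rng = np.random.default_rng(10)
    hits = sum(
        proteomics.estimate_pi0(rng.random(10_000)) >= 0.95 for _ in range(100)
    )
    assert hits >= 95


def test_adaptive_adjustment_scales_by_pi0():
    p = np.array([0.001, 0.01, 0.2, 0.8])
    adj_full, _ = proteomics.adjust_adaptive_bh(p, pi0=1.0)
    adj_half, _ = proteomics.adjust_adaptive_bh(p, pi0=0.5)
    assert np.allclose(adj_half, np.minimum(adj_full * 0.5, 1.0))


# ---------------------------------------------------------------------------
# gates and enrichment


def test_fc_gate_boundary_and_symmetry():
    assert proteomics.fc_gate(math.log2(1.5))
    assert proteomics.fc_gate(-1.0)
    assert not proteomics.fc_gate(0.5)
    assert round(proteomics.LOG2_FC_GATE, 2) == 0.58


def test_fold_enrichment_arithmetic():
    fold, _ = proteomics.fold_enrichment(5, 10, 100, 1000)  # expected = 1
    assert fold == pytest.approx(5.0)
    fold_prop, _ = proteomics.fold_enrichment(2, 10, 200, 1000)  # expected = 2
    assert fold_prop == pytest.approx(1.0)


def test_hypergeometric_tail_matches_bruteforce():
    genome, term, size = 50, 10, 8
    for hits in range(0, size + 1):
        _, p = proteomics.fold_enrichment(hits, size, term, genome)
        brute = sum(
            math.comb(term, k) * math.comb(genome - term, size - k) / math.comb(genome, size)
            for k in range(hits, min(term, size) + 1)
        )
        assert p == pytest.approx(brute, rel=1e-9)


# ---------------------------------------------------------------------------
# full pipeline


def test_pipeline_calls_respect_both_thresholds():
    pep, _ = simulate.gen_proteomics(n_proteins=400, seed=12, missing_rates=(0.05, 0.05))
    res = proteomics.run_differential_pipeline(pep, seed=12)
    called = res.table[res.table["call"] == proteomics.CALL_DIFFERENTIAL]
    assert (called["adj_p"] <= res.fdr).all()
    assert (called["log2FC"].abs() >= math.log2(res.fc_threshold) - 1e-12).all()


def test_pipeline_controls_fdr_with_sensitivity():
    fps = tps = fns = calls = 0
    for seed in range(2):
        pep, truth = simulate.gen_proteomics(n_proteins=1000, seed=seed)
        res = proteomics.run_differential_pipeline(pep, seed=seed)
        diff_truth = set(truth.parameters["differential"])
        called = set(res.differential)
        fps += len(called - diff_truth)
        tps += len(called & diff_truth)
        fns += len(diff_truth - called)
        calls += len(called)
    assert fps / max(calls, 1) <= 0.05
    assert tps / (tps + fns) > 0.5
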