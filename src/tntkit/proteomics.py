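"""Label-free interactome differential-abundance workflow.

Reimplements the study's protein-level statistics for two-condition
affinity-purification proteomics:

1. peptide-level filter (>= 2 peptides per protein, >= 1 unique),
2. protein quantification by summed peptide intensities (+ iBAQ),
3. log2 transform and median centering within conditions,
4. presence/absence partition (proteins all-missing in exactly one
   condition are called qualitatively exclusive and bypass testing),
5. missing-value imputation for testable proteins,
6. moderated two-sample t-test with empirical-Bayes variance shrinkage,
7. adaptive Benjamini-Hochberg adjustment (pi0-sharpened) at FDR 1%,
   combined with the fold-change gate at FC 1.5 (|log2 FC| >= ~0.58),
9. GO fold-enrichment arithmetic (observed / expected, hypergeometric p).

The moderated test follows the classical empirical-Bayes construction: the
per-protein residual variance s^2 (d = nA + nB - 2 df) is shrunk toward a
prior s0^2 with d0 prior df, s~^2 = (d0 s0^2 + d s^2) / (d0 + d), and the
statistic log2FC / (s~ sqrt(1/nA + 1/nB)) is referred to a t distribution
on d0 + d df.  (d0, s0^2) are estimated by moment matching on log
variances using digamma/trigamma identities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

LOG2_FC_GATE = math.log2(1.5)  # printed to two decimals as 0.58
DEFAULT_FDR = 0.01

CALL_DIFFERENTIAL = "differential"
CALL_NOT = "not-differential"
CALL_EXCLUSIVE_A = "exclusive-to-A"
CALL_EXCLUSIVE_B = "exclusive-to-B"
CALL_BELOW_GATE = "below-FC-gate"


@dataclass
class PeptideTable:
    """Peptide-level intensity rows plus the sample -> condition map.

    ``df`` columns: ``protein``, ``peptide``, ``unique`` (bool),
    ``n_observable`` (theoretically observable peptides for the parent
    protein) and one intensity column per sample (linear scale, NaN =
    missing).  ``condition_of`` maps each sample column to its condition
    label.
    """

    df: pd.DataFrame
    condition_of: dict[str, str]

    def __post_init__(self):
        required = {"protein", "peptide", "unique", "n_observable"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"peptide table lacks columns: {sorted(missing)}")
        unknown = set(self.condition_of) - set(self.df.columns)
        if unknown:
            raise ValueError(f"condition map names absent sample columns: {sorted(unknown)}")
        vals = self.df[self.sample_columns].to_numpy(dtype=float)
        if np.any(vals[~np.isnan(vals)] <= 0):
            raise ValueError("peptide intensities must be > 0 where present")

    @property
    def sample_columns(self) -> list[str]:
        return list(self.condition_of.keys())


@dataclass
class IntensityMatrix:
    """Protein x sample log2 intensities with missingness and provenance.

    ``data`` is indexed by protein id with one column per sample; NaN marks
    missing.  ``imputed`` flags cells filled by :func:`impute_missing`
    (all-False before imputation).
    """

    data: pd.DataFrame
    condition_of: dict[str, str]
    imputed: pd.DataFrame = None

    def __post_init__(self):
        if set(self.condition_of) != set(self.data.columns):
            raise ValueError("condition map must cover exactly the sample columns")
        if self.imputed is None:
            self.imputed = pd.DataFrame(
                False, index=self.data.index, columns=self.data.columns
            )
        if not self.imputed.index.equals(self.data.index) or not self.imputed.columns.equals(
            self.data.columns
        ):
            raise ValueError("imputed flags must align with the data")

    @property
    def conditions(self) -> list[str]:
        seen = []
        for c in self.condition_of.values():
            if c not in seen:
                seen.append(c)
        return seen

    def samples_of(self, condition: str) -> list[str]:
        return [s for s, c in self.condition_of.items() if c == condition]

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(self.data.copy(), dict(self.condition_of), self.imputed.copy())


# ---------------------------------------------------------------------------
# quantification


def protein_filter_quant(peptides: PeptideTable) -> IntensityMatrix:
    """Filter proteins and sum peptide intensities to log2 protein values.

    A protein is retained when it has >= 2 distinct observed peptides of
    which >= 1 is unique to it.  Per-sample protein intensity is the sum of
    its present peptide intensities (log2-transformed); samples where every
    peptide is missing stay missing.
    """
    df = peptides.df
    samples = peptides.sample_columns
    rows = {}
    for protein, grp in df.groupby("protein", sort=True):
        observed_any = grp[samples].notna().any(axis=1)
        observed = grp.loc[observed_any]
        n_pep = observed["peptide"].nunique()
        n_unique = observed.loc[observed["unique"].astype(bool), "peptide"].nunique()
        if n_pep < 2 or n_unique < 1:
            continue
        sums = grp[samples].sum(axis=0, min_count=1)
        rows[protein] = np.log2(sums.to_numpy(dtype=float))
    data = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    data.index.name = "protein"
    return IntensityMatrix(data=data, condition_of=dict(peptides.condition_of))


def ibaq(peptides: PeptideTable) -> pd.DataFrame:
    """Per-protein, per-sample iBAQ: summed intensities / observable peptides."""
    df = peptides.df
    samples = peptides.sample_columns
    if (df["n_observable"] <= 0).any():
        raise ValueError("observable peptide counts must be > 0")
    rows = {}
    for protein, grp in df.groupby("protein", sort=True):
        n_obs = float(grp["n_observable"].iloc[0])
        sums = grp[samples].sum(axis=0, min_count=1)
        rows[protein] = sums.to_numpy(dtype=float) / n_obs
    out = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    out.index.name = "protein"
    return out


# ---------------------------------------------------------------------------
# normalization / missingness


def median_center(matrix: IntensityMatrix) -> IntensityMatrix:
    """Median centering within conditions.

    Each sample's observed values are shifted so all sample medians within
    a condition equal that condition's grand median (the median of the
    condition's pooled observed values).  Missing cells are untouched;
    within-sample differences are preserved exactly.  Idempotent.
    """
    out = matrix.copy()
    for cond in matrix.conditions:
        cols = matrix.samples_of(cond)
        pooled = out.data[cols].to_numpy(dtype=float).ravel()
        pooled = pooled[~np.isnan(pooled)]
        if pooled.size == 0:
            raise ValueError(f"condition {cond!r} has no observed values")
        grand = float(np.median(pooled))
        for col in cols:
            vals = out.data[col]
            if vals.notna().sum() == 0:
                raise ValueError(f"sample {col!r} has no observed values")
            out.data[col] = vals + (grand - float(vals.median()))
    return out


def split_presence(matrix: IntensityMatrix):
    """Partition proteins into condition-exclusive sets and a testable rest.

    Proteins with every value missing in exactly one condition, while
    observed in the other, are qualitatively present/absent: they go to the
    corresponding exclusive set and bypass statistical testing.  Proteins
    missing everywhere are dropped from both (nothing can be said about
    them).  Returns ``(exclusive_to_first, exclusive_to_second, testable)``
    where the first two are lists of protein ids ordered as in the matrix
    and ``testable`` is an :class:`IntensityMatrix` restricted to the rest.
    """
    conds = matrix.conditions
    if len(conds) != 2:
        raise ValueError("presence/absence split requires exactly two conditions")
    a_cols = matrix.samples_of(conds[0])
    b_cols = matrix.samples_of(conds[1])
    miss_a = matrix.data[a_cols].isna().all(axis=1)
    miss_b = matrix.data[b_cols].isna().all(axis=1)
    exclusive_a = list(matrix.data.index[~miss_a & miss_b])
    exclusive_b = list(matrix.data.index[miss_a & ~miss_b])
    testable_idx = matrix.data.index[~miss_a & ~miss_b]
    testable = IntensityMatrix(
        data=matrix.data.loc[testable_idx].copy(),
        condition_of=dict(matrix.condition_of),
        imputed=matrix.imputed.loc[testable_idx].copy(),
    )
    return exclusive_a, exclusive_b, testable


def impute_missing(
    matrix: IntensityMatrix,
    seed: int | None = None,
    stochastic: bool = False,
) -> IntensityMatrix:
    """Fill missing cells of testable proteins under a per-condition model.

    Default (deterministic) mode fills each missing cell with the mean of
    the protein's observed values in that condition — the maximum-likelihood
    estimate of a per-protein, per-condition Gaussian mean.  With
    ``stochastic=True`` a seeded Gaussian draw around that mean (sd of the
    observed values, or 0 for a single observation) is used instead.
    Observed cells are never altered; imputed cells are flagged.
    """
    out = matrix.copy()
    rng = np.random.default_rng(seed)
    for cond in matrix.conditions:
        cols = matrix.samples_of(cond)
        block = out.data[cols]
        obs_counts = block.notna().sum(axis=1)
        if (obs_counts == 0).any():
            bad = list(block.index[obs_counts == 0])[:5]
            raise ValueError(
                f"testable proteins with no observed value in condition {cond!r}: {bad}"
            )
        means = block.mean(axis=1)
        sds = block.std(axis=1, ddof=1).fillna(0.0)
        for col in cols:
            missing = block[col].isna()
            if not missing.any():
                continue
            fill = means[missing]
            if stochastic:
                fill = fill + rng.standard_normal(fill.size) * sds[missing]
            out.data.loc[missing, col] = fill
            out.imputed.loc[missing, col] = True
    return out


# ---------------------------------------------------------------------------
# testing


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-matched empirical-Bayes prior (d0, s0^2) from residual variances.

    Matches the mean and variance of z = log(s^2) to the scaled-F model
    implied by inverse-chi-square variances: Var(z) = trigamma(df/2) +
    trigamma(d0/2), E(z) = log(s0^2) + digamma(df/2) - log(df/2)
    - digamma(d0/2) + log(d0/2).  When the observed spread of log variances
    is no larger than the sampling noise, d0 is infinite (complete
    shrinkage) and s0^2 matches the mean alone.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        raise ValueError("need >= 2 positive variances to estimate the prior")
    z = np.log(s2)
    e_z = float(np.mean(z))
    var_z = float(np.var(z, ddof=1))
    half_d = df / 2.0
    if var_z < 1e-12:
        # no spread at all: the common variance is known exactly, so no
        # log-chi-square bias correction applies
        return math.inf, math.exp(e_z)
    excess = var_z - float(special.polygamma(1, half_d))
    mean_shift = float(special.digamma(half_d)) - math.log(half_d)
    if excess <= 0:
        return math.inf, math.exp(e_z - mean_shift)
    half_d0 = _trigamma_inverse(excess)
    d0 = 2.0 * half_d0
    s0_sq = math.exp(
        e_z - mean_shift + float(special.digamma(half_d0)) - math.log(half_d0)
    )
    return d0, s0_sq


def moderated_test(matrix: IntensityMatrix, d0: float | None = None) -> pd.DataFrame:
    """Moderated two-sample t-test per protein on a complete matrix.

    Requires >= 2 samples per condition and no missing values
    (post-imputation).  Returns a DataFrame indexed by protein with columns
    ``log2FC`` (mean A - mean B), ``s2``, ``t`` (moderated), ``p``
    (two-sided), plus the estimated ``d0``/``s0_sq`` as attrs.  Forcing
    ``d0=0`` recovers the ordinary pooled two-sample t-test exactly.
    """
    conds = matrix.conditions
    if len(conds) != 2:
        raise ValueError("moderated test requires exactly two conditions")
    a_cols = matrix.samples_of(conds[0])
    b_cols = matrix.samples_of(conds[1])
    n_a, n_b = len(a_cols), len(b_cols)
    if n_a < 2 or n_b < 2:
        raise ValueError("need >= 2 samples per condition")
    a = matrix.data[a_cols].to_numpy(dtype=float)
    b = matrix.data[b_cols].to_numpy(dtype=float)
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("matrix must be complete (impute first)")

    fc = a.mean(axis=1) - b.mean(axis=1)
    ss = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (b - b.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    df_resid = n_a + n_b - 2
    s2 = ss / df_resid
    if np.all(s2 == 0):
        raise ValueError("all residual variances are zero; degenerate data")

    if d0 is None:
        d0_est, s0_sq = estimate_variance_prior(s2, df_resid)
    elif d0 == 0:
        d0_est, s0_sq = 0.0, float("nan")
    else:
        d0_est = float(d0)
        s0_sq = estimate_variance_prior(s2, df_resid)[1]

    if math.isinf(d0_est):
        s2_mod = np.full_like(s2, s0_sq)
        df_total = math.inf
    elif d0_est == 0:
        s2_mod = s2
        df_total = float(df_resid)
    else:
        s2_mod = (d0_est * s0_sq + df_resid * s2) / (d0_est + df_resid)
        df_total = d0_est + df_resid

    se = np.sqrt(s2_mod * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fc / se
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    out = pd.DataFrame(
        {"log2FC": fc, "s2": s2, "t": t, "p": p}, index=matrix.data.index
    )
    out.attrs["d0"] = d0_est
    out.attrs["s0_sq"] = s0_sq
    out.attrs["df_total"] = df_total
    return out


def estimate_pi0(p: np.ndarray) -> float:
    """Conservative estimate of the true-null proportion: min(1, 2*mean(p))."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    return min(1.0, 2.0 * float(np.mean(p)))


def adjust_adaptive_bh(p, pi0: float | None = None) -> tuple[np.ndarray, float]:
    """Adaptive Benjamini-Hochberg adjustment sharpened by pi0.

    adjusted p_(i) = min over j >= i of pi0 * m * p_(j) / j, capped at 1.
    With pi0 = 1 this is exactly the textbook BH procedure.  Returns the
    adjusted p-values (original order) and the pi0 used.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p)
    if not 0 < pi0 <= 1:
        raise ValueError("pi0 must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ecdf = np.arange(1, m + 1) / m
    ranked = (p[order] * pi0) / ecdf
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj, float(pi0)


def fc_gate(log2_fc: float, fc_threshold: float = 1.5) -> bool:
    """Eligibility for significance: |log2 FC| >= log2(threshold).

    The boundary is inclusive: the study excludes FC strictly below 1.5,
    and its printed 0.58 is the rounded display of log2(1.5).
    """
    if not np.isfinite(log2_fc):
        raise ValueError("log2 fold change must be finite")
    return abs(log2_fc) >= math.log2(fc_threshold)


def fold_enrichment(
    hits: int, list_size: int, term_genes: int, genome_size: int
) -> tuple[float, float]:
    """GO-style fold enrichment (observed / expected) + hypergeometric p.

    expected = list_size * term_genes / genome_size; p is the one-sided
    hypergeometric tail P(X >= hits) (Fisher's exact, enrichment side).
    """
    if not 0 <= hits <= list_size:
        raise ValueError("hits must lie in [0, list size]")
    if not 0 <= term_genes <= genome_size:
        raise ValueError("term genes must lie in [0, genome size]")
    expected = list_size * term_genes / genome_size if genome_size else 0.0
    if expected == 0:
        raise ValueError("expected count is zero; fold enrichment undefined")
    fold = hits / expected
    p = float(stats.hypergeom.sf(hits - 1, genome_size, term_genes, list_size))
    return fold, p


# ---------------------------------------------------------------------------
# full pipeline


@dataclass
class DifferentialResult:
    """Full-pipeline output: per-protein table plus the thresholds used."""

    table: pd.DataFrame
    pi0: float
    d0: float
    s0_sq: float
    fdr: float
    fc_threshold: float

    @property
    def differential(self) -> list:
        return list(self.table.index[self.table["call"] == CALL_DIFFERENTIAL])

    @property
    def exclusive(self) -> list:
        mask = self.table["call"].isin([CALL_EXCLUSIVE_A, CALL_EXCLUSIVE_B])
        return list(self.table.index[mask])


def run_differential_pipeline(
    peptides: PeptideTable,
    fdr: float = DEFAULT_FDR,
    fc_threshold: float = 1.5,
    seed: int | None = None,
    stochastic_imputation: bool = False,
) -> DifferentialResult:
    """Filter -> quantify -> center -> split -> impute -> gate -> test -> BH.

    All testable proteins are tested and BH-adjusted together; the
    fold-change gate then acts as a call-level filter: ``differential``
    requires both adjusted p <= ``fdr`` and |log2 FC| >= log2(fc).
    Adjusting only the gate-passing subset would be anticonservative (null
    proteins that pass the gate by chance carry selectively small
    p-values), so the gate never shrinks the multiple-testing family.
    Condition-exclusive proteins are reported as qualitatively differential
    (exclusive-to-A / exclusive-to-B).
    """
    matrix = protein_filter_quant(peptides)
    matrix = median_center(matrix)
    conds = matrix.conditions
    excl_a, excl_b, testable = split_presence(matrix)
    complete = impute_missing(testable, seed=seed, stochastic=stochastic_imputation)

    stats_all = moderated_test(complete)
    adj, pi0 = adjust_adaptive_bh(stats_all["p"].to_numpy())
    gate_mask = stats_all["log2FC"].abs() >= math.log2(fc_threshold)

    table = stats_all.copy()
    table["adj_p"] = adj
    table["call"] = CALL_BELOW_GATE
    table.loc[gate_mask, "call"] = CALL_NOT
    table.loc[gate_mask & (table["adj_p"] <= fdr), "call"] = CALL_DIFFERENTIAL

    extra = pd.DataFrame(
        {
            "log2FC": np.nan,
            "s2": np.nan,
            "t": np.nan,
            "p": np.nan,
            "adj_p": np.nan,
            "call": [CALL_EXCLUSIVE_A] * len(excl_a) + [CALL_EXCLUSIVE_B] * len(excl_b),
        },
        index=pd.Index(list(excl_a) + list(excl_b), name=table.index.name),
    )
    full = pd.concat([table, extra]).sort_index()
    full.attrs["conditions"] = conds
    return DifferentialResult(
        table=full,
        pi0=pi0,
        d0=stats_all.attrs["d0"],
        s0_sq=stats_all.attrs["s0_sq"],
        fdr=fdr,
        fc_threshold=fc_threshold,
    )
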