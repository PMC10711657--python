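# Methods

`tntkit` implements the quantitative machinery of a tunnelling-nanotube
(TNT) study built around micropatterned neuronal (CAD) cells: how far
F-actin polymerizes inside membrane nanotubes, whether the micropattern
arrays used to control intercellular distance were manufactured correctly,
how often patterned cells become TNT-connected, how much vesicular cargo
they exchange, and how an affinity-purification interactome shifts between
two treatment conditions.  Every stage is exercised on synthetic data with
recorded ground truth, so the statistical behaviour of each estimator is
testable without any raw microscopy or mass-spectrometry data.

## Nanotube actin profiles and the decay length 2ℓ

A membrane nanotube pulled from a cell with an optically trapped bead is
initially devoid of actin; filaments then polymerize in from the cell body.
The F-actin reporter intensity along the tube is modelled as

    I(X) = baseline + (I0 − baseline) · exp(−X / ℓ),

with the origin X = 0 at the position of maximum membrane-channel
intensity within the plasma-membrane rim at the tube base.  The reported
summary is the characteristic decay length **2ℓ**, the distance at which
the intensity above baseline has fallen to 1/e² of its value at the
origin.

The extraction pipeline mirrors standard line-profile practice:

1. **Cross-section width.** The membrane channel perpendicular to the tube
   axis is fit to a Gaussian (amplitude, centre, σ, offset) at several
   axial positions; σ is the median over positions.  Fits with amplitude
   below 3× the residual noise, or σ pinned at the sampling window, are
   rejected; more than half failing raises an error (e.g. no ridge at
   all).
2. **Band averaging.** The actin channel is averaged across a
   perpendicular band of half-width 2σ, sampled by bilinear interpolation
   at 0.5-pixel steps along the axis polyline at pixel-pitch spacing.
   Linear interpolation is used throughout; the original analysis
   interpolated profiles without stating the scheme.
3. **Normalization.** Intensities are background-subtracted using the mean
   of a user-supplied background region and divided by the (equally
   background-subtracted) mean cytosolic signal, removing reporter
   expression differences.  By construction the normalized cytosol mean is
   1.
4. **Origin.** X = 0 is the maximum of the membrane band profile within
   the proximal 25 % of the axis arc length; numerical ties break toward
   the cell body.  The window fraction is a free parameter — the original
   description says only "near the base of the nanotube".
5. **Decay fit.** Nonlinear least squares with ℓ ∈ (0, 10·span],
   baseline ≥ 0.  The additive baseline absorbs residual background in
   real profiles; `pin_baseline_zero` recovers the stricter pure
   exponential.  Non-convergence or ℓ at a bound is flagged, never
   silently returned.
6. **Infiltration category.** The extent of actin infiltration is the
   smallest X at which k = 5 consecutive samples fall at or below
   background + 2× background spread; profiles never meeting the
   criterion are censored at the profile span.  Extents are binned in
   5-µm classes ([0–5) … ≥ 20 µm).  k is configurable; the study states
   no numeric criterion.

## Optical-tweezer force traces

Force follows the harmonic trap relation F = κ·Δx.  κ is calibrated by
the viscous-drag method: at stage velocity v the bead sits at offset
x = γv/κ, so κ is the least-squares slope of γv against x through the
origin.  The drag coefficient uses Faxén's fifth-order correction for a
sphere moving parallel to a wall,

    γ = 6πηr / (1 − (9/16)s + (1/8)s³ − (45/256)s⁴ − (1/16)s⁵),  s = r/h,

in units where Pa·s·µm ≡ pN·s/µm.  The study reports an average stiffness
of 60 pN/µm, which the synthetic sweeps use as the true value.

Traces are presented raw and with a 10-point centred moving average
(edges truncated).  Retraction events — retrograde flow outcompeting tip
polymerization and yanking the bead toward the cell — appear as force
peaks ΔF.  Peaks are prominent local maxima (default prominence 2 pN,
separation 5 s, both configurable; the study states no thresholds).  ΔF is
the apex minus the preceding local baseline.  The baseline *level* is the
median of the smoothed force over the inter-peak segment excluding the
approach window before the apex: the raw segment minimum would be biased
low by the expected extreme of the smoothed noise (≈1 pN at 1 pN noise
over 100-s segments), systematically inflating small ΔF.  On noiseless
traces the two definitions coincide.  The segment trough still marks the
reported onset time.  Peak detection is invariant to adding a constant to
the whole series.

## Micropattern FFT quality control

The adhesive micropatterns are hexagonal arrays of circles (diameter
31 µm; edge gaps D of 15/20/30/40 µm; centre spacing d = diameter + D).
QC compares the azimuthally averaged magnitude of the centred 2-D DFT
against the reciprocal-lattice shells of a hexagonal lattice,
|G_hk| = (2/(√3·d))·√(h² + hk + k²).  The image mean is subtracted
(DC = 0), no window is applied by default, and the radial bin width is one
DFT frequency step of the shorter axis — the finest lossless binning.
Bins extend to the corner of the frequency plane so the binned power sums
to the full spectral power (Parseval).  Peaks are local maxima of the
3-bin-smoothed profile above median + 3×MAD with matching prominence; a
shell passes when its nearest peak lies within the stated bin tolerance.
Because printed guide lines could mark either the true first shell or
simply 1/d, the fidelity report carries both.

## Connectivity statistics on patterned arrays

The lattice is addressed in axial hexagonal coordinates (pointy-top,
6-neighbour adjacency).  The key statistic is

    % TNT-connected = 100 · |sites incident to ≥ 1 TNT edge| / |eligible sites|,

where eligible sites are occupied patterns with at least one occupied
nearest neighbour — isolated occupied patterns cannot possibly be
TNT-connected across patterns and are excluded from the denominator.  One
cell per pattern is assumed (the single-cell patterning design), so
"connected pattern" and "connected cell" coincide; a pattern connected by
two TNTs counts once.  An empty denominator is an error, not 0 %.  TNT
identification itself (thin < 800 nm, membranous and F-actin positive,
substrate-detached, continuous) is an upstream annotation; this module
consumes the resulting edge table.

Trajectory analysis scores inter-pattern translocations: a cell counts as
translocated when its track leaves the home circle and then dwells inside
a neighbouring pattern circle for ≥ 2 consecutive samples (configurable; no
numeric rule is stated in the source analysis).  TNT lifetimes observed
under a 300-min cap are summarized by the median with censored records
held at the cap — valid while the censored fraction is below 50 %, and
flagged unreliable otherwise.  A Kaplan–Meier treatment is deliberately
out of scope.

## Transfer assays

Total transfer is the percentage of acceptor cells containing
donor-derived labelled vesicles.  Contact-mediated transfer subtracts the
conditioned-medium (secretion-only) control percentage; negative values
are flagged rather than clamped so the clamping bias is never silently
introduced.  Relative transfer normalizes a treatment to its control
(control = 100 %); the default averages per-replicate ratios (matching
per-experiment mean ± SEM reporting), with a pooled-ratio option, because
the two estimators genuinely differ on unequal replicates.  Flow-cytometry
transfer is Q2/Q1 (double-positive over acceptor-gate events) and agrees
exactly with the imaging percentage on identical counts.

## Proteomics differential abundance

Two-condition label-free workflow: proteins need ≥ 2 observed peptides
including ≥ 1 unique; per-sample protein intensity is the sum of present
peptide intensities, log2-transformed; iBAQ divides the summed intensity
by the count of theoretically observable peptides.  Samples are median-
centred within conditions (all sample medians set to the condition's
pooled median).  Proteins observed in exactly one condition are
*qualitatively* present/absent — they bypass testing and are reported as
exclusive.  Remaining missing values are imputed per protein and condition
with the Gaussian maximum-likelihood estimate (the condition mean of
observed values), deterministically by default with a seeded stochastic
option.  This is a deliberate, documented simplification of
likelihood-based imputation tools whose internal missingness model is not
described in the source narrative; the synthetic generator therefore also
uses ignorable (random or condition-exclusive) missingness, not
left-censoring.

The moderated t-test shrinks each protein's residual variance s² (d =
nA + nB − 2 df) toward a prior: s̃² = (d0·s0² + d·s²)/(d0 + d), with the
statistic log2FC / (s̃·√(1/nA + 1/nB)) referred to t with d0 + d df.
(d0, s0²) are estimated by moment matching on z = log s²:
Var(z) = ψ′(d/2) + ψ′(d0/2) and E(z) = log s0² + ψ(d/2) − log(d/2)
− ψ(d0/2) + log(d0/2), inverting the trigamma by Newton iteration.  When
the spread of log variances does not exceed its sampling noise the prior
df is infinite (complete shrinkage, normal reference); forcing d0 = 0
recovers the ordinary pooled t-test exactly.  The estimator is pluggable.

Multiple testing uses adaptive Benjamini–Hochberg: adjusted
p_(i) = min_{j≥i} π0·p_(j)/(j/m), with the conservative default
π0̂ = min(1, 2·mean(p)); π0 = 1 reproduces textbook BH bit-for-bit, and
π0 is always reported and overridable (the robust estimator referenced by
the original workflow is not reproduced here).

**Where the gate sits.** A protein is called differential only when both
adjusted p ≤ 0.01 *and* |log2 FC| ≥ log2(1.5) ≈ 0.58 (boundary
inclusive; 0.58 is the rounded display of log2 1.5).  The test and the BH
adjustment run over *all* testable proteins, with the fold-change gate
applied afterwards as a call-level filter.  Restricting the multiple-
testing family to gate-passing proteins would be anticonservative: null
proteins that cross the gate by chance do so precisely when their noise is
large relative to their variance estimate, so their p-values are
selectively small, and simulations under this package's calibration
conditions showed the gate-then-test order inflating the empirical FDR to
tens of percent at a 1 % target.  With the family kept whole, the
simulated pipeline holds empirical FDR around 1 % with sensitivity near
90 % (3 vs 3, 2 000 proteins, 10 % true effects of 2 log2 units).

GO fold enrichment is the plain observed/expected ratio with expected =
list size × term size / genome size, and a one-sided hypergeometric tail
p-value.

## Synthetic data: what it emulates, and what it does not

Each generator draws from a single seeded `numpy` Generator and attaches a
`TruthRecord` (JSON sidecar) holding every quantity the recovery tests
need; identical seed and parameters reproduce outputs bit-for-bit.

* **Pattern images**: filled circles at hexagonal sites, optional rotation,
  additive Gaussian noise.  No printing defects, edge blur, or intensity
  gradients.
* **Tube images**: a rectangular cell body, a bright membrane rim at the
  cell edge (whose maximum defines X = 0), a straight axis-aligned tube
  ridge of Gaussian cross-section σ_m = 0.4 µm, and an actin channel whose
  band-averaged tube intensity is exactly I0·exp(−X/ℓ) above background
  (the parameter I0 is defined in band-average terms so normalized
  profiles start near I0/cytosol).  A 0.2-µm Gaussian blur stands in for
  the PSF — the imaging optics are not specified in the source, and only
  the relative profile shape matters; Poisson noise on expected counts
  reflects photon-counting detection, with Gaussian and noise-free options
  for closed-form checks.  Default plateau 50 counts over a background of
  2 with a cytosol at 50 counts gives signal-to-noise comparable to a
  bright live-cell reporter.  Curved tubes are supported by the extractor
  (arbitrary polylines) but not generated by default.
* **Force traces**: baseline force plus triangular rise/relax peaks at
  scheduled apex times, Gaussian force noise, divided by κ to give bead
  displacement at 20 Hz.  No trap anharmonicity, drift, or bead-tracking
  noise model; overlapping scheduled peaks are flagged in the truth
  record.
* **Lattices**: independent Bernoulli occupancy and independent TNT edges
  between occupied neighbours — no spatial correlation of occupancy or
  distance-dependent edge probability.
* **Transfer**: binomial outcomes with additive contact and secretion
  routes acting on disjoint cells; flow counts mirror the co-culture table
  exactly.
* **Proteomics**: per-protein log2 means N(25, 2²), variances from a
  scaled inverse-χ² prior (d0 = 4, s0² = 0.09, i.e. within-group sd
  ≈ 0.3 log2 units — typical label-free replicate scatter), a
  differential subset shifted ± effect in one condition, fixed per-peptide
  intensity fractions so protein sums reproduce the intended values, and
  (random, condition-exclusive) missingness.  Random dropout always
  leaves ≥ 1 observed value per condition so the testable set satisfies
  the imputation precondition.  No peptide-level ionization effects,
  shared peptides, or intensity-dependent (left-censored) missingness —
  so passing tests demonstrate calibration of the statistics under the
  stated model, not robustness to MNAR missingness.

## Numerical choices and degenerate inputs

* Gaussian and exponential fits use `scipy.optimize.curve_fit` with
  explicit bounds and data-driven initial values; degenerate fits (flat
  membrane, ℓ at a bound, zero variance everywhere) raise or flag rather
  than returning silently.
* The moving average truncates at the edges (no padding); window 1 is the
  identity.
* Exact ties for the profile origin are resolved within a 1e-9 relative
  tolerance toward the cell body, so floating-point jitter in polyline
  interpolation cannot flip the documented tie-break.
* `percent_tnt_connected` with an empty denominator raises; a median of
  durations with ≥ 50 % censoring is flagged unreliable.
* Trigamma inversion uses Newton iteration from x ≈ 0.5 + 1/y with a
  closed-form fallback for extreme arguments.

## Problem sizes used in validation

The packaged validation (`scripts/acceptance.py` and the test suite) runs
at deliberately desk-scale sizes chosen to keep Monte-Carlo error well
below the tolerances being checked: 20 tubes per decay length ℓ ∈ {1, 3,
6} µm; one 512² D15 pattern image; 50 force traces of 300 s at 20 Hz; the
full 186 462-configuration enumeration of the 9-site lattice block; 200
simulated co-cultures of 10⁴ acceptors; and 10 proteomes of 2 000
proteins (plus one 5 000-protein null).  The study's headline measured
values (e.g. decay lengths 2.78 vs 5.80 µm, median connectivity 9.8 %,
relative transfer 124.5 %) derive from raw data not available at desk
scale; validation is therefore property-based — recovery of known ground
truth, oracle agreement, and error calibration — rather than numerical
reproduction of those measurements.

## Known limitations

* Automatic tube segmentation, kymographs, deconvolution and 3-D profiles
  are out of scope; the tube axis and reference regions are inputs.
* Bead tracking from video is out of scope; traces begin at displacement
  series.
* The imputation model is ignorable-missingness ML, not a left-censoring
  model; condition-exclusive proteins are handled by the presence/absence
  partition instead.
* Duration summaries use cap-censored medians, not survival estimators.
* The π0 estimator is deliberately conservative; a smoother-based or
  "robust" estimator can be supplied via the `pi0` argument.
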