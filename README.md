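# tntkit

Analysis toolkit for quantitative tunnelling-nanotube (TNT) experiments.

TNTs are thin, substrate-detached, F-actin-containing membrane protrusions
that directly connect distant cells and transfer cargo — reaching tens of
microns, far beyond typical filopodia.  Studying how they form involves a
characteristic mix of measurements: micropatterned cell arrays to control
intercellular distance, optical tweezers to pull membrane nanotubes and
watch actin polymerize into them, co-culture assays to score vesicle
transfer, and affinity-purification proteomics to track the actin
machinery involved.  `tntkit` implements the quantitative analysis for
each of these, plus synthetic-data generators with recorded ground truth
so every estimator can be validated end to end:

* **`tntkit.pattern_qc`** — FFT radial profiles of micropattern images and
  their match to the expected hexagonal reciprocal-lattice shells
  (circles of diameter 31 µm at centre spacing d = diameter + gap).
* **`tntkit.tube_profile`** — Gaussian cross-section fitting, band-averaged
  and cytosol-normalized actin profiles along pulled nanotubes, the
  exponential decay length **2ℓ** (distance at which the origin intensity
  falls to 1/e²), and actin-infiltration categories.
* **`tntkit.force_trace`** — trap-stiffness calibration by the viscous-drag
  method with Faxén's wall correction, F = κ·Δx conversion, 10-point
  moving-average presentation, and ΔF retraction-peak extraction.
* **`tntkit.connectivity`** — the percentage of TNT-connected micropatterns
  (excluding isolated occupied patterns from the denominator),
  inter-pattern translocation counting, and cap-censored TNT-duration
  summaries.
* **`tntkit.transfer_assay`** — total, secretion-corrected and relative
  vesicle-transfer percentages; flow-cytometry Q2/Q1 transfer.
* **`tntkit.proteomics`** — label-free differential abundance: peptide
  filtering, iBAQ, median centering within conditions, presence/absence
  partition, imputation, a moderated t-test with empirical-Bayes variance
  shrinkage, adaptive Benjamini–Hochberg FDR control with a 1.5-fold-change
  gate (|log2 FC| ≥ 0.58), and GO fold-enrichment arithmetic.
* **`tntkit.simulate`** — generators for all of the above with
  `TruthRecord` JSON sidecars; identical seeds reproduce outputs
  bit-for-bit.

## Worked example: recovering a decay length

Simulate a two-channel nanotube image whose actin decays with ℓ = 3 µm
(so 2ℓ = 6 µm) under Poisson noise, then run the full profile pipeline:

```python
import numpy as np
from tntkit import simulate, tube_profile

params = simulate.TubeSimParams(ell_um=3.0, tube_length_um=15.0,
                                i0=50.0, noise="poisson")
image, truth = simulate.gen_tube_image(params, seed=42)

xfit = tube_profile.fit_cross_section(image, np.linspace(6.0, 13.0, 5))
profile = tube_profile.extract_actin_profile(image, xfit)
fit = tube_profile.fit_decay(profile)
infil = tube_profile.infiltration_extent(profile)

print(f"sigma = {xfit.sigma_um:.3f} um  (band half-width 2*sigma = {xfit.half_width_um:.3f} um)")
print(f"I0 = {fit.i0:.3f} (cytosol units), 2l = {fit.two_ell_um:.3f} um (true 6.000), baseline = {fit.baseline:.4f}")
print(f"infiltration extent = {infil.extent_um:.1f} um, category {infil.category}, censored={infil.censored}")
```

prints

```
sigma = 0.431 um  (band half-width 2*sigma = 0.863 um)
I0 = 0.925 (cytosol units), 2l = 5.729 um (true 6.000), baseline = 0.0043
infiltration extent = 8.2 um, category [5-10), censored=False
```

The membrane ridge width σ is recovered near the simulated 0.4 µm, and the
fitted decay length 2ℓ lands within ~5 % of the true 6 µm for this single
noisy tube; the normalized intensity at the tube base (0.93) sits near
I0/cytosol = 1 by construction.  The infiltration category is the 5-µm bin
in which the profile becomes indistinguishable from background.

The same workflows are available from the shell, e.g.:

```bash
tntkit simulate tube --ell 3 --seed 42 --out tube.tif
tntkit analyze tube tube.tif
tntkit simulate pattern --separation 15 --out pattern.tif
tntkit qc pattern pattern.tif --tol 1
```

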