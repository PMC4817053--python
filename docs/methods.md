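# Methods

This note records the models behind each analysis stage, the parameters
that matter (with units and defaults), what the synthetic-data generators
do and do not emulate, and the numerical choices made where the design was
genuinely open.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Peptide chemistry

Masses are sums over elemental composition: residue formulas for the 20
amino acids, water, terminal-group deltas (succinyl +C₄H₄O₃; *p*-nitroanilide
+C₆H₄N₂O, i.e. condensation with *p*-nitroaniline minus water) and
modification deltas (phospho +HPO₃ 79.96633 Da, mono/di/tri-oxidation
+15.99491/+31.98983/+47.98474 Da, carbamidomethyl +57.02146 Da).
Monoisotopic atomic masses are IUPAC values to ≥5 decimals; average masses
use the conventional standard atomic weights.  Charging uses the proton
mass (1.007276 Da); adduct m/z is (M + n·(m_cation − m_e))/n so that Na/K
adducts are electron-correct to <1 mDa.  Heavy-isotope peaks use a fixed
A+k spacing of k·1.00336/z (¹³C-dominant approximation); full isotopic fine
structure and envelope abundances (averagine) are out of scope because the
quantitation only targets the monoisotopic and A+1 positions.

Fragmentation covers singly charged b/y ions; a neutral-loss companion is
emitted only when the fragment actually contains the required group
(an oxidized Met for CH₄SO; a phospho residue for HPO₃/H₃PO₄/H₃PO₄+H₂O).
Tryptic digestion cleaves after K/R except before P — the standard
convention — with 0..N missed cleavages and 1-based span annotation.

A residue carries at most one oxidation-state label; modification targets
are validated against the table (phospho on H/S/T/Y, mono/di-oxidation on
M/C/Y/W, tri-oxidation on C).

## Spectral container and formats

`SpectralDataset` holds centroid scans with strictly increasing times in
minutes and serves both chromatographic runs and infusion time courses.
The native format is a long-form CSV (`scan_time_min, mz, intensity`);
mzML is read through pyteomics.  Ensembles round-trip through multi-model
PDB (biotite) at PDB coordinate precision (0.001 Å).

## Synthetic data generators

All generators take a seed and are bit-reproducible; every dataset comes
with a ground-truth table sufficient to predict each downstream statistic.

**LC-MS runs.**  Each ion species contributes a Gaussian elution profile
(amplitude normalized so its time integral equals the configured
abundance) at its monoisotopic and A+1 m/z (A+1 at 0.4 relative
intensity — a typical value for ~700–800 Da peptides; the exact value
cancels in all ratios).  Per-centroid m/z jitter is N(0, 1.5 ppm) against
the 5-ppm extraction tolerance; intensity noise is multiplicative Gaussian
(CV 5 %) with an additive noise floor and sparse background centroids.
Shot-noise (Poisson) statistics and co-elution artifacts are not modelled:
AUC-ratio statistics only need the second moments to be realistic.
Replicate-level biology enters as a 2 % CV on the injected oxidation odds,
and the realized per-replicate odds are recorded as truth.  Defaults
(3 replicates, 20-min run, 1-s scans, σ = 0.1 min peaks, control odds
0.01, dose odds 0.09/0.26/0.41) make the default scenario a desk-scale
facsimile of a three-dose peroxide titration with 9/26/41-fold effects.
The control oxidation level is a free parameter because only fold changes,
not absolute control stoichiometries, are constrained.

**Infusion time courses.**  Dephosphorylation is pseudo-first-order — the
substrate (2.4 mM) vastly exceeds the enzyme (0.37 µM) — so the phospho
fraction decays as f(t) = f₀·e^(−kt) with f₀ = 0.375 by default (the
midpoint of the 35–40 % phosphorylation yield of the chemical synthesis).
Each scan holds the six assay peaks with adduct pools H/Na/K =
0.60/0.25/0.15 (protonated form dominant under acidic ESI, as in the
reference spectra where the H⁺ peak is the base peak).  Total ion current
is conserved: conversion moves intensity from the phospho to the
non-phospho family, never destroys it.  An optional source-loss fraction
transfers phospho intensity to the non-phospho peaks in every scan
(ESI-source phosphate loss), and optional per-adduct rate multipliers
model slower conversion of the Na/K pools.  Scan timestamps are reaction
times; for real instrument data the ~1-min infusion dead time can be added
via the `dead_time_min` argument of the analysis functions.

**Conformational ensembles.**  Residues are isotropic Gaussian clouds
(default σ = 0.5 Å, a typical well-ordered-residue RMSF) around a
reference CA trace (random 3.8 Å-step walk unless supplied); the second
ensemble's means are displaced by a configurable per-residue 3-vector.
Frames are independent draws — the generator reproduces conformational
*densities*, not dynamics, autocorrelation, or anharmonic/multi-basin
behavior, so passing tests validate the density-comparison machinery, not
force-field realism.

**Progress curves.**  Substrate depletes under ds/dt = −V_max·s/(K_m+s)
(RK4, 50 sub-steps per sampling interval); absorbance is ε·ℓ·product with
Gaussian noise (SD 0.005 AU).  Defaults K_m = 7 mM (control) with a
1.4-fold-lower treated value of 5 mM, V_max = 0.02 mM/min (k_cat ≈ 9.5
min⁻¹ at 2.1 µM enzyme), substrate 0.8–40 mM at five levels, 2 h at 3-min
sampling — values chosen so the curves are measurably curved yet far from
exhausted within the assay window.

## Oxidation quantitation

XICs sum all centroids within ±tolerance (ppm) of any target per scan.
Peak windows default to apex ± extension until intensity decays below 1 %
of apex — manual integration in a vendor browser is not reproducible, so a
rule is required; the window and tolerance are logged in results.  AUC is
trapezoidal.  Undefined ratios (zero non-oxidized AUC) become NaN with a
warning and are excluded from group means rather than imputed — exclusion
is conservative and keeps group means interpretable.  The *t*-test is the
homoscedastic two-tailed two-sample test; two zero-variance groups with
equal means give p = 1, with different means p = 0 (flagged as below
machine epsilon).  `global_oxidation_ratio` and `normalize_modbase`
implement the run-level summaries: summed oxidized over summed
non-oxidized intensity, and per-site mod/base values scaled so the largest
site is 1.0.  mod/base is taken as (summed modified intensity)/(summed
unmodified intensity) per site — the plain reading of the term.

## Activity analysis

Windows are left-closed right-open ([0,5), [5,10), …); window spectra are
per-scan mean intensities after greedy centroid merging within the match
tolerance (±0.3 m/z by default — unit-resolution infusion spectra, distinct
from the 5-ppm LC tolerance; both configurable).  The control reference is
the mean over all control windows.

Fold changes are computed on the phosphorylation-level scale
f = r/(1+r) rather than on the raw ratio r.  Reason: with first-order
conversion and conserved total ion current the *fraction* declines exactly
as e^(−kt), while the raw ratio declines faster (its denominator grows as
product accumulates — at f₀ = 0.375 a true 100-fold conversion would read
as 159-fold on the ratio scale).  The fraction scale therefore reports the
actual conversion factor of the phosphopeptide pool; `scale="ratio"`
provides the raw-ratio alternative.  −log₁₀(fold) is reported per window,
so a 100-fold decrease reads as 2.

## Ensemble discriminability

η is defined operationally: after superposing both ensembles onto the same
reference (Kabsch SVD rotation, determinant-corrected against
reflections), each residue's flattened coordinates feed a regularized
linear discriminant (LDA with Ledoit-Wolf shrinkage), and η is its
balanced accuracy under repeated stratified k-fold cross-validation
(5 folds × 10 repeats by default, seeded; dips below 0.5 from fold noise
are clipped to chance).  This satisfies the properties a
density-difference statistic needs — bounded in [0.5, 1], chance level for
identical distributions, monotone in ensemble separation — and makes the
0.69 flag threshold a meaningful point between chance and full separation.
It is a reimplementation choice, not a transcription of any particular
density-overlap formula, and 0.69 is configurable, not derived: for two
isotropic Gaussian clouds of width σ, the Bayes accuracy at mean
separation d is Φ(d/2σ), so 0.69 corresponds to d ≈ 1 Å at σ = 0.5 Å.

Two caveats the test geometry reflects: (i) whole-molecule rigid fitting
absorbs part of a *localized* mean shift, attenuating the shifted
residue's apparent CoM deviation (~15 % for 1 shifted residue of 24) and
leaking ~shift/n_residues into the others — with study-like dilution
(an 11-residue loop of 125) the leak is negligible; (ii) η at fixed
separation depends on cloud width, so the 0.69 ↔ 1 Å correspondence is
specific to σ ≈ 0.5 Å clouds.

Frame extraction takes every k-th trajectory frame with both endpoints
inclusive: a contiguous 150-ns span at 50 ps yields 3001 frames.

## Kinetics

Path length ℓ = V/(πr²) in consistent units (0.1989 cm default).
Negative absorbances clip to zero with a warning.

Initial velocities: "the most linear portion" needs an operational rule.
The default anchors the window at the curve start, grows it while linear
R² improves, and reports the *tangent at the window start* from a
quadratic fit over the chosen window.  The quadratic tangent matters:
even inside a visually linear early window the slope decays by
~½·k·Δt (substrate depletion), and a plain window slope underestimates v₀
at low S — enough to bias K_m upward by >10 % under the default noise
level, because noise lets long or mid-curve windows win the R² contest.
The unanchored max-R²-window slope remains available as
`method="window"` for comparison with that convention.  Both methods are
invariant to constant absorbance offsets (blank subtraction), and the
chosen window and R² are reported.

The MM fit is unweighted nonlinear least squares via `scipy.curve_fit`
with data-driven start values; 95 % CIs come from the linearized
covariance with a *t* critical value (the convention of the commercial
packages this replaces).  k_cat = V_max/[E] with [E] in µM (default 2.1).
Saturating data (flat v over S ≫ K_m) yields V_max ≈ v with a small K_m
whose CI is wider than the estimate — flagged by warning rather than
refused.  Fold comparisons report both orientations with CI-overlap flags
and fold CIs from relative errors combined in quadrature (delta method).
Substrate depletion is deliberately *modelled in the generator* but
*ignored in the estimator*, so the round-trip tests exercise the
estimator against realistic curvature.

## Scenario scale and determinism

The default scenarios use the full study geometry (3 replicates, 30-min
infusion, 125 residues × 3001 frames); unit tests run reduced sizes
(hundreds of frames, short runs) chosen so the whole suite completes in
about a minute while Monte-Carlo tolerances (3 SE bands, ±0.02 on η)
remain meaningful.  Every stochastic path is seeded; scenario reports
embed the seed, a config hash and the package version, and rerunning a
scenario with the same seed reproduces the report byte for byte.

## Known limitations

- No peptide-spectrum matching, FDR or localization scoring: peptide
  identity is an input, as in any targeted re-quantitation.
- Isotope envelopes are two-peak approximations; charge states are not
  deconvolved (multiple charge states may be summed as extra targets).
- The ensemble generator cannot validate claims about real MD ensembles
  (correlated frames, anisotropic/multimodal densities); η itself applies
  unchanged to such data when read from multi-model PDB.
- CIs on MM parameters are linearized; strongly non-quadratic likelihoods
  (poorly constrained K_m) deserve profile likelihoods, which are not
  implemented.
- The infusion analysis assumes equal ionization efficiency of the
  phospho and non-phospho forms when interpreting f as a mole fraction;
  a differing response factor rescales f without changing fold-change
  linearity.
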