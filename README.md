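# proteox

Quantitative mass-spectrometry and modelling toolkit for studying how
reactive-oxygen stress affects a small phosphohistidine phosphatase — a
125-residue enzyme whose peptide substrate, succinyl-Ala-His-Pro-Phe-
*p*-nitroanilide (Suc-AHPF-pNA), carries an acid-labile phospho group on
histidine.  The package is aimed at proteomics and enzymology groups who
need the four analyses below as reproducible, tested code rather than
vendor-browser clicks, and at method developers who want seeded synthetic
data with exact ground truth for every stage.

## What it computes

**Peptide chemistry** (`proteox.chem`) — monoisotopic/average masses from
elemental composition, H⁺/Na⁺/K⁺ adduct m/z with proper proton/electron
accounting, A+1 isotope positions, b/y fragment ions with the diagnostic
neutral losses (−64 Da CH₄SO from methionine sulfoxide; −80/−98/−116 Da
phosphate series from phosphohistidine), and tryptic digestion
(cleave after K/R, suppressed before P).

**Oxidation stoichiometry** (`proteox.oxquant`) — extracted-ion
chromatograms at ppm tolerance (default 5 ppm, monoisotopic + A+1 targets),
trapezoidal peak areas, and the per-site statistic

&nbsp;&nbsp;&nbsp;&nbsp;ratio = AUC(oxidized) / AUC(non-oxidized),

averaged over replicates per treatment group, with fold changes versus
control and a two-tailed homoscedastic two-sample *t*-test.

**Phosphatase activity by direct infusion** (`proteox.activity`) — 5-min
spectral averaging, the adduct-summed ratio r = Σ(phospho peaks)/Σ(non-
phospho peaks) over the six assay peaks (m/z 691/713/729 and 771/793/809),
and per-window fold changes of the phosphorylation level f = r/(1+r)
against an untreated control, reported as −log₁₀(fold change).

**Conformational discriminability** (`proteox.ensembles`) — Kabsch
least-squares superposition of every frame onto a reference structure,
then per-residue η: the cross-validated balanced accuracy of a linear
discriminant labelling frames by ensemble from that residue's coordinates
(η = 0.5 chance … 1 fully separated; default flag threshold 0.69 ≈ 1 Å
center-of-mass deviation for 0.5 Å clouds).

**Michaelis–Menten kinetics** (`proteox.kinetics`) — Beer–Lambert
conversion of A405 with the path length from well geometry
(ℓ = V/πr², 0.199 cm for 100 µl at r = 4 mm; ε = 17.8 mM⁻¹cm⁻¹), initial
velocities from the most linear early portion of each progress curve, and
nonlinear least-squares fits of v = V_max·S/(K_m+S) with 95 % CIs and
k_cat = V_max/[E].

**Synthetic data** (`proteox.synth`) generates every input with recorded
ground truth; `proteox.workflow` runs three end-to-end scenarios and writes
seed-reproducible JSON/CSV reports.

## Worked example

```bash
python examples/oxidation_quantitation.py
```

```
group     truth fold   recovered   rel.err   p-value
100uM          9.08        9.20     1.2%   7.78e-09
500uM         26.07       25.89     0.7%   4.39e-08
1mM           40.78       40.99     0.5%   5.77e-08
```

Three replicate LC-MS runs per group are simulated with oxidized:
non-oxidized abundance odds 9×, 26× and 41× the control level; the XIC
pipeline recovers each injected fold change within ~1 % and flags all dose
groups as significant versus control.  The other example scripts
(`peptide_masses.py`, `infusion_activity.py`, `ensemble_discriminability.py`,
`michaelis_menten.py`) exercise the remaining stages the same way; for
instance `infusion_activity.py` prints the −log₁₀(fold change) staircase of
a first-order dephosphorylation (k = ln 100/10 min⁻¹) whose instantaneous
value at t = 10 min is exactly 2, i.e. a 100-fold conversion.

## Layout

```
src/proteox/      chem, spectra, synth, oxquant, activity, ensembles,
                  kinetics, workflow
examples/         one narrative script per capability
tests/            unit, property and acceptance suites (pytest + hypothesis)
docs/methods.md   models, assumptions, parameter choices, limitations
```
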