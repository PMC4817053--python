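"""Masses, adduct m/z and diagnostic fragments of the assay substrate.

The phosphohistidine phosphatase substrate is succinyl-Ala-His-Pro-Phe-
p-nitroanilide ("Suc-AHPF-pNA"); its phospho form carries HPO3 on His.
"""

from proteox.chem import (
    adduct_mz,
    apply_modification,
    average_mass,
    fragment_ions,
    monoisotopic_mass,
    parse_peptide,
    precursor_loss_mz,
    tryptic_digest,
)

substrate = parse_peptide("Suc-AHPF-pNA")
phospho = apply_modification(substrate, "phospho", 2)

print(f"substrate average MW      : {average_mass(substrate):8.1f} Da (vendor-grade MW)")
print(f"substrate monoisotopic    : {monoisotopic_mass(substrate):8.4f} Da")
for name, pep in (("non-phospho", substrate), ("phospho", phospho)):
    mzs = ", ".join(f"[M+{a}]+ {adduct_mz(pep, a, 1):7.2f}" for a in ("H", "Na", "K"))
    print(f"{name:12s} adducts      : {mzs}")
print("-> the six infusion-assay peaks at nominal m/z 691/713/729 and 771/793/809")

losses = precursor_loss_mz(phospho)
print("\nphosphohistidine precursor neutral losses (acid-labile P-N bond):")
for label, mz in losses:
    print(f"  {label:12s} m/z {mz:7.2f}")

oxpep = parse_peptide("VYEAGM(ox)K")
ions = dict(fragment_ions(oxpep, losses=["CH4SO"]))
print(f"\nmethionine-sulfoxide peptide VYEAGM(ox)K: y2 {ions['y2']:.2f}, "
      f"y2-CH4SO {ions['y2-CH4SO']:.2f} (the diagnostic -64 Da loss)")

print("\ntryptic digest of a toy protein (cleave after K/R, not before P):")
for p in tryptic_digest("MAKRGPCWKPR", max_missed=1):
    print(f"  {p.sequence:8s} span {p.start}-{p.end}  missed={p.missed_cleavages}")
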