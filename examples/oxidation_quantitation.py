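"""Site-specific oxidation fold changes from synthetic LC-MS replicates.

Simulates three replicate runs for a control group and three peroxide dose
groups whose oxidized:non-oxidized abundance odds are 9x, 26x and 41x the
control level, then recovers the fold changes with 5-ppm XIC quantitation
(monoisotopic + A+1 targets, trapezoidal AUC, homoscedastic t-test).
"""

from proteox.workflow import run_oxidation_scenario

report = run_oxidation_scenario(seed=1)
print("group     truth fold   recovered   rel.err   p-value")
for group, g in report["groups"].items():
    print(
        f"{group:8s}  {g['truth_fold']:9.2f}   {g['recovered_fold']:9.2f}"
        f"   {g['relative_error']:6.1%}   {g['p_value']:.2e}"
    )
print(
    "\nEach row compares the generator's injected oxidation odds ratio with the\n"
    "fold change the XIC pipeline measured; p tests treated vs control replicates."
)
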