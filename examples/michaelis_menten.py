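"""Michaelis-Menten kinetics from colorimetric pNPP progress curves.

Simulates A405 progress curves (ext. coeff 17.8 mM^-1 cm^-1, path length
from the 100-ul / 4-mm-radius well geometry) for a control enzyme
(Km 7 mM) and a treated enzyme (Km 5 mM, a 1.4-fold decrease) at five
substrate concentrations from 0.8 to 40 mM, extracts initial velocities
from the most linear early portion of each curve, fits v = Vmax*S/(Km+S),
and compares the two fits.
"""

import warnings

from proteox.kinetics import (
    BeerLambertConfig,
    absorbance_to_concentration,
    compare_kinetics,
    fit_michaelis_menten,
    initial_velocity,
)
from proteox.synth import ProgressCurveSimConfig, simulate_pnpp_progress


def fit_assay(km_mM: float, seed: int):
    config = ProgressCurveSimConfig(Km_mM=km_mM, seed=seed)
    curves, _ = simulate_pnpp_progress(config)
    beer = BeerLambertConfig()
    v0, substrate = [], []
    for s0, grp in curves.groupby("substrate_mM"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # noise can dip A405 below 0
            conc = absorbance_to_concentration(grp.absorbance.to_numpy(), beer)
        v0.append(initial_velocity(grp.time_min.to_numpy(), conc))
        substrate.append(s0)
    return fit_michaelis_menten(v0, substrate, enzyme_uM=2.1)


control = fit_assay(7.0, seed=11)
treated = fit_assay(5.0, seed=12)

for name, fit in (("control", control), ("treated", treated)):
    print(f"{name}: Km = {fit.Km_mM:5.2f} mM  (95% CI {fit.Km_ci[0]:.2f}-{fit.Km_ci[1]:.2f}),"
          f"  Vmax = {fit.Vmax_mM_min:.4f} mM/min,  kcat = {fit.kcat_min:.1f} min^-1")

comparison = compare_kinetics(control, treated)
print(f"\nKm fold (control/treated)  : {comparison.Km_fold_a_over_b:.2f}  (truth 1.40)")
print(f"Vmax fold (control/treated): {comparison.Vmax_fold_a_over_b:.2f}  (truth 1.00)")
print(f"Km CIs overlap: {comparison.Km_ci_overlap};  Vmax CIs overlap: {comparison.Vmax_ci_overlap}")
print("\nA lower treated Km with unchanged Vmax/kcat means tighter apparent substrate\n"
      "binding but identical turnover - the signature probed by this assay pair.")
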