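"""Per-residue discriminability between two conformational ensembles.

Generates a 40-residue protein as per-residue Gaussian clouds (sigma 0.5 A)
in two conditions, with the second condition's loop (residues 10-15, 1-based)
displaced by 1.5 A.  After least-squares superposition onto the reference,
eta scores each residue: 0.5 = the two ensembles are indistinguishable
there, 1 = fully separated; residues with eta >= 0.69 (about a 1 A
center-of-mass shift at this cloud width) are flagged.
"""

import numpy as np

from proteox.ensembles import discriminability_profile, superpose
from proteox.synth import EnsembleSimConfig, simulate_ensembles

n = 40
shift = np.zeros((n, 3))
shift[9:15, 0] = 1.5  # residues 10-15
ens_a, ens_b, truth = simulate_ensembles(
    EnsembleSimConfig(n_residues=n, n_frames=500, mean_shift=shift, coord_sd=0.5, seed=2)
)
profile = discriminability_profile(superpose(ens_a), superpose(ens_b), n_repeats=3)

print("residue   eta    CoM dev (A)   flagged   true shift (A)")
for (_, row), true in zip(profile.table.iterrows(), truth.com_shift):
    mark = " *" if row.flagged else ""
    print(f"{int(row.residue) + 1:5d}   {row.eta:.3f}   {row.com_deviation:8.2f}"
          f"      {str(bool(row.flagged)):5s}   {true:6.2f}{mark}")
print("\nFlags concentrate on the displaced loop; unshifted residues sit near\n"
      "chance (eta ~ 0.5) with CoM deviations from sampling noise only.")
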