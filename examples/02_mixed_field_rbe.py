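"""Depth-RBE and biological-dose enhancement of target fragments.

Evaluates the 150 MeV/u field for the three inclusion scenarios (primary
protons only / all protons / all particles) on the alpha/beta = 2 Gy
tissue and prints where the fragment enhancement of the biological dose
is largest.
"""

import numpy as np

from fragrbe import (ALL_PARTICLES, ALL_PROTONS, PRIMARIES,
                     BraggKleemanStopping, ScoringGeometry, TISSUES,
                     TransportConfig, bk_range, generate_field, make_lq_table,
                     normalize_spectra, rbe_and_biodose_profile,
                     scenario_dose_scale)

geom = ScoringGeometry()
cube, _ = generate_field(150.0, geom, TransportConfig(seed=1))
spc = normalize_spectra(cube)
stopping = BraggKleemanStopping(geom)
tissue = TISSUES["ab2"]
lq = make_lq_table(tissue, list(cube.fluence), cube.energy_grids, stopping)

# all scenarios share the incident fluence; the all-particle field is
# scaled so its peak physical dose is 2 Gy
scale = scenario_dose_scale(spc, lq, stopping, ALL_PARTICLES, 2.0)
profiles = {m.name: rbe_and_biodose_profile(spc, lq, tissue, m, stopping,
                                            dose_scale=scale)
            for m in (PRIMARIES, ALL_PROTONS, ALL_PARTICLES)}

z = spc.depth_grid.centers
r = bk_range(150.0, geom)
upto = z <= r
ratio_all = (profiles["all_particles"].biological_dose[upto]
             / profiles["primaries"].biological_dose[upto])
ratio_ap = (profiles["all_protons"].biological_dose[upto]
            / profiles["primaries"].biological_dose[upto])
imax = int(np.argmax(ratio_all))
print(f"max biological-dose ratio (all particles / primaries): "
      f"{ratio_all[imax]:.3f}")
print(f"  at depth {z[upto][imax]:.2f} cm "
      f"({z[upto][imax]/r*100:.0f}% of range)")
print(f"max ratio for all protons / primaries: {ratio_ap.max():.3f}")
print(f"ratio at the Bragg peak: {ratio_all[-1]:.3f}")
# The enhancement peaks in the plateau and nearly vanishes on the peak,
# where slow primary protons dominate cell killing.
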