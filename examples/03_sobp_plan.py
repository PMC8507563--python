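"""Optimize spread-out Bragg peaks and evaluate their mixed-field biology.

Builds the 60-230 MeV/u beam library, flattens the physical dose over
30 mm box targets at 160 mm and 280 mm, and prints the achieved flatness
and the entrance-channel biological-dose enhancement of each plan.
"""

import numpy as np

from fragrbe import (ALL_PARTICLES, PRIMARIES, BeamLibrary,
                     BraggKleemanStopping, ScoringGeometry, TISSUES,
                     TransportConfig, make_lq_table, optimize_weights,
                     optimize_weights_biological, plan_field,
                     rbe_and_biodose_profile, scenario_dose_scale)

geom = ScoringGeometry()
cfg = TransportConfig(seed=1)
library = BeamLibrary.generate(geom, cfg)
stopping = BraggKleemanStopping(geom)
tissue = TISSUES["ab2"]
lq = make_lq_table(tissue, list(library.energy_grids), library.energy_grids,
                   stopping)

for center_cm in (16.0, 28.0):
    plan = optimize_weights(library, center_cm, 3.0)
    spc, ddd = plan_field(plan, library)
    z = spc.depth_grid.centers
    scale = scenario_dose_scale(spc, lq, stopping, ALL_PARTICLES, 2.0)
    prof_all = rbe_and_biodose_profile(spc, lq, tissue, ALL_PARTICLES,
                                       stopping, dose_scale=scale)
    prof_p = rbe_and_biodose_profile(spc, lq, tissue, PRIMARIES, stopping,
                                     dose_scale=scale)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = prof_all.biological_dose / prof_p.biological_dose
    lo, hi = plan.target_interval
    entrance = (z > 1.0) & (z < lo)
    imax = int(np.nanargmax(np.where(entrance, ratio, np.nan)))
    print(f"SOBP at {center_cm*10:.0f} mm: physical flatness "
          f"{plan.achieved_flatness:.2%}")
    print(f"  entrance max all-particle/primaries ratio "
          f"{np.nanmax(ratio[entrance]):.3f} at {z[imax]:.1f} cm; "
          f"in-target max {np.nanmax(ratio[(z >= lo) & (z <= hi)]):.3f}")

plan_bio = optimize_weights_biological(library, tissue, lq, 16.0, 3.0)
print(f"biologically optimized 160 mm plan: photon-equivalent-dose "
      f"flatness {plan_bio.achieved_flatness:.2%}")
# The fragment enhancement is largest in the entrance channel and grows
# with target depth; inside the target slow primaries dominate.
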