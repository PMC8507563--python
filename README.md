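# fragrbe

Mixed-field RBE analysis of nuclear **target fragments** in proton-therapy
beams.

Clinical proton therapy treats the relative biological effectiveness (RBE)
of the beam as a constant 1.1, and the treatment-planning chain usually
ignores the nuclear fragments that beam protons knock out of tissue nuclei
(secondary protons, deuterons, tritons, helium, and heavier recoils up to
oxygen). These fragments are slow, therefore high-LET, and therefore
disproportionately effective at killing cells. `fragrbe` is a library for
quantifying that effect: it generates depth-resolved mixed particle fields
in water, reduces them to normalized spectra tables, and evaluates cell
survival, photon-equivalent ("biological") dose and RBE for three nested
inclusion scenarios — *primary protons only*, *all protons*, and *all
particles* — for pristine Bragg peaks and optimized spread-out Bragg peaks
(SOBPs).

## The model

**Field.** A pencil beam of protons (60–230 MeV/u) impinges on a water
column divided into 200 depth slices. Primary protons slow down along the
Bragg–Kleeman range–energy rule `R(E) = a·(E/E0)^p` (a = 0.0022 cm,
p = 1.77, E0 = 1 MeV), straggle with a Bohr-like Gaussian range spread, and
are removed by nuclear interactions with mean free path λ. Removals feed
secondary protons (which build up with depth, then die away) and a
configurable catalogue of target-fragment channels (largest: ⁴He, below
500 mb), scored as equilibrium slowing-down spectra. Fluence
`F(E_prim, z, T, E_kin)` is scored per particle type `T = {A, Z,
generation}`; a seeded toy Monte-Carlo mode scores the same quantity with
the track-length estimator `F = Σᵢ lᵢ / V`.

**Spectra.** Fluence is normalized to particle numbers `N` such that the
primary-proton numbers at zero depth sum to one, with densities
`dN/dE` per MeV/u — the lookup format of a treatment-planning mixed-field
calculus. Text and HDF5 dialects (SPC/DDD) round-trip these tables.

**Biology.** Cell survival follows the linear-quadratic-linear (LQL)
model: `-ln s = αD + βD²` below a threshold dose `D_t`, continuing linearly
above it with the maximum slope `S_m = α + 2βD_t`. A mixed field is reduced
to effective parameters by dose-weighted averaging,

    ᾱ = Σ_l w_l S_l α_l / Σ_l w_l S_l     (β̄ analogously),

where `w_l` are the spectrum particle numbers and `S_l` the per-bin
stopping powers. Per-species ion coefficients `α_l(LET)` come from a
tissue-scaled LET parametrization (amplification ∝ LET²/(α/β) at low LET,
saturating and declining in the overkill regime), or from external tables.
Biological dose is the photon dose producing the same LQL effect; RBE is
its ratio to the physical dose; RBE50/RBE80 are evaluated at the 50% / 80%
survival levels.

**Plans.** A 60–230 MeV/u library in 5 MeV/u steps is superposed into
SOBPs; nonnegative least squares flattens the physical (or, iteratively,
the biological) dose over a 30 mm box target at 160 or 280 mm depth.

## Worked example

```python
import numpy as np
from fragrbe import (ALL_PARTICLES, PRIMARIES, BraggKleemanStopping,
                     ScoringGeometry, TISSUES, TransportConfig, bk_range,
                     generate_field, make_lq_table, normalize_spectra,
                     rbe_and_biodose_profile, scenario_dose_scale)

geom = ScoringGeometry()
cube, dose = generate_field(150.0, geom, TransportConfig(seed=1))
spc = normalize_spectra(cube)
stopping = BraggKleemanStopping(geom)
tissue = TISSUES["ab2"]                       # alpha/beta = 2 Gy, Dt = 8 Gy
lq = make_lq_table(tissue, list(cube.fluence), cube.energy_grids, stopping)

scale = scenario_dose_scale(spc, lq, stopping, ALL_PARTICLES, 2.0)
all_p = rbe_and_biodose_profile(spc, lq, tissue, ALL_PARTICLES, stopping,
                                dose_scale=scale)
prim = rbe_and_biodose_profile(spc, lq, tissue, PRIMARIES, stopping,
                               dose_scale=scale)
z = spc.depth_grid.centers
upto = z <= bk_range(150.0, geom)
ratio = all_p.biological_dose[upto] / prim.biological_dose[upto]
i = ratio.argmax()
print(f"max biological-dose ratio {ratio[i]:.3f} "
      f"at {z[upto][i] / bk_range(150.0, geom) * 100:.0f}% of range")
```

prints

```
max biological-dose ratio 1.328 at 35% of range
```

i.e. including all target fragments raises the biological dose of a
150 MeV/u beam on a radio-resistant (α/β = 2 Gy) tissue by ~33% relative
to the primaries-only calculation, with the maximum in the plateau —
the enhancement nearly vanishes at the Bragg peak (ratio 1.015), where
slow primary protons dominate cell killing. The `examples/` scripts walk
through field generation, scenario comparisons, SOBP planning and the
survival/RBE-level statistics, each printing the quantities it computes.

A thin CLI mirrors the workflow: `fragrbe generate`, `fragrbe plan`,
`fragrbe biology`, `fragrbe compare` (see `--help`).

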