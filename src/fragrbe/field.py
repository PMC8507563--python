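"""Depth-resolved particle-field containers and the spectrum calculus.

The central objects mirror the treatment-planning lookup chain:

``FluenceSpectrumCube``
    The scored fluence F(Eprim, z, T, Ekin) per unit primary, in cm^-2.
``SPCTable``
    Particle numbers N(Eprim, z, T, Ekin) normalized so that the
    primary-proton numbers sum to one in the first depth slice, together
    with the bin-width-normalized densities dN/dE (per MeV/u).
``DepthDoseSet``
    Per-component depth-dose profiles D(Eprim, z, T) in Gy*cm^2 per
    primary (dose-area-product convention for a pencil beam).

All containers key their per-species arrays by :class:`ParticleType` and
share a :class:`DepthGrid`; kinetic-energy binning may differ per species
(heavier fragments use a reduced upper limit for resolution).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, Mapping

import numpy as np

from .errors import CoverageError, EmptyFieldError, GridError
from .grids import DepthGrid, EnergyGrid
from .particles import PRIMARY_PROTON, ParticleType, ScenarioMask

#: MeV per gram -> Gy  (1 MeV = 1.602176634e-13 J; 1 g = 1e-3 kg)
MEV_PER_G_TO_GY = 1.602176634e-10


def _check_layout(depth_grid: DepthGrid,
                  energy_grids: Mapping[ParticleType, EnergyGrid],
                  arrays: Mapping[ParticleType, np.ndarray]) -> None:
    for ptype, arr in arrays.items():
        if ptype not in energy_grids:
            raise GridError(f"no energy grid for component {ptype.label}")
        expected = (depth_grid.n_slices, energy_grids[ptype].n_bins)
        if arr.shape != expected:
            raise GridError(
                f"array for {ptype.label} has shape {arr.shape}, expected {expected}"
            )


@dataclass
class FluenceSpectrumCube:
    """Scored fluence histogram F(z, T, Ekin) for one primary energy."""

    eprim: float  # MeV/u
    depth_grid: DepthGrid
    energy_grids: Dict[ParticleType, EnergyGrid]
    fluence: Dict[ParticleType, np.ndarray]  # cm^-2 per primary
    metadata: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_layout(self.depth_grid, self.energy_grids, self.fluence)

    @property
    def species(self) -> list[ParticleType]:
        return sorted(self.fluence)

    def validate(self, *, rtol: float = 1e-9) -> None:
        """Check the container invariants; raise on violation."""
        for ptype, arr in self.fluence.items():
            if np.any(arr < -rtol * max(1.0, float(np.abs(arr).max(initial=0.0)))):
                raise ValueError(f"negative fluence for {ptype.label}")
        prim = self.fluence.get(PRIMARY_PROTON)
        if prim is not None and prim.shape[0] > 1:
            tot = prim.sum(axis=1)
            if np.any(np.diff(tot) > rtol * max(tot.max(), 1e-300) + 1e-300):
                raise ValueError("primary-proton fluence increases with depth")

    def scaled(self, factor: float) -> "FluenceSpectrumCube":
        return FluenceSpectrumCube(
            self.eprim, self.depth_grid, dict(self.energy_grids),
            {t: a * factor for t, a in self.fluence.items()},
            dict(self.metadata),
        )


@dataclass
class SPCTable:
    """Normalized particle numbers N and densities dN/dE per (z, T, Ekin)."""

    eprim: float
    depth_grid: DepthGrid
    energy_grids: Dict[ParticleType, EnergyGrid]
    n: Dict[ParticleType, np.ndarray]      # dimensionless
    metadata: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_layout(self.depth_grid, self.energy_grids, self.n)

    @property
    def species(self) -> list[ParticleType]:
        return sorted(self.n)

    @property
    def dnde(self) -> Dict[ParticleType, np.ndarray]:
        """Bin-width-normalized particle numbers, (MeV/u)^-1."""
        return {t: arr / self.energy_grids[t].width for t, arr in self.n.items()}

    def primary_normalization(self) -> float:
        """Sum of primary-proton numbers in the first depth slice."""
        prim = self.n.get(PRIMARY_PROTON)
        if prim is None:
            return 0.0
        return float(prim[0].sum())


@dataclass
class DepthDoseSet:
    """Per-component depth-dose profiles, Gy*cm^2 per primary."""

    eprim: float
    depth_grid: DepthGrid
    dose: Dict[ParticleType, np.ndarray]  # (n_slices,)
    metadata: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        for ptype, arr in self.dose.items():
            if arr.shape != (self.depth_grid.n_slices,):
                raise GridError(
                    f"dose array for {ptype.label} has shape {arr.shape}, "
                    f"expected ({self.depth_grid.n_slices},)"
                )

    @property
    def species(self) -> list[ParticleType]:
        return sorted(self.dose)

    @property
    def total(self) -> np.ndarray:
        """Total dose profile; equals the sum of the components."""
        out = np.zeros(self.depth_grid.n_slices)
        for arr in self.dose.values():
            out += arr
        return out


def normalize_spectra(cube: FluenceSpectrumCube) -> SPCTable:
    """Convert a fluence cube into a normalized spectra table.

    The particle numbers are the scored fluence divided by the
    energy-integrated primary-proton fluence in the first depth slice, so
    that the primary numbers at zero depth sum to exactly one.  The
    normalization cancels any overall scale of the cube.
    """
    prim = cube.fluence.get(PRIMARY_PROTON)
    if prim is None or not np.any(prim[0] > 0):
        raise EmptyFieldError(
            "cube has no primary-proton fluence in the first depth slice"
        )
    norm = float(prim[0].sum())
    n = {t: arr / norm for t, arr in cube.fluence.items()}
    meta = dict(cube.metadata)
    meta["normalization"] = norm
    return SPCTable(cube.eprim, cube.depth_grid, dict(cube.energy_grids), n, meta)


def fluence_to_dose(cube: FluenceSpectrumCube, stopping_power) -> DepthDoseSet:
    """Fold a fluence cube with mass stopping powers into depth doses.

    ``stopping_power`` is a callable ``(ParticleType, E[MeV/u]) ->
    MeV*cm^2/g`` (per particle).  The returned doses are in Gy*cm^2 per
    primary: dose(z, T) = sum_E F(z, T, E) * S(T, E) * 1.602e-10.
    """
    dose: Dict[ParticleType, np.ndarray] = {}
    for ptype, arr in cube.fluence.items():
        centers = cube.energy_grids[ptype].centers
        try:
            s = np.asarray(stopping_power(ptype, centers), dtype=float)
        except Exception as exc:  # noqa: BLE001 - reported as coverage gap
            raise CoverageError(
                f"stopping power unavailable for {ptype.label}: {exc}"
            ) from exc
        if s.shape != centers.shape or np.any(~np.isfinite(s)) or np.any(s <= 0):
            bad = centers[np.where(~np.isfinite(s) | (s <= 0))[0][:1]]
            raise CoverageError(
                f"stopping power not positive for {ptype.label} near "
                f"E={bad} MeV/u"
            )
        dose[ptype] = (arr * s[None, :]).sum(axis=1) * MEV_PER_G_TO_GY
    return DepthDoseSet(cube.eprim, cube.depth_grid, dose, dict(cube.metadata))


def scenario_filter(obj, mask: ScenarioMask):
    """Keep only the components matched by an inclusion-scenario mask."""
    if isinstance(obj, FluenceSpectrumCube):
        keep = {t: a for t, a in obj.fluence.items() if mask(t)}
        grids = {t: obj.energy_grids[t] for t in keep}
        return FluenceSpectrumCube(obj.eprim, obj.depth_grid, grids, keep,
                                   dict(obj.metadata))
    if isinstance(obj, SPCTable):
        keep = {t: a for t, a in obj.n.items() if mask(t)}
        grids = {t: obj.energy_grids[t] for t in keep}
        return SPCTable(obj.eprim, obj.depth_grid, grids, keep, dict(obj.metadata))
    if isinstance(obj, DepthDoseSet):
        keep = {t: a for t, a in obj.dose.items() if mask(t)}
        return DepthDoseSet(obj.eprim, obj.depth_grid, keep, dict(obj.metadata))
    raise TypeError(f"cannot filter object of type {type(obj).__name__}")
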