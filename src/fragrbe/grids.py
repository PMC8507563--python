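"""Uniform depth and energy grids used by all scorers and tables."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, GridError


@dataclass(frozen=True)
class DepthGrid:
    """Uniform slicing of the water column along the beam axis.

    Depth zero is the phantom front face; slice 0 is the first slice and
    "z = 0" in the spectrum normalization refers to it.
    """

    n_slices: int = 200
    length: float = 20.0  # cm water-equivalent

    def __post_init__(self) -> None:
        if self.n_slices < 1:
            raise ConfigError(f"n_slices must be >= 1, got {self.n_slices}")
        if self.length <= 0:
            raise ConfigError(f"depth-grid length must be > 0, got {self.length}")

    @property
    def dz(self) -> float:
        return self.length / self.n_slices

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(0.0, self.length, self.n_slices + 1)

    @property
    def centers(self) -> np.ndarray:
        return (np.arange(self.n_slices) + 0.5) * self.dz


@dataclass(frozen=True)
class EnergyGrid:
    """Uniform kinetic-energy binning in MeV/u spanning [0, upper]."""

    n_bins: int = 200
    upper: float = 230.0  # MeV/u

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ConfigError(f"n_bins must be >= 1, got {self.n_bins}")
        if self.upper <= 0:
            raise ConfigError(f"energy upper limit must be > 0, got {self.upper}")

    @property
    def width(self) -> float:
        return self.upper / self.n_bins

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(0.0, self.upper, self.n_bins + 1)

    @property
    def centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.width

    @property
    def widths(self) -> np.ndarray:
        return np.full(self.n_bins, self.width)


def check_same_grid(a, b, what: str = "grid") -> None:
    """Raise GridError unless two grids are identical."""
    if a != b:
        raise GridError(f"{what} mismatch: {a} != {b}")
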