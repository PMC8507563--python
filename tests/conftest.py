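"""Shared fixtures: generated fields, beam library, LQ tables.

Everything is generated programmatically at test time; the synthetic
generator is the single source of fixture data.
"""

import numpy as np
import pytest
from hypothesis import settings

from fragrbe import (BeamLibrary, BraggKleemanStopping, ScoringGeometry,
                     TISSUES, TransportConfig, generate_field, make_lq_table,
                     normalize_spectra)

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def geom():
    return ScoringGeometry()


@pytest.fixture(scope="session")
def cfg():
    return TransportConfig(seed=1)


@pytest.fixture(scope="session")
def stopping(geom):
    return BraggKleemanStopping(geom)


@pytest.fixture(scope="session")
def field150(geom, cfg):
    """Default 150 MeV/u analytic field: (cube, dose set)."""
    return generate_field(150.0, geom, cfg)


@pytest.fixture(scope="session")
def spc150(field150):
    return normalize_spectra(field150[0])


@pytest.fixture(scope="session")
def lq_ab2(field150, stopping):
    cube = field150[0]
    return make_lq_table(TISSUES["ab2"], list(cube.fluence),
                         cube.energy_grids, stopping)


@pytest.fixture(scope="session")
def lq_ab10(field150, stopping):
    cube = field150[0]
    return make_lq_table(TISSUES["ab10"], list(cube.fluence),
                         cube.energy_grids, stopping)


@pytest.fixture(scope="session")
def library(geom, cfg):
    """Full 60-230 MeV/u beam library (35 energies)."""
    return BeamLibrary.generate(geom, cfg)


@pytest.fixture(scope="session")
def lq_ab2_library(library, stopping):
    return make_lq_table(TISSUES["ab2"], list(library.energy_grids),
                         library.energy_grids, stopping)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
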