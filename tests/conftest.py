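"""Shared fixtures: published film constants and fast solver settings."""
import numpy as np
import pytest

from erofilm import DiffusivitySet, FranzGeometry, SwellingParams

# Film material constants (dry thickness, solvent fractions, solvent
# diffusivity, erosion constant) for the two formulations studied.
TABLE_NO_CD = dict(L0=87e-6, phi0=0.21, phig=0.3, phieq=0.89, DGs=7.95e-9, C=67.72e-6)
TABLE_CD = dict(L0=126e-6, phi0=0.12, phig=0.18, phieq=0.85, DGs=7.95e-9, C=84.37e-6)

# drug diffusivities estimated from Franz-cell release data (m²/s)
D0F = 5.78e-10          # furosemide in the solvent solution
DMF = 0.5 * D0F         # furosemide in the dialysis membrane
DGF = 6.5e-11           # furosemide in the swollen gel
DGF_CD = 5.4e-11        # furosemide/HP-β-CD complex in the swollen gel


@pytest.fixture
def film_no_cd() -> SwellingParams:
    return SwellingParams(**TABLE_NO_CD)


@pytest.fixture
def film_cd() -> SwellingParams:
    return SwellingParams(**TABLE_CD)


@pytest.fixture
def blank_franz():
    """Blank-solution Franz configuration: 0.1 mL of 0.18 mg/mL over 1 cm²."""
    geom = FranzGeometry(delta_d=1e-3)
    diff = DiffusivitySet(Dd=D0F, Dm=DMF, D0=D0F)
    return geom, diff, 18e-9  # M0 = 18 μg in kg


@pytest.fixture
def coarse_franz_kwargs():
    """Reduced chain resolution for fits and repeated runs."""
    return dict(n_donor=16, n_membrane=6, n_cil=16, n_tc=12, n_arm=16, n_dense=40)


@pytest.fixture
def hourly_schedule():
    return np.arange(1, 11) * 3600.0
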