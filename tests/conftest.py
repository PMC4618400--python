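import numpy as np
import pytest
from hypothesis import settings

from lsferric.epr import powder_pattern

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")
from lsferric.synthetic import EPR_SPECIES_PRESETS

# Published signed g values, table-scaled coefficients, splittings and
# predicted transitions for the butyrate-bound (BA) and aqueous active
# (Aq) enzyme forms; the ground truth for the analysis tests.
TABLE1 = {
    "BA": {
        "g": (-2.14, 2.29, -1.97),
        "coeffs_scaled": (0.07, 0.04, 1.00),
        "delta": -4030.0,
        "v_abs": 2560.0,
        "rhombicity": 0.32,
        "transitions": (2750.0, 5300.0),
    },
    "Aq": {
        "g": (-2.13, 2.21, -1.99),
        "coeffs_scaled": (0.05, 0.03, 1.00),
        "delta": -5010.0,
        "v_abs": 2320.0,
        "rhombicity": 0.23,
        "transitions": (3850.0, 6170.0),
    },
}

# Published UV-Vis band tables: (label, energy cm^-1, eps, delta_eps,
# C/D x 1e4) at 5 K / 7 T.
BAND_TABLE_BA = [
    ("a", 13600, 1250, 36, 306),
    ("b", 15700, 500, 10, 213),
    ("c", 17500, 350, 2, 61),
    ("d", 19500, 760, 38, 532),
    ("e", 21800, 1060, 14, 140),
    ("f", 24700, 2050, -59, 306),
    ("g", 27000, 2200, -3, 15),
    ("h", 30000, 3350, -14, 44),
]
BAND_TABLE_AQ = [
    ("a", 14300, 1200, 54, 479),
    ("b", 16900, 310, -4, 137),
    ("c", 20100, 450, 16, 378),
    ("d", 21700, 780, 16, 218),
    ("e", 23900, 1000, -9, 96),
    ("f", 27500, 3180, -32, 107),
    ("g", 30600, 2890, -13, 48),
]

FIELD_GRID = np.linspace(260.0, 380.0, 1024)


@pytest.fixture(scope="session")
def aq_components():
    """Noiseless powder patterns of the two pH-7.5 aqueous-form species."""
    models = [EPR_SPECIES_PRESETS["Aq-major"], EPR_SPECIES_PRESETS["Aq-minor-high-pH"]]
    return models, [powder_pattern(m, FIELD_GRID, 9.40) for m in models]
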