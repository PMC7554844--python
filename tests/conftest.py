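import numpy as np
import pytest

from tigrade.presets import BULK_MODULUS, material, material_names
from tigrade.ti_core import TIParams, c1_continuity_C5


@pytest.fixture(scope="session")
def valve_materials() -> dict:
    return {n: material(n) for n in material_names()}


def random_ti_params(rng: np.random.Generator, f_range=(0.5, 1.5)) -> TIParams:
    """A physically plausible random TI parameter draw.

    C5 is set to a random multiple of the slope-continuity value so the
    discontinuity index stays in a realistic band.
    """
    c1 = 10.0 ** rng.uniform(3, 6)
    c2 = 0.0 if rng.random() < 0.5 else 10.0 ** rng.uniform(2, 4)
    c3 = 10.0 ** rng.uniform(1, 5)
    c4 = rng.uniform(5.0, 40.0)
    ls = rng.uniform(1.02, 1.3)
    base = TIParams(c1, c2, c3, c4, 1.0, 0.0, ls, BULK_MODULUS)
    c5 = rng.uniform(*f_range) * c1_continuity_C5(base)
    return TIParams(c1, c2, c3, c4, c5, 0.0, ls, BULK_MODULUS).with_c0_continuity()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
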