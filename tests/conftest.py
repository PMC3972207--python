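import numpy as np
import pytest

from rdident.rd_model import RDSpringMaterial


def draw_material(rng: np.random.Generator) -> RDSpringMaterial:
    """Generic damped admissible material: kR, mR in [0.5, 2], loss ratios in [0.02, 0.3]."""
    kR = rng.uniform(0.5, 2.0)
    mR = rng.uniform(0.5, 2.0)
    return RDSpringMaterial(
        kR=kR,
        kI=kR * rng.uniform(0.02, 0.3),
        mR=mR,
        mI=-mR * rng.uniform(0.02, 0.3),
    )


def draw_omega(rng: np.random.Generator, mat: RDSpringMaterial) -> float:
    """Drive frequency in [0.3, 0.9] x undamped resonance."""
    return rng.uniform(0.3, 0.9) * mat.undamped_resonance


@pytest.fixture
def rng():
    return np.random.default_rng(20140401)


@pytest.fixture
def material():
    """Fixed generic damped material used across the suite."""
    return RDSpringMaterial(kR=1.0, kI=0.1, mR=1.0, mI=-0.05)
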