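import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from aortaseg.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def tav_case():
    """Noiseless tricuspid phantom with known ground truth."""
    spec = PhantomSpec(valve_type="TAV", noise_sigma=0.0, seed=1)
    img, lab = generate_phantom(spec)
    return img, lab, spec


@pytest.fixture(scope="session")
def bav0_case():
    spec = PhantomSpec(valve_type="BAV0", noise_sigma=0.0, seed=1)
    img, lab = generate_phantom(spec)
    return img, lab, spec


@pytest.fixture(scope="session")
def bav1_case():
    spec = PhantomSpec(valve_type="BAV1", noise_sigma=0.0, seed=1)
    img, lab = generate_phantom(spec)
    return img, lab, spec
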