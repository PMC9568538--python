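import numpy as np
import pytest

from shutterblinds import ConfusionMatrix
from shutterblinds.reference import CLASS_LABELS, DISFA_CONFUSION, UNBC_CONFUSION


@pytest.fixture(scope="session")
def unbc_cm() -> ConfusionMatrix:
    return ConfusionMatrix(UNBC_CONFUSION, CLASS_LABELS)


@pytest.fixture(scope="session")
def disfa_cm() -> ConfusionMatrix:
    return ConfusionMatrix(DISFA_CONFUSION, CLASS_LABELS)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def checker_face() -> np.ndarray:
    """A deterministic non-constant 224x224x3 face-like test image."""
    r = np.arange(224)
    img = ((r[:, None] // 16 + r[None, :] // 16) % 2 * 180 + 40).astype(np.uint8)
    return np.repeat(img[:, :, None], 3, axis=2)
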