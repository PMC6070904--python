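import numpy as np
import pytest

from iupair.basegeom import ReferenceFrame, load_templates
from iupair.ensemble import EnsembleConfig, sample_ensemble, sequence_spec
from iupair.pairing import build_wobble_pair


@pytest.fixture(scope="session")
def templates():
    return load_templates()


@pytest.fixture(scope="session")
def relaxed_iu():
    """The restrained-relaxed I-U wobble pair (in duplex context)."""
    return build_wobble_pair()


@pytest.fixture(scope="session")
def relaxed_au():
    """The same relaxation protocol applied to a canonical A-U pair."""
    return build_wobble_pair(pair_type="AU")


@pytest.fixture(scope="session")
def uii_small():
    """A small UII ensemble with default (correlated) switching."""
    spec = sequence_spec("UII")
    return sample_ensemble(spec, EnsembleConfig(n_frames=300, seed=42))


def random_frame(rng):
    """A uniformly random proper rigid frame."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    return ReferenceFrame(rng.normal(size=3) * 5.0, R)
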