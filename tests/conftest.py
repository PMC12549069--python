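import numpy as np
import pytest

from dynamotypes.atlas import generate_seizure
from dynamotypes.registry import get_spec
from dynamotypes.sphere import load_packaged_curves


@pytest.fixture(scope="session")
def curves():
    return load_packaged_curves()


@pytest.fixture(scope="session")
def record_cache():
    """Session-wide cache of generated seizure records keyed by
    (onset, offset, method, noise_level, cutoff, seed): end-to-end
    generation is the expensive step shared by many tests."""
    cache: dict = {}

    def get(onset, offset, method=None, noise_level="none", cutoff=None, seed=1,
            **kwargs):
        key = (onset, offset, method, noise_level, cutoff, seed,
               tuple(sorted(kwargs.items())))
        if key not in cache:
            cache[key] = generate_seizure(
                get_spec(onset, offset), method=method,
                noise_level=noise_level, cutoff=cutoff, seed=seed, **kwargs,
            )
        return cache[key]

    return get


@pytest.fixture(scope="session")
def sn_sh_record(record_cache):
    """Canonical fold/homoclinic (Epileptor-like) seizure, unfiltered."""
    return record_cache("SN", "SH")


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
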