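import numpy as np
import pytest

from replidyn import RepliconSpec, shape_density

PHAGE_LENGTH = 126_000
PHAGE_BINS = 126


def _simulate_profile(
    mode: str,
    seed: int,
    ori: int = 60_500,
    ptr: float = 2.0,
    rc_decay: float = 1e-4,
    mix: float = 0.5,
    depth: int = 10**5,
    n_bins: int = PHAGE_BINS,
    length: int = PHAGE_LENGTH,
) -> np.ndarray:
    """Multinomial read counts from a single replication-shape profile."""
    spec = RepliconSpec(
        name="phage",
        length=length,
        mode=mode,
        ori_pos=ori,
        ptr=ptr,
        rc_decay=rc_decay,
        mix_weight=mix,
        bin_size=length // n_bins,
    )
    dens = shape_density(spec, 8.0, n_bins)
    rng = np.random.default_rng(seed)
    return rng.multinomial(depth, dens)


@pytest.fixture(scope="session")
def simulate_profile():
    """Factory for noisy single-replicon coverage profiles."""
    return _simulate_profile
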