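import numpy as np
import pytest

from fractkit import CascadeSpec, TimeSeries, generate_cascade, generate_fgn


@pytest.fixture(scope="session")
def devil_spec() -> CascadeSpec:
    """The classic three-interval cascade with weights (0.2, 0.6, 0.2)."""
    return CascadeSpec(base=3, weights=(0.2, 0.6, 0.2), depth=8)


@pytest.fixture(scope="session")
def devil_cascade(devil_spec) -> TimeSeries:
    return generate_cascade(devil_spec)


@pytest.fixture(scope="session")
def triadic_windows(devil_spec) -> np.ndarray:
    """Window sizes aligned with the cascade's construction scales,
    skipping the two finest refinement levels (small-window bias)."""
    return devil_spec.base ** np.arange(3, devil_spec.depth)


@pytest.fixture(scope="session")
def white_noise() -> TimeSeries:
    return generate_fgn(4096, 0.5, seed=11)


@pytest.fixture(scope="session")
def brownian() -> TimeSeries:
    ts = generate_fgn(4096, 0.5, seed=12)
    return ts.with_values(np.cumsum(ts.values), label="Brownian motion")
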