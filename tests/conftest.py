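import numpy as np
import pytest

from coronalign import (
    AnchorSampler,
    SectionAnchor,
    SeriesAlignment,
    generate_phantom,
    sample_random_anchors,
)


@pytest.fixture(scope="session")
def phantom():
    """Default deterministic phantom volume (64 x 128 x 64)."""
    return generate_phantom(seed=0)


@pytest.fixture(scope="session")
def small_phantom():
    """A smaller phantom for quicker rendering-heavy tests."""
    return generate_phantom(seed=1, shape=(32, 48, 32))


def make_random_series(seed: int, n: int = 20, name: str = "series") -> SeriesAlignment:
    """A seeded random (non-canonical) series of well-formed anchors."""
    rng = np.random.default_rng(seed)
    sections = []
    for k in range(n):
        o = rng.uniform(0, 100, 3)
        u = np.array([rng.uniform(40, 120), rng.uniform(-15, 15), rng.uniform(-5, 5)])
        v = np.array([rng.uniform(-5, 5), rng.uniform(-15, 15), rng.uniform(40, 120)])
        sections.append(
            SectionAnchor.from_components(
                f"img_s{k + 1:03d}.png",
                np.concatenate([o, u, v]),
                width=50 + 7 * k,  # deterministic per position so series ensemble
                height=60 + 5 * k,
                cutting_index=k + 1,
            )
        )
    return SeriesAlignment(name=name, sections=sections)


@pytest.fixture()
def random_series():
    return make_random_series(seed=7)
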