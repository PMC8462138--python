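import numpy as np
import pytest

import chromamesh as cm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def convex_outline_62():
    """General-position convex 62-gon (elliptical fish outline)."""
    return cm.make_outline(62, elongation=2.0, seed=3, center=(180.0, 120.0), size=70.0)


@pytest.fixture(scope="session")
def tiny_study(tmp_path_factory):
    """Small complete synthetic study shared across tests (read-only)."""
    out = tmp_path_factory.mktemp("study") / "fixture"
    cfg = cm.SynthConfig(
        n_populations=2,
        n_per_population=5,
        rounds=2,
        image_height=160,
        image_width=240,
        seed=11,
    )
    manifest = cm.synth_study(cfg, out)
    return cfg, manifest, out
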