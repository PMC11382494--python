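import numpy as np
import pytest

import hetsynth as hs


@pytest.fixture(scope="session")
def paper_cohort() -> hs.CohortTable:
    """Study-style simulated cohort: 2,500 rows, 21 variables (12 binary)."""
    return hs.generate_cohort(hs.paper_like_spec(n=2500, seed=7))


@pytest.fixture(scope="session")
def small_cohort() -> hs.CohortTable:
    """Small cohort for fast training-loop tests."""
    return hs.generate_cohort(hs.paper_like_spec(n=400, seed=3))


@pytest.fixture(scope="session")
def two_region() -> hs.CohortTable:
    return hs.generate_two_region(hs.TwoRegionSpec(n=1200, seed=5))


@pytest.fixture(scope="session")
def bimodal_mixture() -> np.ndarray:
    """Exposure-linked 0/4 mixture with imbalanced (0.3) exposure."""
    rng = np.random.default_rng(11)
    e = rng.uniform(size=2500) < 0.3
    return np.where(e, rng.normal(4.0, 1.0, 2500), rng.normal(0.0, 1.0, 2500))


@pytest.fixture(scope="session")
def trained_small(small_cohort) -> tuple:
    """A quickly trained VAE + pipeline shared across tests."""
    pipe = hs.TransformPipeline.fit(small_cohort, {"x_skew1": "boxcox"})
    t01 = pipe.forward(small_cohort)
    cfg = hs.VAEConfig(epochs=30, seed=2)
    model = hs.train_vae(t01, cfg, pipeline=pipe)
    return model, pipe, t01
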