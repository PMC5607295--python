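import numpy as np
import pytest

import polarprobe as pp


@pytest.fixture
def unpolarised_probe() -> pp.ProbeModel:
    """Ideal probe seeded by a fully depolarised source: unit effective gains."""
    return pp.ProbeModel.ideal(source_dop=0.0)


@pytest.fixture
def study_probe() -> pp.ProbeModel:
    """Ideal channels, but the partially polarised source (DOP 15%)."""
    return pp.ProbeModel.ideal(source_dop=0.15)


def random_gains(rng: np.random.Generator, sigma: float = 0.25) -> dict:
    """Log-normal per-pair couplings with spread comparable to a real probe."""
    return {p: float(np.exp(rng.normal(0.0, sigma))) for p in pp.PAIR_SCHEME}


def random_physical_sample(seed: int) -> pp.TissueSample:
    """A random decomposable tissue-like sample (physical by construction)."""
    rng = np.random.default_rng(seed)
    return pp.make_synthetic_tissue(
        diatten=float(rng.uniform(0.0, 0.4)),
        diatten_axis_deg=float(rng.uniform(0.0, 180.0)),
        seed=seed,
    )
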