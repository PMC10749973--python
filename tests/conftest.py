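import numpy as np
import pytest

from thighasym.model import HUHistogram, ModeParams, NTRAParams, evaluate_trimodal


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def truth_params():
    """A realistic trimodal parameter set (total mass 1e5)."""
    return NTRAParams(
        fat=ModeParams(N=33000.0, mu=-60.0, sigma=25.0, alpha=0.3),
        connective=ModeParams(N=22000.0, mu=15.0, sigma=12.0, alpha=0.0),
        muscle=ModeParams(N=45000.0, mu=55.0, sigma=13.0, alpha=3.1),
    )


@pytest.fixture
def exact_histogram(truth_params):
    """Noiseless histogram: the model curve evaluated at the 401 bin centres."""
    x = np.arange(-200, 201, dtype=float)
    return HUHistogram(counts=evaluate_trimodal(x, truth_params))


def random_truth(rng) -> NTRAParams:
    """Random valid parameter set with modes well inside their windows."""
    return NTRAParams(
        fat=ModeParams(
            N=rng.uniform(2e4, 4e4), mu=rng.uniform(-90, -35),
            sigma=rng.uniform(15, 35), alpha=rng.uniform(-1.5, 1.5),
        ),
        connective=ModeParams(
            N=rng.uniform(1e4, 3e4), mu=rng.uniform(5, 30),
            sigma=rng.uniform(6, 18), alpha=0.0,
        ),
        muscle=ModeParams(
            N=rng.uniform(3e4, 5e4), mu=rng.uniform(48, 70),
            sigma=rng.uniform(8, 18), alpha=rng.uniform(0.5, 4.0),
        ),
    )
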