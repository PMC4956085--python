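import numpy as np
import pytest

from raresphere.abundance_models import TADModel, sample_community, sample_counts
from raresphere.bayes_fit import MCMCConfig, fit_tad
from raresphere.data_model import AbundanceVector, FrequencyCounts


def make_fc_from_counts(counts: np.ndarray) -> FrequencyCounts:
    obs = counts[counts > 0]
    vals, freqs = np.unique(obs, return_counts=True)
    return FrequencyCounts({int(k): int(f) for k, f in zip(vals, freqs)})


def simulate_fc(model: TADModel, S: int, N: int, seed: int) -> FrequencyCounts:
    rng = np.random.default_rng(seed)
    p = sample_community(model, S, rng)
    return make_fc_from_counts(sample_counts(p, N, rng))


# a moderately heavy-tailed sichel on the count scale: ~5% of species
# unseen at mean count 60, enough for a nondegenerate richness posterior
def recovery_model(mean: float) -> TADModel:
    from scipy.special import kve

    gamma, omega = -0.6, 0.05
    r = kve(gamma + 1, omega) / kve(gamma, omega)
    scale = mean / r
    return TADModel("sichel", (gamma, omega * scale, omega / scale))


@pytest.fixture(scope="session")
def tiny_av() -> AbundanceVector:
    return AbundanceVector(("a", "b", "c", "d"), np.array([5, 3, 1, 1]))


@pytest.fixture(scope="session")
def desk_fc() -> FrequencyCounts:
    return simulate_fc(recovery_model(8000 / 200), 200, 8000, seed=11)


@pytest.fixture(scope="session")
def desk_chain(desk_fc):
    """One reusable posterior chain from a desk-scale sichel fit."""
    cfg = MCMCConfig(
        n_burnin=4000, n_samples=8000, thin=4, seed=5, s_max=50_000
    )
    return fit_tad(desk_fc, "sichel", cfg)
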