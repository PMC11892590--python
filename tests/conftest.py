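import numpy as np
import pytest

import phyloprev as pp


def random_tree(n_tips: int, seed: int):
    """Random Yule tree with positive branch lengths (test utility)."""
    return pp.simulate_tree(n_tips, birth_rate=1.0, seed=seed)


@pytest.fixture(scope="session")
def small_sim():
    """A 60-species synthetic dataset with pathwise covariate and known truth."""
    cfg = pp.SyntheticConfig(n_tips_per_class=30, seed=42)
    return pp.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_dataset(small_sim):
    return small_sim.dataset()


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    """A short-chain fit of the full model on the small dataset, reused by
    summary/prediction/inference tests."""
    est = pp.PoissonPhyloGLMM(spec=pp.ModelSpec(pathwise="shared"),
                              iterations=30_000, thin=30, seed=7)
    est.fit(small_dataset)
    return est


@pytest.fixture
def rng():
    return np.random.default_rng(0)
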