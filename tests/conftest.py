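import numpy as np
import pytest

from clawmorph import (
    ClawParams,
    PhyloCovariance,
    Scenario,
    gpa,
    make_claw,
    phylo_covariance,
    simulate_tree,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def random_configuration(rng, noise=0.02):
    """A valid random claw-like configuration (noisy synthetic claw)."""
    theta_sheath = float(rng.uniform(60, 150))
    theta_core = theta_sheath * float(rng.uniform(0.6, 0.8))
    # keep the core circle nested: length_ratio < (theta_core+10)/(theta_sheath+10)
    cap = (theta_core + 10) / (theta_sheath + 10)
    params = ClawParams(
        theta_sheath=theta_sheath,
        theta_core=theta_core,
        length_ratio=cap * float(rng.uniform(0.7, 0.95)),
        radius=float(rng.uniform(5, 20)),
        noise_sd=noise,
    )
    cfg, _ = make_claw(params, seed=int(rng.integers(2**31)))
    return cfg


@pytest.fixture(scope="session")
def tree24():
    return simulate_tree(24, seed=11)


@pytest.fixture(scope="session")
def cov24(tree24):
    return phylo_covariance(tree24)


@pytest.fixture(scope="session")
def tree64():
    return simulate_tree(64, seed=13)


@pytest.fixture(scope="session")
def cov64(tree64):
    return phylo_covariance(tree64)


@pytest.fixture(scope="session")
def star8():
    from clawmorph import read_newick

    nwk = "(" + ",".join(f"t{i}:1" for i in range(1, 9)) + ");"
    return phylo_covariance(read_newick(nwk))


@pytest.fixture(scope="session")
def small_sample():
    """GPA-aligned sample of 10 noisy synthetic claws."""
    r = np.random.default_rng(77)
    configs = [random_configuration(r) for _ in range(10)]
    return gpa(configs)


@pytest.fixture(scope="session")
def tiny_scenario():
    return Scenario(n_species=12, specimens_per_species=2)
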