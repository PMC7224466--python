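import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from metqg.simulate import SimConfig, TraitSim, paper_like_config, simulate_met

settings.register_profile(
    "det", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


def single_trait_config(seed, *, sigma_g2=4.0, sigma_ge2=1.0,
                        sigma2=(1.0, 1.0, 1.0), blocks=None, g_cov=None,
                        missing_rate=0.05, n_full_sibs=30, n_parents=2):
    blocks = blocks or {"A": 6, "B": 3, "C": 3}
    q = len(blocks)
    trait = TraitSim("y", env_means=(10.0,) * q, sigma_g2=sigma_g2,
                     sigma_ge2=sigma_ge2, sigma2_by_env=tuple(sigma2)[:q],
                     g_cov=g_cov)
    return SimConfig(seed=seed, traits=(trait,), blocks=blocks,
                     spacing={e: 3.0 for e in blocks}, derive=False,
                     missing_rate=missing_rate, n_full_sibs=n_full_sibs,
                     n_parents=n_parents)


@pytest.fixture(scope="session")
def paper_met():
    """One realisation of the full study design (seed fixed)."""
    d, truth = simulate_met(paper_like_config(seed=11))
    return d, truth


@pytest.fixture(scope="session")
def small_met():
    """A compact 3-environment dataset for fast model fits."""
    cfg = single_trait_config(5, n_full_sibs=12, blocks={"A": 3, "B": 2, "C": 2},
                              missing_rate=0.0)
    d, truth = simulate_met(cfg)
    return d, truth


@pytest.fixture(scope="session")
def balanced_single():
    """Balanced single-environment trial: 30 genotypes x 6 blocks."""
    cfg = single_trait_config(42, sigma_ge2=0.0, sigma2=(4.0,), blocks={"A": 6},
                              missing_rate=0.0, n_parents=0)
    d, truth = simulate_met(cfg)
    return d, truth


def anova_sigma_g2(d, trait="y"):
    """Expected-mean-squares moment estimator on a balanced RCB trial."""
    ge = d.records.pivot_table(index="genotype", columns="block", values=trait)
    m, r = ge.shape
    arr = ge.to_numpy()
    mu = arr.mean()
    ss_g = r * ((ge.mean(1) - mu) ** 2).sum()
    ss_b = m * ((ge.mean(0) - mu) ** 2).sum()
    ss_e = ((arr - mu) ** 2).sum() - ss_g - ss_b
    ms_g = ss_g / (m - 1)
    ms_e = ss_e / ((m - 1) * (r - 1))
    return (ms_g - ms_e) / r, ms_e
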