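import numpy as np
import pandas as pd
import pytest

from diallelkit import (
    DiallelDesign,
    GeneratorConfig,
    PhenotypePanel,
    TraitSettings,
    paper_like_config,
    simulate_trial,
)


@pytest.fixture(scope="session")
def design8() -> DiallelDesign:
    """The study layout: 8 parents, 3 blocks, two irrigation regimes."""
    return DiallelDesign(
        parent_ids=tuple(f"P{i}" for i in range(1, 9)),
        n_blocks=3,
        regimes=("well_watered", "water_deficit"),
    )


@pytest.fixture(scope="session")
def small_config(design8) -> GeneratorConfig:
    """A three-trait generator config with noise, for fast structural tests."""
    return GeneratorConfig(
        design=design8,
        traits={
            "grain_yield": TraitSettings(
                mu=30.0, sigma_gca=1.5, sigma_sca=1.2, sigma_block=0.6,
                sigma_error=1.8, regime_effect=0.747,
            ),
            "plant_height": TraitSettings(
                mu=100.0, sigma_gca=5.0, sigma_sca=4.0, sigma_block=2.0,
                sigma_error=6.0, regime_effect=0.877, direction="lower",
            ),
            "grain_protein": TraitSettings(
                mu=12.0, sigma_gca=0.6, sigma_sca=0.5, sigma_block=0.25,
                sigma_error=0.7, regime_effect=1.22,
            ),
        },
        seed=42,
    )


@pytest.fixture(scope="session")
def small_panel(small_config) -> PhenotypePanel:
    panel, _ = simulate_trial(small_config)
    return panel


@pytest.fixture(scope="session")
def small_truth(small_config):
    _, truth = simulate_trial(small_config)
    return truth


@pytest.fixture(scope="session")
def noiseless_config(design8) -> GeneratorConfig:
    """Genetic structure present but zero block and plot error."""
    return GeneratorConfig(
        design=design8,
        traits={
            "grain_yield": TraitSettings(
                mu=30.0, sigma_gca=1.5, sigma_sca=1.2, sigma_block=0.0,
                sigma_error=0.0, regime_effect=0.747,
            ),
        },
        seed=7,
    )


@pytest.fixture(scope="session")
def paper_panel() -> PhenotypePanel:
    """The full 18-trait study-shaped preset, generated once per session."""
    panel, _ = simulate_trial(paper_like_config(), seed=11)
    return panel


def random_mean_table(design: DiallelDesign, rng: np.random.Generator, trait="t", regime="r"):
    """A random symmetric entry-mean table for oracle comparisons."""
    from diallelkit import TraitMeanTable

    entries = design.entries()
    vals = rng.normal(20.0, 5.0, size=len(entries))
    means = pd.Series(
        vals, index=pd.MultiIndex.from_tuples(entries, names=["parent_a", "parent_b"])
    )
    return TraitMeanTable(trait=trait, regime=regime, means=means, design=design)
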