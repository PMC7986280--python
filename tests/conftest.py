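import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from metscreen import synthetic_data as sd

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def small_design():
    return sd.TrialDesign(
        n_years=2, n_blocks=2, n_genotypes=3, conditions=("stress",),
        trait_names=("X",),
    )


@pytest.fixture
def small_spec():
    return sd.VarianceSpec(
        traits={"X": sd.TraitVariance(mean=5.0, year=1.0, block_in_year=0.5,
                                      genotype=2.0, gxy=1.0, residual=1.0)}
    )


@pytest.fixture
def small_trial(small_design, small_spec):
    return sd.simulate_trial(small_design, small_spec, seed=3)


def random_balanced_trial(rng, n_years, n_blocks, n_genotypes):
    """A random balanced single-condition table, no model structure."""
    design = sd.TrialDesign(
        n_years=n_years, n_blocks=n_blocks, n_genotypes=n_genotypes,
        conditions=("stress",), trait_names=("X",),
    )
    spec = sd.VarianceSpec(
        traits={"X": sd.TraitVariance(
            mean=float(rng.normal(0, 3)),
            year=float(rng.uniform(0, 4)),
            block_in_year=float(rng.uniform(0, 2)),
            genotype=float(rng.uniform(0, 6)),
            gxy=float(rng.uniform(0, 3)),
            residual=float(rng.uniform(0.2, 3)),
        )}
    )
    return sd.simulate_trial(design, spec, seed=int(rng.integers(2**31)))
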