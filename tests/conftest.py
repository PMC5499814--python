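import numpy as np
import pytest

from posiselect.simulator import (SimulationConfig, build_scheme,
                                  default_species_tree, evolve)


@pytest.fixture(scope="session")
def nine_taxon_tree():
    return default_species_tree()


@pytest.fixture(scope="session")
def small_family(nine_taxon_tree):
    """One simulated scheme-N gene family (150 codons), reused read-only."""
    rng = np.random.default_rng(1234)
    return evolve(SimulationConfig(root_length=150), rng)


@pytest.fixture(scope="session")
def selected_family(nine_taxon_tree):
    """A gene family with strong positive selection on the human branch."""
    rng = np.random.default_rng(99)
    scheme = build_scheme("custom", fg_fraction=0.05, target_mean=0.9)
    cfg = SimulationConfig(
        root_length=300,
        scheme_per_branch={frozenset(["human"]): scheme})
    return evolve(cfg, rng)
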