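import numpy as np
import pytest

from sipgrad.synthetic_sip import (
    GradientSpec,
    TaxonSpec,
    demo_community,
    demo_gradient,
    simulate_experiment,
)


@pytest.fixture(scope="session")
def demo_sim():
    """One simulated paired amended/control experiment on the 20-taxon
    benchmark community (seed 0, depth 1e5)."""
    return simulate_experiment(demo_community(), demo_gradient(seed=0))


@pytest.fixture()
def small_taxa():
    """A minimal 3-taxon community: one fully labeled responder and two
    unlabeled background taxa."""
    return [
        TaxonSpec("Labeled", 45, 0.3, growth_factor=4.0,
                  label_atom_fraction=1.0, labeled_cell_fraction=1.0),
        TaxonSpec("LightBg", 34, 0.4),
        TaxonSpec("HeavyBg", 60, 0.3),
    ]


@pytest.fixture()
def small_sim(small_taxa):
    return simulate_experiment(small_taxa, demo_gradient(seed=11))
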