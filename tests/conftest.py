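import numpy as np
import pytest

import domhier as dh


@pytest.fixture
def params():
    return dh.default_parameters()


@pytest.fixture
def small_params():
    """A desk-sized population: 4 groups of 4+4, short contest phase."""
    return dh.default_parameters().replace(
        n_groups=4, group_size=4, other_sex_size=4,
        rounds_per_generation=120, generations=5, replicates=2, seed=7,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(123)


def make_group(qualities, traits=None, p=None):
    """Deterministic fixture group of competing-sex Individuals.

    ``traits`` may be a single TraitSet (shared) or a list; genotypes are
    monomorphic at the trait values so expression reproduces them exactly
    (for clamped traits the values must be inside the clamp range).
    """
    p = p or dh.default_parameters()
    qualities = list(qualities)
    if traits is None:
        traits = dh.TraitSet.from_array(np.array(p.founder_traits))
    if isinstance(traits, dh.TraitSet):
        traits = [traits] * len(qualities)
    members = []
    for i, (q, t) in enumerate(zip(qualities, traits)):
        g = dh.Genotype.monomorphic(t.as_array())
        members.append(dh.Individual(id=i, sex="competing", genotype=g, q=float(q)))
    return members
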