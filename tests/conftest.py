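import numpy as np
import pytest

import litterbmd as lb


def make_group(dose, litters):
    """Build a DoseGroup from (size, affected) pairs."""
    recs = tuple(
        lb.LitterRecord("s1", "mouse", dose, f"L{i}", n, a)
        for i, (n, a) in enumerate(litters)
    )
    return lb.DoseGroup(dose=dose, litters=recs)


def make_study(groups_dict, species="mouse", study_id="s1"):
    """Build a LitterStudy from {dose: [(size, affected), ...]}."""
    groups = tuple(
        lb.DoseGroup(
            dose=d,
            litters=tuple(
                lb.LitterRecord(study_id, species, d, f"L{d}-{i}", n, a)
                for i, (n, a) in enumerate(litters)
            ),
        )
        for d, litters in sorted(groups_dict.items())
    )
    return lb.LitterStudy(study_id=study_id, species=species, groups=groups)


@pytest.fixture
def worked_group():
    """The three-litter worked example: (5,1), (5,0), (5,4) at one dose."""
    return make_group(0.0, [(5, 1), (5, 0), (5, 4)])


@pytest.fixture
def simulated_study():
    """One seeded species-typical simulated mouse study."""
    return lb.simulate_study(lb.species_config("mouse", seed=7))


@pytest.fixture
def random_studies():
    """A small batch of seeded simulated studies for distributional checks."""
    return [lb.simulate_study(lb.species_config("mouse", seed=100 + i))
            for i in range(5)]
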