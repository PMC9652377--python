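import numpy as np
import pytest

from quests import RadiusSet
from quests.fixtures import ClusterSpec, EnsembleSpec, make_dimer_ensemble


@pytest.fixture
def radii():
    return RadiusSet()


@pytest.fixture
def single_sphere_radii():
    """One pseudo-atom type: radius 2.0 Å, probe 1.4 Å (closed-form friendly)."""
    return RadiusSet(by_element={"C": 2.0}, probe_radius=1.4)


def two_cluster_spec(n_models=500, seed=11, outside=0.0):
    """Two well-separated planted conformations: open-like (52°, 12 Å, lower
    energy, 70%) and closed-like (−15°, 16 Å, 30%); separation >= 5 sd."""
    return EnsembleSpec(
        clusters=[
            ClusterSpec(0.7, 52.0, 3.0, 12.0, 0.5, -30.0, 2.0, "open"),
            ClusterSpec(0.3, -15.0, 3.0, 16.0, 0.5, -27.0, 2.0, "closed"),
        ],
        n_models=n_models,
        seed=seed,
        outside_filter_fraction=outside,
    )


@pytest.fixture
def planted_two_cluster_ensemble():
    return make_dimer_ensemble(two_cluster_spec())
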