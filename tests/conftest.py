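import numpy as np
import pytest

from linkedrings import ChannelSpec, Conformation, ModelParams
from linkedrings.catalog import catalog_conformation


@pytest.fixture(scope="session")
def params40() -> ModelParams:
    return ModelParams(N=40)


@pytest.fixture(scope="session")
def bulk() -> ChannelSpec:
    return ChannelSpec.bulk()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240321)


@pytest.fixture(scope="session")
def hopf40() -> Conformation:
    return catalog_conformation("2_1^2", 40)


def perpendicular_circles(n=48, radius=1.0, offset=1.0):
    """Canonical Hopf embedding: two interlocked perpendicular circles."""
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    c1 = radius * np.column_stack([np.cos(th), np.sin(th), 0 * th])
    c2 = np.column_stack([offset + radius * np.cos(th),
                          0 * th, radius * np.sin(th)])
    return c1, c2


@pytest.fixture(scope="session")
def stretched_hopf():
    """A tension-equilibrated stretched Hopf pair (N=40, narrow channel)."""
    from linkedrings.catalog import prepare_stretched
    from linkedrings.params import StretchProtocol
    prot = StretchProtocol(force_magnitude=20.0, prep_diameter=5.5,
                           prep_duration=80.0)
    p = ModelParams(N=40)
    confs, _ = prepare_stretched("2_1^2", prot, p,
                                 np.random.default_rng(77), 1)
    return confs[0]


@pytest.fixture(scope="session")
def equilibrated_hopf():
    """An equilibrium Hopf pair in a moderate channel (N=40)."""
    from linkedrings.catalog import _orient_along_x, _squeeze_into_channel
    from linkedrings.dynamics import maxwell_velocities, simulate
    p = ModelParams(N=40)
    chan = ChannelSpec.for_rings(6.0, 80)
    conf = catalog_conformation("2_1^2", 40)
    _orient_along_x(conf)
    conf.velocities = maxwell_velocities(conf.n_beads, p,
                                         np.random.default_rng(5))
    _squeeze_into_channel(conf, p, chan, 99)
    simulate(conf, p, chan, duration=300.0, sample_interval=300.0, seed=6)
    return conf
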