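import numpy as np
import pytest

from cartoptics import SampleGeometry, TransportConfig


@pytest.fixture(scope="session")
def grid_5nm():
    return 400.0 + 5.0 * np.arange(201)  # 400..1400 nm


@pytest.fixture(scope="session")
def bulk_geometry():
    return SampleGeometry(thickness=2.0, radius=7.5)


@pytest.fixture(scope="session")
def section_geometry():
    return SampleGeometry(thickness=0.1, radius=7.5)


@pytest.fixture(scope="session")
def bulk_transport_config(bulk_geometry):
    return TransportConfig(bulk_geometry, photons=10_000, seed=11)


@pytest.fixture(scope="session")
def bulk_lut(bulk_transport_config):
    """24x24 log-spaced lookup table at 1e4 photons per node.

    Built once per session; used by the inversion-closure tests.
    """
    from cartoptics import build_lookup_table

    return build_lookup_table(bulk_transport_config, nodes=(24, 24))
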