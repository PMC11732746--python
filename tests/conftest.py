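import io as _stringio

import pytest

from mscflux import DEFAULT_GEOMETRY, MSCDeployment
from mscflux.io import read_concentrations


@pytest.fixture
def geom():
    return DEFAULT_GEOMETRY


@pytest.fixture
def make_deployment():
    """Factory for a POC deployment with sensible defaults, overridable
    per test."""

    def _make(**overrides):
        kwargs = dict(
            cruise="DY111",
            station="TS",
            occupation="1",
            deployment_id="TS-1-0001",
            depth_m=60.0,
            substance="POC",
            p_top=1.0,
            p_base=2.0,
            p_tray=10.0,
        )
        kwargs.update(overrides)
        return MSCDeployment(**kwargs)

    return _make


def frame_to_deployments(frame):
    """Round a concentration frame through the CSV reader."""
    buffer = _stringio.StringIO(frame.to_csv(index=False))
    deployments, rejects = read_concentrations(buffer)
    assert rejects.empty
    return deployments
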