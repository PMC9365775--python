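"""Shared fixtures: the default solar-minimum source and the dosimetry
results that several test modules inspect.  Everything is deterministic, so
session scope is safe and keeps the suite fast."""

import pytest

import gcrdose as g
from gcrdose.dosimetry import dose_breakdown
from gcrdose.transport_1d import ShieldConfig, transmit


@pytest.fixture(scope="session")
def source():
    return g.build_full_source()


@pytest.fixture(scope="session")
def rbe_params():
    return g.load_parameter_set("lymphocyte-simple-exchange")


@pytest.fixture(scope="session")
def free_space(source, rbe_params):
    return dose_breakdown(source, rbe_params=rbe_params)


@pytest.fixture(scope="session")
def shielded_20(source, rbe_params):
    """Dose breakdowns behind 20 g/cm^2 of each shield material."""
    out = {}
    for name in ("Al", "PE", "CFRP"):
        result = transmit(source, ShieldConfig(g.MATERIALS[name], 20.0))
        out[name] = dose_breakdown(result.combined(), rbe_params=rbe_params)
    return out
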