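import numpy as np
import pytest

from dorsaflow import (
    HydroContext,
    InterfaceModel,
    RampProtocol,
    build_calibration,
    step_force_schedule,
)


@pytest.fixture(scope="session")
def ctx() -> HydroContext:
    return HydroContext()


@pytest.fixture(scope="session")
def iface() -> InterfaceModel:
    return InterfaceModel()


@pytest.fixture(scope="session")
def ramp_protocol() -> RampProtocol:
    return RampProtocol()


@pytest.fixture(scope="session")
def ramp_calibrations(ctx, ramp_protocol) -> dict:
    """One force calibration per ramp flow rate (expensive; built once)."""
    return {q: build_calibration(q, ctx) for q in ramp_protocol.rates}


@pytest.fixture(scope="session")
def ramp_forces(ramp_protocol, ramp_calibrations, ctx) -> np.ndarray:
    return step_force_schedule(
        ramp_protocol, ramp_calibrations, ctx.reference_height
    )
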