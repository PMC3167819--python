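import numpy as np
import pytest

from quorumfate.signaling import (CellInputs, CellState, RegulatoryCurve,
                                  SignalingParams, default_params)


@pytest.fixture(scope="session")
def params() -> SignalingParams:
    """The shipped calibrated parameter set."""
    return default_params()


@pytest.fixture()
def quiet_inputs() -> CellInputs:
    return CellInputs(wnt_ext=0.0, dkk_ext=0.0, bound_ecad=0.0, dsl_sum=0.0)


@pytest.fixture()
def active_inputs(params) -> CellInputs:
    """Inputs of a well-supported cell: ambient Wnt, some DSL, no Dkk1."""
    return CellInputs(wnt_ext=params.wnt_ext, dkk_ext=0.0, bound_ecad=2.0,
                      dsl_sum=4.0)


def up_curve(vmax=1.0, half_sat=1.0, hill=2.0) -> RegulatoryCurve:
    return RegulatoryCurve("up", vmax, half_sat, hill)


def down_curve(vmax=1.0, half_sat=1.0, hill=2.0) -> RegulatoryCurve:
    return RegulatoryCurve("down", vmax, half_sat, hill)


@pytest.fixture()
def seeded_state(params) -> CellState:
    return params.initial_state
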