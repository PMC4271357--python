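"""Shared fixtures: simulation runs are expensive, so sweeps are session-scoped."""

import numpy as np
import pytest

from aortasv import ModelParameters, simulate
from aortasv.experiments import COMPLIANCE_SCALES, PMAX_GRID


@pytest.fixture(scope="session")
def normal_params():
    return ModelParameters()


@pytest.fixture(scope="session")
def normal_record(normal_params):
    """Table-style defaults: linear compliance, HR 80, Pmax 120."""
    return simulate(normal_params)


@pytest.fixture(scope="session")
def linear_records(normal_params, normal_record):
    """Linear-mode records keyed by compliance scale {1/3, 1/2, 1, 3/2}."""
    out = {}
    for scale in COMPLIANCE_SCALES:
        if scale == 1.0:
            out[scale] = normal_record
        else:
            out[scale] = simulate(normal_params.scale_compliance(scale))
    return out


@pytest.fixture(scope="session")
def fung_records_hr80(normal_params):
    base = normal_params.replace(compliance_mode="fung")
    return {pm: simulate(base.replace(p_max=pm)) for pm in PMAX_GRID}


@pytest.fixture(scope="session")
def fung_records_hr120(normal_params):
    base = normal_params.replace(compliance_mode="fung", frequency=2.0)
    return {pm: simulate(base.replace(p_max=pm)) for pm in PMAX_GRID}


@pytest.fixture(scope="session")
def zero_drive_record(normal_params):
    """Arrested circulation: no pump drive at all."""
    return simulate(normal_params.replace(p_max=0.0))


def synthetic_pulse(period=0.75, t_p=0.12, t_h=0.33, dbp=80.0, sbp=120.0,
                    n_beats=3, fs=1000.0):
    """Piecewise-linear pulse train: onset -> peak -> halftime point -> next onset."""
    t = np.arange(0.0, n_beats * period, 1.0 / fs)
    phase = t % period
    half = 0.5 * (sbp + dbp)
    v = np.where(
        phase < t_p,
        dbp + (sbp - dbp) * phase / t_p,
        np.where(
            phase < t_h,
            sbp + (half - sbp) * (phase - t_p) / (t_h - t_p),
            half + (dbp - half) * (phase - t_h) / (period - t_h),
        ),
    )
    return t, v
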