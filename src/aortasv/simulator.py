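"""Lumped-parameter mock circulation: pump, ten aortic segments, venous reservoir.

The model is a closed hydraulic circuit.  A compliant pump compartment is
squeezed by a half-sinusoidal external pressure and ejects through a one-way
valve into the aortic root.  Ten compliant aortic segments are chained through
small inline resistances and blood-column inertances; nine of them leak
through large systemic runoff resistances into a lumped venous reservoir,
which refills the pump through the inflow valve.  Marching is explicit Euler
at dt = 1e-5 s, with the inertial flow term treated implicitly (backward
difference solved for the current flow), which is unconditionally stable.

Aortic segments may follow a linear volume-pressure law or the exponential
(Fung) law, whose dynamic compliance is C(P) = 2·C_ref·P_ref/(P + P_ref),
equal to C_ref at the reference pressure and falling as the vessel distends.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._march import march
from .params import (DOWNSTREAM, MMHG_CGS, N_SEGMENTS, RUNOFF_SEGMENTS,
                     UPSTREAM, ModelParameters)

__all__ = [
    "external_pump_pressure", "external_pump_pressure_rate",
    "dynamic_compliance", "inertance", "CirculationState", "initial_state",
    "step", "SimulationRecord", "simulate", "true_stroke_volume",
]


def external_pump_pressure(t, p: ModelParameters):
    """Half-sinusoidal squeezing pressure P_ext(t) = P_max·max(0, sin(ωt)), mmHg."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = p.p_max * np.maximum(0.0, np.sin(p.omega * t))
    return float(out) if out.ndim == 0 else out


def external_pump_pressure_rate(t, p: ModelParameters):
    """Time derivative of the external pump pressure, mmHg/s.

    P_max·ω·cos(ωt) while the drive is on (sin(ωt) > 0), zero in diastole.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    phase = p.omega * t
    out = np.where(np.sin(phase) > 0.0, p.p_max * p.omega * np.cos(phase), 0.0)
    return float(out) if out.ndim == 0 else out


def dynamic_compliance(pressure, c_ref, p_ref, mode: str = "fung"):
    """Dynamic (instantaneous) compliance at a given distending pressure, ml/mmHg.

    ``linear`` returns c_ref.  ``fung`` returns 2·c_ref·p_ref/(P + p_ref):
    the local slope of the exponential volume-pressure curve of a Fung
    biomaterial, normalised so that C(p_ref) = c_ref.
    """
    if c_ref <= 0 or p_ref <= 0:
        raise ValueError("c_ref and p_ref must be positive")
    if mode == "linear":
        return c_ref if np.ndim(pressure) == 0 else np.full(np.shape(pressure), c_ref)
    if mode != "fung":
        raise ValueError(f"unknown compliance mode {mode!r}")
    pressure = np.asarray(pressure, dtype=float)
    if np.any(pressure <= -p_ref):
        raise ValueError("pressure <= -p_ref: volume-pressure law undefined")
    out = 2.0 * c_ref * p_ref / (pressure + p_ref)
    return float(out) if out.ndim == 0 else out


def inertance(density: float, seg_length: float, area: float) -> float:
    """Blood-column inertance L = ρ·s/A, converted to mmHg/(ml/s²)."""
    if seg_length == 0:
        return 0.0
    if area <= 0:
        raise ValueError("collapsed segment: cross-sectional area must be > 0")
    return density * seg_length / area / MMHG_CGS


# ----------------------------------------------------------------------


@dataclass
class CirculationState:
    """Instantaneous state of every compartment (reference implementation)."""

    t: float
    pump_volume: float
    pump_pressure: float
    seg_volume: np.ndarray        # (10,) ml
    seg_pressure: np.ndarray      # (10,) mmHg
    venous_volume: float
    venous_pressure: float
    inline_flow: np.ndarray       # (9,) ml/s through the inertial junctions
    pump_inflow: float = 0.0
    pump_outflow: float = 0.0
    outflow_integral: float = 0.0

    def total_volume(self) -> float:
        return self.pump_volume + self.venous_volume + float(self.seg_volume.sum())


def initial_state(p: ModelParameters) -> CirculationState:
    """Cold start: arrested circulation at the mean circulatory pressure."""
    return CirculationState(
        t=0.0,
        pump_volume=p.pump_vol_init,
        pump_pressure=p.p_init,
        seg_volume=np.full(N_SEGMENTS, p.seg_volume_init),
        seg_pressure=np.full(N_SEGMENTS, p.p_init),
        venous_volume=p.venous_vol_init,
        venous_pressure=p.p_init,
        inline_flow=np.zeros(len(UPSTREAM)),
    )


def step(state: CirculationState, p: ModelParameters) -> CirculationState:
    """One explicit-Euler step of size dt.

    Order of computation per step: valve flows (one-way), inline aortic
    flows via the implicit inertial update, systemic runoff by Ohm's law,
    volume balances, then pressure increments ΔP = ΔV/C with the dynamic
    compliance of the active mode; the pump pressure additionally advances
    by the external-pressure rate.  This is the slow, readable reference
    for the compiled kernel used by :func:`simulate`.
    """
    dt = p.dt
    seg_p = state.seg_pressure
    seg_v = state.seg_volume

    q_in = max(0.0, (state.venous_pressure - state.pump_pressure) / p.r_pump_in)
    q_out = max(0.0, (state.pump_pressure - seg_p[0]) / p.r_pump_out)

    r_junc = p.junction_resistances()
    iflow = state.inline_flow.copy()
    for j in range(len(UPSTREAM)):
        area = seg_v[UPSTREAM[j]] / p.seg_length
        L = inertance(p.blood_density, p.seg_length, area)
        dp = seg_p[UPSTREAM[j]] - seg_p[DOWNSTREAM[j]]
        iflow[j] = (dp * dt + L * iflow[j]) / (r_junc[j] * dt + L)

    runoff = np.zeros(N_SEGMENTS)
    for m in RUNOFF_SEGMENTS:
        runoff[m] = (seg_p[m] - state.venous_pressure) / p.r_systemic_each

    dv_seg = -runoff
    dv_seg[0] += q_out
    np.add.at(dv_seg, DOWNSTREAM, iflow)
    np.add.at(dv_seg, UPSTREAM, -iflow)
    dv_pump = q_in - q_out
    dv_ven = runoff.sum() - q_in

    c_seg = p.c_seg_array()
    if p.compliance_mode == "fung":
        c_now = 2.0 * c_seg * p.p_ref / (seg_p + p.p_ref)
    else:
        c_now = c_seg

    new_seg_p = seg_p + dv_seg * dt / c_now
    new_seg_v = seg_v + dv_seg * dt
    if np.any(new_seg_v <= 0) or not np.all(np.isfinite(new_seg_p)):
        bad = int(np.argmin(new_seg_v))
        raise FloatingPointError(f"aortic segment a{bad} collapsed or diverged")

    pext_rate = external_pump_pressure_rate(state.t, p)
    return replace(
        state,
        t=state.t + dt,
        pump_volume=state.pump_volume + dv_pump * dt,
        pump_pressure=state.pump_pressure + dv_pump * dt / p.c_pump + pext_rate * dt,
        seg_volume=new_seg_v,
        seg_pressure=new_seg_p,
        venous_volume=state.venous_volume + dv_ven * dt,
        venous_pressure=state.venous_pressure + dv_ven * dt / p.c_venous,
        inline_flow=iflow,
        pump_inflow=q_in,
        pump_outflow=q_out,
        outflow_integral=state.outflow_integral + q_out * dt,
    )


# ----------------------------------------------------------------------


@dataclass
class SimulationRecord:
    """Sampled time series from the recording window of one run (1 kHz default)."""

    sample_times: np.ndarray          # (n,) s
    seg_pressure_series: np.ndarray   # (n, 10) mmHg
    seg_radius_series: np.ndarray     # (n, 10) cm
    pump_outflow_series: np.ndarray   # (n,) ml/s
    pump_pressure_series: np.ndarray  # (n,) mmHg
    venous_pressure_series: np.ndarray  # (n,) mmHg
    params: ModelParameters | None = None
    outflow_integral: float = 0.0     # ml ejected during the window (exact accumulator)
    volume_drift_rel: float = 0.0     # max relative drift of total circuit volume

    def __post_init__(self) -> None:
        n = len(self.sample_times)
        for name in ("seg_pressure_series", "seg_radius_series",
                     "pump_outflow_series", "pump_pressure_series",
                     "venous_pressure_series"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != sample_times length")

    @property
    def sample_dt(self) -> float:
        return float(np.mean(np.diff(self.sample_times)))

    @property
    def n_beats(self) -> int:
        if self.params is None:
            raise ValueError("record has no parameter echo; pass n_beats explicitly")
        return self.params.n_beats_recorded

    def channel(self, label: str):
        """Return one named channel ('p_a5', 'r_a3', 'q_pump_out', 'p_pump', 'p_ven')."""
        from .waveforms import PressureWaveform

        if label.startswith("p_a"):
            values = self.seg_pressure_series[:, int(label[3:])]
        elif label.startswith("r_a"):
            values = self.seg_radius_series[:, int(label[3:])]
        elif label == "q_pump_out":
            values = self.pump_outflow_series
        elif label == "p_pump":
            values = self.pump_pressure_series
        elif label == "p_ven":
            values = self.venous_pressure_series
        else:
            raise KeyError(f"unknown channel {label!r}")
        return PressureWaveform(self.sample_times, values, label)


_COMPARTMENT_NAMES = [f"a{m}" for m in range(N_SEGMENTS)] + ["pump", "venous"]


def simulate(p: ModelParameters) -> SimulationRecord:
    """Run the mock circulation from a cold start and record [startprint, stopprint].

    All compartments start at the mean circulatory pressure p_init with their
    nominal volumes; the pump drive is switched on at t = 0 and the system is
    marched to stopprint.  Samples are saved every (skipnumber+1) steps within
    the recording window, by which time the system has reached its periodic
    steady state.
    """
    n_steps = int(round(p.stopprint / p.dt))
    stride = p.skipnumber + 1
    ks = np.arange(0, n_steps + 1, stride)
    t = ks * p.dt
    mask = (t >= p.startprint - 0.5 * p.dt) & (t <= p.stopprint + 0.5 * p.dt)
    sample_ks = ks[mask].astype(np.int64)
    if len(sample_ks) == 0:
        raise ValueError("recording window contains no samples")

    (out_t, out_p, out_r, out_q, out_pp, out_pv,
     outflow_int, drift, status, bad) = march(
        n_steps, p.dt, p.omega, p.p_max,
        p.r_pump_in, p.r_pump_out, p.junction_resistances(),
        UPSTREAM.astype(np.int64), DOWNSTREAM.astype(np.int64),
        p.r_systemic_each, p.c_seg_array(), p.c_venous, p.c_pump,
        p.seg_length, p.blood_density,
        p.compliance_mode == "fung", p.p_ref, p.p_init,
        np.full(N_SEGMENTS, p.seg_volume_init), p.pump_vol_init,
        p.venous_vol_init, sample_ks, p.startprint, p.stopprint,
    )
    if status != 0:
        raise FloatingPointError(
            f"simulation diverged in compartment {_COMPARTMENT_NAMES[bad]} "
            "(negative volume or non-finite pressure); try a smaller dt"
        )
    return SimulationRecord(
        sample_times=out_t,
        seg_pressure_series=out_p,
        seg_radius_series=out_r,
        pump_outflow_series=out_q,
        pump_pressure_series=out_pp,
        venous_pressure_series=out_pv,
        params=p,
        outflow_integral=float(outflow_int),
        volume_drift_rel=float(drift),
    )


def true_stroke_volume(rec: SimulationRecord, n_beats: int | None = None,
                       use_accumulator: bool = False) -> float:
    """Actual stroke volume: integrated aortic-valve outflow per beat, ml.

    The recording window must span a whole number of beats.  By default the
    integral is a trapezoidal sum over the sampled outflow series; the exact
    per-step accumulator from the marching loop is available as a cross-check.
    """
    if n_beats is None:
        n_beats = rec.n_beats
    if n_beats < 1:
        raise ValueError("recording window must span >= 1 whole beat")
    if rec.params is not None:
        beats = (rec.sample_times[-1] - rec.sample_times[0]) * rec.params.frequency
        if abs(beats - round(beats)) > 0.01:
            raise ValueError(f"window spans {beats:.4f} beats; need a whole number")
    if use_accumulator:
        return rec.outflow_integral / n_beats
    total = np.trapezoid(rec.pump_outflow_series, rec.sample_times)
    return float(total) / n_beats
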