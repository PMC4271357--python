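"""Stroke-volume estimation from pulse wave velocity and pulse contour.

The chain is: Bramwell-Hill compliance from PWV and aortic volume
(C = V/(ρv²) in CGS, ×1333.22 for ml/mmHg); the halftime method
SV = C·PP/(2(1 − λ·t_h/T)), which accounts for peripheral runoff up to the
halftime point; the runoff-weighting factor λ from a piecewise-linear
pulse model (≈1.1 for normal contours); and an optional correction for
the Fung-type nonlinear compliance of a real aorta, which makes the
PWV-derived (diastolic) compliance overestimate the effective compliance
at large pulse pressures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .params import MMHG_CGS
from .simulator import SimulationRecord
from .waveforms import average_features, mid_aortic_area, pulse_wave_velocity

__all__ = [
    "ComplianceEstimate", "SVEstimate", "compliance_from_pwv",
    "tapering_factor", "lambda_correction", "halftime_sv", "small_animal_sv",
    "nonlinear_correction_exact", "nonlinear_correction_series",
    "cardiac_output", "estimate_from_record",
]


@dataclass(frozen=True)
class ComplianceEstimate:
    """Total aortic compliance inferred noninvasively."""

    pwv: float            # cm/s
    a_mid: float          # cm², mid-aortic cross-section
    l_eff: float          # cm, effective aortic length
    aortic_volume: float  # ml = a_mid · l_eff · taper_factor
    density: float        # g/ml
    c_total: float        # ml/mmHg
    taper_factor: float = 1.0


@dataclass(frozen=True)
class SVEstimate:
    """Halftime-method stroke volume with all intermediates."""

    lambda_: float
    sv_uncorrected: float     # ml
    correction_ratio: float   # (0, 1]
    sv_corrected: float       # ml
    cardiac_output: float     # ml/s
    cvp: float                # mmHg
    compliance: ComplianceEstimate | None = None
    t_h: float = float("nan")
    t_p: float = float("nan")
    period: float = float("nan")
    pp: float = float("nan")
    sbp: float = float("nan")
    dbp: float = float("nan")

    @property
    def cardiac_output_l_min(self) -> float:
        return self.cardiac_output * 60.0 / 1000.0


def compliance_from_pwv(pwv: float, a_mid: float, l_eff: float,
                        density: float = 1.03,
                        taper_factor: float = 1.0) -> float:
    """Bramwell-Hill total compliance C = V/(ρ·v²) in ml/mmHg.

    V = a_mid·l_eff·taper_factor is the aortic volume; the 1333.22 factor
    converts the CGS value to clinical units.
    """
    if min(pwv, a_mid, l_eff, density, taper_factor) <= 0:
        raise ValueError("all inputs must be positive")
    volume = a_mid * l_eff * taper_factor
    return MMHG_CGS * volume / (density * pwv**2)


def compliance_cgs(pwv: float, volume: float, density: float = 1.03) -> float:
    """Bramwell-Hill compliance in CGS units, ml/(dyn/cm²)."""
    if min(pwv, volume, density) <= 0:
        raise ValueError("all inputs must be positive")
    return volume / (density * pwv**2)


def tapering_factor(taper_total: float, r0: float) -> float:
    """Compliance ratio of a linearly tapered aorta to a uniform one.

    For radius r(x) = r0 − ϵx over length L, with total taper ϵL, the
    integrated compliance exceeds that of the untapered mid-radius tube by
    1 + (1/3)·(ϵL/(2r0))²; about 1.04 for the anatomic taper ϵL/r0 ≈ 0.75.
    """
    if r0 <= 0:
        raise ValueError("r0 must be positive")
    if not 0 <= taper_total < 2 * r0:
        raise ValueError("total taper must lie in [0, 2·r0)")
    return 1.0 + (taper_total / (2.0 * r0)) ** 2 / 3.0


def lambda_correction(t_p: float, t_h: float, period: float,
                      sbp: float, dbp: float, cvp: float = 0.0) -> float:
    """Runoff-weighting factor λ: mean perfusion over [0, t_h] vs. whole cycle.

    Models the pulse as piecewise linear (diastolic point → peak → halftime
    point → next diastolic point).  With PH′ = (SBP+DBP)/2 − CVP and
    β = PP/(4·PH′),

        λ = [1 + β(1 − t_p/t_h)] / [1 − β(T + t_p − 2t_h)/T].

    λ is 1 for a flat pulse and ≈1.1 for normal contours, because perfusion
    pressure early in the cycle exceeds the cycle average.
    """
    if not 0 < t_p < t_h < period:
        raise ValueError("need 0 < t_p < t_h < period")
    if sbp < dbp:
        raise ValueError("need sbp >= dbp")
    if cvp >= dbp:
        raise ValueError("cvp must be below diastolic pressure")
    ph_prime = 0.5 * (sbp + dbp) - cvp
    beta = (sbp - dbp) / (4.0 * ph_prime)
    numer = 1.0 + beta * (1.0 - t_p / t_h)
    denom = 1.0 - beta * (period + t_p - 2.0 * t_h) / period
    if denom <= 0:
        raise ValueError("pathological timing: denominator of λ is not positive")
    return numer / denom


def halftime_sv(c_total: float, pp: float, t_h: float, period: float,
                lambda_: float = 1.1) -> float:
    """Halftime-method stroke volume SV = C·PP / (2·(1 − λ·t_h/T)), ml.

    At the halftime point the aortic pressure has fallen midway between
    systolic and diastolic, so the portion of the beat still stored in the
    aorta is C·(PP/2); the rest, λ·CO·t_h, has already run off into the
    periphery.  The volume balance SV = C·PP/2 + λ·(SV/T)·t_h solved for SV
    gives the formula.
    """
    if lambda_ * t_h >= period:
        raise ValueError("λ·t_h >= period: runoff would exceed the cycle")
    return c_total * pp / (2.0 * (1.0 - lambda_ * t_h / period))


def small_animal_sv(c_total: float, pp: float, t_e: float, period: float) -> float:
    """Ejection-time variant SV = C·PP/(1 − t_e/T), ml.

    Valid when the pulse traverses the whole aorta within the ejection time
    t_e (small animals), so pressures equilibrate by end-ejection.
    """
    if t_e >= period:
        raise ValueError("t_e must be shorter than the period")
    return c_total * pp / (1.0 - t_e / period)


def nonlinear_correction_exact(pp: float, dbp: float, p_ref: float = 80.0,
                               strict: bool = False) -> float:
    """Exact Fung-compliance correction ratio SV′/SV.

    For an aorta whose dynamic compliance falls as 1/(P + P_ref), the volume
    between two pressures follows a logarithmic law, and the stroke volume
    computed with the PWV-derived diastolic compliance must be scaled by

        (2(DBP+P_ref)/PP) · ln(1 + PP/(2(DBP+P_ref))) ,

    which → 1 as PP → 0 and falls below 1 for large pulse pressures.
    """
    if dbp <= 0 or p_ref <= 0:
        raise ValueError("dbp and p_ref must be positive")
    if pp <= 0:
        if strict:
            raise ValueError("pp must be positive")
        return 1.0
    x = pp / (2.0 * (dbp + p_ref))
    return math.log1p(x) / x


def nonlinear_correction_series(pp: float, dbp: float, p_ref: float = 80.0) -> float:
    """Two-term series form of the correction, 1 − PP/(4(DBP+P_ref))."""
    if dbp <= 0 or p_ref <= 0:
        raise ValueError("dbp and p_ref must be positive")
    return 1.0 - pp / (4.0 * (dbp + p_ref))


def cardiac_output(sv: float, period: float) -> float:
    """Cardiac output = stroke volume / cycle length, ml/s."""
    if period <= 0:
        raise ValueError("period must be positive")
    return sv / period


def cardiac_output_l_min(sv: float, period: float) -> float:
    return cardiac_output(sv, period) * 60.0 / 1000.0


# ----------------------------------------------------------------------


def estimate_from_record(rec: SimulationRecord,
                         apply_nonlinear: bool = False,
                         cvp: float = 0.0,
                         l_eff: float | None = None,
                         taper_factor: float = 1.0,
                         p_ref: float = 80.0,
                         pressure_channel: str = "p_a5",
                         timing_channel: str = "r_a5",
                         pwv_channels: tuple[str, str] = ("p_a2", "p_a8"),
                         pwv_distance_cm: float = 30.0) -> SVEstimate:
    """Full noninvasive pipeline applied to one simulation record.

    PWV from the foot-to-foot transit between segments 2 and 8; mid-aortic
    area from diastolic radii; Bramwell-Hill total compliance with the
    actual aortic length; timing (t_p, t_h, T) from the mid-aortic radius
    contour (the ultrasound surrogate) and pressures from the mid-aortic
    pressure channel; λ per run; halftime-method SV, optionally scaled by
    the exact Fung nonlinearity correction.
    """
    params = rec.params
    if l_eff is None:
        if params is None:
            raise ValueError("l_eff required when the record has no parameter echo")
        l_eff = params.seg_length * 10.0
    period_hint = params.period if params is not None else None

    def _stage(name, fn):
        try:
            return fn()
        except ValueError as exc:
            raise ValueError(f"[{name}] {exc}") from exc

    pwv = _stage("pulse_wave_velocity", lambda: pulse_wave_velocity(
        rec, *pwv_channels, distance_cm=pwv_distance_cm, period=period_hint))
    a_mid = _stage("mid_aortic_area", lambda: mid_aortic_area(rec))
    density = params.blood_density if params is not None else 1.03
    c_total = compliance_from_pwv(pwv, a_mid, l_eff, density, taper_factor)
    compliance = ComplianceEstimate(
        pwv=pwv, a_mid=a_mid, l_eff=l_eff,
        aortic_volume=a_mid * l_eff * taper_factor,
        density=density, c_total=c_total, taper_factor=taper_factor)

    timing = _stage("timing_features", lambda: average_features(
        rec.channel(timing_channel),
        period_hint if period_hint is not None else 1.0))
    pressures = _stage("pressure_features", lambda: average_features(
        rec.channel(pressure_channel),
        period_hint if period_hint is not None else timing.period))

    lam = _stage("lambda_correction", lambda: lambda_correction(
        timing.t_p, timing.t_h, timing.period,
        pressures.sbp, pressures.dbp, cvp))
    sv_unc = _stage("halftime_sv", lambda: halftime_sv(
        c_total, pressures.pp, timing.t_h, timing.period, lam))
    ratio = (nonlinear_correction_exact(pressures.pp, pressures.dbp, p_ref)
             if apply_nonlinear else 1.0)
    sv_corr = sv_unc * ratio
    return SVEstimate(
        lambda_=lam, sv_uncorrected=sv_unc, correction_ratio=ratio,
        sv_corrected=sv_corr, cardiac_output=cardiac_output(sv_corr, timing.period),
        cvp=cvp, compliance=compliance,
        t_h=timing.t_h, t_p=timing.t_p, period=timing.period,
        pp=pressures.pp, sbp=pressures.sbp, dbp=pressures.dbp,
    )
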