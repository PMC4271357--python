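"""Pulse-contour feature extraction.

Everything the stroke-volume estimator needs from sampled waveforms:
beat boundaries, systolic/diastolic levels, the foot of the upstroke
(for transit-time pulse wave velocity), time-to-peak t_p, halftime t_h,
and the diastolic mid-aortic cross-section.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .simulator import SimulationRecord

__all__ = [
    "PressureWaveform", "PulseFeatures", "segment_beats", "detect_foot",
    "foot_times", "pulse_wave_velocity", "extract_features",
    "average_features", "mid_aortic_area",
]


@dataclass(frozen=True)
class PressureWaveform:
    """One uniformly sampled channel (pressure in mmHg or radius in cm)."""

    sample_times: np.ndarray
    values: np.ndarray
    channel_label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.sample_times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "sample_times", t)
        object.__setattr__(self, "values", v)
        if t.shape != v.shape or t.ndim != 1 or len(t) < 2:
            raise ValueError("need matching 1-D time/value arrays with >= 2 samples")
        steps = np.diff(t)
        if np.ptp(steps) > 1e-9:
            raise ValueError("sampling must be uniform (within 1 ns)")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            raise ValueError("non-finite samples")

    @property
    def dt(self) -> float:
        return float(self.sample_times[1] - self.sample_times[0])


@dataclass(frozen=True)
class PulseFeatures:
    """Levels and characteristic times of one beat.

    t_p is onset-to-peak, t_h the halftime (onset until the contour last
    falls through the systolic/diastolic midpoint before the next beat),
    both measured from the beat onset; ph is the half level (SBP+DBP)/2.
    """

    sbp: float
    dbp: float
    pp: float
    ph: float
    t_p: float
    t_h: float
    period: float
    foot_time: float
    diastolic_level: float

    def __post_init__(self) -> None:
        if not (self.dbp < self.ph < self.sbp):
            raise ValueError("need dbp < half level < sbp")
        if not (0 < self.t_p < self.t_h < self.period):
            raise ValueError("need 0 < t_p < t_h < period")


def segment_beats(w: PressureWaveform, period: float) -> list[tuple[int, int]]:
    """Locate beats: half-open index windows [onset, next onset).

    Onsets are the diastolic minima, found as peaks of the negated signal
    separated by roughly one cardiac period.  Only complete beats (bounded
    by two detected onsets) are returned.
    """
    v = w.values
    if np.ptp(v) == 0:
        raise ValueError(f"constant signal in channel {w.channel_label!r}: no beats")
    distance = max(2, int(0.7 * period / w.dt))
    prominence = 0.02 * np.ptp(v)
    minima, _ = find_peaks(-v, distance=distance, prominence=prominence)
    if len(minima) < 2:
        raise ValueError(
            f"fewer than two diastolic minima found in {w.channel_label!r}; "
            "waveform must span more than one period"
        )
    return [(int(minima[i]), int(minima[i + 1])) for i in range(len(minima) - 1)]


def detect_foot(w: PressureWaveform, beat: tuple[int, int],
                dbp: float, pp: float) -> float:
    """Time of the pulse foot: first upward crossing of DBP + 2% of PP.

    The threshold sits just above the diastolic level, marking the very
    beginning of the upstroke, insensitive to reflected-wave augmentation.
    Linear interpolation between the bracketing samples; exact hits resolve
    to the earlier sample time.
    """
    i0, i1 = beat
    thresh = dbp + 0.02 * pp
    t = w.sample_times
    v = w.values
    for i in range(i0, i1):
        if v[i] == thresh:
            return float(t[i])
        if v[i] < thresh <= v[i + 1]:
            frac = (thresh - v[i]) / (v[i + 1] - v[i])
            return float(t[i] + frac * (t[i + 1] - t[i]))
    raise ValueError(f"no upstroke crossing of {thresh:.4g} within beat {beat}")


def extract_features(w: PressureWaveform, beat: tuple[int, int]) -> PulseFeatures:
    """Levels and times of one beat window.

    DBP is the value at the beat onset (the pre-upstroke minimum), SBP the
    beat maximum.  The halftime t_h is found by scanning backwards from just
    before the next onset for the last downward crossing of the half level,
    avoiding any large oscillations right after the peak.
    """
    i0, i1 = beat
    t = w.sample_times
    v = w.values
    dbp = float(v[i0])
    seg = v[i0:i1]
    ipk = i0 + int(np.argmax(seg))
    sbp = float(v[ipk])
    if sbp <= dbp:
        raise ValueError("degenerate beat: no pulse amplitude")
    pp = sbp - dbp
    half = 0.5 * (sbp + dbp)
    t_p = float(t[ipk] - t[i0])

    # backward scan for the last downward crossing of the half level
    t_h = None
    for i in range(i1 - 2, ipk - 1, -1):
        if v[i] >= half > v[i + 1]:
            if v[i] == half:
                t_cross = t[i]
            else:
                frac = (v[i] - half) / (v[i] - v[i + 1])
                t_cross = t[i] + frac * (t[i + 1] - t[i])
            t_h = float(t_cross - t[i0])
            break
    if t_h is None:
        raise ValueError("contour never falls through the half level after the peak")

    period = float(t[i1] - t[i0])
    foot = detect_foot(w, beat, dbp, pp)
    return PulseFeatures(sbp=sbp, dbp=dbp, pp=pp, ph=half, t_p=t_p, t_h=t_h,
                         period=period, foot_time=foot, diastolic_level=dbp)


def average_features(w: PressureWaveform, period: float) -> PulseFeatures:
    """Arithmetic mean of per-beat features over all complete beats."""
    beats = segment_beats(w, period)
    feats = [extract_features(w, b) for b in beats]
    mean = lambda attr: float(np.mean([getattr(f, attr) for f in feats]))
    return PulseFeatures(
        sbp=mean("sbp"), dbp=mean("dbp"), pp=mean("pp"), ph=mean("ph"),
        t_p=mean("t_p"), t_h=mean("t_h"), period=mean("period"),
        foot_time=feats[0].foot_time, diastolic_level=mean("diastolic_level"),
    )


def foot_times(w: PressureWaveform, period: float) -> list[float]:
    """Foot time of every complete beat in the waveform."""
    out = []
    for beat in segment_beats(w, period):
        f = extract_features(w, beat)
        out.append(f.foot_time)
    return out


def pulse_wave_velocity(rec: SimulationRecord,
                        proximal: str = "p_a2", distal: str = "p_a8",
                        distance_cm: float = 30.0,
                        period: float | None = None) -> float:
    """Foot-to-foot pulse wave velocity between two aortic sites, cm/s.

    The transit time between the upstroke feet of the proximal and distal
    channels is divided into the center-to-center distance (30 cm for
    segments 2 and 8, six segments of 5 cm), averaged over complete beats.
    """
    return pwv_between(rec.channel(proximal), rec.channel(distal),
                       distance_cm,
                       period if period is not None else rec.params.period)


def pwv_between(w_prox: PressureWaveform, w_dist: PressureWaveform,
                distance_cm: float, period: float) -> float:
    """Foot-to-foot PWV from two already-extracted channels, cm/s."""
    f_prox = foot_times(w_prox, period)
    f_dist = foot_times(w_dist, period)
    velocities = []
    for fp in f_prox:
        later = [fd for fd in f_dist if fp < fd < fp + 0.5 * period]
        if later:
            velocities.append(distance_cm / (min(later) - fp))
    if not velocities:
        raise ValueError("no matching proximal/distal foot pairs "
                         "(non-positive or missing transit times)")
    return float(np.mean(velocities))


def mid_aortic_area(rec: SimulationRecord,
                    segments: tuple[int, ...] = (4, 5, 6)) -> float:
    """Diastolic cross-section of the mid aorta, cm².

    The radius is averaged over the diastolic (beat-onset) values of the
    mid-aortic radius channels across all complete beats, emulating an
    ultrasound measurement at the aortic midpoint; returns π·r̄².
    """
    period = rec.params.period
    radii = []
    for m in segments:
        w = rec.channel(f"r_a{m}")
        for i0, _ in segment_beats(w, period):
            radii.append(w.values[i0])
    r_bar = float(np.mean(radii))
    return float(np.pi * r_bar**2)
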