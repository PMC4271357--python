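"""Model parameters for the 12-compartment mock circulation.

The parameter set describes a normal adult human systemic circulation:
a left-ventricular pump compartment, ten aortic segments (aortic root,
brachiocephalic branch, aortic arch, descending thoracic and abdominal
aorta, iliac arteries) connected by small inline resistances and blood-column
inertances, nine systemic runoff resistances, and a lumped venous reservoir.
Units are mmHg, ml and seconds throughout.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: dyn/cm^2 per mmHg — the single CGS-to-clinical conversion constant.
MMHG_CGS = 1333.22

N_SEGMENTS = 10

#: junction j carries flow i_aj from segment UPSTREAM[j] to DOWNSTREAM[j].
#: Flow path: pump -> a0 -> a2; a2 feeds the brachiocephalic dead-end a1 and
#: the descending chain a3 -> ... -> a9.
UPSTREAM = np.array([0, 2, 2, 3, 4, 5, 6, 7, 8])
DOWNSTREAM = np.array([2, 1, 3, 4, 5, 6, 7, 8, 9])

#: junctions feeding the narrow brachiocephalic (a1) and iliac (a9) trees
#: carry the larger branch resistance.
BRANCH_JUNCTIONS = (1, 8)

#: segments drained by the nine systemic runoff resistances (a0 has none).
RUNOFF_SEGMENTS = tuple(range(1, 10))


def _positive(name: str, value: float) -> None:
    if not np.all(np.asarray(value) > 0):
        raise ValueError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter set for a simulation run.

    Defaults reproduce the normal-adult parameterisation: total systemic
    resistance 95/83.3 ≈ 1.14 mmHg/(ml/s) split over nine parallel branches,
    total aortic compliance 1.3 ml/mmHg split over ten segments, heart rate
    80/min, peak pump squeeze 120 mmHg.
    """

    r_systemic_each: float = 10.3      # mmHg/(ml/s), each of 9 runoff branches
    r_pump_in: float = 0.01            # mmHg/(ml/s), inflow (mitral) valve
    r_pump_out: float = 0.01           # mmHg/(ml/s), outflow (aortic) valve
    r_inline: float = 0.005            # mmHg/(ml/s), ordinary aortic junctions
    r_branch: float = 0.1              # mmHg/(ml/s), brachiocephalic & iliac
    c_seg_ref: float | tuple = 0.13    # ml/mmHg, per segment (scalar or 10-vector)
    c_venous: float = 10.0             # ml/mmHg
    c_pump: float = 12.0               # ml/mmHg, diastolic pump compliance
    seg_length: float = 5.0            # cm
    seg_radius_init: float = 1.5       # cm
    venous_vol_init: float = 2000.0    # ml
    pump_vol_init: float = 200.0       # ml
    frequency: float = 4.0 / 3.0       # Hz (80/min)
    p_max: float = 120.0               # mmHg, peak external pump pressure
    dt: float = 1e-5                   # s, Euler step
    startprint: float = 1.5            # s, recording window start
    stopprint: float = 3.0             # s, recording window end
    skipnumber: int = 99               # samples skipped between saved points
    p_init: float = 10.0               # mmHg, mean circulatory pressure
    blood_density: float = 1.03        # g/ml
    compliance_mode: str = "linear"    # "linear" | "fung"
    p_ref: float = 80.0                # mmHg, Fung reference pressure

    def __post_init__(self) -> None:
        for name in ("r_systemic_each", "r_pump_in", "r_pump_out", "r_inline",
                     "r_branch", "c_venous", "c_pump", "seg_length",
                     "seg_radius_init", "venous_vol_init", "pump_vol_init",
                     "frequency", "dt"):
            _positive(name, getattr(self, name))
        _positive("c_seg_ref", self.c_seg_array())
        if self.p_max < 0:
            raise ValueError("p_max must be non-negative")
        if not (0 < self.startprint < self.stopprint):
            raise ValueError("need stopprint > startprint > 0")
        if self.skipnumber < 0:
            raise ValueError("skipnumber must be >= 0")
        if not (0.25 <= self.blood_density <= 2.0):
            raise ValueError("blood_density outside sanity range [0.25, 2]")
        if self.compliance_mode not in ("linear", "fung"):
            raise ValueError(f"unknown compliance_mode {self.compliance_mode!r}")
        _positive("p_ref", self.p_ref)
        beats = (self.stopprint - self.startprint) * self.frequency
        if beats < 1 or abs(beats - round(beats)) > 1e-6:
            warnings.warn(
                f"recording window spans {beats:.4g} cardiac periods; "
                "beat-averaged quantities assume a whole number >= 1",
                stacklevel=2,
            )

    # ------------------------------------------------------------------
    @property
    def omega(self) -> float:
        """Angular frequency of the pump drive, rad/s."""
        return 2.0 * math.pi * self.frequency

    @property
    def period(self) -> float:
        """Cardiac cycle length T, s."""
        return 1.0 / self.frequency

    @property
    def seg_volume_init(self) -> float:
        """Initial volume of one aortic segment, ml (cylinder at rest)."""
        return math.pi * self.seg_radius_init**2 * self.seg_length

    @property
    def n_beats_recorded(self) -> int:
        return int(round((self.stopprint - self.startprint) * self.frequency))

    @property
    def sample_dt(self) -> float:
        """Interval between saved samples, s."""
        return self.dt * (self.skipnumber + 1)

    def c_seg_array(self) -> np.ndarray:
        """Per-segment reference compliance as a length-10 vector."""
        c = np.asarray(self.c_seg_ref, dtype=float)
        if c.ndim == 0:
            return np.full(N_SEGMENTS, float(c))
        if c.shape != (N_SEGMENTS,):
            raise ValueError("c_seg_ref must be a scalar or a 10-vector")
        return c.copy()

    def junction_resistances(self) -> np.ndarray:
        """Resistance of each of the nine inline junctions, mmHg/(ml/s)."""
        r = np.full(len(UPSTREAM), self.r_inline)
        for j in BRANCH_JUNCTIONS:
            r[j] = self.r_branch
        return r

    def replace(self, **changes) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def scale_compliance(self, scale: float) -> "ModelParameters":
        """Return parameters with every aortic segment compliance scaled."""
        c = self.c_seg_array() * scale
        if np.ptp(c) == 0:
            return self.replace(c_seg_ref=float(c[0]))
        return self.replace(c_seg_ref=tuple(c))

    # ------------------------------------------------------------------
    # Config-file round trip, using field names patterned on the standard
    # parameter table (Rs, Ri, Ro, ...).
    _KEYMAP = (
        ("Rs", "r_systemic_each"), ("Ri", "r_pump_in"), ("Ro", "r_pump_out"),
        ("Ra_inline", "r_inline"), ("Ra_branch", "r_branch"),
        ("Ca", "c_seg_ref"), ("Cv", "c_venous"), ("Cp", "c_pump"),
        ("SegLength", "seg_length"), ("SegRadius", "seg_radius_init"),
        ("VenousVol", "venous_vol_init"), ("PumpVol", "pump_vol_init"),
        ("frequency", "frequency"), ("Pmax", "p_max"), ("dt", "dt"),
        ("startprint", "startprint"), ("stopprint", "stopprint"),
        ("skipnumber", "skipnumber"), ("Pinit", "p_init"),
        ("density", "blood_density"), ("compliance_mode", "compliance_mode"),
        ("Pref", "p_ref"),
    )

    def to_dict(self) -> dict:
        out = {}
        for key, attr in self._KEYMAP:
            v = getattr(self, attr)
            if isinstance(v, tuple):
                v = list(v)
            out[key] = v
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        lookup = dict(cls._KEYMAP)
        kwargs = {}
        for key, value in d.items():
            if key not in lookup:
                raise KeyError(f"unknown config key {key!r}")
            if isinstance(value, list):
                value = tuple(value)
            kwargs[lookup[key]] = value
        return cls(**kwargs)


def load_config(path: str | Path) -> ModelParameters:
    """Load a YAML or JSON parameter file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        import yaml

        data = yaml.safe_load(text)
    return ModelParameters.from_dict(data)


def save_config(params: ModelParameters, path: str | Path) -> None:
    path = Path(path)
    data = params.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        import yaml

        path.write_text(yaml.safe_dump(data, sort_keys=False))


# ----------------------------------------------------------------------
# Parameter derivations for the normal adult (used to justify the defaults).

def derive_total_systemic_resistance(map_mmhg: float = 95.0,
                                     co_ml_s: float = 83.3) -> float:
    """Total systemic vascular resistance = mean arterial pressure / CO.

    With the normal MAP of 95 mmHg and cardiac output of 5 l/min
    (83.3 ml/s) this gives 1.14 mmHg/(ml/s); each of the nine parallel
    runoff branches is nine times that.
    """
    _positive("co_ml_s", co_ml_s)
    return map_mmhg / co_ml_s


def derive_total_aortic_compliance(volume_per_beat: float = 83.3,
                                   pp: float = 40.0,
                                   t_e: float = 0.28,
                                   period: float = 0.75) -> float:
    """Normal total aortic compliance from the ejection-time windkessel relation.

    C = (V/PP)·(1 − t_e/T): the pulse-pressure step receives the ejected
    volume minus the runoff during ejection.  With nominal values this is
    2.08·(1 − 0.28/0.75) ≈ 1.3 ml/mmHg, i.e. 0.13 ml/mmHg per segment.
    """
    if not 0 < t_e < period:
        raise ValueError("need 0 < t_e < period")
    _positive("pp", pp)
    return (volume_per_beat / pp) * (1.0 - t_e / period)
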