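"""Longitudinal relaxivity of dissolved oxygen: model core.

Dissolved molecular oxygen is paramagnetic and adds linearly to the
longitudinal relaxation rate of a simple fluid:

    R1 = R1,0 + r1Ox * pO2

where ``r1Ox`` (s^-1/mmHg) is the relaxivity of oxygen in that fluid.
The relaxivity itself disperses with the main magnetic field B0 and
drifts linearly with temperature; this module implements the empirical
four-parameter model

    r1Ox(B0, T) = C1 / (1 + C2 * B0^2) + C3 + CTemp * T

with r1Ox on the 1e-4 s^-1/mmHg scale, B0 in tesla and T in degrees
Celsius.  The Lorentzian term mirrors the magnetic relaxation dispersion
of water protons coupled to the oxygen electron spin; C3 is a
field-independent floor and CTemp the linear temperature slope.

Model parameters are kept on the 1e-4 scale (the scale on which the
constants are O(1)); the linear R1/pO2 relation uses SI s^-1/mmHg.
Conversion between the two scales is an explicit, named operation.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ModelParameters",
    "ConditionPoint",
    "LinearR1Relation",
    "CALIBRATED_B0_RANGE",
    "CALIBRATED_TEMP_RANGE",
    "PARAMETER_NAMES",
    "CalibrationRangeWarning",
    "NegativePO2Warning",
    "relaxivity",
    "dispersion_curve",
    "r1_with_oxygen",
    "infer_pO2",
    "delta_t1",
    "relaxivity_to_si",
    "relaxivity_from_si",
    "kelvin_to_celsius",
]

#: Scale factor between the internal 1e-4 s^-1/mmHg relaxivity scale and SI.
_SCALE = 1e-4

#: Field-strength range (tesla) spanned by the calibration data.
CALIBRATED_B0_RANGE = (0.011, 8.45)
#: Temperature range (deg C) spanned by the calibration data.
CALIBRATED_TEMP_RANGE = (21.0, 40.0)

PARAMETER_NAMES = ("c1", "c2", "c3", "c_temp")

PARAMETER_UNITS = {
    "c1": "1e-4 s^-1/mmHg",
    "c2": "T^-2",
    "c3": "1e-4 s^-1/mmHg",
    "c_temp": "1e-4 s^-1/mmHg/degC",
}


class CalibrationRangeWarning(UserWarning):
    """A query point lies outside the calibrated (B0, temperature) range."""


class NegativePO2Warning(UserWarning):
    """A measured R1 below the zero-oxygen baseline implies negative pO2."""


@dataclass(frozen=True)
class ModelParameters:
    """Constants of the dispersion model, on the 1e-4 s^-1/mmHg scale.

    ``active_mask`` supports nested reduced models: an inactive parameter
    is treated as fixed at zero (the field is never deleted).  ``c1`` is
    always active — a pure-offset model is expressed by masking ``c2``
    so the Lorentzian degenerates to the constant ``c1``.
    """

    c1: float
    c2: float
    c3: float
    c_temp: float
    active_mask: tuple[bool, bool, bool, bool] = (True, True, True, True)

    def __post_init__(self) -> None:
        if not self.active_mask[0]:
            raise ValueError("c1 must always be active")
        if len(self.active_mask) != 4:
            raise ValueError("active_mask must have four entries")
        if self.c1 < 0 or self.c2 < 0:
            raise ValueError(
                "c1 and c2 must be non-negative for a physically "
                "decreasing dispersion"
            )

    def as_array(self) -> np.ndarray:
        """All four constants with inactive entries zeroed, in canonical order."""
        values = np.array([self.c1, self.c2, self.c3, self.c_temp], dtype=float)
        values[~np.asarray(self.active_mask)] = 0.0
        return values

    def active_values(self) -> np.ndarray:
        """The free (active) constants only, in canonical order."""
        return self.as_array()[np.asarray(self.active_mask)]

    @property
    def k(self) -> int:
        """Number of free parameters."""
        return int(sum(self.active_mask))

    @classmethod
    def from_active(
        cls, values: Sequence[float], active_mask: Sequence[bool]
    ) -> "ModelParameters":
        """Rebuild full parameters from the free values of a masked model."""
        mask = tuple(bool(m) for m in active_mask)
        full = np.zeros(4)
        full[np.asarray(mask)] = np.asarray(values, dtype=float)
        return cls(*full, active_mask=mask)

    def with_mask(self, active_mask: Sequence[bool]) -> "ModelParameters":
        return replace(self, active_mask=tuple(bool(m) for m in active_mask))

    def to_dict(self) -> dict:
        return {
            "parameters": {
                name: {"value": float(v), "units": PARAMETER_UNITS[name]}
                for name, v in zip(PARAMETER_NAMES, (self.c1, self.c2, self.c3, self.c_temp))
            },
            "active_mask": list(self.active_mask),
            "scale": "1e-4 s^-1/mmHg",
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, payload: dict) -> "ModelParameters":
        values = [payload["parameters"][name]["value"] for name in PARAMETER_NAMES]
        mask = tuple(bool(m) for m in payload.get("active_mask", (True,) * 4))
        return cls(*values, active_mask=mask)

    @classmethod
    def from_json(cls, text: str) -> "ModelParameters":
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class ConditionPoint:
    """A (field strength, temperature) query point: tesla, deg C."""

    b0: float
    temperature: float

    def __post_init__(self) -> None:
        if self.b0 < 0:
            raise ValueError("b0 must be non-negative")


@dataclass(frozen=True)
class LinearR1Relation:
    """The linear R1 / pO2 calibration of a fluid, on the SI scale.

    r1_0    baseline relaxation rate without oxygen, s^-1
    r1ox    relaxivity of oxygen, s^-1/mmHg
    """

    r1_0: float
    r1ox: float

    def __post_init__(self) -> None:
        if self.r1_0 <= 0:
            raise ValueError("r1_0 must be positive")
        if self.r1ox <= 0:
            raise ValueError("r1ox must be positive")


def relaxivity_to_si(value_1e4):
    """Convert relaxivity from the 1e-4 s^-1/mmHg scale to SI s^-1/mmHg."""
    return np.asarray(value_1e4, dtype=float) * _SCALE


def relaxivity_from_si(value_si):
    """Convert relaxivity from SI s^-1/mmHg to the 1e-4 s^-1/mmHg scale."""
    return np.asarray(value_si, dtype=float) / _SCALE


def kelvin_to_celsius(temperature_k: float) -> float:
    return temperature_k - 273.15


def _check_calibrated_range(b0, temperature) -> None:
    b0 = np.asarray(b0, dtype=float)
    temperature = np.asarray(temperature, dtype=float)
    lo_b, hi_b = CALIBRATED_B0_RANGE
    lo_t, hi_t = CALIBRATED_TEMP_RANGE
    if np.any(b0 < lo_b) or np.any(b0 > hi_b):
        warnings.warn(
            f"field strength outside the calibrated range [{lo_b}, {hi_b}] T; "
            "the model is extrapolating (below the low-field end the true "
            "dispersion is expected to curve back down)",
            CalibrationRangeWarning,
            stacklevel=3,
        )
    if np.any(temperature < lo_t) or np.any(temperature > hi_t):
        warnings.warn(
            f"temperature outside the calibrated range [{lo_t}, {hi_t}] C; "
            "the model is extrapolating",
            CalibrationRangeWarning,
            stacklevel=3,
        )


def relaxivity(params: ModelParameters, pt: ConditionPoint | None = None, *,
               b0=None, temperature=None, warn_out_of_range: bool = False):
    """Evaluate the dispersion model at one or many (B0, T) points.

    Returns r1Ox on the 1e-4 s^-1/mmHg scale.  Accepts either a
    :class:`ConditionPoint` or explicit ``b0``/``temperature`` arrays.
    Inactive parameters contribute zero.  With ``warn_out_of_range``,
    points outside the calibrated field/temperature range raise a
    :class:`CalibrationRangeWarning` (the value is still returned — the
    model extrapolates but was not calibrated there).
    """
    if pt is not None:
        b0, temperature = pt.b0, pt.temperature
    if b0 is None or temperature is None:
        raise TypeError("provide a ConditionPoint or both b0 and temperature")
    b0 = np.asarray(b0, dtype=float)
    temperature = np.asarray(temperature, dtype=float)
    if np.any(b0 < 0):
        raise ValueError("b0 must be non-negative")
    if warn_out_of_range:
        _check_calibrated_range(b0, temperature)
    c1, c2, c3, c_temp = params.as_array()
    value = c1 / (1.0 + c2 * b0**2) + c3 + c_temp * temperature
    return value if value.ndim else float(value)


def dispersion_curve(params: ModelParameters, b0_grid, temperature: float,
                     **kwargs) -> np.ndarray:
    """Relaxivity along a field-strength grid at fixed temperature.

    Returns a (n, 2) array of (b0, r1Ox) pairs, e.g. for profile plots.
    """
    b0_grid = np.atleast_1d(np.asarray(b0_grid, dtype=float))
    if b0_grid.size == 0:
        raise ValueError("b0 grid must be non-empty")
    values = relaxivity(params, b0=b0_grid, temperature=temperature, **kwargs)
    return np.column_stack([b0_grid, values])


def r1_with_oxygen(rel: LinearR1Relation, pO2) -> float:
    """Longitudinal relaxation rate (s^-1) at a given oxygen partial pressure."""
    pO2 = np.asarray(pO2, dtype=float)
    if np.any(pO2 < 0):
        raise ValueError("pO2 must be non-negative")
    out = rel.r1_0 + rel.r1ox * pO2
    return out if out.ndim else float(out)


def infer_pO2(rel: LinearR1Relation, measured_r1) -> float:
    """Invert the linear calibration: pO2 = (R1 - R1,0) / r1Ox, in mmHg.

    A measurement below the zero-oxygen baseline yields a negative pO2
    and a :class:`NegativePO2Warning`; the value is returned unclamped so
    the caller can see the magnitude of the inconsistency.
    """
    measured_r1 = np.asarray(measured_r1, dtype=float)
    pO2 = (measured_r1 - rel.r1_0) / rel.r1ox
    if np.any(pO2 < 0):
        warnings.warn(
            "measured R1 below the zero-oxygen baseline; returning negative pO2",
            NegativePO2Warning,
            stacklevel=2,
        )
    return pO2 if pO2.ndim else float(pO2)


def delta_t1(initial_t1: float, r1ox: float, delta_pO2: float) -> float:
    """T1 shortening (ms) produced by an oxygen increase of ``delta_pO2`` mmHg.

    Because pO2 is linear in R1 = 1000/T1(ms), not in T1, the T1 change
    depends on the starting T1:

        dT1 = T1 - 1000 / (1000/T1 + r1ox * dpO2)

    with ``r1ox`` in SI s^-1/mmHg.
    """
    if initial_t1 <= 0:
        raise ValueError("initial_t1 must be positive")
    r1_new = 1000.0 / initial_t1 + r1ox * delta_pO2
    return initial_t1 - 1000.0 / r1_new
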