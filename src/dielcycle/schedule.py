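"""Modulated diel light schedules.

A cyclostat imposes a sinusoidally modulated light/dark cycle: irradiance in
each band (PAR, UV-A, UV-B) follows a half-sine between dawn and dusk and is
zero during the dark period.  The schedule entrains the simulated population
and labels scenarios; the cell-cycle model itself is gated by clock time, not
by instantaneous dose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LightSchedule",
    "irradiance_at",
    "E_MAX_PAR_HL",
    "NOMINAL_E_MAX_PAR",
    "E_MAX_PAR_LL",
    "E_MAX_UVA",
    "E_MAX_UVB",
]

#: Measured midday PAR maximum of the high-light regime (umol photons m-2 s-1).
E_MAX_PAR_HL = 875.0
#: Nominal midday PAR setting of the same regime; the measured value is preferred.
NOMINAL_E_MAX_PAR = 900.0
#: Midday PAR maximum of the low-light regime.
E_MAX_PAR_LL = 100.0
#: Midday UV-A (320-400 nm) maximum of the UV-supplemented regime (W m-2).
E_MAX_UVA = 7.59
#: Midday UV-B (280-320 nm) maximum of the UV-supplemented regime (W m-2).
E_MAX_UVB = 0.57

BANDS = ("PAR", "UVA", "UVB")


@dataclass(frozen=True)
class LightSchedule:
    """Half-sine modulated diel irradiance program.

    Parameters
    ----------
    t_dawn : float
        Clock hour of virtual sunrise (hours since midnight).
    photoperiod_h : float
        Length of the light period in hours; must lie in (0, 24).
    e_max_par : float
        Midday PAR maximum, umol photons m-2 s-1.
    e_max_uva, e_max_uvb : float
        Midday UV-A / UV-B maxima, W m-2 (0 for UV-free regimes).
    """

    t_dawn: float = 6.0
    photoperiod_h: float = 12.0
    e_max_par: float = E_MAX_PAR_HL
    e_max_uva: float = 0.0
    e_max_uvb: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.photoperiod_h < 24.0:
            raise ValueError(
                f"photoperiod_h must be in (0, 24), got {self.photoperiod_h}"
            )
        if not 0.0 <= self.t_dawn < 24.0:
            raise ValueError(f"t_dawn must be in [0, 24), got {self.t_dawn}")
        for band in BANDS:
            if self.e_max(band) < 0:
                raise ValueError(f"negative irradiance maximum for {band}")

    @property
    def t_dusk(self) -> float:
        """Clock hour of the light-to-dark transition (LDT), mod 24."""
        return (self.t_dawn + self.photoperiod_h) % 24.0

    def e_max(self, band: str) -> float:
        try:
            return {
                "PAR": self.e_max_par,
                "UVA": self.e_max_uva,
                "UVB": self.e_max_uvb,
            }[band]
        except KeyError:
            raise ValueError(f"unknown band {band!r}; expected one of {BANDS}")


def irradiance_at(t, schedule: LightSchedule, band: str = "PAR"):
    """Irradiance at clock time ``t`` (hours) for one band of a schedule.

    Inside the photoperiod the irradiance is
    ``E(t) = e_max * sin(pi * (t - t_dawn) / photoperiod_h)``;
    outside it is exactly 0.  ``t`` may be a scalar or an array and is
    interpreted mod 24 h, so multi-day absolute times are accepted.
    """
    e_max = schedule.e_max(band)
    t = np.asarray(t, dtype=float)
    phase = (t - schedule.t_dawn) % 24.0
    inside = phase < schedule.photoperiod_h
    value = np.where(
        inside,
        e_max * np.sin(np.pi * np.clip(phase, 0.0, schedule.photoperiod_h)
                       / schedule.photoperiod_h),
        0.0,
    )
    if value.ndim == 0:
        return float(value)
    return value
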