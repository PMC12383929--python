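"""Evaporative water loss from the exposed tear film.

Evaporation is modeled as a constant calibrated rate (default 0.2 µL/min,
the mean evaporative rate reported for dry-eye patients) applied to the
exposed tear film only while the eye is open; the lids cover the film during
closure and deposition, so the flux is zeroed there.  Evaporation removes
water only — osmoles stay behind, so tear-film osmolarity rises during the
interblink.

The two calibration coefficients that tie the underlying breakup-time flux
model to this constant rate are retained as metadata on the parameter set;
they are not active physics here.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["EvaporationParams", "evaporation_rate"]


@dataclass(frozen=True)
class EvaporationParams:
    """Evaporation model parameters.

    Attributes
    ----------
    calibrated_rate : float
        Constant open-eye evaporation rate [µL/min].
    pressure_coeff : float
        Pressure-to-evaporative-flux calibration [K/Pa] (metadata).
    pressure_temp_coeff : float
        Pressure/temperature-to-mass-flux calibration [K·m²·s/kg] (metadata).
    active_phases : tuple of str
        Blink-cycle phases during which the flux applies.
    """

    calibrated_rate: float = 0.2
    pressure_coeff: float = 0.1
    pressure_temp_coeff: float = 3.0e4
    active_phases: tuple[str, ...] = ("interblink",)

    def __post_init__(self) -> None:
        if self.calibrated_rate < 0.0:
            raise ValueError("calibrated_rate must be >= 0")


def evaporation_rate(phase: str, params: EvaporationParams) -> float:
    """Evaporative volume-loss rate [µL/min] for the given blink phase.

    Returns ``params.calibrated_rate`` during active (open-eye) phases and
    0 otherwise.
    """
    return params.calibrated_rate if phase in params.active_phases else 0.0
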