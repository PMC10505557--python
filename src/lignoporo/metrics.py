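"""Small derived biomass metrics: green density and percent change."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError

__all__ = ["DensitySample", "green_density", "percent_change"]


@dataclass(frozen=True)
class DensitySample:
    """Inputs for a green-density measurement.

    m_dry_mg : oven-dry mass of the cut, mg.
    area_mm2 : wet cross-sectional area, mm^2.
    thickness_um : wet-thickness replicates (typically 3 positions), um.
    The wet volume is mean(thickness) * area.
    """

    m_dry_mg: float
    area_mm2: float
    thickness_um: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.m_dry_mg <= 0:
            raise DomainError("dry mass must be positive")
        if self.area_mm2 <= 0:
            raise DomainError("area must be positive")
        if not self.thickness_um or any(t <= 0 for t in self.thickness_um):
            raise DomainError("thickness replicates must be positive")

    @property
    def volume_mm3(self) -> float:
        return float(np.mean(self.thickness_um)) * 1e-3 * self.area_mm2


def green_density(sample: DensitySample) -> float:
    """Green density R = m_dry / V_wet in kg m^-3.

    mg/mm^3 equals g/cm^3; the factor 1000 converts to kg m^-3.
    """
    return sample.m_dry_mg / sample.volume_mm3 * 1000.0


def percent_change(treatment: float, control: float) -> float:
    """(treatment - control) / control * 100; the sign follows the treatment."""
    if control == 0:
        raise DomainError("percent change undefined for zero control")
    return (treatment - control) / control * 100.0
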