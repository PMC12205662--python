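"""Hydrostatic pressure drop and wall shear for gravity-driven refreshment.

Media refreshment by pipetting into one reservoir raises a hydrostatic
head h_M over the outlet; assuming fully developed laminar flow in the
tubular channel, the resulting pressure drop and peak wall shear are

    ΔP = ρ · g · h_M            τ_max = ΔP · R / (2 L)

with ρ the medium density, R the channel radius and L its length.  The
shear expression carries a sign fixed by the flow direction; magnitudes
are reported here.  All quantities are SI (Pa out).
"""

from __future__ import annotations

import math
from dataclasses import dataclass


def _require_positive(**kwargs):
    for name, v in kwargs.items():
        if not math.isfinite(v) or v <= 0:
            raise ValueError(f"{name} must be strictly positive and finite, got {v!r}")


@dataclass(frozen=True)
class FlowConditions:
    """Inputs of the hydrostatic shear estimate (SI units)."""

    h_M: float  # m, liquid-level difference reservoir → outlet
    R: float  # m, channel radius
    L: float  # m, channel length
    rho: float = 1000.0  # kg/m³, cell medium
    g: float = 9.81  # m/s²
    volume_added: float | None = None  # μl
    reservoir_diameter: float | None = None  # m

    def __post_init__(self):
        _require_positive(rho=self.rho, g=self.g, R=self.R, L=self.L)
        if self.h_M < 0:
            raise ValueError("h_M must be non-negative")
        if self.R >= self.L:
            raise ValueError("channel radius must be smaller than its length")

    def pressure_drop(self) -> float:
        if self.h_M == 0:
            return 0.0
        return hydrostatic_pressure_drop(self.rho, self.g, self.h_M)

    def max_shear(self) -> float:
        dp = self.pressure_drop()
        return 0.0 if dp == 0 else max_wall_shear(dp, self.R, self.L)


def hydrostatic_pressure_drop(rho: float, g: float, h_M: float) -> float:
    """ΔP = ρ · g · h_M, Pa."""
    _require_positive(rho=rho, g=g, h_M=h_M)
    return rho * g * h_M


def max_wall_shear(delta_P: float, R: float, L: float) -> float:
    """Magnitude of the peak wall shear stress, τ = ΔP · R / (2 L), Pa."""
    _require_positive(delta_P=delta_P, R=R, L=L)
    return delta_P * R / (2.0 * L)


def reservoir_head(volume_added: float, reservoir_diameter: float) -> float:
    """Liquid head (m) from a media volume (μl) in a cylindrical well (m)."""
    _require_positive(volume_added=volume_added, reservoir_diameter=reservoir_diameter)
    volume_m3 = volume_added * 1e-9
    area = math.pi * (reservoir_diameter / 2.0) ** 2
    return volume_m3 / area
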