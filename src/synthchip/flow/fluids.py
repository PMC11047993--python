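"""Fluid properties of the two-phase system.

The continuous phase is the fluorocarbon oil FC-3283; the dispersed
phase is water.  The interfacial tension is not a measured property of
the device and is config-exposed; 0.040 N/m is typical for a
fluorocarbon/water pair without surfactant.  The 135 degree contact
angle models hydrophobic channel walls (measured through the aqueous
phase, so the water is non-wetting).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["FluidPair"]


@dataclass(frozen=True)
class FluidPair:
    """SI-unit fluid pair; derived dimensionless groups as properties."""

    mu_c: float = 1.365e-3   # continuous-phase dynamic viscosity, Pa s
    rho_c: float = 1.82e3    # continuous-phase density, kg/m^3
    mu_d: float = 1.0e-3     # dispersed-phase (water) viscosity, Pa s
    rho_d: float = 1.0e3     # dispersed-phase density, kg/m^3
    sigma: float = 0.040     # interfacial tension, N/m
    theta_wall_deg: float = 135.0  # contact angle at walls, degrees (in water)

    def __post_init__(self) -> None:
        for name in ("mu_c", "rho_c", "mu_d", "rho_d", "sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.theta_wall_deg < 180.0:
            raise ValueError("contact angle must lie strictly between 0 and 180")

    def capillary_number(self, speed_m_s: float = 3e-3) -> float:
        """Ca = mu_c U / sigma — about 1e-4 at the 3 mm/s injection speed."""
        return self.mu_c * speed_m_s / self.sigma

    def reynolds_number(self, speed_m_s: float = 3e-3, length_m: float = 1e-6) -> float:
        """Re at the given reference length (creeping flow: ~4e-3 at 1 µm)."""
        return self.rho_c * speed_m_s * length_m / self.mu_c

    @property
    def viscosity_ratio(self) -> float:
        """mu_d / mu_c (dispersed over continuous)."""
        return self.mu_d / self.mu_c
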