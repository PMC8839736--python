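"""Thermal environment shared by every model in the package.

All mechanics in this package use single-molecule force-spectroscopy units:
forces in pN, lengths in nm, energies in pN·nm.  Boltzmann's constant in
these units is kB = 0.0138065 pN·nm/K, so room temperature (23 °C,
296.15 K) gives kBT ≈ 4.090 pN·nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Boltzmann constant in pN·nm per kelvin.
KB_PN_NM = 0.0138065

#: Default experimental temperature: 23 °C.
ROOM_TEMPERATURE_K = 296.15


@dataclass(frozen=True)
class EnvParams:
    """Temperature and derived thermal energy.

    Parameters
    ----------
    temperature : float
        Absolute temperature in kelvin. Must be positive.
    """

    temperature: float = ROOM_TEMPERATURE_K

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")

    @property
    def kBT(self) -> float:
        """Thermal energy kB·T in pN·nm."""
        return KB_PN_NM * self.temperature

    @property
    def beta(self) -> float:
        """Inverse thermal energy 1/kBT in (pN·nm)^-1."""
        return 1.0 / self.kBT


#: Shared room-temperature environment (23 °C).
ROOM = EnvParams()
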