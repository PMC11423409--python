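"""Physical constants and thermodynamic state.

Units throughout the package: distances in nm, energies in kJ/mol,
temperatures in K, times in ps.  Angstrom values are accepted only at
I/O boundaries with an explicit unit tag and converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Boltzmann constant in kJ/mol/K (CODATA, molar gas constant / 1000).
K_B = 0.0083144626

#: Avogadro constant, 1/mol.
N_AVOGADRO = 6.02214076e23

ANGSTROM_PER_NM = 10.0


@dataclass(frozen=True)
class ThermoState:
    """Temperature and derived inverse temperature for an NVT ensemble."""

    temperature: float = 300.0  # K
    k_B: float = K_B

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")

    @property
    def kT(self) -> float:
        """Thermal energy in kJ/mol."""
        return self.k_B * self.temperature

    @property
    def beta(self) -> float:
        """Inverse thermal energy in mol/kJ."""
        return 1.0 / self.kT


def nm_from(value: float, unit: str) -> float:
    """Convert a length to nm. ``unit`` is one of ``nm``/``angstrom``/``A``."""
    u = unit.strip().lower()
    if u in ("nm", "nanometer", "nanometre"):
        return float(value)
    if u in ("a", "ang", "angstrom", "å"):
        return float(value) / ANGSTROM_PER_NM
    raise ValueError(f"unknown length unit {unit!r}")
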