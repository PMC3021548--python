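"""Physical constants, unit system, and environment-dependent quantities.

Internal unit system: length in nm, force in pN, energy in pN·nm, time in µs.
Translational drag is then pN·µs/nm and rotational drag pN·nm·µs, which keeps
every quantity in the models O(1e-2..1e2).  Conversion factors to SI are
provided for the boundary (Stokes drags are conventionally quoted in kg/s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = [
    "K_B",
    "KG_PER_S_TO_INTERNAL",
    "PhysicalEnvironment",
    "LinkerSpec",
    "thermal_energy",
    "water_viscosity",
    "stokes_drag_translation",
    "stokes_drag_rotation",
    "entropic_spring_constant",
    "kd_from_binding_energy",
    "binding_energy_from_kd",
]

#: Boltzmann constant in pN·nm/K (CODATA k_B = 1.380649e-23 J/K).
K_B = 1.380649e-2

#: 1 kg/s = 1e9 pN·µs/nm (and 1 kg·nm²/s = 1e9 pN·nm·µs).
KG_PER_S_TO_INTERNAL = 1.0e9

#: Reference viscosity used throughout the models: η = 0.01 g cm⁻¹ s⁻¹ = 1e-3 Pa·s.
ETA_REFERENCE = 1.0e-3

# Dynamic viscosity of water, °C -> mPa·s (CRC Handbook / Kestin et al. 1978).
# Spans slightly beyond the supported 283-323 K range so the interpolant has
# well-behaved end slopes.
_WATER_TABLE_C = np.array([5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0, 45.0, 50.0, 55.0])
_WATER_TABLE_MPAS = np.array(
    [1.5182, 1.3059, 1.1375, 1.0016, 0.8900, 0.7972, 0.7190, 0.6527, 0.5958, 0.5465, 0.5050]
)
_water_interp = PchipInterpolator(_WATER_TABLE_C, _WATER_TABLE_MPAS)

#: Supported temperature range for viscosity (~10-50 °C).
T_MIN, T_MAX = 283.0, 323.15


def thermal_energy(temperature: float) -> float:
    """Thermal energy k_B·T in pN·nm.  298 K -> 4.114 pN·nm."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return K_B * temperature


def water_viscosity(temperature: float, mode: str = "constant") -> float:
    """Viscosity of water in Pa·s for temperatures in [283, 323] K.

    mode="constant" returns the reference value 1e-3 Pa·s regardless of
    temperature (the value used for all fixed-temperature runs); mode="table"
    interpolates a literature water-viscosity table (monotonically decreasing
    in T), which is what the temperature-sweep experiments use.
    """
    if not (T_MIN <= temperature <= T_MAX):
        raise ValueError(
            f"temperature {temperature} K outside supported range [{T_MIN}, {T_MAX}] K"
        )
    if mode == "constant":
        return ETA_REFERENCE
    if mode == "table":
        return float(_water_interp(temperature - 273.15)) * 1.0e-3
    raise ValueError(f"unknown viscosity mode {mode!r}")


def stokes_drag_translation(eta: float, radius: float, units: str = "si") -> float:
    """Stokes translational drag 6πηr of a sphere.

    eta in Pa·s, radius in nm.  units="si" returns kg/s, units="internal"
    returns pN·µs/nm.  (1e-3 Pa·s, 3 nm) -> 5.65e-11 kg/s.
    """
    if eta <= 0 or radius <= 0:
        raise ValueError("eta and radius must be positive")
    gamma = 6.0 * math.pi * eta * radius * 1.0e-9  # kg/s
    if units == "si":
        return gamma
    if units == "internal":
        return gamma * KG_PER_S_TO_INTERNAL
    raise ValueError(f"unknown units {units!r}")


def stokes_drag_rotation(eta: float, radius: float, units: str = "si") -> float:
    """Stokes rotational drag 8πηr³ of a sphere.

    eta in Pa·s, radius in nm.  units="si" returns kg·nm²/s, units="internal"
    returns pN·nm·µs.  (1e-3 Pa·s, 3.5 nm) -> 1.0776e-9 kg·nm²/s.
    """
    if eta <= 0 or radius <= 0:
        raise ValueError("eta and radius must be positive")
    gamma = 8.0 * math.pi * eta * radius**3 * 1.0e-9  # kg·nm²/s
    if units == "si":
        return gamma
    if units == "internal":
        return gamma * KG_PER_S_TO_INTERNAL
    raise ValueError(f"unknown units {units!r}")


def entropic_spring_constant(n_residues: int, segment_length: float, kBT: float) -> float:
    """Gaussian-chain entropic spring constant K = 3·kBT/(N·a²) in pN/nm.

    A random coil of N segments of length a resists end-to-end extension with
    an entropic restoring force of stiffness 3kBT/(Na²).  For the 16-residue
    inter-domain linker (a = 0.3 nm) at kBT = 4.11 pN·nm this gives 8.56 pN/nm,
    matching force-spectroscopy estimates for short peptide tethers.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    if segment_length <= 0:
        raise ValueError("segment_length must be positive")
    return 3.0 * kBT / (n_residues * segment_length**2)


def kd_from_binding_energy(u: float) -> float:
    """Dissociation constant (molar) for a binding free energy of u k_BT.

    K_d = (1 M)·exp(−u); u = 13 gives 2.26 µM.
    """
    if u < 0:
        raise ValueError("binding energy must be >= 0 k_BT")
    return math.exp(-u)


def binding_energy_from_kd(kd: float) -> float:
    """Binding free energy in k_BT for a dissociation constant kd (molar)."""
    if kd <= 0:
        raise ValueError("kd must be positive")
    return -math.log(kd)


@dataclass(frozen=True)
class LinkerSpec:
    """The flexible polypeptide linker joining the two domains.

    n_residues: number of amino acids N; segment_length: per-residue length a
    in nm.  The chain cannot extend past its contour length N·a.
    """

    n_residues: int = 16
    segment_length: float = 0.3

    def __post_init__(self):
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")
        if self.segment_length <= 0:
            raise ValueError("segment_length must be positive")

    @property
    def max_extension(self) -> float:
        """Contour length N·a in nm (4.8 nm for the default linker)."""
        return self.n_residues * self.segment_length

    def spring_constant(self, kBT: float) -> float:
        """Entropic spring constant of this linker at thermal energy kBT."""
        return entropic_spring_constant(self.n_residues, self.segment_length, kBT)


@dataclass(frozen=True)
class PhysicalEnvironment:
    """Temperature, viscosity and the drag coefficients derived from them.

    Drags are stored in internal units: gamma_dna / gamma_nuc in pN·µs/nm
    (translational, sphere radii r_D = 3 nm and r = 3.5 nm respectively) and
    gamma_rot in pN·nm·µs (rotational, r = 3.5 nm).
    """

    temperature: float = 298.0
    viscosity: float = ETA_REFERENCE
    r_dna: float = 3.0
    r_nuc: float = 3.5

    @classmethod
    def from_temperature(
        cls,
        temperature: float = 298.0,
        viscosity_mode: str = "constant",
        viscosity: float | None = None,
        r_dna: float = 3.0,
        r_nuc: float = 3.5,
    ) -> "PhysicalEnvironment":
        if viscosity is None:
            viscosity = water_viscosity(temperature, mode=viscosity_mode)
        return cls(temperature=temperature, viscosity=viscosity, r_dna=r_dna, r_nuc=r_nuc)

    @property
    def kBT(self) -> float:
        return thermal_energy(self.temperature)

    @property
    def gamma_dna(self) -> float:
        return stokes_drag_translation(self.viscosity, self.r_dna, units="internal")

    @property
    def gamma_nuc(self) -> float:
        return stokes_drag_translation(self.viscosity, self.r_nuc, units="internal")

    @property
    def gamma_rot(self) -> float:
        return stokes_drag_rotation(self.viscosity, self.r_nuc, units="internal")
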