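"""Unit system shared by the particle and continuum solvers.

The particle (MD) side works in GROMACS-style molecular units: lengths in
nanometres, masses in daltons, energies in kJ/mol.  The derived time unit
``sqrt(Da nm^2 / (kJ/mol))`` is then exactly one picosecond (to the precision
of the CODATA Avogadro constant), so femtosecond time steps are plain
rescalings.  The continuum (FEM) side works in engineering units: lengths in
nanometres, forces in nanonewtons, elastic moduli in gigapascals
(1 GPa = 1 nN/nm^2).  Conversions are applied only at the coupling boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

# CODATA 2018 exact values
AVOGADRO = 6.02214076e23  # 1/mol
BOLTZMANN_KJ_MOL_K = 0.0083144626  # kJ mol^-1 K^-1

#: one kJ mol^-1 nm^-1 expressed in newtons
_KJ_MOL_NM_IN_N = 1.0e3 / (AVOGADRO * 1.0e-9)

#: internal MD time unit (sqrt(Da nm^2 / kJ mol^-1)) in picoseconds
MD_TIME_UNIT_PS = 1.0

# force conversions used at the MD <-> FEM boundary
KJ_MOL_NM_TO_PN = _KJ_MOL_NM_IN_N / 1.0e-12  # ~1.66054 pN
KJ_MOL_NM_TO_NN = _KJ_MOL_NM_IN_N / 1.0e-9
NN_TO_KJ_MOL_NM = 1.0 / KJ_MOL_NM_TO_NN
# spring stiffnesses
NN_PER_NM_TO_KJ_MOL_NM2 = NN_TO_KJ_MOL_NM
KJ_MOL_NM2_TO_NN_PER_NM = KJ_MOL_NM_TO_NN


class UnitError(ValueError):
    """Raised when a conversion between incompatible units is requested."""


# Every unit is (dimension, scale-to-base).  Base units per dimension:
# length nm, time ps, mass Da, energy kJ/mol, force kJ/mol/nm,
# stiffness kJ/mol/nm^2, pressure GPa, velocity nm/ps, temperature K.
_UNITS: dict[str, tuple[str, float]] = {
    # length
    "nm": ("length", 1.0),
    "um": ("length", 1.0e3),
    "m": ("length", 1.0e9),
    "angstrom": ("length", 0.1),
    # time
    "fs": ("time", 1.0e-3),
    "ps": ("time", 1.0),
    "ns": ("time", 1.0e3),
    "s": ("time", 1.0e12),
    # mass
    "Da": ("mass", 1.0),
    "kg": ("mass", 1.0e-3 * AVOGADRO),
    # energy
    "kJ/mol": ("energy", 1.0),
    "J": ("energy", 1.0e-3 * AVOGADRO),
    # force
    "kJ/mol/nm": ("force", 1.0),
    "pN": ("force", 1.0 / KJ_MOL_NM_TO_PN),
    "nN": ("force", 1.0 / KJ_MOL_NM_TO_NN),
    "N": ("force", 1.0e9 / KJ_MOL_NM_TO_NN),
    # spring stiffness
    "kJ/mol/nm^2": ("stiffness", 1.0),
    "nN/nm": ("stiffness", NN_PER_NM_TO_KJ_MOL_NM2),
    # pressure / modulus
    "GPa": ("pressure", 1.0),
    "nN/nm^2": ("pressure", 1.0),
    "MPa": ("pressure", 1.0e-3),
    "Pa": ("pressure", 1.0e-9),
    # velocity
    "nm/ps": ("velocity", 1.0),
    "m/s": ("velocity", 1.0e-3),
    "nm/ns": ("velocity", 1.0e-3),
    # temperature
    "K": ("temperature", 1.0),
}


def convert(value: float, from_unit: str, to_unit: str) -> float:
    """Convert ``value`` between two compatible units.

    Raises
    ------
    UnitError
        If either unit is unknown or the two units measure different
        dimensions; the message names both units.
    """
    try:
        dim_a, scale_a = _UNITS[from_unit]
    except KeyError:
        raise UnitError(f"unknown unit {from_unit!r}") from None
    try:
        dim_b, scale_b = _UNITS[to_unit]
    except KeyError:
        raise UnitError(f"unknown unit {to_unit!r}") from None
    if dim_a != dim_b:
        raise UnitError(
            f"cannot convert {from_unit!r} ({dim_a}) to {to_unit!r} ({dim_b})"
        )
    return value * (scale_a / scale_b)


@dataclass(frozen=True)
class UnitSystem:
    """Declarative record of the unit conventions used throughout a run."""

    length: str = "nm"
    time_step: str = "fs"
    time_report: str = "ns"
    mass: str = "Da"
    energy: str = "kJ/mol"
    force_internal: str = "kJ/mol/nm"
    force_report: str = "nN"
    modulus: str = "GPa"
    temperature: str = "K"


DEFAULT_UNITS = UnitSystem()
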