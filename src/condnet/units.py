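"""Unit systems and physical constants.

Two unit systems are supported, mirroring the conventions of bead-spring
molecular dynamics codes:

``real``
    lengths in Å, energies in kcal/mol, masses in amu, times in fs,
    charges in elementary charges.
``reduced``
    Lennard-Jones reduced units: lengths in σ, energies in ε, masses in m,
    times in τ = σ√(m/ε); k_B = 1 and the Coulomb constant is 1.

All conversions live here; modules never inline unit factors.
"""

from __future__ import annotations

#: Boltzmann constant in kcal/(mol·K).
KB_KCAL_MOL_K = 0.0019872041

#: Coulomb's constant in kcal·Å/(mol·e²), the value used by MD codes in
#: "real" units.
COULOMB_REAL = 332.0637

#: Conversion from amu·Å²/fs² to kcal/mol (kinetic-energy prefactor).
MVV2E_REAL = 2390.0573615334906

_SYSTEMS = ("real", "reduced")


def boltzmann(units: str) -> float:
    """k_B in the energy/temperature units of the given system."""
    _check(units)
    return KB_KCAL_MOL_K if units == "real" else 1.0


def coulomb_constant(units: str) -> float:
    """Default Coulomb prefactor C for the Debye-Hückel term."""
    _check(units)
    return COULOMB_REAL if units == "real" else 1.0


def mvv_to_energy(units: str) -> float:
    """Factor turning m·v² (native mass × native velocity²) into energy."""
    _check(units)
    return MVV2E_REAL if units == "real" else 1.0


def _check(units: str) -> None:
    if units not in _SYSTEMS:
        raise ValueError(f"unknown unit system {units!r}; expected one of {_SYSTEMS}")
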