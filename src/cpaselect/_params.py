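"""Physical constants and per-element parameter tables.

Radii are in Å, energies in kcal/mol, temperatures in K throughout the
package.  The van der Waals set is Bondi's; the well depths are the UFF
dispersion parameters, used by the default steric potential of the
torsion scan.
"""

from __future__ import annotations

#: Gas constant in kcal mol^-1 K^-1.
R_KCAL = 1.987204e-3

#: 1 hartree in kcal/mol (CODATA).
HARTREE_TO_KCAL = 627.5094740631

#: Bondi van der Waals radii (Å).
BONDI_VDW = {
    "H": 1.20, "He": 1.40,
    "B": 1.92, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47, "Ne": 1.54,
    "Si": 2.10, "P": 1.80, "S": 1.80, "Cl": 1.75, "Ar": 1.88,
    "Br": 1.85, "I": 1.98, "Se": 1.90,
}
DEFAULT_VDW = 1.70

#: UFF Lennard-Jones well depths (kcal/mol).
UFF_EPS = {
    "H": 0.044, "B": 0.180, "C": 0.105, "N": 0.069, "O": 0.060,
    "F": 0.050, "Si": 0.402, "P": 0.305, "S": 0.274, "Cl": 0.227,
    "Br": 0.251, "I": 0.339,
}
DEFAULT_EPS = 0.105

VDW_RADII_SETS = {"bondi": BONDI_VDW}


def vdw_radius(symbol: str, radii_set: str = "bondi") -> float:
    try:
        table = VDW_RADII_SETS[radii_set]
    except KeyError:  # pragma: no cover - config error
        raise ValueError(f"unknown vdW radii set {radii_set!r}") from None
    return table.get(symbol, DEFAULT_VDW)


def lj_well_depth(symbol: str) -> float:
    return UFF_EPS.get(symbol, DEFAULT_EPS)
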