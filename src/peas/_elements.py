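"""Per-element constants used across the package.

Van der Waals radii follow Bondi's compilation; covalent radii are the
single-bond values of Cordero et al. Both tables cover the elements that
occur in small organic ions; anything outside the table falls back to a
carbon-like default so that exotic inputs degrade gracefully instead of
crashing.
"""

from __future__ import annotations

# Bondi van der Waals radii, Å
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "He": 1.40,
    "B": 1.92,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "Na": 2.27,
    "Mg": 1.73,
    "Si": 2.10,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "K": 2.75,
    "Br": 1.85,
    "I": 1.98,
}

DEFAULT_VDW_RADIUS = 1.70

# Cordero single-bond covalent radii, Å (for bond perception from geometry)
COVALENT_RADII: dict[str, float] = {
    "H": 0.31,
    "B": 0.84,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "F": 0.57,
    "Na": 1.66,
    "Mg": 1.41,
    "Si": 1.11,
    "P": 1.07,
    "S": 1.05,
    "Cl": 1.02,
    "K": 2.03,
    "Br": 1.20,
    "I": 1.39,
}

DEFAULT_COVALENT_RADIUS = 0.76

# Periodic-table symbols accepted by the XYZ parser (main group + common
# transition metals; enough to reject typos like "CA" or "Xx").
ELEMENT_SYMBOLS: frozenset[str] = frozenset(
    """H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co
    Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te
    I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir
    Pt Au Hg Tl Pb Bi Po At Rn""".split()
)


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element, DEFAULT_VDW_RADIUS)


def covalent_radius(element: str) -> float:
    return COVALENT_RADII.get(element, DEFAULT_COVALENT_RADIUS)
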