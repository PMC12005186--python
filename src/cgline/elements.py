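"""Element data used for hydrogen completion, masses and volume estimation.

Implicit-hydrogen valences follow the OpenSMILES organic subset: for an atom
with bond-order sum *b*, the number of implicit hydrogens is ``v - b`` for the
smallest listed valence ``v >= b`` (zero if the atom exceeds every listed
valence).
"""

# OpenSMILES organic-subset default valences (lowest-first).
DEFAULT_VALENCES = {
    "B": (3,),
    "C": (4,),
    "N": (3, 5),
    "O": (2,),
    "P": (3, 5),
    "S": (2, 4, 6),
    "F": (1,),
    "Cl": (1,),
    "Br": (1,),
    "I": (1,),
    "H": (1,),
}

ORGANIC_SUBSET = {"B", "C", "N", "O", "P", "S", "F", "Cl", "Br", "I"}

AROMATIC_ELEMENTS = {"B", "C", "N", "O", "P", "S", "Se", "As"}

# Standard atomic weights (g/mol), enough coverage for typical organic and
# force-field molecules; extend as needed.
ATOMIC_MASSES = {
    "H": 1.008, "B": 10.81, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "Na": 22.990, "Mg": 24.305, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "K": 39.098, "Ca": 40.078, "Fe": 55.845,
    "Zn": 65.38, "Se": 78.971, "Br": 79.904, "I": 126.904, "*": 0.0,
}

# Atomic van-der-Waals volume contributions (A^3) for the bond/ring-corrected
# additive estimator (Zhao, Abraham & Zissimos, J. Org. Chem. 2003):
#   V = sum(atom contributions) - 5.92*N_bonds - 14.7*N_aromatic_rings
#       - 3.8*N_nonaromatic_rings
VDW_VOLUME = {
    "H": 7.24, "B": 40.48, "C": 20.58, "N": 15.60, "O": 14.71,
    "F": 13.31, "Cl": 22.45, "Br": 26.52, "I": 32.52, "P": 24.43,
    "S": 24.43, "Si": 38.79, "Se": 28.73, "Te": 36.62, "As": 26.52,
}

# Recognised two-letter element symbols (subset of the periodic table that is
# plausible in this context); used to validate bracket-atom tokens.
TWO_LETTER = {
    "He", "Li", "Be", "Ne", "Na", "Mg", "Al", "Si", "Cl", "Ar", "Ca",
    "Sc", "Ti", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn", "Ga", "Ge",
    "As", "Se", "Br", "Kr", "Rb", "Sr", "Zr", "Nb", "Mo", "Tc", "Ru",
    "Rh", "Pd", "Ag", "Cd", "In", "Sn", "Sb", "Te", "Xe", "Cs", "Ba",
    "Pt", "Au", "Hg", "Tl", "Pb", "Bi",
}

ONE_LETTER = {"H", "B", "C", "N", "O", "F", "P", "S", "K", "I", "V", "W", "U", "Y"}


def implicit_hydrogens(element, bond_order_sum):
    """Number of hydrogens completing *element* at the given bond-order sum.

    Returns 0 for elements without a default valence or for over-valent atoms.
    """
    for valence in DEFAULT_VALENCES.get(element, ()):
        if bond_order_sum <= valence:
            return int(valence - bond_order_sum)
    return 0


def lowest_valence(element, bond_order_sum):
    """Smallest standard valence able to host *bond_order_sum*, else None."""
    for valence in DEFAULT_VALENCES.get(element, ()):
        if bond_order_sum <= valence:
            return valence
    return None
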