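"""Monoisotopic mass constants.

All masses in Da. Residue masses are the standard monoisotopic values for
the 20 canonical amino acids (residue = amino acid minus water).
"""

PROTON = 1.00727646677
H2O = 18.0105646863
NH3 = 17.0265491015

#: Spacing of adjacent isotope peaks in a neutral-mass envelope (C13 - C12).
ISOTOPE_SPACING = 1.0033548378

#: Methanesulfenic acid CH3SOH (CH4OS), the characteristic neutral loss of
#: oxidized methionine and of sulfoxide-containing crosslinker stubs.
CH3SOH = 63.99828575

MONO_RESIDUE_MASSES = {
    "G": 57.02146372,
    "A": 71.03711379,
    "S": 87.03202840,
    "P": 97.05276385,
    "V": 99.06841391,
    "T": 101.04767847,
    "C": 103.00918496,
    "L": 113.08406398,
    "I": 113.08406398,
    "N": 114.04292744,
    "D": 115.02694302,
    "Q": 128.05857751,
    "K": 128.09496302,
    "E": 129.04259309,
    "M": 131.04048491,
    "H": 137.05891186,
    "F": 147.06841391,
    "R": 156.10111102,
    "Y": 163.06332853,
    "W": 186.07931295,
}

CANONICAL_RESIDUES = frozenset(MONO_RESIDUE_MASSES)

# Common modification deltas (Da).
CARBAMIDOMETHYL = 57.021464
OXIDATION = 15.994915
DEAMIDATION = 0.984016
METHYLATION = 14.015650


def mz_from_neutral(neutral_mass: float, charge: int) -> float:
    """m/z of an ion of the given neutral mass carrying `charge` protons."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (neutral_mass + charge * PROTON) / charge


def neutral_from_mz(mz: float, charge: int) -> float:
    return mz * charge - charge * PROTON


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error of `observed` vs `theoretical` in ppm."""
    return (observed - theoretical) / theoretical * 1e6
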