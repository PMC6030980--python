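"""Independent oracles used by the test suite.

Deliberately shares no code or tables with the package: atomic masses and
residue formulas are written down separately here, formulas are parsed from
strings, and the peak matcher is a brute-force all-pairs search.
"""

from __future__ import annotations

import re

# NIST atomic masses of the lightest isotopes, typed independently of the
# package's element table.
ATOMIC = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
}

# Residue (amino acid minus water) molecular formulas.
AA_FORMULA = {
    "G": "C2H3NO",
    "A": "C3H5NO",
    "S": "C3H5NO2",
    "P": "C5H7NO",
    "V": "C5H9NO",
    "T": "C4H7NO2",
    "C": "C3H5NOS",
    "L": "C6H11NO",
    "I": "C6H11NO",
    "N": "C4H6N2O2",
    "D": "C4H5NO3",
    "Q": "C5H8N2O2",
    "K": "C6H12N2O",
    "E": "C5H7NO3",
    "M": "C5H9NOS",
    "H": "C6H7N3O",
    "F": "C9H9NO",
    "R": "C6H12N4O",
    "Y": "C9H9NO2",
    "W": "C11H10N2O",
}

WATER = 2 * ATOMIC["H"] + ATOMIC["O"]
AMMONIA = 3 * ATOMIC["H"] + ATOMIC["N"]
PROTON = 1.00727646677  # CODATA


def formula_mass(formula: str) -> float:
    mass = 0.0
    for element, count in re.findall(r"([A-Z][a-z]?)(\d*)", formula):
        if element:
            mass += ATOMIC[element] * (int(count) if count else 1)
    return mass


def residue_mass(code: str) -> float:
    return formula_mass(AA_FORMULA[code])


def peptide_mass(sequence: str, mod_deltas: list[float] = ()) -> float:
    """Neutral peptide mass from residue formulas + water + mod deltas."""
    return sum(residue_mass(c) for c in sequence) + WATER + sum(mod_deltas)


def ion_mz(neutral: float, charge: int) -> float:
    return (neutral + charge * PROTON) / charge


def b_ion(sequence: str, i: int) -> float:
    """Neutral b_i mass of an unmodified peptide."""
    return sum(residue_mass(c) for c in sequence[:i])


def y_ion(sequence: str, j: int) -> float:
    """Neutral y_j mass of an unmodified peptide."""
    return sum(residue_mass(c) for c in sequence[-j:]) + WATER


def brute_force_match(peak_mzs, fragment_mzs, tolerance_ppm: float):
    """All-pairs closest-peak-within-tolerance matcher.

    Returns the set of (fragment_index, peak_index) pairs: for each
    fragment, the peak minimizing |observed - theoretical|, kept only if
    within the ppm tolerance of the theoretical m/z.
    """
    matches = set()
    for fi, fmz in enumerate(fragment_mzs):
        window = fmz * tolerance_ppm * 1e-6
        best = None
        best_d = None
        for pi, pmz in enumerate(peak_mzs):
            d = abs(pmz - fmz)
            if d <= window and (best_d is None or d < best_d):
                best, best_d = pi, d
        if best is not None:
            matches.add((fi, best))
    return matches
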