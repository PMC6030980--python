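"""Monoisotopic mass model for peptides, modifications and fragment arithmetic.

The peptide sequence grammar follows the single-spectrum text-input
convention of cross-link spectrum viewers: uppercase one-letter residue
codes, a lowercase token immediately after a residue naming a
post-translational modification on that residue, and a single ``#``
immediately after a residue marking the cross-link site, e.g.::

    PEPMoxTIDE     Met-3 oxidized
    KVLGK#AR       cross-linker attached to Lys-5

Modification positions are 1-based residue indices; 0 denotes the
N-terminus and ``len(sequence) + 1`` the C-terminus, matching the
mzIdentML ``location`` convention.

All masses are monoisotopic (lightest-isotope) and expressed in daltons.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

__all__ = [
    "CONSTANTS",
    "ELEMENT_MASSES",
    "Modification",
    "ModificationRegistry",
    "Peptide",
    "PhysicalConstants",
    "ResidueTable",
    "SequenceParseError",
    "UnknownModificationError",
    "default_residue_table",
    "default_modification_registry",
    "mz_from_neutral",
    "neutral_from_mz",
    "parse_sequence",
    "peptide_neutral_mass",
    "render_sequence",
]


class SequenceParseError(ValueError):
    """Raised when a peptide sequence string violates the grammar."""


class UnknownModificationError(SequenceParseError):
    """Raised when a lowercase modification token is not in the registry."""


# --------------------------------------------------------------------------
# Physical constants (monoisotopic, Da)
# --------------------------------------------------------------------------

#: Monoisotopic atomic masses of the elements occurring in unmodified
#: peptides (CODATA/IUPAC lightest-isotope values).
ELEMENT_MASSES: Mapping[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
}


@dataclass(frozen=True)
class PhysicalConstants:
    """Masses entering every fragment-ion equation, in Da."""

    proton_mass: float = 1.00727646688
    water_mass: float = 18.0105646863
    ammonia_mass: float = 17.0265491015
    #: Average spacing of isotope-cluster peaks (mass of a neutron capture
    #: in organic molecules, dominated by 13C-12C).
    isotope_spacing: float = 1.0033548378
    #: Hydrogen-atom mass added for the radical z-dot ion convention.
    hydrogen_mass: float = 1.00782503207


CONSTANTS = PhysicalConstants()

PROTON = CONSTANTS.proton_mass
WATER = CONSTANTS.water_mass
AMMONIA = CONSTANTS.ammonia_mass
ISOTOPE_SPACING = CONSTANTS.isotope_spacing


# --------------------------------------------------------------------------
# Residue table
# --------------------------------------------------------------------------

#: Elemental composition of each canonical amino-acid residue
#: (the repeating unit, i.e. the amino acid minus water).
_RESIDUE_COMPOSITIONS: Mapping[str, Mapping[str, int]] = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}


def _composition_mass(composition: Mapping[str, int]) -> float:
    return sum(ELEMENT_MASSES[el] * n for el, n in composition.items())


@dataclass(frozen=True)
class ResidueTable:
    """Registry of residue codes with elemental composition and mass.

    Ambiguous codes (B/Z/X) are deliberately absent: annotation requires
    exact monoisotopic masses.
    """

    entries: Mapping[str, tuple[Mapping[str, int], float]]

    def __contains__(self, code: str) -> bool:
        return code in self.entries

    def mass(self, code: str) -> float:
        try:
            return self.entries[code][1]
        except KeyError:
            raise KeyError(f"unknown residue code {code!r}") from None

    def composition(self, code: str) -> Mapping[str, int]:
        return self.entries[code][0]

    def codes(self) -> tuple[str, ...]:
        return tuple(self.entries)

    def residues_matching(self, mass: float, tolerance_da: float) -> list[str]:
        """Residue codes whose monoisotopic mass lies within ``tolerance_da``."""
        return [c for c, (_, m) in self.entries.items() if abs(m - mass) <= tolerance_da]


def default_residue_table() -> ResidueTable:
    """The 20 canonical residues with IUPAC monoisotopic masses."""
    return ResidueTable(
        entries={
            code: (comp, _composition_mass(comp))
            for code, comp in _RESIDUE_COMPOSITIONS.items()
        }
    )


_DEFAULT_TABLE = default_residue_table()


# --------------------------------------------------------------------------
# Modifications
# --------------------------------------------------------------------------

_MOD_NAME_RE = re.compile(r"[a-z][a-z0-9]*\Z")


@dataclass(frozen=True)
class Modification:
    """A mass shift attached to a residue or terminus.

    ``specificity`` is the set of residue codes (or terminus markers
    ``"N-term"``/``"C-term"``) the modification is known to occur on; it is
    advisory — parsing does not reject off-specificity placements, mirroring
    the hypothesis-testing use case where users move modifications around.
    """

    name: str
    mass_delta: float
    specificity: frozenset[str] = frozenset()
    origin: str = "user-defined"  # or "input-data"

    def __post_init__(self) -> None:
        if not _MOD_NAME_RE.match(self.name):
            raise ValueError(
                f"modification name {self.name!r} must match [a-z][a-z0-9]*"
            )
        if not (self.mass_delta == self.mass_delta and abs(self.mass_delta) != float("inf")):
            raise ValueError("modification mass_delta must be finite")


class ModificationRegistry:
    """Mutable lowercase-token → :class:`Modification` mapping.

    Re-registering an existing name overwrites its mass, which is how the
    "change a modification mass in the table" workflow is expressed.
    """

    def __init__(self, mods: Iterable[Modification] = ()) -> None:
        self._mods: dict[str, Modification] = {}
        for m in mods:
            self._mods[m.name] = m

    def register(
        self,
        name: str,
        mass_delta: float,
        specificity: Iterable[str] = (),
        origin: str = "user-defined",
    ) -> Modification:
        mod = Modification(name, float(mass_delta), frozenset(specificity), origin)
        self._mods[mod.name] = mod
        return mod

    def __contains__(self, name: str) -> bool:
        return name in self._mods

    def __getitem__(self, name: str) -> Modification:
        try:
            return self._mods[name]
        except KeyError:
            raise UnknownModificationError(
                f"unknown modification token {name!r}"
            ) from None

    def __iter__(self):
        return iter(self._mods.values())

    def __len__(self) -> int:
        return len(self._mods)

    def names(self) -> tuple[str, ...]:
        return tuple(self._mods)

    def copy(self) -> "ModificationRegistry":
        return ModificationRegistry(self._mods.values())

    # -- plain-text persistence (two columns: name, mass_delta) ------------

    def save_table(self, path) -> None:
        with open(path, "w", encoding="ascii") as fh:
            fh.write("# modification registry: name<TAB>mass_delta_Da\n")
            for mod in self._mods.values():
                fh.write(f"{mod.name}\t{mod.mass_delta:.6f}\n")

    @classmethod
    def load_table(cls, path) -> "ModificationRegistry":
        reg = cls()
        with open(path, encoding="ascii") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) < 2:
                    raise ValueError(
                        f"{path}:{lineno}: expected 'name mass_delta', got {line!r}"
                    )
                reg.register(parts[0], float(parts[1]))
        return reg


def default_modification_registry() -> ModificationRegistry:
    """Starter registry covering the most common modifications.

    ox   +15.99491  oxidation (Met)
    cm   +57.02146  carbamidomethylation (Cys)
    ph   +79.96633  phosphorylation (Ser/Thr/Tyr)
    deam  +0.98402  deamidation (Asn/Gln)
    ac   +42.01057  acetylation (Lys / protein N-terminus)

    Users override or extend it via :meth:`ModificationRegistry.register`
    or a two-column text table.
    """
    reg = ModificationRegistry()
    reg.register("ox", 15.99491, {"M"})
    reg.register("cm", 57.02146, {"C"})
    reg.register("ph", 79.96633, {"S", "T", "Y"})
    reg.register("deam", 0.98402, {"N", "Q"})
    reg.register("ac", 42.01057, {"K", "N-term"})
    return reg


# --------------------------------------------------------------------------
# Peptide and the sequence grammar
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Peptide:
    """A residue sequence with positioned modifications.

    ``mods`` holds ``(position, Modification)`` pairs; positions are 1-based
    residue indices, with 0 = N-terminus and ``len+1`` = C-terminus.
    """

    sequence: str
    mods: tuple[tuple[int, Modification], ...] = ()

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError("peptide sequence must be non-empty")
        for code in self.sequence:
            if code not in _DEFAULT_TABLE:
                raise SequenceParseError(f"unknown residue code {code!r}")
        n = len(self.sequence)
        for pos, _mod in self.mods:
            if not 0 <= pos <= n + 1:
                raise ValueError(
                    f"modification position {pos} outside [0, {n + 1}]"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def with_mod_moved(self, old_pos: int, new_pos: int) -> "Peptide":
        """Return a copy with the modification at ``old_pos`` moved."""
        moved = False
        new_mods = []
        for pos, mod in self.mods:
            if pos == old_pos and not moved:
                new_mods.append((new_pos, mod))
                moved = True
            else:
                new_mods.append((pos, mod))
        if not moved:
            raise ValueError(f"no modification at position {old_pos}")
        return replace(self, mods=tuple(new_mods))


_TOKEN_RE = re.compile(r"([A-Z])([a-z][a-z0-9]*)?(#)?")


def parse_sequence(
    text: str,
    registry: Optional[ModificationRegistry] = None,
    residue_table: Optional[ResidueTable] = None,
) -> tuple[Peptide, Optional[int]]:
    """Parse a sequence string into a :class:`Peptide` and cross-link site.

    Returns ``(peptide, link_position)``; ``link_position`` is the 1-based
    index of the residue carrying ``#``, or ``None`` for a linear peptide.

    Raises :class:`SequenceParseError` on grammar violations and
    :class:`UnknownModificationError` for unregistered lowercase tokens.
    """
    if registry is None:
        registry = default_modification_registry()
    if residue_table is None:
        residue_table = _DEFAULT_TABLE
    if not text:
        raise SequenceParseError("empty sequence")

    residues: list[str] = []
    mods: list[tuple[int, Modification]] = []
    link_position: Optional[int] = None

    i = 0
    while i < len(text):
        m = _TOKEN_RE.match(text, i)
        if not m or not m.group(1):
            raise SequenceParseError(
                f"unexpected character {text[i]!r} at position {i + 1}: "
                "sequences start each token with an uppercase residue letter"
            )
        residue, mod_token, link = m.group(1), m.group(2), m.group(3)
        if residue not in residue_table:
            raise SequenceParseError(
                f"unknown residue letter {residue!r} at position {i + 1}"
            )
        residues.append(residue)
        index = len(residues)
        if mod_token is not None:
            mods.append((index, registry[mod_token]))
        if link is not None:
            if link_position is not None:
                raise SequenceParseError(
                    "multiple cross-link symbols '#' in sequence"
                )
            link_position = index
        i = m.end()

    return Peptide("".join(residues), tuple(mods)), link_position


def render_sequence(peptide: Peptide, link_position: Optional[int] = None) -> str:
    """Inverse of :func:`parse_sequence` (canonical form).

    Terminal modifications (positions 0 and len+1) have no in-line grammar
    slot and are rendered attached to the first/last residue token.
    """
    n = len(peptide.sequence)
    by_pos: dict[int, list[str]] = {}
    for pos, mod in peptide.mods:
        slot = min(max(pos, 1), n)  # clamp termini onto adjacent residue
        by_pos.setdefault(slot, []).append(mod.name)
    out: list[str] = []
    for idx, residue in enumerate(peptide.sequence, start=1):
        out.append(residue)
        for name in by_pos.get(idx, ()):
            out.append(name)
        if link_position == idx:
            out.append("#")
    return "".join(out)


# --------------------------------------------------------------------------
# Mass arithmetic
# --------------------------------------------------------------------------


def peptide_neutral_mass(
    peptide: Peptide, residue_table: Optional[ResidueTable] = None
) -> float:
    """Neutral monoisotopic mass: Σ residues + water + Σ modification deltas."""
    table = residue_table or _DEFAULT_TABLE
    mass = sum(table.mass(code) for code in peptide.sequence) + WATER
    mass += sum(mod.mass_delta for _pos, mod in peptide.mods)
    return mass


def mz_from_neutral(neutral_mass: float, charge: int) -> float:
    """m/z of a protonated ion: (M + z·m_proton) / z."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (neutral_mass + charge * PROTON) / charge


def neutral_from_mz(mz: float, charge: int) -> float:
    """Inverse of :func:`mz_from_neutral`."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return mz * charge - charge * PROTON
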