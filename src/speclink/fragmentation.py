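"""Theoretical fragment-ion generation for linear and cross-linked PSMs.

Supported series are the unfragmented precursor and b, c, y, z backbone
ions.  Neutral masses follow the standard prefix/suffix partition::

    b_i = sum(residues 1..i)            + mods located in 0..i
    y_j = sum(residues n-j+1..n) + H2O  + mods located in n-j+1..n+1
    c_i = b_i + NH3
    z_j = y_j - NH3          (classical z; z_radical adds one H for z-dot)

Cross-link rule: a fragment whose residue range covers the link site of its
peptide carries the cross-linker mass plus the entire neutral mass of the
partner peptide (the partner does not fragment in that ion), and the
precursor of a cross-linked PSM is the sum of both peptides plus the linker.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .mass_model import (
    AMMONIA,
    CONSTANTS,
    WATER,
    Peptide,
    ResidueTable,
    default_residue_table,
    mz_from_neutral,
    peptide_neutral_mass,
)

__all__ = [
    "AnnotationSettings",
    "CrossLinkedPSM",
    "FragmentIon",
    "ION_SERIES",
    "Tolerance",
    "apply_neutral_losses",
    "generate_fragments",
]

ION_SERIES = ("precursor", "b", "c", "y", "z")

#: Residues that support loss of water / ammonia from a fragment.
H2O_LOSS_RESIDUES = frozenset("STED")
NH3_LOSS_RESIDUES = frozenset("RKNQ")


# --------------------------------------------------------------------------
# Settings
# --------------------------------------------------------------------------

_TOL_RE = re.compile(r"\s*([0-9.eE+-]+)\s*(ppm|da)\s*\Z", re.IGNORECASE)


@dataclass(frozen=True)
class Tolerance:
    """A match tolerance: positive value plus unit ('ppm' or 'Da')."""

    value: float
    unit: str  # "ppm" | "Da"

    def __post_init__(self) -> None:
        unit = self.unit.lower()
        if unit not in ("ppm", "da"):
            raise ValueError(f"tolerance unit must be ppm or Da, got {self.unit!r}")
        object.__setattr__(self, "unit", "ppm" if unit == "ppm" else "Da")
        if not self.value > 0:
            raise ValueError(f"tolerance value must be > 0, got {self.value}")

    @classmethod
    def parse(cls, text: str) -> "Tolerance":
        """Parse forms like ``"10ppm"`` or ``"0.02Da"`` (case-insensitive)."""
        m = _TOL_RE.match(text)
        if not m:
            raise ValueError(f"cannot parse tolerance {text!r} (expected e.g. '10ppm', '0.02Da')")
        return cls(float(m.group(1)), m.group(2))

    def window_da(self, theoretical_mz: float) -> float:
        """Half-width of the acceptance window around ``theoretical_mz``, in Th."""
        if self.unit == "ppm":
            return theoretical_mz * self.value * 1e-6
        return self.value

    def __str__(self) -> str:
        return f"{self.value:g}{self.unit}"


@dataclass(frozen=True)
class AnnotationSettings:
    """The annotation hypothesis: which ions to consider and how to match.

    ``max_fragment_charge`` caps fragment charge states; the effective range
    is ``1..min(precursor_charge, max_fragment_charge)``.
    """

    tolerance: Tolerance = Tolerance(10.0, "ppm")
    ion_types: frozenset[str] = frozenset({"precursor", "b", "y"})
    max_fragment_charge: int = 2
    losses_enabled: bool = True
    z_radical: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "ion_types", frozenset(self.ion_types))
        unknown = self.ion_types - set(ION_SERIES)
        if unknown:
            raise ValueError(f"unknown ion types: {sorted(unknown)}")
        if self.max_fragment_charge < 1:
            raise ValueError("max_fragment_charge must be >= 1")


# --------------------------------------------------------------------------
# PSM
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CrossLinkedPSM:
    """One or two peptides matched to a spectrum.

    Linear PSMs have a single peptide and no link/linker; cross-linked PSMs
    carry two peptides, per-peptide 1-based link positions and the
    cross-linker mass.  ``rank`` 1 is the top match; higher ranks are
    alternative explanations of the same spectrum.
    """

    peptides: tuple[Peptide, ...]
    link_positions: tuple[int, ...] = ()
    crosslinker_mass: Optional[float] = None
    precursor_charge: int = 2
    precursor_mz: Optional[float] = None
    scores: Mapping[str, float] = field(default_factory=dict)
    decoy_flags: tuple[bool, ...] = ()
    pass_threshold: bool = True
    rank: int = 1
    # spectrum provenance
    psm_id: str = ""
    peak_list_filename: str = ""
    scan_number: Optional[int] = None
    scan_index: Optional[int] = None
    proteins: tuple[str, ...] = ()
    #: opaque per-PSM annotations from tolerant readers (extra CSV columns,
    #: per-PSM tolerance/ion-type hints); never interpreted by this module
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 1 <= len(self.peptides) <= 2:
            raise ValueError("a PSM has one or two peptides")
        if self.is_crosslinked:
            if len(self.link_positions) != 2 or self.crosslinker_mass is None:
                raise ValueError(
                    "cross-linked PSM requires two link positions and a cross-linker mass"
                )
            for pep, pos in zip(self.peptides, self.link_positions):
                if not 1 <= pos <= len(pep):
                    raise ValueError(
                        f"link position {pos} outside peptide of length {len(pep)}"
                    )
        if self.precursor_charge < 1:
            raise ValueError("precursor charge must be >= 1")
        if not self.decoy_flags:
            object.__setattr__(self, "decoy_flags", (False,) * len(self.peptides))

    @property
    def is_crosslinked(self) -> bool:
        return len(self.peptides) == 2

    @property
    def is_decoy(self) -> bool:
        return any(self.decoy_flags)

    def neutral_mass(self, table: Optional[ResidueTable] = None) -> float:
        """Neutral mass of the intact (possibly cross-linked) precursor."""
        mass = sum(peptide_neutral_mass(p, table) for p in self.peptides)
        if self.is_crosslinked:
            mass += self.crosslinker_mass
        return mass


# --------------------------------------------------------------------------
# Fragments
# --------------------------------------------------------------------------

PEPTIDE_IDS = ("alpha", "beta")


@dataclass(frozen=True)
class FragmentIon:
    """A theoretical fragment: series + index + charge + neutral mass + m/z.

    ``start``/``end`` give the fragment's 1-based residue range within its
    peptide (used for neutral-loss eligibility and the fragmentation key);
    ``contains_link`` marks fragments carrying linker + partner peptide.
    """

    series: str
    index: int  # 0 for precursor
    peptide_id: str  # "alpha" | "beta"
    charge: int
    neutral_mass: float
    mz: float
    loss: Optional[str] = None  # None | "H2O" | "NH3"
    contains_link: bool = False
    start: int = 1
    end: int = 1

    @property
    def label(self) -> str:
        """Human-readable label, e.g. ``b3``, ``y2-H2O``, ``P``."""
        base = "P" if self.series == "precursor" else f"{self.series}{self.index}"
        if self.loss:
            base += f"-{self.loss}"
        if self.charge > 1:
            base += f"({self.charge}+)"
        return base


def _prefix_masses(peptide: Peptide, table: ResidueTable) -> list[float]:
    """Cumulative residue+mod mass of prefixes 1..i (no water)."""
    mod_at = [0.0] * (len(peptide) + 2)
    for pos, mod in peptide.mods:
        mod_at[pos] += mod.mass_delta
    out = []
    acc = mod_at[0]  # N-terminal mods belong to every prefix
    for i, code in enumerate(peptide.sequence, start=1):
        acc += table.mass(code) + mod_at[i]
        out.append(acc)
    return out


def generate_fragments(
    psm: CrossLinkedPSM,
    settings: AnnotationSettings,
    residue_table: Optional[ResidueTable] = None,
) -> list[FragmentIon]:
    """All theoretical fragments of ``psm`` under ``settings``.

    One :class:`FragmentIon` per peptide × series × cleavage index × charge,
    with charges ``1..min(precursor_charge, settings.max_fragment_charge)``
    (the precursor ion additionally appears at the precursor charge itself).
    An empty ion-type set yields an empty list.
    """
    table = residue_table or default_residue_table()
    max_z = min(psm.precursor_charge, settings.max_fragment_charge)
    charges = range(1, max_z + 1)
    fragments: list[FragmentIon] = []

    pep_masses = [peptide_neutral_mass(p, table) for p in psm.peptides]

    if "precursor" in settings.ion_types:
        neutral = psm.neutral_mass(table)
        prec_charges = sorted(set(charges) | {psm.precursor_charge})
        for z in prec_charges:
            fragments.append(
                FragmentIon(
                    series="precursor",
                    index=0,
                    peptide_id="alpha",
                    charge=z,
                    neutral_mass=neutral,
                    mz=mz_from_neutral(neutral, z),
                    contains_link=psm.is_crosslinked,
                    start=1,
                    end=len(psm.peptides[0]),
                )
            )

    backbone = settings.ion_types & {"b", "c", "y", "z"}
    for p_idx, peptide in enumerate(psm.peptides):
        pid = PEPTIDE_IDS[p_idx]
        n = len(peptide)
        prefixes = _prefix_masses(peptide, table)
        total = pep_masses[p_idx]
        link_pos = psm.link_positions[p_idx] if psm.is_crosslinked else None
        partner_extra = 0.0
        if psm.is_crosslinked:
            partner_extra = psm.crosslinker_mass + pep_masses[1 - p_idx]

        z_offset = CONSTANTS.hydrogen_mass if settings.z_radical else 0.0

        for i in range(1, n):  # cleavage after residue i
            prefix = prefixes[i - 1]
            suffix = total - prefix  # includes water and suffix/C-term mods
            for series in backbone:
                if series in ("b", "c"):
                    neutral = prefix if series == "b" else prefix + AMMONIA
                    start, end, index = 1, i, i
                    has_link = link_pos is not None and link_pos <= i
                else:  # y / z, suffix length j = n - i
                    j = n - i
                    neutral = suffix if series == "y" else suffix - AMMONIA + z_offset
                    start, end, index = i + 1, n, j
                    has_link = link_pos is not None and link_pos > i
                if has_link:
                    neutral += partner_extra
                for z in charges:
                    fragments.append(
                        FragmentIon(
                            series=series,
                            index=index,
                            peptide_id=pid,
                            charge=z,
                            neutral_mass=neutral,
                            mz=mz_from_neutral(neutral, z),
                            contains_link=has_link,
                            start=start,
                            end=end,
                        )
                    )

    return fragments


def apply_neutral_losses(
    fragments: Sequence[FragmentIon],
    psm: CrossLinkedPSM,
    enabled: bool = True,
) -> list[FragmentIon]:
    """Augment ``fragments`` with single-neutral-loss variants.

    A fragment whose own residue range contains Ser/Thr/Glu/Asp gains an
    H2O-loss variant; Arg/Lys/Asn/Gln gains an NH3-loss variant.  Only one
    loss per variant; base fragments are retained.  With ``enabled`` False
    the input list is returned unchanged.
    """
    if not enabled:
        return list(fragments)
    out = list(fragments)
    pid_to_idx = {pid: i for i, pid in enumerate(PEPTIDE_IDS)}
    for frag in fragments:
        if frag.loss is not None:
            continue
        peptide = psm.peptides[pid_to_idx[frag.peptide_id]]
        # eligibility from the fragment's own residue range only: a fragment
        # carrying the intact partner peptide does not gain losses from the
        # partner's residues (keeps cross-linked and linear+mass-shift
        # representations of the same ion exactly equivalent)
        residues = set(peptide.sequence[frag.start - 1 : frag.end])
        variants = []
        if residues & H2O_LOSS_RESIDUES:
            variants.append(("H2O", WATER))
        if residues & NH3_LOSS_RESIDUES:
            variants.append(("NH3", AMMONIA))
        for loss_name, loss_mass in variants:
            neutral = frag.neutral_mass - loss_mass
            out.append(
                FragmentIon(
                    series=frag.series,
                    index=frag.index,
                    peptide_id=frag.peptide_id,
                    charge=frag.charge,
                    neutral_mass=neutral,
                    mz=mz_from_neutral(neutral, frag.charge),
                    loss=loss_name,
                    contains_link=frag.contains_link,
                    start=frag.start,
                    end=frag.end,
                )
            )
    return out
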