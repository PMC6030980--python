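"""On-demand spectrum annotation: peak↔fragment matching, isotope clusters,
QC error tables, the peak-distance measuring tool, and re-annotation.

Matching semantics: every theoretical fragment is assigned the observed
peak with the smallest |Δm/z| within tolerance (closest, not most intense —
the per-fragment error is what the QC plots display).  One peak may carry
several fragment labels.  Errors are signed, observed − theoretical.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .fragmentation import (
    AnnotationSettings,
    CrossLinkedPSM,
    FragmentIon,
    Tolerance,
    apply_neutral_losses,
    generate_fragments,
)
from .mass_model import ISOTOPE_SPACING, ResidueTable, default_residue_table

__all__ = [
    "AnnotatedSpectrum",
    "MeasureResult",
    "PeakMatch",
    "QcPoint",
    "Spectrum",
    "annotate",
    "match_isotope_cluster",
    "measure",
    "qc_points",
    "reannotate",
    "revert",
]

#: Isotope clusters are extended at most this far beyond the monoisotopic
#: peak, and stop at the first missing peak.
MAX_ISOTOPE_PEAKS = 6


# --------------------------------------------------------------------------
# Spectrum
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Spectrum:
    """A peak list with provenance.

    Peaks are kept sorted ascending by m/z; intensities must be >= 0.
    """

    mz: np.ndarray
    intensity: np.ndarray
    filename: str = ""
    scan_id: str = ""
    scan_index: Optional[int] = None
    precursor_mz: Optional[float] = None
    precursor_charge: Optional[int] = None
    title: str = ""

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        if mz.shape != intensity.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if np.any(intensity < 0):
            raise ValueError("intensities must be non-negative")
        order = np.argsort(mz, kind="stable")
        object.__setattr__(self, "mz", mz[order])
        object.__setattr__(self, "intensity", intensity[order])

    @classmethod
    def from_peaks(cls, peaks: Iterable[tuple[float, float]], **kwargs) -> "Spectrum":
        pairs = list(peaks)
        mz = np.array([p[0] for p in pairs], dtype=float)
        inten = np.array([p[1] for p in pairs], dtype=float)
        return cls(mz=mz, intensity=inten, **kwargs)

    def __len__(self) -> int:
        return len(self.mz)


# --------------------------------------------------------------------------
# Matches
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PeakMatch:
    """One observed peak explained by one theoretical fragment.

    ``isotope_peak`` 0 is the monoisotopic match; k > 0 are isotope-cluster
    peaks k spacings above it.  Errors are signed (observed − theoretical).
    """

    peak_index: int
    fragment: FragmentIon
    isotope_peak: int
    error_da: float
    error_ppm: float


@dataclass(frozen=True)
class AnnotatedSpectrum:
    """The result of matching a PSM against a spectrum.

    Carries the full theoretical fragment list, all peak matches, and a
    snapshot of the first (psm, settings) pair so any chain of
    re-annotations can be reverted exactly.
    """

    spectrum: Spectrum
    psm: CrossLinkedPSM
    settings: AnnotationSettings
    fragments: tuple[FragmentIon, ...]
    matches: tuple[PeakMatch, ...]
    original_psm: CrossLinkedPSM = None  # type: ignore[assignment]
    original_settings: AnnotationSettings = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.original_psm is None:
            object.__setattr__(self, "original_psm", self.psm)
        if self.original_settings is None:
            object.__setattr__(self, "original_settings", self.settings)

    @property
    def monoisotopic_matches(self) -> tuple[PeakMatch, ...]:
        return tuple(m for m in self.matches if m.isotope_peak == 0)


def _closest_peak_within(
    mz_array: np.ndarray, target: float, window: float
) -> Optional[int]:
    """Index of the peak closest to ``target`` within ±``window``, else None."""
    if len(mz_array) == 0:
        return None
    i = int(np.searchsorted(mz_array, target))
    best = None
    best_d = window
    for j in (i - 1, i):
        if 0 <= j < len(mz_array):
            d = abs(mz_array[j] - target)
            if d <= best_d:
                best_d = d
                best = j
    return best


def _make_match(
    peak_index: int, observed: float, theoretical: float, fragment: FragmentIon, k: int
) -> PeakMatch:
    err_da = observed - theoretical
    return PeakMatch(
        peak_index=peak_index,
        fragment=fragment,
        isotope_peak=k,
        error_da=err_da,
        error_ppm=err_da / theoretical * 1e6,
    )


def annotate(
    spectrum: Spectrum,
    psm: CrossLinkedPSM,
    settings: AnnotationSettings,
    residue_table: Optional[ResidueTable] = None,
) -> AnnotatedSpectrum:
    """Match every theoretical fragment to its closest peak within tolerance.

    Neutral-loss variants are generated first (if enabled), then each
    fragment independently matched; matched fragments are extended into
    isotope clusters.  An empty spectrum yields zero matches.
    """
    fragments = apply_neutral_losses(
        generate_fragments(psm, settings, residue_table), psm, settings.losses_enabled
    )
    matches: list[PeakMatch] = []
    for frag in fragments:
        window = settings.tolerance.window_da(frag.mz)
        idx = _closest_peak_within(spectrum.mz, frag.mz, window)
        if idx is None:
            continue
        mono = _make_match(idx, float(spectrum.mz[idx]), frag.mz, frag, 0)
        matches.append(mono)
        matches.extend(match_isotope_cluster(spectrum, mono, settings))
    return AnnotatedSpectrum(
        spectrum=spectrum,
        psm=psm,
        settings=settings,
        fragments=tuple(fragments),
        matches=tuple(matches),
    )


def match_isotope_cluster(
    spectrum: Spectrum, match: PeakMatch, settings: AnnotationSettings
) -> list[PeakMatch]:
    """Extend a monoisotopic match into its isotope cluster.

    Peaks are sought at ``observed_mz + k * spacing / charge`` for
    k = 1, 2, …; extension stops at the first gap and after
    ``MAX_ISOTOPE_PEAKS`` peaks.  The search is anchored on the observed
    monoisotopic peak so a calibration offset does not break the cluster.
    """
    if match.isotope_peak != 0:
        raise ValueError("isotope clusters extend monoisotopic matches only")
    base = float(spectrum.mz[match.peak_index])
    charge = match.fragment.charge
    out: list[PeakMatch] = []
    for k in range(1, MAX_ISOTOPE_PEAKS + 1):
        target = base + k * ISOTOPE_SPACING / charge
        window = settings.tolerance.window_da(target)
        idx = _closest_peak_within(spectrum.mz, target, window)
        if idx is None:
            break  # first gap terminates the cluster
        out.append(
            _make_match(idx, float(spectrum.mz[idx]), target, match.fragment, k)
        )
    return out


# --------------------------------------------------------------------------
# QC error table
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class QcPoint:
    """One QC-plot point: x (intensity or m/z) vs match error in ppm."""

    x: float
    error_ppm: float
    peptide_id: str
    is_loss: bool
    label: str


def qc_points(
    annotated: AnnotatedSpectrum, axis: str = "intensity", absolute: bool = False
) -> list[QcPoint]:
    """Error-vs-intensity or error-vs-m/z points, one per monoisotopic match.

    Points carry the peptide id (alpha/beta) and loss status so the plot can
    use the two-peptide colors with lighter neutral-loss points.
    """
    if axis not in ("intensity", "mz"):
        raise ValueError(f"axis must be 'intensity' or 'mz', got {axis!r}")
    points = []
    for m in annotated.monoisotopic_matches:
        x = (
            float(annotated.spectrum.intensity[m.peak_index])
            if axis == "intensity"
            else float(annotated.spectrum.mz[m.peak_index])
        )
        err = abs(m.error_ppm) if absolute else m.error_ppm
        points.append(
            QcPoint(
                x=x,
                error_ppm=err,
                peptide_id=m.fragment.peptide_id,
                is_loss=m.fragment.loss is not None,
                label=m.fragment.label,
            )
        )
    return points


# --------------------------------------------------------------------------
# Measuring tool
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class MeasureResult:
    charge: int
    mass_delta: float
    residue_matches: tuple[str, ...]


def measure(
    spectrum: Spectrum,
    peak_a: int,
    peak_b: int,
    max_charge: int = 3,
    tolerance: Tolerance = Tolerance(0.01, "Da"),
    residue_table: Optional[ResidueTable] = None,
) -> list[MeasureResult]:
    """Distance between two peaks, converted to mass at charges 1..max_charge.

    For each charge the m/z distance is scaled to a neutral mass difference
    and compared against the residue table; residues within tolerance are
    reported — the tool for explaining unannotated peak gaps.  A zero gap
    reports no residue matches.
    """
    if max_charge < 1:
        raise ValueError("max_charge must be >= 1")
    n = len(spectrum)
    for idx in (peak_a, peak_b):
        if not 0 <= idx < n:
            raise IndexError(f"peak index {idx} outside spectrum of {n} peaks")
    table = residue_table or default_residue_table()
    dist = abs(float(spectrum.mz[peak_a]) - float(spectrum.mz[peak_b]))
    results = []
    for z in range(1, max_charge + 1):
        delta = dist * z
        if delta == 0.0:
            matches: tuple[str, ...] = ()
        else:
            if tolerance.unit == "ppm":
                tol_da = delta * tolerance.value * 1e-6
            else:
                tol_da = tolerance.value
            matches = tuple(sorted(table.residues_matching(delta, tol_da)))
        results.append(MeasureResult(charge=z, mass_delta=delta, residue_matches=matches))
    return results


# --------------------------------------------------------------------------
# Re-annotation / revert
# --------------------------------------------------------------------------


def reannotate(
    annotated: AnnotatedSpectrum,
    psm: Optional[CrossLinkedPSM] = None,
    settings: Optional[AnnotationSettings] = None,
    residue_table: Optional[ResidueTable] = None,
) -> AnnotatedSpectrum:
    """Re-run annotation under a modified hypothesis.

    Any of the PSM (sequence, modifications, link position, precursor
    charge) or the settings (ion types, tolerance, losses) may be replaced;
    the snapshot of the *first* annotation is carried along so
    :func:`revert` restores it exactly.  The input object is not mutated.
    """
    new = annotate(
        annotated.spectrum,
        psm if psm is not None else annotated.psm,
        settings if settings is not None else annotated.settings,
        residue_table,
    )
    return replace(
        new,
        original_psm=annotated.original_psm,
        original_settings=annotated.original_settings,
    )


def revert(
    annotated: AnnotatedSpectrum, residue_table: Optional[ResidueTable] = None
) -> AnnotatedSpectrum:
    """Recompute the original annotation from the retained snapshot."""
    return annotate(
        annotated.spectrum,
        annotated.original_psm,
        annotated.original_settings,
        residue_table,
    )
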