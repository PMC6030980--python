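"""Synthetic MGF + CSV fixture pairs with known ground truth.

Every module is testable without downloads: the generator builds random
linear and cross-linked PSMs, plants all their b/y fragment peaks (with
Gaussian ppm jitter emulating mass-measurement error) among uniform-random
noise peaks, and records which peak indices are true fragments.  A fixed
seed makes the emitted files byte-identical across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .annotation import AnnotatedSpectrum, Spectrum, annotate
from .fragmentation import (
    AnnotationSettings,
    CrossLinkedPSM,
    FragmentIon,
    Tolerance,
    generate_fragments,
)
from .io_formats import Dataset, write_mgf
from .mass_model import default_modification_registry, mz_from_neutral

__all__ = ["FixtureSet", "FixtureSpec", "evaluate_recovery", "make_fixtures"]

#: BS3/DSS-class amine-reactive cross-linker, monoisotopic mass of the
#: bridging modification in Da.
CROSSLINKER_MASS = 138.06808

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: ion hypothesis used both for planting peaks and for recovery
FIXTURE_SETTINGS = AnnotationSettings(
    tolerance=Tolerance(20.0, "ppm"),
    ion_types=frozenset({"b", "y"}),
    max_fragment_charge=1,
    losses_enabled=False,
)


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic dataset.

    ``jitter_ppm`` is the Gaussian sigma of the relative mass error applied
    to every planted fragment peak; ``noise_peaks`` uniform-random peaks are
    added per spectrum.  All fractions lie in [0, 1] and ``seed`` fixes
    every random draw.
    """

    n_psms: int = 200
    peptide_length: tuple[int, int] = (6, 14)
    crosslink_fraction: float = 0.5
    noise_peaks: int = 30
    jitter_ppm: float = 5.0
    decoy_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("crosslink_fraction", "decoy_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.peptide_length[0] < 2 or self.peptide_length[1] < self.peptide_length[0]:
            raise ValueError("invalid peptide length range")
        if self.n_psms < 1 or self.noise_peaks < 0 or self.jitter_ppm < 0:
            raise ValueError("invalid fixture spec")


@dataclass
class FixtureSet:
    mgf_path: Path
    csv_path: Path
    truth_path: Path
    #: per PSM: {"psm_id", "scan_index", "peaks": {peak_index: [fragment keys]}}
    truth: list[dict]
    spectra: list[Spectrum] = field(default_factory=list)
    psms: list[CrossLinkedPSM] = field(default_factory=list)

    def dataset(self) -> Dataset:
        return Dataset(
            identifier="synthetic",
            spectra=list(self.spectra),
            psms=list(self.psms),
            registry=default_modification_registry(),
        )


def fragment_key(frag: FragmentIon) -> str:
    """Stable identity of a planted fragment: peptide.series+index/charge."""
    return f"{frag.peptide_id}.{frag.series}{frag.index}/{frag.charge}"


def _random_peptide(rng: np.random.Generator, lo: int, hi: int) -> str:
    length = int(rng.integers(lo, hi + 1))
    return "".join(RESIDUES[i] for i in rng.integers(0, len(RESIDUES), length))


def _make_psm(rng: np.random.Generator, spec: FixtureSpec, k: int) -> CrossLinkedPSM:
    from .mass_model import Peptide

    lo, hi = spec.peptide_length
    crosslinked = rng.random() < spec.crosslink_fraction
    decoy = rng.random() < spec.decoy_fraction
    below = rng.random() < 0.1
    score = float(np.round(rng.uniform(1.0, 50.0), 3))
    if crosslinked:
        pep_a = Peptide(_random_peptide(rng, lo, hi))
        pep_b = Peptide(_random_peptide(rng, lo, hi))
        link_a = int(rng.integers(1, len(pep_a) + 1))
        link_b = int(rng.integers(1, len(pep_b) + 1))
        charge = int(rng.integers(3, 5))
        psm = CrossLinkedPSM(
            peptides=(pep_a, pep_b),
            link_positions=(link_a, link_b),
            crosslinker_mass=CROSSLINKER_MASS,
            precursor_charge=charge,
            scores={"score": score},
            decoy_flags=(decoy, False),
            pass_threshold=not below,
            psm_id=f"psm{k}",
            scan_index=k,
        )
    else:
        pep = Peptide(_random_peptide(rng, lo, hi))
        charge = int(rng.integers(2, 4))
        psm = CrossLinkedPSM(
            peptides=(pep,),
            precursor_charge=charge,
            scores={"score": score},
            decoy_flags=(decoy,),
            pass_threshold=not below,
            psm_id=f"psm{k}",
            scan_index=k,
        )
    mz = mz_from_neutral(psm.neutral_mass(), psm.precursor_charge)
    return replace(psm, precursor_mz=float(np.round(mz, 6)))


def make_fixtures(spec: FixtureSpec, out_dir) -> FixtureSet:
    """Generate the MGF + CSV pair and the ground-truth match table.

    For each PSM the spectrum contains every b/y fragment peak (cross-link
    mass shifts included) at singly-charged m/z with ppm jitter, plus
    ``spec.noise_peaks`` uniform noise peaks.  Identical seed and spec give
    byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    mgf_path = out_dir / "synthetic.mgf"
    csv_path = out_dir / "synthetic.csv"
    truth_path = out_dir / "synthetic_truth.json"

    spectra: list[Spectrum] = []
    psms: list[CrossLinkedPSM] = []
    truth: list[dict] = []
    csv_rows: list[str] = []

    for k in range(spec.n_psms):
        psm = _make_psm(rng, spec, k)
        psm = replace(psm, peak_list_filename=mgf_path.name)
        fragments = generate_fragments(psm, FIXTURE_SETTINGS)
        planted_mz = []
        planted_keys = []
        for frag in fragments:
            jitter = rng.normal(0.0, spec.jitter_ppm) * 1e-6
            planted_mz.append(frag.mz * (1.0 + jitter))
            planted_keys.append(fragment_key(frag))
        planted_mz_arr = np.array(planted_mz)
        lo = 100.0
        hi = float(planted_mz_arr.max()) + 100.0 if len(planted_mz_arr) else 1500.0
        noise_mz = rng.uniform(lo, hi, spec.noise_peaks)
        all_mz = np.concatenate([planted_mz_arr, noise_mz])
        intensity = np.round(rng.lognormal(mean=9.0, sigma=1.0, size=len(all_mz)), 3)
        all_mz = np.round(all_mz, 6)
        # merge coinciding peaks (e.g. two isobaric fragments with zero
        # jitter) so every planted fragment maps to a unique peak index
        uniq_mz, inverse = np.unique(all_mz, return_inverse=True)
        uniq_intensity = np.zeros(len(uniq_mz))
        np.add.at(uniq_intensity, inverse, intensity)
        uniq_intensity = np.round(uniq_intensity, 3)

        peaks_truth: dict[str, list[str]] = {}
        for j, key in enumerate(planted_keys):
            peaks_truth.setdefault(str(int(inverse[j])), []).append(key)

        spectrum = Spectrum(
            mz=uniq_mz,
            intensity=uniq_intensity,
            filename=mgf_path.name,
            scan_id=str(k + 1),
            scan_index=k,
            precursor_mz=psm.precursor_mz,
            precursor_charge=psm.precursor_charge,
            title=f"synthetic scan={k + 1}",
        )
        spectra.append(spectrum)
        psms.append(psm)
        truth.append(
            {"psm_id": psm.psm_id, "scan_index": k, "peaks": peaks_truth}
        )

        from .mass_model import render_sequence

        if psm.is_crosslinked:
            seq1 = render_sequence(psm.peptides[0], psm.link_positions[0])
            seq2 = render_sequence(psm.peptides[1], psm.link_positions[1])
            linker = f"{CROSSLINKER_MASS!r}"
        else:
            seq1 = render_sequence(psm.peptides[0])
            seq2 = ""
            linker = ""
        csv_rows.append(
            ",".join(
                [
                    psm.psm_id,
                    str(k + 1),  # scanNumber
                    str(k),  # scanIndex
                    mgf_path.name,
                    seq1,
                    seq2,
                    "",
                    "",
                    linker,
                    str(psm.precursor_charge),
                    f"{psm.scores['score']!r}",
                    f"SYN{2 * k}",
                    f"SYN{2 * k + 1}" if seq2 else "",
                    "true" if psm.decoy_flags[0] else "false",
                    ("true" if psm.decoy_flags[1] else "false") if seq2 else "",
                    "true" if psm.pass_threshold else "false",
                ]
            )
        )

    write_mgf(spectra, mgf_path)
    header = (
        "id,scanNumber,scanIndex,peakListFileName,pepSeq1,pepSeq2,linkPos1,"
        "linkPos2,crosslinkerModMass,charge,score,protein1,protein2,decoy1,"
        "decoy2,passThreshold"
    )
    csv_path.write_text(header + "\n" + "\n".join(csv_rows) + "\n", encoding="ascii")
    truth_path.write_text(
        json.dumps(truth, sort_keys=True, indent=0) + "\n", encoding="ascii"
    )
    return FixtureSet(
        mgf_path=mgf_path,
        csv_path=csv_path,
        truth_path=truth_path,
        truth=truth,
        spectra=spectra,
        psms=psms,
    )


def evaluate_recovery(
    fixtures: FixtureSet,
    settings: AnnotationSettings = FIXTURE_SETTINGS,
) -> tuple[float, list[AnnotatedSpectrum]]:
    """Annotate every fixture PSM and score planted-peak recovery.

    A planted fragment counts as recovered when annotation matches that
    fragment (same peptide/series/index/charge) to the exact peak index it
    was planted at.  Returns the recovered fraction and the annotations.
    """
    recovered = 0
    total = 0
    annotated_all = []
    for psm, spectrum, entry in zip(fixtures.psms, fixtures.spectra, fixtures.truth):
        annotated = annotate(spectrum, psm, settings)
        annotated_all.append(annotated)
        got = {
            (m.peak_index, fragment_key(m.fragment))
            for m in annotated.monoisotopic_matches
        }
        for peak_index, keys in entry["peaks"].items():
            for key in keys:
                total += 1
                if (int(peak_index), key) in got:
                    recovered += 1
    return (recovered / total if total else 0.0), annotated_all
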