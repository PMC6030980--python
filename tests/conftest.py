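import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # oracle.py, fixture_docs.py

from speclink import (
    AnnotationSettings,
    CrossLinkedPSM,
    FixtureSpec,
    Peptide,
    Tolerance,
    default_modification_registry,
    make_fixtures,
)

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def registry():
    return default_modification_registry()


@pytest.fixture
def by_settings():
    """b/y ions, singly charged, no losses: the planted-peak hypothesis."""
    return AnnotationSettings(
        tolerance=Tolerance(20.0, "ppm"),
        ion_types=frozenset({"b", "y"}),
        max_fragment_charge=1,
        losses_enabled=False,
    )


def random_peptide(rng, lo=5, hi=15):
    length = int(rng.integers(lo, hi + 1))
    return "".join(RESIDUES[i] for i in rng.integers(0, len(RESIDUES), length))


def random_modified_peptide(rng, registry, lo=5, hi=30, max_mods=3):
    """A random Peptide with 0..max_mods registered modifications placed at
    distinct positions (termini included); returns (peptide, deltas)."""
    seq = random_peptide(rng, lo, hi)
    mods = []
    names = registry.names()
    n_mods = int(rng.integers(0, max_mods + 1))
    positions = rng.choice(len(seq) + 2, size=min(n_mods, len(seq)), replace=False)
    for pos in positions:
        mod = registry[names[int(rng.integers(0, len(names)))]]
        mods.append((int(pos), mod))
    pep = Peptide(seq, tuple(mods))
    return pep, [m.mass_delta for _p, m in mods]


def random_crosslinked_psm(rng, lo=4, hi=12, linker=138.06808):
    a = Peptide(random_peptide(rng, lo, hi))
    b = Peptide(random_peptide(rng, lo, hi))
    return CrossLinkedPSM(
        peptides=(a, b),
        link_positions=(int(rng.integers(1, len(a) + 1)), int(rng.integers(1, len(b) + 1))),
        crosslinker_mass=linker,
        precursor_charge=int(rng.integers(3, 6)),
    )


@pytest.fixture(scope="session")
def small_fixture_set(tmp_path_factory):
    """A shared 30-PSM synthetic dataset with 5 ppm jitter."""
    spec = FixtureSpec(n_psms=30, jitter_ppm=5.0, noise_peaks=20, seed=11)
    return make_fixtures(spec, tmp_path_factory.mktemp("fixtures"))
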