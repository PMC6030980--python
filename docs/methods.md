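# Methods

## Mass model

All arithmetic is monoisotopic.  Residue masses are derived at import time
from elemental compositions and IUPAC/CODATA lightest-isotope atomic masses
(H 1.00782503207, C 12, N 14.0030740048, O 15.9949146196, S 31.97207100),
so the residue table is internally consistent by construction (G =
57.02146, …).  Fixed constants: proton 1.00727646688 Da, water
18.0105646863 Da, ammonia 17.0265491015 Da, isotope spacing 1.0033548378 Da
(the average 13C−12C increment, used for cluster detection at spacing/z).
Ambiguous residue codes B/Z/X are rejected rather than averaged: annotation
needs exact masses, and a guessed average would silently bias every
downstream error.

Modification positions are 1-based residue indices with 0 for the
N-terminus and n+1 for the C-terminus, matching mzIdentML's `location`
convention, so identifications imported from mzIdentML need no index
translation.  The built-in registry ships ox (+15.99491, M), cm (+57.02146,
C), ph (+79.96633, S/T/Y), deam (+0.98402, N/Q) and ac (+42.01057, K,
N-term) as a documented default; any token can be added or overwritten at
runtime or loaded from a two-column text table, and re-registering a name
replaces its mass (that is how "edit the modification table" is expressed
programmatically).  Specificity is advisory only — hypothesis testing
explicitly includes moving a modification onto residues it would not
normally occur on.

## Fragmentation

b/c/y/z and the unfragmented precursor.  z is classical z = y − NH3 by
default; a `z_radical` flag adds one hydrogen for the ETD z-dot convention,
since both conventions circulate and the difference (1.00783 Da) is far
above usual tolerances.  Modifications partition with the residue that
carries them (N-terminal mods go with every prefix, C-terminal with every
suffix), which preserves the exact complementarity b_i + y_{n−i} = M for
modified peptides.

Cross-linked fragments: a fragment whose residue range covers its
peptide's link site gains linker + intact partner mass.  This makes a
cross-linked peptide exactly equivalent to the same linear peptide carrying
a single (linker + partner) modification at the link site — an identity
the test suite exploits as an oracle.  To keep that identity exact,
neutral-loss eligibility considers only the fragment's own residue range,
not the carried partner's residues; losses from the intact partner are a
known simplification.

Fragment charge states run 1..min(precursor charge, `max_fragment_charge`),
the precursor charge being the physical ceiling; the default cap of 2
reflects that singly and doubly charged fragments dominate CID/HCD spectra.
Only single-loss variants are generated (no −H2O−NH3 combinations), keeping
the label space the size seen in practice.  Loss eligibility is
residue-dependent (H2O: S/T/E/D; NH3: R/K/N/Q) — a deliberate choice; an
unconditional-loss policy would only add never-matching fragments but is
not what is implemented here.

## Matching

Per fragment, the observed peak with the smallest |Δm/z| within tolerance
wins — closest, not most intense, because the per-fragment error is what
the QC plots display.  One peak may carry several fragment labels; all are
kept (ties between fragments for a peak are not broken).  Tolerance is
`value` + unit, ppm windows scaling with m/z, Da windows constant; the
string forms `10ppm` / `0.02Da` parse case-insensitively.  Errors are
signed observed − theoretical, recorded in both Da and ppm.

Isotope clusters extend each monoisotopic match at +k·1.0033548/z for
k = 1, 2, …, stopping at the first missing peak and capped at k = 6
(bounded, deterministic).  The search is anchored on the *observed*
monoisotopic peak so a calibration offset shifts the whole cluster instead
of breaking it; the recorded isotope-peak error is relative to that
anchored prediction.  QC points are one per monoisotopic match (isotope
peaks would triple-count the same ion), labeled by peptide (alpha/beta) and
loss status for the two-color rendering.

Re-annotation recomputes from scratch under a replaced PSM or settings and
carries the first (PSM, settings) snapshot along, so revert is exact by
construction rather than by caching rendered state; annotations are
immutable throughout.

## I/O

The MGF reader builds a byte-offset index in a single pass and re-reads
only the requested block afterwards; a `BEGIN IONS` without `END IONS`
fails with the offending line number.  Spectra resolve by ordinal index
first, then SCANS number, then TITLE — MGF files frequently lack SCANS.
The writer emits full-precision floats (`repr`), making write→read a peak-
identical round trip.

mzML and mzIdentML are parsed with lxml, namespace-tolerant so 1.1 and 1.2
documents both work, driven by cvParam accessions (64/32-bit float, zlib /
no compression, m/z vs intensity arrays, selected-ion m/z and charge).
Numpress-compressed arrays are recognized and rejected by name.  Cross-link
pairing follows PSI mzIdentML 1.2: Modification elements carrying
cross-link donor (MS:1002509) and acceptor (MS:1002510) cvParams are fused
into one PSM by shared value; an orphaned donor or acceptor is a hard
error listing the value.  All numeric cvParams on an identification item
are carried as named scores; rank, isDecoy and passThreshold map to fields,
with rank > 1 serving as alternative explanations.

The CSV dialect is defined by this package (frozen in the README).  The
dataset store is one SQLite file per dataset — trivially copyable,
shareable and deletable; spectra are stored as JSON float arrays (exact
round trip via repr) and PSMs as JSON records.  The annotation JSON is
validated by pydantic models; the shipped `annotation_schema.json` is
generated from those models, and a test pins the two together.

## SVG export

Rendering is a pure function of (annotation, style): floats are formatted
to fixed precision and element order is deterministic, so re-rendering is
byte-identical.  In the spectrum view, peaks are the only `<line>` elements
(axes and label leaders are `<path>`), so element counts audit peak counts
directly.  Labels de-overlap by a greedy left-to-right pass that stacks
colliding labels upward and adds dashed leader lines — an automatic,
reproducible stand-in for manual label dragging.  Default palette: alpha
red, beta blue; neutral-loss items are lightened by mixing toward white;
loss labels can be suppressed.

## Synthetic data

The generator emulates a centroided MS2 peak list for each random PSM:
every b/y fragment peak (singly charged, cross-link shifts included) with
Gaussian relative mass error, plus uniform-random noise peaks with
log-normal intensities.  Defaults: 200 PSMs, peptide lengths 6–14, 50%
cross-linked (linker 138.06808 Da, the BS3/DSS bridge), 30 noise peaks per
spectrum, 5 ppm jitter (a typical Orbitrap calibration spread) against a
20 ppm matching tolerance (4σ, so ≥99% of planted peaks fall inside the
window), 10% decoys.  Peaks that coincide after rounding to 6 decimals are
merged so each planted fragment owns a unique peak index.

What it does not emulate: isotope envelopes, correlated calibration drift,
intensity structure of real fragmentation, co-isolated precursors, or
realistic decoy sequences.  Passing the recovery tests therefore
demonstrates the correctness of the matching machinery under known truth,
not search-engine-grade performance on real data.

## Problem sizes

The test suite and acceptance script use 200 peptides/PSMs for mass and
complementarity sweeps, 100 spectra for matcher-oracle equivalence, 50
PSMs for the cross-link equivalence and 200 PSMs for recovery runs —
large enough for the Monte-Carlo estimates to be stable to well under a
percentage point while the whole suite runs in seconds.

## Known limitations

- No a/x ions, internal fragments, immonium ions, or cleavable-linker stub
  fragments; no average-mass mode.
- No rescoring or FDR machinery: decoy and threshold flags are carried and
  filterable, never computed.
- Loop-links within one peptide are not modeled; CSV mono-links are folded
  into a modification.
- mzML writing is out of scope (reading only), as is mzIdentML writing.
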