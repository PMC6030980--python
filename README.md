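# speclink

Annotation of tandem mass spectra against linear and **cross-linked**
peptide-spectrum matches (PSMs), with standard-format I/O, QC error
statistics, a peak-distance measuring tool, re-annotation under modified
hypotheses, and deterministic SVG export of the three classic views:
annotated spectrum, peptide fragmentation key, and match-error QC plots.

It is aimed at people who need to look at individual spectra and stay in
control of the identification process: mass spectrometrists reviewing
search-engine output (especially from cross-linking experiments, where a
fragment spanning the link site carries the cross-linker plus the entire
partner peptide), authors preparing annotated spectra for publication, and
tool developers who need a scriptable, file-format-compliant annotator.

## The model

For a peptide of residues $r_1 \dots r_n$ with positioned modification
masses, backbone fragments are computed from monoisotopic residue masses:

$$b_i = \sum_{k \le i} m(r_k), \qquad y_j = \sum_{k > n-j} m(r_k) + m_{\mathrm{H_2O}},
\qquad c_i = b_i + m_{\mathrm{NH_3}}, \qquad z_j = y_j - m_{\mathrm{NH_3}}$$

with $m/z = (M + z\,m_\mathrm{p})/z$.  For a pair of peptides $\alpha,\beta$
joined by a cross-linker of mass $L$ at sites $s_\alpha, s_\beta$, any
fragment of $\alpha$ whose residue range contains $s_\alpha$ additionally
carries $L + M_\beta$ (the partner does not fragment in that ion), and
symmetrically; the precursor is $M_\alpha + M_\beta + L$.  Neutral-loss
variants ($-\mathrm{H_2O}$ for S/T/E/D, $-\mathrm{NH_3}$ for R/K/N/Q) are
generated per fragment.

Each theoretical fragment is matched to the observed peak with the smallest
$|\Delta m/z|$ within the tolerance (ppm or Da); matched peaks are extended
into isotope clusters at spacing $1.00335/z$ Th until the first gap.  Match
errors are signed, observed − theoretical, and reported in ppm and Da.

## Worked example

```python
import numpy as np
from speclink import *

pa, la = parse_sequence("GK#AR")          # '#' marks the cross-link site
pb, lb = parse_sequence("VGK#F")
psm = CrossLinkedPSM(peptides=(pa, pb), link_positions=(la, lb),
                     crosslinker_mass=138.06808, precursor_charge=3)
settings = AnnotationSettings(tolerance=Tolerance(10, "ppm"),
                              ion_types=frozenset({"b", "y"}),
                              max_fragment_charge=1, losses_enabled=False)
# a synthetic spectrum containing every b/y peak with ~3 ppm noise
frags = generate_fragments(psm, settings)
rng = np.random.default_rng(0)
mzs = np.sort([f.mz * (1 + rng.normal(0, 3e-6)) for f in frags])
spectrum = Spectrum(mz=np.round(mzs, 5),
                    intensity=np.round(rng.uniform(10, 100, len(mzs)), 1))
annotated = annotate(spectrum, psm, settings)
```

prints, for the first matches:

```
total mass 1017.59712
12 theoretical fragments, 12 matched
  alpha y3   m/z 961.58293  obs 961.58329  err  +0.38 ppm  link=True
  alpha b1   m/z  58.02874  obs  58.02872  err  -0.35 ppm  link=False
  alpha y2   m/z 246.15607  obs 246.15654  err  +1.93 ppm  link=False
  alpha b2   m/z 773.45560  obs 773.45585  err  +0.32 ppm  link=True
```

`total mass` is $M_\alpha + M_\beta + L$.  `y3` of GKAR (KAR) spans the
K2 link site, so its mass includes the linker plus the whole VGKF peptide
(`link=True`); `b1` (G alone) does not.  The signed ppm errors are what the
QC plots display.  `spectrum_svg`, `fragkey_svg` and `qc_svg` render the
three views; `measure` converts a peak-distance to masses at several charge
states and lists residues whose mass explains the gap.

From the shell, the same pipeline is:

```sh
speclink fixtures --n-psms 4 --seed 2 --out fx/
speclink annotate --peaks fx/synthetic.mgf --ids fx/synthetic.csv \
         --tolerance 20ppm --ions b,y --out annotations.json
speclink render --annotation annotations.json --view spectrum --out spectrum.svg
```

## File formats

Peak lists: MGF (byte-offset indexed; TITLE/PEPMASS/CHARGE/SCANS honored)
and mzML (zlib or uncompressed, 32/64-bit float arrays).  Identifications:
mzIdentML 1.1/1.2 — including cross-link donor/acceptor pairing via the
MS:1002509/MS:1002510 cvParams — and a CSV dialect.  All readers accept
`.gz`/`.zip` compressed input.  Annotation results serialize to a versioned
JSON document (schema in `src/speclink/annotation_schema.json`); parsed
datasets persist one-file-per-dataset as SQLite.

### CSV identification dialect

Header row required.  Mandatory columns: `pepSeq1`, `charge`, and one of
`scanNumber`/`scanIndex`.

| column | meaning |
|---|---|
| `id` | PSM identifier (default: row number) |
| `scanNumber` / `scanIndex` | spectrum reference (index preferred) |
| `peakListFileName` | peak-list file the scan lives in |
| `pepSeq1`, `pepSeq2` | peptide sequences in the grammar below; empty `pepSeq2` = linear PSM |
| `linkPos1`, `linkPos2` | 1-based link sites (alternative to in-sequence `#`) |
| `crosslinkerModMass` | cross-linker mass in Da |
| `charge` | precursor charge |
| `score` | primary score (higher = better) |
| `protein1`, `protein2` | protein accessions |
| `decoy1`, `decoy2` | per-peptide decoy flags (`true`/`false`) |
| `passThreshold` | search-engine threshold flag |
| `fragmentTolerance`, `ionTypes` | optional per-PSM annotation hints |

Unknown extra columns are preserved (numeric → scores, other → metadata).

Sequence grammar: uppercase residue letters; a lowercase token directly
after a residue names a modification on it (`Mox`, `Ccm`, …; registry
extensible at runtime or via a two-column text table); a single `#` after a
residue marks the cross-link site (`GK#AR`).

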