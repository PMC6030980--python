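"""Readers and writers for the standard formats, plus the dataset store.

Peak lists: MGF (byte-offset indexed, written and read) and mzML (binary
data arrays, zlib or uncompressed, 32/64-bit floats).  Identifications:
mzIdentML 1.1/1.2 (including cross-link donor/acceptor pairing) and a CSV
dialect documented in the README.  All readers accept ``.gz`` and ``.zip``
compressed inputs transparently.

Annotation results serialize to a versioned JSON document (schema shipped
as ``annotation_schema.json``); datasets persist to a single SQLite file
each, with filtered/ordered PSM queries on top.
"""

from __future__ import annotations

import base64
import gzip
import io
import json
import re
import sqlite3
import zipfile
import zlib
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, List, Mapping, Optional, Sequence, Union

import numpy as np
from lxml import etree
from pydantic import BaseModel, Field

from .annotation import AnnotatedSpectrum, PeakMatch, Spectrum, annotate
from .fragmentation import (
    AnnotationSettings,
    CrossLinkedPSM,
    FragmentIon,
    Tolerance,
)
from .mass_model import (
    Modification,
    ModificationRegistry,
    Peptide,
    default_modification_registry,
    parse_sequence,
    render_sequence,
)

__all__ = [
    "Dataset",
    "FormatError",
    "MgfReader",
    "MzmlReader",
    "PsmFilter",
    "build_dataset",
    "list_psms",
    "load_annotation_json",
    "load_dataset",
    "read_csv_ids",
    "read_mgf",
    "read_mzidentml",
    "read_mzml",
    "save_dataset",
    "sniff_format",
    "write_annotation_json",
    "write_mgf",
]

PathLike = Union[str, Path]


class FormatError(ValueError):
    """Raised when an input file violates its format."""


# --------------------------------------------------------------------------
# Compression handling
# --------------------------------------------------------------------------


def open_binary(path: PathLike) -> io.BytesIO:
    """Read a file into a seekable buffer, decompressing .gz/.zip archives.

    A .zip archive must contain exactly one member (the data file).
    """
    path = Path(path)
    if path.suffix.lower() == ".gz":
        with gzip.open(path, "rb") as fh:
            return io.BytesIO(fh.read())
    if path.suffix.lower() == ".zip":
        with zipfile.ZipFile(path) as zf:
            names = zf.namelist()
            if len(names) != 1:
                raise FormatError(
                    f"{path}: zip archive must contain exactly one file, "
                    f"found {len(names)}"
                )
            return io.BytesIO(zf.read(names[0]))
    return io.BytesIO(path.read_bytes())


def _inner_name(path: PathLike) -> str:
    """Logical filename with any compression suffix stripped."""
    path = Path(path)
    if path.suffix.lower() in (".gz", ".zip"):
        return path.stem
    return path.name


# --------------------------------------------------------------------------
# MGF — indexed reader and writer
# --------------------------------------------------------------------------

_CHARGE_RE = re.compile(r"(\d+)\s*([+-]?)")


class MgfReader:
    """Byte-offset-indexed reader over an MGF peak-list file.

    The index is built in a single pass; fetching spectrum *k* afterwards
    re-reads only that spectrum's byte range.  TITLE, PEPMASS, CHARGE and
    SCANS headers are honored.  Spectra are addressable by ordinal index,
    SCANS number, or TITLE.
    """

    def __init__(self, path: PathLike) -> None:
        self.path = Path(path)
        self.filename = _inner_name(path)
        self._buf = open_binary(path)
        #: list of (start_offset, end_offset, begin_line_number)
        self._index: list[tuple[int, int, int]] = []
        self._scan_to_index: dict[int, int] = {}
        self._title_to_index: dict[str, int] = {}
        self._build_index()

    def _build_index(self) -> None:
        buf = self._buf
        buf.seek(0)
        begin_offset = None
        begin_line = None
        lineno = 0
        offset = 0
        for raw in buf:
            lineno += 1
            line = raw.strip()
            if line == b"BEGIN IONS":
                if begin_offset is not None:
                    raise FormatError(
                        f"{self.path}:{begin_line}: BEGIN IONS block not "
                        f"terminated by END IONS before line {lineno}"
                    )
                begin_offset = offset
                begin_line = lineno
            elif line == b"END IONS":
                if begin_offset is None:
                    raise FormatError(
                        f"{self.path}:{lineno}: END IONS without BEGIN IONS"
                    )
                self._index.append((begin_offset, offset + len(raw), begin_line))
                begin_offset = None
            offset += len(raw)
        if begin_offset is not None:
            raise FormatError(
                f"{self.path}:{begin_line}: BEGIN IONS block missing END IONS"
            )
        # secondary lookups need the headers; read them per block (cheap,
        # header lines only)
        for k in range(len(self._index)):
            header = self._block_headers(k)
            if "SCANS" in header:
                try:
                    self._scan_to_index[int(header["SCANS"])] = k
                except ValueError:
                    pass
            if "TITLE" in header:
                self._title_to_index[header["TITLE"]] = k

    def __len__(self) -> int:
        return len(self._index)

    def _block_lines(self, k: int) -> list[str]:
        start, end, _ = self._index[k]
        self._buf.seek(start)
        return self._buf.read(end - start).decode("utf-8", "replace").splitlines()

    def _block_headers(self, k: int) -> dict[str, str]:
        headers: dict[str, str] = {}
        for line in self._block_lines(k):
            line = line.strip()
            if line in ("BEGIN IONS", "END IONS") or not line:
                continue
            if "=" in line:
                key, _, value = line.partition("=")
                headers[key.strip().upper()] = value.strip()
            else:
                break  # first peak line ends the header section
        return headers

    def __getitem__(self, k: int) -> Spectrum:
        start, end, begin_line = self._index[k]
        headers: dict[str, str] = {}
        mzs: list[float] = []
        intensities: list[float] = []
        in_header = True
        for off, line in enumerate(self._block_lines(k)):
            line = line.strip()
            if line in ("BEGIN IONS", "END IONS") or not line:
                continue
            if in_header and "=" in line and not line[0].isdigit():
                key, _, value = line.partition("=")
                headers[key.strip().upper()] = value.strip()
                continue
            in_header = False
            parts = line.split()
            try:
                mzs.append(float(parts[0]))
                intensities.append(float(parts[1]) if len(parts) > 1 else 0.0)
            except (ValueError, IndexError):
                raise FormatError(
                    f"{self.path}:{begin_line + off}: malformed peak line {line!r}"
                ) from None
        precursor_mz = None
        if "PEPMASS" in headers:
            precursor_mz = float(headers["PEPMASS"].split()[0])
        precursor_charge = None
        if "CHARGE" in headers:
            m = _CHARGE_RE.search(headers["CHARGE"])
            if m:
                precursor_charge = int(m.group(1))
        scan_id = headers.get("SCANS", str(k))
        return Spectrum(
            mz=np.array(mzs),
            intensity=np.array(intensities),
            filename=self.filename,
            scan_id=scan_id,
            scan_index=k,
            precursor_mz=precursor_mz,
            precursor_charge=precursor_charge,
            title=headers.get("TITLE", ""),
        )

    def __iter__(self):
        return (self[k] for k in range(len(self)))

    def get_by_scan(self, scan_number: int) -> Spectrum:
        try:
            return self[self._scan_to_index[scan_number]]
        except KeyError:
            raise KeyError(f"no spectrum with SCANS={scan_number}") from None

    def get_by_title(self, title: str) -> Spectrum:
        try:
            return self[self._title_to_index[title]]
        except KeyError:
            raise KeyError(f"no spectrum with TITLE={title!r}") from None

    @property
    def byte_offsets(self) -> list[tuple[int, int]]:
        return [(s, e) for s, e, _ in self._index]


def read_mgf(path: PathLike) -> MgfReader:
    """Open an MGF file (optionally .gz/.zip) with a byte-offset index."""
    return MgfReader(path)


def write_mgf(spectra: Iterable[Spectrum], path: PathLike) -> None:
    """Write spectra as MGF, preserving full float precision (round-trip safe)."""
    with open(path, "w", encoding="ascii") as fh:
        for k, spec in enumerate(spectra):
            fh.write("BEGIN IONS\n")
            title = spec.title or f"{spec.filename or 'spectrum'} index={k}"
            fh.write(f"TITLE={title}\n")
            if spec.precursor_mz is not None:
                fh.write(f"PEPMASS={spec.precursor_mz!r}\n")
            if spec.precursor_charge is not None:
                fh.write(f"CHARGE={spec.precursor_charge}+\n")
            if spec.scan_id:
                try:
                    fh.write(f"SCANS={int(spec.scan_id)}\n")
                except ValueError:
                    pass
            for mz, inten in zip(spec.mz, spec.intensity):
                fh.write(f"{float(mz)!r} {float(inten)!r}\n")
            fh.write("END IONS\n")


# --------------------------------------------------------------------------
# mzML
# --------------------------------------------------------------------------

_ACC_64BIT = "MS:1000523"
_ACC_32BIT = "MS:1000521"
_ACC_NO_COMPRESSION = "MS:1000576"
_ACC_ZLIB = "MS:1000574"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INTENSITY_ARRAY = "MS:1000515"
_ACC_SELECTED_MZ = "MS:1000744"
_ACC_CHARGE_STATE = "MS:1000041"

#: compression cvParam accessions we recognise but do not support
_KNOWN_UNSUPPORTED_COMPRESSION = {
    "MS:1002312": "MS-Numpress linear prediction compression",
    "MS:1002313": "MS-Numpress positive integer compression",
    "MS:1002314": "MS-Numpress short logged float compression",
    "MS:1002746": "MS-Numpress linear prediction compression followed by zlib",
    "MS:1002747": "MS-Numpress positive integer compression followed by zlib",
    "MS:1002748": "MS-Numpress short logged float compression followed by zlib",
}


def _cv_accessions(element) -> dict[str, str]:
    """accession → name for all cvParams directly under ``element``."""
    return {
        cv.get("accession", ""): cv.get("name", "")
        for cv in element.iter("{*}cvParam")
    }


def _decode_binary_array(bda) -> np.ndarray:
    params = _cv_accessions(bda)
    for acc, name in params.items():
        if acc in _KNOWN_UNSUPPORTED_COMPRESSION:
            raise FormatError(
                f"unsupported binary-array compression scheme: "
                f"{name or _KNOWN_UNSUPPORTED_COMPRESSION[acc]} ({acc})"
            )
    if _ACC_64BIT in params:
        dtype = "<f8"
    elif _ACC_32BIT in params:
        dtype = "<f4"
    else:
        raise FormatError("binaryDataArray lacks a 32-/64-bit float cvParam")
    binary = bda.find("{*}binary")
    text = (binary.text or "") if binary is not None else ""
    try:
        raw = base64.b64decode(text, validate=True)
    except Exception as exc:
        raise FormatError(f"invalid base64 binary payload: {exc}") from exc
    if _ACC_ZLIB in params:
        try:
            raw = zlib.decompress(raw)
        except zlib.error as exc:
            raise FormatError(f"zlib decompression failed: {exc}") from exc
    elif _ACC_NO_COMPRESSION not in params:
        # tolerate a missing "no compression" cvParam (some writers omit it)
        pass
    itemsize = np.dtype(dtype).itemsize
    if len(raw) % itemsize:
        raise FormatError(
            f"binary payload of {len(raw)} bytes is not a whole number of "
            f"{itemsize}-byte floats (truncated?)"
        )
    return np.frombuffer(raw, dtype=dtype).astype(float)


class MzmlReader:
    """Reader over an mzML document; spectra by nativeID or ordinal index."""

    def __init__(self, path: PathLike) -> None:
        self.path = Path(path)
        self.filename = _inner_name(path)
        try:
            tree = etree.parse(open_binary(path))
        except etree.XMLSyntaxError as exc:
            raise FormatError(f"{path}: not well-formed XML: {exc}") from exc
        self._spectra = list(tree.iter("{*}spectrum"))
        self._id_to_index = {
            el.get("id"): k for k, el in enumerate(self._spectra) if el.get("id")
        }

    def __len__(self) -> int:
        return len(self._spectra)

    def native_ids(self) -> list[str]:
        return [el.get("id", "") for el in self._spectra]

    def __getitem__(self, k: int) -> Spectrum:
        el = self._spectra[k]
        mz = intensity = None
        for bda in el.iter("{*}binaryDataArray"):
            params = _cv_accessions(bda)
            if _ACC_MZ_ARRAY in params:
                mz = _decode_binary_array(bda)
            elif _ACC_INTENSITY_ARRAY in params:
                intensity = _decode_binary_array(bda)
        if mz is None or intensity is None:
            raise FormatError(
                f"{self.path}: spectrum {el.get('id')!r} lacks m/z or "
                "intensity binary arrays"
            )
        precursor_mz = precursor_charge = None
        for ion in el.iter("{*}selectedIon"):
            params = {
                cv.get("accession"): cv.get("value")
                for cv in ion.iter("{*}cvParam")
            }
            if _ACC_SELECTED_MZ in params:
                precursor_mz = float(params[_ACC_SELECTED_MZ])
            if _ACC_CHARGE_STATE in params:
                precursor_charge = int(params[_ACC_CHARGE_STATE])
        native_id = el.get("id", "")
        scan_match = re.search(r"scan=(\d+)", native_id)
        return Spectrum(
            mz=mz,
            intensity=intensity,
            filename=self.filename,
            scan_id=scan_match.group(1) if scan_match else native_id,
            scan_index=k,
            precursor_mz=precursor_mz,
            precursor_charge=precursor_charge,
            title=native_id,
        )

    def get_by_id(self, native_id: str) -> Spectrum:
        try:
            return self[self._id_to_index[native_id]]
        except KeyError:
            raise KeyError(f"no spectrum with nativeID {native_id!r}") from None

    def __iter__(self):
        return (self[k] for k in range(len(self)))


def read_mzml(path: PathLike) -> MzmlReader:
    """Open an mzML file (optionally .gz/.zip)."""
    return MzmlReader(path)


# --------------------------------------------------------------------------
# mzIdentML
# --------------------------------------------------------------------------

_ACC_XL_DONOR = "MS:1002509"
_ACC_XL_ACCEPTOR = "MS:1002510"

_NON_SCORE_SII_ACCESSIONS = {
    "MS:1002511",  # cross-link spectrum identification item
}


def _mod_token_from_name(name: str, delta: float) -> str:
    token = re.sub(r"[^a-z0-9]", "", name.lower())
    if not token or not token[0].isalpha():
        sign = "p" if delta >= 0 else "m"
        token = f"mod{sign}{abs(delta):.5f}".replace(".", "")
    return token


def read_mzidentml(
    path: PathLike, registry: Optional[ModificationRegistry] = None
) -> tuple[list[CrossLinkedPSM], ModificationRegistry]:
    """Parse mzIdentML 1.1/1.2 identifications.

    SpectrumIdentificationItems become PSMs with rank, decoy and threshold
    flags, and all numeric cvParams carried as named scores.  Pairs of
    Modification elements bearing cross-link donor/acceptor cvParams
    (MS:1002509 / MS:1002510) with a shared value are fused into a single
    cross-linked PSM; an unpaired donor or acceptor raises
    :class:`FormatError` naming the orphan value.

    Returns the PSM list and a modification registry extended with every
    modification named in the document (``origin='input-data'``).
    """
    registry = registry.copy() if registry is not None else default_modification_registry()
    try:
        tree = etree.parse(open_binary(path))
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"{path}: not well-formed XML: {exc}") from exc
    root = tree.getroot()

    db_accession = {
        el.get("id"): el.get("accession", "")
        for el in root.iter("{*}DBSequence")
    }

    # Peptide id -> (sequence, positioned mods, crosslink role info)
    peptides: dict[str, dict] = {}
    for pep_el in root.iter("{*}Peptide"):
        seq_el = pep_el.find("{*}PeptideSequence")
        seq = (seq_el.text or "").strip() if seq_el is not None else ""
        mods: list[tuple[int, Modification]] = []
        xl_role = None  # ("donor"|"acceptor", value, location, delta)
        for mod_el in pep_el.iter("{*}Modification"):
            location = int(mod_el.get("location", "0"))
            delta = float(mod_el.get("monoisotopicMassDelta", "0"))
            params = {
                cv.get("accession"): (cv.get("name", ""), cv.get("value", ""))
                for cv in mod_el.iter("{*}cvParam")
            }
            if _ACC_XL_DONOR in params:
                xl_role = ("donor", params[_ACC_XL_DONOR][1], location, delta)
                continue
            if _ACC_XL_ACCEPTOR in params:
                xl_role = ("acceptor", params[_ACC_XL_ACCEPTOR][1], location, delta)
                continue
            names = [n for n, _v in params.values() if n] or ["unknown modification"]
            token = _mod_token_from_name(names[0], delta)
            mod = registry.register(token, delta, origin="input-data")
            mods.append((location, mod))
        peptides[pep_el.get("id")] = {
            "sequence": seq,
            "mods": tuple(mods),
            "xl": xl_role,
        }

    evidence = {
        el.get("id"): {
            "peptide_ref": el.get("peptide_ref"),
            "is_decoy": el.get("isDecoy", "false").lower() == "true",
            "accession": db_accession.get(el.get("dBSequence_ref"), ""),
        }
        for el in root.iter("{*}PeptideEvidence")
    }

    spectra_data = {
        el.get("id"): Path(el.get("location", "")).name
        for el in root.iter("{*}SpectraData")
    }

    def build_peptide(info: dict) -> Peptide:
        return Peptide(info["sequence"], info["mods"])

    psms: list[CrossLinkedPSM] = []
    for sir in root.iter("{*}SpectrumIdentificationResult"):
        spectrum_id = sir.get("spectrumID", "")
        filename = spectra_data.get(sir.get("spectraData_ref"), "")
        scan_index = scan_number = None
        m = re.search(r"index=(\d+)", spectrum_id)
        if m:
            scan_index = int(m.group(1))
        m = re.search(r"scan=(\d+)", spectrum_id)
        if m:
            scan_number = int(m.group(1))

        items = []
        for sii in sir.findall("{*}SpectrumIdentificationItem"):
            pep_ref = sii.get("peptide_ref")
            info = peptides.get(pep_ref)
            if info is None:
                raise FormatError(f"{path}: unresolved peptide_ref {pep_ref!r}")
            ev_refs = [
                e.get("peptideEvidence_ref")
                for e in sii.findall("{*}PeptideEvidenceRef")
            ]
            evs = [evidence[e] for e in ev_refs if e in evidence]
            scores: dict[str, float] = {}
            for cv in sii.findall("{*}cvParam"):
                acc, name, value = cv.get("accession"), cv.get("name", ""), cv.get("value", "")
                if acc in _NON_SCORE_SII_ACCESSIONS or not name:
                    continue
                try:
                    scores[name] = float(value)
                except (TypeError, ValueError):
                    pass
            items.append(
                {
                    "id": sii.get("id", ""),
                    "rank": int(sii.get("rank", "1")),
                    "charge": int(sii.get("chargeState", "2")),
                    "exp_mz": float(sii.get("experimentalMassToCharge", "nan")),
                    "pass_threshold": sii.get("passThreshold", "true").lower() == "true",
                    "pep_info": info,
                    "is_decoy": any(e["is_decoy"] for e in evs),
                    "proteins": tuple(e["accession"] for e in evs if e["accession"]),
                    "scores": scores,
                }
            )

        donors = {
            it["pep_info"]["xl"][1]: it
            for it in items
            if it["pep_info"]["xl"] and it["pep_info"]["xl"][0] == "donor"
        }
        acceptors = {
            it["pep_info"]["xl"][1]: it
            for it in items
            if it["pep_info"]["xl"] and it["pep_info"]["xl"][0] == "acceptor"
        }
        orphans = set(donors) ^ set(acceptors)
        if orphans:
            raise FormatError(
                f"{path}: unpaired cross-link donor/acceptor value(s): "
                f"{sorted(orphans)}"
            )

        common = dict(
            peak_list_filename=filename,
            scan_number=scan_number,
            scan_index=scan_index,
        )
        for value, donor in donors.items():
            acceptor = acceptors[value]
            psms.append(
                CrossLinkedPSM(
                    peptides=(
                        build_peptide(donor["pep_info"]),
                        build_peptide(acceptor["pep_info"]),
                    ),
                    link_positions=(
                        donor["pep_info"]["xl"][2],
                        acceptor["pep_info"]["xl"][2],
                    ),
                    crosslinker_mass=donor["pep_info"]["xl"][3],
                    precursor_charge=donor["charge"],
                    precursor_mz=donor["exp_mz"],
                    scores={**acceptor["scores"], **donor["scores"]},
                    decoy_flags=(donor["is_decoy"], acceptor["is_decoy"]),
                    pass_threshold=donor["pass_threshold"] and acceptor["pass_threshold"],
                    rank=donor["rank"],
                    psm_id=donor["id"],
                    proteins=donor["proteins"] + acceptor["proteins"],
                    **common,
                )
            )
        paired_ids = {it["id"] for it in list(donors.values()) + list(acceptors.values())}
        for it in items:
            if it["id"] in paired_ids:
                continue
            psms.append(
                CrossLinkedPSM(
                    peptides=(build_peptide(it["pep_info"]),),
                    precursor_charge=it["charge"],
                    precursor_mz=it["exp_mz"],
                    scores=it["scores"],
                    decoy_flags=(it["is_decoy"],),
                    pass_threshold=it["pass_threshold"],
                    rank=it["rank"],
                    psm_id=it["id"],
                    proteins=it["proteins"],
                    **common,
                )
            )
    return psms, registry


# --------------------------------------------------------------------------
# CSV identification dialect
# --------------------------------------------------------------------------

CSV_MANDATORY = ("pepSeq1", "charge")
CSV_KNOWN_COLUMNS = (
    "id",
    "scanNumber",
    "scanIndex",
    "peakListFileName",
    "pepSeq1",
    "pepSeq2",
    "linkPos1",
    "linkPos2",
    "crosslinkerModMass",
    "charge",
    "score",
    "protein1",
    "protein2",
    "decoy1",
    "decoy2",
    "passThreshold",
    "fragmentTolerance",
    "ionTypes",
)


def _cell(row, name):
    import pandas as pd

    if name not in row or pd.isna(row[name]):
        return None
    value = row[name]
    if isinstance(value, str) and not value.strip():
        return None
    return value


def _to_bool(value, default=False) -> bool:
    if value is None:
        return default
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in ("1", "true", "t", "yes")


def read_csv_ids(
    path: PathLike, registry: Optional[ModificationRegistry] = None
) -> list[CrossLinkedPSM]:
    """Read identifications from the documented CSV dialect.

    Peptide columns use the sequence grammar (lowercase modification tokens,
    ``#`` cross-link site); ``linkPos1``/``linkPos2`` columns may state link
    positions instead of in-sequence ``#``.  An empty ``pepSeq2`` means a
    linear PSM.  Unknown extra columns are preserved: numeric ones as scores,
    others as opaque metadata.
    """
    import pandas as pd

    registry = registry or default_modification_registry()
    with open_binary(path) as buf:
        frame = pd.read_csv(io.TextIOWrapper(buf, encoding="utf-8"))
    missing = [c for c in CSV_MANDATORY if c not in frame.columns]
    if "scanNumber" not in frame.columns and "scanIndex" not in frame.columns:
        missing.append("scanNumber or scanIndex")
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s): {', '.join(missing)}")

    extra_columns = [c for c in frame.columns if c not in CSV_KNOWN_COLUMNS]
    psms: list[CrossLinkedPSM] = []
    for row_no, row in frame.iterrows():
        seq1 = _cell(row, "pepSeq1")
        if seq1 is None:
            raise FormatError(f"{path}: row {row_no + 1}: empty pepSeq1")
        pep1, link1 = parse_sequence(str(seq1), registry)
        seq2 = _cell(row, "pepSeq2")
        link_pos1 = _cell(row, "linkPos1")
        link_pos2 = _cell(row, "linkPos2")
        linker_mass = _cell(row, "crosslinkerModMass")
        if link1 is None and link_pos1 is not None:
            link1 = int(link_pos1)
        if seq2 is not None:
            pep2, link2 = parse_sequence(str(seq2), registry)
            if link2 is None and link_pos2 is not None:
                link2 = int(link_pos2)
            if link1 is None or link2 is None or linker_mass is None:
                raise FormatError(
                    f"{path}: row {row_no + 1}: cross-linked row requires link "
                    "positions for both peptides and crosslinkerModMass"
                )
            peptides: tuple[Peptide, ...] = (pep1, pep2)
            links: tuple[int, ...] = (int(link1), int(link2))
            xl_mass: Optional[float] = float(linker_mass)
        else:
            if link1 is not None and linker_mass is None:
                raise FormatError(
                    f"{path}: row {row_no + 1}: linkPos given without pepSeq2 "
                    "and without crosslinkerModMass"
                )
            peptides, links, xl_mass = (pep1,), (), None
            if link1 is not None:
                # mono-link: linker (hydrolyzed) carried as a modification
                mod = registry.register(
                    _mod_token_from_name("monolink", float(linker_mass)),
                    float(linker_mass),
                    origin="input-data",
                )
                peptides = (Peptide(pep1.sequence, pep1.mods + ((int(link1), mod),)),)

        scores: dict[str, float] = {}
        score = _cell(row, "score")
        if score is not None:
            scores["score"] = float(score)
        metadata: dict[str, str] = {}
        for col in extra_columns:
            value = _cell(row, col)
            if value is None:
                continue
            try:
                scores[col] = float(value)
            except (TypeError, ValueError):
                metadata[col] = str(value)
        for col in ("fragmentTolerance", "ionTypes"):
            value = _cell(row, col)
            if value is not None:
                metadata[col] = str(value)

        proteins = tuple(
            str(p) for p in (_cell(row, "protein1"), _cell(row, "protein2")) if p
        )
        scan_number = _cell(row, "scanNumber")
        scan_index = _cell(row, "scanIndex")
        psms.append(
            CrossLinkedPSM(
                peptides=peptides,
                link_positions=links,
                crosslinker_mass=xl_mass,
                precursor_charge=int(row["charge"]),
                scores=scores,
                decoy_flags=tuple(
                    _to_bool(_cell(row, c)) for c in ("decoy1", "decoy2")
                )[: len(peptides)],
                pass_threshold=_to_bool(_cell(row, "passThreshold"), True),
                rank=1,
                psm_id=str(_cell(row, "id") or row_no),
                peak_list_filename=str(_cell(row, "peakListFileName") or ""),
                scan_number=None if scan_number is None else int(scan_number),
                scan_index=None if scan_index is None else int(scan_index),
                proteins=proteins,
                metadata=metadata,
            )
        )
    return psms


# --------------------------------------------------------------------------
# Annotation JSON (versioned schema)
# --------------------------------------------------------------------------

SCHEMA_VERSION = "1.0"


class ModModel(BaseModel):
    position: int
    name: str
    mass_delta: float


class PeptideModel(BaseModel):
    sequence: str
    mods: List[ModModel] = Field(default_factory=list)
    link_position: Optional[int] = None


class FragmentModel(BaseModel):
    series: str
    index: int
    peptide_id: str
    charge: int
    neutral_mass: float
    mz: float
    loss: Optional[str] = None
    contains_link: bool = False
    start: int = 1
    end: int = 1
    label: str = ""


class PeakModel(BaseModel):
    mz: float
    intensity: float


class MatchModel(BaseModel):
    peak_index: int
    fragment_index: int
    isotope_peak: int
    error_da: float
    error_ppm: float


class SettingsModel(BaseModel):
    tolerance_value: float
    tolerance_unit: str
    ion_types: List[str]
    max_fragment_charge: int
    losses_enabled: bool
    z_radical: bool


class PrecursorModel(BaseModel):
    charge: int
    mz: Optional[float] = None


class AnnotationDocument(BaseModel):
    """The versioned annotation JSON: everything needed to re-render the
    annotated spectrum, fragmentation key and QC plots without recomputation."""

    schema_version: str = SCHEMA_VERSION
    peptides: List[PeptideModel]
    crosslinker_mass: Optional[float] = None
    precursor: PrecursorModel
    settings: SettingsModel
    peaks: List[PeakModel]
    fragments: List[FragmentModel]
    matches: List[MatchModel]
    spectrum_source: dict = Field(default_factory=dict)


def write_annotation_json(annotated: AnnotatedSpectrum) -> dict:
    """Serialize an annotation to the versioned JSON document (validated)."""
    psm = annotated.psm
    frag_index = {id(f): i for i, f in enumerate(annotated.fragments)}
    doc = AnnotationDocument(
        peptides=[
            PeptideModel(
                sequence=p.sequence,
                mods=[
                    ModModel(position=pos, name=mod.name, mass_delta=mod.mass_delta)
                    for pos, mod in p.mods
                ],
                link_position=(
                    psm.link_positions[i] if psm.is_crosslinked else None
                ),
            )
            for i, p in enumerate(psm.peptides)
        ],
        crosslinker_mass=psm.crosslinker_mass,
        precursor=PrecursorModel(
            charge=psm.precursor_charge, mz=psm.precursor_mz
        ),
        settings=SettingsModel(
            tolerance_value=annotated.settings.tolerance.value,
            tolerance_unit=annotated.settings.tolerance.unit,
            ion_types=sorted(annotated.settings.ion_types),
            max_fragment_charge=annotated.settings.max_fragment_charge,
            losses_enabled=annotated.settings.losses_enabled,
            z_radical=annotated.settings.z_radical,
        ),
        peaks=[
            PeakModel(mz=float(mz), intensity=float(inten))
            for mz, inten in zip(annotated.spectrum.mz, annotated.spectrum.intensity)
        ],
        fragments=[
            FragmentModel(
                series=f.series,
                index=f.index,
                peptide_id=f.peptide_id,
                charge=f.charge,
                neutral_mass=f.neutral_mass,
                mz=f.mz,
                loss=f.loss,
                contains_link=f.contains_link,
                start=f.start,
                end=f.end,
                label=f.label,
            )
            for f in annotated.fragments
        ],
        matches=[
            MatchModel(
                peak_index=m.peak_index,
                fragment_index=frag_index[id(m.fragment)],
                isotope_peak=m.isotope_peak,
                error_da=m.error_da,
                error_ppm=m.error_ppm,
            )
            for m in annotated.matches
        ],
        spectrum_source={
            "filename": annotated.spectrum.filename,
            "scan_id": annotated.spectrum.scan_id,
            "scan_index": annotated.spectrum.scan_index,
        },
    )
    return doc.model_dump()


def validate_annotation_json(doc: dict) -> AnnotationDocument:
    """Validate a document against the annotation schema (raises on failure)."""
    return AnnotationDocument.model_validate(doc)


def load_annotation_json(doc: dict) -> AnnotatedSpectrum:
    """Reconstruct an :class:`AnnotatedSpectrum` from its JSON document."""
    model = validate_annotation_json(doc)
    peptides = []
    for pm in model.peptides:
        mods = tuple(
            (m.position, Modification(m.name, m.mass_delta, origin="input-data"))
            for m in pm.mods
        )
        peptides.append(Peptide(pm.sequence, mods))
    link_positions = tuple(
        pm.link_position for pm in model.peptides if pm.link_position is not None
    )
    psm = CrossLinkedPSM(
        peptides=tuple(peptides),
        link_positions=link_positions if len(peptides) == 2 else (),
        crosslinker_mass=model.crosslinker_mass,
        precursor_charge=model.precursor.charge,
        precursor_mz=model.precursor.mz,
    )
    settings = AnnotationSettings(
        tolerance=Tolerance(model.settings.tolerance_value, model.settings.tolerance_unit),
        ion_types=frozenset(model.settings.ion_types),
        max_fragment_charge=model.settings.max_fragment_charge,
        losses_enabled=model.settings.losses_enabled,
        z_radical=model.settings.z_radical,
    )
    spectrum = Spectrum(
        mz=np.array([p.mz for p in model.peaks]),
        intensity=np.array([p.intensity for p in model.peaks]),
        filename=str(model.spectrum_source.get("filename", "")),
        scan_id=str(model.spectrum_source.get("scan_id", "")),
        scan_index=model.spectrum_source.get("scan_index"),
        precursor_mz=model.precursor.mz,
        precursor_charge=model.precursor.charge,
    )
    fragments = tuple(
        FragmentIon(
            series=f.series,
            index=f.index,
            peptide_id=f.peptide_id,
            charge=f.charge,
            neutral_mass=f.neutral_mass,
            mz=f.mz,
            loss=f.loss,
            contains_link=f.contains_link,
            start=f.start,
            end=f.end,
        )
        for f in model.fragments
    )
    matches = tuple(
        PeakMatch(
            peak_index=m.peak_index,
            fragment=fragments[m.fragment_index],
            isotope_peak=m.isotope_peak,
            error_da=m.error_da,
            error_ppm=m.error_ppm,
        )
        for m in model.matches
    )
    return AnnotatedSpectrum(
        spectrum=spectrum,
        psm=psm,
        settings=settings,
        fragments=fragments,
        matches=matches,
    )


def annotation_json_schema() -> dict:
    """The JSON-Schema document describing the annotation JSON."""
    return AnnotationDocument.model_json_schema()


# --------------------------------------------------------------------------
# Dataset store (single SQLite file per dataset)
# --------------------------------------------------------------------------


@dataclass
class Dataset:
    """Parsed spectra + identifications, persistable as one SQLite file."""

    identifier: str
    spectra: list[Spectrum] = field(default_factory=list)
    psms: list[CrossLinkedPSM] = field(default_factory=list)
    registry: ModificationRegistry = field(default_factory=default_modification_registry)
    provenance: dict = field(default_factory=dict)

    def resolve_spectrum(self, psm: CrossLinkedPSM) -> Spectrum:
        """Find the spectrum a PSM refers to.

        Resolution order: explicit scan index, then scan number, then MGF
        TITLE substring match.
        """
        candidates = [
            s
            for s in self.spectra
            if not psm.peak_list_filename or s.filename == psm.peak_list_filename
        ]
        if psm.scan_index is not None:
            for s in candidates:
                if s.scan_index == psm.scan_index:
                    return s
        if psm.scan_number is not None:
            for s in candidates:
                if s.scan_id == str(psm.scan_number):
                    return s
        if psm.scan_number is not None:
            for s in candidates:
                if s.title and str(psm.scan_number) in s.title:
                    return s
        raise KeyError(
            f"PSM {psm.psm_id!r}: no spectrum for file="
            f"{psm.peak_list_filename!r} scan_index={psm.scan_index} "
            f"scan_number={psm.scan_number}"
        )


@dataclass(frozen=True)
class PsmFilter:
    """The identification-table toggles: decoy / threshold / linear hiding,
    substring search, and score-based ordering."""

    hide_decoys: bool = False
    hide_below_threshold: bool = False
    hide_linear: bool = False
    text_query: str = ""
    order_by_score: Optional[str] = None


def list_psms(dataset: Dataset, psm_filter: PsmFilter = PsmFilter()) -> list[CrossLinkedPSM]:
    """Apply the three hide-toggles, substring search and score ordering.

    ``order_by_score`` sorts descending; it must name a score present in at
    least one PSM, otherwise :class:`KeyError` is raised.  PSMs lacking the
    score sort last.
    """
    out = []
    query = psm_filter.text_query.lower()
    for psm in dataset.psms:
        if psm_filter.hide_decoys and psm.is_decoy:
            continue
        if psm_filter.hide_below_threshold and not psm.pass_threshold:
            continue
        if psm_filter.hide_linear and not psm.is_crosslinked:
            continue
        if query:
            haystack = " ".join(
                [render_sequence(p) for p in psm.peptides] + list(psm.proteins)
            ).lower()
            if query not in haystack:
                continue
        out.append(psm)
    score = psm_filter.order_by_score
    if score is not None:
        if not any(score in psm.scores for psm in dataset.psms):
            raise KeyError(f"unknown score name {score!r}")
        out.sort(
            key=lambda p: (score in p.scores, p.scores.get(score, float("-inf"))),
            reverse=True,
        )
    return out


def _psm_to_record(psm: CrossLinkedPSM) -> dict:
    link = list(psm.link_positions) if psm.is_crosslinked else []
    return {
        "psm_id": psm.psm_id,
        "sequences": [
            render_sequence(p, link[i] if psm.is_crosslinked else None)
            for i, p in enumerate(psm.peptides)
        ],
        "mod_masses": [
            [[pos, mod.name, mod.mass_delta] for pos, mod in p.mods]
            for p in psm.peptides
        ],
        "crosslinker_mass": psm.crosslinker_mass,
        "precursor_charge": psm.precursor_charge,
        "precursor_mz": psm.precursor_mz,
        "scores": dict(psm.scores),
        "decoy_flags": list(psm.decoy_flags),
        "pass_threshold": psm.pass_threshold,
        "rank": psm.rank,
        "peak_list_filename": psm.peak_list_filename,
        "scan_number": psm.scan_number,
        "scan_index": psm.scan_index,
        "proteins": list(psm.proteins),
        "metadata": dict(psm.metadata),
    }


def _psm_from_record(rec: dict, registry: ModificationRegistry) -> CrossLinkedPSM:
    peptides = []
    links = []
    for seq, mods in zip(rec["sequences"], rec["mod_masses"]):
        # re-register recorded masses so parsing resolves exactly as saved
        for _pos, name, delta in mods:
            registry.register(name, delta, origin="input-data")
        pep, link = parse_sequence(seq, registry)
        peptides.append(pep)
        if link is not None:
            links.append(link)
    is_xl = len(peptides) == 2
    return CrossLinkedPSM(
        peptides=tuple(peptides),
        link_positions=tuple(links) if is_xl else (),
        crosslinker_mass=rec["crosslinker_mass"],
        precursor_charge=rec["precursor_charge"],
        precursor_mz=rec["precursor_mz"],
        scores=rec["scores"],
        decoy_flags=tuple(bool(b) for b in rec["decoy_flags"]),
        pass_threshold=bool(rec["pass_threshold"]),
        rank=int(rec["rank"]),
        psm_id=rec["psm_id"],
        peak_list_filename=rec["peak_list_filename"],
        scan_number=rec["scan_number"],
        scan_index=rec["scan_index"],
        proteins=tuple(rec["proteins"]),
        metadata=rec["metadata"],
    )


def save_dataset(dataset: Dataset, path: PathLike) -> None:
    """Persist a dataset to a single SQLite file (overwrites)."""
    path = Path(path)
    if path.exists():
        path.unlink()
    con = sqlite3.connect(path)
    try:
        con.executescript(
            """
            CREATE TABLE meta (key TEXT PRIMARY KEY, value TEXT);
            CREATE TABLE spectra (
                idx INTEGER PRIMARY KEY, filename TEXT, scan_id TEXT,
                scan_index INTEGER, title TEXT, precursor_mz REAL,
                precursor_charge INTEGER, mz TEXT, intensity TEXT
            );
            CREATE TABLE psms (idx INTEGER PRIMARY KEY, record TEXT);
            CREATE TABLE modifications (
                name TEXT PRIMARY KEY, mass_delta REAL, specificity TEXT,
                origin TEXT
            );
            """
        )
        con.execute(
            "INSERT INTO meta VALUES (?, ?)", ("identifier", dataset.identifier)
        )
        con.execute(
            "INSERT INTO meta VALUES (?, ?)",
            ("provenance", json.dumps(dataset.provenance, sort_keys=True)),
        )
        con.execute(
            "INSERT INTO meta VALUES (?, ?)",
            ("saved_at", datetime.now(timezone.utc).isoformat()),
        )
        for k, s in enumerate(dataset.spectra):
            con.execute(
                "INSERT INTO spectra VALUES (?,?,?,?,?,?,?,?,?)",
                (
                    k,
                    s.filename,
                    s.scan_id,
                    s.scan_index,
                    s.title,
                    s.precursor_mz,
                    s.precursor_charge,
                    json.dumps([float(v) for v in s.mz]),
                    json.dumps([float(v) for v in s.intensity]),
                ),
            )
        for k, psm in enumerate(dataset.psms):
            con.execute(
                "INSERT INTO psms VALUES (?, ?)",
                (k, json.dumps(_psm_to_record(psm), sort_keys=True)),
            )
        for mod in dataset.registry:
            con.execute(
                "INSERT OR REPLACE INTO modifications VALUES (?,?,?,?)",
                (mod.name, mod.mass_delta, ",".join(sorted(mod.specificity)), mod.origin),
            )
        con.commit()
    finally:
        con.close()


def load_dataset(path: PathLike) -> Dataset:
    """Load a dataset saved by :func:`save_dataset`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    con = sqlite3.connect(path)
    try:
        try:
            meta = dict(con.execute("SELECT key, value FROM meta"))
            mod_rows = list(con.execute("SELECT * FROM modifications"))
            spec_rows = list(con.execute("SELECT * FROM spectra ORDER BY idx"))
            psm_rows = list(con.execute("SELECT record FROM psms ORDER BY idx"))
        except sqlite3.DatabaseError as exc:
            raise FormatError(f"{path}: not a dataset store: {exc}") from exc
        registry = ModificationRegistry()
        for name, delta, spec, origin in mod_rows:
            registry.register(
                name, delta, {s for s in spec.split(",") if s}, origin=origin
            )
        spectra = [
            Spectrum(
                mz=np.array(json.loads(mz)),
                intensity=np.array(json.loads(inten)),
                filename=filename,
                scan_id=scan_id,
                scan_index=scan_index,
                precursor_mz=pre_mz,
                precursor_charge=pre_z,
                title=title,
            )
            for (_k, filename, scan_id, scan_index, title, pre_mz, pre_z, mz, inten)
            in spec_rows
        ]
        psms = [_psm_from_record(json.loads(rec), registry) for (rec,) in psm_rows]
        return Dataset(
            identifier=meta.get("identifier", path.stem),
            spectra=spectra,
            psms=psms,
            registry=registry,
            provenance=json.loads(meta.get("provenance", "{}")),
        )
    finally:
        con.close()


# --------------------------------------------------------------------------
# Format sniffing and dataset assembly
# --------------------------------------------------------------------------


def sniff_format(path: PathLike) -> str:
    """Identify a file as mgf / mzml / mzid / csv by extension, falling back
    to content (``BEGIN IONS`` vs XML root element vs delimited header)."""
    name = _inner_name(path).lower()
    for ext, fmt in ((".mgf", "mgf"), (".mzml", "mzml"), (".mzid", "mzid"), (".csv", "csv")):
        if name.endswith(ext):
            return fmt
    head = open_binary(path).read(4096)
    if b"BEGIN IONS" in head:
        return "mgf"
    if head.lstrip().startswith(b"<"):
        root = re.search(rb"<\s*([A-Za-z:]+)", head.lstrip())
        tag = (root.group(1).decode() if root else "").split(":")[-1].lower()
        if tag == "mzml" or b"<mzML" in head:
            return "mzml"
        if tag == "mzidentml" or b"<MzIdentML" in head:
            return "mzid"
        raise FormatError(
            f"{path}: unrecognized XML root {tag!r}; supported formats: "
            "MGF, mzML, mzIdentML, CSV"
        )
    if b"," in head.splitlines()[0] if head.splitlines() else False:
        return "csv"
    raise FormatError(
        f"{path}: cannot identify format; supported formats: MGF, mzML, "
        "mzIdentML, CSV"
    )


def read_peaklist(path: PathLike) -> Union[MgfReader, MzmlReader]:
    fmt = sniff_format(path)
    if fmt == "mgf":
        return read_mgf(path)
    if fmt == "mzml":
        return read_mzml(path)
    raise FormatError(f"{path}: {fmt} is not a peak-list format")


def read_identifications(
    path: PathLike, registry: Optional[ModificationRegistry] = None
) -> tuple[list[CrossLinkedPSM], ModificationRegistry]:
    fmt = sniff_format(path)
    if fmt == "mzid":
        return read_mzidentml(path, registry)
    if fmt == "csv":
        registry = registry.copy() if registry else default_modification_registry()
        return read_csv_ids(path, registry), registry
    raise FormatError(f"{path}: {fmt} is not an identification format")


def build_dataset(
    peaks_path: PathLike, ids_path: PathLike, identifier: str = ""
) -> Dataset:
    """Parse a peak-list + identification file pair into a dataset."""
    reader = read_peaklist(peaks_path)
    psms, registry = read_identifications(ids_path)
    return Dataset(
        identifier=identifier or Path(ids_path).stem,
        spectra=list(reader),
        psms=psms,
        registry=registry,
        provenance={
            "peaks_file": str(peaks_path),
            "ids_file": str(ids_path),
            "parsed_at": datetime.now(timezone.utc).isoformat(),
        },
    )
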