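"""Programmatic builders for handcrafted mzIdentML and mzML test documents."""

from __future__ import annotations

import base64
import zlib

import numpy as np

MZID_HEADER = """<?xml version="1.0" encoding="UTF-8"?>
<MzIdentML id="doc" version="1.2.0"
 xmlns="http://psidev.info/psi/pi/mzIdentML/1.2"
 creationDate="2020-01-01T00:00:00">
 <cvList>
  <cv id="PSI-MS" fullName="PSI-MS" uri="https://example.org/psi-ms.obo"/>
 </cvList>
"""

MZID_MIDDLE = """ <AnalysisCollection>
  <SpectrumIdentification id="si" spectrumIdentificationProtocol_ref="sip"
    spectrumIdentificationList_ref="sil1">
   <InputSpectra spectraData_ref="sd1"/>
   <SearchDatabaseRef searchDatabase_ref="sdb1"/>
  </SpectrumIdentification>
 </AnalysisCollection>
 <AnalysisProtocolCollection>
  <SpectrumIdentificationProtocol id="sip" analysisSoftware_ref="sw">
   <SearchType><cvParam cvRef="PSI-MS" accession="MS:1001083" name="ms-ms search"/></SearchType>
  </SpectrumIdentificationProtocol>
 </AnalysisProtocolCollection>
 <DataCollection>
  <Inputs>
   <SearchDatabase id="sdb1" location="db.fasta">
    <DatabaseName><userParam name="db"/></DatabaseName>
   </SearchDatabase>
   <SpectraData id="sd1" location="peaks.mgf">
    <FileFormat><cvParam cvRef="PSI-MS" accession="MS:1001062" name="Mascot MGF format"/></FileFormat>
    <SpectrumIDFormat><cvParam cvRef="PSI-MS" accession="MS:1000774" name="multiple peak list nativeID format"/></SpectrumIDFormat>
   </SpectraData>
  </Inputs>
  <AnalysisData>
   <SpectrumIdentificationList id="sil1">
"""

MZID_FOOTER = """   </SpectrumIdentificationList>
  </AnalysisData>
 </DataCollection>
</MzIdentML>
"""


def linear_mzid() -> str:
    """One spectrum, two ranked SIIs on the same peptide; rank-2 fails the
    threshold.  A second spectrum carries a decoy identification."""
    seq = """ <SequenceCollection>
  <DBSequence id="db1" accession="PROT1" searchDatabase_ref="sdb1"/>
  <DBSequence id="db2" accession="PROT2" searchDatabase_ref="sdb1"/>
  <Peptide id="pep1">
   <PeptideSequence>MPEPTIDEK</PeptideSequence>
   <Modification location="1" monoisotopicMassDelta="15.99491">
    <cvParam cvRef="PSI-MS" accession="MS:1001524" name="Oxidation" value=""/>
   </Modification>
  </Peptide>
  <Peptide id="pep2"><PeptideSequence>GKAR</PeptideSequence></Peptide>
  <PeptideEvidence id="pe1" peptide_ref="pep1" dBSequence_ref="db1" isDecoy="false"/>
  <PeptideEvidence id="pe2" peptide_ref="pep2" dBSequence_ref="db2" isDecoy="true"/>
 </SequenceCollection>
"""
    sil = """    <SpectrumIdentificationResult id="sir1" spectrumID="index=0" spectraData_ref="sd1">
     <SpectrumIdentificationItem id="sii1" rank="1" chargeState="2"
       experimentalMassToCharge="537.26" peptide_ref="pep1" passThreshold="true">
      <PeptideEvidenceRef peptideEvidence_ref="pe1"/>
      <cvParam cvRef="PSI-MS" accession="MS:1001153" name="search engine specific score" value="33.0"/>
     </SpectrumIdentificationItem>
     <SpectrumIdentificationItem id="sii2" rank="2" chargeState="2"
       experimentalMassToCharge="537.26" peptide_ref="pep1" passThreshold="false">
      <PeptideEvidenceRef peptideEvidence_ref="pe1"/>
      <cvParam cvRef="PSI-MS" accession="MS:1001153" name="search engine specific score" value="3.0"/>
     </SpectrumIdentificationItem>
    </SpectrumIdentificationResult>
    <SpectrumIdentificationResult id="sir2" spectrumID="index=1" spectraData_ref="sd1">
     <SpectrumIdentificationItem id="sii3" rank="1" chargeState="2"
       experimentalMassToCharge="222.64" peptide_ref="pep2" passThreshold="true">
      <PeptideEvidenceRef peptideEvidence_ref="pe2"/>
      <cvParam cvRef="PSI-MS" accession="MS:1001153" name="search engine specific score" value="12.0"/>
     </SpectrumIdentificationItem>
    </SpectrumIdentificationResult>
"""
    return MZID_HEADER + seq + MZID_MIDDLE + sil + MZID_FOOTER


def crosslink_mzid(orphan: bool = False) -> str:
    """A cross-linked PSM: donor on GKAR K2, acceptor on VGKF K3, shared
    cvParam value "1.0".  With ``orphan`` True the acceptor is omitted."""
    acceptor_mod = (
        ""
        if orphan
        else """   <Modification location="3" monoisotopicMassDelta="0">
    <cvParam cvRef="PSI-MS" accession="MS:1002510" name="cross-link acceptor" value="1.0"/>
   </Modification>
"""
    )
    seq = f""" <SequenceCollection>
  <DBSequence id="db1" accession="PROTA" searchDatabase_ref="sdb1"/>
  <DBSequence id="db2" accession="PROTB" searchDatabase_ref="sdb1"/>
  <Peptide id="pepA">
   <PeptideSequence>GKAR</PeptideSequence>
   <Modification location="2" monoisotopicMassDelta="138.06808">
    <cvParam cvRef="PSI-MS" accession="MS:1002509" name="cross-link donor" value="1.0"/>
   </Modification>
  </Peptide>
  <Peptide id="pepB">
   <PeptideSequence>VGKF</PeptideSequence>
{acceptor_mod}  </Peptide>
  <PeptideEvidence id="peA" peptide_ref="pepA" dBSequence_ref="db1" isDecoy="false"/>
  <PeptideEvidence id="peB" peptide_ref="pepB" dBSequence_ref="db2" isDecoy="false"/>
 </SequenceCollection>
"""
    sil = """    <SpectrumIdentificationResult id="sir1" spectrumID="index=0" spectraData_ref="sd1">
     <SpectrumIdentificationItem id="siiA" rank="1" chargeState="3"
       experimentalMassToCharge="336.54" peptide_ref="pepA" passThreshold="true">
      <PeptideEvidenceRef peptideEvidence_ref="peA"/>
      <cvParam cvRef="PSI-MS" accession="MS:1002511" name="cross-link spectrum identification item" value="1.0"/>
      <cvParam cvRef="PSI-MS" accession="MS:1001153" name="search engine specific score" value="20.5"/>
     </SpectrumIdentificationItem>
     <SpectrumIdentificationItem id="siiB" rank="1" chargeState="3"
       experimentalMassToCharge="336.54" peptide_ref="pepB" passThreshold="true">
      <PeptideEvidenceRef peptideEvidence_ref="peB"/>
      <cvParam cvRef="PSI-MS" accession="MS:1002511" name="cross-link spectrum identification item" value="1.0"/>
      <cvParam cvRef="PSI-MS" accession="MS:1001153" name="search engine specific score" value="20.5"/>
     </SpectrumIdentificationItem>
    </SpectrumIdentificationResult>
"""
    return MZID_HEADER + seq + MZID_MIDDLE + sil + MZID_FOOTER


# --------------------------------------------------------------------------
# mzML
# --------------------------------------------------------------------------


def _encode(array: np.ndarray, dtype: str, compress: bool) -> str:
    raw = np.asarray(array, dtype=dtype).tobytes()
    if compress:
        raw = zlib.compress(raw)
    return base64.b64encode(raw).decode()


def _binary_array(array, kind: str, dtype: str, compress: bool,
                  payload: str | None = None,
                  compression_cv: str | None = None) -> str:
    acc_kind = "MS:1000514" if kind == "mz" else "MS:1000515"
    name_kind = "m/z array" if kind == "mz" else "intensity array"
    acc_float = "MS:1000523" if dtype == "<f8" else "MS:1000521"
    name_float = "64-bit float" if dtype == "<f8" else "32-bit float"
    if compression_cv is None:
        compression_cv = (
            '<cvParam accession="MS:1000574" name="zlib compression"/>'
            if compress
            else '<cvParam accession="MS:1000576" name="no compression"/>'
        )
    text = _encode(array, dtype, compress) if payload is None else payload
    return f"""     <binaryDataArray encodedLength="{len(text)}">
      <cvParam accession="{acc_float}" name="{name_float}"/>
      {compression_cv}
      <cvParam accession="{acc_kind}" name="{name_kind}"/>
      <binary>{text}</binary>
     </binaryDataArray>
"""


def mzml_doc(spectra, dtype: str = "<f8", compress: bool = False,
             mz_payload_override: str | None = None,
             compression_cv: str | None = None) -> str:
    """Minimal mzML with the given [(native_id, mz, intensity, precursor)].

    ``precursor`` is None or (mz, charge).  Overrides allow constructing
    deliberately broken documents (truncated base64, unsupported
    compression cvParams).
    """
    blocks = []
    for k, (native_id, mz, intensity, precursor) in enumerate(spectra):
        precursor_xml = ""
        if precursor is not None:
            pmz, pz = precursor
            precursor_xml = f"""    <precursorList count="1"><precursor>
     <selectedIonList count="1"><selectedIon>
      <cvParam accession="MS:1000744" name="selected ion m/z" value="{pmz!r}"/>
      <cvParam accession="MS:1000041" name="charge state" value="{pz}"/>
     </selectedIon></selectedIonList>
    </precursor></precursorList>
"""
        mz_xml = _binary_array(
            mz, "mz", dtype, compress,
            payload=mz_payload_override if k == 0 else None,
            compression_cv=compression_cv,
        )
        int_xml = _binary_array(intensity, "intensity", dtype, compress,
                                compression_cv=compression_cv)
        blocks.append(
            f"""   <spectrum index="{k}" id="{native_id}" defaultArrayLength="{len(mz)}">
    <cvParam accession="MS:1000511" name="ms level" value="2"/>
{precursor_xml}    <binaryDataArrayList count="2">
{mz_xml}{int_xml}    </binaryDataArrayList>
   </spectrum>
"""
        )
    return (
        '<?xml version="1.0" encoding="utf-8"?>\n'
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">\n'
        ' <run id="run1">\n'
        f'  <spectrumList count="{len(spectra)}">\n'
        + "".join(blocks)
        + "  </spectrumList>\n </run>\n</mzML>\n"
    )
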