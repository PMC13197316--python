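"""Reading and writing acquisitions (mzML) and the pipeline's tabular artifacts.

One acquisition = one time-ordered sequence of centroid (or profile) mass
spectra for a single participant, plus daily background acquisitions.
Both directions of mzML I/O are implemented here directly against the PSI
standard (cvParam accessions, base64-encoded binary arrays with optional
zlib compression, 32/64-bit floats); the writer emits centroid spectra
with scan start times in seconds and round-trips bit-identically through
the reader.
"""

from __future__ import annotations

import base64
import logging
import struct
import xml.etree.ElementTree as ET
import zlib
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyRunError, MzmlError, SchemaError
from .annotate import parse_formula
from .errors import FormulaError

logger = logging.getLogger(__name__)

__all__ = [
    "ScanSpectrum",
    "AcquisitionRun",
    "CompoundRecord",
    "read_mzml",
    "write_mzml",
    "read_compound_db",
    "write_compound_db",
    "write_feature_table",
    "read_feature_table",
]

DEFAULT_MZ_WINDOW = (50.0, 300.0)


@dataclass
class ScanSpectrum:
    """One time-stamped mass spectrum.

    ``mz`` is strictly increasing and aligned with non-negative
    ``intensity``; ``scan_time`` is seconds from run start.
    """

    scan_time: float
    mz: np.ndarray
    intensity: np.ndarray
    centroided: bool = True

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("mz must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")


@dataclass
class AcquisitionRun:
    """A full acquisition: scans in time order for one participant.

    ``participant_id`` is the cohort id, or ``"background"`` for the daily
    ambient-air acquisitions.
    """

    run_id: str
    participant_id: str
    scans: list[ScanSpectrum]
    acquired_date: date = field(default_factory=date.today)

    def __post_init__(self):
        if len(self.scans) < 2:
            raise EmptyRunError(
                f"run {self.run_id!r} has {len(self.scans)} scan(s); need >= 2"
            )
        times = np.array([s.scan_time for s in self.scans])
        if not np.all(np.diff(times) > 0):
            raise ValueError("scan times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([s.scan_time for s in self.scans])

    @property
    def n_scans(self) -> int:
        return len(self.scans)

    @property
    def duration(self) -> float:
        return float(self.scans[-1].scan_time)

    @property
    def is_background(self) -> bool:
        return self.participant_id == "background"


@dataclass(frozen=True)
class CompoundRecord:
    """One compound database entry (name, elemental formula, provenance)."""

    name: str
    formula: str
    source_db: str  # HMDB | HBDB | literature
    external_id: str = ""
    previously_in_breath: bool = False


# ---------------------------------------------------------------------------
# mzML
# ---------------------------------------------------------------------------

_MZML_NS = "http://psi.hupo.org/ms/mzml"


def _encode_array(a: np.ndarray) -> str:
    return base64.b64encode(struct.pack(f"<{a.size}d", *a)).decode("ascii")


def write_mzml(run: AcquisitionRun, path: str | Path) -> Path:
    """Write an acquisition as centroid mzML, one spectrum per scan.

    Scan start times are stored in seconds; arrays as uncompressed
    little-endian 64-bit floats.
    """
    path = Path(path)
    lines = [
        '<?xml version="1.0" encoding="utf-8"?>',
        f'<mzML xmlns="{_MZML_NS}" version="1.1.0" id="{run.run_id}">',
        "  <cvList count=\"1\">",
        '    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology"'
        ' URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>',
        "  </cvList>",
        f'  <run id="{run.run_id}" startTimeStamp="{run.acquired_date.isoformat()}T00:00:00Z">',
        f'    <spectrumList count="{run.n_scans}">',
    ]
    for i, scan in enumerate(run.scans):
        mode = ("MS:1000127", "centroid spectrum") if scan.centroided else (
            "MS:1000128", "profile spectrum")
        npts = scan.mz.size
        lines += [
            f'      <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{npts}">',
            f'        <cvParam cvRef="MS" accession="{mode[0]}" name="{mode[1]}"/>',
            '        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>',
            '        <scanList count="1">',
            "          <scan>",
            f'            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time"'
            f' value="{scan.scan_time!r}" unitCvRef="UO" unitAccession="UO:0000010"'
            ' unitName="second"/>',
            "          </scan>",
            "        </scanList>",
            '        <binaryDataArrayList count="2">',
        ]
        for accession, name, arr in (
            ("MS:1000514", "m/z array", scan.mz),
            ("MS:1000515", "intensity array", scan.intensity),
        ):
            b64 = _encode_array(arr)
            lines += [
                f'          <binaryDataArray encodedLength="{len(b64)}">',
                '            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>',
                '            <cvParam cvRef="MS" accession="MS:1000576" name="no compression"/>',
                f'            <cvParam cvRef="MS" accession="{accession}" name="{name}"/>',
                f"            <binary>{b64}</binary>",
                "          </binaryDataArray>",
            ]
        lines += ["        </binaryDataArrayList>", "      </spectrum>"]
    lines += ["    </spectrumList>", "  </run>", "</mzML>", ""]
    path.write_text("\n".join(lines))
    return path


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary_array(bda: ET.Element) -> dict | None:
    """Decode one <binaryDataArray>; returns None for non-m/z/intensity
    arrays."""
    dtype, compressed, kind = "<d", False, None
    b64 = ""
    for child in bda.iter():
        name = _local(child.tag)
        if name == "cvParam":
            acc = child.get("accession", "")
            if acc == "MS:1000523":
                dtype = "<d"  # 64-bit float
            elif acc == "MS:1000521":
                dtype = "<f"  # 32-bit float
            elif acc == "MS:1000574":
                compressed = True
            elif acc == "MS:1000514":
                kind = "mz"
            elif acc == "MS:1000515":
                kind = "intensity"
        elif name == "binary":
            b64 = child.text or ""
    if kind is None:
        return None
    raw = base64.b64decode(b64)
    if compressed:
        raw = zlib.decompress(raw)
    arr = np.frombuffer(raw, dtype=np.dtype(dtype)).astype(np.float64)
    return {"kind": kind, "data": arr}


def _parse_spectrum(elem: ET.Element, index: int) -> ScanSpectrum:
    centroided = True
    scan_time = None
    mz = inten = None
    for child in elem.iter():
        name = _local(child.tag)
        if name == "cvParam":
            acc = child.get("accession", "")
            if acc == "MS:1000128":
                centroided = False
            elif acc == "MS:1000016":
                t = float(child.get("value"))
                unit = (child.get("unitName") or "second").lower()
                scan_time = t * 60.0 if "min" in unit else t
        elif name == "binaryDataArray":
            decoded = _decode_binary_array(child)
            if decoded is not None:
                if decoded["kind"] == "mz":
                    mz = decoded["data"]
                else:
                    inten = decoded["data"]
    sid = elem.get("id", f"index {index}")
    if mz is None or inten is None:
        raise MzmlError(f"spectrum {sid!r} lacks m/z or intensity arrays")
    if scan_time is None:
        raise MzmlError(f"spectrum {sid!r} lacks a scan start time")
    if mz.size != inten.size:
        raise MzmlError(f"spectrum {sid!r}: array length mismatch "
                        f"({mz.size} vs {inten.size})")
    return ScanSpectrum(scan_time, np.array(mz), np.array(inten),
                        centroided=centroided)


def read_mzml(
    path: str | Path,
    mz_window: tuple[float, float] | None = DEFAULT_MZ_WINDOW,
    run_id: str | None = None,
    participant_id: str | None = None,
) -> AcquisitionRun:
    """Read an mzML acquisition into an :class:`AcquisitionRun`.

    Scans are sorted by start time and m/z values restricted to
    ``mz_window`` (default 50-300, the full-scan acquisition window).
    Handles centroid/profile cvParams, scan start times in seconds or
    minutes, 32/64-bit float arrays and zlib compression.  Raises
    :class:`MzmlError` (naming the offending spectrum) for malformed
    files and :class:`EmptyRunError` for runs with fewer than two scans.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    scans = []
    try:
        context = ET.iterparse(str(path), events=("end",))
        for i, (_, elem) in enumerate(
                (ev for ev in context if _local(ev[1].tag) == "spectrum")):
            spec = _parse_spectrum(elem, i)
            if mz_window is not None:
                keep = (spec.mz >= mz_window[0]) & (spec.mz <= mz_window[1])
                spec = ScanSpectrum(spec.scan_time, spec.mz[keep],
                                    spec.intensity[keep], spec.centroided)
            scans.append(spec)
            elem.clear()
    except (MzmlError, EmptyRunError):
        raise
    except Exception as exc:  # noqa: BLE001
        raise MzmlError(f"cannot parse mzML file {path.name}: {exc}") from exc
    scans.sort(key=lambda s: s.scan_time)
    rid = run_id or path.stem
    pid = participant_id if participant_id is not None else _infer_participant(rid)
    return AcquisitionRun(run_id=rid, participant_id=pid, scans=scans)


def _infer_participant(run_id: str) -> str:
    return "background" if "background" in run_id.lower() else run_id


# ---------------------------------------------------------------------------
# compound databases
# ---------------------------------------------------------------------------

_DB_COLUMNS = {"name", "formula", "source", "id"}


def read_compound_db(path: str | Path) -> list[CompoundRecord]:
    """Read a delimited compound table (columns name, formula, source, id).

    Rows with unparseable formulas are skipped; each skip emits a logged
    warning and the total skipped count is logged at the end.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = _DB_COLUMNS - set(df.columns)
    if missing:
        raise SchemaError(f"compound table missing column(s): {sorted(missing)}")
    records, skipped = [], 0
    for _, row in df.iterrows():
        try:
            parse_formula(row["formula"])
        except FormulaError as exc:
            skipped += 1
            logger.warning("skipping %r: unparseable formula %r (%s)",
                           row["name"], row["formula"], exc)
            continue
        records.append(CompoundRecord(
            name=row["name"],
            formula=row["formula"],
            source_db=row["source"],
            external_id=row["id"],
            previously_in_breath=str(row.get("previously_in_breath", "")).lower()
            in ("1", "true", "yes"),
        ))
    if skipped:
        logger.info("compound db %s: %d record(s) skipped", path, skipped)
    return records


def write_compound_db(records: list[CompoundRecord], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [
            {
                "name": r.name,
                "formula": r.formula,
                "source": r.source_db,
                "id": r.external_id,
                "previously_in_breath": r.previously_in_breath,
            }
            for r in records
        ]
    ).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------


def write_feature_table(matrix, path: str | Path) -> Path:
    """Write a cohort matrix as CSV: rows = features (m/z index printed at
    full precision, always >= 4 decimals), columns = participants, empty
    cells = missing.  The round-trip through :func:`read_feature_table` is
    lossless."""
    path = Path(path)
    df = matrix.values if hasattr(matrix, "values") and isinstance(
        getattr(matrix, "values"), pd.DataFrame) else matrix
    out = df.copy()
    out.index = [repr(float(mz)) for mz in out.index]
    out.index.name = "mz"
    out.to_csv(path)
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature table back; the m/z index must be collision-free."""
    df = pd.read_csv(path, index_col="mz")
    idx = df.index.astype(float)
    if idx.duplicated().any():
        raise SchemaError(f"duplicate m/z index values in {path}")
    df.index = idx
    return df
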