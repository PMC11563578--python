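"""MS2 spectrum containers, mzML/mzXML reading, and windowed peak queries.

Spectra are assumed centroided (the quantification pipeline operates on
centroided FTMS2 data); profile data is not resampled.  Scan identity is
(run id, scan number); both mzXML ``num`` and mzML ``scan=N`` ids map to the
scan number.

The mzML/mzXML readers here are deliberately compact: they decode centroided
peak arrays (32/64-bit, optionally zlib-compressed, base64), MS level,
precursor and retention time — the subset the quantification pipeline
consumes.  A lightweight JSON fixture format is also supported for fast
tests, and a minimal mzML 1.1 writer is provided (64-bit, uncompressed
arrays) that round-trips through the reader.
"""

from __future__ import annotations

import base64
import json
import struct
import warnings
import zlib
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, List, NamedTuple, Optional, Sequence

import numpy as np

from .masschem import tolerance_window

__all__ = ["Peak", "Spectrum", "SpectraRun", "read_run", "write_mzml",
           "write_json_run", "read_json_run", "peaks_in_window"]


class Peak(NamedTuple):
    mz: float
    intensity: float


@dataclass
class Spectrum:
    """One scan: sorted peak arrays plus scan metadata."""

    run_id: str
    scan: int
    ms_level: int = 2
    precursor_mz: Optional[float] = None
    precursor_charge: Optional[int] = None
    rt: Optional[float] = None  # seconds
    mz: np.ndarray = field(default_factory=lambda: np.empty(0))
    intensity: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays differ in length")
        if self.mz.size and np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return self.mz.size

    @property
    def peaks(self) -> List[Peak]:
        return [Peak(m, i) for m, i in zip(self.mz, self.intensity)]


@dataclass
class SpectraRun:
    """All spectra of one MS run, iterated in scan-number order."""

    run_id: str
    spectra: List[Spectrum] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.spectra.sort(key=lambda s: s.scan)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    def __len__(self) -> int:
        return len(self.spectra)

    def counts_by_ms_level(self) -> dict:
        out: dict = {}
        for s in self.spectra:
            out[s.ms_level] = out.get(s.ms_level, 0) + 1
        return out

    def by_scan(self) -> dict:
        return {s.scan: s for s in self.spectra}


def _scan_number(native_id: str) -> int:
    # mzML native ids look like "controllerType=0 ... scan=123"; fall back to
    # the last integer token.
    for token in str(native_id).split():
        if token.startswith("scan="):
            return int(token[5:])
    digits = "".join(ch if ch.isdigit() else " " for ch in str(native_id)).split()
    if digits:
        return int(digits[-1])
    raise ValueError(f"cannot extract a scan number from id {native_id!r}")


def read_run(path: str | Path, fmt: str = "auto") -> SpectraRun:
    """Read an mzML/mzXML/JSON file into a :class:`SpectraRun`.

    ``fmt``: "mzML", "mzXML", "json" or "auto" (by extension).  A file with
    zero MS2 spectra triggers a warning but still returns the (possibly
    empty) run.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if fmt == "auto":
        ext = path.suffix.lower()
        fmt = {".mzml": "mzML", ".mzxml": "mzXML", ".json": "json"}.get(ext)
        if fmt is None:
            raise ValueError(f"cannot infer format from extension {ext!r}")
    if fmt == "json":
        return read_json_run(path)

    run_id = path.stem
    try:
        if fmt == "mzML":
            spectra = _read_mzml(path, run_id)
        elif fmt == "mzXML":
            spectra = _read_mzxml(path, run_id)
        else:
            raise ValueError(f"unknown format {fmt!r}")
    except ET.ParseError as exc:
        raise ValueError(f"malformed XML in {path}: {exc}") from exc
    run = SpectraRun(run_id, spectra)
    if not any(s.ms_level == 2 for s in run):
        warnings.warn(f"{path.name}: no MS2 spectra found", stacklevel=2)
    return run


def _strip(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_array(text: str, *, bits: int, compressed: bool,
                  byte_order: str = "<") -> np.ndarray:
    raw = base64.b64decode(text or "")
    if compressed:
        raw = zlib.decompress(raw)
    code = "d" if bits == 64 else "f"
    n = len(raw) // struct.calcsize(code)
    return np.asarray(struct.unpack(f"{byte_order}{n}{code}", raw), dtype=float)


def _read_mzml(path: Path, run_id: str) -> List[Spectrum]:
    spectra: List[Spectrum] = []
    for event, elem in ET.iterparse(str(path), events=("end",)):
        if _strip(elem.tag) != "spectrum":
            continue
        params = {}  # accession -> value, spectrum-level and nested
        for cv in elem.iter():
            if _strip(cv.tag) == "cvParam":
                params.setdefault(cv.get("accession"), cv.get("value", ""))
        arrays = {}
        for bda in elem.iter():
            if _strip(bda.tag) != "binaryDataArray":
                continue
            acc = {cv.get("accession") for cv in bda if _strip(cv.tag) == "cvParam"}
            binary = next((c for c in bda if _strip(c.tag) == "binary"), None)
            arr = _decode_array(
                binary.text if binary is not None else "",
                bits=64 if "MS:1000523" in acc else 32,
                compressed="MS:1000574" in acc,
            )
            if "MS:1000514" in acc:
                arrays["mz"] = arr
            elif "MS:1000515" in acc:
                arrays["intensity"] = arr
        rt = None
        if "MS:1000016" in params:
            rt = float(params["MS:1000016"])
            unit = next(
                (cv.get("unitName") for cv in elem.iter()
                 if _strip(cv.tag) == "cvParam" and cv.get("accession") == "MS:1000016"),
                None,
            )
            if unit == "minute":
                rt *= 60.0
        spectra.append(Spectrum(
            run_id=run_id,
            scan=_scan_number(elem.get("id", "")),
            ms_level=int(params.get("MS:1000511", 2) or 2),
            precursor_mz=float(params["MS:1000744"]) if "MS:1000744" in params else None,
            precursor_charge=int(params["MS:1000041"]) if params.get("MS:1000041") else None,
            rt=rt,
            mz=arrays.get("mz", np.empty(0)),
            intensity=arrays.get("intensity", np.empty(0)),
        ))
        elem.clear()
    return spectra


def _read_mzxml(path: Path, run_id: str) -> List[Spectrum]:
    spectra: List[Spectrum] = []
    for event, elem in ET.iterparse(str(path), events=("end",)):
        if _strip(elem.tag) != "scan":
            continue
        prec_mz = prec_z = None
        mz = intensity = np.empty(0)
        for child in elem.iter():
            tag = _strip(child.tag)
            if tag == "precursorMz" and child.text:
                prec_mz = float(child.text)
                z = child.get("precursorCharge")
                prec_z = int(z) if z else None
            elif tag == "peaks":
                # mzXML peaks are interleaved m/z,intensity in network order
                pairs = _decode_array(
                    child.text or "",
                    bits=int(child.get("precision", "32")),
                    compressed=child.get("compressionType") == "zlib",
                    byte_order=">",
                )
                mz, intensity = pairs[0::2], pairs[1::2]
        rt = elem.get("retentionTime")  # e.g. "PT12.5S"
        if rt:
            rt = float(rt.strip("PTS"))
        spectra.append(Spectrum(
            run_id=run_id,
            scan=int(elem.get("num")),
            ms_level=int(elem.get("msLevel", 2)),
            precursor_mz=prec_mz,
            precursor_charge=prec_z,
            rt=rt,
            mz=mz,
            intensity=intensity,
        ))
        elem.clear()
    return spectra


def peaks_in_window(
    s: Spectrum, center: float, tol: float, unit: str = "Da"
) -> List[Peak]:
    """All peaks with m/z in the inclusive window around ``center``.

    Binary search over the sorted m/z array; an empty list is a valid result.
    """
    low, high = tolerance_window(center, tol, unit)
    # widen by a few ulps so exact-boundary peaks are included regardless of
    # rounding differences between the stored and computed bound
    low -= 4 * np.finfo(float).eps * abs(low)
    high += 4 * np.finfo(float).eps * abs(high)
    i = int(np.searchsorted(s.mz, low, side="left"))
    j = int(np.searchsorted(s.mz, high, side="right"))
    return [Peak(float(s.mz[k]), float(s.intensity[k])) for k in range(i, j)]


# ---------------------------------------------------------------------------
# JSON fixture format
# ---------------------------------------------------------------------------

def write_json_run(run: SpectraRun, path: str | Path) -> None:
    """Write a run in the documented JSON fixture schema.

    Schema: ``{"run_id": str, "spectra": [{"scan": int, "ms_level": int,
    "precursor_mz": float|null, "precursor_charge": int|null, "rt":
    float|null, "mz": [float], "intensity": [float]}]}``.
    """
    doc = {
        "run_id": run.run_id,
        "spectra": [
            {
                "scan": s.scan,
                "ms_level": s.ms_level,
                "precursor_mz": s.precursor_mz,
                "precursor_charge": s.precursor_charge,
                "rt": s.rt,
                "mz": [float(x) for x in s.mz],
                "intensity": [float(x) for x in s.intensity],
            }
            for s in run
        ],
    }
    Path(path).write_text(json.dumps(doc))


def read_json_run(path: str | Path) -> SpectraRun:
    doc = json.loads(Path(path).read_text())
    return SpectraRun(
        doc["run_id"],
        [
            Spectrum(
                run_id=doc["run_id"],
                scan=e["scan"],
                ms_level=e.get("ms_level", 2),
                precursor_mz=e.get("precursor_mz"),
                precursor_charge=e.get("precursor_charge"),
                rt=e.get("rt"),
                mz=e["mz"],
                intensity=e["intensity"],
            )
            for e in doc["spectra"]
        ],
    )


# ---------------------------------------------------------------------------
# Minimal mzML 1.1 writer
# ---------------------------------------------------------------------------

_MZML_NS = "http://psi.hupo.org/ms/mzml"


def _b64(values: Sequence[float]) -> str:
    return base64.b64encode(struct.pack(f"<{len(values)}d", *values)).decode()


def _cv(parent: ET.Element, accession: str, name: str, value: str = "",
        unit: Optional[tuple] = None) -> None:
    attrs = {"cvRef": "MS", "accession": accession, "name": name, "value": value}
    if unit:
        attrs.update(unitCvRef=unit[0], unitAccession=unit[1], unitName=unit[2])
    ET.SubElement(parent, "cvParam", attrs)


def write_mzml(run: SpectraRun, path: str | Path) -> None:
    """Write a minimal mzML 1.1 document readable by standard mzML parsers.

    Peak arrays are 64-bit floats, uncompressed, base64-encoded; spectrum ids
    are ``scan=N`` so scan numbers round-trip.
    """
    root = ET.Element("mzML", {"xmlns": _MZML_NS, "version": "1.1.0"})
    cvlist = ET.SubElement(root, "cvList", count="1")
    ET.SubElement(cvlist, "cv", id="MS", fullName="PSI-MS", URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo")
    fdesc = ET.SubElement(root, "fileDescription")
    fcontent = ET.SubElement(fdesc, "fileContent")
    _cv(fcontent, "MS:1000580", "MSn spectrum")
    soft = ET.SubElement(root, "softwareList", count="1")
    ET.SubElement(soft, "software", id="xlquant", version="0.1.0")
    icl = ET.SubElement(root, "instrumentConfigurationList", count="1")
    ET.SubElement(icl, "instrumentConfiguration", id="IC1")
    dpl = ET.SubElement(root, "dataProcessingList", count="1")
    dp = ET.SubElement(dpl, "dataProcessing", id="DP1")
    pm = ET.SubElement(dp, "processingMethod", order="1", softwareRef="xlquant")
    _cv(pm, "MS:1000544", "Conversion to mzML")

    mrun = ET.SubElement(root, "run", id=run.run_id,
                         defaultInstrumentConfigurationRef="IC1")
    slist = ET.SubElement(mrun, "spectrumList", count=str(len(run)),
                          defaultDataProcessingRef="DP1")
    for idx, s in enumerate(run):
        sp = ET.SubElement(slist, "spectrum", index=str(idx),
                           id=f"scan={s.scan}", defaultArrayLength=str(len(s)))
        _cv(sp, "MS:1000511", "ms level", str(s.ms_level))
        _cv(sp, "MS:1000580", "MSn spectrum")
        _cv(sp, "MS:1000127", "centroid spectrum")
        if s.rt is not None:
            sc_list = ET.SubElement(sp, "scanList", count="1")
            _cv(sc_list, "MS:1000795", "no combination")
            sc = ET.SubElement(sc_list, "scan")
            _cv(sc, "MS:1000016", "scan start time", repr(s.rt / 60.0),
                ("UO", "UO:0000031", "minute"))
        if s.precursor_mz is not None:
            plist = ET.SubElement(sp, "precursorList", count="1")
            prec = ET.SubElement(plist, "precursor")
            silist = ET.SubElement(prec, "selectedIonList", count="1")
            si = ET.SubElement(silist, "selectedIon")
            _cv(si, "MS:1000744", "selected ion m/z", repr(s.precursor_mz),
                ("MS", "MS:1000040", "m/z"))
            if s.precursor_charge is not None:
                _cv(si, "MS:1000041", "charge state", str(s.precursor_charge))
        bal = ET.SubElement(sp, "binaryDataArrayList", count="2")
        for arr, acc, name, unit in (
            (s.mz, "MS:1000514", "m/z array", ("MS", "MS:1000040", "m/z")),
            (s.intensity, "MS:1000515", "intensity array",
             ("MS", "MS:1000131", "number of detector counts")),
        ):
            data = _b64(arr)
            bda = ET.SubElement(bal, "binaryDataArray", encodedLength=str(len(data)))
            _cv(bda, "MS:1000523", "64-bit float")
            _cv(bda, "MS:1000576", "no compression")
            _cv(bda, acc, name, unit=unit)
            ET.SubElement(bda, "binary").text = data

    ET.indent(root)
    ET.ElementTree(root).write(str(path), xml_declaration=True, encoding="unicode")
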