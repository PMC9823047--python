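"""mzML input/output and chromatogram extraction.

Acquisitions are modelled as RT-ordered sequences of centroid spectra. Two
acquisition geometries occur in this workflow:

* DIA here means full-scan acquisition repeated at fixed in-source collision
  energies (0/20/40 V), one run per energy channel — every spectrum is MS1
  and fragments appear in-source in the elevated-energy channels;
* DDA is interleaved MS1 + data-dependent MS2 (TopN) in a single run.

Reading and writing go through a lightweight mzML 1.1 layer (plain or
indexed input, 32/64-bit float arrays, zlib or no compression, gzip files)
so that simulated acquisitions round-trip through the standard format.
Retention times are minutes end-to-end (mzML times in seconds are converted
on read).
"""

from __future__ import annotations

import base64
import gzip
import struct
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from lxml import etree

__all__ = [
    "SpectrumRecord",
    "AcquisitionRun",
    "EICTrace",
    "read_mzml",
    "write_mzml",
    "tic",
    "extract_eic",
]


@dataclass
class SpectrumRecord:
    """One centroided spectrum.

    ``in_source_ce_v`` is the in-source collision energy of the DIA channel
    the spectrum belongs to (0 for plain MS1); ``nce`` lists the normalized
    collision energies summed into a ddMS2 spectrum.
    """

    scan_index: int
    rt_min: float
    ms_level: int
    mz: np.ndarray
    intensity: np.ndarray
    in_source_ce_v: float = 0.0
    nce: tuple[float, ...] = ()
    precursor_mz: float | None = None
    isolation_width_mz: float = 1.5
    polarity: str = "negative"

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays must have equal length")
        if self.mz.size and np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
        if self.rt_min < 0:
            raise ValueError("rt_min must be non-negative")
        if self.ms_level == 2 and self.precursor_mz is None:
            raise ValueError("MS2 spectrum requires precursor_mz")

    @property
    def total_intensity(self) -> float:
        return float(self.intensity.sum())


@dataclass
class AcquisitionRun:
    """An RT-ordered sequence of spectra plus acquisition metadata."""

    spectra: list[SpectrumRecord]
    mode: str = "DDA"  # "DIA_channel" | "DDA"
    channel_ce_v: float | None = None
    scan_range: tuple[float, float] = (150.0, 1000.0)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        rts = [s.rt_min for s in self.spectra]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValueError("spectra must be strictly RT-ordered")
        if self.mode == "DIA_channel" and any(
            s.ms_level != 1 for s in self.spectra
        ):
            raise ValueError("a DIA channel run contains only MS1 spectra")

    def __len__(self) -> int:
        return len(self.spectra)

    def ms1_spectra(self) -> list[SpectrumRecord]:
        return [s for s in self.spectra if s.ms_level == 1]

    def ms2_spectra(self) -> list[SpectrumRecord]:
        return [s for s in self.spectra if s.ms_level == 2]


@dataclass
class EICTrace:
    """Intensity versus retention time for one m/z window (or the TIC)."""

    target_mz: float
    tol_ppm: float
    rt_min: np.ndarray
    intensity: np.ndarray
    ms_level: int = 1

    def __post_init__(self) -> None:
        self.rt_min = np.asarray(self.rt_min, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.rt_min.shape != self.intensity.shape:
            raise ValueError("rt and intensity must have equal length")

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.rt_min, self.intensity]),
            delimiter=",",
            header="rt_min,intensity",
            comments="",
        )


# ---------------------------------------------------------------------------
# mzML writing

_NS = "http://psi.hupo.org/ms/mzml"


def _cv(parent, accession: str, name: str, value: str = "", **units) -> None:
    attrs = {"cvRef": "MS", "accession": accession, "name": name, "value": value}
    attrs.update(units)
    etree.SubElement(parent, "cvParam", **attrs)


def _user(parent, name: str, value: str) -> None:
    etree.SubElement(parent, "userParam", name=name, value=value)


def _binary_array(parent, values: np.ndarray, accession: str, name: str) -> None:
    data = struct.pack(f"<{values.size}d", *np.asarray(values, dtype=np.float64))
    b64 = base64.b64encode(data).decode("ascii")
    arr = etree.SubElement(
        parent, "binaryDataArray", encodedLength=str(len(b64))
    )
    _cv(arr, "MS:1000523", "64-bit float")
    _cv(arr, "MS:1000576", "no compression")
    unit = (
        {"unitCvRef": "MS", "unitAccession": "MS:1000040", "unitName": "m/z"}
        if accession == "MS:1000514"
        else {
            "unitCvRef": "MS",
            "unitAccession": "MS:1000131",
            "unitName": "number of detector counts",
        }
    )
    _cv(arr, accession, name, **unit)
    etree.SubElement(arr, "binary").text = b64


def write_mzml(run: AcquisitionRun, path: str | Path) -> None:
    """Serialize a run as plain (non-indexed) centroid mzML 1.1."""
    root = etree.Element(
        "mzML", xmlns=_NS, version="1.1.0", id=Path(path).stem
    )
    cv_list = etree.SubElement(root, "cvList", count="2")
    etree.SubElement(
        cv_list, "cv", id="MS",
        fullName="Proteomics Standards Initiative Mass Spectrometry Ontology",
        URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
    )
    etree.SubElement(
        cv_list, "cv", id="UO", fullName="Unit Ontology",
        URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo",
    )
    fdesc = etree.SubElement(root, "fileDescription")
    fcontent = etree.SubElement(fdesc, "fileContent")
    _cv(fcontent, "MS:1000579", "MS1 spectrum")
    if any(s.ms_level == 2 for s in run.spectra):
        _cv(fcontent, "MS:1000580", "MSn spectrum")
    _cv(fcontent, "MS:1000127", "centroid spectrum")

    sw_list = etree.SubElement(root, "softwareList", count="1")
    sw = etree.SubElement(sw_list, "software", id="phthalscreen", version="0.1.0")
    _cv(sw, "MS:1000799", "custom unreleased software tool", "phthalscreen")

    icl = etree.SubElement(root, "instrumentConfigurationList", count="1")
    ic = etree.SubElement(icl, "instrumentConfiguration", id="IC1")
    _cv(ic, "MS:1000031", "instrument model")

    dpl = etree.SubElement(root, "dataProcessingList", count="1")
    dp = etree.SubElement(dpl, "dataProcessing", id="DP1")
    pm = etree.SubElement(dp, "processingMethod", order="1", softwareRef="phthalscreen")
    _cv(pm, "MS:1000544", "Conversion to mzML")

    run_el = etree.SubElement(
        root, "run", id="run1", defaultInstrumentConfigurationRef="IC1"
    )
    for key, value in {
        "mode": run.mode,
        "channel_ce_v": "" if run.channel_ce_v is None else str(run.channel_ce_v),
        "scan_range_low": str(run.scan_range[0]),
        "scan_range_high": str(run.scan_range[1]),
        **{k: str(v) for k, v in run.metadata.items()},
    }.items():
        _user(run_el, key, value)

    slist = etree.SubElement(
        run_el, "spectrumList", count=str(len(run.spectra)),
        defaultDataProcessingRef="DP1",
    )
    for i, spec in enumerate(run.spectra):
        el = etree.SubElement(
            slist, "spectrum", index=str(i),
            id=f"scan={spec.scan_index}",
            defaultArrayLength=str(spec.mz.size),
        )
        _cv(el, "MS:1000511", "ms level", str(spec.ms_level))
        _cv(el, "MS:1000579" if spec.ms_level == 1 else "MS:1000580",
            "MS1 spectrum" if spec.ms_level == 1 else "MSn spectrum")
        _cv(el, "MS:1000127", "centroid spectrum")
        _cv(el, "MS:1000129", "negative scan")
        _user(el, "in_source_ce_v", str(spec.in_source_ce_v))
        if spec.nce:
            _user(el, "nce_levels", ",".join(str(v) for v in spec.nce))

        scan_list = etree.SubElement(el, "scanList", count="1")
        _cv(scan_list, "MS:1000795", "no combination")
        scan = etree.SubElement(scan_list, "scan")
        _cv(
            scan, "MS:1000016", "scan start time", repr(spec.rt_min),
            unitCvRef="UO", unitAccession="UO:0000031", unitName="minute",
        )
        if spec.ms_level == 2:
            plist = etree.SubElement(el, "precursorList", count="1")
            prec = etree.SubElement(plist, "precursor")
            iso = etree.SubElement(prec, "isolationWindow")
            _cv(iso, "MS:1000827", "isolation window target m/z",
                repr(spec.precursor_mz))
            half = spec.isolation_width_mz / 2.0
            _cv(iso, "MS:1000828", "isolation window lower offset", repr(half))
            _cv(iso, "MS:1000829", "isolation window upper offset", repr(half))
            sil = etree.SubElement(prec, "selectedIonList", count="1")
            sel = etree.SubElement(sil, "selectedIon")
            _cv(sel, "MS:1000744", "selected ion m/z", repr(spec.precursor_mz))
            _cv(sel, "MS:1000041", "charge state", "1")
            act = etree.SubElement(prec, "activation")
            _cv(act, "MS:1000422", "beam-type collision-induced dissociation")

        arrays = etree.SubElement(el, "binaryDataArrayList", count="2")
        _binary_array(arrays, spec.mz, "MS:1000514", "m/z array")
        _binary_array(arrays, spec.intensity, "MS:1000515", "intensity array")

    tree = etree.ElementTree(root)
    tree.write(
        str(path), xml_declaration=True, encoding="utf-8", pretty_print=True
    )


# ---------------------------------------------------------------------------
# mzML reading


class MzmlFormatError(ValueError):
    """Raised for malformed or unsupported (e.g. profile-mode) mzML input."""


def _cv_params(el) -> dict[str, str]:
    return {
        cv.get("accession"): cv.get("value", "")
        for cv in el.findall(f"{{{_NS}}}cvParam")
    }


def _decode_binary_array(arr_el, scan_id: str) -> np.ndarray:
    acc = _cv_params(arr_el)
    binary = arr_el.find(f"{{{_NS}}}binary")
    raw = base64.b64decode(binary.text or "")
    if "MS:1000574" in acc:  # zlib compression
        raw = zlib.decompress(raw)
    elif "MS:1000576" not in acc and any(
        a in acc for a in ("MS:1002312", "MS:1002313", "MS:1002746", "MS:1002747")
    ):
        raise MzmlFormatError(
            f"{scan_id}: MS-Numpress encoded arrays are not supported"
        )
    dtype = "<f4" if "MS:1000521" in acc else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(np.float64)


def _parse_spectrum(el, path, ordinal: int) -> SpectrumRecord:
    sid = el.get("id", f"index={ordinal}")
    params = _cv_params(el)
    if "MS:1000128" in params:
        raise MzmlFormatError(
            f"{path}: spectrum {sid} is profile mode; "
            "only centroided data is supported"
        )
    user = {
        up.get("name"): up.get("value", "")
        for up in el.findall(f"{{{_NS}}}userParam")
    }
    try:
        level = int(params["MS:1000511"])
    except KeyError as exc:
        raise MzmlFormatError(
            f"{path}: spectrum {sid} lacks an ms level cvParam"
        ) from exc

    rt = 0.0
    scan = el.find(f"{{{_NS}}}scanList/{{{_NS}}}scan")
    if scan is not None:
        for cv in scan.findall(f"{{{_NS}}}cvParam"):
            if cv.get("accession") == "MS:1000016":
                rt = float(cv.get("value"))
                if "second" in (cv.get("unitName") or "minute"):
                    rt /= 60.0

    precursor = None
    iso_width = 1.5
    if level >= 2:
        prec = el.find(f"{{{_NS}}}precursorList/{{{_NS}}}precursor")
        if prec is None:
            raise MzmlFormatError(
                f"{path}: MS{level} spectrum {sid} lacks precursor metadata"
            )
        sel = prec.find(f"{{{_NS}}}selectedIonList/{{{_NS}}}selectedIon")
        sel_params = _cv_params(sel) if sel is not None else {}
        if "MS:1000744" not in sel_params:
            raise MzmlFormatError(
                f"{path}: MS{level} spectrum {sid} lacks a selected ion m/z"
            )
        precursor = float(sel_params["MS:1000744"])
        iso = prec.find(f"{{{_NS}}}isolationWindow")
        if iso is not None:
            iso_params = _cv_params(iso)
            lo = float(iso_params.get("MS:1000828", 0.75))
            hi = float(iso_params.get("MS:1000829", 0.75))
            iso_width = lo + hi

    mz = np.empty(0)
    inten = np.empty(0)
    for arr in el.findall(
        f"{{{_NS}}}binaryDataArrayList/{{{_NS}}}binaryDataArray"
    ):
        acc = _cv_params(arr)
        values = _decode_binary_array(arr, f"{path}:{sid}")
        if "MS:1000514" in acc:
            mz = values
        elif "MS:1000515" in acc:
            inten = values
    if mz.size != inten.size:
        raise MzmlFormatError(
            f"{path}: spectrum {sid} has mismatched m/z and intensity arrays"
        )

    nce: tuple[float, ...] = ()
    if user.get("nce_levels"):
        nce = tuple(float(v) for v in user["nce_levels"].split(","))
    return SpectrumRecord(
        scan_index=int(el.get("index", ordinal)),
        rt_min=rt,
        ms_level=level,
        mz=mz,
        intensity=inten,
        in_source_ce_v=float(user.get("in_source_ce_v", 0.0) or 0.0),
        nce=nce,
        precursor_mz=precursor,
        isolation_width_mz=iso_width,
    )


def read_mzml(path: str | Path, mode: str | None = None) -> AcquisitionRun:
    """Read a centroided mzML file into an :class:`AcquisitionRun`.

    Plain and indexed mzML are accepted, gzipped or not; binary arrays may
    be 32- or 64-bit float, zlib-compressed or raw. ``mode`` overrides
    acquisition-mode inference (a run containing MS2 scans is taken to be
    DDA, otherwise a DIA channel).
    """
    path = Path(path)
    opener = gzip.open if path.open("rb").read(2) == b"\x1f\x8b" else open
    try:
        with opener(path, "rb") as fh:
            tree = etree.parse(fh)
    except etree.XMLSyntaxError as exc:
        raise MzmlFormatError(f"{path}: not well-formed mzML: {exc}") from exc

    root = tree.getroot()
    if root.tag == f"{{{_NS}}}indexedmzML":
        root = root.find(f"{{{_NS}}}mzML")
    if root is None or root.tag != f"{{{_NS}}}mzML":
        raise MzmlFormatError(f"{path}: no <mzML> element found")

    spectra = [
        _parse_spectrum(el, path, i)
        for i, el in enumerate(
            root.findall(
                f"{{{_NS}}}run/{{{_NS}}}spectrumList/{{{_NS}}}spectrum"
            )
        )
    ]
    run_meta = {
        up.get("name"): up.get("value")
        for up in root.findall(f"{{{_NS}}}run/{{{_NS}}}userParam")
    }

    has_ms2 = any(s.ms_level == 2 for s in spectra)
    inferred = run_meta.pop("mode", None) or ("DDA" if has_ms2 else "DIA_channel")
    channel = run_meta.pop("channel_ce_v", None) or None
    lo = float(run_meta.pop("scan_range_low", 150.0) or 150.0)
    hi = float(run_meta.pop("scan_range_high", 1000.0) or 1000.0)
    return AcquisitionRun(
        spectra=spectra,
        mode=mode or inferred,
        channel_ce_v=float(channel) if channel is not None else None,
        scan_range=(lo, hi),
        metadata=run_meta,
    )


# ---------------------------------------------------------------------------
# Chromatogram extraction


def tic(run: AcquisitionRun) -> EICTrace:
    """Total ion chromatogram over the MS1 spectra of a run."""
    ms1 = run.ms1_spectra()
    rts = np.array([s.rt_min for s in ms1])
    totals = np.array([s.total_intensity for s in ms1])
    return EICTrace(target_mz=0.0, tol_ppm=0.0, rt_min=rts, intensity=totals)


def extract_eic(
    run: AcquisitionRun,
    target_mz: float,
    tol_ppm: float = 5.0,
    ms_level: int = 1,
) -> EICTrace:
    """Extracted ion chromatogram for a closed ppm window around ``target_mz``.

    Each contributing spectrum yields one point equal to the sum of centroid
    intensities with ``|mz - target| <= tol_ppm * target / 1e6``; for
    ``ms_level=2`` only MS2 scans contribute (the EIC MS/MS view of DDA
    data). A target outside the run's scan range returns a zero trace with a
    warning.
    """
    specs = [s for s in run.spectra if s.ms_level == ms_level]
    lo_r, hi_r = run.scan_range
    if not (lo_r <= target_mz <= hi_r) and ms_level == 1:
        warnings.warn(
            f"target m/z {target_mz} outside scan range {run.scan_range}; "
            "returning a zero trace"
        )
        rts = np.array([s.rt_min for s in specs])
        return EICTrace(target_mz, tol_ppm, rts, np.zeros(len(specs)),
                        ms_level=ms_level)

    half = tol_ppm * target_mz / 1e6
    rts = np.empty(len(specs))
    vals = np.empty(len(specs))
    for i, s in enumerate(specs):
        lo = np.searchsorted(s.mz, target_mz - half, side="left")
        hi = np.searchsorted(s.mz, target_mz + half, side="right")
        rts[i] = s.rt_min
        vals[i] = s.intensity[lo:hi].sum()
    return EICTrace(target_mz, tol_ppm, rts, vals, ms_level=ms_level)
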