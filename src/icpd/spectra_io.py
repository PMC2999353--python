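"""Reading, writing and in-memory representation of centroided LC/MS runs.

Two interchange formats are supported:

* a plain tab-separated table with header ``scan  rt  mz  intensity`` and one
  row per centroid peak (scan indices 0-based, retention times in seconds);
* mzML 1.1 with MS1 centroid spectra, via a self-contained reader/writer
  pair (64-bit float arrays, base64, optional zlib on read) built on the
  standard library XML tooling.
"""

from __future__ import annotations

import base64
import struct
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .isotope_model import ValidationError

__all__ = ["CentroidScan", "LCMSMap", "read_map", "write_map", "centroid_scan"]

TSV_COLUMNS = ["scan", "rt", "mz", "intensity"]


@dataclass
class CentroidScan:
    """One centroided MS1 spectrum: peaks (mz, intensity) at retention time rt."""

    rt: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt < 0:
            raise ValidationError(f"retention time must be >= 0, got {self.rt}")
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValidationError("mz and intensity must be matching 1-D arrays")
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            raise ValidationError(f"peaks not strictly ascending in mz at rt={self.rt}")
        if np.any(self.intensity < 0):
            raise ValidationError(f"negative intensity in scan at rt={self.rt}")

    @property
    def n_peaks(self) -> int:
        return self.mz.size


@dataclass
class LCMSMap:
    """An LC/MS run: scans strictly ascending in retention time.

    ``scan_interval`` is the nominal time between consecutive scans in
    seconds; scan indices are 0-based.
    """

    scans: list[CentroidScan]
    scan_interval: float = 1.0
    _cumsum: list[np.ndarray] | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        rts = np.array([s.rt for s in self.scans])
        if rts.size and np.any(np.diff(rts) <= 0):
            bad = int(np.flatnonzero(np.diff(rts) <= 0)[0]) + 1
            raise ValidationError(f"scans not strictly ascending in rt at index {bad}")
        if not self.scan_interval > 0:
            raise ValidationError("scan_interval must be positive")

    @property
    def n_scans(self) -> int:
        return len(self.scans)

    @property
    def n_peaks(self) -> int:
        return sum(s.n_peaks for s in self.scans)

    def intensity_cumsum(self, t: int) -> np.ndarray:
        """Prefix sums of scan ``t``'s intensities (cached), for fast window sums."""
        if self._cumsum is None:
            self._cumsum = [None] * len(self.scans)  # type: ignore[list-item]
        if self._cumsum[t] is None:
            c = np.zeros(self.scans[t].n_peaks + 1)
            np.cumsum(self.scans[t].intensity, out=c[1:])
            self._cumsum[t] = c
        return self._cumsum[t]

    def min_positive_intensity(self) -> float:
        """Smallest positive intensity in the map (1.0 for an empty map)."""
        best = np.inf
        for s in self.scans:
            pos = s.intensity[s.intensity > 0]
            if pos.size:
                best = min(best, float(pos.min()))
        return best if np.isfinite(best) else 1.0


def _infer_format(path: str | Path, format: str | None) -> str:
    if format is not None:
        fmt = format.lower()
    else:
        fmt = "mzml" if str(path).lower().endswith(".mzml") else "tsv"
    if fmt not in ("mzml", "tsv"):
        raise ValidationError(f"unknown map format {format!r}")
    return fmt


def read_map(
    path: str | Path, format: str | None = None, centroid: bool = False
) -> LCMSMap:
    """Read an LC/MS map from tsv or mzML.

    Profile-mode mzML spectra are rejected unless ``centroid=True``, in which
    case :func:`centroid_scan` is applied per scan.  The format is inferred
    from the extension when not given.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"no such file: {path}")
    fmt = _infer_format(path, format)
    return _read_mzml(path, centroid) if fmt == "mzml" else _read_tsv(path)


def _read_tsv(path: Path) -> LCMSMap:
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise ValidationError(f"empty map file: {path}") from None
    missing = [c for c in TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"map tsv {path} missing columns {missing}")
    by_index: dict[int, CentroidScan] = {}
    for idx, grp in df.groupby("scan", sort=True):
        order = np.argsort(grp["mz"].to_numpy(), kind="stable")
        by_index[int(idx)] = CentroidScan(
            rt=float(grp["rt"].iloc[0]),
            mz=grp["mz"].to_numpy()[order],
            intensity=grp["intensity"].to_numpy()[order],
        )
    if not by_index:
        return LCMSMap(scans=[])
    indices = np.array(sorted(by_index))
    rts = np.array([by_index[i].rt for i in indices])
    if indices.size > 1:
        interval = float(np.median(np.diff(rts) / np.diff(indices)))
    else:
        interval = 1.0
    # scans with no peaks carry no tsv rows; restore them (from index 0) so
    # scan indices keep their meaning
    scans: list[CentroidScan] = []
    start_rt = rts[0] - indices[0] * interval
    if start_rt < 0:
        raise ValidationError(
            f"scan index/rt mismatch in {path}: extrapolated first rt is negative"
        )
    for idx in range(0, int(indices[-1]) + 1):
        if idx in by_index:
            scans.append(by_index[idx])
        else:
            rt = start_rt + idx * interval
            scans.append(CentroidScan(rt=float(rt), mz=np.array([]), intensity=np.array([])))
    return LCMSMap(scans=scans, scan_interval=interval)


_MZML_NS = "{http://psi.hupo.org/ms/mzml}"

# PSI-MS controlled-vocabulary accessions used when decoding spectra
_ACC_MS_LEVEL = "MS:1000511"
_ACC_PROFILE = "MS:1000128"
_ACC_SCAN_START = "MS:1000016"
_ACC_FLOAT64 = "MS:1000523"
_ACC_FLOAT32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INTENSITY_ARRAY = "MS:1000515"


def _decode_binary_array(array_el: ET.Element) -> tuple[str | None, np.ndarray]:
    """Decode one <binaryDataArray>: returns (kind, values)."""
    import zlib

    accs = {cv.get("accession") for cv in array_el.findall(f"{_MZML_NS}cvParam")}
    kind = "mz" if _ACC_MZ_ARRAY in accs else "intensity" if _ACC_INTENSITY_ARRAY in accs else None
    binary = array_el.find(f"{_MZML_NS}binary")
    raw = base64.b64decode((binary.text or "").strip()) if binary is not None else b""
    if _ACC_ZLIB in accs:
        raw = zlib.decompress(raw)
    dtype = "<f4" if _ACC_FLOAT32 in accs else "<f8"
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def _read_mzml(path: Path, centroid: bool) -> LCMSMap:
    """Minimal mzML 1.1 reader: MS1 spectra, 32/64-bit float, zlib or raw."""
    scans: list[CentroidScan] = []
    for _, spectrum in ET.iterparse(str(path)):
        if spectrum.tag != f"{_MZML_NS}spectrum":
            continue
        params = {cv.get("accession"): cv for cv in spectrum.iter(f"{_MZML_NS}cvParam")}
        level = params.get(_ACC_MS_LEVEL)
        if level is not None and level.get("value") not in ("", "1"):
            spectrum.clear()
            continue
        rt = 0.0
        start = params.get(_ACC_SCAN_START)
        if start is not None:
            rt = float(start.get("value"))
            if "minute" in (start.get("unitName") or ""):
                rt *= 60.0
        mz = inten = np.array([])
        for array_el in spectrum.iter(f"{_MZML_NS}binaryDataArray"):
            kind, values = _decode_binary_array(array_el)
            if kind == "mz":
                mz = values
            elif kind == "intensity":
                inten = values
        if mz.size != inten.size:
            raise ValidationError(f"array length mismatch in spectrum {spectrum.get('id')!r}")
        if _ACC_PROFILE in params:
            if not centroid:
                raise ValidationError(
                    f"profile-mode spectrum {spectrum.get('id')!r}; "
                    "pass centroid=True to centroid on the fly"
                )
            mz, inten = centroid_scan(mz, inten)
        scans.append(CentroidScan(rt=rt, mz=mz, intensity=inten))
        spectrum.clear()
    scans.sort(key=lambda s: s.rt)
    rts = [s.rt for s in scans]
    interval = float(np.median(np.diff(rts))) if len(rts) > 1 else 1.0
    return LCMSMap(scans=scans, scan_interval=interval)


def write_map(lcms_map: LCMSMap, path: str | Path, format: str | None = None) -> None:
    """Write an LC/MS map as tsv (one row per centroid peak) or mzML."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "tsv":
        rows = {
            "scan": np.concatenate(
                [np.full(s.n_peaks, i, dtype=int) for i, s in enumerate(lcms_map.scans)]
            )
            if lcms_map.scans
            else np.array([], dtype=int),
            "rt": np.concatenate(
                [np.full(s.n_peaks, s.rt) for s in lcms_map.scans]
            )
            if lcms_map.scans
            else np.array([]),
            "mz": np.concatenate([s.mz for s in lcms_map.scans])
            if lcms_map.scans
            else np.array([]),
            "intensity": np.concatenate([s.intensity for s in lcms_map.scans])
            if lcms_map.scans
            else np.array([]),
        }
        pd.DataFrame(rows, columns=TSV_COLUMNS).to_csv(
            path, sep="\t", index=False, float_format="%.10g"
        )
    else:
        _write_mzml(lcms_map, path)


def _b64(values: np.ndarray) -> str:
    raw = struct.pack(f"<{values.size}d", *values.astype(float))
    return base64.b64encode(raw).decode("ascii")


def _cv(parent: ET.Element, accession: str, name: str, value: str = "", **attrs) -> None:
    ET.SubElement(
        parent, "cvParam", cvRef="MS", accession=accession, name=name, value=value, **attrs
    )


def _write_mzml(lcms_map: LCMSMap, path: Path) -> None:
    root = ET.Element(
        "mzML", xmlns="http://psi.hupo.org/ms/mzml", version="1.1.0", id="icpd-export"
    )
    cv_list = ET.SubElement(root, "cvList", count="2")
    ET.SubElement(
        cv_list, "cv", id="MS", fullName="Proteomics Standards Initiative Mass Spectrometry Ontology",
        URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
    )
    ET.SubElement(
        cv_list, "cv", id="UO", fullName="Unit Ontology",
        URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo",
    )
    run = ET.SubElement(root, "run", id="run1")
    spec_list = ET.SubElement(run, "spectrumList", count=str(lcms_map.n_scans))
    for i, scan in enumerate(lcms_map.scans):
        spec = ET.SubElement(
            spec_list, "spectrum", index=str(i), id=f"scan={i}",
            defaultArrayLength=str(scan.n_peaks),
        )
        _cv(spec, "MS:1000511", "ms level", "1")
        _cv(spec, "MS:1000127", "centroid spectrum")
        scans_el = ET.SubElement(spec, "scanList", count="1")
        _cv(scans_el, "MS:1000795", "no combination")
        scan_el = ET.SubElement(scans_el, "scan")
        ET.SubElement(
            scan_el, "cvParam", cvRef="MS", accession="MS:1000016",
            name="scan start time", value=f"{scan.rt:.8f}",
            unitCvRef="UO", unitAccession="UO:0000010", unitName="second",
        )
        arrays = ET.SubElement(spec, "binaryDataArrayList", count="2")
        for accession, name, data in (
            ("MS:1000514", "m/z array", scan.mz),
            ("MS:1000515", "intensity array", scan.intensity),
        ):
            encoded = _b64(data)
            arr = ET.SubElement(arrays, "binaryDataArray", encodedLength=str(len(encoded)))
            _cv(arr, "MS:1000523", "64-bit float")
            _cv(arr, "MS:1000576", "no compression")
            _cv(arr, accession, name)
            ET.SubElement(arr, "binary").text = encoded
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, xml_declaration=True, encoding="utf-8")


def centroid_scan(
    mz_grid: np.ndarray, intensities: np.ndarray, floor: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Pick local maxima of a profile-mode spectrum as centroid peaks.

    Each centroid's m/z is the intensity-weighted mean over the local maximum
    and its immediate neighbours; its intensity is the apex intensity.
    Maxima at or below ``floor`` are discarded.
    """
    mz_grid = np.asarray(mz_grid, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    if mz_grid.shape != intensities.shape or mz_grid.ndim != 1:
        raise ValidationError("mz grid and intensities must be matching 1-D arrays")
    if mz_grid.size and np.any(np.diff(mz_grid) <= 0):
        raise ValidationError("mz grid must be strictly ascending")
    n = mz_grid.size
    out_mz, out_int = [], []
    for i in range(n):
        v = intensities[i]
        if v <= floor or v <= 0:
            continue
        left = intensities[i - 1] if i > 0 else -np.inf
        right = intensities[i + 1] if i < n - 1 else -np.inf
        if v > left and v > right:
            lo, hi = max(i - 1, 0), min(i + 2, n)
            w = intensities[lo:hi]
            out_mz.append(float(np.dot(mz_grid[lo:hi], w) / w.sum()))
            out_int.append(float(v))
    return np.asarray(out_mz), np.asarray(out_int)
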