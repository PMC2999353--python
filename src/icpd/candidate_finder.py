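"""Peptide candidate generation (the MZlist / MassList stage).

Every centroid m/z observed anywhere in the run is a potential isotopologue
of some peptide.  Centroids are pooled over all scans, grouped into
mass-accuracy bins of width 2*dmz ppm (with dmz ppm overlap between
consecutive bins so no peptide is split by a bin edge), and each bin's
extracted ion chromatogram is segmented into elution windows: maximal runs
of non-zero scans, bridged across gaps of at most ``g`` scans, kept when
they contain at least ``s`` non-zero scans.  Each surviving (bin, segment)
pair becomes an m/z candidate; near-duplicates created by the bin overlap
are merged to a fixpoint; finally each m/z candidate is expanded into one
neutral-mass hypothesis per charge state 1..CS, assuming the observed m/z is
the monoisotopic peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .isotope_model import CONSTANTS, PhysicalConstants, ValidationError
from .spectra_io import LCMSMap

__all__ = [
    "MZCandidate",
    "PeptideCandidate",
    "collect_centroids",
    "bin_mz",
    "bin_xic",
    "extract_segments",
    "make_mzlist",
    "expand_charge_states",
]


@dataclass(frozen=True)
class MZCandidate:
    """One m/z value with an elution window (inclusive scan indices).

    ``weight`` is the summed intensity backing the candidate; it is carried
    so that merges can recompute the intensity-weighted mean m/z.
    """

    mz: float
    rt_start: int
    rt_end: int
    weight: float = 0.0

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValidationError("candidate mz must be positive")
        if self.rt_start > self.rt_end:
            raise ValidationError("rt_start must be <= rt_end")


@dataclass(frozen=True)
class PeptideCandidate:
    """A neutral-mass hypothesis for one MZCandidate at one charge state."""

    mass: float
    cs_hypothesis: int
    rt_start: int
    rt_end: int
    source_mz: float

    def __post_init__(self) -> None:
        if not self.mass > 0:
            raise ValidationError("candidate mass must be positive")
        if self.cs_hypothesis < 1:
            raise ValidationError("charge hypothesis must be >= 1")


@dataclass(frozen=True)
class _Bin:
    """Member centroids (indices into the pooled arrays) of one m/z bin."""

    lo: float
    hi: float
    members: np.ndarray


def collect_centroids(lcms_map: LCMSMap) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pool all centroids of the run into flat (scan, mz, intensity) arrays."""
    if not lcms_map.scans:
        return np.array([], dtype=int), np.array([]), np.array([])
    scan = np.concatenate(
        [np.full(s.n_peaks, i, dtype=int) for i, s in enumerate(lcms_map.scans)]
    )
    mz = np.concatenate([s.mz for s in lcms_map.scans])
    intensity = np.concatenate([s.intensity for s in lcms_map.scans])
    return scan, mz, intensity


def bin_mz(
    centroids: tuple[np.ndarray, np.ndarray, np.ndarray], dmz: float
) -> list[_Bin]:
    """Greedy mass-accuracy binning of pooled centroids.

    Centroids are sorted by m/z; a new bin opens when the next m/z exceeds
    the current bin's anchor (its lowest member) by more than 2*dmz ppm.
    Each bin's upper edge is then extended dmz ppm into the next bin, so a
    centroid near an edge may belong to two bins.
    """
    if not dmz > 0:
        raise ValidationError("dmz must be positive")
    _, mz, _ = centroids
    if mz.size == 0:
        return []
    order = np.argsort(mz, kind="stable")
    mzs = mz[order]
    bins: list[tuple[float, float, int, int]] = []  # (anchor, edge, start, stop)
    start = 0
    anchor = mzs[0]
    for i in range(1, mzs.size):
        edge = anchor * (1.0 + 2e-6 * dmz)
        if mzs[i] > edge:
            bins.append((anchor, edge, start, i))
            start, anchor = i, mzs[i]
    bins.append((anchor, anchor * (1.0 + 2e-6 * dmz), start, mzs.size))
    out: list[_Bin] = []
    for anchor, edge, lo_i, hi_i in bins:
        ext = edge * (1.0 + 1e-6 * dmz)
        hi_ext = int(np.searchsorted(mzs, ext, side="left"))
        out.append(_Bin(lo=anchor, hi=ext, members=order[lo_i:max(hi_i, hi_ext)]))
    return out


def bin_xic(
    mz_bin: _Bin,
    centroids: tuple[np.ndarray, np.ndarray, np.ndarray],
    n_scans: int,
) -> np.ndarray:
    """Extracted ion chromatogram of a bin: summed member intensity per scan."""
    scan, _, intensity = centroids
    trace = np.zeros(n_scans)
    np.add.at(trace, scan[mz_bin.members], intensity[mz_bin.members])
    return trace


def extract_segments(trace: np.ndarray, s: int, g: int) -> list[tuple[int, int]]:
    """Elution windows of an XIC: non-zero runs bridged over gaps <= g scans.

    Runs whose merged span contains fewer than ``s`` non-zero scans are
    discarded.  Windows are inclusive scan-index pairs with non-zero
    endpoints.
    """
    if s < 1:
        raise ValidationError("minimum segment length s must be >= 1")
    if g < 0:
        raise ValidationError("gap tolerance g must be >= 0")
    nz = np.flatnonzero(np.asarray(trace) > 0)
    if nz.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(nz) > g + 1)
    segments = []
    for group in np.split(nz, breaks + 1):
        if group.size >= s:
            segments.append((int(group[0]), int(group[-1])))
    return segments


def _ppm_close(mz_a: float, mz_b: float, dmz: float) -> bool:
    return abs(mz_a - mz_b) <= dmz * 1e-6 * min(mz_a, mz_b)


def _windows_overlap(a: MZCandidate, b: MZCandidate) -> bool:
    return a.rt_start <= b.rt_end and b.rt_start <= a.rt_end


def _merge_group(group: list[MZCandidate]) -> MZCandidate:
    w = np.array([max(c.weight, 1e-300) for c in group])
    mz = float(np.dot([c.mz for c in group], w) / w.sum())
    return MZCandidate(
        mz=mz,
        rt_start=min(c.rt_start for c in group),
        rt_end=max(c.rt_end for c in group),
        weight=float(sum(c.weight for c in group)),
    )


def _merge_pass(cands: list[MZCandidate], dmz: float) -> tuple[list[MZCandidate], bool]:
    cands = sorted(cands, key=lambda c: (c.mz, c.rt_start))
    parent = list(range(len(cands)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, a in enumerate(cands):
        for j in range(i + 1, len(cands)):
            b = cands[j]
            if not _ppm_close(a.mz, b.mz, dmz):
                break  # sorted by mz: later candidates are farther away
            if _windows_overlap(a, b):
                parent[find(i)] = find(j)
    groups: dict[int, list[MZCandidate]] = {}
    for i, c in enumerate(cands):
        groups.setdefault(find(i), []).append(c)
    merged = sorted(
        (_merge_group(g) for g in groups.values()), key=lambda c: (c.mz, c.rt_start)
    )
    return merged, len(merged) < len(cands)


def make_mzlist(
    lcms_map: LCMSMap, dmz: float = 10.0, s: int = 3, g: int = 2
) -> list[MZCandidate]:
    """Build the m/z candidate list: bin, segment, recompute mean m/z, merge.

    The m/z of each candidate is the intensity-weighted mean of the bin's
    member centroids inside its elution window.  Candidates within dmz ppm
    of each other with overlapping windows are merged (union window,
    weighted mean m/z), repeatedly until a fixpoint is reached.
    """
    centroids = collect_centroids(lcms_map)
    scan, mz, intensity = centroids
    cands: list[MZCandidate] = []
    for mz_bin in bin_mz(centroids, dmz):
        trace = bin_xic(mz_bin, centroids, lcms_map.n_scans)
        m_scan = scan[mz_bin.members]
        m_mz = mz[mz_bin.members]
        m_int = intensity[mz_bin.members]
        for a, b in extract_segments(trace, s, g):
            inside = (m_scan >= a) & (m_scan <= b) & (m_int > 0)
            w = m_int[inside]
            if w.sum() <= 0:
                continue
            cands.append(
                MZCandidate(
                    mz=float(np.dot(m_mz[inside], w) / w.sum()),
                    rt_start=a,
                    rt_end=b,
                    weight=float(w.sum()),
                )
            )
    changed = True
    while changed:
        cands, changed = _merge_pass(cands, dmz)
    return cands


def expand_charge_states(
    mzlist: list[MZCandidate],
    max_charge: int = 4,
    constants: PhysicalConstants = CONSTANTS,
) -> list[PeptideCandidate]:
    """Expand each m/z candidate into one mass hypothesis per charge state.

    The observed m/z is assumed to be the monoisotopic (iso = 0) peak, so
    mass = mz * cs - cs * w_p for each hypothesized charge cs.
    """
    if max_charge < 1:
        raise ValidationError("max_charge must be >= 1")
    out = []
    for cand in mzlist:
        for cs in range(1, max_charge + 1):
            out.append(
                PeptideCandidate(
                    mass=cand.mz * cs - cs * constants.proton_mass,
                    cs_hypothesis=cs,
                    rt_start=cand.rt_start,
                    rt_end=cand.rt_end,
                    source_mz=cand.mz,
                )
            )
    return out
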