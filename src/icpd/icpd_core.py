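"""Information-combining isotope scoring: the detector core.

For each peptide candidate the raw evidence is a trace grid
``y[t, cs, iso]``: summed centroid intensity in scan ``t`` of the candidate's
elution window, within +-dmz ppm of the predicted m/z of charge state ``cs``
and isotope position ``iso``.  Under the generative model

    y[t, cs, iso] = A * C(t) * f(cs) * f(iso) + noise,

where A is total abundance, C(t) the elution profile (sums to 1 over the
window) and f(cs), f(iso) the charge-state and isotope distributions (each
summing to 1), summing over charge states and matched-filtering over time
with weights w(t) = C(t) / sum_t C(t)^2 yields a combined observation

    y_hat[iso] = sum_t sum_cs w(t) * y[t, cs, iso]

whose mean is exactly A * f(iso): the charge-state distribution cancels by
summation and the matched filter has unit gain.  The summed noise is treated
as Gaussian (central limit theorem) with a single variance sigma'^2 that
scales with abundance as a power law, sigma'^2 = c * A_hat^p with
p in {1, 2, 3}.  The isotope matching score is the Gaussian log-likelihood
of y_hat under the theoretical averagine pattern.

A single-scan baseline scorer (isotope pattern read off the one scan and
charge state with the largest summed intensity, abundance taken as the
highest single peak intensity) is provided for comparison; it uses strictly
less information and is noisier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .candidate_finder import PeptideCandidate, expand_charge_states, make_mzlist
from .isotope_model import (
    CONSTANTS,
    PhysicalConstants,
    TheoreticalPattern,
    ValidationError,
    mz_grid,
    theoretical_pattern,
)
from .spectra_io import LCMSMap

__all__ = [
    "DetectorParams",
    "TraceGrid",
    "ElutionProfile",
    "CombinedPattern",
    "NoiseModel",
    "ScoredPeak",
    "extract_trace_grid",
    "estimate_elution_profile",
    "combine_observations",
    "single_scan_pattern",
    "calibrate_noise_constant",
    "matching_score",
    "single_scan_score",
    "icpd_pipeline",
    "outlist_to_frame",
    "write_outlist",
    "read_outlist",
]

logger = logging.getLogger("icpd")

OUTLIST_COLUMNS = ["mass", "cs", "rt_start", "rt_end", "score", "volume", "max_intensity"]

#: Score assigned to candidates with no evidence (empty trace grid).
NO_EVIDENCE_SCORE = float("-inf")


@dataclass(frozen=True)
class DetectorParams:
    """All tunable detector parameters.

    dmz        mass-accuracy window, ppm (instrument mass accuracy)
    s          minimum number of non-zero scans in an elution segment
    g          maximum bridged gap in an XIC, scans
    max_charge highest charge state hypothesized (CS)
    n_iso      isotope positions scored per candidate
    p          noise-variance exponent, sigma'^2 = c * A^p, p in {1, 2, 3}
    c          noise-variance scale; calibrated from the data when None
    score_mode "combined" (information combining) or "single_scan" baseline
    """

    dmz: float = 10.0
    s: int = 3
    g: int = 2
    max_charge: int = 4
    n_iso: int = 5
    p: int = 3
    c: float | None = None
    score_mode: str = "combined"

    def __post_init__(self) -> None:
        if self.p not in (1, 2, 3):
            raise ValidationError(f"noise exponent p must be 1, 2 or 3, got {self.p}")
        if self.c is not None and not self.c > 0:
            raise ValidationError("noise constant c must be positive")
        if self.score_mode not in ("combined", "single_scan"):
            raise ValidationError(f"unknown score_mode {self.score_mode!r}")
        if not self.dmz > 0 or self.s < 1 or self.g < 0 or self.max_charge < 1:
            raise ValidationError("invalid detector parameters")
        if self.n_iso < 1:
            raise ValidationError("n_iso must be >= 1")


@dataclass(frozen=True)
class NoiseModel:
    """Power-law noise variance sigma'^2 = c * A^p on the combined pattern."""

    p: int
    c: float

    def __post_init__(self) -> None:
        if self.p not in (1, 2, 3):
            raise ValidationError(f"noise exponent p must be 1, 2 or 3, got {self.p}")
        if not self.c > 0:
            raise ValidationError("noise constant c must be positive")

    def variance(self, abundance: float, floor: float = 0.0) -> float:
        return self.c * max(abundance, floor) ** self.p


@dataclass
class TraceGrid:
    """Chromatographic evidence of one candidate over (scan, charge, isotope)."""

    candidate: PeptideCandidate
    y: np.ndarray  # shape (T, max_charge, n_iso), non-negative

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        expected_t = self.candidate.rt_end - self.candidate.rt_start + 1
        if self.y.ndim != 3 or self.y.shape[0] != expected_t:
            raise ValidationError("trace grid shape does not match candidate window")
        if np.any(self.y < 0):
            raise ValidationError("trace grid intensities must be non-negative")

    @property
    def volume(self) -> float:
        return float(self.y.sum())

    @property
    def max_intensity(self) -> float:
        return float(self.y.max()) if self.y.size else 0.0


@dataclass(frozen=True)
class ElutionProfile:
    """Normalized elution distribution C(t) over a candidate window."""

    C: np.ndarray
    empty: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "C", np.asarray(self.C, dtype=float))
        if np.any(self.C < 0):
            raise ValidationError("elution profile must be non-negative")
        if not self.empty and not np.isclose(self.C.sum(), 1.0, atol=1e-9):
            raise ValidationError("elution profile must sum to 1")


@dataclass
class CombinedPattern:
    """The combined observation y_hat[iso] with its abundance estimate."""

    y_hat: np.ndarray
    A_hat: float
    n_obs: int
    sigma2: float | None = None  # filled in by matching_score

    def __post_init__(self) -> None:
        self.y_hat = np.asarray(self.y_hat, dtype=float)


@dataclass
class ScoredPeak:
    """One OutList entry: a candidate with its score and peak parameters."""

    candidate: PeptideCandidate
    score: float
    volume: float
    max_intensity: float
    pattern: CombinedPattern

    def __post_init__(self) -> None:
        if self.volume + 1e-9 < self.max_intensity:
            raise ValidationError("peak volume cannot be below max intensity")


def extract_trace_grid(
    lcms_map: LCMSMap,
    candidate: PeptideCandidate,
    dmz: float = 10.0,
    max_charge: int = 4,
    n_iso: int = 5,
    constants: PhysicalConstants = CONSTANTS,
) -> TraceGrid:
    """Sum centroid intensities in +-dmz ppm windows around every predicted m/z.

    Windows are half-open [lo, hi).  Cells with no centroid are zero.
    """
    if candidate.rt_start < 0 or candidate.rt_end >= lcms_map.n_scans:
        raise ValidationError(
            f"candidate window [{candidate.rt_start}, {candidate.rt_end}] outside map"
        )
    targets = mz_grid(candidate.mass, max_charge, n_iso, constants)
    lo = (targets * (1.0 - dmz * 1e-6)).ravel()
    hi = (targets * (1.0 + dmz * 1e-6)).ravel()
    T = candidate.rt_end - candidate.rt_start + 1
    y = np.zeros((T, max_charge, n_iso))
    for t in range(T):
        scan = lcms_map.scans[candidate.rt_start + t]
        if scan.n_peaks == 0:
            continue
        csum = lcms_map.intensity_cumsum(candidate.rt_start + t)
        i_lo = np.searchsorted(scan.mz, lo, side="left")
        i_hi = np.searchsorted(scan.mz, hi, side="left")
        y[t] = (csum[i_hi] - csum[i_lo]).reshape(max_charge, n_iso)
    return TraceGrid(candidate=candidate, y=y)


def estimate_elution_profile(grid: TraceGrid) -> ElutionProfile:
    """Elution profile estimate: total grid intensity per scan, normalized."""
    total = grid.y.sum(axis=(1, 2))
    mass = total.sum()
    if mass <= 0:
        return ElutionProfile(C=np.zeros_like(total), empty=True)
    return ElutionProfile(C=total / mass)


def combine_observations(grid: TraceGrid, profile: ElutionProfile) -> CombinedPattern:
    """Combine the grid across scans and charge states into y_hat[iso].

    Uses matched-filter weights w(t) = C(t) / sum_t C(t)^2, the
    minimum-variance unbiased linear combination under i.i.d. cell noise:
    sum_t w(t) C(t) = 1, so E[y_hat[iso]] = A * f(iso) with coefficient one
    and the charge-state distribution cancelled by summation.
    """
    T, n_cs, n_iso = grid.y.shape
    if profile.empty:
        return CombinedPattern(y_hat=np.zeros(n_iso), A_hat=0.0, n_obs=T * n_cs)
    w = profile.C / np.dot(profile.C, profile.C)
    y_hat = np.tensordot(w, grid.y.sum(axis=1), axes=1)
    return CombinedPattern(y_hat=y_hat, A_hat=float(y_hat.sum()), n_obs=T * n_cs)


def single_scan_pattern(grid: TraceGrid) -> CombinedPattern:
    """Baseline pattern from the single most intense (scan, charge) cell row.

    The isotope pattern is read off the one scan and charge state with the
    largest summed intensity; the abundance estimate is the highest single
    peak intensity in that scan.
    """
    row_sums = grid.y.sum(axis=2)
    if row_sums.max(initial=0.0) <= 0:
        return CombinedPattern(y_hat=np.zeros(grid.y.shape[2]), A_hat=0.0, n_obs=1)
    t_star, cs_star = np.unravel_index(int(np.argmax(row_sums)), row_sums.shape)
    return CombinedPattern(
        y_hat=grid.y[t_star, cs_star].copy(),
        A_hat=float(grid.y[t_star].max()),
        n_obs=1,
    )


def calibrate_noise_constant(
    patterns: list[CombinedPattern],
    theos: list[TheoreticalPattern],
    p: int,
    min_patterns: int = 10,
) -> float:
    """Estimate the noise scale c of sigma'^2 = c * A^p from the data itself.

    For each candidate with positive abundance the mean squared residual of
    y_hat against A_hat * f(iso) is divided by A_hat^p; c is the median of
    these ratios over candidates.  The median keeps genuine peptides (small
    residuals) and gross outliers from dominating the scale.  An all-zero
    residual set falls back to a tiny positive floor.
    """
    ratios = []
    a_max = 0.0
    for pattern, theo in zip(patterns, theos):
        if pattern.A_hat <= 0:
            continue
        a_max = max(a_max, pattern.A_hat)
        resid = pattern.y_hat - pattern.A_hat * theo.f_iso
        ratios.append(float(np.mean(resid**2)) / pattern.A_hat**p)
    if len(ratios) < min_patterns:
        raise ValidationError(
            f"noise calibration needs >= {min_patterns} candidates with evidence, "
            f"got {len(ratios)}; pass the noise constant c explicitly"
        )
    c = float(np.median(ratios))
    if c <= 0.0:  # all residuals zero: fall back to a tiny positive floor
        c = 1e-12 * a_max**p
        logger.warning("zero calibrated noise variance; using floor c = %.3g", c)
    return c


def matching_score(
    pattern: CombinedPattern,
    theo: TheoreticalPattern,
    noise: NoiseModel,
    a_floor: float = 0.0,
    include_normalization: bool = False,
) -> float:
    """Gaussian log-likelihood of y_hat under the theoretical isotope pattern.

    sigma'^2 = c * max(A_hat, a_floor)^p.  By default the score is the
    quadratic misfit -sum_iso (y_hat - A_hat f)^2 / (2 sigma'^2): the
    log-likelihood up to a candidate-dependent additive constant, maximal
    (zero) at a perfect pattern match for any abundance.  The full
    log-density (``include_normalization=True``) adds
    -(n_iso/2) log(2 pi sigma'^2), which is monotone-equivalent for a fixed
    candidate but ranks *across* candidates by inverse abundance once
    residuals are small — see the methods note for why thresholding uses
    the quadratic form.  Candidates with no evidence (A_hat = 0) score -inf.
    """
    if pattern.A_hat < 0:
        raise ValidationError("A_hat must be non-negative")
    if pattern.A_hat == 0:
        return NO_EVIDENCE_SCORE
    sigma2 = noise.variance(pattern.A_hat, floor=a_floor)
    pattern.sigma2 = sigma2
    resid = pattern.y_hat - pattern.A_hat * theo.f_iso
    score = -float(np.dot(resid, resid)) / (2.0 * sigma2)
    if include_normalization:
        score -= 0.5 * pattern.y_hat.size * np.log(2.0 * np.pi * sigma2)
    return float(score)


def single_scan_score(
    grid: TraceGrid,
    theo: TheoreticalPattern,
    noise: NoiseModel,
    a_floor: float = 0.0,
) -> float:
    """Isotope matching score of the single-scan baseline pattern."""
    return matching_score(single_scan_pattern(grid), theo, noise, a_floor)


def icpd_pipeline(lcms_map: LCMSMap, params: DetectorParams = DetectorParams()) -> list[ScoredPeak]:
    """Run the full detector: candidates, trace grids, combining, scoring.

    Returns the OutList sorted by descending score.  Noise calibration uses
    the candidate population itself unless ``params.c`` is given.
    Thresholding is left to the caller.
    """
    mzlist = make_mzlist(lcms_map, dmz=params.dmz, s=params.s, g=params.g)
    masslist = expand_charge_states(mzlist, max_charge=params.max_charge)
    logger.info("candidates: %d m/z, %d mass hypotheses", len(mzlist), len(masslist))
    if not masslist:
        return []
    a_floor = lcms_map.min_positive_intensity()

    grids: list[TraceGrid] = []
    patterns: list[CombinedPattern] = []
    theos: list[TheoreticalPattern] = []
    for cand in masslist:
        grid = extract_trace_grid(
            lcms_map, cand, dmz=params.dmz, max_charge=params.max_charge, n_iso=params.n_iso
        )
        if params.score_mode == "single_scan":
            pattern = single_scan_pattern(grid)
        else:
            pattern = combine_observations(grid, estimate_elution_profile(grid))
        grids.append(grid)
        patterns.append(pattern)
        theos.append(theoretical_pattern(cand.mass, n_iso=params.n_iso))

    c = params.c
    if c is None:
        c = calibrate_noise_constant(patterns, theos, params.p)
        logger.info("calibrated noise constant c = %.4g (p = %d)", c, params.p)
    noise = NoiseModel(p=params.p, c=c)

    peaks = []
    for grid, pattern, theo in zip(grids, patterns, theos):
        score = matching_score(pattern, theo, noise, a_floor=a_floor)
        peaks.append(
            ScoredPeak(
                candidate=grid.candidate,
                score=score,
                volume=grid.volume,
                max_intensity=grid.max_intensity,
                pattern=pattern,
            )
        )
    peaks.sort(key=lambda pk: pk.score, reverse=True)
    return peaks


def outlist_to_frame(peaks: list[ScoredPeak]) -> pd.DataFrame:
    """OutList as a DataFrame with the standard columns."""
    return pd.DataFrame(
        [
            {
                "mass": pk.candidate.mass,
                "cs": pk.candidate.cs_hypothesis,
                "rt_start": pk.candidate.rt_start,
                "rt_end": pk.candidate.rt_end,
                "score": pk.score,
                "volume": pk.volume,
                "max_intensity": pk.max_intensity,
            }
            for pk in peaks
        ],
        columns=OUTLIST_COLUMNS,
    )


def write_outlist(peaks: list[ScoredPeak] | pd.DataFrame, path: str | Path) -> None:
    df = peaks if isinstance(peaks, pd.DataFrame) else outlist_to_frame(peaks)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_outlist(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in OUTLIST_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"outlist {path} missing columns {missing}")
    return df
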