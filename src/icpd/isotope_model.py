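"""Theoretical isotope distributions and m/z arithmetic.

A tryptic peptide of neutral monoisotopic mass ``M`` observed at charge state
``cs`` registers a ladder of isotopologue peaks at

    MZ(M, cs, iso) = (M + cs * w_p + iso * w_n) / cs

where ``iso`` counts heavy-isotope substitutions (dominated by C13), ``w_p``
is the proton mass and ``w_n`` the C13-C12 mass spacing.  The relative
intensities of the ladder, the isotope pattern ``f(iso)``, are predicted from
mass alone through the averagine model: the expected carbon count scales
linearly with mass, and the number of C13 atoms is Poisson distributed with
rate (expected carbons) x (natural C13 abundance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import poisson

__all__ = [
    "ValidationError",
    "PhysicalConstants",
    "CONSTANTS",
    "TheoreticalPattern",
    "averagine_carbons",
    "theoretical_pattern",
    "mz_of",
    "ppm_window",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition or invariant."""


@dataclass(frozen=True)
class PhysicalConstants:
    """Masses and composition constants used throughout the detector.

    ``isotope_spacing`` is the C13-C12 mass difference (1.003355 Da), the
    spacing a high-resolution instrument actually observes between
    isotopologue peaks, not the free-neutron mass.
    """

    proton_mass: float = 1.007276  # Da
    isotope_spacing: float = 1.003355  # Da, C13 - C12
    c13_abundance: float = 0.0107
    averagine_unit_mass: float = 111.1254  # Da
    averagine_carbons_per_unit: float = 4.9384

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if not value > 0:
                raise ValidationError(f"constant {name!r} must be positive")


CONSTANTS = PhysicalConstants()


@dataclass(frozen=True)
class TheoreticalPattern:
    """Averagine isotope pattern ``f(iso)`` for one neutral mass.

    ``f_iso[k]`` is the fraction of the peptide population carrying ``k``
    heavy substitutions, truncated to the first ``n_iso`` positions and
    renormalized to sum to one.
    """

    f_iso: np.ndarray
    mass: float

    def __post_init__(self) -> None:
        f = np.asarray(self.f_iso, dtype=float)
        object.__setattr__(self, "f_iso", f)
        if f.ndim != 1 or f.size < 1:
            raise ValidationError("f_iso must be a non-empty 1-D vector")
        if np.any(f < 0) or not np.isclose(f.sum(), 1.0, atol=1e-9):
            raise ValidationError("f_iso must be non-negative and sum to 1")
        if not f[0] > 0:
            raise ValidationError("monoisotopic fraction f_iso[0] must be positive")

    @property
    def n_iso(self) -> int:
        return self.f_iso.size


def averagine_carbons(mass: float, constants: PhysicalConstants = CONSTANTS) -> float:
    """Expected carbon count of a peptide of the given neutral mass (Da)."""
    if not mass > 0:
        raise ValidationError(f"mass must be positive, got {mass}")
    return constants.averagine_carbons_per_unit * mass / constants.averagine_unit_mass


def theoretical_pattern(
    mass: float, n_iso: int = 5, constants: PhysicalConstants = CONSTANTS
) -> TheoreticalPattern:
    """Poisson-averagine isotope pattern, truncated and renormalized.

    The C13 count is modelled as Poisson with rate
    lambda = averagine_carbons(mass) * c13_abundance; contributions of other
    elements (N, O, S, H) to the pattern are neglected, which underweights
    the heavy isotopologues by a few percent (see the methods note).
    """
    if not mass > 0:
        raise ValidationError(f"mass must be positive, got {mass}")
    if int(n_iso) != n_iso or n_iso < 1:
        raise ValidationError(f"n_iso must be a positive integer, got {n_iso}")
    lam = averagine_carbons(mass, constants) * constants.c13_abundance
    f = poisson.pmf(np.arange(int(n_iso)), lam)
    return TheoreticalPattern(f_iso=f / f.sum(), mass=float(mass))


def mz_of(
    mass: float, cs: int, iso: int, constants: PhysicalConstants = CONSTANTS
) -> float:
    """m/z (Th) of the ``iso``-th isotopologue at charge state ``cs``."""
    if not mass > 0:
        raise ValidationError(f"mass must be positive, got {mass}")
    if cs < 1:
        raise ValidationError(f"charge state must be >= 1, got {cs}")
    if iso < 0:
        raise ValidationError(f"isotope position must be >= 0, got {iso}")
    return (mass + cs * constants.proton_mass + iso * constants.isotope_spacing) / cs


def mz_grid(
    mass: float, max_charge: int, n_iso: int, constants: PhysicalConstants = CONSTANTS
) -> np.ndarray:
    """Matrix of m/z targets, shape (max_charge, n_iso), row cs-1, column iso."""
    cs = np.arange(1, max_charge + 1, dtype=float)[:, None]
    iso = np.arange(n_iso, dtype=float)[None, :]
    if not mass > 0:
        raise ValidationError(f"mass must be positive, got {mass}")
    return (mass + cs * constants.proton_mass + iso * constants.isotope_spacing) / cs


def ppm_window(mz: float, dmz: float) -> tuple[float, float]:
    """Half-open mass-accuracy window [lo, hi) of +-``dmz`` ppm around ``mz``."""
    if not mz > 0:
        raise ValidationError(f"mz must be positive, got {mz}")
    if not dmz > 0:
        raise ValidationError(f"dmz must be positive, got {dmz}")
    return mz * (1.0 - dmz * 1e-6), mz * (1.0 + dmz * 1e-6)
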