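"""Independent test oracles, kept free of the package's model code.

The elemental-convolution oracle computes the isotope distribution of the
rounded averagine formula exactly, by convolving the isotope distributions
of each element's atoms (binomial/multinomial over nominal mass shifts).
It is deliberately *not* a Poisson model, so it can judge the package's
Poisson approximation.
"""

from __future__ import annotations

import numpy as np

# averagine: atoms per 111.1254 Da of peptide mass
AVERAGINE_UNIT = {"C": 4.9384, "H": 7.7583, "N": 1.3577, "O": 1.4773, "S": 0.0417}
AVERAGINE_UNIT_MASS = 111.1254

# natural isotope abundances by nominal mass shift (IUPAC 2013 rounding)
ISOTOPES = {
    "C": [0.9893, 0.0107],
    "H": [0.999885, 0.000115],
    "N": [0.99636, 0.00364],
    "O": [0.99757, 0.00038, 0.00205],
    "S": [0.9499, 0.0075, 0.0425, 0.0, 0.0001],
}


def _power_convolve(dist: np.ndarray, n: int, max_len: int = 64) -> np.ndarray:
    """Distribution of the sum of n i.i.d. draws, by binary exponentiation."""
    acc = np.array([1.0])
    base = np.asarray(dist, dtype=float)
    while n:
        if n & 1:
            acc = np.convolve(acc, base)[:max_len]
        base = np.convolve(base, base)[:max_len]
        n >>= 1
    return acc


def elemental_pattern(mass: float, n_iso: int = 5) -> np.ndarray:
    """Exact isotope pattern of the rounded averagine formula at this mass."""
    dist = np.array([1.0])
    for element, per_unit in AVERAGINE_UNIT.items():
        n_atoms = int(round(per_unit * mass / AVERAGINE_UNIT_MASS))
        dist = np.convolve(dist, _power_convolve(ISOTOPES[element], n_atoms))[:64]
    head = dist[:n_iso]
    return head / head.sum()


def total_variation(p: np.ndarray, q: np.ndarray) -> float:
    return 0.5 * float(np.abs(np.asarray(p) - np.asarray(q)).sum())
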