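"""Ground-truth LC/MS simulator.

Emulates the generative model the detector assumes: each peptide of total
abundance A disperses over charge states (distribution f(cs)), isotope
positions (averagine pattern f(iso)) and elution time (profile C(t), which
need not be Gaussian), so the expected centroid intensity in scan t at the
(cs, iso) m/z position is mu = A * C(t) * f(cs) * f(iso).  Each emitted
cell receives zero-mean Gaussian noise of variance c * mu^p + baseline_var:
the power law acts on each peak's own expected intensity, the way shot and
detector noise do, so the noise summed over a peptide's cells again scales
as a power of its total abundance A.  Negative results are clamped to zero
and zero/sub-threshold intensities are omitted (centroided data carries no
explicit zeros).  Each emitted centroid
m/z is jittered by a Gaussian ppm error to exercise the detector's
mass-accuracy windows.  Non-peptide contaminants lacking averagine-like
isotope structure (single spikes, wrong-spacing doublets, flat multiplets)
are added as decoys.

Per-cell SNR of a peptide is defined as its largest expected cell intensity
(apex scan, dominant charge, monoisotopic position) divided by the noise
standard deviation of its cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import exponnorm, norm

from .isotope_model import ValidationError, mz_of, theoretical_pattern

__all__ = [
    "SimPeptide",
    "Contaminant",
    "SimConfig",
    "GroundTruth",
    "sample_elution",
    "simulate_map",
    "make_benchmark",
    "make_snr_benchmark",
    "write_truth",
    "read_truth",
]

ELUTION_SHAPES = ("gaussian", "exp-mod-gaussian", "asymmetric-triangle", "plateau")
TRUTH_COLUMNS = ["mass", "rt_start", "rt_end", "abundance", "cs_dist"]


@dataclass(frozen=True)
class SimPeptide:
    """One simulated peptide: mass, abundance, charge dispersion, elution."""

    mass: float
    abundance: float
    cs_dist: tuple[float, ...]  # fractions over charge states 1..len(cs_dist)
    shape: str = "gaussian"
    apex: int = 10
    width: float = 4.0
    n_iso: int = 5
    tier: str | None = None

    def __post_init__(self) -> None:
        if not self.mass > 0 or not self.abundance > 0:
            raise ValidationError("mass and abundance must be positive")
        if not np.isclose(sum(self.cs_dist), 1.0, atol=1e-9) or min(self.cs_dist) < 0:
            raise ValidationError("cs_dist must be non-negative and sum to 1")
        if self.width < 1:
            raise ValidationError("elution width must be >= 1 scan")


@dataclass(frozen=True)
class Contaminant:
    """A non-peptide decoy trace without averagine isotope structure.

    kinds: ``single-spike`` (one lone m/z trace), ``wrong-spacing-doublet``
    (partner peak at a spacing no charge state explains), ``flat-multiplet``
    (four equal-intensity peaks at 1 Th spacing, a flat non-averagine
    pattern).
    """

    kind: str
    mz: float
    intensity: float  # apex cell intensity
    apex: int = 10
    width: float = 4.0
    shape: str = "gaussian"

    KINDS = ("single-spike", "wrong-spacing-doublet", "flat-multiplet")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValidationError(f"unknown contaminant kind {self.kind!r}")
        if not self.mz > 0 or not self.intensity > 0:
            raise ValidationError("contaminant mz and intensity must be positive")


@dataclass
class SimConfig:
    """Full description of one simulated run (seed fixed => identical map)."""

    n_scans: int
    peptides: list[SimPeptide]
    contaminants: list[Contaminant] = field(default_factory=list)
    scan_interval: float = 1.0
    noise_c: float = 0.0
    noise_p: int = 1
    baseline_var: float = 0.0
    mz_jitter_ppm: float = 0.0
    drop_threshold: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_scans < 1:
            raise ValidationError("n_scans must be >= 1")
        if self.noise_c < 0 or self.baseline_var < 0 or self.mz_jitter_ppm < 0:
            raise ValidationError("noise parameters must be non-negative")


@dataclass
class GroundTruth:
    """Truth tables: one row per simulated peptide, plus contaminant locations."""

    peptides: pd.DataFrame
    contaminants: pd.DataFrame


def sample_elution(shape: str, apex: int, width: float, n_scans: int) -> np.ndarray:
    """Discretized elution profile C(t): non-negative, sums to one.

    ``width`` is the full width at half maximum in scans for the peaked
    shapes and the plateau length for ``plateau``.
    """
    if shape not in ELUTION_SHAPES:
        raise ValidationError(f"unknown elution shape {shape!r}; choose from {ELUTION_SHAPES}")
    if width < 1:
        raise ValidationError("width must be >= 1 scan")
    if not 0 <= apex < n_scans:
        raise ValidationError("apex must lie inside the scan range")
    t = np.arange(n_scans, dtype=float)
    if shape == "gaussian":
        sigma = width / 2.3548200450309493  # FWHM -> sigma
        c = norm.pdf(t, loc=apex, scale=sigma)
    elif shape == "exp-mod-gaussian":
        sigma = width / 2.3548200450309493
        c = exponnorm.pdf(t, K=2.0, loc=apex, scale=sigma)  # tailing peak
    elif shape == "asymmetric-triangle":
        rise, fall = 0.8 * width, 1.2 * width
        c = np.where(
            t <= apex,
            np.clip(1.0 - (apex - t) / rise, 0.0, None),
            np.clip(1.0 - (t - apex) / fall, 0.0, None),
        )
    else:  # plateau
        start = max(apex - int(width) // 2, 0)
        c = np.zeros(n_scans)
        c[start : min(start + int(width), n_scans)] = 1.0
    # finite support: a detector emits no centroid where no ion signal is;
    # renormalization keeps the profile (and hence total abundance) exact
    c[c < 1e-3 * c.max()] = 0.0
    total = c.sum()
    if total <= 0:
        raise ValidationError("elution profile has no support inside the scan range")
    return c / total


def _emit(
    cells: dict[int, list[tuple[float, float]]],
    scan: int,
    mz: float,
    mean: float,
    sigma: float,
    jitter_ppm: float,
    drop: float,
    rng: np.random.Generator,
) -> None:
    value = mean + (rng.normal(0.0, sigma) if sigma > 0 else 0.0)
    if jitter_ppm > 0:
        mz = mz * (1.0 + rng.normal(0.0, jitter_ppm) * 1e-6)
    value = max(value, 0.0)  # detectors emit non-negative centroids
    if value <= drop or value <= 0:
        return
    cells.setdefault(scan, []).append((mz, value))


def _cell_sigma(mu: float, config: SimConfig) -> float:
    """Noise standard deviation of one cell with expected intensity mu."""
    return float(np.sqrt(config.noise_c * mu**config.noise_p + config.baseline_var))


def simulate_map(config: SimConfig):
    """Generate an LC/MS map and its ground truth from a simulation config.

    Returns ``(LCMSMap, GroundTruth)``.  m/z collisions between species are
    allowed (realistic) and resolved by summing intensities of exactly
    coincident centroids.
    """
    from .spectra_io import CentroidScan, LCMSMap

    rng = np.random.default_rng(config.seed)
    cells: dict[int, list[tuple[float, float]]] = {}
    truth_rows = []
    for pep in config.peptides:
        C = sample_elution(pep.shape, pep.apex, pep.width, config.n_scans)
        support = np.flatnonzero(C)
        f_iso = theoretical_pattern(pep.mass, n_iso=pep.n_iso).f_iso
        for t in support:
            for cs0, f_cs in enumerate(pep.cs_dist):
                if f_cs <= 0:
                    continue
                for iso in range(pep.n_iso):
                    mu = pep.abundance * C[t] * f_cs * f_iso[iso]
                    _emit(
                        cells,
                        int(t),
                        mz_of(pep.mass, cs0 + 1, iso),
                        mu,
                        _cell_sigma(mu, config),
                        config.mz_jitter_ppm,
                        config.drop_threshold,
                        rng,
                    )
        truth_rows.append(
            {
                "mass": pep.mass,
                "rt_start": int(support[0]),
                "rt_end": int(support[-1]),
                "abundance": pep.abundance,
                "cs_dist": ",".join(f"{v:g}" for v in pep.cs_dist),
                "tier": pep.tier if pep.tier is not None else "",
            }
        )

    contam_rows = []
    for con in config.contaminants:
        C = sample_elution(con.shape, con.apex, con.width, config.n_scans)
        support = np.flatnonzero(C)
        scale = con.intensity / C.max()
        if con.kind == "single-spike":
            partners = [(con.mz, 1.0)]
        elif con.kind == "wrong-spacing-doublet":
            partners = [(con.mz, 1.0), (con.mz + 0.68, 0.8)]  # no charge explains 0.68 Th
        else:  # flat-multiplet
            partners = [(con.mz + k * 1.0, 1.0) for k in range(4)]
        for t in support:
            for mz, rel in partners:
                mu = scale * C[t] * rel
                _emit(
                    cells, int(t), mz, mu, _cell_sigma(mu, config),
                    config.mz_jitter_ppm, config.drop_threshold, rng,
                )
        contam_rows.append(
            {
                "kind": con.kind,
                "mz": con.mz,
                "rt_start": int(support[0]),
                "rt_end": int(support[-1]),
                "intensity": con.intensity,
            }
        )

    scans = []
    for t in range(config.n_scans):
        if t not in cells:  # scans with no signal stay in the map, empty
            scans.append(
                CentroidScan(rt=t * config.scan_interval, mz=np.array([]), intensity=np.array([]))
            )
            continue
        mz, inten = np.array(cells[t]).T
        uniq, inverse = np.unique(mz, return_inverse=True)
        summed = np.zeros_like(uniq)
        np.add.at(summed, inverse, inten)
        scans.append(
            CentroidScan(rt=t * config.scan_interval, mz=uniq, intensity=summed)
        )
    truth = GroundTruth(
        peptides=pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS + ["tier"]),
        contaminants=pd.DataFrame(
            contam_rows, columns=["kind", "mz", "rt_start", "rt_end", "intensity"]
        ),
    )
    return LCMSMap(scans=scans, scan_interval=config.scan_interval), truth


# ---------------------------------------------------------------------------
# Benchmark presets
# ---------------------------------------------------------------------------

def _apex_fraction(shape: str, apex: int, width: float, n_scans: int) -> float:
    return float(sample_elution(shape, apex, width, n_scans).max())


def _random_cs_dist(rng: np.random.Generator, max_charge: int = 4) -> tuple[float, ...]:
    main = int(rng.integers(1, 4))
    dist = [0.0] * max_charge
    share = float(rng.uniform(0.6, 1.0))
    dist[main - 1] = share
    neighbor = main + 1 if main < max_charge else main - 1
    dist[neighbor - 1] = 1.0 - share
    return tuple(dist)


def make_snr_benchmark(
    n_peptides: int,
    snr: float | list[float],
    n_contaminants: int,
    seed: int = 0,
    n_scans: int = 400,
    noise_p: int = 1,
    noise_c: float = 1.0,
) -> SimConfig:
    """Peptides placed at exact per-cell SNR targets plus contaminant decoys.

    The per-cell SNR of a peptide is its apex cell (apex scan, dominant
    charge, monoisotopic position) expected intensity mu over that cell's
    noise standard deviation sqrt(c * mu^p).  With p = 1 (Poisson-like
    counting noise, the default) this gives mu = c * snr^2 and the
    abundance A = mu / k, where k is the apex cell's fraction of A.
    Contaminant apex intensities are drawn to match the peptide apex
    intensity range, so intensity alone cannot separate them.
    """
    rng = np.random.default_rng(seed)
    snrs = list(np.atleast_1d(np.asarray(snr, dtype=float)))
    peptides = []
    apex_intensities = []
    for i in range(n_peptides):
        target = snrs[i % len(snrs)]
        shape = ELUTION_SHAPES[int(rng.integers(len(ELUTION_SHAPES)))]
        width = float(rng.uniform(3.0, 7.0))
        apex = int(rng.integers(12, n_scans - 12))
        cs_dist = _random_cs_dist(rng)
        mass = float(rng.uniform(800.0, 2400.0))
        f0 = theoretical_pattern(mass).f_iso[0]
        k = _apex_fraction(shape, apex, width, n_scans) * max(cs_dist) * f0
        if noise_p == 2:
            raise ValidationError("p = 2 gives scale-free SNR; target SNR is unattainable")
        apex_mu = float((target * np.sqrt(noise_c)) ** (1.0 / (1.0 - noise_p / 2.0)))
        abundance = apex_mu / k
        peptides.append(
            SimPeptide(
                mass=mass, abundance=abundance, cs_dist=cs_dist, shape=shape,
                apex=apex, width=width, tier=f"snr{target:g}",
            )
        )
        apex_intensities.append(apex_mu)
    contaminants = []
    lo, hi = (min(apex_intensities), max(apex_intensities)) if apex_intensities else (1e3, 1e4)
    for i in range(n_contaminants):
        contaminants.append(
            Contaminant(
                kind=Contaminant.KINDS[i % 3],
                mz=float(rng.uniform(350.0, 1600.0)),
                intensity=float(rng.uniform(lo, hi)),
                apex=int(rng.integers(12, n_scans - 12)),
                width=float(rng.uniform(3.0, 7.0)),
                shape=ELUTION_SHAPES[int(rng.integers(len(ELUTION_SHAPES)))],
            )
        )
    return SimConfig(
        n_scans=n_scans, peptides=peptides, contaminants=contaminants,
        noise_c=noise_c, noise_p=noise_p, mz_jitter_ppm=10.0 / 3.0, seed=seed + 1,
    )


def make_benchmark(preset: str, seed: int = 0):
    """Deterministic benchmark maps: noise_free, low_snr_sweep, dynamic_range.

    * ``noise_free``: 20 peptides spanning 800-2320 Da with varied charge
      dispersions and elution shapes, no noise of any kind — exactness and
      end-to-end recovery checks.
    * ``low_snr_sweep``: 15 peptides per per-cell SNR tier {2, 5, 10, 20}
      plus 60 matched-intensity contaminants, counting-statistics noise.
    * ``dynamic_range``: 40 peptides log-spaced over 4 orders of magnitude
      of abundance over a fixed additive noise floor (the desk-scale
      analogue of a high-dynamic-range protein standard), plus 40
      contaminants.
    """
    if preset == "noise_free":
        shapes = list(ELUTION_SHAPES)
        cs_dists = [
            (0.0, 1.0, 0.0, 0.0),
            (0.0, 0.5, 0.5, 0.0),
            (1.0, 0.0, 0.0, 0.0),
            (0.3, 0.4, 0.3, 0.0),
        ]
        peptides = [
            SimPeptide(
                mass=800.0 + 80.0 * i,
                abundance=1e6,
                cs_dist=cs_dists[i % 4],
                shape=shapes[i % 4],
                apex=15 + 10 * i,
                width=4.0 + (i % 3),
            )
            for i in range(20)
        ]
        config = SimConfig(n_scans=240, peptides=peptides, seed=seed)
    elif preset == "low_snr_sweep":
        config = make_snr_benchmark(
            n_peptides=60, snr=[2.0, 5.0, 10.0, 20.0], n_contaminants=60,
            seed=seed, n_scans=300,
        )
    elif preset == "dynamic_range":
        rng = np.random.default_rng(seed)
        abundances = np.logspace(3.5, 7.5, 40)
        peptides = []
        for i, a in enumerate(abundances):
            peptides.append(
                SimPeptide(
                    mass=float(rng.uniform(800.0, 2400.0)),
                    abundance=float(a),
                    cs_dist=_random_cs_dist(rng),
                    shape=ELUTION_SHAPES[i % 4],
                    apex=int(rng.integers(12, 288)),
                    width=float(rng.uniform(3.0, 7.0)),
                    tier=f"decade{i // 10}",
                )
            )
        contaminants = [
            Contaminant(
                kind=Contaminant.KINDS[i % 3],
                mz=float(rng.uniform(350.0, 1600.0)),
                intensity=float(rng.uniform(1e2, 1e5)),
                apex=int(rng.integers(12, 288)),
                width=float(rng.uniform(3.0, 7.0)),
            )
            for i in range(40)
        ]
        config = SimConfig(
            n_scans=300, peptides=peptides, contaminants=contaminants,
            baseline_var=300.0**2, mz_jitter_ppm=10.0 / 3.0, seed=seed + 1,
        )
    else:
        raise ValidationError(
            f"unknown preset {preset!r}; choose noise_free, low_snr_sweep or dynamic_range"
        )
    return simulate_map(config)


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    """Write the peptide truth table; contaminants go to ``<stem>.contaminants.tsv``."""
    path = Path(path)
    truth.peptides.to_csv(path, sep="\t", index=False, float_format="%.10g")
    side = path.with_suffix(".contaminants.tsv")
    truth.contaminants.to_csv(side, sep="\t", index=False, float_format="%.10g")


def read_truth(path: str | Path) -> GroundTruth:
    path = Path(path)
    peptides = pd.read_csv(path, sep="\t")
    missing = [c for c in TRUTH_COLUMNS if c not in peptides.columns]
    if missing:
        raise ValidationError(f"truth table {path} missing columns {missing}")
    side = path.with_suffix(".contaminants.tsv")
    contaminants = (
        pd.read_csv(side, sep="\t")
        if side.exists()
        else pd.DataFrame(columns=["kind", "mz", "rt_start", "rt_end", "intensity"])
    )
    return GroundTruth(peptides=peptides, contaminants=contaminants)
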