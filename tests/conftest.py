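import numpy as np
import pytest

import icpd


def toy_map(scan_peaks, scan_interval=1.0):
    """Build an LCMSMap from a list of per-scan [(mz, intensity), ...] lists."""
    scans = []
    for t, peaks in enumerate(scan_peaks):
        peaks = sorted(peaks)
        scans.append(
            icpd.CentroidScan(
                rt=t * scan_interval,
                mz=np.array([p[0] for p in peaks]),
                intensity=np.array([p[1] for p in peaks]),
            )
        )
    return icpd.LCMSMap(scans=scans, scan_interval=scan_interval)


@pytest.fixture(scope="session")
def noise_free_run():
    """Noise-free benchmark map, its truth and the detector's OutList."""
    lcms_map, truth = icpd.make_benchmark("noise_free", seed=1)
    peaks = icpd.icpd_pipeline(lcms_map, icpd.DetectorParams())
    return lcms_map, truth, peaks


@pytest.fixture(scope="session")
def single_peptide_map():
    """One noise-free peptide at charge 2, Gaussian elution, with its truth."""
    config = icpd.SimConfig(
        n_scans=40,
        peptides=[
            icpd.SimPeptide(
                mass=1200.0, abundance=1e6, cs_dist=(0.0, 1.0, 0.0, 0.0),
                shape="gaussian", apex=20, width=5.0,
            )
        ],
        seed=3,
    )
    return icpd.simulate_map(config)
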