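"""Trace extraction, information combining, noise calibration and scoring."""

import numpy as np
import pytest

import icpd
from icpd.icpd_core import NO_EVIDENCE_SCORE

from conftest import toy_map


def truth_candidate(row, cs=1):
    return icpd.PeptideCandidate(
        mass=float(row["mass"]), cs_hypothesis=cs,
        rt_start=int(row["rt_start"]), rt_end=int(row["rt_end"]),
        source_mz=icpd.mz_of(float(row["mass"]), cs, 0),
    )


def model_grid(mass, A, C, cs_dist, n_iso=5, max_charge=4):
    """Noise-free grid built directly from the generative model."""
    f = icpd.theoretical_pattern(mass, n_iso=n_iso).f_iso
    y = (
        A
        * np.asarray(C)[:, None, None]
        * np.asarray(cs_dist)[None, :max_charge, None]
        * f[None, None, :]
    )
    cand = icpd.PeptideCandidate(
        mass=mass, cs_hypothesis=1, rt_start=0, rt_end=len(C) - 1, source_mz=mass
    )
    return icpd.TraceGrid(candidate=cand, y=y), f


class TestExtractTraceGrid:
    def test_noise_free_peptide_matches_model(self, single_peptide_map):
        lcms_map, truth = single_peptide_map
        row = truth.peptides.iloc[0]
        grid = icpd.extract_trace_grid(lcms_map, truth_candidate(row))
        f = icpd.theoretical_pattern(row["mass"]).f_iso
        C = icpd.sample_elution("gaussian", 20, 5.0, 40)
        window = slice(int(row["rt_start"]), int(row["rt_end"]) + 1)
        # only the true charge column is populated, proportional to C(t) f(iso)
        assert grid.y[:, [0, 2, 3], :].sum() == 0
        np.testing.assert_allclose(
            grid.y[:, 1, :], 1e6 * np.outer(C[window], f), rtol=1e-9
        )

    def test_empty_region_gives_zero_grid(self):
        lcms_map = toy_map([[(500.0, 1.0)]] * 5)
        cand = icpd.PeptideCandidate(
            mass=2000.0, cs_hypothesis=2, rt_start=1, rt_end=3, source_mz=1001.007276
        )
        assert icpd.extract_trace_grid(lcms_map, cand).y.sum() == 0

    def test_two_centroids_in_one_window_summed(self):
        mz0 = icpd.mz_of(1000.0, 1, 0)
        lcms_map = toy_map([[(mz0 * (1 - 3e-6), 2.0), (mz0 * (1 + 3e-6), 3.0)]])
        cand = icpd.PeptideCandidate(
            mass=1000.0, cs_hypothesis=1, rt_start=0, rt_end=0, source_mz=mz0
        )
        grid = icpd.extract_trace_grid(lcms_map, cand, dmz=10.0)
        assert grid.y[0, 0, 0] == pytest.approx(5.0)

    def test_window_outside_map_rejected(self):
        lcms_map = toy_map([[(500.0, 1.0)]] * 3)
        cand = icpd.PeptideCandidate(
            mass=1000.0, cs_hypothesis=1, rt_start=1, rt_end=5, source_mz=1001.0
        )
        with pytest.raises(icpd.ValidationError):
            icpd.extract_trace_grid(lcms_map, cand)


class TestElutionProfileAndCombining:
    def test_noise_free_profile_and_combination_exact(self):
        C = icpd.sample_elution("asymmetric-triangle", 10, 5.0, 25)
        C = C[C > 0]
        grid, f = model_grid(1400.0, 2e5, C, (0.0, 0.7, 0.3, 0.0))
        prof = icpd.estimate_elution_profile(grid)
        np.testing.assert_allclose(prof.C, C, rtol=1e-9)
        pattern = icpd.combine_observations(grid, prof)
        np.testing.assert_allclose(pattern.y_hat, 2e5 * f, rtol=1e-9)
        assert pattern.A_hat == pytest.approx(2e5, rel=1e-9)

    def test_all_zero_grid_flagged_empty(self):
        cand = icpd.PeptideCandidate(
            mass=1000.0, cs_hypothesis=1, rt_start=0, rt_end=4, source_mz=1001.0
        )
        grid = icpd.TraceGrid(candidate=cand, y=np.zeros((5, 4, 5)))
        prof = icpd.estimate_elution_profile(grid)
        assert prof.empty
        pattern = icpd.combine_observations(grid, prof)
        assert pattern.A_hat == 0.0 and np.all(pattern.y_hat == 0)

    def test_profile_estimate_close_to_truth_under_noise(self):
        # median L1 error over replicates stays small at per-cell SNR 10
        rng = np.random.default_rng(5)
        C = icpd.sample_elution("gaussian", 12, 5.0, 25)
        C = C[C > 0]
        grid0, f = model_grid(1400.0, 2e5, C, (0.0, 1.0, 0.0, 0.0))
        sig = grid0.y / 10.0
        errors = []
        for _ in range(300):
            y = np.clip(grid0.y + rng.normal(0.0, 1.0, grid0.y.shape) * sig, 0, None)
            noisy = icpd.TraceGrid(candidate=grid0.candidate, y=y)
            est = icpd.estimate_elution_profile(noisy).C
            errors.append(np.abs(est - C).sum())
        assert np.median(errors) < 0.1

    def test_combined_pattern_estimate_less_noisy_than_single_scan(self):
        # pooling >= 2 scans reduces the variance of the *normalized* isotope
        # pattern estimate y_hat / sum(y_hat); the raw combined vector uses
        # the whole signal, the single-scan one only a fraction of it
        rng = np.random.default_rng(6)
        C = np.full(4, 0.25)
        grid0, f = model_grid(1200.0, 1e5, C, (1.0, 0.0, 0.0, 0.0))
        sigma = 300.0
        combined, single = [], []
        for _ in range(500):
            noise = rng.normal(0.0, sigma, grid0.y.shape)
            noise[grid0.y == 0] = 0.0
            y = np.clip(grid0.y + noise, 0, None)
            noisy = icpd.TraceGrid(candidate=grid0.candidate, y=y)
            yc = icpd.combine_observations(noisy, icpd.ElutionProfile(C=C)).y_hat
            ys = icpd.single_scan_pattern(noisy).y_hat
            combined.append(yc / yc.sum())
            single.append(ys / ys.sum())
        v_comb = np.var(combined, axis=0)
        v_single = np.var(single, axis=0)
        assert np.all(v_comb < v_single)


class TestNoiseCalibration:
    def test_recovers_known_constant_within_factor_two(self):
        rng = np.random.default_rng(7)
        c0, p = 2.5e-3, 2
        patterns, theos = [], []
        for _ in range(200):
            mass = rng.uniform(800, 2000)
            theo = icpd.theoretical_pattern(mass)
            A = rng.uniform(1e4, 1e5)
            y_hat = A * theo.f_iso + rng.normal(0, np.sqrt(c0 * A**p), 5)
            patterns.append(
                icpd.CombinedPattern(y_hat=y_hat, A_hat=float(y_hat.sum()), n_obs=20)
            )
            theos.append(theo)
        c = icpd.calibrate_noise_constant(patterns, theos, p)
        assert c0 / 2 < c < c0 * 2

    def test_scale_invariance_at_p2(self):
        # doubling all intensities leaves c invariant when p = 2
        rng = np.random.default_rng(8)
        theo = icpd.theoretical_pattern(1500.0)
        base = []
        for _ in range(50):
            A = rng.uniform(1e4, 1e5)
            y_hat = A * theo.f_iso + rng.normal(0, 0.03 * A, 5)
            base.append((y_hat, A))
        def calib(scale):
            pats = [
                icpd.CombinedPattern(y_hat=scale * y, A_hat=scale * float(y.sum()), n_obs=1)
                for y, _ in base
            ]
            return icpd.calibrate_noise_constant(pats, [theo] * len(pats), p=2)
        assert calib(2.0) == pytest.approx(calib(1.0), rel=1e-9)

    def test_too_few_patterns_rejected(self):
        theo = icpd.theoretical_pattern(1000.0)
        pats = [icpd.CombinedPattern(y_hat=theo.f_iso, A_hat=1.0, n_obs=1)] * 3
        with pytest.raises(icpd.ValidationError, match="c explicitly"):
            icpd.calibrate_noise_constant(pats, [theo] * 3, p=1)

    def test_zero_residuals_fall_back_to_floor(self):
        theo = icpd.theoretical_pattern(1000.0)
        pats = [
            icpd.CombinedPattern(y_hat=100.0 * theo.f_iso, A_hat=100.0, n_obs=1)
            for _ in range(12)
        ]
        c = icpd.calibrate_noise_constant(pats, [theo] * 12, p=3)
        assert c == pytest.approx(1e-12 * 100.0**3)


class TestMatchingScore:
    def test_perfect_match_is_maximum(self):
        theo = icpd.theoretical_pattern(1500.0)
        noise = icpd.NoiseModel(p=1, c=1.0)
        perfect = icpd.CombinedPattern(y_hat=1e4 * theo.f_iso, A_hat=1e4, n_obs=1)
        assert icpd.matching_score(perfect, theo, noise) == pytest.approx(0.0)
        full = icpd.matching_score(perfect, theo, noise, include_normalization=True)
        assert full == pytest.approx(-2.5 * np.log(2 * np.pi * 1e4))

    def test_score_decreases_away_from_match(self):
        theo = icpd.theoretical_pattern(1500.0)
        noise = icpd.NoiseModel(p=1, c=1.0)
        direction = np.array([1.0, -1.0, 0.5, 0.0, -0.5])
        scores = []
        for eps in (0.0, 50.0, 100.0, 200.0):
            y = 1e4 * theo.f_iso + eps * direction
            pat = icpd.CombinedPattern(y_hat=y, A_hat=1e4, n_obs=1)
            scores.append(icpd.matching_score(pat, theo, noise))
        assert np.all(np.diff(scores) < 0)

    def test_averagine_shape_beats_flat_shape(self):
        theo = icpd.theoretical_pattern(1500.0)
        noise = icpd.NoiseModel(p=1, c=1.0)
        a = icpd.CombinedPattern(y_hat=1e4 * theo.f_iso, A_hat=1e4, n_obs=1)
        flat = icpd.CombinedPattern(y_hat=np.full(5, 2e3), A_hat=1e4, n_obs=1)
        assert icpd.matching_score(a, theo, noise) > icpd.matching_score(flat, theo, noise)

    def test_no_evidence_scores_minus_infinity(self):
        theo = icpd.theoretical_pattern(1000.0)
        noise = icpd.NoiseModel(p=3, c=1.0)
        empty = icpd.CombinedPattern(y_hat=np.zeros(5), A_hat=0.0, n_obs=1)
        assert icpd.matching_score(empty, theo, noise) == NO_EVIDENCE_SCORE


class TestSingleScanBaseline:
    def test_one_scan_peptide_gives_same_pattern_vector(self):
        C = np.array([1.0])
        grid, f = model_grid(1300.0, 5e4, C, (0.0, 1.0, 0.0, 0.0))
        combined = icpd.combine_observations(grid, icpd.ElutionProfile(C=C))
        single = icpd.single_scan_pattern(grid)
        np.testing.assert_allclose(single.y_hat, combined.y_hat, rtol=1e-12)
        # conventions differ only in the abundance estimate
        assert single.A_hat == pytest.approx(5e4 * f[0], rel=1e-9)
        assert combined.A_hat == pytest.approx(5e4, rel=1e-9)

    def test_all_zero_grid_minus_infinity(self):
        cand = icpd.PeptideCandidate(
            mass=1000.0, cs_hypothesis=1, rt_start=0, rt_end=2, source_mz=1001.0
        )
        grid = icpd.TraceGrid(candidate=cand, y=np.zeros((3, 4, 5)))
        theo = icpd.theoretical_pattern(1000.0)
        assert icpd.single_scan_score(grid, theo, icpd.NoiseModel(p=1, c=1.0)) == NO_EVIDENCE_SCORE


class TestPipeline:
    def test_empty_map_empty_outlist(self):
        assert icpd.icpd_pipeline(icpd.LCMSMap(scans=[])) == []

    def test_noise_free_top_candidates_are_truth(self, noise_free_run):
        _, truth, peaks = noise_free_run
        truth_masses = truth.peptides["mass"].to_numpy()
        seen = []
        for pk in peaks:
            mass = pk.candidate.mass
            match = np.abs(truth_masses - mass) <= 10e-6 * truth_masses
            if not match.any():
                break  # first non-truth candidate ends the leading block
            seen.append(int(np.argmax(match)))
        assert len(set(seen)) == len(truth_masses)

    def test_volume_and_max_intensity_invariant(self, noise_free_run):
        _, _, peaks = noise_free_run
        for pk in peaks:
            assert pk.volume >= pk.max_intensity >= 0.0

    def test_outlist_sorted_descending(self, noise_free_run):
        _, _, peaks = noise_free_run
        scores = [pk.score for pk in peaks]
        assert scores == sorted(scores, reverse=True)

    def test_score_ranking_invariant_under_rescaling(self):
        # global intensity rescaling with recalibrated c preserves the ranking
        config = icpd.SimConfig(
            n_scans=60,
            peptides=[
                icpd.SimPeptide(mass=900.0 + 150 * i, abundance=1e5 * (i + 1),
                                cs_dist=(0.0, 1.0, 0.0, 0.0), apex=10 + 12 * i, width=4.0)
                for i in range(4)
            ],
            noise_c=1.0, noise_p=1, seed=9,
        )
        lcms_map, _ = icpd.simulate_map(config)
        scaled = icpd.LCMSMap(
            scans=[
                icpd.CentroidScan(rt=s.rt, mz=s.mz, intensity=7.0 * s.intensity)
                for s in lcms_map.scans
            ],
            scan_interval=lcms_map.scan_interval,
        )
        params = icpd.DetectorParams(p=2)
        key = lambda pk: (round(pk.candidate.mass, 3), pk.candidate.cs_hypothesis,
                          pk.candidate.rt_start)
        order_a = [key(pk) for pk in icpd.icpd_pipeline(lcms_map, params)]
        order_b = [key(pk) for pk in icpd.icpd_pipeline(scaled, params)]
        assert order_a == order_b

    def test_outlist_round_trip(self, noise_free_run, tmp_path):
        _, _, peaks = noise_free_run
        path = tmp_path / "outlist.tsv"
        icpd.write_outlist(peaks, path)
        df = icpd.read_outlist(path)
        assert list(df.columns) == icpd.icpd_core.OUTLIST_COLUMNS
        assert len(df) == len(peaks)
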