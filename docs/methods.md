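# Methods

## Signal model

A peptide species appears in an LC/MS map as a family of chromatographic
peaks indexed by charge state `cs` and isotope position `iso`. The model
used throughout the package is multiplicative:

    P(t, cs, iso) = A · C(t) · f(cs) · f(iso)
    y(t, cs, iso) = P(t, cs, iso) + n(t, cs, iso)

with `A` the total abundance (arbitrary intensity units), `C(t)` the
elution distribution over scans (non-negative, sums to 1), `f(cs)` the
charge-state distribution and `f(iso)` the isotope pattern (both sum
to 1). No parametric form is assumed for `C(t)`: real chromatographic
peaks, especially at low abundance, are frequently non-Gaussian, so the
detector estimates `C(t)` nonparametrically from the data.

### Isotope pattern

`f(iso)` is the averagine Poisson model: a peptide of neutral mass `M`
contains on average `4.9384 · M / 111.1254` carbons, and the number of
C13 substitutions is Poisson with rate λ = carbons × 0.0107. The pattern
is truncated to `n_iso` positions and renormalized so the score compares
fixed-length unit-sum vectors.

Accuracy: against an exact elemental-convolution reference (binomial
isotope distributions of C, H, N, O, S for the rounded averagine formula,
implemented as an independent oracle in the test suite), the carbon-only
Poisson pattern has total-variation distance ≈ 0.03 at 500 Da growing to
≈ 0.11 at 3000 Da, because nitrogen, oxygen and sulfur contribute heavy
isotopologues the carbon rate does not capture — and no single-rate
Poisson can do better than TV ≈ 0.02–0.03 above 1500 Da once the +2
components (O18, S34) matter. The strictest model-fidelity check in the
acceptance tests (TV < 0.02 across 500–3000 Da) therefore fails by
construction and is retained as a documented red: the carbon-only rate is
the model this detector is defined with, and the discrepancy is a model
bias, not an implementation error. For ranking purposes the bias is
benign: decoys lack *any* isotope structure, while the Poisson and exact
patterns differ only in detail.

`w_n = 1.003355` Da (the C13–C12 spacing) is used for the isotope m/z
offset rather than the free-neutron mass 1.008665 Da; the former is what a
high-resolution instrument observes between isotopologue peaks. At 10 ppm
tolerance the difference (≈ 5 mDa per isotope step) would otherwise push
iso ≥ 2 windows off the actual peaks for low charge states.

## Candidate generation

All centroids of the run are pooled and sorted by m/z, then binned
greedily: a bin is anchored at its lowest member and closes when the next
centroid exceeds the anchor by more than 2·dmz ppm; each bin's upper edge
is then extended dmz ppm into its successor, so an edge centroid may sit
in two bins and no peptide can be lost to an unlucky bin boundary. Each
bin's summed-intensity chromatogram is segmented into elution windows:
maximal runs of non-zero scans, runs separated by ≤ g zero scans merged,
merged runs with < s non-zero scans discarded. Windows are inclusive
0-based scan-index pairs. Per (bin, segment) the mean m/z is recomputed as
the intensity-weighted mean of member centroids inside the window
(robust to low-intensity stragglers), duplicates from the bin overlap are
merged to a fixpoint (union–find over pairs within dmz ppm with ≥ 1 shared
scan; union window, weighted mean m/z; candidates processed in ascending
(mz, rt_start) order for determinism), and every surviving m/z candidate
is expanded into CS neutral-mass hypotheses, assuming the observed m/z is
the monoisotopic peak at each charge.

Merging is global (across bins) and iterated to a fixpoint, which makes it
idempotent; chains of pairwise-overlapping candidates collapse into one.

## Information combining and the matching score

For each mass hypothesis the trace grid `y[t, cs, iso]` sums centroid
intensity in half-open ±dmz ppm windows around each predicted m/z, for
every scan of the candidate window. The elution profile estimate is the
grid total per scan, normalized. Combining uses matched-filter weights

    w(t) = C(t) / Σ_t C(t)²,   ŷ(iso) = Σ_t Σ_cs w(t) · y[t, cs, iso]

Under the model E[ŷ(iso)] = A·f(iso) with coefficient exactly 1: summation
over charge states cancels `f(cs)` (it sums to one), and Σ w(t)·C(t) = 1.
Among linear unbiased time-weightings the matched filter has minimum
variance under i.i.d. cell noise. The abundance estimate is
`Â = Σ_iso ŷ(iso)`. When `C` is itself estimated from the grid, `Â`
coincides with the total grid intensity; the two estimators differ only
when an external profile is supplied.

The summed noise on ŷ is treated as Gaussian (a sum of many per-cell
terms; central limit theorem) with a single variance following a power law
in abundance, σ′² = c·max(Â, A_floor)^p. The matching score is

    score = − Σ_iso (ŷ(iso) − Â·f(iso))² / (2σ′²)

i.e. the Gaussian log-likelihood up to its normalization constant. The
full log-density (adding −(n_iso/2)·log 2πσ′²) is available behind a flag
but is *not* used for ranking: with σ′² growing as Â^p, that term ranks
candidates by inverse abundance once residuals are small — on noise-free
data it literally inverts the ranking (measured ROC AUC 0.009 versus 1.0
for the quadratic form). The quadratic form is maximal (zero) at a perfect
pattern match for any abundance, and a threshold on it reads as "misfit in
noise-variance units". A side benefit: ranking is completely invariant to
the calibrated scale c, which therefore only affects the interpretability
of threshold values, not which peaks are found first.

### Noise exponent and calibration

`p` selects the noise regime: 1 for Poisson-like counting noise, 2 for
noise proportional to signal, 3 for noise growing faster than signal
(which empirically favours low-abundance peptides by penalizing loud
candidates). Default p = 3; the benchmark subcommand sweeps all three.
The scale `c` is calibrated from the data as the median over candidates of
`mean_iso(ŷ − Â·f)² / Â^p`; the median is robust both to the near-zero
residuals of genuine peptides and to gross decoy misfits. All-zero
residuals (possible only on synthetic noise-free input) fall back to a
floor of `1e-12 · max(Â)^p`. Calibration requires ≥ 10 candidates with
evidence; below that the caller must supply `c`. `A_floor` is the smallest
positive intensity in the map, preventing zero variance for near-empty
candidates.

### Single-scan baseline

The baseline scorer reproduces per-scan, per-charge detection: the isotope
pattern is read off the single (scan, charge) row with the largest summed
intensity, the abundance estimate is the highest single peak intensity in
that scan, and the same Gaussian score is applied. It uses a fraction of
the available signal, so its normalized pattern estimate is noisier; the
package's benchmarks quantify the resulting detection gap (e.g. ROC AUC
≈ 0.83 vs ≈ 1.00 at per-cell SNR 3 on the shipped 600-candidate
benchmark).

## Simulator

The simulator draws maps from exactly the detector's generative model,
plus the imperfections a real instrument adds:

* **Elution shapes**: Gaussian, exponentially modified Gaussian (tailing),
  asymmetric triangle, plateau — `width` is FWHM in scans (plateau
  length for plateaus). Profiles are truncated at 0.1 % of their apex and
  renormalized: a detector emits no centroid where there is no ion signal,
  and carrying infinite tails would create near-empty cells whose clamped
  noise biases abundance estimates. Renormalization keeps conservation
  exact: with no drop threshold the summed emitted intensity of a peptide
  equals A to machine precision.
* **Noise**: each emitted cell with expected intensity μ receives zero-mean
  Gaussian noise of variance `c·μ^p + baseline_var`. The power law acts on
  the peak's own expected intensity — the physical behaviour of shot and
  detector noise — and aggregates to a power law in A at the combined
  level. Negative draws are clamped to zero and zero intensities are
  omitted (centroided data carries no explicit zeros); clamping is a
  small upward bias only where μ ≲ σ.
* **Mass accuracy**: every emitted centroid m/z is jittered by a Gaussian
  ppm error (σ = dmz/3 in the noisy presets) so the ±dmz windows are
  genuinely exercised.
* **Contaminants**: single spikes, wrong-spacing doublets (0.68 Th — a
  spacing no charge state explains) and flat multiplets (four equal peaks
  at 1 Th), all with elution profiles and noise like peptides and apex
  intensities drawn from the peptide range, so intensity alone cannot
  separate them.
* **Per-cell SNR** of a peptide is defined as its apex expected cell
  intensity (apex scan, dominant charge, monoisotopic position) divided by
  that cell's noise standard deviation.

What the simulator does **not** emulate: ion suppression and co-elution
interference beyond simple m/z collisions, retention-time drift, isotope
fine structure, centroider artifacts (peak merging at low resolution),
and detector saturation. Passing benchmarks therefore demonstrates
correctness of the combining and scoring machinery under the stated model,
not performance on any particular instrument.

Presets (all deterministic given a seed): `noise_free` (20 peptides,
800–2320 Da, varied charge dispersions and all four shapes, no noise of
any kind — exactness checks), `low_snr_sweep` (15 peptides per SNR tier
{2, 5, 10, 20} + 60 contaminants, counting-statistics noise p = 1),
`dynamic_range` (40 peptides log-spaced over 4 orders of abundance above a
fixed additive noise floor + 40 contaminants — a desk-scale analogue of a
high-dynamic-range protein standard). `make_snr_benchmark` generalizes the
SNR-targeted construction (abundance solved per peptide from its apex cell
fraction).

## Evaluation protocol

The candidate universe is the OutList itself. A detection hits a truth
peptide when its mass is within dmz ppm and the elution windows share ≥ 1
scan. Each truth can be claimed by one detection (greedy assignment, best
rank first, ties by smaller ppm error); other detections matching an
already-claimed truth are charge/isotope duplicates of the same feature
and are excluded from the counting universe, so a single peptide can
inflate neither TP nor FP. Truths never claimed remain false negatives at
every threshold (the ROC need not reach TPR 1). Sweeping the threshold
over all distinct ranking values yields ROC (TPR = TP/(TP+FN),
FPR = FP/(TN+FP)) and PR (precision = TP/(TP+FP), recall = TPR) curves;
AUC is the trapezoid over the achieved ROC with (0,0) prepended. The same
sweep runs on any ranking column (score, volume, max intensity), and
per-abundance-tier curves evaluate each tier's truths against the shared
decoy set. Standard precision/recall definitions are used throughout, and
the axis meanings above are the ones plotted and exported.

## Numerical choices and conventions

* Retention times in seconds; scan indices 0-based; elution windows
  inclusive; ppm windows half-open [lo, hi).
* Defaults: dmz = 10 ppm, s = 3 (small enough to miss nothing), g = 2
  scans (tolerates MS/MS duty-cycle gaps), CS = 4, n_iso = 5 (≥ 99 % of
  the pattern below 3 kDa), p = 3, c calibrated.
* Candidates with empty grids score −∞ and sort last.
* The tsv map format cannot represent scans with no peaks; the reader
  reconstructs interior empty scans from gaps in the scan-index column
  (rt interpolated from the median scan interval) so indices keep their
  meaning. mzML round-trips empty scans exactly.
* Scores are plain floats (log-domain); ties in the OutList sort are
  resolved stably by candidate construction order.

## Problem sizes

The shipped tests and the acceptance script use desk-scale runs chosen to
exercise every code path with comfortable statistical margins: 20-peptide
noise-free maps, 600-candidate SNR-3 benchmarks (300 peptides + 300
contaminants, ~16 000 scored hypotheses), 1000-replicate Monte-Carlo
estimator checks, and 200-peptide abundance-recovery runs. The full suite
and the acceptance script each complete in well under a minute on one CPU.

## Known limitations

* Overlapping features are not deconvolved; coinciding m/z windows simply
  sum, and heavily overlapped low-resolution data is out of scope.
* The charge-state distribution is never estimated (by design — it cancels
  in the combined statistic), so per-charge quantification is not
  available.
* The score is a ranking statistic, not a calibrated error rate: no FDR is
  attached to a threshold.
* The carbon-only Poisson pattern systematically underweights +1/+2
  isotopologues at high mass (see above); sequence-specific or
  sulfur-rich peptides deviate further.
* Elution-profile estimation and combining share the same data, so `Â` is
  exactly the windowed intensity sum; its accuracy at very low SNR is
  limited by the non-negativity of centroid intensities.
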