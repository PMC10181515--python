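# Methods

## Signals, preprocessing and framing

A subject record holds an SpO2 trace, per-minute apnea labels, and either
a single-lead ECG or a precomputed RR series.  Minute k covers
[60k, 60(k+1)) seconds (0-based, half-open).

**R-peak detection** is the classic energy pipeline: 5-15 Hz Butterworth
band-pass, derivative, squaring, 150 ms moving-window integration,
adaptive signal/noise thresholds (exponential updates, factor 0.125) with
a 200 ms refractory period and a half-threshold search-back for gaps
longer than 1.66x the running RR median.  Detected peaks are refined to
the local band-passed maximum.  On template-rendered ECGs the detector
recovers >99% of beats within ±50 ms.

**RR artifact filtering** compares each interval against a band built
from the previously *accepted* intervals: running median ±
(3 × 1.4826·MAD + 20 ms) over the last 40 accepted beats.  The band
follows gradual drifts but rejects ectopic-like excursions.  Flagged
intervals are removed, not interpolated — interpolation would fabricate
samples that the spectral and recurrence features would then treat as
physiology.  Removal decisions depend only on accepted history, which
makes the filter idempotent.  Series under 10 intervals pass through with
a warning.

**SpO2 cleaning** removes zero samples and saturations below 50%
(sensor drop-outs and implausible readings) and subtracts the recording
mean once, per recording, not per frame: variances are shift-invariant,
so only the spectral features see the (global) centering, and a per-frame
subtraction would leak frame information into overlapping neighbors.
Cleaned traces keep explicit sample times, so downstream windows know
where the gaps are.  Frames whose SpO2 window keeps less than 50% of its
nominal samples are flagged unusable and skipped by the extractor.

Frames span 5 labelled minutes, step 1 minute, and take the central
minute's label; N labelled minutes yield N − 4 frames.

## HRV features (73 per frame)

The tachogram of a frame is resampled at 1 Hz by cubic spline against
beat time (clamped at the observed boundary beats) and mean-subtracted,
so DFT bins are in Hz and the 0-0.5 Hz HRV band is exactly the retained
half-spectrum.

* **Filter bank (34)**: periodogram S(k) = |X_N(k)|²/N, k = 0..N/2; the
  DC bin is dropped and the remaining bins are partitioned into 34
  contiguous equal-width rectangular bands over (0, 0.5] Hz.  Each band
  reports ln(band power / total power), floored at 1e-12 before the log
  so empty bands stay finite.  With 300 samples the first band covers
  (0, 0.0147] Hz, inside the 0.01-0.04 Hz cyclic-variation band; a pure
  0.25 Hz respiratory modulation lands at the band-16/17 edge and
  maximizes band 17.
* **Cepstrum (20)**: c = Re IFFT(log |FFT(x)|) with the magnitude floored
  at 1e-12; coefficients CC1..CC20 are c(0)..c(19), so CC1 is the mean
  log spectral magnitude (a pure gain moves only CC1, by log g).
* **DFA (2)**: integrate the mean-subtracted intervals, detrend linearly
  in windows of t beats with 50% overlap, F(t) = RMS residual; α is the
  least-squares slope of log F vs log t on a log-spaced grid of ~10
  scales.  α1 uses 10-40 beats, α2 70-194.  The 50% overlap is what makes
  the 194-beat scale usable inside a ~300-beat frame (two windows); with
  disjoint windows α2 would be a single-window fit.  α2 is reported
  absent when the series is shorter than twice the smallest long-range
  scale.  Sanity anchors: white noise → 0.5, 1/f noise → 1.0, integrated
  noise → 1.5, all recovered within ±0.1 in seeded tests.

## Recurrence features (17 per frame)

The RR interval series is delay-embedded (Takens), presets (m=7, τ=4)
and (m=8, τ=5); utilities estimate τ (first autocorrelation zero) and m
(false nearest neighbors) but the presets are the defaults.  The FAN
recurrence matrix marks, per column, the k = ⌊0.05 · N_eligible⌋ nearest
states by Euclidean norm, excluding a Theiler band of 1 (the line of
identity only).  Distance ties at the cutoff go to the smaller row index
(stable sort), so the matrix — generally asymmetric — is fully
deterministic, even for constant segments where all distances tie.

Measures (line of identity zeroed throughout): REC (density), DET / L /
Lmax / ENTR on diagonal runs ≥ lmin = 2 (ENTR is the Shannon entropy of
the ≥ lmin length distribution), LAM / TT / Vmax on vertical runs ≥ vmin
= 2, T1 (mean spacing of recurrence points down a column), T2 (mean
spacing of vertical-run starts), RT / RTmax / RF = 1/RTmax / ENTW on
white vertical runs, RPDE = ENTW / ln RTmax (0 when RTmax ≤ 1), and
Clust / Trans as mean local clustering and transitivity of the graph
A = R ∨ Rᵀ.  These operationalizations follow the common
recurrence-toolbox conventions and are locked by a brute-force oracle in
the tests (exhaustive run scanning, explicit triangle counting), not by
published values.  Measures whose underlying structure count is zero are
reported as 0 with a flag.  Two boundary facts worth knowing: a full
matrix still has two isolated corner diagonals, so DET = (N²−N−2)/(N²−N),
not exactly 1; and the recurrence plot of a period-2 signal has *solid*
diagonals — only an isolated-dot pattern gives DET = 0.

## SpO2 features (22 per frame)

`varSAT1m` and `varSAT5m` are sample variances (n−1 denominator) of the
cleaned trace over the central minute and the whole frame; both windows
must keep ≥ 50% of their nominal samples.  For the spectral features the
frame is decimated to 1 Hz by per-second averaging (anti-alias for the 8
or 50 Hz native rates; seconds emptied by artifact removal are linearly
interpolated), then periodogram + 20-band filter bank over (0, 0.5] Hz as
above.  Band 1 covers (0, 0.025] Hz and contains the 0.01-0.04 Hz
event-repetition band, which is why a desaturation saw-tooth train at one
event per 45 s maximizes it.

## Selection, classification, diagnosis

Selection step one: on each of 200 iterations (default; the 8-subject
preset instead enumerates all C(5,3)·C(3,2) = 30 folds of 3 OSA + 2
control training subjects) the learning-set subjects are split into two
halves, and greedy forward selection — each step adds the feature that
maximizes validation accuracy of the balanced LDA, stopping at the first
non-improving step — contributes one subset.  Features are ranked by
selection count, ties broken by mean selection step then name.  Step two
re-draws splits from an independent seed stream and traces mean
validation misclassification against rank-prefix size k; the chosen
subset is the prefix at the first minimum (a one-standard-error k is
reported alongside, since the curve is often flat near the minimum).
Subjects are never split across the two sides — frames of one patient
correlate strongly, and letting them straddle the split would leak.

The LDA uses class means, pooled covariance (ridge λ on the diagonal as a
singularity fallback, warning at λ = 1e-6) and the prior log-odds; after
undersampling the priors are equal.  ROC/AUC come from a threshold sweep
(trapezoid rule; ties move simultaneously); the operating point minimizes
√(FPR² + (1−TPR)²) on the *learning-set* ROC and is frozen before test
scoring — tuning it on the test ROC is also possible but is not the
default, since it optimistically biases the reported point metrics.

Per-recording AHI proxy: 60 × predicted apneic minutes / minutes, in
[0, 60] by construction; OSA iff proxy > limit (strictly — an AHI exactly
at the limit is called normal).  Bland-Altman: differences AHI_a − AHI_m,
bias = mean, s_d with n−1, limits bias ± z·s_d and CI of the bias
bias ± z·s_d/√n with z = Φ⁻¹(0.975) ≈ 1.959964.  The 1.96 factor is the
standard limits-of-agreement definition and is what reproduces published
interval arithmetic from printed bias/SD pairs; a ±1·s_d interval would
cover only ~68% of differences.

## Synthetic cohort generator

The generator emulates what the features measure and nothing more:

* apneic minutes are placed by a two-state Markov chain with stationary
  apneic fraction target_ahi/60 and mean run length 4 min for patients
  (1 min for controls), producing the consecutive-event clusters that
  motivate the 5-minute variance;
* the RR series has base interval 0.95 s with multiplicative lognormal
  jitter (σ = 0.03); apneic minutes add a ±12% brady-tachycardia
  oscillation with period 20-60 s (default 40 s), normal minutes a ±4%
  modulation at 0.25 Hz;
* each apneic run spawns one event per oscillation period; for
  desaturating subjects 90% of events produce a saw-tooth desaturation —
  onset 10-30 s after event start, linear 4% (± 0.8%) drop over 15 s,
  resaturation at 0.6%/s — on a 96-99% baseline with 0.15% sensor noise,
  quantized to 0.1% steps.  Event placement keeps each desaturation span
  inside its labelled run: the run ends when breathing resumes, so the
  final nadir falls near the run end rather than in the following
  normal-labelled minute;
* non-desaturating subjects get no regular desaturations, only a 10%
  chance of a barely-3% dip per event (plus occasional sub-threshold
  1.5% dips), so their measured ODI (≥3% dips/h) stays below AHI/2 — the
  defining constraint of the phenotype, which the generator verifies and
  refuses to violate;
* controls desaturate on only 30% of their rare events.

Default recording length is 480 min (a full night).  The end-to-end test
suite and examples use a scaled-down cohort — 16 subjects (6/6/4) at
60-90 min — which keeps the full pipeline under a minute per feature
family; selection there runs 12 iterations with the error curve capped at
k = 20.  Subject-level jitter draws target AHI from (0.5, 4), (30, 58)
and (26, 50) events/h for the three groups, oscillation period from
(25, 55) s and baseline SpO2 from (96, 99)%.

What the generator does *not* model: hypopnea/apnea subtypes, arousal
micro-structure, position/REM effects, oximeter averaging artifacts,
ectopy bursts, or any cardiorespiratory coupling beyond the label-gated
modulations.  Passing end-to-end tests therefore demonstrates that the
pipeline recovers the intended statistical signatures and orderings
(oximetry ≥ HRV on desaturators, HRV more sensitive on non-desaturators),
not clinical-grade accuracy on real recordings.

## Numerical choices

Spectral floors 1e-12 (band ratios and cepstrum magnitudes); LDA ridge
fallback 1e-6; undersampling re-seeded per iteration from the master
seed; all randomness flows from `numpy.random.default_rng` generators
seeded explicitly, so every result in the package is reproducible
bit-for-bit under a fixed seed.  Learning/test splits with odd group
counts send ⌊n/2⌋ subjects to the learning set.  CSV round-trips write
floats with 17 significant digits (bit-exact).

## Known limitations

* The Physionet-layout reader requires the optional `wfdb` package; the
  pipeline itself consumes only the in-memory record type and the CSV
  fixture layout.
* Filter-bank band edges of published per-band statistics cannot be
  mapped exactly without the original band definitions, so per-band
  medians from the literature serve as sanity references only.
* The per-minute AHI proxy saturates at 60 events/h and undercounts
  multi-event minutes; this is inherent to minute-resolution labels.
* Recurrence-time measures (T1/T2/RT) follow toolbox conventions that
  differ between software packages; comparisons across packages should
  check definitions first.
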