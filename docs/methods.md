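# Methods

This note documents the models behind `hrvfatigue`, the definitions
adopted where the field (or the study design this package emulates)
leaves them open, the numerical choices, and what the synthetic data do
and do not establish.

## IPFM RR generation

Beat times follow the integral pulse frequency modulation model: an
integrator of the instantaneous rate fires a beat at every integer
crossing,

    ∫₀^{t_k} (1 + m(t)) / T0 dt = k,

with `T0` the mean interbeat interval and `m(t)` a sum of per-band
modulations. Each band (VLF/LF/HF) contributes a single sinusoid
`a·sin(2πft + φ)` by default because sinusoids give analytic ground
truth; phases are drawn from the spec's seed. Amplitudes are fractions
of the mean rate and must sum below 1 so the rate stays positive.
Integration uses the cumulative trapezoid on a 4 ms grid with linear
interpolation at integer crossings, giving sub-millisecond beat-time
accuracy at negligible cost.

**Ground truth includes the beat aperture.** The HRV stage analyzes the
RR *tachogram*, not `m(t)` itself. Each interval averages the rate over
roughly one beat, so a modulation at frequency `f` reaches the
tachogram attenuated by `sinc(f·T0)`. The generator therefore reports
per-band truth `(a · T0_ms · sinc(f·T0))² / 2` ms². Empirically the
Welch estimate recovers this within a few percent (an HF sinusoid at
0.25 Hz is attenuated to ≈ 0.84× its naive power at T0 = 0.9 s, which
the naive formula would miss entirely). Recovery tests and the 2:1
LF:HF ratio experiment are stated against this aperture-corrected
truth. Default band frequencies: 0.02 / 0.10 / 0.25 Hz. The VLF
amplitude defaults low (0.01) because 5-min segments barely resolve the
bottom of the VLF band.

## ECG synthesis

One PQRST complex per beat, each wave a Gaussian bump
(amplitude µV, σ s, offset s from the R apex): P (150, 0.025, −0.20),
Q (−150, 0.010, −0.035), R (1000, 0.012, 0), S (−200, 0.010, +0.035),
T (300, 0.060, +0.30). R apices land on the nearest sample at the
configured rate (500 Hz default). The record is padded by the template
half-width at both ends so boundary complexes are rendered whole; true
R indices (pre-noise) are returned for detector scoring. Baseline
wander is a single sinusoid (amplitude/frequency configurable), plus
white Gaussian noise. Adjacent P/T waves may overlap at high heart
rates — that is physiological; an error is raised only when beat
spacing falls below the QRS sub-template support (~0.13 s), where R
apices would merge. An optional ectopy injector replaces interval pairs
with time-preserving short+long couplets for artifact-filter tests.

## Pan–Tompkins detection

The classic stages are kept; two adaptations matter:

- The original integer filters assume 200 Hz records. Here the
  band-pass is a Butterworth 5–15 Hz, order 3, applied
  forward-backward (zero phase) at the record's own rate — resampling
  to 200 Hz would cost R-timing precision at 500 Hz.
- After integration-window detection, peaks are refined to the local
  maximum of the band-passed signal within ±150 ms, then of the
  baseline-corrected signal within ±25 ms, because RR-interval work
  needs sample-accurate apices.

Thresholding: signal/noise running levels start from the max/mean of
the first 2 s of the integrated trace (the learning phase; records
shorter than 10 s are rejected), `THRESHOLD = noise + 0.25·(signal −
noise)`, 200 ms refractory, T-wave rejection by comparing maximal
slopes when a candidate falls within 360 ms of the last beat, and a
search-back pass at half threshold when no beat arrives within 166 % of
the running average RR (last 8 intervals). Lead II is analyzed when
present (rhythm-analysis convention); the lead is configurable.

The RR artifact filter (on by default, optional) drops intervals
outside [300, 2000] ms or deviating > 30 % from the running median of
5; removing more than 20 % of a segment sets a quality-warning flag.

## HRV feature definitions

Two formula dialects are provided; the default (`"printed"`) follows
the study-protocol conventions this package emulates, the alternative
(`"conventional"`) the common textbook forms:

| feature | printed (default) | conventional |
|---|---|---|
| SDNN | population form, 1/N | sample form, 1/(N−1) |
| RMSSD | 1/(N−1) over the N−1 squared diffs | same |
| PNN50 | NN50 / N | NN50 / (N−1) |

SDSD is the population standard deviation of successive differences
(the only reading on which a *dispersion* formula makes sense; note the
exact identity SD1 = SDSD/√2, and SD1 = RMSSD/√2 whenever the mean
successive difference is zero).

Where the literature gives no single formula, the adopted definitions
are:

- **TINN** — RR histogram with 1/128 s bins (centers on multiples of
  7.8125 ms). A triangle with apex pinned at the modal bin's histogram
  point is fitted by exhaustive search of its zero crossings (N, M)
  over bin edges, minimizing summed squared error against the bin
  counts; TINN = M − N. The search space extends one histogram-width
  beyond the occupied range so wide shallow triangles are reachable.
  The error splits at the apex, so the two sides are searched
  independently (the test oracle does the full joint search). A single
  occupied bin returns 0 with a degenerate-histogram flag. Note a
  geometric consequence of edge-constrained crossings: bin centers and
  edges interleave by half a bin, so an *exactly* fitting symmetric
  triangle always has an odd base width.
- **VLI** — dispersion of Poincaré points along the line of identity,
  i.e. the population SD of (RRᵢ + RRᵢ₊₁)/√2, identically SD2. Chosen
  because published group summaries for VLI and SD2 are numerically
  near-identical; alternative vector-length definitions exist in the
  literature and are deliberately not implemented.
- **PI (Porta index)** — 100 × #(ΔRR < 0) / #(ΔRR ≠ 0); undefined
  (NaN + flag) when every difference is zero.
- **CCM₁** — mean absolute triangle area of three consecutive lag-1
  Poincaré points, normalized by π·SD1·SD2: with N′ points,
  `CCM = Σ|A(i)| / ((N′−2)·π·SD1·SD2)`. Undefined when the fitted
  ellipse is degenerate (S = 0) — note that points collinear along any
  ±45° line force S = 0, so the "collinear ⇒ CCM = 0" case only arises
  for collinearity off those axes.

**Spectrum.** The tachogram (each interval at its closing beat time) is
cubic-spline-resampled at 4 Hz, linearly detrended, and estimated by
Welch with 120 s Hann windows at 50 % overlap (resolution 1/120 Hz ≤
0.01 Hz); at least 120 s of cumulative time is required. Band powers
integrate trapezoidal panels assigned to VLF/LF/HF by midpoint
frequency, so the bands partition the integral exactly; **TP is defined
as VLF + LF + HF** (power below 0.003 Hz is excluded), which makes
HFn + LFn = 100 hold identically. A spectrum with TP ≤ 1e-10 ms²
(e.g. a constant tachogram) leaves the normalized powers undefined
rather than normalizing numerical residue. A Lomb–Scargle estimator on
the irregular beat times is available behind a flag
(variance-normalized to a one-sided density).

Undefined features propagate as NaN plus a reason flag, never as
silent zeros; `extract_all` converts sub-operation errors to flags so a
degenerate feature cannot abort a batch.

## Statistics

The analysis layer reproduces the screening-then-test flow typical of
these studies, including one deliberate infidelity-to-textbook choice:
the per-feature post-fatigue vs post-stimulation comparison uses
**independent-samples** tests by default even though the states are
within-subject, because that is the analysis convention being
reproduced; a paired variant (paired *t* / Wilcoxon) sits behind
`paired=True`. Branch selection: both samples pass Shapiro–Wilk
(p > 0.05) → *t*-test (pooled when Levene passes, Welch otherwise);
otherwise Mann–Whitney U. The branch taken is recorded in every result.

Sign conventions follow the published tables: X̄ = mean(first sample) −
mean(second sample), so an increase after intervention appears as a
negative X̄ (and negative *t* in the paired accuracy tests).

No multiple-testing correction is applied across the 21 features by
default (again fidelity); Benjamini–Hochberg is available via
`correction="bh"`. Bonferroni post-hoc p-values are raw p × number of
pairs, capped at 1, and run only when the omnibus ANOVA rejects. The
baseline-equivalence check is a plain repeated-measures one-way ANOVA
without sphericity correction, flagged as such. The cross-group
comparison of fatigue-induced rates of change is implemented as a
one-way ANOVA on per-subject rates — an interpretation, since the
aggregation model behind such published F rows is typically unstated.

Rates of change divide by the post-fatigue baseline and are undefined
(flagged) at a zero baseline.

## Synthetic cohorts: what they do and do not show

`generate_cohort` draws, per subject × state: an IPFM RR series from a
state-shifted modulation spec, a subjective-fatigue total from a
clipped Normal distributed over 15 items (each 0–4), and 375 trials
(5 min at 800 ms inter-stimulus interval) with a 5 % no-response rate,
correctness calibrated so the *scored* accuracy (non-responses count as
errors) hits the cell mean in expectation, and RT ~ Normal(450, 80) ms
truncated to (0, 800]. Accuracy cell means/SDs default to published
group summaries; subjective-scale and autonomic-modulation shifts
reproduce published effect *directions* only, because per-subject raw
values are not deposited — the defaults are the package's own
realistic magnitudes and are not tuned to reproduce published test
statistics. Per-cell RNG streams derive deterministically from
(master seed, group, subject, state), so cohorts are pure functions of
their design and insertion-order independent.

`generate_feature_cohort` draws the 21-feature matrix directly from
per-feature Normal baselines (resting-state plausible means/SDs) with
per-cell shifts in SD units. It exists for calibration and power
studies of the statistics layer, where thousands of cohorts are needed
and signal-level synthesis would be pointless overhead. HFn is derived
as 100 − LFn (the normalization constraint), but other cross-feature
dependencies (e.g. SD2 vs VLI, RMSSD vs SD1) are *not* enforced — the
draw is independent per feature. Consequently these cohorts validate
the inferential machinery, not the feature extractor; the two are
linked by the signal-level tests (detector performance, spectral
recovery, end-to-end RR recovery with mean absolute error < 4 ms).

Neither generator models respiration–heart coupling, ectopy (except
via the explicit injector), non-stationarity within a segment, or
realistic ECG morphology variation. Passing tests therefore establish
correctness of the algorithms under spectrally structured, stationary,
artifact-controlled conditions — not performance on clinical
recordings.

## Problem sizes and numerics

The validation suite uses: 200 random RR series (lengths 50–400) for
the feature-oracle sweep at 1e-9 relative tolerance; 20 five-minute
noisy records (60–100 bpm) for detector scoring at ±20 ms; 2000
ten-subject null cohorts for the per-cell false-positive rate (5 % ±
1.5 %); and 100 forty-subject cohorts with 1-SD shifts for sign-pattern
power (≥ 80 % per feature). The acceptance script uses 1000 null
cohorts. Frequency-domain oracle checks apply to series with ≥ 120 s
of cumulative time, the minimum the Welch configuration accepts.

Tie-breaks and degeneracies: the TINN search prefers the
nearest-to-apex crossing on ties (strict improvement by > 1e-12);
zero-variance paired differences return t = 0, p = 1; an all-tied
Mann–Whitney cell returns p = 1 with a degeneracy flag; Shapiro–Wilk on
a constant sample reports a degenerate screen (treated as non-normal).
File formats are plain text (CSV / ms-per-line RR / YAML config / JSON
reports); every output names the hash of the run configuration that
produced it.

## Known limitations

- The detector is tuned for clean-to-moderately-noisy resting ECG;
  there is no arrhythmia handling, no multi-lead fusion, and no
  streaming mode.
- TINN on short segments (< a few hundred intervals) is
  histogram-starved and noisy; values are returned but should be read
  with care.
- The Lomb–Scargle path is a convenience alternative, normalized to
  match total variance; its band powers can differ from Welch's by a
  few percent on short segments.
- The independent-samples default for within-subject contrasts is a
  fidelity choice, not a statistical recommendation; use
  `paired=True` for the statistically appropriate variant.
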