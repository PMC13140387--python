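# Methods

This note records the models, parameter choices and numerical decisions
behind `upstates`, in the spirit of a methods appendix. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Signal model and preprocessing

All potentials are microvolts in memory; time is seconds, session-relative,
sample index 0-based. The working sampling rate is 763 Hz (recordings at a
native 3 kHz are polyphase-resampled with anti-aliasing). Band-passes are
Butterworth filters applied forward-backward (`sosfiltfilt`): onset latency
is the analysis currency throughout, and a causal filter's group delay would
bias every latency, synchrony-lag and refractory quantity. "8th order" is
the design order before the forward-backward pass (a band-pass of design
order 8 uses `N = 4` in scipy's convention), so the effective magnitude
response is the squared 8th-order response. Three analysis bands are used in
different places — 0.1–1 Hz (slow LFP), 0.1–10 Hz (Up-state detection,
the default `detection_band_hz`), 0.1–150 Hz (oscillation analysis) — and
each stage takes its band from `AnalysisConfig` rather than hard-coding one.

Band power uses the six canonical bands (delta 2–4, theta 4–8, alpha 8–14,
beta 14–30, low gamma 30–70, high gamma 70–150 Hz), each band-passed and
averaged in 1 s Hann windows with a 50 ms hop (the window/hop are a package
choice; nothing downstream depends on them). The dB trace is relative to the
session median per band and is masked where power is zero.

## Up-state detection

Onsets are local maxima of the negated detection-band trace with

- topographic prominence ≥ 3 × SD of the whole session's detection-band
  trace (the normalisation window is a package choice; the SD is
  offset-invariant, so detection is too),
- pairwise spacing ≥ 382 samples, interpreted at 763 Hz (≈ 0.5007 s) and
  rescaled proportionally at other rates,
- followed by removal of any candidate with another candidate in its
  preceding 2 s. The reference set for this rule is the full candidate list,
  removed or not, so removal chains across the successive waves of one
  multi-wave Up state and only the first wave survives.

The prominence filter is applied **before** the minimum-distance rule
(highest peak wins ties), matching the common peak-finder convention in
which both options are set together; the test suite pins the whole rule
chain against a literal O(n²) reference.

The fixed-threshold detector (depth comparisons, default 0.1 mV = 100 µV)
finds downward crossings of −threshold with a 2 s refractory. It reports the
post-crossing trough minimum as the onset time by default: the crossing
itself leads the trough peak by roughly 110 ms for a 250 µV, 400 ms-wide
onset wave, so reporting the trough keeps both detectors on the same
landmark and their onset sets directly comparable (`report="crossing"`
restores the raw crossing time).

Classification: an onset is deviant-evoked iff it lies in the **closed**
window 100–500 ms after a deviant; when two deviants qualify, the most
recent wins. The trigger kind is configurable (OMIS, POST) for omission
analyses. The evoked fraction is the percentage of trigger events with a
linked evoked onset.

## Synchrony

The synchrogram is the histogram of (Up onset − event onset) lags in 50 ms
bins spanning −1000…+1000 ms, normalised per event. Bins are half-open
[lo, hi); lags are rounded to 1 ns before binning so that an exact-latency
lag (e.g. 200 ms on the dot) cannot straddle a bin edge through
floating-point representation error. The peak is searched over non-negative
lags; total synchrony sums the 5 bins (250 ms) centred on the peak bin.

The null shuffles each event independently by an offset drawn uniformly from
the non-zero multiples of 100 ms within ±1 s (a common-offset-per-iteration
variant is available). Zero is excluded so every shuffle actually displaces
every event — a null containing the identity would dilute the control.
Events shifted past the block edge wrap circularly over the block duration,
conserving the event count and local rate; truncation would bias the null
low. 100 iterations give per-bin null means/SDs and a peak-bin z-score.
Group-level comparisons (deviant vs preceding-standard totals, one value per
animal) use an unpaired pooled-variance t-test.

## Evoked-response statistics

Epochs are cut per channel with optional baseline correction subtracting the
mean of −100…0 ms (a package default; the window is configurable). Trials
truncated by session edges are dropped and counted. Per-trial RMS uses
0–500 ms by default.

The bimodality coefficient uses the adjusted Fisher–Pearson skewness and
bias-corrected excess kurtosis:

    BC = (g1² + 1) / (g2 + 3(n−1)² / ((n−2)(n−3)))

Gaussian data give BC → 1/3, uniform → 5/9 (the 0.555 bimodality threshold),
a symmetric two-point mixture → 1. The bias-corrected (sample-size-adjusted)
denominator is used deliberately: with the printed precision of typical
reports, the corrected and asymptotic versions differ at n of a few hundred.
Group-level histograms z-score RMS within each animal before pooling.
Normality is checked with a one-sample KS test of the z-scored values
against N(0, 1).

Partition statistics (evoked vs fail, or spontaneous vs evoked with optional
alignment of trials to their negative peaks) report mean ± t-based 95 % CI
per condition and a pointwise two-sample t-test mask, **uncorrected** at
α = 0.05 — the convention for significance bars on ERP panels; a
cluster-correction flag exists but is off by default. Response latency is
the first time ≥ 0 at which a pointwise one-sample t-test is significant for
at least 13 ms consecutively (10 samples at 763 Hz); absence of any such run
is a valid "no response" outcome. This estimator marks the departure of the
waveform from baseline, not its peak, so per-channel *differences* (the
traveling-wave quantity) are unbiased even though individual latencies sit
near the waveform foot.

Condition contrasts (deviant vs many-standards, awake vs anaesthetised)
summarise each trial by its window RMS and compare via a pooled t-test or a
linear mixed model (REML) with condition fixed, random intercepts per
animal and a tone-frequency variance component when frequencies are given;
trial-to-trial variation is the residual. A singular variance component is
dropped (logged) before falling back to the t-test.

## Refractory timing and hazard

For each deviant we record the time since the previous Up onset — excluding
any Up inside that deviant's own 100–500 ms triggering window, so the
outcome cannot leak into its own predictor — the time since the previous
deviant, and the outcome. The rank-sum test uses mid-ranks, the tie-corrected
normal variance and a 0.5 continuity correction (reported as Z).

The Cox model runs on the clock "time since the last Up onset": each
inter-Up gap is one episode, discretised at 50 ms, with the time-varying
covariate "a deviant was delivered 100–500 ms before this bin" (the same
exposure window the classifier uses). Runs of bins with constant exposure
are merged into single (start, stop] intervals — the partial likelihood only
changes at event times, so this is exact, not an approximation. The fit
(lifelines, `CoxTimeVaryingFitter`) carries a small ridge penalty (0.01) to
keep the estimate defined when strong evocation quasi-separates exposed
bins. The covariate coding and time scale make β's magnitude
implementation-specific; its sign and significance are the meaningful
outputs.

## The synthetic generator

The generator emulates the statistical structure of a urethane-anaesthetised
rat ECoG session; it is a waveform-level phenomenological model, not a
biophysical one.

State process — alternating Down/Up dwell times: Down ~ Gamma(shape 4,
mean 3 s × depth), Up ~ Uniform(1, 3) s, giving a rhythmic but variable
~0.2 Hz slow oscillation. Each deviant evokes an Up at 200 ms latency with
probability `p(t) = p_max · logistic((t − t50)/slope)` in the time `t` since
the previous Up onset — the logistic form is a modelling choice (the
refractory effect is observed, its functional form is not) — suppressed
while an Up is already in progress. Defaults `p_max = 0.8`, `t50 = 1.5 s`,
`slope = 0.5 s` were fixed once so that the default session's measured
evocation fraction lands near the reported population mean (57 %); the
acceptance script prints the value each run actually produces.

Rendering — every Up is a negative raised-cosine trough (amplitude uniform
200–300 µV, width 400 ms, **centred** on the onset so the detected peak and
the ground-truth onset coincide), a −40 µV plateau with 100 ms cosine ramps
for the Up duration, and 10–80 Hz band-passed noise (30 µV SD) under the
same envelope. Tones add a −20 µV, 60 ms-wide deflection centred 50 ms after
onset. Per-channel traveling-wave delays shift all rendered waveforms;
ground truth stays on the undelayed reference timeline. Background is
1/f-amplitude-spectrum noise (20 µV SD) plus white noise (10 µV SD); onset
peak amplitude and early-response amplitude are independent parameters
because the recordings do not establish that they coincide.

Modes — `awake` disables the Up-state process entirely and halves the
background (desynchronised, low-amplitude), so awake sessions have strictly
smaller SD than anaesthetised ones. The `depth` scalar multiplies the mean
Down dwell and scales `p_max` by a gain rising to 1 at depth 1, flat to 1.5,
then declining to 0 at depth 3 — reproducing the non-monotone dose
dependence in which moderate deepening strengthens evocation until very deep
anaesthesia prevents Down-state exit.

Seeding — one root seed; independent substreams (state process, per-channel
noise, nested activity) are spawned deterministically, so components are
reproducible in isolation.

What the generator does **not** emulate: electrode-specific noise spectra
and artifacts, true propagating wavefronts (delays are per-channel
constants), graded MMN-like adaptation of the early response,
state-dependent modulation of the early component, non-stationary anaesthetic
drift within a session. Tests passing on synthetic sessions therefore
validate the *pipeline's correctness and statistical calibration* under the
assumed structure, not the biological claims on real recordings; the
recorded-data benchmark test runs only when the deposited sessions are
available locally.

## Numerical and degenerate-input conventions

- Zero-SD traces and traces shorter than the minimum peak distance detect
  nothing (warning, not an error).
- `evoked_fraction` with zero trigger events is an error (undefined), as are
  bimodality statistics with n < 4 or zero variance, rank-sum groups with
  < 5 records, and Cox designs with < 10 events or constant exposure.
- Windows are half-open [lo, hi) in ms except the evoked-classification
  window (closed, matching its inclusive definition); window-membership
  comparisons carry a 1 ns tolerance.
- The 0.1 mV fixed threshold is converted to 100 µV at config load; configs
  may specify either unit.
- Byte-identical run reports under a fixed seed are a tested invariant of
  the pipeline; reports contain no timestamps for this reason.

## Test problem sizes

Unit and property tests use sessions of 40–300 s with 1–6 channels; the
acceptance-style checks use 200 deviants (evocation-fraction recovery),
100 seeds × ~150 deviants (refractory and hazard recovery), 50 seeds × three
evocation levels (hazard monotonicity), 200 random traces (detector oracle
equivalence), 200 replicates (significance-mask calibration) and 10⁶-sample
reference distributions (bimodality asymptotics). These sizes were chosen so
the statistical tolerances quoted in each test are comfortably powered.
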