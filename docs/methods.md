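# Methods

`socialphot` quantifies bulk fiber-photometry recordings of genetically
defined neural populations during social behavior, together with the
anatomical (viral tracing) and physiological (optogenetic slice
electrophysiology) measurements used to characterize the same circuits.
This note documents the models, the defaults and why they were chosen, the
numerical decisions, and what the synthetic-data generator does and does
not emulate.

## Signal model and normalization

Raw fluorescence is modeled as

    F_raw(t) = F0 · d(t) · (1 + a(t)) + ε(t)

where `d(t)` is slow multiplicative photobleaching, `a(t)` the calcium
transient in fractional units, and `ε` sensor/shot noise. The pipeline
inverts this in three steps.

**Baseline (F_baseline).** A window of 25% of the recording
(`window_fraction`, matching the moving-window convention of the original
analysis tooling) slides at a stride of one fifth of the window. Within
each window, the samples lying between the 0.10 and 0.15 within-window
quantiles (`quantile`, `quantile + band`) are averaged — both their values
and their times — to give one anchor. A low quantile is robust to calcium
transients, which are strictly upward; recording the anchor at the band's
mean *time* rather than the window center means that on transient-free
signals the anchors fall on the drift curve itself, so the estimator is
unbiased under pure bleaching (this is verified against generator ground
truth to < 1% of the drift span). Anchors closer than half a stride are
merged (near-coincident anchors make a cubic spline oscillate), the
anchors are interpolated with a cubic spline, and the baseline is extended
linearly beyond the first/last anchor (cubic extrapolation of noisy
anchors diverges). Edge windows are truncated, never padded. NaN samples
are rejected rather than imputed; traces are assumed gap-free.

**ΔF/F and Fz.** `dff = (F_raw − F_baseline)/F_baseline`, then
`Fz = zscore(dff)` over the whole trace with the sample-SD (n−1)
convention. Z-scoring is per recording file. Because whole-trace z-scoring
centres the *mean* of the trace at zero, the quiescent floor of a trace
with positive transients sits below Fz = 0; the Fz image of ΔF/F = 0 is
carried on the trace (`FzTrace.zero_level`) so that decay metrics can
reference the true floor instead of zero.

## Event-aligned metrics

* **PETH**: trial snippets aligned to bout onset or offset, bin-averaged
  onto a fixed grid (defaults pre = 10 s, post = 20 s, bin = 0.2 s —
  window and bin are analysis choices, configurable). Hierarchy is trials
  → per-animal mean → grand mean ± s.e.m. across animals. Trials keep raw
  Fz; there is no per-trial renormalization at this stage.
* **Pointwise significance**: per-bin two-sided one-sample t-test against
  Fz = 0 across animals, Benjamini–Hochberg step-up across bins at
  q = 0.05, flagging only bins whose group mean is *positive*
  (significantly increased responses). Zero-variance bins get p = 1 when
  the mean is zero and p = 0 otherwise. The t-test and BH machinery come
  from scipy/statsmodels; the test suite checks BH against a literal
  enumeration of the step-up definition.
* **Trial responses**: each bout's trace is normalized by subtracting Fz
  at time 0, taken as the mean of the two samples straddling the onset
  (robust to single-sample noise). A trial responds iff the normalized
  trace reaches Z ≥ 1 between onset and offset; latency is the first
  crossing. Percent-responsive is pooled over trials by default;
  per-animal averaging is available (`percent_responsive(..., mode=)`).
  Bouts overlapping a previous bout's decay are retained as trials.
* **Preference index**:
  `PI_t = (Z_t − 0.5(Z_a + Z_b)) / (|Z_t| + 0.5|Z_a + Z_b|)` over the
  three social stimuli, bounded in [−1, 1], undefined when the denominator
  vanishes. `Z` values are bout-weighted means (per-bout mean first, then
  across bouts), so long bouts do not dominate.
* **Offset decay**: time for the offset-aligned PETH to fall to 10% of its
  value at time 0, measured relative to an asymptote (the quiescent floor,
  estimated from the PETH tail or supplied as `zero_level`). For a
  plateau-then-exponential response this equals `tau_off · ln 10`. In the
  head-fixed schedule the 40-s inter-presentation interval is shorter than
  a slow (12-s) decay needs to settle, so the slow-class measurement uses
  each block's *final* presentation, whose recovery window is free of the
  next pulse.

## Behavior conventions

Bouts are half-open intervals `[onset, offset)` in seconds. Grooming of a
stimulus is folded into investigation (per stimulus); abutting same-label
bouts separated by less than one 25-Hz annotation frame are coalesced
(frame-quantization artifact). An investigation bout counts as "followed
by attack" iff an attack onset falls within `gap_max` (default 1 s,
configurable and reported) after its offset; whether intervening
behaviors disqualify a pair is not specified by the source convention, so
the gap rule is the declared proxy. Velocity is the mean per-frame
Euclidean displacement over the first 5 min of the track (25 fps).

## Circuit quantification

Starter-cell QC uses strict inequalities ("more than"): rabies brains pass
at > 70% starter cells in the target, anterograde at > 65%. Regions
adjacent to the injection site (LH, anterior MeA, and AAA for rabies) are
excluded *before* normalization. Input fractions are counts over the
post-exclusion total (summing to 1); the reported subset is fractions
> 2%. Projection intensity is
`I_norm = max(I_raw − I_background, 0) / max I_signal` (negative signal is
clamped — background can exceed signal in empty regions); reported at
I_norm ≥ 0.2 plus an always-include set (VMHvl). The 2% floor is applied
to group means by default. Point-to-line distances use infinite-line
projection, not segment clamping. Region names pass through as given;
unknown names are not an error.

## PSC detection and classification

Detection operates on the across-sweep mean current (single amplitude and
latency per cell). Baseline mean/SD come from a 50-ms window ending at
light onset. The expected polarity follows the holding potential: inward
(negative) at −70 mV (oEPSC), outward (positive) at 0 mV (oIPSC). A cell
is responsive iff the mean current deflects in the expected direction
strictly beyond 1.5× the baseline SD within 50 ms of light onset *and
stays beyond it for ≥ 0.3 ms*. The sustained-crossing requirement is
necessary: the extremum of ~1000 noise samples essentially always exceeds
1.5 SD, so a sample-wise rule alone would call every noise sweep
responsive; a real synaptic current outlasts its rise time, so the
duration requirement costs no sensitivity. Latency is the start of the
first sustained crossing; amplitude is the baseline-subtracted extremum,
sign-rectified. Classification follows the pharmacology truth table:
no ACSF response → none; ACSF response abolished by TTX and recovered
under TTX + 4-AP → monosynaptic; not recovered → polysynaptic; a response
surviving TTX is flagged inconsistent, and missing pharmacology leaves the
cell unclassifiable.

## Synthetic data: what it emulates, and what it does not

The generator produces the two recording paradigms with their schedule
constants (head-fixed: five 10-s presentations per stimulus with 40-s
intervals and ≥ 5 min between stimuli; freely-moving: minutes-long
stimulus presence with exponential investigation bout/gap structure and
optional investigation→attack sequences). Transients use a saturating
rise (tau_r = 0.2 s) during the bout and exponential decay after offset;
per-bout responses are Bernoulli with stimulus-specific probability.

Class presets encode the two response phenotypes being emulated: the
male-tuned profile responds to males only (amplitude 0.10 ΔF/F) with slow
offset decay (tau_off = 12 s, 10%-return ≈ 27.6 s > 10 s); the broadly
social profile responds to all social stimuli (amplitudes 0.08–0.10,
strongest to females) with fast offset decay. The fast class's tau_off is
1.2 s so that its 10%-return time (tau·ln 10 ≈ 2.8 s) respects the
reported sub-3-s return to baseline; a 1.5-s constant would put the
10%-return at 3.45 s, contradicting that bound. Bleaching is
multiplicative (A = 0.2, tau equal to the session length); noise is
i.i.d. Gaussian on the raw trace (SD 0.5 on F0 = 100, ~0.5% ΔF/F — sensor
rate and noise are declared defaults, not inferred from any recording).
Response probabilities default to 0.9; the 32% / 55% per-trial response
rates are used as generator settings where trial-response recovery is
exercised.

Not emulated: biophysical calcium-to-fluorescence coupling, spike
inference, motion or hemodynamic artifacts, isosbestic channels,
correlated (pink) noise, and behavioral idiosyncrasies such as bout-rate
nonstationarity. Passing tests therefore demonstrate that the pipeline's
arithmetic and detection logic recover known ground truth under a
plausible generative model — not that the model captures every property
of real recordings.

## Problem sizes and numerical notes

Acceptance-style measurements use 10 sessions per profile for PI
recovery, 6 animals for decay PETHs, 200 cohorts × 8 animals for null
calibration of the pointwise test, ~200 investigation bouts for
response-rate recovery, 20,000 cells for multinomial count fixtures, and
40 latency cases (1–20 ms × two holding potentials) at 20 kHz for the PSC
suite — sizes at which every binomial/Monte-Carlo tolerance in the test
suite is meaningful. All randomness flows through a single integer seed
per simulated object; identical (config, seed) reproduce bit-identical
outputs. Ties in BH share the fate of their rank (equal p-values are
rejected or retained together). Degenerate inputs (zero-variance traces,
empty bout selections, zero denominators) raise informative errors or
return explicit undefined/empty flags rather than NaNs, as documented per
function.

## Known limitations

* The baseline estimator's low-quantile band biases the baseline slightly
  low on noisy traces (~1.5 noise SD); whole-trace z-scoring absorbs the
  constant part of this bias.
* Offset-decay times measured through the full pipeline run ~5–15% below
  `tau_off·ln 10` because the PETH tail asymptote is estimated from a
  finite window and baseline wiggle leaks into the decay; the
  measurement is accurate well within the ±20% envelope used in tests.
* Freely-moving bout structure is memoryless (exponential); real
  investigation bouts cluster.
* `run_pipeline` orchestrates simulation-sourced runs; file-sourced runs
  are supported through the CLI stages (`preprocess`, `metrics`, ...)
  rather than the one-shot `run` command.
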