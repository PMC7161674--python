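# Methods

## The paradigm being modelled

A trace-conditioning session consists of a 5-minute quiet baseline followed
by sixteen trials at a fixed 25-s inter-stimulus interval. Each trial opens
with a symbolic tone pattern (two short grave notes for music; the same two
plus a long note a fifth higher for noxious pressure), and — in sequence A —
the announced stimulus follows. Three noxious stimuli are actually
delivered (NOC1–NOC3); the eighth trial (NOC\*) presents the
noxious-associated tones alone to probe the conditioned response (CR), and
the whole of sequence B is tones-only to probe extinction. The 25-s ISI
exists because a skin-conductance wave rises within seconds but returns to
baseline asymptotically; spacing prevents overlap of consecutive waves.
Onsets in this package are deterministic and uniformly spaced at exactly
the ISI, which makes every epoching computation exactly reproducible; the
paradigm itself only requires a minimum spacing. Trial time stamps mark
tone onset, since all response latencies are measured from stimulus
announcement.

## Electrodermal model and feature extraction

Skin conductance is treated as tonic + phasic. The phasic wave shape is a
two-exponential Bateman kernel h(t) = e^(−t/τd) − e^(−t/τr) with defaults
τr = 0.75 s, τd = 2.0 s at 32 Hz — the standard sudomotor impulse-response
model. The synthetic generator injects each response with a unit-peak
kernel so an "amplitude" is literally the phasic peak in µS, which makes
amplitude-recovery tests exact on noiseless data.

Decomposition (`eda.decompose_phasic`) estimates the tonic level as a
running 10th percentile over 30 s, smoothed by a 4-s moving average; the
floor percentile tracks the between-wave baseline even in sequence B where
every 25-s interval still contains several seconds of quiescence. The
phasic residual is clipped at zero and deconvolved by the unit-area kernel
with Tikhonov regularisation (λ = 10⁻³ of the kernel's spectral peak) to
obtain a nonnegative sudomotor driver. The driver is used only for latency
checks; all reported features are read from the phasic conductance itself,
because the wave (not the driver) is what the bedside criterion describes.

Per trial, within a 10-s search window from tone onset:

* **peak magnitude** — maximum phasic value minus the value at tone onset
  (floored at 0); subtracting the onset value makes features invariant to
  any constant offset and to residual tonic level;
* **time to peak** — first-maximum convention;
* **decay time** — time from the peak until the signal first returns to
  onset value + 10% of the magnitude. Because the true decay is
  asymptotic, a threshold is required; 10% is the package's operational
  definition. Decay tracking may continue past the search window but is
  capped at the next trial's onset.

**CR rule:** present iff M(NOC\*) > M(MUS4) and M(NOC3) > M(NOC\*), strict
inequalities, with an optional magnitude floor (default 0; the empirically
learned 0.05 µS threshold is available as a preset, kept separate because
the rule itself is ordinal while the floor is a learned quantity). Ties
fail. The rule is magnitude-only; time-to-peak and decay are compared
statistically but do not enter the decision.

## Sample Entropy

SampEn(m, r, N) = −ln(A/B): B counts ordered template pairs of length
m = 2 within tolerance r (Chebyshev distance, self-matches excluded, both
lengths drawn from the first N − m start indices), A the same for length
m + 1. The tolerance is r = 0.15 × the segment's sample SD — the universal
HRV-software convention — so the measure is scale invariant. Degenerate
zero-match cases return a distinct UNDEFINED result (NaN value with the
counts preserved) rather than infinity, so downstream tables serialise. A
constant segment has zero tolerance but identical templates still match at
distance 0, giving SampEn = 0 (perfect regularity). No detrending is
applied before the computation. Entropy is evaluated per protocol segment
(baseline, sequence A, sequence B), each with its own SD.

## Synthetic generator

`synthgen` emulates what the analysis needs to see, not the physiology in
full. GSR = constant 2 µS + low-pass (< 0.05 Hz) Gaussian-random-walk
drift + event-locked Bateman responses + white noise. Response latency is
drawn per trial from a truncated normal (1.5 ± 0.3 s on [0.5, 4] s), which
keeps latency + kernel rise (≈ 1.18 s) inside the 10-s window. Delivered
noxious responses habituate multiplicatively (0.9 per repetition);
tone-only noxious responses extinguish (0.65 per repetition) starting from
the conditioned amplitude; music trials get a fixed smaller amplitude.
Tachograms are beat-indexed: rr_k = mean + respiratory-sinus-arrhythmia
sinusoid (0.25 Hz, evaluated at the beat's cumulative time) + AR(1)-filtered
Gaussian innovations; segments are annotated where cumulative time crosses
the protocol boundaries.

Three archetypes encode the group contrasts: healthy controls and
conditioned patients (UWS_CR) have a positive conditioned amplitude and
noise-dominated, irregular tachograms; non-conditioned patients
(UWS_NOCR) have zero conditioned amplitude and a strongly autocorrelated,
RSA-dominated, hence regular tachogram. Amplitude and rhythm values are
plausible-range choices (e.g. 0.35–0.6 µS for responses to delivered
pressure, RR means 780–850 ms), fixed once as part of the generator's
design so that the qualitative contracts hold: CR detectable in HC/UWS_CR
and absent in UWS_NOCR, and mean sequence-A SampEn of UWS_CR exceeding
UWS_NOCR by a wide margin (≈ 2.4 vs ≈ 1.4 under defaults).

What the generator does **not** emulate: movement artifacts (excluded,
not corrected, in the bedside workflow), respiration and its coupling to
both signals, inter-subject amplitude heterogeneity beyond the archetype
level, and any pathology-specific ECG morphology (RR series are the input
boundary). Passing recovery tests therefore demonstrates correctness of
the pipeline's numerics on clean, model-matched data — not robustness to
real-world artifact.

## Statistics

Paired contrasts use the Wilcoxon signed-rank test (zero differences
dropped, mid-ranks for ties), unpaired contrasts the Mann-Whitney test.
Both report a signed z from the tie-corrected normal approximation without
continuity correction; the signed-rank statistic is the negative-rank sum,
so "x larger than y" prints a negative z — the convention of the
commercial packages whose outputs these mirror. The plain normal
approximation is accurate to ≈ 0.02 in p only from about n ≥ 9 (validated
exhaustively in the tests against mid-p sign-flip/permutation
enumeration); below that the deviation can reach ~0.05–0.1, and both tests
expose an `exact=True` enumeration option for such sizes.

Effect size: r = |Z|/√N (reported to two decimals), categorised as
< 0.1 not significant, [0.1, 0.3) low, [0.3, 0.5) medium, ≥ 0.5 high.
Published reports mix two N conventions — subjects versus pooled paired
observations — and the same Z can legitimately yield different r under
each (|−3.180|/√13 = 0.88 but /√26 = 0.62); both conventions are callable
and neither is silently preferred. The comparison grid evaluates every
within-group trial contrast per wave feature, adjacent-segment SampEn
contrasts, and all between-group contrasts, flagging significance at the
fixed α = 0.005 used as a multiple-comparison guard.

## One-R and prognosis

One-R discretises each attribute by Holte's algorithm: sort by value, grow
a bin until its majority class has `min_bucket` members (default 6, the
canonical small-disjunct guard), extend while the next instance carries
that class (never cutting between equal values), merge adjacent same-class
bins, place cuts at midpoints. The attribute with minimal training error
wins; ties go to column order. Boundary values fall in the lower bin,
consistent with rules printed as strict "<". Cross-validation is
stratified k-fold (default k = 10, default seed 1): within each class,
instances are shuffled by a seed-derived generator and dealt round-robin,
which makes the metrics invariant to instance order; per-fold models are
evaluated on held-out folds and pooled into one confusion matrix.

Greedy 1R attains the exhaustive single-threshold optimum on
threshold-separable tables (the case the oracle tests instantiate); on
heavily interleaved data it can be one or two errors above the brute-force
optimum, which is inherent to the algorithm, not a defect.

Confusion metrics are percentages (sensitivity, specificity, precision,
accuracy, FPR = 100 − specificity, FNR = 100 − sensitivity) plus F1 on
[0, 1]; presentation rounding is half-up to integers with raw values
retained. Note one arithmetic consequence on the packaged cohort:
precision = 8/9 = 88.9%, which rounds to 89.

Prognosis treats the bedside CR flag as the predictor and "final diagnosis
MCS within the four-week observation window" as the positive outcome. The
two patients who evolved only after six months are encoded `UWS_LATE` and
count as negatives for that window (an `late_as_positive` switch recounts
them as positives, dropping sensitivity to 80%); the four-week reading is
the one under which the flag shows sensitivity 100%, specificity 95%,
accuracy 97%.

## Problem sizes and numerical choices

Monte-Carlo suites use: 200 subjects for CR detection rates, 1000 random
series (N = 20–200) for the SampEn oracle, 50 seeds for the SampEn group
margin, 20 replicates for the statistical-power check and the pipeline
recovery — sizes at which the binomial uncertainty of each estimate is
well inside the asserted margins. Seeded `numpy` generators drive all
randomness; per-subject seeds derive from a master seed so cohorts are
bit-reproducible. Kernel truncation is at 10⁻⁴ of the peak; deconvolution
regularisation at 10⁻³ (results are insensitive over ~10⁻²–10⁻⁴ on
noiseless data, trading driver sharpness against noise amplification).

## Known limitations

* The phasic decomposition is a deterministic re-specification, not a
  re-implementation of any specific commercial/academic tool; absolute
  driver units are arbitrary (only peak locations are interpreted).
* The CR rule presumes the three probe trials are artifact-free; no
  automatic artifact rejection is provided.
* One-R is intentionally the only classifier; it is a baseline and an
  interpretability device, not a performance ceiling.
* Cohort-level statistical results on real recordings depend on signal
  properties the generator only sketches; the packaged cohort table is the
  sole real-data-derived fixture, and only counts and confusion-matrix
  arithmetic are computed from it.
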