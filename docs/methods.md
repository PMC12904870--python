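# Methods

## Scope and model

`snorelab` analyzes annotated sleep audio of OSA patients to compare the
measured (third) snore of apnea-terminated episodes against the measured
snore of episodes followed by further snoring. The acoustic model treats a
snore as a source-filter system: quasi-periodic soft-tissue vibration (the
source, fundamental 60–300 Hz) excites the resonant cavities of the upper
airway (the filter, formants F1–F3), with an additive turbulent-noise
component. All seven analysis variables are parameters of this model:
pitch trajectory and HNR describe the source, F1–F3 and F2/F1 the filter,
and SER the resulting spectral energy balance.

## Event selection

The annotation layer operates on a marker table (onset, offset, kind,
RMS level), the machine-readable equivalent of manually placed time
markers. Rules, in order:

- *Episode*: a maximal run of snore markers that stay "similar" —
  inter-onset gap ≤ 10 s (one slow breathing cycle; also prevents a run
  from spanning an apnea) and consecutive RMS level difference ≤ 8 dB.
  No published threshold exists for either constant; both are config
  fields (`AnnotationConfig`).
- *Terminal*: an episode ends in apnea iff an apnea marker (≥ 10 s, AASM)
  lies between its last snore and the next one. Inferring apneas from
  unmarked silent gaps ≥ 10 s is implemented but off by default, because
  apnea markers are assumed audio-visually confirmed while silence alone
  is weaker evidence (no airflow channel exists in DISE recordings).
- *Measurement*: episodes of ≥ 3 events contribute exactly one measured
  sound, the third; it is labeled preapneic or continuous by the terminal.
  All other events carry exclusion reasons (`not_third`, `isolated_event`,
  `opening_snore`, `maneuver`, `level_jump`).
- *Opening snore*: the first snore after an apnea is excluded and the
  episode count restarts at the next event. The alternative convention
  (discarding the interrupted episode entirely) was considered and
  rejected: restarting preserves more measurable episodes and matches the
  rationale that only the opening snore itself is acoustically atypical.
  On a toy timeline apnea→s1..s4 this means s1 is excluded and s4 (the
  third of s2..s4) is measured.
- Events overlapping maneuver or level-jump markers are excluded even if
  they would have been the measured sound; such an episode then yields no
  measurement (never a substitute event).

## Feature extraction

All features are computed at 16 kHz (signals are resampled on entry);
this covers F3 up to 4 kHz with margin and fixes FFT sizes.

**Pitch.** Frames of 40 ms with 10 ms hop. Per frame the normalized
autocorrelation r(τ) = Σx[n]x[n+τ] / √(E_head·E_tail) is evaluated; the
energy-matched denominator keeps r unbiased as the overlap shrinks, so at
the true period r estimates the periodic power fraction P_h/(P_h+P_n).
Candidate peaks in lag range [rate/300, rate/60] (a few samples of margin
keep edge peaks visible) are refined at fractional lags by interpolating
the numerator with a Hann-windowed sinc kernel (±16 taps) and the
denominator linearly — interpolating the ratio directly overshoots r > 1
on harmonic-rich signals, which would inflate HNR by ~2 dB at the 20 dB
end. Among peaks within 90 % of the best correlation the smallest lag
wins (octave-error guard). Frames with peak r < 0.45 are unvoiced. The
per-event summary is the least-squares slope of F0 over time (Hz/s, the
"pitch" variable of the comparison) plus the mean voiced F0 as an
auxiliary column; at least two voiced frames are required, else NaN.

**HNR.** Per voiced frame, HNR = 10·log₁₀(r/(1−r)) with r evaluated at a
*trend-smoothed* pitch lag: per-frame lags (octave outliers ≥ 15 % from
the median rejected) are fit linearly over time and r is read off at the
fitted lag. Evaluating r at each frame's own correlation maximum would
max-pick the noise autocorrelation fluctuation and bias the noise power
low (~ +2 dB at true HNR 20 dB). The event value is the mean of frame dB
values, clamped to [−20, +40] dB. Calibration on ground-truth synthesis
is within ±1.1 dB over true ratios of 0–20 dB.

**Formants.** The signal is resampled to 2 × 4000 Hz, pre-emphasized from
50 Hz, cut into 25 ms Gaussian-windowed frames (10 ms hop), and fit with
an order-10 autocorrelation-method linear predictor (Levinson via a
Toeplitz solve, with a 10⁻⁹ ridge). Complex root pairs with
50 Hz < f < 4000 Hz and bandwidth < 400 Hz are kept and assigned F1..F3 in
ascending order. The per-event value is the median over frames — the
summary statistic of the reference analysis tool is not documented, so
the median was chosen for robustness to tracker glitches; only frames
resolving all three slots vote, so a frame that misses F1 cannot shift F2
into the wrong slot. Recovery error on three-resonator synthetics is
< 1 % (tolerance asserted: 5 %). For a single expected resonance the
matched model order is 4 (two poles per resonance plus two).

**SER.** From the whole event's power spectrum with the DC bin excluded:
energy in (1 kHz, rate/2] over energy in (0, 1 kHz]; 1 kHz is the cutoff
most snore studies use. logSER = log₁₀(max(SER, 10⁻³)); the floor makes
the logarithm defined for events with essentially no high-band energy.
Base 10 is used throughout (the reference minima are mutually consistent
under base 10, not under the natural log). SER is scale-invariant and the
two band energies sum to the total (Parseval) to 10⁻⁶ relative.

Undefined components (silent event, unvoiced event, no resonance
structure) propagate as NaN and are dropped — with a logged count — before
testing; they are never imputed as zeros.

## Statistics

Descriptives use the n−1 standard deviation. Per variable the gate is:
Shapiro–Wilk on both groups (α = 0.05) → if both pass, Levene
(median-centered, α = 0.05) decides Student vs Welch t; any normality
failure → Mann–Whitney U. The gate is an inference — the reference report
lists which test was used per variable but not its decision rule — so a
fixed per-variable preset reproducing that assignment
(F1, F3 → Student; F2, logSER → Welch; F2/F1, HNR, pitch → Mann–Whitney)
ships as `REPORTED_TEST_ASSIGNMENT`.

U counts pairs where the first group exceeds the second (ties
half-counted), so the rank-biserial r = 2U/(n₁n₂) − 1 is +1 when the first
group is uniformly larger. Exact p-values are used for tie-free samples
with both n ≤ 20, the tie-corrected normal approximation otherwise; exact
p equals brute-force enumeration over rank assignments (tested to
n₁+n₂ = 10). Degenerate conventions: zero variance in both groups with
equal means gives p = 1; zero pooled SD gives an undefined effect size.

Cohen's d from summary statistics uses (n−1)-weighted pooling when group
sizes are known and equal-weight pooling √((s₁²+s₂²)/2) otherwise —
per-group event counts are not published, so equal-weight is the default
for recomputation from reference summaries. No multiple-testing
correction is applied by default (the reference report shows raw p-values
across seven variables); Holm adjustment is available as a config flag.
SER enters testing as logSER; interpretation stays on the raw scale.

The observed type-I error of the full gate under a Gaussian null
(n = 50/group, 1000 simulations) stays below 0.07 at nominal 0.05.

## Synthetic data

**Event generator.** A band-limited impulse train (Hann-windowed sinc
pulses at fractional sample positions — integer rounding would act as
~0.3-sample RMS jitter and decorrelate the harmonics) at f0 with optional
linear drift and cycle-to-cycle jitter, filtered through a cascade of
three second-order all-pole resonators. Independent Gaussian noise passes
through the same cascade and is mixed at an exactly measured power ratio
(the target HNR); a Tukey envelope (20 % taper) and an RMS gain set the
level. Identical seeds give bit-identical waveforms.

**Night generator.** Episodes of configurable size and terminal are laid
out with breathing-cycle inter-onset gaps (3–6 s), inter-episode gaps of
11–15 s (beyond the similarity bound), apnea silences of 12–20 s with
markers, and optionally a +10 dB opening snore after each apnea. Ground
truth labels follow the selection rules exactly, including the convention
that without an inserted opening snore the next episode's first event
becomes the excluded opening snore. Group event parameters center the
formants on the reference group means; HNR group means (8.0 vs 5.5 dB)
are package defaults preserving the reported direction (more harmonic
content before apnea), because the reference HNR cells are unreadable.

**Cohort generator.** Feature-level draws from per-variable (mean, SD)
per group — defaults are the reference summaries. Formants and F2/F1 are
Gaussians truncated to positive values with the per-event ordering
F1 < F2 < F3 enforced by redraw; SER is parameterized through Gaussian
logSER (log-normal SER), reproducing the skewness that forces the log
transform; the remaining variables are Gaussian. The F2/F1 means (2.42 vs
2.22, the ratio of the clean formant means) are package defaults for the
same unreadable-cell reason and are flagged `NON_REFERENCE`.

**What the generator does not emulate.** Real DISE audio has sedation
effects, posture changes, breathing and resumption sounds, variable
recording chains, and within-patient correlation of events; the generator
has none of these (apneas are pure silence, events are independent
draws). Passing round-trip tests therefore shows the pipeline implements
its rules and estimators correctly — not that the estimators are robust
to every artifact of clinical recordings. Note also that cycle jitter
(default 1 %) lowers the autocorrelation-measured HNR of rendered events
below the constructed component power ratio; calibration tests use
jitter 0.

## Problem sizes

Test and recomputation sizes were chosen to keep everything desk-scale:
cohort simulations use 100 replicates at n = 165/group (the scale of the
331-event reference corpus split evenly); null calibration uses 1000
simulations at n = 50/group; labeling fidelity uses a 50-episode night;
audio-level round trips use single events of 1–1.5 s and nights of 8–20
episodes.

## Known limitations

- The level-jump threshold (8 dB) and similarity gap (10 s) are
  operationalizations of visually verified criteria; results on marginal
  runs depend on them.
- The formant tracker assumes three resonances below 4 kHz; strongly
  damped (> 400 Hz bandwidth) or merged formants drop frames and can
  leave F3 undefined.
- HNR clamps at +40 dB (numerical ceiling of r → 1) and −20 dB.
- Hypopneas are not modeled as a separate class; episodes are either
  apnea-terminated or not.
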