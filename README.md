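# snorelab

Acoustic comparison of **preapneic** versus **continuous/simple** snoring
sounds in patients with obstructive sleep apnea (OSA).

Snoring that immediately precedes an apnea may carry an acoustic signature
distinct from ongoing "simple" snoring in the same patients — a potential
predictor of impending airway obstruction. `snorelab` implements the full
desk pipeline for testing this hypothesis on annotated sleep-endoscopy
(DISE) audio:

1. **Event selection** — a snoring *episode* is at least three similar
   snoring events in a row; the *third* sound of each episode is measured.
   If an apnea (≥ 10 s, AASM definition) follows, that sound is labeled
   *preapneic*; if more snoring follows, *continuous*. Opening snores after
   apneas, isolated events, maneuver-contaminated sounds and level jumps
   are excluded.
2. **Acoustic features** per measured event:
   - pitch trajectory: F0 by normalized autocorrelation, summarized as the
     least-squares slope dF0/dt in Hz/s;
   - formants F1–F3 by linear-prediction (LPC) root-finding, plus the
     F2/F1 ratio;
   - harmonics-to-noise ratio HNR = 10·log₁₀(r/(1−r)) dB, with r the
     normalized autocorrelation at the pitch period;
   - spectral energy ratio SER = E(>1 kHz)/E(≤1 kHz) and logSER = log₁₀ SER.
3. **Group statistics** — descriptive table per variable and group;
   Shapiro–Wilk/Levene-gated choice of Student t, Welch t, or
   Mann–Whitney U; Cohen's d or rank-biserial correlation r = 2U/(n₁n₂) − 1
   as effect size. SER is log-transformed before testing.
4. **Synthetic data** — since no public snore corpus exists, a
   source-filter generator (band-limited impulse train through a cascade of
   three resonators, plus cascade-filtered noise at a controlled
   harmonic-to-noise power ratio) produces events, whole annotated nights,
   and feature-level cohorts with exact ground truth.

## Worked example

Render a synthetic night, annotate it, extract features, and compare the
groups:

```python
import pandas as pd
from snorelab.audio_io import write_wav
from snorelab.synth import default_night_spec, synthesize_night
from snorelab.pipeline import RunConfig, run_pipeline

spec = default_night_spec(n_episodes=20, seed=1)
signal, markers, truth = synthesize_night(spec)
write_wav("night.wav", signal)
pd.DataFrame([{"onset_s": m.onset_s, "offset_s": m.offset_s,
               "kind": m.kind, "level_db": m.level_db}
              for m in markers]).to_csv("markers.csv", index=False)

result = run_pipeline(RunConfig(["night.wav"], ["markers.csv"], out_dir="out"))
print(result.comparison.round(4).to_string(index=False))
```

This prints (10 measured events per group from the 20 episodes; the other
68 snores are excluded by the selection rules):

```
        variable         test  statistic  p_value  effect_size   effect_kind  n_apnea  n_continuous  significant
           f1_hz    student_t    -3.2581   0.0044      -1.4570      cohens_d       10            10         True
           f2_hz    student_t     1.3053   0.2082       0.5837      cohens_d       10            10        False
           f3_hz    student_t    -0.9715   0.3442      -0.4345      cohens_d       10            10        False
           f2_f1    student_t     3.3199   0.0038       1.4847      cohens_d       10            10         True
          hnr_db    student_t     1.5684   0.1342       0.7014      cohens_d       10            10        False
pitch_slope_hz_s    student_t     2.3348   0.0313       1.0442      cohens_d       10            10         True
         log_ser mann_whitney    19.0000   0.0185      -0.6200 rank_biserial       10            10         True
```

Each row is one feature: the gate-selected test, its statistic, the
two-sided p-value, and the matching effect size. Here the generator's
preapneic group was built with a lower F1 (≈ 847 vs 929 Hz), and the
pipeline recovers that difference as significant (p = 0.0044, d = −1.46;
the effect is larger than in clinical data because a single synthetic
night has far less between-event variability than a patient cohort).

The same stages are scriptable from the shell:

```sh
snorelab synth night -o night.wav --markers markers.csv --episodes 20 --seed 1
snorelab annotate label markers.csv -o labels.csv
snorelab features extract night.wav labels.csv -o features.csv
snorelab stats compare features.csv
```

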