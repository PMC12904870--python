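"""Synthetic snore generation: source-filter events, whole nights, cohorts.

Three levels of synthesis back the test material:

* **event** — a single snore rendered by a source-filter model: an impulse
  train at the fundamental (with drift and jitter) excites a cascade of
  three second-order resonators (the upper-airway "formants"); independent
  noise passed through the same cascade is mixed at a controlled
  harmonic-to-noise power ratio.  Soft-tissue vibration exciting resonant
  cavities is exactly this structure, so every acoustic feature has a known
  ground truth.
* **night** — a timeline of snore episodes with breathing gaps, >= 10 s
  apnea silences with markers, and optional louder opening snores, plus the
  ground-truth measurement labels the annotation layer must reproduce.
* **cohort** — feature-level two-group samples drawn from the reference
  group summary statistics (SER log-normal so logSER is Gaussian).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.signal.windows import tukey

from snorelab.annotation import (
    LABEL_CONTINUOUS,
    LABEL_EXCLUDED,
    LABEL_PREAPNEIC,
    REASON_ISOLATED,
    REASON_NOT_THIRD,
    REASON_OPENING,
    EventMarker,
    LabeledEvent,
)
from snorelab.audio_io import AudioSignal, rms_db
from snorelab.reference import GROUP_SUMMARY

logger = logging.getLogger(__name__)

__all__ = [
    "SynthParams",
    "SnoreGroupModel",
    "EpisodeSpec",
    "NightSpec",
    "CohortSpec",
    "synthesize_snore_event",
    "synthesize_night_markers",
    "synthesize_night",
    "sample_feature_cohort",
    "preapneic_group_model",
    "continuous_group_model",
    "default_night_spec",
]


@dataclass
class SynthParams:
    """Controls for one synthetic snore event.

    ``hnr_db`` is the harmonic-to-noise power ratio realized exactly (as a
    measured ratio of the two rendered components) before enveloping;
    ``level_db`` is the final RMS level re full scale.
    """

    f0_hz: float = 110.0
    f0_slope_hz_s: float = 0.0
    jitter_pct: float = 1.0
    formants: tuple = ((850.0, 100.0), (2050.0, 120.0), (3220.0, 150.0))
    hnr_db: float = 10.0
    duration_s: float = 1.2
    level_db: float = -20.0

    def __post_init__(self) -> None:
        if not 40.0 <= self.f0_hz <= 400.0:
            raise ValueError(f"f0 must lie in [40, 400] Hz, got {self.f0_hz}")
        freqs = [f for f, _ in self.formants]
        if sorted(freqs) != freqs:
            raise ValueError("formant frequencies must be ascending")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")


def _resonator_cascade(x: np.ndarray, formants, rate: float) -> np.ndarray:
    """Filter through second-order all-pole resonators in series."""
    y = x
    for f, bw in formants:
        r = np.exp(-np.pi * bw / rate)
        theta = 2.0 * np.pi * f / rate
        y = lfilter([1.0 - r], [1.0, -2.0 * r * np.cos(theta), r * r], y)
    return y


_PULSE_HALF_WIDTH = 32  # taps per side of the band-limited pulse


def _impulse_train(params: SynthParams, rate: float, n: int, rng: np.random.Generator):
    """Band-limited impulse train at the (drifting, jittered) fundamental.

    Pulses are windowed-sinc kernels placed at fractional sample positions;
    integer-sample rounding would act as ~0.3-sample RMS jitter and
    decorrelate the harmonic component at high frequencies.
    """
    imp = np.zeros(n)
    ks = np.arange(-_PULSE_HALF_WIDTH, _PULSE_HALF_WIDTH + 1)
    hann = 0.5 + 0.5 * np.cos(np.pi * ks / (_PULSE_HALF_WIDTH + 1))
    t = 0.0
    while t < params.duration_s:
        pos = t * rate
        center = int(round(pos))
        if center >= n:
            break
        idx = center + ks
        ok = (idx >= 0) & (idx < n)
        imp[idx[ok]] += np.sinc(idx[ok] - pos) * hann[ok]
        f_inst = max(20.0, params.f0_hz + params.f0_slope_hz_s * t)
        period = (1.0 / f_inst) * (1.0 + params.jitter_pct / 100.0 * rng.standard_normal())
        t += max(period, 1.0 / rate)
    return imp


def _render_components(params: SynthParams, rate: float, rng: np.random.Generator):
    """(harmonic, noise) components, power-matched to the target HNR."""
    fmax, bwmax = max((f, b) for f, b in params.formants)
    if rate < 2.0 * (fmax + 2.0 * bwmax):
        raise ValueError(
            f"rate {rate} Hz too low for formant {fmax} Hz (bandwidth {bwmax} Hz)"
        )
    n = int(round(params.duration_s * rate))
    harm = _resonator_cascade(_impulse_train(params, rate, n, rng), params.formants, rate)
    if not np.isfinite(params.hnr_db):
        return harm, np.zeros(n)
    noise = _resonator_cascade(rng.standard_normal(n), params.formants, rate)
    p_h = float(np.mean(harm**2))
    p_n = float(np.mean(noise**2))
    noise *= np.sqrt(p_h / (p_n * 10.0 ** (params.hnr_db / 10.0)))
    return harm, noise


def synthesize_snore_event(
    params: Optional[SynthParams] = None,
    rate: float = 16000.0,
    seed=None,
) -> tuple:
    """Render one snore event; returns (AudioSignal, params echo).

    ``seed`` may be an int or a ``numpy.random.Generator``.  Identical
    seeds give bit-identical waveforms.
    """
    params = params or SynthParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    harm, noise = _render_components(params, rate, rng)
    x = harm + noise
    x *= tukey(len(x), alpha=0.2)  # soft attack/decay
    rms = float(np.sqrt(np.mean(x**2)))
    if rms > 0:
        x *= 10.0 ** (params.level_db / 20.0) / rms
    return AudioSignal(x, rate), replace(params)


@dataclass
class SnoreGroupModel:
    """Distribution of event parameters within one snore group."""

    name: str
    f0_mean_hz: float = 110.0
    f0_sd_hz: float = 15.0
    f0_slope_mean_hz_s: float = 20.0
    f0_slope_sd_hz_s: float = 15.0
    jitter_pct: float = 1.0
    formant_means_hz: tuple = (850.0, 2050.0, 3220.0)
    formant_sds_hz: tuple = (60.0, 60.0, 80.0)
    formant_bandwidths_hz: tuple = (100.0, 120.0, 150.0)
    hnr_mean_db: float = 8.0
    hnr_sd_db: float = 2.0
    duration_range_s: tuple = (1.0, 1.4)
    level_mean_db: float = -20.0
    level_sd_db: float = 1.0

    def draw_params(self, rng: np.random.Generator) -> SynthParams:
        f0 = float(np.clip(rng.normal(self.f0_mean_hz, self.f0_sd_hz), 60.0, 300.0))
        freqs = []
        lo = 100.0
        for m, s in zip(self.formant_means_hz, self.formant_sds_hz):
            f = float(np.clip(rng.normal(m, s), lo + 400.0, m + 4 * s))
            freqs.append(f)
            lo = f
        return SynthParams(
            f0_hz=f0,
            f0_slope_hz_s=float(rng.normal(self.f0_slope_mean_hz_s, self.f0_slope_sd_hz_s)),
            jitter_pct=self.jitter_pct,
            formants=tuple(zip(freqs, self.formant_bandwidths_hz)),
            hnr_db=float(rng.normal(self.hnr_mean_db, self.hnr_sd_db)),
            duration_s=float(rng.uniform(*self.duration_range_s)),
            level_db=float(rng.normal(self.level_mean_db, self.level_sd_db)),
        )


def preapneic_group_model() -> SnoreGroupModel:
    """Event-parameter distribution for apnea-terminated episodes."""
    return SnoreGroupModel(
        name="apnea",
        formant_means_hz=(846.73, 2046.89, 3218.38),
        hnr_mean_db=GROUP_SUMMARY["hnr_db"]["apnea"][0],
    )


def continuous_group_model() -> SnoreGroupModel:
    """Event-parameter distribution for continuous/simple snoring."""
    return SnoreGroupModel(
        name="continuous",
        formant_means_hz=(929.28, 2059.18, 3245.42),
        hnr_mean_db=GROUP_SUMMARY["hnr_db"]["continuous"][0],
    )


@dataclass
class EpisodeSpec:
    """One episode on the synthetic night: n events, how it ends, which group."""

    n_events: int = 4
    terminal: str = "none"  # "apnea" | "none"
    group: str = "continuous"  # "apnea"/"preapneic" | "continuous"

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        if self.terminal not in ("apnea", "none"):
            raise ValueError(f"terminal must be 'apnea' or 'none', got {self.terminal!r}")


@dataclass
class NightSpec:
    """A whole synthetic night: episode sequence, gap distributions, seed."""

    episodes: list = field(default_factory=list)
    interonset_range_s: tuple = (3.0, 6.0)
    episode_gap_range_s: tuple = (11.0, 15.0)  # terminal=none; > similarity bound
    apnea_gap_range_s: tuple = (12.0, 20.0)  # >= 10 s AASM minimum
    include_opening_snore: bool = True
    opening_level_boost_db: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.apnea_gap_range_s[0] < 10.0:
            raise ValueError("apnea gaps must be >= 10 s (AASM minimum)")


def default_night_spec(n_episodes: int = 10, seed: int = 0) -> NightSpec:
    """Alternating apnea/continuous episodes of 3-5 events each."""
    rng = np.random.default_rng(seed)
    episodes = []
    for i in range(n_episodes):
        terminal = "apnea" if i % 2 == 0 else "none"
        episodes.append(EpisodeSpec(
            n_events=int(rng.integers(3, 6)),
            terminal=terminal,
            group="apnea" if terminal == "apnea" else "continuous",
        ))
    return NightSpec(episodes=episodes, seed=seed)


def _group_model(name: str) -> SnoreGroupModel:
    if name in ("apnea", "preapneic"):
        return preapneic_group_model()
    return continuous_group_model()


def synthesize_night_markers(spec: NightSpec):
    """Build the night timeline without audio.

    Returns ``(markers, truth, params_by_event)``: the event/apnea marker
    list, ground-truth :class:`LabeledEvent` annotations following the
    selection criteria exactly, and the per-snore synthesis parameters
    (aligned with the snore markers, for later rendering).
    """
    rng = np.random.default_rng(spec.seed)
    markers: list = []
    truth: list = []
    event_params: list = []
    t = 2.0
    pending_opening = False

    for ep in spec.episodes:
        model = _group_model(ep.group)
        if pending_opening and spec.include_opening_snore:
            p = model.draw_params(rng)
            p = replace(p, level_db=p.level_db + spec.opening_level_boost_db)
            m = EventMarker(t, t + p.duration_s, "snore", level_db=p.level_db)
            markers.append(m)
            truth.append(LabeledEvent(m, LABEL_EXCLUDED, REASON_OPENING))
            event_params.append(p)
            t += float(rng.uniform(*spec.interonset_range_s))
            pending_opening = False

        # Without an inserted opening snore, the episode's own first event
        # directly follows the apnea, so the selection rule makes *it* the
        # excluded opening snore and the episode count restarts after it.
        opening_offset = 1 if pending_opening else 0
        pending_opening = False

        measurable = ep.n_events - opening_offset >= 3
        for j in range(ep.n_events):
            p = model.draw_params(rng)
            m = EventMarker(t, t + p.duration_s, "snore", level_db=p.level_db)
            markers.append(m)
            event_params.append(p)
            if j < opening_offset:
                truth.append(LabeledEvent(m, LABEL_EXCLUDED, REASON_OPENING))
            elif not measurable:
                truth.append(LabeledEvent(m, LABEL_EXCLUDED, REASON_ISOLATED))
            elif j - opening_offset == 2:
                label = LABEL_PREAPNEIC if ep.terminal == "apnea" else LABEL_CONTINUOUS
                truth.append(LabeledEvent(m, label))
            else:
                truth.append(LabeledEvent(m, LABEL_EXCLUDED, REASON_NOT_THIRD))
            t += float(rng.uniform(*spec.interonset_range_s))

        last_offset = markers[-1].offset_s
        if ep.terminal == "apnea":
            gap = float(rng.uniform(*spec.apnea_gap_range_s))
            markers.append(EventMarker(last_offset + 0.2, last_offset + 0.2 + gap, "apnea"))
            t = last_offset + 0.2 + gap + 1.0
            pending_opening = True
        else:
            t = markers[-1].onset_s + float(rng.uniform(*spec.episode_gap_range_s))

    snores = [m for m in markers if m.kind == "snore"]
    return markers, truth, dict(zip((id(m) for m in snores), event_params))


def synthesize_night(spec: NightSpec, rate: float = 16000.0):
    """Render the full night's audio; returns (AudioSignal, markers, truth)."""
    markers, truth, params_by_event = synthesize_night_markers(spec)
    rng = np.random.default_rng(spec.seed + 1)
    total = max(m.offset_s for m in markers) + 2.0
    x = np.zeros(int(round(total * rate)))
    for m in markers:
        if m.kind != "snore":
            continue
        p = params_by_event[id(m)]
        sig, _ = synthesize_snore_event(p, rate=rate, seed=rng)
        i0 = int(round(m.onset_s * rate))
        x[i0:i0 + len(sig.samples)] += sig.samples[: len(x) - i0]
    return AudioSignal(x, rate), markers, truth


@dataclass
class CohortSpec:
    """Feature-level two-group cohort drawn from group summary statistics.

    ``params`` maps variable -> group -> (mean, sd); the default is the
    reference summary.  SER is parameterized through logSER (Gaussian on
    the log10 scale, hence log-normal SER, mirroring the skewness that
    makes the raw ratio non-normal).
    """

    n_per_group: int = 165
    params: dict = field(default_factory=lambda: {k: dict(v) for k, v in GROUP_SUMMARY.items()})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 3:
            raise ValueError("n_per_group must be >= 3")
        for var, groups in self.params.items():
            for g, (_, sd) in groups.items():
                if sd < 0:
                    raise ValueError(f"{var}/{g}: sd must be >= 0")


_POSITIVE_VARS = ("f1_hz", "f2_hz", "f3_hz", "f2_f1")


def _truncated_normal(rng, mean, sd, n, low=0.0):
    """Gaussian draws redrawn while <= low (plain rejection; low tail mass)."""
    if sd == 0:
        return np.full(n, float(mean))
    x = rng.normal(mean, sd, size=n)
    for _ in range(100):
        bad = x <= low
        if not bad.any():
            break
        x[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return x


def sample_feature_cohort(spec: Optional[CohortSpec] = None) -> pd.DataFrame:
    """Draw a labeled feature table of two groups of ``n_per_group`` events."""
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    frames = []
    for group, label in (("apnea", LABEL_PREAPNEIC), ("continuous", LABEL_CONTINUOUS)):
        cols = {}
        for var, groups in spec.params.items():
            if group not in groups:
                continue
            mean, sd = groups[group]
            if var == "log_ser":
                cols["log_ser"] = rng.normal(mean, sd, size=spec.n_per_group)
            elif var in _POSITIVE_VARS:
                cols[var] = _truncated_normal(rng, mean, sd, spec.n_per_group)
            else:
                cols[var] = rng.normal(mean, sd, size=spec.n_per_group)
        df = pd.DataFrame(cols)
        if "log_ser" in df.columns:
            df["ser"] = 10.0 ** df["log_ser"]
        # keep the formant ordering invariant F1 < F2 < F3 per event
        if {"f1_hz", "f2_hz", "f3_hz"}.issubset(df.columns):
            bad = ~((df["f1_hz"] < df["f2_hz"]) & (df["f2_hz"] < df["f3_hz"]))
            for _ in range(100):
                if not bad.any():
                    break
                for var in ("f1_hz", "f2_hz", "f3_hz"):
                    mean, sd = spec.params[var][group]
                    df.loc[bad, var] = _truncated_normal(rng, mean, sd, int(bad.sum()))
                bad = ~((df["f1_hz"] < df["f2_hz"]) & (df["f2_hz"] < df["f3_hz"]))
        df.insert(0, "label", label)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "event_id", np.arange(len(out)))
    return out
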