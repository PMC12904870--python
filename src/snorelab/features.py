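"""Per-event acoustic features of a snore sound.

Seven variables are computed per measured snore event, matching the standard
descriptors of voice/snore acoustics:

* pitch trajectory — fundamental frequency (F0) tracked per frame by
  normalized autocorrelation, summarized as the least-squares slope in Hz/s
  (the "melody" of the event) plus an auxiliary mean F0;
* formants F1-F3 — upper-airway resonances from linear-prediction (LPC)
  root-finding, summarized as per-event medians, with the F2/F1 ratio;
* HNR — harmonics-to-noise ratio in dB, from the normalized autocorrelation
  value at the pitch period: HNR = 10 log10(r / (1 - r));
* SER — spectral energy ratio, energy above a cutoff (default 1 kHz) over
  energy below it, and its base-10 logarithm logSER.

Undefined components (unvoiced event, no resonance structure, silence)
propagate as NaN, never as zeros.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.fft import irfft, next_fast_len, rfft, rfftfreq
from scipy.linalg import solve_toeplitz
from scipy.signal.windows import gaussian as gaussian_window

from snorelab.audio_io import AudioSignal, frame_signal, resample

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureConfig",
    "PitchTrack",
    "FormantTrack",
    "FeatureVector",
    "estimate_pitch",
    "pitch_statistics",
    "estimate_formants",
    "formant_medians",
    "formant_ratio",
    "compute_hnr",
    "compute_ser",
    "extract_features",
    "FEATURE_COLUMNS",
]

FEATURE_COLUMNS = [
    "f1_hz", "f2_hz", "f3_hz", "f2_f1", "hnr_db",
    "pitch_slope_hz_s", "mean_f0_hz", "ser", "log_ser",
]


@dataclass
class FeatureConfig:
    """Analysis parameters.

    Pitch search spans 60-300 Hz: snore fundamentals sit below speech
    ranges.  Formant analysis covers up to 4 kHz, enough for F3 of snoring
    (observed up to ~4 kHz), with LPC order 10 (two poles per expected
    formant plus two).  The SER cutoff of 1 kHz is the value most snore
    studies use.
    """

    analysis_rate: float = 16000.0
    # pitch / HNR
    pitch_fmin_hz: float = 60.0
    pitch_fmax_hz: float = 300.0
    pitch_window_s: float = 0.040
    pitch_hop_s: float = 0.010
    voicing_threshold: float = 0.45
    # formants
    n_formants: int = 3
    max_formant_hz: float = 4000.0
    lpc_order: int = 10
    formant_window_s: float = 0.025
    formant_hop_s: float = 0.010
    max_formant_bandwidth_hz: float = 400.0
    min_formant_hz: float = 50.0
    preemphasis_hz: float = 50.0
    # spectral energy ratio
    ser_cutoff_hz: float = 1000.0
    ser_floor: float = 1e-3


@dataclass
class PitchTrack:
    """Frame-wise F0 estimates with voicing decisions and peak strengths."""

    times: np.ndarray
    f0_hz: np.ndarray
    voicing: np.ndarray
    strength: np.ndarray  # normalized autocorrelation at the pitch period

    def voiced_fraction(self) -> float:
        return float(np.mean(self.voicing)) if len(self.voicing) else 0.0


@dataclass
class FormantTrack:
    """Per-frame formant candidates, ascending in frequency."""

    times: np.ndarray
    formants: list  # list (per frame) of lists of (frequency_hz, bandwidth_hz)


@dataclass
class FeatureVector:
    """The per-event feature set; NaN marks an undefined component."""

    f1_hz: float = np.nan
    f2_hz: float = np.nan
    f3_hz: float = np.nan
    f2_f1: float = np.nan
    hnr_db: float = np.nan
    pitch_slope_hz_s: float = np.nan
    mean_f0_hz: float = np.nan
    ser: float = np.nan
    log_ser: float = np.nan

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in FEATURE_COLUMNS}


def _autocorrelation_parts(x: np.ndarray):
    """(ac, denom): lagged product sum and its energy normalization.

    ac[tau] = sum x[n] x[n+tau]; denom[tau] = sqrt(E_head E_tail) over the
    two overlapping segments.  r = ac/denom approximates the periodic power
    fraction P_h / (P_h + P_n) at the true period, staying unbiased as the
    overlap shrinks.
    """
    x = x - x.mean()
    n = len(x)
    e_total = float(np.dot(x, x))
    if e_total <= 0.0:
        return np.zeros(n), np.full(n, 1e-300)
    nfft = next_fast_len(2 * n)
    spec = rfft(x, nfft)
    ac = irfft(spec * np.conj(spec), nfft)[:n]
    csum = np.cumsum(x * x)
    e_head = np.empty(n)
    e_tail = np.empty(n)
    e_head[0] = e_tail[0] = e_total
    e_head[1:] = csum[-2::-1]          # sum over x[0 .. n-tau-1]^2
    e_tail[1:] = e_total - csum[:-1]   # sum over x[tau .. n-1]^2
    denom = np.sqrt(np.maximum(e_head * e_tail, 1e-300))
    return ac, denom


_INTERP_TAPS = 16


def _interp_kernel(frac: np.ndarray) -> np.ndarray:
    """Hann-windowed sinc interpolation weights for fractional offsets."""
    return np.sinc(frac) * (0.5 + 0.5 * np.cos(np.pi * frac / (_INTERP_TAPS + 1)))


def _r_at_lag(ac: np.ndarray, denom: np.ndarray, lag: float) -> float:
    """r = ac/denom evaluated at a fractional lag (windowed-sinc numerator)."""
    k = np.arange(
        max(0, int(round(lag)) - _INTERP_TAPS),
        min(len(ac), int(round(lag)) + _INTERP_TAPS + 1),
    )
    if len(k) < 3 or not (k[0] <= lag <= k[-1]):
        return 0.0
    num = float(_interp_kernel(lag - k) @ ac[k])
    den = float(np.interp(lag, k, denom[k]))
    return min(num / den, 1.0)


def _sinc_peak(ac: np.ndarray, denom: np.ndarray, k0: int, step: float = 0.01):
    """Refine a discrete peak of r = ac/denom at fractional lags.

    The product sum ``ac`` of a band-limited signal is itself band-limited,
    so it is interpolated with a windowed sinc (the peak is much sharper
    than one sample); the slowly varying energy normalization is
    interpolated linearly.  Interpolating the ratio directly would
    overshoot r > 1.  Returns (lag, value) of the maximum on [k0-1, k0+1].
    """
    lo = max(0, k0 - _INTERP_TAPS)
    hi = min(len(ac), k0 + _INTERP_TAPS + 1)
    ks = np.arange(lo, hi)
    grid = np.arange(max(lo, k0 - 1), min(hi - 1, k0 + 1) + step / 2, step)
    num = _interp_kernel(grid[:, None] - ks[None, :]) @ ac[lo:hi]
    den = np.interp(grid, ks, denom[lo:hi])
    vals = num / den
    i = int(np.argmax(vals))
    return float(grid[i]), float(min(vals[i], 1.0))


def _local_maxima(r: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Indices of local maxima of r on [lo, hi), endpoints included."""
    seg = r[lo:hi]
    if len(seg) < 3:
        return np.array([], dtype=int)
    padded = np.concatenate(([-np.inf], seg, [-np.inf]))
    idx = np.flatnonzero((padded[1:-1] > padded[:-2]) & (padded[1:-1] >= padded[2:])) + lo
    return idx


def estimate_pitch(
    signal: AudioSignal,
    fmin: Optional[float] = None,
    fmax: Optional[float] = None,
    cfg: Optional[FeatureConfig] = None,
) -> PitchTrack:
    """Frame-wise F0 by normalized autocorrelation peak search.

    Candidate peaks in the lag range [rate/fmax, rate/fmin] are refined by
    sinc interpolation; among peaks within 90% of the best correlation the
    smallest lag wins (octave-error guard).  Frames whose peak correlation
    falls below the voicing threshold are flagged unvoiced.
    """
    cfg = cfg or FeatureConfig()
    fmin = fmin if fmin is not None else cfg.pitch_fmin_hz
    fmax = fmax if fmax is not None else cfg.pitch_fmax_hz
    rate = signal.rate
    if not (0 < fmin < fmax <= rate / 2):
        raise ValueError(f"need 0 < fmin < fmax <= rate/2, got ({fmin}, {fmax})")
    frames = frame_signal(signal, cfg.pitch_window_s, cfg.pitch_hop_s)
    times, f0s, voiced, strength = [], [], [], []
    for frame, center in frames:
        x = frame.samples
        ac, denom = _autocorrelation_parts(x)
        r = ac / denom
        # a few samples of margin so peaks at the range edges stay visible
        lag_lo = max(2, int(np.floor(rate / fmax)) - 3)
        lag_hi = min(len(r) - 2, int(np.ceil(rate / fmin)) + 4)
        best_f0, best_r, is_voiced = np.nan, 0.0, False
        if lag_hi > lag_lo + 2:
            peaks = _local_maxima(r, lag_lo, lag_hi)
            if len(peaks) == 0:
                peaks = np.array([lag_lo + int(np.argmax(r[lag_lo:lag_hi]))])
            r_best = float(np.max(r[peaks]))
            # prefer the shortest-lag peak among near-best candidates
            cand = peaks[r[peaks] >= 0.9 * r_best]
            k0 = int(cand[0])
            lag, rv = _sinc_peak(ac, denom, k0)
            if lag > 0:
                best_f0 = rate / lag
                best_r = rv
                is_voiced = rv >= cfg.voicing_threshold and fmin * 0.9 <= best_f0 <= fmax * 1.1
        times.append(center)
        f0s.append(best_f0 if is_voiced else np.nan)
        voiced.append(is_voiced)
        strength.append(best_r)
    return PitchTrack(
        np.asarray(times), np.asarray(f0s), np.asarray(voiced, dtype=bool), np.asarray(strength)
    )


def pitch_statistics(track: PitchTrack):
    """(mean F0 in Hz, least-squares F0 slope in Hz/s) over voiced frames.

    Requires at least two voiced frames; otherwise both are NaN.
    """
    v = track.voicing
    if int(v.sum()) < 2:
        return np.nan, np.nan
    t = track.times[v]
    f = track.f0_hz[v]
    mean_f0 = float(np.mean(f))
    if np.ptp(t) <= 0:
        return mean_f0, np.nan
    slope = float(np.polyfit(t, f, 1)[0])
    return mean_f0, slope


def estimate_formants(
    signal: AudioSignal,
    n_formants: Optional[int] = None,
    max_formant_hz: Optional[float] = None,
    cfg: Optional[FeatureConfig] = None,
) -> FormantTrack:
    """Frame-wise formants by LPC root-finding.

    The signal is resampled to twice the formant ceiling, pre-emphasized,
    Gaussian-windowed, and fit with an autocorrelation-method linear
    predictor.  Complex root pairs with frequency inside
    (min_formant_hz, max_formant_hz) and bandwidth under the ceiling are
    kept and assigned F1..Fn in ascending frequency.
    """
    cfg = cfg or FeatureConfig()
    n_formants = n_formants or cfg.n_formants
    max_formant_hz = max_formant_hz or cfg.max_formant_hz
    work = resample(signal, 2.0 * max_formant_hz)
    rate = work.rate
    alpha = np.exp(-2.0 * np.pi * cfg.preemphasis_hz / rate)
    x = np.empty_like(work.samples)
    x[0] = work.samples[0]
    x[1:] = work.samples[1:] - alpha * work.samples[:-1]
    pre = AudioSignal(x, rate, work.t0)

    frames = frame_signal(pre, cfg.formant_window_s, cfg.formant_hop_s)
    order = cfg.lpc_order
    times, per_frame = [], []
    floor_rms = np.sqrt(np.mean(np.square(pre.samples))) * 1e-4 + 1e-12
    for frame, center in frames:
        y = frame.samples
        if np.sqrt(np.mean(np.square(y))) < floor_rms:
            continue
        w = y * gaussian_window(len(y), std=len(y) / 6.0)
        nfft = next_fast_len(2 * len(w))
        spec = rfft(w, nfft)
        ac = irfft(spec * np.conj(spec), nfft)[: order + 1]
        ac[0] *= 1.0 + 1e-9  # white-noise ridge for numerical stability
        try:
            a = solve_toeplitz(ac[:order], ac[1 : order + 1])
        except np.linalg.LinAlgError:
            logger.warning("singular prediction system at t=%.3f s; frame dropped", center)
            continue
        if not np.all(np.isfinite(a)):
            logger.warning("non-finite prediction coefficients at t=%.3f s; frame dropped", center)
            continue
        roots = np.roots(np.concatenate(([1.0], -a)))
        roots = roots[np.imag(roots) > 0]
        freqs = np.angle(roots) * rate / (2.0 * np.pi)
        bws = -np.log(np.maximum(np.abs(roots), 1e-12)) * rate / np.pi
        keep = (freqs > cfg.min_formant_hz) & (freqs < max_formant_hz) & (
            bws < cfg.max_formant_bandwidth_hz
        )
        pairs = sorted(zip(freqs[keep], bws[keep]))
        times.append(center)
        per_frame.append([(float(f), float(b)) for f, b in pairs])
    return FormantTrack(np.asarray(times), per_frame)


def formant_medians(track: FormantTrack, n_formants: int = 3) -> np.ndarray:
    """Median frequency of each formant slot over frames (NaN when absent).

    Only frames that resolved at least ``n_formants`` candidates vote, so a
    frame that missed F1 cannot shift F2 down a slot.
    """
    out = np.full(n_formants, np.nan)
    complete = [fr for fr in track.formants if len(fr) >= n_formants]
    if len(complete) >= max(1, len(track.formants) // 4):
        for i in range(n_formants):
            out[i] = float(np.median([fr[i][0] for fr in complete]))
    return out


def formant_ratio(f1: float, f2: float) -> float:
    """F2/F1; NaN when F1 is non-positive or undefined."""
    if not np.isfinite(f1) or not np.isfinite(f2) or f1 <= 0:
        return np.nan
    return f2 / f1


def compute_hnr(
    signal: AudioSignal,
    fmin: Optional[float] = None,
    fmax: Optional[float] = None,
    cfg: Optional[FeatureConfig] = None,
    track: Optional[PitchTrack] = None,
) -> float:
    """Event harmonics-to-noise ratio in dB.

    Per voiced frame, with r the normalized autocorrelation at the pitch
    period, frame HNR = 10 log10(r / (1-r)); the event value is the mean
    over voiced frames, clamped to [-20, +40] dB.  NaN when no frame is
    voiced.
    """
    cfg = cfg or FeatureConfig()
    if track is None:
        track = estimate_pitch(signal, fmin, fmax, cfg)
    v = track.voicing
    if int(v.sum()) == 0:
        return np.nan
    # Evaluate r at a trend-smoothed pitch lag rather than each frame's own
    # correlation maximum: the per-frame maximum rides on top of the noise
    # autocorrelation fluctuation and would bias the noise power low.
    rate = signal.rate
    lags = rate / track.f0_hz[v]
    t_v = track.times[v]
    med = float(np.median(lags))
    inlier = np.abs(lags - med) < 0.15 * med  # reject octave-error frames
    if int(inlier.sum()) >= 4 and np.ptp(t_v[inlier]) > 0:
        lag_fit = np.polyval(np.polyfit(t_v[inlier], lags[inlier], 1), track.times)
    else:
        lag_fit = np.full(len(track.times), med)
    frames = frame_signal(signal, cfg.pitch_window_s, cfg.pitch_hop_s)
    rs = []
    for (frame, _), voiced, lag in zip(frames, v, lag_fit):
        if not voiced:
            continue
        ac, denom = _autocorrelation_parts(frame.samples)
        r = _r_at_lag(ac, denom, lag)
        if r > 0.0:
            rs.append(r)
    if not rs:
        return np.nan
    r = np.clip(np.asarray(rs), 1e-4, 1.0 - 1e-4)
    hnr = float(np.mean(10.0 * np.log10(r / (1.0 - r))))
    return float(np.clip(hnr, -20.0, 40.0))


def compute_ser(signal: AudioSignal, cutoff_hz: Optional[float] = None,
                cfg: Optional[FeatureConfig] = None):
    """(SER, logSER): spectral energy above the cutoff over energy below it.

    Band energies come from the event's power spectrum with the DC bin
    excluded; logSER = log10(max(SER, floor)).  Returns (NaN, NaN) for a
    silent event.
    """
    cfg = cfg or FeatureConfig()
    cutoff_hz = cutoff_hz if cutoff_hz is not None else cfg.ser_cutoff_hz
    rate = signal.rate
    if not (0 < cutoff_hz < rate / 2):
        raise ValueError(f"cutoff must lie in (0, rate/2), got {cutoff_hz}")
    x = signal.samples
    spec = np.abs(rfft(x)) ** 2
    freqs = rfftfreq(len(x), d=1.0 / rate)
    power = spec[1:]  # DC excluded
    freqs = freqs[1:]
    total = float(power.sum())
    if total <= 0.0:
        return np.nan, np.nan
    low = float(power[freqs <= cutoff_hz].sum())
    high = float(power[freqs > cutoff_hz].sum())
    if low <= 0.0:
        return np.inf, np.log10(max(high, cfg.ser_floor))
    ser = high / low
    return ser, float(np.log10(max(ser, cfg.ser_floor)))


def extract_features(signal: AudioSignal, cfg: Optional[FeatureConfig] = None) -> FeatureVector:
    """Assemble the full per-event feature vector for one measured snore."""
    cfg = cfg or FeatureConfig()
    if len(signal.samples) == 0 or not np.any(signal.samples):
        return FeatureVector()
    work = resample(signal, cfg.analysis_rate) if signal.rate != cfg.analysis_rate else signal

    track = estimate_pitch(work, cfg=cfg)
    mean_f0, slope = pitch_statistics(track)
    hnr = compute_hnr(work, cfg=cfg, track=track)

    ftrack = estimate_formants(work, cfg=cfg)
    f123 = formant_medians(ftrack, cfg.n_formants)
    f1, f2, f3 = (f123.tolist() + [np.nan] * 3)[:3]
    ratio = formant_ratio(f1, f2)

    ser, log_ser = compute_ser(work, cfg=cfg)
    return FeatureVector(
        f1_hz=f1, f2_hz=f2, f3_hz=f3, f2_f1=ratio, hnr_db=hnr,
        pitch_slope_hz_s=slope, mean_f0_hz=mean_f0, ser=ser, log_ser=log_ser,
    )
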