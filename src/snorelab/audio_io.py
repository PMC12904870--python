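"""PCM WAV reading/writing, resampling, and frame slicing.

All downstream acoustic analysis operates on :class:`AudioSignal`, a mono
float waveform with a known sampling rate.  Audio is normalized to the
nominal amplitude range [-1, 1] on read; absolute level is carried only as
an RMS figure where the annotation layer needs it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

logger = logging.getLogger(__name__)

__all__ = [
    "AudioSignal",
    "AudioFormatError",
    "read_wav",
    "write_wav",
    "resample",
    "frame_signal",
    "rms_db",
]


class AudioFormatError(ValueError):
    """Raised when a file is not decodable PCM WAV audio."""


@dataclass
class AudioSignal:
    """A sampled mono waveform.

    Parameters
    ----------
    samples : ndarray of float
        Amplitudes, nominal range [-1, 1].
    rate : float
        Sampling frequency in Hz, > 0.
    t0 : float
        Start time in seconds relative to the recording origin.
    """

    samples: np.ndarray
    rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("AudioSignal samples must be one-dimensional (mono)")
        if not self.rate > 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return len(self.samples) / self.rate

    def slice(self, start_s: float, end_s: float) -> "AudioSignal":
        """Cut [start_s, end_s), times relative to the recording origin."""
        i0 = max(0, int(round((start_s - self.t0) * self.rate)))
        i1 = min(len(self.samples), int(round((end_s - self.t0) * self.rate)))
        return AudioSignal(self.samples[i0:i1].copy(), self.rate, t0=self.t0 + i0 / self.rate)


def rms_db(x: np.ndarray) -> float:
    """RMS level in dB relative to full scale (amplitude 1.0)."""
    r = float(np.sqrt(np.mean(np.square(x)))) if len(x) else 0.0
    if r <= 0.0:
        return -np.inf
    return 20.0 * np.log10(r)


# full-scale divisor per integer PCM dtype (scipy returns 24-bit as int32)
_PCM_SCALE = {
    np.dtype(np.int16): 2.0**15,
    np.dtype(np.int32): 2.0**31,
}


def read_wav(path) -> AudioSignal:
    """Read a PCM WAV file as a normalized mono :class:`AudioSignal`.

    Integer PCM (8/16/24/32-bit) is scaled to [-1, 1]; 32/64-bit float is
    taken as-is.  Stereo or multichannel audio is averaged across channels.
    """
    try:
        rate, data = wavfile.read(path)
    except ValueError as exc:
        raise AudioFormatError(f"{path}: not decodable as PCM WAV ({exc})") from exc
    if data.size == 0:
        raise AudioFormatError(f"{path}: file contains zero audio samples")
    if data.dtype == np.uint8:  # 8-bit WAV is unsigned
        x = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in _PCM_SCALE:
        x = data.astype(np.float64) / _PCM_SCALE[data.dtype]
    elif np.issubdtype(data.dtype, np.floating):
        x = data.astype(np.float64)
    else:
        raise AudioFormatError(f"{path}: unsupported sample format {data.dtype}")
    if x.ndim == 2:
        x = x.mean(axis=1)
    return AudioSignal(x, float(rate), t0=0.0)


def write_wav(path, signal: AudioSignal) -> None:
    """Write 16-bit PCM WAV.  Amplitudes are clipped to [-1, 1]."""
    x = np.clip(signal.samples, -1.0, 1.0)
    pcm = np.clip(np.round(x * 32768.0), -32768, 32767).astype(np.int16)
    wavfile.write(path, int(round(signal.rate)), pcm)


def resample(signal: AudioSignal, target_rate: float) -> AudioSignal:
    """Band-limited resampling to ``target_rate`` (polyphase FIR)."""
    if not target_rate > 0:
        raise ValueError(f"target_rate must be positive, got {target_rate}")
    if target_rate == signal.rate:
        return AudioSignal(signal.samples.copy(), signal.rate, signal.t0)
    ratio = Fraction(target_rate / signal.rate).limit_denominator(10_000)
    y = resample_poly(signal.samples, ratio.numerator, ratio.denominator)
    return AudioSignal(y, target_rate, signal.t0)


def frame_signal(signal: AudioSignal, window_s: float, hop_s: float):
    """Cut a signal into overlapping frames.

    Returns a list of ``(frame, center_time)`` pairs where ``frame`` is an
    :class:`AudioSignal` of length ``round(window_s * rate)`` and
    ``center_time`` is the frame center in seconds (recording origin).
    A signal shorter than one window yields a single whole-signal frame.
    """
    if hop_s <= 0 or window_s <= 0:
        raise ValueError("window_s and hop_s must be positive")
    if hop_s > window_s:
        raise ValueError(f"hop_s ({hop_s}) must not exceed window_s ({window_s})")
    n = len(signal.samples)
    win = int(round(window_s * signal.rate))
    hop = int(round(hop_s * signal.rate))
    if win > n:
        logger.warning(
            "window (%.3f s) longer than signal (%.3f s); using a single whole-signal frame",
            window_s, signal.duration,
        )
        return [(AudioSignal(signal.samples.copy(), signal.rate, signal.t0),
                 signal.t0 + signal.duration / 2.0)]
    out = []
    for start in range(0, n - win + 1, hop):
        frame = AudioSignal(signal.samples[start:start + win], signal.rate,
                            t0=signal.t0 + start / signal.rate)
        out.append((frame, signal.t0 + (start + win / 2.0) / signal.rate))
    return out
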