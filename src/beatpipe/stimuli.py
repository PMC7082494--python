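"""Binaural and monaural beat stimulus synthesis and envelope analysis.

A binaural beat presents two pure tones of slightly different frequency
dichotically (one per ear); the beat percept at ``f_high - f_low`` arises
centrally and is present in neither channel's spectrum nor envelope. A
monaural beat sums the two tones digitally — ``(tone_low + tone_high) / 2``
— and presents the mixture diotically, so its envelope physically contains
the beat frequency. The envelope is read out as the FFT of the magnitude of
the analytic (Hilbert) signal.
"""

from __future__ import annotations

import wave
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

__all__ = [
    "StereoStimulus",
    "PowerSpectrum",
    "synthesize_beat",
    "rms_normalize",
    "envelope_spectrum",
    "write_wav",
]

#: fraction of samples discarded at each edge before the envelope FFT,
#: to keep Hilbert edge transients out of the low-frequency peaks
EDGE_TRIM_FRACTION = 0.05


@dataclass
class PowerSpectrum:
    """One-sided power spectrum on the FFT grid of the analysed segment."""

    freqs: np.ndarray
    power: np.ndarray
    fs: float
    n_samples: int

    def peak_frequency(self, exclude_dc: bool = True) -> float:
        """Frequency of the largest power value (optionally ignoring DC)."""
        start = 1 if exclude_dc else 0
        return float(self.freqs[start + int(np.argmax(self.power[start:]))])


@dataclass
class StereoStimulus:
    """Two-channel beat stimulus with its construction metadata.

    ``kind == "binaural"`` puts the lower tone on the left channel and the
    higher tone on the right (lower tone always to the left ear);
    ``kind == "monaural"`` puts the identical summed mixture on both.
    """

    left: np.ndarray
    right: np.ndarray
    fs: float
    f_low: float
    f_high: float
    kind: str
    duration_s: float
    beat_hz: float = field(init=False)

    def __post_init__(self) -> None:
        if self.kind not in ("binaural", "monaural"):
            raise ValueError(f"unknown stimulus kind: {self.kind!r}")
        if len(self.left) != len(self.right):
            raise ValueError("left/right channel length mismatch")
        self.beat_hz = self.f_high - self.f_low


def rms_normalize(signal: np.ndarray, target_rms: float) -> np.ndarray:
    """Scale ``signal`` by a single positive factor so its RMS equals ``target_rms``.

    Raises
    ------
    ValueError
        If the signal is identically zero (scaling undefined) or the target
        is not positive.
    """
    signal = np.asarray(signal, dtype=float)
    rms = float(np.sqrt(np.mean(signal**2)))
    if rms == 0.0:
        raise ValueError("cannot RMS-normalize an all-zero signal")
    if target_rms <= 0:
        raise ValueError("target_rms must be positive")
    return signal * (target_rms / rms)


def synthesize_beat(
    kind: str,
    f_low: float,
    f_high: float,
    duration_s: float,
    fs: float,
    amplitude: float = 1.0,
) -> StereoStimulus:
    """Synthesize a binaural or monaural beat stimulus.

    Both tones start at equal (zero) phase. The monaural mixture is
    ``(tone_low + tone_high) / 2`` on both channels; the binaural stimulus
    is dichotic pure tones, lower tone left. Each output channel is
    RMS-normalized to ``amplitude / sqrt(2)`` (the RMS of a pure tone of
    peak ``amplitude``), so both channels leave at equal RMS.

    Parameters
    ----------
    kind : {"binaural", "monaural"}
    f_low, f_high : float
        Carrier frequencies in Hz, ``0 < f_low <= f_high < fs / 2``.
    duration_s : float
        Stimulus duration in seconds, > 0.
    fs : float
        Sampling rate in Hz.
    amplitude : float
        Peak-amplitude convention for the normalization target.
    """
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if not (0 < f_low <= f_high):
        raise ValueError("need 0 < f_low <= f_high")
    if f_high >= fs / 2:
        raise ValueError(
            f"carrier {f_high} Hz violates the Nyquist limit {fs / 2} Hz"
        )
    if kind not in ("binaural", "monaural"):
        raise ValueError(f"unknown stimulus kind: {kind!r}")

    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    tone_low = amplitude * np.sin(2 * np.pi * f_low * t)
    tone_high = amplitude * np.sin(2 * np.pi * f_high * t)

    target = amplitude / np.sqrt(2.0)
    if kind == "binaural":
        left = rms_normalize(tone_low, target)
        right = rms_normalize(tone_high, target)
    else:
        mix = rms_normalize((tone_low + tone_high) / 2.0, target)
        left = mix
        right = mix.copy()
    return StereoStimulus(
        left=left, right=right, fs=fs, f_low=f_low, f_high=f_high,
        kind=kind, duration_s=duration_s,
    )


def envelope_spectrum(
    channel_samples: np.ndarray,
    fs: float,
    edge_trim: float = EDGE_TRIM_FRACTION,
) -> PowerSpectrum:
    """Power spectrum of the signal envelope (magnitude of the analytic signal).

    The envelope is mean-removed before the transform so the DC term does
    not mask a low-frequency beat peak, and ``edge_trim`` of the samples at
    each end are discarded first to suppress Hilbert edge transients.
    """
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    x = np.asarray(channel_samples, dtype=float)
    envelope = np.abs(hilbert(x))
    k = int(round(edge_trim * len(envelope)))
    if k > 0:
        envelope = envelope[k:-k]
    envelope = envelope - envelope.mean()
    n = len(envelope)
    spectrum = np.fft.rfft(envelope)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    power = ((2.0 / n) * np.abs(spectrum)) ** 2
    return PowerSpectrum(freqs=freqs, power=power, fs=fs, n_samples=n)


def write_wav(stimulus: StereoStimulus, path: str) -> None:
    """Write a stereo 16-bit PCM WAV for listening/inspection.

    Channels are jointly scaled to 90% full scale; all analysis uses the
    float arrays, never the PCM export.
    """
    peak = max(np.abs(stimulus.left).max(), np.abs(stimulus.right).max())
    scale = 0.9 * 32767.0 / peak if peak > 0 else 1.0
    stacked = np.column_stack([stimulus.left, stimulus.right]) * scale
    pcm = stacked.astype(np.int16)
    with wave.open(path, "wb") as fh:
        fh.setnchannels(2)
        fh.setsampwidth(2)
        fh.setframerate(int(round(stimulus.fs)))
        fh.writeframes(pcm.tobytes())
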