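"""Band-limited synchronization indices on 8-s non-overlapping windows.

Long-range indices per electrode pair:

* PLV — ``|mean_t exp(i (phi_i - phi_j))|`` per window, averaged over
  windows. Sensitive to any consistent phase relation, including zero-lag
  (volume-conduction) coupling; amplitude-blind.
* iCOH — the imaginary part of the normalized cross-spectral coherency,
  ``Im(S_ij / sqrt(S_ii S_jj))``, with the cross-spectrum estimated as the
  mean over Hann-tapered 8-s windows and the result averaged over the
  band's frequency bins (a +-1 Hz tolerance around the beat frequency for
  the beat bands). Zero for in-phase and anti-phase coupling, hence blind
  to volume conduction.

Local indices per electrode: the mean Hilbert (analytic-signal) envelope
amplitude, and the windowed-periodogram band power ("Fourier power").

"Sliding" windows with no stated overlap are read as non-overlapping tiles
starting at the data start; a trailing partial window is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "BANDS",
    "BEAT_BAND_CENTERS",
    "BandDefinition",
    "AnalyticSignal",
    "design_fir",
    "fir_bandpass",
    "analytic_signal",
    "band_analytic",
    "plv",
    "plv_matrix",
    "hilbert_amplitude_index",
    "icoh",
    "icoh_matrix",
    "autospectrum_index",
]


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0 < self.lo < self.hi:
            raise ValueError(f"invalid band {self.name}: ({self.lo}, {self.hi})")


#: canonical analysis bands: the traditional EEG bands plus the two beat bands
BANDS: dict[str, BandDefinition] = {
    b.name: b
    for b in (
        BandDefinition("delta", 1.0, 4.0),
        BandDefinition("theta", 5.0, 8.0),
        BandDefinition("alpha", 9.0, 12.0),
        BandDefinition("beta", 13.0, 30.0),
        BandDefinition("gamma", 32.0, 48.0),
        BandDefinition("theta_beat", 6.0, 8.0),
        BandDefinition("gamma_beat", 39.0, 41.0),
    )
}

#: beat-band centre frequencies (band = centre +- 1 Hz)
BEAT_BAND_CENTERS = {"theta_beat": 7.0, "gamma_beat": 40.0}


@dataclass
class AnalyticSignal:
    """Envelope and instantaneous phase of band-limited channels x samples data."""

    amplitude: np.ndarray
    phase: np.ndarray
    fs: float


def _as_band(band) -> BandDefinition:
    if isinstance(band, BandDefinition):
        return band
    if isinstance(band, str):
        return BANDS[band]
    lo, hi = band
    return BandDefinition(f"{lo}-{hi}Hz", float(lo), float(hi))


def design_fir(fs: float, band) -> np.ndarray:
    """Linear-phase FIR band-pass taps for ``band`` at ``fs``.

    Transition width is ``max(1 Hz, 25% of the bandwidth)``; a Hamming
    window with ~3.3 / (transition / fs) taps gives >= 50 dB stopband
    attenuation one transition width beyond the band edges.
    """
    band = _as_band(band)
    if band.hi >= fs / 2:
        raise ValueError(f"band {band.name} exceeds Nyquist at fs={fs}")
    transition = max(1.0, 0.25 * (band.hi - band.lo))
    numtaps = int(round(3.3 * fs / transition))
    numtaps += 1 - numtaps % 2
    return signal.firwin(numtaps, [band.lo, band.hi], fs=fs, pass_zero=False)


def fir_bandpass(data: np.ndarray, fs: float, band) -> np.ndarray:
    """Zero-phase FIR band-pass (forward-backward application of the taps)."""
    taps = design_fir(fs, band)
    data = np.asarray(data, dtype=float)
    if data.shape[-1] <= 3 * len(taps):
        raise ValueError(
            f"data too short ({data.shape[-1]} samples) for a {len(taps)}-tap "
            "filter; provide longer data or a wider band"
        )
    return signal.filtfilt(taps, [1.0], data, axis=-1)


def analytic_signal(data: np.ndarray, fs: float) -> AnalyticSignal:
    """Envelope and phase of (already band-limited) channels x samples data."""
    z = signal.hilbert(np.asarray(data, dtype=float), axis=-1)
    return AnalyticSignal(amplitude=np.abs(z), phase=np.angle(z), fs=fs)


def band_analytic(data: np.ndarray, fs: float, band, trim: bool = True) -> AnalyticSignal:
    """Band-pass then Hilbert; optionally trim one filter length per edge.

    Trimming removes filter and Hilbert edge transients before windowing.
    """
    taps = design_fir(fs, band)
    filtered = fir_bandpass(data, fs, band)
    out = analytic_signal(filtered, fs)
    if trim:
        k = len(taps)
        out = AnalyticSignal(
            amplitude=out.amplitude[..., k:-k], phase=out.phase[..., k:-k], fs=fs
        )
    return out


def _window_count(n_samples: int, fs: float, window_s: float, minimum: int) -> tuple[int, int]:
    w = int(round(window_s * fs))
    n_win = n_samples // w
    if n_win < minimum:
        raise ValueError(
            f"need at least {minimum} full {window_s}-s window(s); "
            f"got {n_samples} samples at fs={fs}"
        )
    return n_win, w


def plv(phase_i: np.ndarray, phase_j: np.ndarray, fs: float, window_s: float = 8.0) -> float:
    """Phase-locking value between two phase series, averaged over windows.

    Per window: ``|1/N sum_t exp(i (phi_i - phi_j))|``; the returned value
    is the mean over all full non-overlapping windows (trailing partial
    window discarded). 1 = perfectly locked, ~0 = unsynchronized.
    """
    phase_i = np.asarray(phase_i, dtype=float)
    phase_j = np.asarray(phase_j, dtype=float)
    if phase_i.shape != phase_j.shape:
        raise ValueError("phase series must have equal length")
    n_win, w = _window_count(phase_i.shape[-1], fs, window_s, minimum=1)
    diffs = np.exp(1j * (phase_i[: n_win * w] - phase_j[: n_win * w])).reshape(n_win, w)
    return float(np.mean(np.abs(diffs.mean(axis=1))))


def plv_matrix(phases: np.ndarray, fs: float, window_s: float = 8.0) -> np.ndarray:
    """All-pairs PLV for channels x samples phases -> symmetric matrix, diag 1."""
    phases = np.asarray(phases, dtype=float)
    n_chan, n_samples = phases.shape
    n_win, w = _window_count(n_samples, fs, window_s, minimum=1)
    z = np.exp(1j * phases[:, : n_win * w]).reshape(n_chan, n_win, w)
    out = np.zeros((n_chan, n_chan))
    for k in range(n_win):
        zw = z[:, k, :]
        out += np.abs(zw @ zw.conj().T) / w
    return out / n_win


def hilbert_amplitude_index(
    analytic: AnalyticSignal, window_s: float = 8.0
) -> np.ndarray:
    """Per-channel mean envelope amplitude over full windows (local index)."""
    amp = np.atleast_2d(analytic.amplitude)
    n_win, w = _window_count(amp.shape[-1], analytic.fs, window_s, minimum=1)
    return amp[:, : n_win * w].mean(axis=-1)


def _windowed_fft(data: np.ndarray, fs: float, window_s: float, minimum: int):
    """Hann-tapered rFFTs of non-overlapping windows -> (windows, chan, freq)."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n_chan, n_samples = data.shape
    n_win, w = _window_count(n_samples, fs, window_s, minimum)
    taper = signal.get_window("hann", w)
    segments = data[:, : n_win * w].reshape(n_chan, n_win, w) * taper
    spectra = np.fft.rfft(segments, axis=-1).transpose(1, 0, 2)
    freqs = np.fft.rfftfreq(w, d=1.0 / fs)
    return spectra, freqs


def _band_mask(freqs: np.ndarray, band) -> np.ndarray:
    band = _as_band(band)
    if band.name in BEAT_BAND_CENTERS:
        f0 = BEAT_BAND_CENTERS[band.name]
        mask = (freqs >= f0 - 1.0) & (freqs <= f0 + 1.0)
    else:
        mask = (freqs >= band.lo) & (freqs <= band.hi)
    if not mask.any():
        raise ValueError(f"no FFT bin inside band {band.name}")
    return mask


def icoh(
    data_i: np.ndarray,
    data_j: np.ndarray,
    fs: float,
    band,
    window_s: float = 8.0,
) -> float:
    """Imaginary coherence between two channels, averaged over band bins.

    Needs >= 2 windows: with a single segment coherency has magnitude 1
    identically and the estimate is degenerate.
    """
    out = icoh_matrix(np.vstack([data_i, data_j]), fs, band, window_s)
    return float(out[0, 1])


def icoh_matrix(
    data: np.ndarray, fs: float, band, window_s: float = 8.0
) -> np.ndarray:
    """All-pairs imaginary coherence -> antisymmetric channels x channels matrix."""
    spectra, freqs = _windowed_fft(data, fs, window_s, minimum=2)
    mask = _band_mask(freqs, band)
    x = spectra[:, :, mask]  # windows x channels x band bins
    cross = np.einsum("wcf,wdf->cdf", x, x.conj()) / x.shape[0]
    auto = np.real(np.einsum("ccf->cf", cross))
    denom = np.sqrt(auto[:, None, :] * auto[None, :, :])
    coherency = np.where(denom > 0, cross / np.where(denom > 0, denom, 1.0), 0.0)
    return coherency.imag.mean(axis=-1)


def autospectrum_index(
    data: np.ndarray, fs: float, band, window_s: float = 8.0
) -> np.ndarray:
    """Per-channel Fourier band power: windowed periodogram averaged over
    windows and over the band's bins (+-1 Hz around the beat frequency for
    beat bands)."""
    spectra, freqs = _windowed_fft(data, fs, window_s, minimum=1)
    mask = _band_mask(freqs, band)
    w = spectra.shape[-1] * 2 - 2 or 1
    taper = signal.get_window("hann", w)
    scale = 2.0 / (fs * np.sum(taper**2))  # one-sided PSD convention
    psd = scale * np.abs(spectra) ** 2
    return psd[:, :, mask].mean(axis=(0, 2))
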