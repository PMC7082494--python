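"""Synthetic multi-subject beat-stimulation EEG studies with known ground truth.

The generator emulates the structure the analysis assumes: 1/f^beta
background EEG, frequency-following energy at the condition's carrier tones
(~380-420 Hz), a steady-state component at the beat frequency (7 or 40 Hz),
optionally phase-coupled electrode pairs and 60-Hz line noise, triggers
every ``trigger_interval_s`` over each block, and per-condition visual
analogue scale (VAS) ratings. Every injected parameter is copied into the
recording's ``ground_truth`` so recovery tests can close the loop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .layout import channel_layout, scalp_channels


def default_assr_topography(n_channels: int) -> np.ndarray:
    """Fronto-central Gaussian gain profile over the scalp channels.

    Steady-state auditory responses are maximal fronto-centrally; a
    spatially varying profile also keeps the component visible after
    common-average referencing (a uniform topography would be removed
    exactly by CAR).
    """
    names, xy = channel_layout(n_channels)
    scalp = scalp_channels(names)
    for anchor in ("FCz", "Cz"):
        if anchor in names:
            center = xy[names.index(anchor)]
            break
    else:
        center = xy[scalp].mean(axis=0)
    d = np.linalg.norm(xy[scalp] - center, axis=1)
    return 0.2 + 0.8 * np.exp(-((d / 1.0) ** 2))

__all__ = [
    "CONDITIONS",
    "EXPERIMENTAL_CONDITIONS",
    "CARRIERS_HZ",
    "BEATS_HZ",
    "condition_family",
    "SynthConfig",
    "SyntheticRecording",
    "generate_condition_recording",
    "generate_study",
    "generate_background",
]

#: study conditions: an eyes-closed baseline plus the 2x2 design
CONDITIONS = (
    "baseline",
    "binaural_theta",
    "binaural_gamma",
    "monaural_theta",
    "monaural_gamma",
)
EXPERIMENTAL_CONDITIONS = CONDITIONS[1:]

#: carrier tone pairs per beat-frequency family
CARRIERS_HZ = {"theta": (396.5, 403.5), "gamma": (380.0, 420.0)}
#: beat (envelope) frequency per family
BEATS_HZ = {"theta": 7.0, "gamma": 40.0}

# defaults mirror the observed monaural > binaural entrainment ordering;
# theta amplitudes are scaled up ~2x because the 1/f background carries
# roughly 6x more power at 7 Hz than at 40 Hz (amplitude ~2.4x)
_DEFAULT_ASSR_AMP = {
    "binaural_theta": 2.0,
    "monaural_theta": 4.0,
    "binaural_gamma": 1.0,
    "monaural_gamma": 2.0,
}


def condition_family(condition: str) -> str | None:
    """Beat-frequency family ("theta"/"gamma") of a condition; None for baseline."""
    if condition == "baseline":
        return None
    return condition.rsplit("_", 1)[1]


@dataclass
class SynthConfig:
    """Parameters of a synthetic study.

    Amplitudes are in microvolts. ``assr_amp`` may be a scalar (same
    steady-state amplitude in every experimental condition) or a mapping
    condition -> amplitude; the default mapping makes monaural beats entrain
    more strongly than binaural ones, as observed empirically.
    ``coupled_pairs`` entries are ``(chan_i, chan_j, (lo_hz, hi_hz),
    phase_lag_rad, coupling_strength)``.
    """

    n_subjects: int = 16
    fs: float = 2048.0
    n_channels: int = 64
    block_s: float = 480.0
    trigger_interval_s: float = 8.0
    noise_exponent: float = 1.0
    noise_scale: float = 10.0
    ffr_amp: float = 1.0
    assr_amp: float | Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_ASSR_AMP)
    )
    assr_topography: Sequence[float] | None = None
    coupled_pairs: Sequence[tuple] = ()
    coupling_amp: float = 5.0
    line_noise_amp: float = 0.0
    vas_effect: Mapping[str, float] = field(default_factory=dict)
    vas_noise_sd: float = 10.0
    vas_subject_sd: float = 10.0
    amp_jitter_sigma: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_scale < 0 or self.ffr_amp < 0 or self.coupling_amp < 0:
            raise ValueError("amplitudes must be non-negative")
        if min(self.assr_amps().values(), default=0.0) < 0:
            raise ValueError("assr_amp values must be non-negative")
        k = self.block_s / self.trigger_interval_s
        if abs(k - round(k)) > 1e-9:
            raise ValueError("trigger_interval_s must tile block_s exactly")
        for pair in self.coupled_pairs:
            _, _, _, lag, strength = pair
            if not (0.0 <= strength <= 1.0):
                raise ValueError("coupling_strength must lie in [0, 1]")
            if not (-np.pi < lag <= np.pi):
                raise ValueError("phase_lag must lie in (-pi, pi]")

    def assr_amps(self) -> dict[str, float]:
        """Per-condition steady-state amplitudes as a plain dict."""
        if isinstance(self.assr_amp, Mapping):
            return {c: float(self.assr_amp.get(c, 0.0)) for c in EXPERIMENTAL_CONDITIONS}
        return {c: float(self.assr_amp) for c in EXPERIMENTAL_CONDITIONS}

    @property
    def n_triggers(self) -> int:
        return int(round(self.block_s / self.trigger_interval_s))


@dataclass
class SyntheticRecording:
    """One block of synthetic EEG: channels x samples plus trigger metadata."""

    data: np.ndarray
    fs: float
    channel_names: list[str]
    trigger_samples: np.ndarray
    condition: str
    ground_truth: dict

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def generate_background(
    n_samples: int,
    fs: float,
    exponent: float,
    rms: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One channel of 1/f^exponent Gaussian noise with the given RMS.

    White Gaussian noise is shaped in the frequency domain by
    ``f**(-exponent / 2)`` (DC removed), giving a power spectrum ~
    ``1 / f**exponent``.
    """
    white = rng.standard_normal(n_samples)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    shaped = np.fft.irfft(spectrum * shaping, n=n_samples)
    current = np.sqrt(np.mean(shaped**2))
    if current > 0 and rms > 0:
        shaped *= rms / current
    elif rms == 0:
        shaped[:] = 0.0
    return shaped


def _narrowband_noise(
    n_samples: int, fs: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to ``band`` (spectral masking)."""
    white = rng.standard_normal(n_samples)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    out = np.fft.irfft(spectrum * mask, n=n_samples)
    rms = np.sqrt(np.mean(out**2))
    return out / rms if rms > 0 else out


def _phase_shift(x: np.ndarray, lag_rad: float) -> np.ndarray:
    """Delay every spectral component of a narrowband signal by ``lag_rad``."""
    return np.real(hilbert(x) * np.exp(-1j * lag_rad))


def generate_condition_recording(
    cfg: SynthConfig,
    condition: str,
    seed: int | np.random.SeedSequence,
    amp_gain: float = 1.0,
) -> SyntheticRecording:
    """Generate one block of synthetic EEG for one condition.

    Baseline blocks contain background (plus coupled pairs / line noise)
    only; experimental blocks add carrier tones at ``ffr_amp`` on all scalp
    channels and a beat-frequency sinusoid at the condition's
    ``assr_amp`` shaped by ``assr_topography``. ``amp_gain`` multiplies the
    injected signal amplitudes (per-subject jitter). Identical
    ``(cfg, condition, seed)`` give bit-identical output.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    rng = np.random.default_rng(seed)
    names, _ = channel_layout(cfg.n_channels)
    scalp = scalp_channels(names)
    n = int(round(cfg.block_s * cfg.fs))
    nyquist = cfg.fs / 2.0

    data = np.empty((cfg.n_channels, n))
    for ch in range(cfg.n_channels):
        data[ch] = generate_background(
            n, cfg.fs, cfg.noise_exponent, cfg.noise_scale, rng
        )

    t = np.arange(n) / cfg.fs
    family = condition_family(condition)
    truth: dict = {
        "condition": condition,
        "noise_exponent": cfg.noise_exponent,
        "noise_scale": cfg.noise_scale,
        "amp_gain": amp_gain,
        "ffr_amp": 0.0,
        "assr_amp": 0.0,
        "coupled_pairs": [list(p[:2]) + [list(p[2]), p[3], p[4]] for p in cfg.coupled_pairs],
    }

    if family is not None:
        carriers = CARRIERS_HZ[family]
        ffr_amp = cfg.ffr_amp * amp_gain
        if ffr_amp > 0:
            if max(carriers) < nyquist:
                for f_c in carriers:
                    phase = rng.uniform(0, 2 * np.pi)
                    tone = ffr_amp * np.sin(2 * np.pi * f_c * t + phase)
                    data[scalp] += tone
                truth["ffr_amp"] = ffr_amp
            else:
                warnings.warn(
                    f"carriers {carriers} exceed Nyquist at fs={cfg.fs}; "
                    "no FFR component injected"
                )
        assr_amp = cfg.assr_amps()[condition] * amp_gain
        if assr_amp > 0:
            gain = (
                default_assr_topography(cfg.n_channels)
                if cfg.assr_topography is None
                else np.asarray(cfg.assr_topography, dtype=float)
            )
            if len(gain) != len(scalp):
                raise ValueError("assr_topography length must match scalp channel count")
            phase = rng.uniform(0, 2 * np.pi)
            beat = np.sin(2 * np.pi * BEATS_HZ[family] * t + phase)
            data[scalp] += assr_amp * gain[:, None] * beat
            truth["assr_amp"] = assr_amp

    for ch_i, ch_j, band, lag, strength in cfg.coupled_pairs:
        band = tuple(band)
        shared = _narrowband_noise(n, cfg.fs, band, rng)
        indep = _narrowband_noise(n, cfg.fs, band, rng)
        amp = cfg.coupling_amp * amp_gain
        data[ch_i] += amp * shared
        data[ch_j] += amp * (
            strength * _phase_shift(shared, lag) + (1.0 - strength) * indep
        )

    if cfg.line_noise_amp > 0 and 60.0 < nyquist:
        phase = rng.uniform(0, 2 * np.pi)
        data += cfg.line_noise_amp * np.sin(2 * np.pi * 60.0 * t + phase)

    # first trigger at t = 1 s so every (-1, 7) window fits inside the block
    trigger_times = 1.0 + cfg.trigger_interval_s * np.arange(cfg.n_triggers)
    trigger_samples = np.round(trigger_times * cfg.fs).astype(int)

    return SyntheticRecording(
        data=data,
        fs=cfg.fs,
        channel_names=names,
        trigger_samples=trigger_samples,
        condition=condition,
        ground_truth=truth,
    )


def generate_study(
    cfg: SynthConfig, seed: int | None = None
) -> tuple[dict[tuple[int, str], SyntheticRecording], pd.DataFrame]:
    """Generate a full study: one recording per subject x condition plus VAS.

    Each subject gets a lognormal amplitude gain (sigma =
    ``amp_jitter_sigma``) applied to all injected signal amplitudes, and a
    Gaussian rating intercept. VAS ratings are ``50 + intercept +
    vas_effect[condition] + noise``, clipped to [0, 100], for both scales
    (mental relaxation and absorption depth).

    Returns
    -------
    recordings : dict
        ``(subject_id, condition) -> SyntheticRecording``.
    vas : pandas.DataFrame
        Columns ``subject, condition, mental_relaxation, absorption_depth``.
    """
    root = np.random.SeedSequence(cfg.seed if seed is None else seed)
    subject_seqs = root.spawn(cfg.n_subjects + 1)
    vas_rng = np.random.default_rng(subject_seqs[-1])

    recordings: dict[tuple[int, str], SyntheticRecording] = {}
    rows = []
    for s in range(cfg.n_subjects):
        seqs = subject_seqs[s].spawn(len(CONDITIONS) + 1)
        subj_rng = np.random.default_rng(seqs[-1])
        gain = float(np.exp(subj_rng.normal(0.0, cfg.amp_jitter_sigma)))
        intercept = subj_rng.normal(0.0, cfg.vas_subject_sd)
        for c, condition in enumerate(CONDITIONS):
            recordings[(s, condition)] = generate_condition_recording(
                cfg, condition, seqs[c], amp_gain=gain
            )
            shift = float(cfg.vas_effect.get(condition, 0.0))
            ratings = {
                scale: float(
                    np.clip(
                        50.0 + intercept + shift + vas_rng.normal(0.0, cfg.vas_noise_sd),
                        0.0,
                        100.0,
                    )
                )
                for scale in ("mental_relaxation", "absorption_depth")
            }
            rows.append({"subject": s, "condition": condition, **ratings})
    vas = pd.DataFrame(rows, columns=["subject", "condition", "mental_relaxation", "absorption_depth"])
    return recordings, vas


def config_to_dict(cfg: SynthConfig) -> dict:
    """JSON/YAML-serializable form of a config (round-trips via SynthConfig(**d))."""
    d = asdict(cfg)
    d["coupled_pairs"] = [list(p[:2]) + [list(p[2]), p[3], p[4]] for p in cfg.coupled_pairs]
    return d
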