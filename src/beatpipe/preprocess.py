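"""Re-referencing, filtering, resampling and epoching.

Two preprocessing branches feed the downstream analyses:

* subcortical (FFR): linked-mastoid reference, zero-phase order-4
  Butterworth high-pass at 100 Hz, epochs from -1 to 7 s around triggers;
* cortical (ASSR/connectivity): linked-mastoid then common-average
  reference, resampling to 512 Hz, zero-phase order-2 Butterworth band-pass
  1-100 Hz plus an FIR notch at 60 Hz, epochs from -1 to 8 s with
  whole-epoch baseline correction.

Zero phase means forward-backward application (``filtfilt``); the effective
filter order doubles, which is accepted and documented.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .layout import MASTOIDS
from .synth import SyntheticRecording

__all__ = [
    "Epochs",
    "rereference",
    "filter_subcortical",
    "filter_cortical",
    "resample",
    "epoch",
    "preprocess_ffr",
    "preprocess_cortical",
    "FFR_WINDOW",
    "ASSR_WINDOW",
]

logger = logging.getLogger(__name__)

FFR_WINDOW = (-1.0, 7.0)
ASSR_WINDOW = (-1.0, 8.0)


@dataclass
class Epochs:
    """Trials x channels x samples with the epoch window metadata."""

    data: np.ndarray
    fs: float
    window: tuple[float, float]
    channel_names: list[str]
    condition: str

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("epochs data must be trials x channels x samples")
        if self.data.shape[0] < 1:
            raise ValueError("need at least one trial")
        expected = int(round((self.window[1] - self.window[0]) * self.fs))
        if self.data.shape[2] != expected:
            raise ValueError(
                f"window {self.window} at fs={self.fs} implies {expected} "
                f"samples, got {self.data.shape[2]}"
            )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


def rereference(
    data: np.ndarray,
    channel_names: list[str],
    scheme: str,
    mastoid_names: tuple[str, str] = MASTOIDS,
) -> np.ndarray:
    """Re-reference channels x samples data.

    ``linked_mastoids`` subtracts the mean of the two mastoid channels from
    every channel; ``common_average`` subtracts the per-sample mean across
    all scalp (non-mastoid) channels.
    """
    data = np.asarray(data, dtype=float)
    if scheme == "linked_mastoids":
        missing = [m for m in mastoid_names if m not in channel_names]
        if missing:
            raise ValueError(f"mastoid channel(s) missing from layout: {missing}")
        idx = [channel_names.index(m) for m in mastoid_names]
        ref = data[idx].mean(axis=0)
        return data - ref
    if scheme == "common_average":
        scalp = [i for i, n in enumerate(channel_names) if n not in mastoid_names]
        ref = data[scalp].mean(axis=0)
        return data - ref
    raise ValueError(f"unknown re-reference scheme {scheme!r}")


def filter_subcortical(data: np.ndarray, fs: float) -> np.ndarray:
    """Zero-phase order-4 Butterworth high-pass at 100 Hz (FFR branch)."""
    if fs <= 400.0:
        raise ValueError(
            f"fs={fs} Hz too low for the subcortical branch; carriers near "
            "400 Hz must be representable"
        )
    sos = signal.butter(4, 100.0, btype="highpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(data, dtype=float), axis=-1)


def _notch_fir(fs: float, f0: float = 60.0, width: float = 1.0) -> np.ndarray:
    """Windowed-sinc FIR band-stop around ``f0`` (+- ``width``)."""
    numtaps = int(round(3.3 * fs / width))
    numtaps += 1 - numtaps % 2  # odd length for a type-I linear-phase FIR
    return signal.firwin(
        numtaps, [f0 - width, f0 + width], fs=fs, pass_zero="bandstop"
    )


def filter_cortical(
    data: np.ndarray, fs: float, notch_hz: float | None = 60.0, notch_width: float = 1.0
) -> np.ndarray:
    """Cortical-branch filtering: 1-100 Hz band-pass then a 60-Hz FIR notch.

    The band-pass is a zero-phase order-2 Butterworth; the notch is a
    linear-phase windowed-sinc band-stop applied forward-backward (net zero
    phase). Requires ``fs >= 256`` so the 100-Hz edge is well inside Nyquist.
    """
    if fs < 256.0:
        raise ValueError(f"fs={fs} Hz too low for 1-100 Hz cortical filtering")
    data = np.asarray(data, dtype=float)
    sos = signal.butter(2, [1.0, 100.0], btype="bandpass", fs=fs, output="sos")
    out = signal.sosfiltfilt(sos, data, axis=-1)
    if notch_hz is not None:
        taps = _notch_fir(fs, notch_hz, notch_width)
        out = signal.filtfilt(taps, [1.0], out, axis=-1)
    return out


def resample(data: np.ndarray, fs: float, fs_new: float) -> np.ndarray:
    """Polyphase resampling of channels x samples data to ``fs_new``."""
    from fractions import Fraction

    frac = Fraction(fs_new / fs).limit_denominator(1000)
    return signal.resample_poly(
        np.asarray(data, dtype=float), frac.numerator, frac.denominator, axis=-1
    )


def epoch(
    recording: SyntheticRecording | None = None,
    window: tuple[float, float] = ASSR_WINDOW,
    *,
    data: np.ndarray | None = None,
    fs: float | None = None,
    trigger_samples: np.ndarray | None = None,
    channel_names: list[str] | None = None,
    condition: str = "",
    baseline_correct: bool = False,
) -> Epochs:
    """Cut one trial per trigger whose full window lies inside the recording.

    Either pass a ``SyntheticRecording`` or the ``data``/``fs``/
    ``trigger_samples`` trio (e.g. after filtering or resampling). Trials
    whose window would cross a recording edge are dropped and logged.
    ``baseline_correct`` subtracts each trial-channel mean (whole-epoch
    baseline).
    """
    if recording is not None:
        data = recording.data
        fs = fs or recording.fs
        trigger_samples = recording.trigger_samples
        channel_names = recording.channel_names
        condition = condition or recording.condition
    if data is None or fs is None or trigger_samples is None:
        raise ValueError("need a recording or data + fs + trigger_samples")
    t_start, t_end = window
    if t_end <= t_start:
        raise ValueError("epoch window must have positive length")
    n_samples = data.shape[-1]
    offset0 = int(round(t_start * fs))
    length = int(round((t_end - t_start) * fs))

    trials = []
    dropped = 0
    for trig in np.asarray(trigger_samples, dtype=int):
        lo = trig + offset0
        hi = lo + length
        if lo < 0 or hi > n_samples:
            dropped += 1
            continue
        trials.append(data[:, lo:hi])
    if dropped:
        logger.info("epoch: dropped %d trigger(s) with out-of-bounds windows", dropped)
    if not trials:
        raise ValueError("no trigger window fits inside the recording")
    cube = np.stack(trials)
    if baseline_correct:
        cube = cube - cube.mean(axis=2, keepdims=True)
    return Epochs(
        data=cube,
        fs=float(fs),
        window=(t_start, t_end),
        channel_names=list(channel_names) if channel_names else [],
        condition=condition,
    )


def preprocess_ffr(recording: SyntheticRecording) -> Epochs:
    """Subcortical branch: linked mastoids, 100-Hz high-pass, (-1, 7) s epochs."""
    ref = rereference(recording.data, recording.channel_names, "linked_mastoids")
    filtered = filter_subcortical(ref, recording.fs)
    return epoch(
        data=filtered,
        fs=recording.fs,
        trigger_samples=recording.trigger_samples,
        channel_names=recording.channel_names,
        condition=recording.condition,
        window=FFR_WINDOW,
    )


def preprocess_cortical(
    recording: SyntheticRecording,
    fs_target: float = 512.0,
    return_continuous: bool = False,
):
    """Cortical branch: mastoid then CAR reference, resample, filter, epoch.

    With ``return_continuous=True`` the filtered continuous array (and the
    resampled trigger indices) is returned instead of epochs — connectivity
    metrics consume 8-s windows of the continuous data.
    """
    ref = rereference(recording.data, recording.channel_names, "linked_mastoids")
    fs = recording.fs
    triggers = np.asarray(recording.trigger_samples, dtype=int)
    if fs_target and fs_target != fs:
        ref = resample(ref, fs, fs_target)
        triggers = np.round(triggers * (fs_target / fs)).astype(int)
        fs = fs_target
    filtered = filter_cortical(ref, fs)
    filtered = rereference(filtered, recording.channel_names, "common_average")
    if return_continuous:
        return filtered, fs, triggers
    return epoch(
        data=filtered,
        fs=fs,
        trigger_samples=triggers,
        channel_names=recording.channel_names,
        condition=recording.condition,
        window=ASSR_WINDOW,
        baseline_correct=True,
    )
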