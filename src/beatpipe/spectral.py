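"""Evoked spectral scoring for FFR and ASSR.

The unit of analysis is a baseline-normalized power score: epochs are
averaged (phase-locked, evoked power), transformed with an FFT whose
power convention recovers amplitude — ``power = ((2/N) |X|)**2``, so a
unit-amplitude sinusoid on an exact bin scores power 1 — the mean power in
a 1-Hz bin around the target frequency is extracted, and expressed as dB
change from the same subject's baseline block at the same bin:

    dB = 10 * log10(activity / baseline)

so +3 dB is a doubling of power. Any constant-factor alternative reading of
the FFT normalization cancels in the ratio and cannot affect scores.
Normalization is done per channel first, then channels are averaged
(normalize-then-average order is fixed); FFR scores finally average the two
carriers of each beat-frequency family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .layout import scalp_channels
from .preprocess import Epochs
from .stimuli import PowerSpectrum
from .synth import BEATS_HZ, CARRIERS_HZ, condition_family

__all__ = [
    "evoked_average",
    "fft_power",
    "bin_power",
    "db_change",
    "channel_bin_powers",
    "ffr_scores",
    "assr_scores",
]


@dataclass
class SpectralScore:
    """One baseline-normalized dB score (kept for symmetry with tables)."""

    subject: int
    condition: str
    target_hz: float
    db_change: float
    scope: str = "channel_mean"


def evoked_average(epochs: Epochs) -> np.ndarray:
    """Arithmetic mean over trials -> channels x samples evoked response."""
    if epochs.n_trials < 1:
        raise ValueError("cannot average empty epochs")
    return epochs.data.mean(axis=0)


def fft_power(evoked: np.ndarray, fs: float) -> PowerSpectrum:
    """One-sided FFT power with the amplitude-recovering 2/N convention.

    ``power[f] = ((2/N) |X(f)|)**2`` for each non-negative frequency; a
    sinusoid of amplitude ``a`` on an exact grid frequency yields power
    ``a**2`` at its bin. The DC term is computed but excluded from
    downstream bin extraction.
    """
    evoked = np.asarray(evoked, dtype=float)
    n = evoked.shape[-1]
    if n < 2:
        raise ValueError("need at least two samples")
    spectrum = np.fft.rfft(evoked, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    power = ((2.0 / n) * np.abs(spectrum)) ** 2
    return PowerSpectrum(freqs=freqs, power=power, fs=fs, n_samples=n)


def bin_power(spectrum: PowerSpectrum, f0: float, width: float = 1.0) -> np.ndarray:
    """Mean power over the 1-Hz (by default) bin centred on ``f0``.

    Bin membership is frequencies within ``f0 +- width/2`` on the actual
    FFT grid, bounds inclusive; no interpolation. Works on a single
    spectrum or channels x freqs power arrays.
    """
    lo, hi = f0 - width / 2.0, f0 + width / 2.0
    if lo < spectrum.freqs[0] or hi > spectrum.freqs[-1]:
        raise ValueError(f"bin [{lo}, {hi}] Hz outside the spectrum range")
    mask = (spectrum.freqs >= lo) & (spectrum.freqs <= hi)
    mask[0] = False  # never let DC contribute
    if not mask.any():
        raise ValueError("no FFT grid frequency inside the requested bin")
    return np.asarray(spectrum.power)[..., mask].mean(axis=-1)


def db_change(activity_power, baseline_power):
    """Eq.-style dB change from baseline: ``10 log10(activity / baseline)``.

    Zero activity is floored at machine epsilon (with a warning) rather than
    returning -inf; non-positive baseline is an error.
    """
    activity = np.asarray(activity_power, dtype=float)
    baseline = np.asarray(baseline_power, dtype=float)
    if np.any(baseline <= 0):
        raise ValueError("baseline power must be strictly positive")
    if np.any(activity < 0):
        raise ValueError("activity power must be non-negative")
    if np.any(activity == 0):
        warnings.warn("zero activity power floored at machine epsilon")
        activity = np.maximum(activity, np.finfo(float).tiny)
    out = 10.0 * np.log10(activity / baseline)
    return float(out) if out.ndim == 0 else out


def channel_bin_powers(
    epochs: Epochs, targets_hz: list[float], width: float = 1.0
) -> np.ndarray:
    """scalp-channels x targets matrix of evoked bin power for one block."""
    evoked = evoked_average(epochs)
    scalp = scalp_channels(epochs.channel_names)
    spectrum = fft_power(evoked[scalp], epochs.fs)
    return np.column_stack([bin_power(spectrum, f0, width) for f0 in targets_hz])


def _score_table(
    study_epochs: dict,
    targets_for_condition,
    family_average: bool,
    width: float = 1.0,
) -> pd.DataFrame:
    subjects = sorted({s for (s, _) in study_epochs})
    rows = []
    for s in subjects:
        if (s, "baseline") not in study_epochs:
            raise ValueError(f"subject {s} has no baseline block")
        base_ep = study_epochs[(s, "baseline")]
        conditions = [c for (ss, c) in study_epochs if ss == s and c != "baseline"]
        for condition in conditions:
            family, targets = targets_for_condition(condition)
            act = channel_bin_powers(study_epochs[(s, condition)], targets, width)
            base = channel_bin_powers(base_ep, targets, width)
            scores_db = db_change(act, base)  # per channel x target
            per_target = scores_db.mean(axis=0)  # channels averaged after Eq. 1
            if family_average:
                rows.append(
                    {
                        "subject": s,
                        "condition": condition,
                        "target": family,
                        "scope": "channel_mean",
                        "db_change": float(per_target.mean()),
                    }
                )
            else:
                for f0, val in zip(targets, per_target):
                    rows.append(
                        {
                            "subject": s,
                            "condition": condition,
                            "target": f0,
                            "scope": "channel_mean",
                            "db_change": float(val),
                        }
                    )
    return pd.DataFrame(rows, columns=["subject", "condition", "target", "scope", "db_change"])


def ffr_scores(
    study_epochs: dict, family: str | None = None, width: float = 1.0
) -> pd.DataFrame:
    """FFR score table: one dB score per subject x condition x carrier family.

    ``study_epochs`` maps ``(subject, condition) -> Epochs`` (FFR branch)
    and must contain a baseline per subject. Every condition is scored at
    the carrier pair of ``family`` (both families when None): per channel
    per carrier dB vs the subject's baseline, channel-averaged, then the two
    carriers of the family averaged into one score.
    """
    families = [family] if family else list(CARRIERS_HZ)
    tables = []
    for fam in families:
        def targets_for(_condition, fam=fam):
            return fam, list(CARRIERS_HZ[fam])

        tables.append(_score_table(study_epochs, targets_for, family_average=True, width=width))
    return pd.concat(tables, ignore_index=True)


def assr_scores(study_epochs: dict, width: float = 1.0) -> pd.DataFrame:
    """ASSR score table: dB at each beat frequency (7, 40 Hz) per subject x condition."""
    def targets_for(_condition):
        return None, [BEATS_HZ["theta"], BEATS_HZ["gamma"]]

    return _score_table(study_epochs, targets_for, family_average=False, width=width)


def condition_targets(condition: str) -> dict:
    """The condition's own carrier pair and beat frequency (for reports)."""
    family = condition_family(condition)
    if family is None:
        return {}
    return {"carriers_hz": CARRIERS_HZ[family], "beat_hz": BEATS_HZ[family]}
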