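"""Synthetic electrode layout: 10/10-convention names and 2-D positions.

Positions come from the standard 10/05 montage shipped with MNE-Python and
are projected to 2-D with the usual azimuthal-equidistant map (the same
flattening used for topographic plots), which is what the Delaunay
adjacency in :mod:`beatpipe.stats` consumes.
"""

from __future__ import annotations

import warnings
from functools import lru_cache

import numpy as np

__all__ = ["channel_layout", "MASTOIDS", "scalp_channels"]

#: mastoid surrogate channels, always the last two of a layout
MASTOIDS = ("TP9", "TP10")

# 62 scalp names from the 10/10 system, ordered in spatial rows from front
# to back so that an evenly-strided subset stays spread over the scalp.
_SCALP_ORDER = [
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2", "Iz",
]


@lru_cache(maxsize=1)
def _montage_positions() -> dict:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        montage = mne.channels.make_standard_montage("standard_1005")
    return montage.get_positions()["ch_pos"]


def _project_2d(pos3d: np.ndarray) -> np.ndarray:
    """Azimuthal-equidistant projection of head-frame 3-D positions."""
    x, y, z = pos3d
    r = np.linalg.norm(pos3d)
    if r == 0:
        return np.zeros(2)
    polar = np.arccos(np.clip(z / r, -1.0, 1.0))
    azimuth = np.arctan2(y, x)
    return np.array([polar * np.cos(azimuth), polar * np.sin(azimuth)])


def channel_layout(n_channels: int) -> tuple[list[str], np.ndarray]:
    """Return ``n_channels`` channel names and their 2-D positions.

    The last two channels are always the mastoid surrogates TP9/TP10; the
    remaining ``n_channels - 2`` are an evenly spread subset of the 10/10
    scalp names (all 62 when ``n_channels == 64``).
    """
    n_scalp = n_channels - len(MASTOIDS)
    if not 1 <= n_scalp <= len(_SCALP_ORDER):
        raise ValueError(
            f"n_channels must be between 3 and {len(_SCALP_ORDER) + 2}"
        )
    idx = np.unique(np.round(np.linspace(0, len(_SCALP_ORDER) - 1, n_scalp)).astype(int))
    if len(idx) < n_scalp:  # fall back for tiny counts with rounding ties
        idx = np.arange(n_scalp)
    names = [_SCALP_ORDER[i] for i in idx] + list(MASTOIDS)
    pos = _montage_positions()
    xy = np.stack([_project_2d(np.asarray(pos[name])) for name in names])
    return names, xy


def scalp_channels(channel_names: list[str]) -> list[int]:
    """Indices of scalp (non-mastoid) channels in a layout."""
    return [i for i, n in enumerate(channel_names) if n not in MASTOIDS]
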