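"""Synthesize binaural and monaural beats and inspect their envelopes.

A monaural beat (the two tones summed and played diotically) physically
carries the beat frequency in its envelope; a binaural beat (one tone per
ear) does not — each ear receives a flat-envelope pure tone.
"""

import numpy as np

from beatpipe import envelope_spectrum, synthesize_beat

for kind in ("monaural", "binaural"):
    for family, (f_low, f_high) in {"theta": (396.5, 403.5), "gamma": (380.0, 420.0)}.items():
        stim = synthesize_beat(kind, f_low, f_high, duration_s=8.0, fs=48000.0)
        ps = envelope_spectrum(stim.left, stim.fs)
        total = ps.power.sum()
        frac = ps.power[np.argmin(np.abs(ps.freqs - stim.beat_hz))] / max(total, 1e-300)
        peak = f"envelope peak {ps.peak_frequency():5.2f} Hz" if frac > 1e-6 else "envelope flat"
        print(
            f"{kind:8s} {family:5s}: carriers {f_low:g}/{f_high:g} Hz, "
            f"beat {stim.beat_hz:g} Hz -> {peak}, "
            f"beat-bin share of envelope power {frac:6.1%}"
        )

print(
    "\nThe monaural envelope peaks at the carrier difference (7 or 40 Hz); "
    "the binaural channels have essentially no envelope energy there — the "
    "beat percept only exists once the two ears' signals meet in the brainstem."
)
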