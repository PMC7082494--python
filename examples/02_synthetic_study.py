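"""Generate a desk-scale synthetic study and look at what it contains.

Each subject contributes five 8-min-style blocks (shortened here):
an eyes-closed baseline plus the four beat conditions. Recordings carry
1/f background EEG, carrier-tone (FFR) and beat-frequency (ASSR)
components, triggers every 8 s, and per-condition VAS ratings.
"""

import numpy as np
from scipy.signal import welch

from beatpipe import SynthConfig, generate_study

cfg = SynthConfig(n_subjects=2, fs=1024.0, n_channels=16, block_s=64.0, seed=42)
recordings, vas = generate_study(cfg)

print(f"{len(recordings)} recordings ({cfg.n_subjects} subjects x 5 conditions)")
rec = recordings[(0, "monaural_gamma")]
print(f"one block: {rec.n_channels} channels x {rec.n_samples} samples "
      f"at {rec.fs:g} Hz, {len(rec.trigger_samples)} triggers")
print("injected ground truth:", {k: rec.ground_truth[k] for k in ("ffr_amp", "assr_amp")})

base = recordings[(0, "baseline")]
freqs, psd = welch(base.data[0], fs=base.fs, nperseg=4096)
mask = (freqs >= 2) & (freqs <= 80)
slope = np.polyfit(np.log(freqs[mask]), np.log(psd[mask]), 1)[0]
print(f"baseline log-log spectral slope 2-80 Hz: {slope:.2f} "
      f"(target -{cfg.noise_exponent:g} for 1/f background)")

print("\nVAS ratings (first rows):")
print(vas.head(5).to_string(index=False))
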