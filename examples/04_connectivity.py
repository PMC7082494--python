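"""PLV vs imaginary coherence on an injected coupled electrode pair.

PLV sees any stable phase relation — including the zero-lag coupling that
volume conduction produces at the scalp. iCOH discards in-phase and
anti-phase components, so it only fires when the coupling carries a real
time delay. A pair coupled at a quarter-cycle lag elevates both; a
zero-lag pair elevates PLV only.
"""

import numpy as np

from beatpipe import icoh, plv
from beatpipe.connectivity import band_analytic
from beatpipe.synth import SynthConfig, generate_condition_recording

for lag, label in ((np.pi / 2, "quarter-cycle lag"), (0.0, "zero lag")):
    cfg = SynthConfig(
        n_subjects=1, fs=512.0, n_channels=8, block_s=64.0,
        ffr_amp=0.0, assr_amp=0.0, noise_scale=1.0,
        coupled_pairs=[(0, 1, (9.0, 12.0), lag, 1.0)], coupling_amp=15.0, seed=3,
    )
    rec = generate_condition_recording(cfg, "baseline", 3)
    sig = band_analytic(rec.data[:3], cfg.fs, "alpha")
    p_coupled = plv(sig.phase[0], sig.phase[1], cfg.fs)
    p_control = plv(sig.phase[0], sig.phase[2], cfg.fs)
    ic = icoh(rec.data[0], rec.data[1], cfg.fs, "alpha")
    print(
        f"{label:18s}: PLV(coupled) = {p_coupled:.3f}, PLV(uncoupled) = "
        f"{p_control:.3f}, iCOH(coupled) = {ic:+.3f}"
    )

print(
    "\nBoth couplings lock the phases (PLV ~ 1 vs ~ 0.2 chance level), but "
    "only the lagged pair survives the imaginary-coherence projection — "
    "the zero-lag pair is indistinguishable from volume conduction."
)
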