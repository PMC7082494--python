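"""FFR and ASSR scoring: evoked FFT power as dB change from baseline.

Epochs are averaged (phase-locked power), FFT'd with the
amplitude-recovering 2/N convention, the 1-Hz bin around each target
frequency is extracted per channel, normalized as 10*log10(condition /
subject's own baseline), channel-averaged, and — for the FFR — averaged
over the two carriers of the beat family. The factorial permutation
RM-ANOVA then tests beat type x beat frequency within subjects.
"""

from beatpipe import SynthConfig, generate_study, assr_scores, ffr_scores, perm_rm_anova
from beatpipe.pipeline import FACTORIAL_ORDER
from beatpipe.preprocess import preprocess_cortical, preprocess_ffr

cfg = SynthConfig(n_subjects=6, fs=1024.0, n_channels=16, block_s=64.0, seed=7)
recordings, _ = generate_study(cfg)

ffr_table = ffr_scores({k: preprocess_ffr(r) for k, r in recordings.items()})
assr_table = assr_scores({k: preprocess_cortical(r) for k, r in recordings.items()})

print("FFR dB change from baseline (mean over subjects):")
print(ffr_table.groupby(["target", "condition"])["db_change"].mean().round(2).to_string())
print("\nASSR dB change from baseline at the beat frequencies:")
print(assr_table.groupby(["target", "condition"])["db_change"].mean().round(2).to_string())

at40 = assr_table[assr_table["target"] == 40.0]
scores = at40.pivot(index="subject", columns="condition", values="db_change")
res = perm_rm_anova(
    scores[list(FACTORIAL_ORDER)].to_numpy(), design="factorial_2x2",
    n_perm=500, seed=1, factor_names=("beat_type", "frequency"),
)
print("\n40-Hz factorial permutation RM-ANOVA:")
for name, r in res.items():
    print(f"  {name:12s} F = {r.observed_stat:7.2f}  p = {r.p:.3f}")
print(
    "\nExpect: carrier-family FFRs track the stimulated carriers; at 40 Hz "
    "monaural gamma entrains hardest, so both main effects and the "
    "interaction come out significant."
)
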