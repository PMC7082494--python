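# beatpipe

Auditory-beat EEG analysis in Python: stimulus synthesis, subcortical and
cortical entrainment scoring, sensor-space functional connectivity, and
within-subject permutation statistics — driven by a synthetic-data
generator with injected ground truth, so every stage can be validated by
parameter recovery.

## The problem

A *binaural beat* arises when two pure tones with a small frequency
mismatch (here carriers near 400 Hz, differing by 7 Hz for θ or 40 Hz for
γ) are presented one per ear: the beat percept is constructed centrally
and is present in neither ear's spectrum nor envelope. A *monaural beat* —
the same tones summed digitally, `(tone_low + tone_high) / 2`, and played
diotically — physically carries the beat in its amplitude envelope.
Comparing the two across the auditory pathway asks whether "binaural"
matters, or only rhythm does. The pipeline quantifies, within subject:

* **FFR** (frequency-following response): phase-locked spectral power at
  the carrier tones in 100-Hz high-passed, linked-mastoid-referenced EEG;
* **ASSR** (auditory steady-state response): power at the beat frequency
  in 1–100 Hz band-passed, common-average-referenced EEG;
* **functional connectivity** per frequency band (δ 1–4, θ 5–8, α 9–12,
  β 13–30, γ 32–48, θ-beat 6–8, γ-beat 39–41 Hz) on 8-s windows;
* **self-report**: visual-analogue ratings of mental relaxation and
  absorption depth, and their relation to the connectivity maps.

## The statistics at the core

Entrainment scores are baseline-normalized evoked power. Epochs are
averaged, FFT'd with the amplitude-recovering convention
`P(f) = ((2/N) |X(f)|)²`, the 1-Hz bin around each target frequency is
extracted, and expressed as

```
dB_f = 10 · log10( activity_f / baseline_f )
```

against the same subject's baseline block (+3 dB = power doubling). Long-
range synchronization uses the phase-locking value on 8-s windows,

```
PLV_ij = | (1/N) Σ_t exp( i (φ_i(t) − φ_j(t)) ) |
```

and the imaginary part of coherency,
`iCOH_ij = mean_f Im( S_ij(f) / √(S_ii(f) S_jj(f)) )`, which discards
zero-lag and anti-phase coupling (volume conduction). Inference is
permutation-based throughout and never mixes data across subjects:
repeated-measures ANOVA F statistics against within-row label
permutations, paired t against sign flips, Holm's step-down correction for
post hocs, and a cluster-based permutation test on sensor maps (paired t
per spatial-spectral point → z-scoring → |z| > 3 cluster forming over the
electrode adjacency → summed cluster mass → max-statistic null from
within-subject condition flips, clusters reported at p < 0.05 with ≥ 3
points). The neurophenomenological contrast compares each subject's two
highest- vs two lowest-rated conditions.

## Worked example

`examples/` holds one short script per capability. Generating a 6-subject
desk-scale study and scoring the ASSR (`python examples/03_spectral_scoring.py`)
prints, for the 40-Hz bin:

```
40.0    binaural_gamma    1.42
        binaural_theta   -0.14
        monaural_gamma    3.51
        monaural_theta   -0.26

40-Hz factorial permutation RM-ANOVA:
  beat_type    F =   16.74  p = 0.022
  frequency    F =  123.59  p = 0.002
  interaction  F =   94.97  p = 0.002
```

Read: only the γ conditions drive the 40-Hz bin (frequency main effect);
the monaural beat entrains roughly twice as strongly as the binaural one
(3.5 vs 1.4 dB; beat-type effect and interaction), recovering the
amplitude ordering the generator injected. `examples/04_connectivity.py`
shows the PLV/iCOH signature of lag structure:

```
quarter-cycle lag : PLV(coupled) = 0.999, PLV(uncoupled) = 0.151, iCOH(coupled) = +1.000
zero lag          : PLV(coupled) = 0.999, PLV(uncoupled) = 0.151, iCOH(coupled) = +0.000
```

A full run (`beatpipe run --demo --out out/ --seed 1`, or
`run_pipeline(demo_config())` from Python) writes score CSVs, cluster
listings, a manifest with config hash and seeds, and a plain-text summary;
reruns with the same config are byte-identical.

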