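# Methods

This note documents the models, conventions and design choices behind
beatpipe, and what the synthetic-data tests do and do not establish.

## Stimuli

Beats are built from two equal-starting-phase sine tones. Binaural: lower
tone to the left channel, higher to the right. Monaural: the diotic mixture
`(tone_low + tone_high) / 2`. Each channel is RMS-normalized to
`amplitude / √2` by a single positive factor, so both channels leave at
equal RMS; absolute SPL calibration is hardware territory and out of scope.
Envelope analysis takes the magnitude of the analytic (Hilbert) signal,
discards 5% of samples per edge (Hilbert edge transients otherwise distort
low-frequency peaks), removes the mean so the DC term cannot mask the beat
peak, and FFTs the rest. Default analysis duration is 8 s — the relevant
spectra are duration-invariant, so nothing depends on using full 8-min
stimuli. No onset ramp is applied; none is needed for any analysis
contract. WAV export (16-bit PCM, stereo) is for listening only; analysis
always uses the float arrays.

## Synthetic studies

Recordings are channels × samples in µV at configurable `fs` (default
2048 Hz, 64 channels, 480-s blocks; tests run 512–1024 Hz, 16 channels,
32–64-s blocks — every operation is fs-agnostic). Channel names and 2-D
positions come from the standard 10/05 montage (via MNE), with TP9/TP10 as
mastoid surrogates, always the last two channels.

Components, summed per channel:

* **Background**: white Gaussian noise spectrally shaped by `f^(−β/2)`
  (default β = 1, i.e. 1/f power), scaled to `noise_scale` (default 10 µV
  RMS) per channel.
* **FFR component**: sinusoids at the condition's two carriers
  (θ: 396.5/403.5 Hz; γ: 380/420 Hz), amplitude `ffr_amp` (default 1 µV)
  on all scalp channels, random phase per block. Skipped with a warning if
  the carriers exceed Nyquist (e.g. 512-Hz desk runs). No subcortical
  generative modelling is attempted.
* **ASSR component**: one sinusoid at the beat frequency (7 or 40 Hz),
  amplitude per condition — defaults binaural θ 2.0, monaural θ 4.0,
  binaural γ 1.0, monaural γ 2.0 µV — shaped by a fronto-central Gaussian
  topography (gains 0.2–1.0). Two reasons for the shape: steady-state
  responses are fronto-centrally maximal, and a spatially *uniform*
  component would be removed exactly by common-average referencing, which
  we discovered the hard way. θ amplitudes are double the γ ones because
  the 1/f background carries ≈ 6× more power at 7 Hz than at 40 Hz; the
  monaural > binaural ordering mirrors the empirical finding the pipeline
  is meant to recover. No µV values are reported for real FFRs/ASSRs at
  these parameters; the defaults are chosen for detectability at desk
  scale, not biophysical realism.
* **Coupled pairs**: per `(i, j, band, lag, strength)`, one shared
  band-limited Gaussian source injected into both channels, the second
  copy phase-shifted by `lag` via the analytic signal and mixed with an
  independent band-limited source at weight `(1 − strength)`.
* Optional common-mode 60-Hz line noise.

Triggers sit at `t = 1 + 8k` s, so all 60 paper-scale (−1, 7) s FFR
windows fit inside the block while the final (−1, 8) s ASSR window
overruns the block end and is dropped (and logged). Studies add per-subject
lognormal amplitude jitter (σ = 0.2) and VAS ratings
`50 + subject intercept + condition effect + N(0, 10)`, clipped to
[0, 100]; the default condition effect is zero on both scales, matching
the empirical null finding. The Gaussian-with-clipping noise model is a
choice; no rating distribution is documented. All injected parameters are
copied into `ground_truth`.

## Preprocessing

Subcortical branch: linked-mastoid reference, zero-phase order-4
Butterworth high-pass at 100 Hz, (−1, 7) s epochs. Cortical branch:
linked-mastoid reference, polyphase resampling to 512 Hz, zero-phase
order-2 Butterworth band-pass 1–100 Hz, then a linear-phase windowed-sinc
FIR band-stop at 60 ± 1 Hz (length ≈ 3.3·fs taps, ≥ 30 dB at the line
frequency), common-average reference over scalp channels, (−1, 8) s
epochs with whole-epoch baseline correction. "Zero phase" is
forward–backward application throughout, which doubles the effective
order — accepted, as in common practice. Trials align to the sample
nearest the trigger; no sub-sample interpolation. Bad-channel
interpolation and ICA artifact correction are deliberately absent: the
synthetic data contain no artifacts, and those stages would exercise
third-party code, not this pipeline.

## Spectral scoring

Scores use the evoked average (trials averaged before the FFT —
phase-locked power only). The FFT power convention is
`((2/N)|X|)²`, under which a sinusoid of amplitude *a* on an exact grid
frequency scores *a*² at its bin; the stated normalization "square of the
magnitude times 2/N" is ambiguous between this and `(2/N)|X|²`, but any
constant-factor reading cancels in the baseline ratio, so downstream dB
scores are unaffected — we use the amplitude-recovering reading. Bin
extraction averages the FFT grid frequencies within ± width/2 (default
1-Hz bins), bounds inclusive, no interpolation, DC always excluded. dB
normalization is per channel against the same subject's baseline at the
same bin, *then* channels are averaged (the order matters and is fixed);
FFR scores finally average the two carriers of each beat family. Scalp
channels only — mastoid surrogates are excluded from the average. Zero
activity power is floored at the smallest positive float with a warning
rather than returning −∞.

## Connectivity

Band-limiting uses a linear-phase FIR (Hamming-window design, transition
width max(1 Hz, 25% of bandwidth)) applied forward–backward; one filter
length is trimmed from each edge before windowing to drop transients.
Windows are 8-s, non-overlapping, from the data start; a trailing partial
window is discarded ("sliding" with no stated overlap is read as tiling).
PLV is computed per window from the instantaneous phase difference and
averaged over windows — a within-trial (over-time) statistic, not an
across-trials one. iCOH estimates the cross-spectrum as the mean over
Hann-tapered window FFTs (no taper is documented; Hann is the standard
choice), normalizes to coherency, and averages the imaginary part over
the band's frequency bins — for the two beat bands, the bins within
± 1 Hz of the beat frequency. At least two windows are required: a
single-segment coherency has magnitude 1 identically. iCOH is reported
signed, with row→column orientation; cluster statistics consume the
signed value. Local indices per electrode: mean Hilbert envelope
amplitude, and Hann-periodogram band power.

## Permutation inference

All tests permute within subjects only. p-values are
`count(null ≥ observed) / n_perm` (two-sided for t), floored at
`1/n_perm`; every result carries the central 95% interval of its null
distribution, the seed and `n_perm`. One-way RM-ANOVA uses the standard
within-subject decomposition `F = MS_condition / MS_(condition × subject)`.
The 2×2 factorial effects use the two-level-factor identity `F = t²` on
per-subject contrast scores; all three effects are evaluated on one shared
permutation stream (full within-row label permutations — restricted
schemes exist but the unrestricted one matches the described procedure).
Constant data yields p = 1 with a warning. Paired t uses sign flips of the
differences. Holm's step-down correction is delegated to statsmodels and
cross-checked in the tests against the sequential definition.

Cluster test: paired t at each (electrode-or-pair, band) point; the t map
is z-scored across all points of the contrast (pooled mean/SD, both
polarities together); points with |z| > 3 are clustered — within one band,
same polarity — over the spatial adjacency; cluster mass is the sum of
member values; the null collects the *maximum* |mass| per within-subject
sign-flip permutation (max-statistic FWER control; the procedure
description does not say which statistic is collected, and max-statistic
is the standard choice that delivers the stated false-alarm control);
clusters are reported at p < 0.05 with ≥ 3 points. Whether the threshold
of 3 applies to raw t or z-scored values is ambiguous in the source
procedure; we threshold z (it directly follows the z-scoring step) and
expose `threshold_on="t"` as an option. Adjacency is Delaunay
triangulation of the 2-D projected electrode positions with optional
max-distance pruning (never orphaning a channel); two electrode *pairs*
are adjacent iff they share an endpoint. Note a structural consequence of
z-scoring across points: if k of n points carry the effect, attainable z
is capped at √((n−k)/k), so the forming threshold of 3 needs the affected
fraction to be ≲ 1/10 — true at real map sizes (≥ 98 electrode points,
≥ 637 pair points), and the tests respect it.

The neurophenomenological contrast averages each subject's maps over their
two highest-rated experimental conditions minus the two lowest-rated (per
scale), then runs the one-sample (sign-flip) cluster test against zero.
Rating ties are broken by condition presentation order.

## Pipeline, determinism, problem sizes

`RunConfig` holds every seed and parameter; reruns are byte-identical and
the manifest records a hash of the scientific config (output path
excluded). The demo profile uses 8 subjects, 16 channels, 64-s blocks at
1024 Hz (kept above 2× the ~400-Hz carriers so the FFR branch runs) and
200 permutations. The test suite uses 3–8 subjects, 16 channels, 32–64-s
blocks, and 100–500 permutations; the acceptance script uses 200 null
replicate map studies at 200 permutations each. These sizes are the
package's desk-scale defaults; all operations scale to the full
16-subject / 64-channel / 8-min / 1000-permutation geometry unchanged.

## What the synthetic tests do not show

The generator produces stationary Gaussian backgrounds with exactly
sinusoidal entrainment, no ocular/muscle artifacts, no bad channels, no
head-model mixing beyond the injected pairs, and independent noise across
channels. Passing recovery tests therefore demonstrates the correctness
and calibration of the *analysis* — not that real recordings contain
effects of the injected size, nor robustness to artifacts that ICA would
normally handle. iCOH's blindness to zero-lag coupling means truly
instantaneous physiological coupling is indistinguishable from volume
conduction by design, in the synthetic world as in the real one.
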