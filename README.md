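# bistable-alpha

Does posterior alpha power stabilize a perceptual interpretation?
`bistable_alpha` is a tested re-implementation of the analysis chain that
links parieto-occipital alpha-band EEG power (7–11 Hz, peak 9 Hz) to the
duration of individual bistable percepts during Necker-cube viewing, and
that asks whether the percept-lengthening effect of sleep deprivation is
mediated by its known enhancement of eyes-open alpha power.

It is aimed at EEG researchers who want to reproduce, probe, or extend
this style of percept-duration analysis: every stage — percept epoching,
Welch band power, frequency-domain beamforming, nested mixed-effects
regression, Sobel mediation — is a library function with a documented
contract, validated against synthetic data with known ground truth.

## The model

Each button press opens a percept; its duration `d` is the interval to
the next press (percepts outside 1.5–60 s are excluded). With `P` the
7–11 Hz posterior alpha power of the percept's stable interval, the core
regression is a linear mixed-effects model (LMEM) over the four nested
levels of the design — subject *i*, day *j*, session *k*, percept *l*:

    log d_ijkl = β₀ + β₁ · log P_ijkl + u_i + u_ij + u_ijk + ε_ijkl

fit by maximum likelihood, with the Wald statistic z = β̂₁/SE(β̂₁)
referred to the standard normal. Source-level maps repeat the regression
per voxel on DICS beamformer power (unit-gain minimum-variance filters
`w = C'⁻¹l / (lᵀC'⁻¹l)` from the 9 ± 2 Hz multitaper CSD, 5%
regularization, common filter per session), masked one-sided at
z ≥ 2.326. The sleep-deprivation (SD) mediation is the LMEM Sobel test:

    a  : log P ~ SD          (alpha path)
    b,c: log d ~ log P + SD  (coupling path, direct path)
    ab = a·b,  se_ab = √(a²σ_b² + b²σ_a²),  z = ab / se_ab

Because the study's recordings are not deposited, the package includes a
first-class synthetic-data module: gamma-distributed percept durations
(truncated mean calibrated to 8.87 s), a latent alpha log-power that
couples to log duration (b = 0.111) and shifts under sleep deprivation
(a = 0.202, direct effect c = 0.222), nested random intercepts, a 9 Hz
posterior-dominant oscillation on 1/f noise, and a transient alpha dip
around reversals. See `docs/methods.md` for every assumption and default.

## Worked example

```python
from bistable_alpha import Config, GenParams, run_pipeline

cfg = Config(n_channels=16,
             sim=GenParams(n_subjects=8, n_days=2, n_sessions=2,
                           session_length=240, sfreq=256.0))
manifest = run_pipeline(cfg, seed=1, outdir="out")
```

This simulates 32 four-minute sessions of 16-channel EEG, preprocesses
them (average reference, 0.5 Hz high-pass, 50 Hz notch), epochs the
presses, measures per-percept posterior alpha power, and runs every
statistic. With seed 1 it prints/stores:

```
percepts: 778 (758 included)
NS duration mean 10.39 s, median 8.63 s
return transitions 9.2%
alpha slope 0.090 log(s)/log(uV^2), se 0.038, z 2.38, n 387
KS D 0.191
mediation a 0.156 (0.057)  b 0.114 (0.029)  c 0.170 (0.073)
mediated effect ab 0.0178 (0.0079), Sobel z 2.26, p 0.0240
tfr alpha dip at 0.0 s
```

Reading: longer percepts carried more alpha power (0.090 log-seconds per
log-µV², Wald z = 2.38); sleep deprivation shifted the duration
distribution (KS D) and raised alpha power (path a); the Sobel test
attributes a significant part of the duration increase to that alpha
increase (ab = a·b, z = 2.26). The reversal-locked time–frequency map
puts the alpha minimum at the button press. At this moderate simulation
size the estimates scatter around the generative values (b = 0.111,
a = 0.202) within their standard errors; the acceptance and test suites
quantify recovery at larger n.

The same stages are available as CLI verbs:

```sh
bistable-alpha simulate --out sim/ --seed 1 --write-recordings
bistable-alpha epochs --events sim/events.tsv --out percepts.tsv
bistable-alpha power --recording sim/S01_D1_R1.npz --percepts percepts.tsv --out power.tsv
bistable-alpha regress --power power.tsv
bistable-alpha mediate --power power.tsv
bistable-alpha run --config cfg.yaml --seed 1 --out out/
```

## Layout

| Module | Role |
| --- | --- |
| `synthdata` | percept tables, EEG synthesis, toy leadfields |
| `percepts` | press events → percept table, inclusion rule, windowing |
| `spectral` | Welch PSD, band power, sliding windows, TFR, multitaper CSD, pre-reversal time course |
| `beamformer` | DICS filters, per-percept source power, voxel z-maps |
| `inference` | nested LMEMs, Wald tests, KS, Sobel mediation |
| `pipeline` | preprocessing, configuration, end-to-end orchestration, manifest |
| `cli` | `bistable-alpha` command group |
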