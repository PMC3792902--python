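# pulsecam

Non-contact measurement of heart rate (HR) and respiration rate (RR) from
ordinary single-channel video, with a built-in liveness check that rejects
photographs, drawings and other inanimate human-shaped figures.

A camera pointed at exposed skin records tiny periodic brightness
fluctuations caused by the cardiac blood-volume pulse (remote
photoplethysmography), and a chest/shoulder region records the slower
respiratory motion. `pulsecam` turns those fluctuations into rate
estimates for humans and laboratory animals (mouse, zebrafish, pig
presets included), and is aimed at researchers who need contactless vital
signs: sleep and infant monitoring, animal welfare, behavioural
experiments where electrodes are impractical.

## Method

For each analysis window, the spatially averaged ROI brightness series
x(t) is processed as:

1. **Detrending** with the smoothness-priors estimator: the trend is
   `(I + λ²D₂ᵀD₂)⁻¹x` with D₂ the second-difference operator (λ = 20 for
   the cardiac band, λ = 300 for respiration at 15 fps), then the series
   is normalised to zero mean and unit variance.
2. **Delay-coordinate embedding**: the state space of the underlying
   cardio-respiratory dynamics is reconstructed from lagged copies of the
   single observation, `X[i, j] = x[j + i·d]`, with dimension m = 3 and
   delay d = 1.
3. **FastICA** (kurtosis contrast, symmetric decorrelation) unmixes the
   embedding into three independent sources; the source whose one-sided
   periodogram concentrates the largest fraction of its 0–8 Hz power in a
   single bin — the peak-power-density ratio R — is the physiological
   component.
4. **Waveform and rate**: the selected source is smoothed with a centred
   moving average (5 points for pulse, 13 for respiration), passed through
   three layers of normalised autocorrelation to suppress residual noise,
   and Fourier transformed with heavy zero padding; the spectral peak
   inside the physiological band, times 60, is the rate per minute.
5. **Liveness**: the statistic ν = |R_post − R_pre| / R_pre measures how
   much smoothing changes the power concentration of the source signal.
   Live subjects give small ν (Gamma-distributed, a = 1.5335,
   b = 0.0599); inanimate figures give large, roughly Gaussian ν
   (µ = 0.4905, σ = 0.1434). A measurement is live iff the live density
   exceeds the inanimate one at the observed ν; accumulating the
   normalised liveness probability over three successive 10 s windows
   (started 5 s apart) sharply lowers both error rates.

## Worked example

Simulate a 30 s scene at 15 fps (ground truth: 72 bpm, 15 breaths/min)
and measure it back:

```sh
$ pulsecam simulate scene.json --out scene_frames
wrote 450 frames and ground_truth.json to scene_frames

$ pulsecam measure scene_frames --channel mono \
    --roi-bvp 8,6,20,16 --roi-resp 8,30,32,12 \
    --window 30 --stride 30 --out result --seed 1
HR (median over 1 windows): 72 bpm
RR (median over 1 windows): 15 breaths/min
liveness: live
wrote result.csv, result.json
```

where `scene.json` is
`{"duration": 30.0, "frame_rate": 15.0, "hr_freq": 1.2, "rr_freq": 0.25,
"cardiac_amp": 4.0, "resp_amp": 5.0, "noise_sd": 1.0, "seed": 77}`.
The CSV holds one row per analysis window:

```
t_center_s,hr_bpm,rr_bpm,hr_peak_freq_hz,rr_peak_freq_hz,hr_peak_ratio,rr_peak_ratio,valid,liveness_flag
15.0,72.0703125,15.1611328125,1.201171875,0.252685546875,0.0542...,0.0547...,True,live
```

The unrounded 72.07 bpm reflects the FFT grid (15 Hz / 4096 bins ≈
0.22 bpm); the liveness flag comes from the accumulated three-window
rule (the per-window ν values, here ≈ 0.01–0.02, sit deep in the live
Gamma density). `pulsecam agree pairs.csv --out agreement` computes
Bland–Altman statistics (mean difference, ±1.96 SD limits, RMSE, Pearson
r) between a method and a reference rate series and writes the classic
plot.

As a library:

```python
from pulsecam import SceneParams, generate_vital_series, \
    estimate_vitals, RateConfig, DetrendConfig

series = generate_vital_series(SceneParams(seed=7), "cardiac")
est = estimate_vitals(series, RateConfig.bvp(), DetrendConfig.bvp())[0]
print(f"{est.rate:.1f} bpm")        # 72.1 bpm
```

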