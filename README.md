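# binsum — binaural combination of amplitude-modulated tones

`binsum` models how the brain combines amplitude-modulation (AM) signals
across the two ears, for researchers in auditory psychophysics and
steady-state electrophysiology.  It implements a two-channel divisive
gain-control model of binaural combination together with everything
needed to confront it with data: a synthetic 2AFC observer run through
adaptive staircases and probit analysis, a frequency-tagged steady-state
EEG forward model with the coherent-averaging SNR analysis, and
constrained multi-start fitting with model comparison against a
linear-summation alternative.

## The model

Each ear's modulation depth (percent, `C_L`, `C_R`) excites its channel
and divisively suppresses the other before summation:

```
resp = C_L^p / (Z^q + C_L^q + ω·C_R^q)  +  C_R^p / (Z^q + C_R^q + ω·C_L^q)
```

with transducer exponents `p > q ≥ 2`, saturation constant `Z`, and
interaural suppression weight `ω`.  The alternative sums depths linearly
before a single binaural transducer, `resp = (C_L+C_R)^p / (Z^q + (C_L+C_R)^q)`.

Two readouts connect the response to data:

* **discrimination thresholds** — the increment threshold on a pedestal
  is the smallest target depth that raises `resp` by a criterion `σ40`;
  plotted against pedestal depth this traces the classic dipper
  (facilitation, then masking);
* **steady-state SNR** — the response at a tag frequency (40 or 35 Hz)
  maps to an EEG signal-to-noise ratio as `(resp + σ)/σ`, so absent
  signals sit at the SNR floor of 1.

The scientific question is the size of `ω`: in binocular vision the
analogous weight is ≈1 (strong inter-ocular normalization); for hearing,
both simulated paradigms here recover `ω` well below 1 — weak interaural
suppression — which keeps the monaural and binaural dipper handles apart
and lets binaural EEG responses exceed monaural ones at high depths.

## Worked example

```python
>>> from binsum import TABLE1, dipper_curve, simulate_experiment, fit_dipper, FitSpec
>>> truth = TABLE1["6a"]            # published weak-suppression parameters
>>> truth.omega
0.02
>>> data = simulate_experiment(truth, n_participants=6, n_reps=3, rng_seed=11)
>>> round(data.threshold("mon", 0.0) - data.threshold("bin", 0.0), 2)  # dB
2.87
>>> fit = fit_dipper(data, FitSpec(n_restarts=12, seed=11))
>>> round(fit.params.omega, 3), round(fit.rmse, 2)
(0.019, 0.48)
```

The simulated experiment shows 2.87 dB of binaural summation at
detection threshold (factor 1.39), and the free five-parameter fit
recovers the weak suppression weight (0.019 vs the generating 0.02) with
a residual of 0.48 dB RMSE — pure sampling noise from the staircases.

The same study can be driven from the shell.  `binsum
simulate-psychophysics --seed 11 --fixture 6a --out results` writes the
threshold table and trial log; the numbered scripts under `analysis/`
run the full narrative:

```
python analysis/01_model_predictions.py     # qualitative regime predictions
python analysis/02_simulate_psychophysics.py
python analysis/03_simulate_eeg.py
python analysis/04_fit_models.py            # eight-row model comparison
```

The final script prints the comparison table; with seed 11 it reports a
free-fit suppression weight of 0.019 (discrimination) and 0.115 (EEG),
degradation to 5.76 dB / 0.97 SNR RMSE when `ω` is forced to 1, and the
gain-control model beating linear summation on both data sets (0.48 vs
2.45 dB; 0.22 vs 0.35 SNR).

## Layout

```
src/binsum/        model, stimuli, params, observer, ssaep, fitting, pipeline
analysis/          numbered narrative drivers (simulate → fit → compare)
tests/             pytest suite (unit, property and end-to-end checks)
scripts/           acceptance script
docs/methods.md    modelling and simulation methods note
```
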