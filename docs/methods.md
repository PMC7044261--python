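# Methods

## Models

Two candidate architectures for binaural combination of AM depth are
implemented over a common parameter vocabulary (`p`, `q`, `Z`, `ω`,
`σ40`, `σ35`; see `binsum.params`).

**Gain control.**  Each ear's modulation depth (in percent) drives an
accelerating transducer whose denominator pools its own depth, a
saturation constant and the *other* ear's depth weighted by `ω`, and the
two channel outputs sum:

    resp = C_L^p/(Z^q + C_L^q + ω C_R^q) + C_R^p/(Z^q + C_R^q + ω C_L^q).

Constraints: all parameters positive, `q ≥ 2` (the transducer must
accelerate enough to produce dipper facilitation) and `p ≥ q`.  Published
parameter tables round to two decimals, so the bundles admit `p = q`
exactly; the fitting reparameterization keeps `p > q` strictly.

**Linear summation.**  Depths add across ears before a single binaural
transducer, `resp = (C_L+C_R)^p/(Z^q + (C_L+C_R)^q)`; there is no
interaural suppression term.  This model cannot distinguish which ear
carries a modulation, so monaural and dichotic arrangements are
equivalent under it.

An unmodulated carrier contributes nothing (`depth = 0`); any
carrier-driven adjustment of the saturation constant is out of scope.

**Cross-frequency readout.**  In the frequency-tagged EEG conditions the
two ears can carry different modulation frequencies (40 and 35 Hz).  The
response read out at tag `f` takes excitation only from ears whose
modulation carries `f`, while divisive suppression from the opposite ear
pools its depth *regardless* of tag:

    resp_f = Σ_ears C_{ear,f}^p / (Z^q + C_{ear,f}^q + ω C_{other}^q).

This reduces exactly to the binaural equation when both ears carry the
same tag.  The untuned-suppression choice is a genuine design decision:
the same-frequency data cannot distinguish frequency-tuned from untuned
suppression, and the untuned form is the minimal one that reproduces the
observed ordering of the cross-frequency conditions.  No within-ear
cross-frequency suppression term exists because each ear carries at most
one tag in every condition, leaving such a term unidentifiable.

## Mapping to observables

**Thresholds.**  The increment threshold at pedestal `P` is the smallest
target depth `T` whose addition (per the condition's ear arrangement)
raises the model response by `σ40` — the *signed* increase; if strong
suppression makes the response initially fall with `T`, the solver
continues to larger `T` until the signed increase reaches the criterion.
Thresholds are reported as `20·log10(percent depth)` dB.

**Steady-state SNR.**  `SNR = (resp + σ)/σ`, affine in the response and
equal to 1 (the empirical noise floor of the neighbour-bin estimator)
when the response is absent.  Separate `σ40`/`σ35` allow the two tag
frequencies different effective noise levels.

## Numerical policy

All model math is double precision.  The threshold solver localizes the
first upward crossing of the criterion on a log-spaced grid (20 points
per decade) over `T ∈ [1e-4, 1e4]` percent and refines it with 48
bisection iterations on `log T`, far below the 1e-6 relative target; a
cell whose criterion is unreachable in range (or already exceeded at the
lower bracket) raises an explicit non-bracketable error rather than
clipping.  The solver is vectorized across condition × pedestal cells,
and is validated in the tests against an exhaustive 2000-points-per-decade
grid search.

At `ω = 1` the response surface is not perfectly monotone: divisive
suppression can marginally exceed own-channel gain, producing decrements
up to ≈0.3% of the response range.  The solver's first-crossing rule
handles this; the property tests assert strict monotonicity only for
`ω = 0` and non-decrease for the weak-suppression parameter sets.

## Synthetic psychophysics

The observer applies late additive Gaussian noise of SD `σ40` to each
interval's response and picks the larger, giving

    P(correct) = Φ(Δresp / (σ40 √2)).

At `Δresp = σ40` this is Φ(1/√2) ≈ 0.760, so the criterion-based model
threshold and the 75%-correct psychophysical threshold agree to within a
percentage point by construction — the simplest decision model that
makes the two threshold definitions consistent.

The procedure mirrors the study design: four interaural arrangements
(monaural, binaural, dichotic, half-binaural) × eight pedestal depths
(0–64%, octave steps), pairs of 3-down-1-up staircases with 3 dB steps
terminating at the lesser of 70 trials or 12 reversals, three
repetitions per listener, thresholds from a guessing-floored cumulative
log-Gaussian `P(x) = 0.5 + 0.5 Φ((x−μ)/s)` fit to trials pooled across
repetitions by binomial maximum likelihood (`threshold = μ`, the exact
75% point of that curve; no lapse parameter).  Because the three
single-modulated arrangements are the identical stimulus at pedestal 0,
their detection trials are pooled into one cell.  Defaults are the study
sizes: 6 listeners × 3 repetitions.

Conventions the published design leaves open, chosen once: staircases
start 20 dB above the observer's analytic threshold (capped at 100%
modulation); the staircase pair runs on deterministically split random
substreams (equivalent to trial-by-trial interleaving for the
order-invariant pooled analysis); levels are clipped at 100% modulation
with a logged warning and clipped trials stay in the log.  All
randomness flows from one seed through `numpy` `SeedSequence` spawning.

Calibration facts established by the test suite: the 3-down-1-up rule
tracks the observer's 79.4%-correct level (mean of the last eight
reversals within 1.5 dB over 100 runs), and three staircase-pair
repetitions (~400 trials) localize the probit threshold within ±1.5 dB
in ≥90% of runs *at detection-like cells*, where the psychometric
function is steep on the dB axis.  In the Weber (masking) region the
dB-domain slope is shallower and single-cell thresholds scatter more —
as in real data, where the cross-listener average carries the precision.

## Synthetic steady-state EEG

The stimulus waveform is `0.5(1 + m cos(2π f_m t + π)) sin(2π f_c t)`
(1 kHz carrier; envelope minimum at onset).  The scalp signal is
abstracted to one virtual sensor: each tag frequency contributes a
sinusoid of amplitude `gain_f · resp_f` whose phase is fixed across
repetitions, plus white Gaussian noise independent across repetitions.
Harmonics, electrode geometry and the multi-sensor ROI average are
deliberately collapsed; the analysis consumes one scalar per frequency
per cell, which is all the model predicts.  Real EEG noise is coloured
and non-stationary; since the SNR statistic normalizes by neighbouring
bins, colour mainly affects variance, and passing round-trip tests show
estimator consistency, not realism of the noise process.

Analysis replicates the study pipeline exactly: 11-s trials at 1 kHz,
first second discarded, the 10-s window Fourier transformed per
repetition (0.1 Hz bins; the tags fall on exact bins, so a rectangular
window leaks nothing), coefficients averaged coherently across the 10
repetitions, and SNR taken as the tag-bin amplitude over the mean of the
ten surrounding bins (±0.1…±0.5 Hz, centre excluded — "surrounding 10
bins" read as five per side).  Absolute SNRs are averaged across the 12
synthetic participants.

**Estimator bias and gain calibration.**  The neighbour-bin SNR is a
concave (Rice-statistics) function of the underlying spectral amplitude:
its expectation is 1 at amplitude zero but approaches
`amplitude/noise-floor` from below at large amplitudes, whereas the
model curve `(resp+σ)/σ` is affine.  No proportional sensor gain makes
the estimator pointwise-unbiased for an affine curve; the default
calibration (`calibrate_gains`, bias factor 1.26, chosen by minimizing
the mean absolute mismatch between the estimator's expected response and
the affine curve over the operating range SNR ≈ 1–8) makes the analyzed
curves track the generating curves to ≈0.27 SNR units on average across
the design, with the largest residuals (~0.8) at the extreme ends of the
range.  The per-frequency gain scales as `1/σ_f` so both tags land on
their own generating curves.  The same concavity affects any real
recording analysed this way, which is one reason the σ parameters are
fitted rather than measured.  Under this calibration the masker-only
dichotic cell measures ≈3.4–3.6, consistent with its generating value
of 3.57.

## Fitting and model comparison

The objective is the root-mean-square error between model and data over
all points of a panel — dB units for the 26-cell discrimination design
(pooled detection point counted once, binaural detection once; a
count-per-condition alternative is selectable), linear SNR units for the
7-curve × 5-depth EEG design (40 Hz: all five conditions; 35 Hz: the two
cross-frequency conditions; both frequencies weighted equally).

Constraints are enforced by reparameterization (`q = 2 + e^a`,
`p = q + e^b`, `Z = e^c`, `ω = e^d`, `σ = e^g`), so every visited point
is feasible and returned parameters satisfy the constraints exactly.
Optimization is Nelder-Mead from Latin-hypercube-seeded multi-starts
(default 20; the winner is polished with a tighter restart), returning
provenance (restarts, seed, evaluation count).  The procedure is
deterministic given spec + data + seed.  Free parameter sets: gain
control {p, q, Z, σ40, ω} (+σ35 for EEG); linear summation drops ω.
Fixed-parameter evaluations (`evaluate_fixed`) recompute RMSE with
overridden values and no optimization — the "force ω to 1" manipulation.

On noiseless self-generated data the free fits recover the generating
parameters to optimizer precision (RMSE < 1e-8 dB), and the nested
ordering free ≤ ω-fixed refit ≤ ω-forced evaluation holds on every
dataset up to 1e-3 optimizer tolerance.  Across 20 observer-simulated
experiments at study size the free fit classifies suppression as weak
(ω < 0.1) and recovers `log10 Z` within 0.15 in ≥90% of runs.

## Problem sizes

Simulations default to the study design (psychophysics: 6 listeners ×
3 repetitions × 4 conditions × 8 pedestals, paired staircases; EEG: 12
participants × 6 conditions × 5 depths × 10 repetitions of 11-s trials).
The test suite and acceptance script run these sizes, with restart
counts reduced (5–12) for the repeated-fit ensembles; the noiseless
self-fit tests retain the full 20 restarts as the optimizer-thoroughness
check.

## Known limitations

* The cross-frequency suppression rule (untuned) is one of several
  architectures consistent with the same-frequency data.
* Whether observers could exploit a response *decrement* as a cue in
  strong-suppression dichotic masking is unresolved; the solver follows
  the signed-increase criterion only.
* The EEG noise spectrum and per-subject SNR scaling are free
  calibration knobs of the synthetic generator, not estimates of
  physiology.
* No hierarchical/per-participant fitting, bootstrap intervals or
  Bayesian posteriors; the fits describe the across-participant mean.
* Ingestion of deposited empirical data is supported only through the
  package's delimited-text schemas (`DipperDataset.from_csv`,
  `EEGResponseDataset.from_csv`); raw-deposit layouts must be adapted to
  those columns first.
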