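# Methods

This note documents the models, estimators, parameters and design choices
behind `dyadsync`, and what the synthetic validation does and does not
establish about real data.

## Study design assumed by the pipeline

Two participants (a *dyad*) alternate speaker and listener roles across
topic turns of fixed length (default 90 s at 250 Hz), with one joint resting
trial; the default design has 5 topics × 2 turns + 1 rest = 11 epochs per
participant. Each dyad yields **two analysis cases** (each member once as
speaker, once as listener), so a 15-dyad study gives the 30 cases over which
all group statistics run (paired tests with df = 29).

## Estimators

**PLV.** The single-trial phase-locking value is the modulus of the
time-averaged unit phasor of the phase difference,
`PLV = |mean_t exp(i(φ_t − ψ_t))|`, computed within one epoch. Phases are
Hilbert-transform phases of zero-phase band-filtered signals in delta
(1–3 Hz), theta (4–8), alpha (9–12) and beta (15–20). For independent
phases its expectation is ≈ √(π/4T) (≈ 0.006 at T = 22500), not zero; all
inference is therefore relative to surrogates, never to the theoretical
floor.

**Filtering.** All band-pass, high-pass and low-pass steps use one filter
family: windowed-sinc (Hamming) FIRs, order ≥ 3 cycles of the lowest corner
and ≥ 1 s of taps, applied forward-backward (zero phase). The residual DC
gain of high/band-pass designs is nulled exactly. The implementation applies
the forward-backward operator in the frequency domain (|B(f)|² on an
odd-reflect-padded signal) — verified in tests against `scipy.signal.filtfilt`
— and, in the bulk pipeline, fuses the band-pass with the analytic-signal
step into a single FFT pass. 1 s (250 samples) is trimmed from each epoch
edge before any PLV to suppress filter/Hilbert transients; the trim is
configurable and logged.

**Interbrain maps.** Per case: PLV for every listener × speaker channel pair,
band and trial (27 × 27 × 4 × 6 canonically); the resting-trial PLV is
subtracted from each topic trial and topics are averaged (plain subtraction,
no normalization).

**Envelope entrainment.** The speech amplitude envelope is the square root
of short-time power (Hamming window 25 ms, hop 4 ms, 100–4000 Hz band)
resampled to the EEG rate; parameters are config-exposed. The envelope is
band-filtered and Hilbert-transformed exactly like an EEG channel. The mean
PLV over all n(n−1)/2 within-subject sensor pairs is subtracted per band
(intra-brain correction), computed per topic and averaged — equivalent to
correcting after averaging since it is a per-band constant shift. No
rest-baseline subtraction is applied to envelope PLV.

**Surrogates.** Role-preserving trial shuffling: all n(n−1) ordered
non-matching (listener-trial, speaker-trial) or (envelope, EEG-trial)
pairings (20 with five topics), each processed identically to the real data
(same rest subtraction or intra-brain correction), averaged into one
deterministic surrogate value per case. Averaging rather than sampling
removes pairing-choice variance; the paired real-vs-surrogate contrast then
has exactly one surrogate value per case.

**Group test.** Nonparametric bootstrap paired t-test: observed
`t = mean(d)/(sd(d)/√n)` on the case-wise differences; null from resampling
the mean-centered differences with replacement (implemented via multinomial
resample counts, n_boot = 10000 by default); two-sided
`p = (1 + #{|t*| ≥ |t_obs|})/(n_boot + 1)` so p is never zero.
Zero-variance features get p = 1 with a warning. Benjamini–Hochberg FDR
(q = 0.05, via statsmodels) is applied **jointly**: across all 4 × 729 =
2916 interbrain tests, and across all 2 roles × 4 bands × 27 channels = 216
envelope tests. Tests are two-sided with the direction reported;
"enhancement" masks additionally require a positive real-minus-surrogate
mean. Z-score maps (for topographies) z-score PLVs across features within a
band per case, then average real−surrogate over cases; the z-scoring
dimension is a documented choice, config-exposed.

**Mediation.** Per channel pair (A of the listener, B of the speaker) and
band, across the 30 cases: OLS of interbrain coupling on the listener's
entrainment at A (x₁) and the speaker's at B (x₂), full model
`Y = β₀ + β₁x₁ + β₂x₂ + β₁₂x₁x₂ + ε` plus the two single-predictor models.
Significance is the overall-model F-test at p < 0.05 uncorrected (one value
per cell; per-coefficient criteria would be stricter and are available from
the fit objects). With three predictors at n = 30 the full-model df are
(3, 26). The exclusion mask starts from the significantly *enhanced*
interbrain pairs and removes (i) pairs significant in **any** of the three
models — the partial models are explicitly complementary to the full model —
and (ii) pairs whose listener channel (listener role) or speaker channel
(speaker role) is itself significantly entrained in that band. OLS is
closed-form (lstsq / normal equations), cross-checked against statsmodels in
the tests.

## Synthetic data model

Each channel is a sum of one stochastic phase oscillator per band plus 1/f
background noise (spectrally synthesized, unit variance, default exponent 1,
default amplitude 1 vs oscillator amplitude 1). Oscillator phases advance as

```
θ[t+1] = θ[t] + 2πf/rate + κ·g·sin(ψ[t] − θ[t]) + σ·N(0,1)
```

with attraction gain g = 0.2 rad/sample at κ = 1 and phase noise
σ = 0.15 rad/sample. Uncoupled oscillators draw f uniformly within their
band; coupled ones run at the band center, following a shared driver ψ
(random-walk frequency jitter 0.05 rad/sample) that is unique to each epoch
— so genuine coupling exists only within a turn, never across trials, and
resting epochs contain no cross-participant coupling at all. Envelope
entrainment uses the band-filtered envelope phase as the driver. Each
channel-band oscillator follows at most one driver (validated). A per-dyad
multiplier drawn from [1 − kappa_spread, 1] (default spread 0.3) models
between-dyad variability in coupling strength; without it the mediation
regressions would have no across-case variance to detect.

The speech envelope is a sum of half-wave-rectified quasi-rhythmic
modulators: a slow ~2 Hz (phrasal/delta) component (weight 0.5, rate jitter
0.3) and a dominant syllabic component at the configured syllable rate
(default 5 Hz, weight 1.0, jitter 0.4), plus a 0.05 floor. The generous
jitter makes distinct utterances decorrelate within a few seconds, as real
speech does; with weaker jitter the surrogate envelope-PLV floor becomes
unrealistically high. Audio for the WAV path is the envelope applied to a
white-noise carrier.

**What the generator does not emulate:** volume conduction (channels within
a brain are independent, so the intra-brain correction term is small),
ocular/muscle/cardiac artifacts, jaw-movement contamination,
nonstationarity across a session, and realistic montage geometry. Passing
the recovery tests therefore shows the *estimators and inference chain* are
correct under the assumed coupling model — not that the pipeline is robust
to artifacts, which the in-scope preprocessing deliberately does not
attempt to remove (ICA/bad-channel repair are delegated to upstream tools
via a pass-through).

## Randomness and determinism

One master seed; per-dyad substreams via `numpy.random.SeedSequence.spawn`,
and separate spawned streams for the interbrain and envelope bootstrap
tests. Identical config + seed reproduces every table bit-identically; the
provenance record (config + hash) written with each run suffices to
reproduce it.

## Numerical choices

- Bulk phase extraction runs in single precision with unit phasors
  (`y/|y|`); PLV averages ≥ 2·10⁴ samples, so float32 phase error (~10⁻⁵
  rad) is negligible against between-case variance. Reference operations
  and all scalar paths are float64; engine-vs-reference equivalence is
  tested at 2·10⁻⁴.
- All topic × topic PLV matrices of a case/band (real, 20 surrogate
  pairings, rest) come from one batched complex Gram product.
- Degenerate inputs: constant/collinear mediation predictors are flagged
  (`ok=False`, p = NaN); zero-variance bootstrap features get p = 1;
  all-zero audio yields an all-zero envelope with a warning; a missing rest
  epoch warns and disables baseline subtraction.

## Problem sizes used in the shipped analyses and tests

The structural tests exercise the canonical 27-channel, 90-s, 5-topic
design directly. The replicated recovery and mediation-discrimination
studies (20 replicates each, 15 dyads, 5 topics) use a reduced 8 × 8-channel
montage with 30-s turns — sizes chosen so a full 20-replicate study runs in
minutes on one core while leaving the per-test statistics (30 paired cases,
10000 bootstrap resamples, joint FDR) at study scale. The `analysis/`
drivers use the same reduced world. Nothing in the implementation depends
on these sizes; the configuration accepts the full-scale values.

## Known limitations

- The PLV is the only synchrony metric (no coherence/PLI variants), by
  scope.
- The mediation stage is a regression screen, not a formal causal-mediation
  analysis (no indirect-effect estimation or bootstrap CIs on products of
  coefficients).
- The exclusion rule is deliberately conservative: any of three models at
  p < 0.05 uncorrected removes a pair, so a fraction of genuinely direct
  pairs (~10–15 % under the null of no mediation) is sacrificed; the
  replicated tests quantify this trade-off.
- Surrogate and real maps share the rest baseline, so rest-epoch noise is
  common to both members of each paired contrast.
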