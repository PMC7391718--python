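# Methods

This note documents the models, estimators and design choices behind
`phaselag`: what the synthetic cohorts contain, how the connectivity and
graph statistics are defined numerically, how reliability is quantified,
and what the package's passing tests do and do not establish about real
EEG data.

## Synthetic two-session cohorts

### Coupling model

Each channel i carries a sinusoid at the oscillation frequency f (default
7 Hz) with phase

    φ_i(t) = 2πf·t + θ_i + ξ_i(t),

where θ_i is a fixed channel offset and ξ_i is phase jitter, piecewise
constant over blocks of `phase_jitter_interval` seconds (default 0.5 s)
and drawn independently per block as N(0, v_i). Between two channels the
phase difference is (θ_i − θ_j) + (ξ_i − ξ_j), so its circular
consistency is exp(−(v_i + v_j)/2) — a product r_i·r_j of per-channel
consistencies r_i = exp(−v_i/2). The generator inverts this relation:
given a target coupling matrix c_ij = r_i·r_j it sets
v_i = −2·log r_i (r = 1 gives exactly zero jitter; r ≈ 0 gives jitter so
wide the phase is effectively uniform).

This parameterisation is deliberate: pairwise phase relations of a
common-oscillator system are *additive* (lag_ij = θ_i − θ_j) and
*multiplicative* in consistency, so a fully arbitrary matrix of
independent pairwise couplings or lags is not physically realisable by
any multichannel signal. The generator therefore controls coupling
through per-channel quantities and reports the implied pairwise truth:

- r_i = √g · m_i, with g the subject-level coupling strength and m_i a
  fixed channel "texture" profile (log-normal, normalised to max 1 so r
  never clips and g maps linearly onto every pair);
- θ_i are spread evenly over [0, 3π/4] with up to ±¼-spacing jitter and a
  random channel assignment, so every pair's lag is bounded away from 0
  (by half the spacing) and from π (by the span) — both estimators are
  blind at exactly 0 or π, and real alpha networks show distributed lags.

### Variance components

Reliability is designed in, not emergent:

- between subjects: g_s ~ N(coupling_mean, coupling_sd_between), clipped
  to [0, 1] (trait);
- between sessions within subject: g_s,sess = g_s + δ, δ ~
  N(0, session_noise_sd) (state);
- the texture profile and lags are population-level constants, so the
  whole designed between/within variance lives in g.

The designed reliability ceiling is ρ = σ²_b / (σ²_b + σ²_w)
(`PopulationConfig.variance_ratio`); because the coupling-to-connectivity
curve is smooth and both components pass through the same local slope, a
consistency ICC on subject-level connectivity approaches ρ once
epoch-sampling noise is negligible. `config_for_variance_ratio` solves
for the session noise that yields a requested ρ. Both shifts being shared
across pairs also means the SD of a subject's mean coupling equals
κ·coupling_sd_between with κ = mean(m_i·m_j) — there is no 1/√pairs
shrinkage, which is what makes the ratio recoverable from whole-brain
averages at all.

### Defaults and what they emulate

| parameter | default | rationale |
| --- | --- | --- |
| n_channels | 32 | standard infant montage size |
| sampling_rate | 512 Hz | typical post-downsampling rate |
| oscillation_freq | 7 Hz | centre of the infant alpha band (6–8 Hz) |
| coupling_mean | 0.35 | weak-to-moderate phase coupling; yields whole-brain dbWPLI of order 0.01–0.1, the magnitude seen in infant alpha networks |
| coupling_sd_between | 0.10 | trait spread |
| session_noise_sd | 0.065 | state spread; with the trait spread gives ρ ≈ 0.70 |
| sensor_noise_sd | 10.0 | per-epoch, per-bin alpha SNR near 1 — the noisy-infant-EEG regime in which connectivity estimates are strongly epoch-count limited (reliability poor/fair at 30 epochs, rising markedly to 150) |
| mixing_strength | 0.0 | volume conduction off by default; when enabled, applied as the instantaneous mixing M = (1−μ)I + μ/(C−1)(J−I) |
| segment_lengths | 12–30 s blocks, 348 s total | variable clean segments; 348 s makes every segmentation scheme satisfiable (the largest need 300 s) |
| phase_jitter_interval | 0.5 s | phase relations decorrelate across epochs; ≥ 2 jitter draws per epoch at every epoch length |

The defaults were calibrated once, against the generator's own
diagnostics (the true coupling table and replicate sweeps), to place the
simulation in the regime the pipeline is meant to study: weak noisy
coupling, a known reliability ceiling near 0.7, and an epoch-number
dependence large enough to be measurable. Noise is white by default;
`pink_noise=True` applies 1/f amplitude shaping, which matters little for
a band-limited 6–8 Hz analysis.

### What the generator does *not* emulate

No artefacts (blinks, movement, muscle), no electrode geometry or
realistic head model (volume conduction is abstracted as uniform
instantaneous mixing), no non-stationarity beyond block-wise phase
jitter, no per-channel amplitude differences, no alpha-peak variability
across subjects. Passing tests therefore establish the *estimator* and
*pipeline* properties (bias laws, invariances, variance bookkeeping), not
that any particular reliability number will be observed in real infant
EEG.

## Spectral estimation and connectivity

Epochs are demeaned per channel, tapered with a single Hanning window and
Fourier transformed; bin spacing is 1/epoch_length Hz. Connectivity is
computed per frequency bin inside the band (inclusive endpoints, default
6–8 Hz) and the per-bin matrices averaged — not pooled across bins before
estimation — so different epoch lengths average different bin counts over
the same band.

With y_e the per-epoch imaginary cross-spectrum of a pair:

- PLI = |mean_e sgn(y_e)|, with sgn(0) contributing 0;
- WPLI = |Σ y_e| / Σ |y_e| (the plain, positively biased form);
- dbWPLI = ((Σ y_e)² − Σ y_e²) / ((Σ |y_e|)² − Σ y_e²), the debiased
  estimator of the *squared* WPLI built from products of distinct epochs;
  it needs ≥ 2 epochs, and a degenerate denominator (all y_e = 0, e.g.
  purely instantaneous coupling) is defined as 0.

Whole-brain connectivity is the mean of the strict upper triangle, taken
over *signed* dbWPLI values; absolute values are applied only where graph
theory requires non-negative weights. Known closed forms used as oracles:
under independence E[PLI] = 2^(1−n)·C(n−1, ⌊(n−1)/2⌋) ≈ √(2/(πn)) and
E[dbWPLI] ≈ 0 at any n.

## Graph metrics

All graph analysis runs on non-negative (absolute) weights rescaled to a
maximum of 1. The weighted clustering coefficient uses the Onnela
geometric-mean triangle intensity: node i contributes
2·t_i/(k_i(k_i−1)) with t_i = ½·Σ_{j,h} (ŵ_ij ŵ_ih ŵ_jh)^(1/3), k_i the
number of non-zero-weight neighbours, and 0 when k_i < 2. The
characteristic path length inverts weights into lengths (zero weight = no
edge), runs Dijkstra over all pairs, and averages the off-diagonal
distances; pairs in different components are excluded with a warning
(dense phase-lag matrices do not produce them in practice).

Normalisation divides each metric by its mean over surrogate matrices
that uniformly permute the strict-upper-triangle weights and mirror back
— the conventional weight-distribution-preserving, topology-randomising
null. SWI = C^w_norm / L^w_norm holds as an exact identity of the
returned values. 1,000 surrogates is the default; the Monte-Carlo error
of the surrogate mean scales as 1/√n_surrogates, and reduced counts
(64–200) are used in the test suite where only self-consistency is at
stake.

## Reliability statistics

ICC(3,1) — two-way model without interaction, single measurement,
consistency — is computed from first-principles sums of squares:
(MS_R − MS_E)/(MS_R + (k−1)MS_E) with k = 2 sessions. The 95% CI and
p-value follow the standard F-theory for this ICC (F = MS_R/MS_E on
(n−1) and (n−1)(k−1) df); these formulas are the conventional choice for
the consistency ICC and are cross-checked against an independent
implementation in the tests. Negative estimates are retained in `icc` and
clipped to 0 in `icc_clipped`; the CI always refers to the unclipped
estimate. Interpretation bands are applied as contiguous half-open
intervals poor [0, 0.40), fair [0.40, 0.60), good [0.60, 0.75),
excellent [0.75, 1] — the published convention leaves (0.59, 0.60) and
(0.74, 0.75) formally unassigned, and contiguity is the only
tie-break that classifies every value. A fully constant score table
(zero between- and within-subject variance) is reported as ICC 1 with a
degenerate CI and logged. p-values are per cell, uncorrected, and no
ICC-vs-ICC significance testing is performed — patterns across cells are
described, not tested.

Subjects are excluded per scheme combination (not listwise): a
subject/session lacking enough epochs for one combination drops out of
that cell only, and cells with fewer than 3 surviving subjects are marked
unavailable. The constant-amount design selects twenty 6-s epochs once
per subject/session and derives the 1/2/3-s variants by nested
re-segmentation, so all four combinations use identical samples. Epoch
selection uses RNG streams derived from the global seed and the
(subject, session, length, count) cell, independent of the
data-generation streams; all seeds and exclusions are recorded in the run
manifest.

## Numerical choices and degenerate inputs

- sgn(0) = 0 in the PLI; exact zeros arise only from constructed input.
- dbWPLI denominator 0 → value 0 (not NaN), so purely-real cross-spectra
  yield "no lagged coupling".
- Weight rescaling of an all-zero matrix returns it unchanged; surrogate
  normalisation of a degenerate (zero or disconnected-mean) matrix raises.
- ICC guards tiny negative error mean squares (floating-point) at 0.
- Seed derivation uses `numpy.random.SeedSequence` spawn keys (stable
  across platforms and runs); all derived seeds are < 2³¹.

## Problem sizes in the test suite and acceptance script

The reliability experiments run at reduced but statistically adequate
scale: the variance-ratio recovery sweep uses 8–10 replicate cohorts of
40 subjects at {30..150} × 1-s epochs (whole-brain metrics only, no
surrogates needed), and the metric-ordering comparison uses 12–20
replicate cohorts of 15 subjects at 120 × 1 s with 64 surrogates. At
these sizes the Monte-Carlo SE of a replicate-mean ICC is ≈ 0.03–0.04,
small against the effects being checked (an epoch-number ICC gain ≈ 0.1
and a whole-brain-vs-path-length gap ≈ 0.4). Stochastic assertions are
stated with their Monte-Carlo error: the recovered median must lie within
its own 95% CI of the designed ρ, and "ICC non-decreasing with data"
allows adjacent replicate-mean dips within twice their paired SE —
increments shrink toward zero as the epoch subsample approaches the full
session, so exact sample monotonicity is not a property even of the
underlying truth.

## Known limitations

- The coupling→dbWPLI mapping is monotone but nonlinear; the designed ρ
  is recovered up to a small attenuation (replicate-mean ICC ≈ 0.65
  against a designed 0.70 at the default noise level and 150 × 1-s
  epochs) from residual epoch-sampling noise, the session-level jitter
  floor and curvature; single-cohort ICCs additionally spread with
  SD ≈ 0.1 at 40 subjects.
- Whole-brain dbWPLI averages signed values; with near-zero true coupling
  this average can be slightly below the per-pair magnitudes.
- The surrogate null preserves the weight distribution but not degree
  structure; normalised metrics inherit that convention.
- Session-level jitter realisation noise puts a floor on within-subject
  variance that no number of epochs removes (it shrinks only with total
  recording duration).
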