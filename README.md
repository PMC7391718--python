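# phaselag

Test–retest reliability of phase-lag EEG connectivity under epoch
segmentation trade-offs.

Developmental EEG studies face a hard constraint: infants yield short,
scarce stretches of artefact-free signal, and a fixed amount of clean data
can be cut either into many short epochs or a few long ones. Because
phase-lag connectivity estimators behave very differently across that
trade-off — the phase lag index is inflated at small epoch counts, while
its debiased weighted variant is not — the choice of epoch number and
length changes how *reliably* a lab can measure stable individual
differences in brain connectivity. `phaselag` implements the full analysis
chain needed to study this question on synthetic two-session cohorts in
which the true coupling structure, and therefore the design-level
reliability, is known by construction.

## What it computes

**Connectivity.** From epoched multichannel signal, complex Fourier
coefficients are obtained per epoch with a Hanning taper; for a channel
pair the cross-spectrum is X = c_i · conj(c_j). With y_e = ℑ{X_e} per
epoch e:

- phase lag index: `PLI = | E{ sgn(ℑ{X}) } |` — the consistency of the
  lead/lag sign; blind to zero-lag (volume-conduction) coupling, but
  positively biased under independence, E[PLI] ≈ √(2/(πn)) at n epochs;
- debiased weighted PLI (squared):
  `dbWPLI = ((Σ y_e)² − Σ y_e²) / ((Σ |y_e|)² − Σ y_e²)` — magnitude
  weighting plus removal of the same-epoch products cancels the
  small-sample inflation (null mean ≈ 0 at any n);
- the plain WPLI `|E{y}| / E{|y|}` is available for comparison.

Per-bin matrices are averaged over the analysis band (default 6–8 Hz, the
infant alpha range), and reduced to whole-brain connectivity (mean over
all channel pairs) and to weighted graph metrics: the Onnela clustering
coefficient C^w, the characteristic path length L^w on inverse-weight
edges, their normalised versions C^w_norm = C^w/C^w_rand and
L^w_norm = L^w/L^w_rand against 1,000 weight-permuted surrogate networks,
and the small-worldness index SWI = C^w_norm / L^w_norm.

**Reliability.** For each (epoch scheme × estimator × metric) cell, the
two-session scores across subjects give the intra-class correlation
ICC(3,1) = (MS_R − MS_E)/(MS_R + (k−1)·MS_E) — two-way model, single
measure, consistency — with F-based 95% CIs and p-values, clipped at 0 and
categorised as poor (< 0.40), fair, good, or excellent (≥ 0.75).

**Segmentation designs.** Three schemes probe the trade-off: low numbers
of longer epochs ({20..60} × {1..5} s), high numbers of shorter epochs
({30..150} × {1,2} s), and a constant 120 s of data (120 × 1 s, 60 × 2 s,
40 × 3 s, 20 × 6 s) in which the shorter epochs are nested re-segmentations
of the same twenty randomly selected 6-s epochs.

**Synthetic cohorts.** The generator simulates two sessions per subject:
every channel carries a 7 Hz oscillation whose pairwise phase consistency
is controlled analytically through per-channel wrapped-Gaussian phase
jitter (consistency c_ij = r_i·r_j), with a subject-level coupling
strength (between-subject trait variance), a session-level shift
(within-subject state variance), heavy broadband sensor noise, optional
instantaneous mixing emulating volume conduction, and clean segments of
mixed durations. The designed reliability ceiling
ρ = σ²_between/(σ²_between + σ²_within) is known exactly.

## Worked example

```python
from phaselag import ExperimentConfig, PopulationConfig, run_experiment

pop = PopulationConfig(n_subjects=12, seed=7)
cfg = ExperimentConfig(population=pop, approaches=("constant_amount",),
                       methods=("dbwpli",), n_surrogates=200)
res = run_experiment(cfg)
print(res.icc_table[["n_epochs", "epoch_length", "metric", "icc_clipped",
                     "ci_low", "ci_high", "p_value", "category"]].round(3))
```

Output (12 simulated infants, dbWPLI, constant 120 s of data per session):

```
 n_epochs  epoch_length      metric  icc_clipped  ci_low  ci_high  p_value  category
       20             6    c_w_norm        0.432  -0.159    0.795    0.070      fair
       20             6    l_w_norm        0.377  -0.222    0.769    0.102      poor
       20             6         swi        0.518  -0.049    0.832    0.035      fair
       20             6 whole_brain        0.823   0.496    0.946    0.000 excellent
       40             3    c_w_norm        0.159  -0.432    0.654    0.302      poor
       40             3    l_w_norm        0.384  -0.214    0.773    0.097      poor
       40             3         swi        0.625   0.110    0.875    0.011      good
       40             3 whole_brain        0.808   0.462    0.941    0.000 excellent
       60             2    c_w_norm        0.319  -0.284    0.741    0.144      poor
       60             2    l_w_norm        0.000  -0.746    0.273    0.864      poor
       60             2         swi        0.000  -0.869   -0.085    0.986      poor
       60             2 whole_brain        0.796   0.434    0.937    0.001 excellent
      120             1    c_w_norm        0.332  -0.271    0.747    0.134      poor
      120             1    l_w_norm        0.274  -0.329    0.718    0.182      poor
      120             1         swi        0.233  -0.367    0.696    0.222      poor
      120             1 whole_brain        0.779   0.397    0.931    0.001 excellent
```

Whole-brain connectivity is reliably measured (excellent, p < 0.01 in each
scheme) while the surrogate-normalised graph metrics are far less stable —
the ordering this package exists to quantify. Confidence intervals refer
to the unclipped estimate, so a clipped ICC of 0 can sit above its CI.

A `phaselag` command exposes the same pipeline from the shell
(`simulate`, `connectivity`, `graph`, `reliability`, `full-run`); see
`phaselag --help`.

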