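# alphagate

Response-locked alpha-band EEG indexes and robust neural–behavioral
correlation analysis for stroke-rehabilitation outcomes.

## The problem

Upper-extremity rehabilitation trials routinely find that behavioral
scales of activities of daily living (ADL) — SIS-ADL, FIM, NEADL —
barely separate intervention arms, while individual recovery varies
widely.  The *gating-by-inhibition* account of alpha oscillations
(8–12 Hz) offers theory-driven neural indexes of psychomotor
efficiency: before a movement, alpha power **rises over bilateral
temporal cortex** (T7, F7, CP5, T8, F8, CP6), gating out non-motor
interference, while after response onset alpha **falls over
central-frontal motor sites** (F3, Fz, F4, C3, CP1, C4, CP2),
releasing motor cortex for execution.  `alphagate` implements the full
analysis chain that turns multichannel EEG plus a clinical score table
into those indexes and into robust subject-level brain–behavior
correlations, for researchers analysing pre/post intervention designs
(three groups × pre/post here: premotor-cortex tDCS, M1 tDCS, sham —
each combined with mirror therapy).

## The analysis

1. **Preprocessing** — 0.5–40 Hz zero-phase FIR filter, CleanLine-style
   sliding sinusoid regression at the line frequency, epoching −1 to
   +1 s around key-press responses made by the hand contralateral to
   the lesioned hemisphere, linked-mastoid re-reference, pluggable
   ICA/regression ocular-artifact removal, and a qualification gate of
   ≥ 50 artifact-free epochs per subject-session.
2. **Time–frequency** — Morlet wavelets (5 cycles, pad ratio 4,
   one-sided amplitude doubling so a sinusoid of amplitude A yields
   power A²), averaged over epochs, expressed as median-scaled
   absolute power: `10·log10(P / median(P))` per channel × frequency
   within each participant-session.
3. **Window selection** — a cluster-based permutation test over time
   (max-cluster-mass null, sign-flip permutations) controls the
   family-wise error of the pointwise contrast; the canonical analysis
   windows are −65–0 ms (temporal index) and 0–127 ms (central-frontal
   index).
4. **Indexes** — temporal alpha, central-frontal alpha, and their
   ratio (temporal / central-frontal; higher = better psychomotor
   efficiency), reduced to post-minus-pre change scores.
5. **Inference** — the *skipped correlation* per (group × index ×
   clinical outcome) cell: minimum-covariance-determinant (MCD)
   centre/scatter (exhaustive enumeration at n ≤ 15, hence exact at
   n = 12), box-plot rule on robust distances, Pearson's r on the
   retained pairs with t = r·√(n−2)/√(1−r²), and a 95%
   percentile-bootstrap CI (small-sample-adjusted cut-points);
   significance ⇔ 0 outside the CI.  Group-level screening uses a
   3 × 2 mixed ANOVA with Kolmogorov–Smirnov/Levene checks,
   Kruskal–Wallis/Friedman fallbacks and Bonferroni post-hocs.

A synthetic-data module simulates the whole study — 1/f background EEG
plus amplitude-modulated alpha with the planted temporal surge and
central-frontal suppression, clinical tables anchored to published
group means/SDs, planted index↔outcome correlations, blink artifacts,
and optional bivariate outliers — so every stage can be validated
against ground truth without access to patient data.

## Worked example

```python
from alphagate import PipelineConfig, run_pipeline

config = PipelineConfig(
    simulation=dict(n_per_group=5, n_epochs_per_session=12, artifact_rate=0.0),
    minimum_epochs=10, ocular_method="regression", n_bootstrap=200, seed=7,
)
manifest = run_pipeline(config, "out")
print(manifest["n_subjects"], manifest["n_correlation_cells"])
print(manifest["windows_ms"])
```

prints

```
15 45
{'temporal': [-65.0, 0.0], 'central_frontal': [0.0, 127.0]}
```

i.e. 15 simulated subjects (3 groups × 5) survived the epoch gate and
the battery produced all 45 correlation cells (3 groups × 3 indexes ×
5 outcomes) using the canonical analysis windows.  `out/` then holds
`indexes.csv` (per-session index values), `change_scores.csv`,
`correlations.csv` (r, t, CI, outliers and significance per cell),
`anova.csv` (F, df, p per measure and effect), `clusters.json`, and a
`manifest.json` recording seeds, config hash and per-subject
exclusions.  The same pipeline reads real BrainVision triplets
(`input_mode="files"`).  A thin CLI wraps it:
`alphagate --config cfg.yaml --seed 1 --out out run-all`.

```python
from alphagate import skipped_correlation, t_from_r
res = skipped_correlation(x, y, seed=0)   # one cell by hand
res.r, res.t, res.ci, res.outlier_indices, res.significant
```

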