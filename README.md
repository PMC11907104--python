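# microstates

Resting-state EEG microstate analysis in Python: polarity-invariant AAHC
clustering of GFP-peak topographies, hierarchical template sorting and
backfitting, microstate parameter and transition-syntax quantification, and
the full group-statistics battery (mixed ANOVAs with Greenhouse–Geisser
correction, Welch/Bonferroni transition tests, randomization TANOVA) —
plus a synthetic cohort generator with known ground truth so every stage is
testable by parameter recovery.

## The problem

Spontaneous EEG does not wander continuously through topography space: the
scalp potential field stays quasi-stable for ~60–120 ms and then switches
abruptly to a different configuration. These *microstates* — usually the
four canonical classes A–D — are interpreted as transient large-scale
network states, and their dynamics (how long states last, how often they
occur, which state follows which) differ in a range of neurological and
psychiatric conditions, including visual snow syndrome, migraine and
tinnitus. This package implements the standard clinical analysis chain for
comparing microstate dynamics between two groups of subjects.

## The method

For an average-referenced, 2–20 Hz band-passed recording, the global field
power

GFP(t) = sqrt( (1/E) Σ_e (u_e(t) − ū(t))² )

indexes momentary field strength; its local maxima are the highest-SNR
samples. The maps at GFP peaks are clustered by atomize-and-agglomerate
hierarchical clustering (AAHC) into K = 4 classes: each map starts as its
own cluster, and the cluster contributing least *global explained
variance*,

GEV_k = Σ_{t: L(t)=k} ( GFP_t · Corr(u_t, T_k) )² / Σ_t GFP_t²,

is repeatedly dissolved and its members reassigned by best
polarity-invariant spatial correlation |Corr|. Individual template sets are
averaged into group grand means and a grand grand mean, sorted against
canonical norm topographies, and the sorted labels cascaded back down.
Backfitting labels every GFP peak with its best template and interpolates
between peaks, yielding per-subject duration, occurrence, coverage, mean
GFP, GEV and the K×(K−1) transition-syntax percentages, which feed mixed
ANOVAs, Welch t-tests (Cohen's d), Bonferroni-corrected transition
comparisons and a randomization TANOVA on strength-normalized maps.

See `docs/methods.md` for conventions, defaults and limitations.

## Worked example

Simulate a cohort with injected group effects — shorter dwell (×0.85),
lower amplitude (×0.8) and a raised A→B transition probability (+0.15) in
the patient group — and run the full pipeline:

```python
import numpy as np
import microstates as ms

delta = np.zeros((4, 4)); delta[0] = [0.0, 0.15, -0.075, -0.075]
effect = ms.GroupEffect(dwell_scale=0.85, amplitude_scale=0.8,
                        transition_delta=delta)
recs = ms.make_cohort(5, ms.SimulationConfig(n_epochs=4, epoch_s=20.0),
                      effect, seed=42)
res = ms.run_pipeline(recs, ms.PipelineConfig(trim_s=75.0,
                                              n_permutations=1000,
                                              permutation_seed=0))

tab = res.parameter_table
print(tab.groupby("group")[["duration_ms", "occurrence_per_s",
                            "mean_gfp_uv"]].mean().round(2))
g = res.anovas["duration_ms"][0]
print(f"duration group effect: F({g.df[0]:.0f}, {g.df[1]:.0f}) "
      f"= {g.statistic:.2f}, p = {g.p:.4f}")
w = res.overall_tests["mean_gfp_uv"]
print(f"mean GFP: t({w.df:.1f}) = {w.statistic:.2f}, p = {w.p:.2g}, "
      f"d = {w.effect_size:.2f}")
t = {t.name: t for t in res.transition_tests}["transition:A->B"]
print(f"A->B transitions: t({t.df:.1f}) = {t.statistic:.2f}, "
      f"corrected p = {t.p_corrected:.2g}")
```

prints

```
         duration_ms  occurrence_per_s  mean_gfp_uv
group
control        85.10              2.95         3.22
vss            76.73              3.26         2.43
duration group effect: F(1, 8) = 5.22, p = 0.0517
mean GFP: t(37.4) = -7.91, p = 1.7e-09, d = -2.50
A->B transitions: t(6.7) = -9.63, corrected p = 0.00042
```

The patient group's states are ~8 ms shorter and correspondingly more
frequent; the amplitude effect is unmistakable (d ≈ −2.5); and the raised
A→B transition rate survives the Bonferroni correction even at n = 5 per
group, while the duration effect at this tiny sample is only borderline —
at realistic sample sizes (20/group) it is decisive (see the acceptance
checks below).

A command-line interface mirrors the pipeline stage by stage
(`microstates simulate | preprocess | cluster | sort | backfit | params |
stats | run-all`); `microstates run-all --n-per-group 10 --out results/run`
simulates a cohort and writes all intermediate artifacts (templates,
segmentations, parameter and transition tables, a stats report and a run
log with seeds).

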