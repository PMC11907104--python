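# Methods

This note documents the models, conventions and numerical choices behind
the `microstates` package: what each stage computes, which knobs matter,
what the synthetic cohort generator does and does not emulate, and where
the design was genuinely open.

## The microstate model

Resting-state EEG spends most of its time in a small number of quasi-stable
scalp potential topographies ("microstates") that persist for roughly
60–120 ms before switching abruptly. The analysis decomposes a multichannel
recording into a sequence of K = 4 such states (the canonical classes A–D)
and quantifies, per subject and class:

- **duration** — mean lifespan of a state, in ms;
- **occurrence** — states per second;
- **coverage** — percent of analyzed time spent in the class;
- **mean GFP** — mean global field power over the class's samples, in µV;
- **GEV** — fraction of GFP-weighted topographic variance the class
  template explains;
- **syntax** — the K×(K−1) relative transition percentages between
  classes.

GFP at sample *t* is the population (1/E) standard deviation of the
potential across the E electrodes. The 1/E divisor is the convention of the
microstate literature; with average-referenced data it equals the RMS
amplitude over channels. Polarity is ignored throughout (a topography and
its sign-flip count as the same state), which is appropriate for
spontaneous, non-event-locked EEG.

## Pipeline

1. **Average reference** per sample.
2. **Band-pass 2–20 Hz**, zero-phase (forward–backward) Butterworth of
   order 4 per pass. Filtering is applied per epoch because epochs were
   excised from a longer recording and are not continuous; a consequence is
   that each epoch must exceed the filter warm-up (~30 samples). Measured
   response: <5 % amplitude error at 10 Hz, >90 % attenuation at 0.5 and
   40 Hz.
3. **Trim** every subject to the same analyzed length (default 129.996 s,
   i.e. 32 499 samples at 250 Hz), taken epoch-by-epoch from the start.
4. **GFP peaks**: strict local maxima of the GFP inside each epoch; flat
   runs count once at their first sample; epoch edges are never peaks.
   Peaks are the highest-SNR samples and are the only samples used for
   clustering and class assignment.
5. **AAHC** (atomize-and-agglomerate hierarchical clustering) of the peak
   maps into K = 4 clusters, GFP-weighted, polarity-invariant. Every map
   starts as its own cluster; the cluster contributing least global
   explained variance is repeatedly dissolved and its members reassigned to
   the best-correlated surviving cluster. Cluster templates are the
   dominant spatial component (first principal direction) of the member
   maps — robust to polarity mixing, unlike plain averaging. Atomization
   ties break to the cluster with fewer members, then lower index.
   The reported GEV is computed under the final argmax-correlation
   assignment of every map to the final templates — the same rule
   backfitting uses, so refitting a subject with their own templates
   reproduces the fitted GEV exactly.
6. **Template hierarchy**: per-group grand means (equal subject weighting
   of the normalized individual templates), a grand grand mean over group
   means, sorted against a set of canonical norm topographies, then the
   sorted order cascaded back down (grand grand mean → group means →
   individual sets). Sorting searches all K! label permutations
   exhaustively for the maximum summed |correlation| and sign-aligns each
   map to its reference class.
7. **Backfitting**: each GFP peak takes the label of its best-correlated
   template; non-peak samples inherit the label of the nearest peak in the
   same epoch, switching at the midpoint (an exactly equidistant sample
   opens the later peak's run). Epochs without usable peaks stay
   unassigned. Maximal same-label runs become segments; segments touching
   an epoch edge are flagged *truncated*.
8. **Quantification**: truncated segments are excluded from duration means
   only (their true lifespan is unknowable) but still count for occurrence,
   coverage, mean GFP and transitions; a `strict` policy that excludes them
   everywhere is available (`TruncationPolicy`). A class with no complete
   segment gets a missing — never zero — duration. Transitions are ordered
   pairs of consecutive segments within an epoch. No temporal smoothing or
   minimum-duration merging is applied by default.
9. **Outlier screen**: a subject is dropped from a parameter's analyses if
   any class value lies outside the subject's own group mean ± 3 SD for
   that class (single pass, per parameter only).
10. **Statistics**: three mixed ANOVAs (duration, occurrence, coverage;
    group between, class within) with Mauchly's sphericity test and
    Greenhouse–Geisser correction of both the class and the interaction
    degrees of freedom when sphericity is rejected at α = 0.05; Welch
    t-tests with Cohen's d (pooled, n−1-weighted) for overall group
    contrasts pooled over subject×class observations; Welch tests on the
    12 ordered transition pairs with Bonferroni m = 12; and a randomization
    TANOVA.

### TANOVA

Each subject map is normalized to unit GFP so only the spatial distribution
is compared; the effect statistic is the GFP of the difference between the
two group-mean maps; the null comes from reshuffling subjects between
groups preserving group sizes. p uses the add-one estimator
(1 + #{null ≥ observed}) / (1 + N), never exactly zero; the default is
5000 permutations. Internally, subjects are put in a canonical order and
the smaller group size defines the permuted subset, which makes p exactly
invariant to group relabeling and to subject ordering. Two entry points are
provided: per-subject mean maps (overall test) and per-subject per-class
templates (the per-class variant).

## Synthetic cohorts

Clinical recordings of this kind are not openly shareable, so validation
rests on parameter recovery from simulated cohorts with known ground
truth.

The generator draws a semi-Markov state sequence — class from a
row-stochastic transition matrix with zero diagonal (so adjacent states
always differ), dwell from a gamma distribution (default mean 80 ms, shape
4: strictly positive, unimodal, matching the empirical 60–120 ms
quasi-stability; no published generative model exists, this is the
package's choice) — and projects it through the active class's topography
with a 10 Hz (eyes-closed alpha) sinusoidal carrier whose phase resets
uniformly at each transition, so state changes are marked by topography,
not phase continuity. White Gaussian sensor noise is added at a configured
signal-to-noise ratio (default SNR 2, RMS over all channels and samples);
an optional spatially smoothed noise variant exists but defaults off for
determinism. Defaults mirror a routine clinical acquisition: 25-channel
IFCN montage, 250 Hz, 8 × 20 s artifact-free epochs, per-class amplitude
25 µV (≈5 µV GFP at oscillation maxima).

Cohorts have two balanced groups. Group effects are multiplicative on dwell
and amplitude and additive (row-renormalized) on transition rows.
Per-subject lognormal jitter (σ = 0.1) on dwell and amplitude provides
between-subject variance for the ANOVA layer; two thirds of each group are
flagged migraine-comorbid for subgroup re-runs.

The canonical norm templates used for sorting are analytic stand-ins built
from the montage layout (A: right-frontal/left-posterior diagonal, B: the
mirror diagonal, C: anterior–posterior, D: fronto-central versus
periphery); a user-supplied norms file is accepted when sorting real data.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: eye blinks, muscle artifact, electrode drift,
1/f background spectra, spatially correlated noise (by default), volume-
conduction forward models, or topographies that drift within a state. The
simulation validates the pipeline's bookkeeping and statistics, not its
behavior under real-world artifact.

## Numerical choices and degenerate inputs

- Spatial correlations are computed on mean-referenced vectors; a
  zero-variance map raises, except at backfitting peaks where it is
  skipped with a warning.
- Sorting ties (equal permutation objectives within 1e-12) break to the
  lexicographically smallest permutation.
- Template sign after the eigendecomposition is aligned to the weighted
  majority of member maps; an exactly balanced split falls back to making
  the largest-magnitude component positive.
- A fully constant response in the mixed ANOVA (zero effect and zero error
  variance) is reported as F = 0, p = 1 rather than NaN.
- Trimming computes `floor(seconds × fs)` with a 1e-9 guard against float
  representation of the requested seconds.
- The EDF writer quantizes to 16 bits against the header's ASCII-truncated
  physical range so the reader's affine decoding inverts the writer
  exactly; round-trip error is bounded by half a quantization step.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` use: 100 random instances for
the GEV brute-force cross-check (agreement to 1e-12); 20 instances of 12
maps for the AAHC-versus-exhaustive-enumeration check (all set partitions
into 3 blocks, with each block's optimal GEV obtained as the largest
eigenvalue of its weighted outer-product sum); cohorts of 10/group at
8 × 20 s for ground-truth recovery; 500 null simulations at 1000
permutations for TANOVA and mixed-ANOVA type-I calibration; and 20/group
for effect detection (dwell ×0.85, amplitude ×0.8, A→B +0.15).

## Known limitations

- **Greedy suboptimality under amplitude imbalance.** AAHC's
  dissolve-least-GEV step can atomize a spatially coherent cluster whose
  maps happen to have low GFP, landing a few percent below the exhaustive
  partition optimum. With homogeneous weights the algorithm is essentially
  optimal on well-separated data.
- **Short-state invisibility.** Class membership is decided at GFP peaks,
  so a true state shorter than the inter-peak spacing (half the carrier
  period plus noise) contains no peak and is absorbed by its neighbors.
  This biases recovered durations slightly upward (≈+6 ms at the default
  80 ms dwell / 10 Hz carrier) and is inherent to peak-based backfitting,
  not a defect of the implementation.
- **Overall group tests** pool subject×class observations (≈2×21×4
  values), which treats classes within a subject as independent; the mixed
  ANOVAs are the inferentially safer route and both are reported.
- The exhaustive sorting step is O(K!) and restricted to K ≤ 6; the study
  design fixes K = 4.
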