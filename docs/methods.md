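# Methods

## The analysis model

The package treats a multichannel EEG recording as a labeled matrix of
microvolt time series and an *epoch* as a fixed-length slice carrying the
factors of a fully within-subject 2 (condition: neutral / negative) ×
2 (task: elevator / plank walking) design. All network analysis is
channel-space: nodes are electrodes, and no source reconstruction or
volume-conduction correction is attempted beyond the wPLI's intrinsic
insensitivity to zero-lag coupling.

Two connectivity estimators feed three network measures:

* **Pearson connectivity.** The absolute sample correlation between
  channel time series. Absolute values are used because the distance
  transform `d = 1/w` and shortest-path search require nonnegative
  weights; the sign of a scalp correlation is reference-dependent anyway.
  The reciprocal transform (rather than `d = 1 − w`) follows the reading
  of distances "inversely proportional" to coupling strength.
* **wPLI.** Cross-spectra are estimated per Hann-tapered 2-s window with
  50 % overlap (Welch ensemble); the imaginary parts are averaged across
  the frequency bins in 1–40 Hz *before* the index
  `|Σ_k Im S_k| / Σ_k |Im S_k|` is formed over windows `k`. Averaging
  bins first keeps a narrowband coupling from being diluted by the empty
  bins of the analysis band; the index stays in [0, 1] and keeps its
  insensitivity to zero-lag coupling. Imaginary parts below 1e−12 of the
  mean power are floored to zero so that an exactly real cross-spectrum
  yields wPLI = 0 (the zero-denominator convention) rather than numerical
  noise. The plain (not debiased) estimator is used. With K windows the
  null expectation is ≈ √(2/πK), i.e. ~0.13 at 60-s epochs and ~0.27 at
  10-s epochs — finite-sample bias that cancels in within-subject
  contrasts but matters when reading raw values.

* **Efficiency** is the mean inverse shortest-path length over all node
  pairs (Dijkstra on the distance matrix; disconnected pairs contribute
  zero). Parts of the EEG literature label this quantity "local
  efficiency" when applied per region; it is the canonical *global*
  efficiency formula, here applied either to the whole graph or to the
  subgraph induced by a region's electrodes (paths confined to the
  region).
* **Modularity** uses Newman's configuration-null Q at resolution 1 on
  the binarized top-75 %-of-edges network. Louvain community detection is
  order-dependent with deep suboptimal basins on small graphs, so the
  implementation runs the greedy two-phase algorithm from several
  deterministic restarts (default 8; 100 in oracle comparisons) and keeps
  the best-Q partition. Q itself is always recomputed by the package's
  own formula on the returned partition.
* **Eigenvector centrality** is the leading eigenvector of the (wPLI)
  adjacency, computed by power iteration on `A + I` — the shift leaves
  eigenvectors unchanged, guarantees dominance of the Perron eigenvalue,
  and prevents oscillation on near-bipartite graphs. Convergence is
  1e−10 in max-norm with a hard iteration cap that raises on failure. The
  vector is oriented nonnegative and normalized to unit Euclidean norm;
  regional values are means over the region's electrodes.

Proportional thresholding retains exactly `⌈keep · n(n−1)/2⌉` edges
(`keep = 0.75`), with ties broken by descending weight then ascending
label pair, so the network density — and hence the scale of every graph
metric — is identical across subjects and conditions.

## Statistics

With both factors at two levels, each effect of the repeated-measures
ANOVA is exactly the squared paired-t of its within-subject contrast
(subject means across levels for main effects, the double difference for
the interaction), giving F(1, n−1) identical to the classical
sums-of-squares decomposition; no sphericity question arises. Partial eta
squared is `F/(F + df_err)`. A zero-variance contrast (constant input) is
reported as F = 0, p = 1 rather than raising, so degenerate synthetic
cells cannot abort a batch; the event is logged. The KS normality screen
fits the normal to the sample, so its p value is calibrated by seeded
Monte Carlo (the Lilliefors construction, 10,000 replicates by default)
instead of the anti-conservative classical formula. Post hoc contrasts
are paired t tests with Bonferroni `p_adj = min(1, m·p)`. No correction
is applied across the many (scope, metric) ANOVAs by default, mirroring
per-region α = 0.05 reporting practice; a flag enables Bonferroni across
scopes.

## The synthetic-data generator

Every planted coupling is an *edge*: two channels share one sinusoidal
oscillator at one frequency, with a fixed phase lag and a strength in
[0, 1] scaling the shared amplitude; independent white Gaussian noise is
added per channel. This shared-source model is chosen over a neural-mass
model because the ground-truth lag and strength of every pair are then
analytically known, which is what estimator validation needs.

Two deterministic sinusoids at the *same* frequency are phase-locked
within a realization whether or not they share an oscillator, so every
edge receives its own frequency (within-region edges spread over
4–13 Hz, cross-region edges over 14–26 Hz). The default lag is π/4:
visible to both amplitude-based estimators (Pearson picks up
cos π/4 ≈ 0.71 of the shared power) and phase-lag estimators (the
imaginary cross-spectrum has a consistent sign).

Study designs at the reduced test scale (16 channels covering four
regions, 250 Hz, 10-s epochs; the full study scale of 32/1000/60 is a
configuration choice) share: amplitude 3 µV per full-strength oscillator,
noise 1 µV, base within-region strength 0.6 on a ring topology per
region, and a per-subject random intercept of SD 0.05 on all strengths,
which creates the within-subject correlation a repeated-measures analysis
assumes. Strengths pushed outside [0, 1] are clipped and counted in a
logged warning.

* the **null design** makes all four cells identical — the type-I-error
  calibration condition;
* the **frontal design** adds +0.3 to frontal within-region strengths in
  the negative cells (both tasks) — a condition main effect;
* the **cross-region design** adds 70 diffuse between-region couplings
  (a fixed pseudo-random subset of pairs, one oscillator and frequency
  each, strength 0.8) in the negative cells. Because proportional
  thresholding retains a fixed *count* of edges, these added couplings
  crowd within-region pairs out of the retained set, lowering modularity
  — a genuine loss of segregation. Diffuseness matters: concentrated
  bridges between region pairs would hand the community detector new
  exploitable modules and *raise* Q.

What the generator does not emulate: volume conduction and a common
reference (which correlate neighboring real electrodes far above the
planted levels), 1/f background spectra (white noise keeps closed-form
checks valid; a pink-noise flag would add realism, not validity),
artifacts (blinks, EMG, motion), and nonstationarity. Consequently,
passing tests show that the *estimators and statistics* behave correctly
on signals with known coupling; they do not show that preprocessing
choices suffice for real scalp data. In particular the 0.8
window-correlation bad-channel criterion presumes conduction-level
neighbor correlations, which only conduction-like fixtures (near-zero
lag, shared frequency) reproduce; the study designs do not, so the
pipeline skips bad-channel screening for synthetic input.

## Numerical choices

* Bandpass: windowed-sinc (Hamming) FIR, transition width
  `min(max(0.25·low, 2 Hz), high/4, 2·low)` — the last term keeps DC in
  the stopband for low edges under 1 Hz; odd length, applied by centered
  convolution (zero net phase); signals shorter than 3× the kernel raise.
* Line noise: 4-s Hann-weighted windows at 50 % overlap; sine/cosine
  regressors at the line frequency and all window-grid frequencies within
  ±bandwidth/2; the fitted narrowband estimate is subtracted by
  overlap-add.
* Spherical splines: Perrin-style Legendre series, 7 terms, order m = 4,
  ridge 1e−5, zero-sum constraint; electrode positions come from the
  standard idealized 10-10 montage re-centered and projected to the unit
  sphere.
* Sub-seeds for epochs and stages derive from the global seed by CRC-32
  hashing of the (subject, condition, task) identity, so results are
  independent of iteration order; all seeds stay below 2³¹.
* EDF is written as one data record with per-channel physical ranges
  fitted to the data (quantization max|x|/32767); BrainVision supports
  IEEE float-32 and int-16 payloads in both channel orientations.

## Design decisions on open points

* "Plank walking" maps to the end-of-plank segment by default (active
  walking), with `plank_start` and `mean_of_both` as config options —
  three recorded segments feed a two-level task factor, and the mapping
  is a modeling choice.
* Negative Pearson correlations are rectified by absolute value before
  the distance transform; shortest paths are undefined for negative
  weights and channel-space correlation signs are not interpretable.
* Eigenvector centrality consumes the wPLI matrix — the phase-lag measure
  already computed in the pipeline — rather than a separate coherence
  estimate.
* Per-condition modularity is the mean of per-epoch Q values.
* The FCz reference electrode is not assumed present; region maps
  restrict themselves to the electrodes actually recorded, and a region
  drops out of regional analysis below two members.

## Problem sizes

Default validation runs use the reduced scale throughout: type-I
calibration uses 1000 replicate null studies at n = 20 (600 in the
acceptance script); directional-recovery checks use 20 replicate studies
at n = 75 (15 in the script); oracle comparisons use 100 random graphs of
4–7 nodes, where exhaustive partition enumeration (Bell numbers ≤ 877)
and DFS path enumeration are feasible.

## Known limitations

Channel-space metrics inherit reference and conduction effects in real
data; the wPLI finite-sample bias makes raw values scale-dependent across
epoch lengths; Louvain restarts make the found Q a lower bound on the
true maximum, not an exact optimum; and the generator's effect sizes are
calibration knobs for validating recovery, not estimates of any real
study's physiological effect sizes.
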