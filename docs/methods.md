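# Methods

`nanet` reimplements, as a tested pipeline over synthetic data, a
multilayer-network analysis of spontaneous calcium activity in mixed
neuron–astrocyte cultures: dishes imaged under a 2×2 drug-by-injury design
(mGluR5 blockade with MPEP versus vehicle; targeted neuronal micro-injury
versus sham), with astrocyte microdomains (segments) treated as independent
network nodes alongside whole neurons.

## The synthetic study generator

The generator stands in for the study's unreleased imaging data. It is
first-class, tested code; its defaults define the study conditions used by
the test suite and the acceptance script.

**Populations.** Neurons are plated uniformly at random in a
1000 × 1000 (length-unit) field of view; each astrocyte contributes a
cluster of segments (1 + Poisson, mean 5 per cell by default) within a
50-unit cell radius of its center. Defaults: 40 neurons and 3 astrocytes
per dish, emulating dishes with tens of neurons and a handful of active
astrocytes split into ~5 segments each.

**Ground-truth coupling.** Pairs couple by a Bernoulli draw with
probability `(1 − s)·ρ + s·ρ·w_ij`, where `ρ` is the base density (0.15),
`s` the spatial mixing fraction (0.2 at baseline), and `w_ij = 1 − d/d_max`
the linear proximity weight. Connected pairs receive coupling strength 0.8.
Uniform variates are drawn before thresholding, so changing the
probabilities under the same seed yields nested edge sets — conditions
perturb the same dish rather than resampling it.

**Event trains and traces.** Each ROI fires a Poisson event train —
neurons at 0.08 Hz, astrocyte segments at 0.02 Hz by default; the source
study reports rates only graphically, so these are free parameters set in
the range typical of spontaneous activity in dissociated cortical culture.
Coupled pairs share events through a common latent train: each pair owns a
latent Poisson train whose events are copied into both members with
probability equal to the coupling strength, so one knob controls the trace
correlation. The latent rate is `share_scale · min(r_i, r_j) / d̄`, with
`share_scale = 0.8` and `d̄` the dish's baseline mean coupled degree; the
division splits each node's shared-rate budget over a typical partner
count, and over-budget nodes have their shared copies thinned so marginal
event rates stay at the configured values in expectation. Events are
convolved with unit-peak double-exponential templates (rise/decay
0.1 s / 0.6 s for neurons, 0.5 s / 2 s for segments — GCaMP6f-like
kinetics, faster in neurons) and i.i.d. Gaussian noise (σ = 0.1 of the
template peak) is added. Sampling is 20 Hz (50 ms exposure), 120 s per
recording by default.

**Condition effects.** Effects are multiplicative knobs attached to
(arm, timepoint) cells and are identity at baseline:

- MPEP lowers the neuronal event rate (×0.6) from the post-drug timepoint.
- Injury, at the post-injury timepoint, scales the *probability* of
  neuron–neuron coupling (×1.5) — more coupled pairs with an unchanged
  weight distribution — and doubles the spatial mixing fraction with a
  density compensation, so coupling becomes more local without changing
  how many couplings exist. A pure strength multiplier was rejected during
  design: under max-weight-normalized (Onnela) clustering, uniformly
  stronger edges deflate the normalized triangle products and cancel the
  density-driven clustering increase.
- MPEP pre-treatment attenuates both injury knobs back to ×1.0,
  emulating the protective interaction the analysis is designed to detect.

What the generator deliberately does **not** model: biophysical astrocyte
Ca²⁺ dynamics (IP₃, waves), pixel-level movies, bursting/up-down states,
non-stationary rates, photobleaching, and whole-cell astrocyte events that
synchronize many pairs at once. Because pairwise latent trains conserve
each node's rate budget, mean pairwise correlation necessarily falls as a
node gains partners — real recordings, where one network burst can
correlate many pairs simultaneously, are not so constrained. Passing tests
therefore demonstrate that the *analysis* recovers what was planted under
these statistical assumptions, not that real cultures behave this way.

## Trace processing and event detection

Traces are linearly detrended, low-pass filtered (4th-order Butterworth,
2 Hz cutoff, zero-phase `filtfilt` so event timing is preserved), and
z-scored; constant traces map to zeros. Events are detected by
sliding-window Pearson correlation against the per-cell-type template
library; local maxima with r ≥ 0.8 become events, and overlapping
candidates within one template length are resolved greedily to the
highest-correlation onset. The strict default threshold stands in for the
original pipeline's manual event confirmation, whose acceptance rate is
unknowable. True events closer together than one template length can merge
into a single detection; the detection-quality tests therefore use isolated
insertions, and rate summaries inherit a small downward bias at high rates.

ROIs with no events in any of a dish's recordings are dropped from all of
them; dishes left with fewer than two active astrocyte segments are flagged
and excluded from astrocyte-layer analyses (they remain in neuron and
multilayer analyses).

## Functional and spatial networks

A pair's functional weight is the Pearson correlation of the processed
traces, gated by a surrogate test: the observed r is compared, via a
two-sided normal z test at α = 0.05, with its distribution over 100
amplitude-adjusted Fourier transform (AAFT) surrogates of one member of the
pair. AAFT surrogates preserve the marginal distribution exactly (sorted
values are identical by construction) and the power spectrum approximately;
Gaussianization uses normal order statistics (Blom offsets), a deterministic
variant of the classical sorted-noise construction. Surrogates are built
once per ROI (for the higher-index member of each pair) from seeds derived
from the master seed. Significant edges keep their signed r; all topology
metrics use |w| (the fraction of negative edges is available for logging).
Spatial weights are `1 − d/d_max` on centroid distances with `d_max` the
FOV diagonal, zero diagonal by convention.

## Multilayer assembly and metrics

Neuron–neuron, astrocyte–astrocyte, and interlayer blocks concatenate into
one symmetric matrix (neurons first) so single-layer machinery applies.
Intralayer nodal strength is normalized by (own-layer size − 1), interlayer
strength by the other layer's size; the reported interlayer mean pools the
node-level normalized interlayer strengths of both layers. The
balance-control operation subsamples the neuron layer uniformly down to the
astrocyte count (25 repeats by default, metrics averaged).

Metrics follow the Brain Connectivity Toolbox's weighted forms: density κ;
mean normalized degree K and strength S; Onnela clustering C on weights
rescaled by the matrix maximum (nodes of degree < 2 contribute 0);
betweenness B on lengths 1/|w|, normalized by (N−1)(N−2)/2; global
efficiency E as the mean inverse shortest-path distance over ordered pairs
(disconnected pairs contribute 0). Null networks are Maslov–Sneppen edge
swaps carrying weights on edges, with 100 swap proposals per edge (10 for
the small astrocyte networks); networks with ≤ 3 edges are returned
unchanged. Observed-minus-null deltas use a 100-member ensemble mean by
default (a single randomization per dish is noisy for small networks), and
per-dish deltas feed two-sided one-sample t tests.

## Spatial–functional dependence

Per connection class (NN, AA, interlayer), pairs pooled across dishes of a
condition are binned by spatial weight into 30 equal-width bins over [0, 1]
(empty bins dropped); connection probability = nonzero edges / pairs per
bin, regressed on the bin-mean spatial weight with a 95% CI on the slope.
Edge-weight regression uses all pairs including zero-weight ones (edge
existence is the probability curve's job); a nonzero-only mode exists
behind a flag. The 2-D correlation subtracts a uniform-random-matrix
baseline averaged over 100 draws to remove finite-size jitter.

## Communities

Partitions maximize Newman–Girvan modularity `Q = (1/2m) Σ (w_ij −
γ k_i k_j / 2m) δ(g_i, g_j)` on |w|. Because the modularity landscape is
rough on small networks, the consensus routine runs the Louvain heuristic
50 times, aligns each run's arbitrary labels to the highest-Q run by
Hungarian maximum-overlap matching, takes per-node modal labels (ties to
the smallest label), and recomputes Q on the consensus. The functional
resolution is fixed at γ = 1; the spatial γ is grid-searched
(0.5–2.0, step 0.05, ties to the smallest γ) to match the functional
community count — a reproducible replacement for manual tuning, anchored on
the functional side because the spec leaves the anchor open. Partitions are
compared by a pair-counting adjusted Rand index; astrocyte segments'
morphological (parent-cell) partition serves as the "actual" partition in
three-way comparisons. Module participation is the fraction of modules
containing at least one node of a cell type. On weakly structured graphs
the 50-run consensus can still vary between batches; the per-run partitions
are retained on the result object for audit.

## Statistics

Topology outcomes are fit with identity-link normal GLMs (which reproduce
OLS exactly; this is asserted in tests): outcome ~ intercept + MPEP
indicator + Sham indicator (1 = uninjured) + interaction + covariate, the
covariate being mean nodal strength for C/B/E and event rate for S. With
this coding an injury-driven increase appears as a negative Sham
coefficient. Per-arm injury contrasts (−β_Sham and −(β_Sham + β_int)) are
exposed directly. Group comparisons use one-/two-way ANOVA with Tukey or
Holm–Šidák corrections and paired/unpaired t tests. No correction is
applied across GLM outcomes. Dishes are treated as independent; there are
no mixed effects.

## The effect-recovery experiment

`nanet.experiments.run_effect_recovery` replays the full pipeline over
independent master seeds with the planted injury effect and over a matched
no-effect study. Because each dish's baseline recording shares the
ground-truth coupling draws with its post-injury recording, the injury
response is estimated as a within-dish change from baseline — the paired
design the imaging timepoints exist for — which cancels dish-level
structural variation in the topology metrics. Per replicate study the
pattern score asks whether the combined neuronal clustering-plus-efficiency
change (dC + dE) is larger in the untreated injured arm than untreated
sham, whether the efficiency change alone is larger, and whether the
combined response is attenuated in the MPEP arm; per-metric C and E
directions are reported alongside. The combined score is used because the
clustering effect attainable under the generator's rate-budget constraint
is modest, so the per-metric C sign alone is recovered in only a fraction
of replicate studies at the emulated 9-dishes-per-arm design (the pooled C
contrast across replicates is positive and is reported). Vs-null deltas
are reported by the pipeline but are not the pattern score: under spatially
localized coupling the efficiency delta moves opposite to efficiency itself
(local graphs are less efficient than their degree-preserving rewirings).
The no-effect study's GLM Sham z statistics check calibration (~5% of
|z| > 1.96 expected).

Problem sizes for this experiment (and the run-directory drivers) are
scaled for desk-scale reproduction: 9 dishes per arm, 25 neurons and
2 astrocytes × ~4 segments per dish, 120 s recordings, baseline +
post-injury timepoints. The dish count matches the emulated design; the
smaller networks keep the rate-budget dilution of per-pair correlation
mild, which is where edge-detection power is highest.

## Numerical choices and degenerate inputs

- Constant traces: preprocessing returns zeros; AAFT and the edge test
  refuse them (silent ROIs simply carry no edges in matrix construction).
- Zero surrogate-correlation variance raises rather than fabricating a z.
- Empty graphs: modularity and consensus raise; efficiency/clustering of
  edgeless graphs are 0; betweenness of n < 3 graphs is 0.
- Gamma-grid ties break to the smallest γ; consensus label ties to the
  smallest label; all randomness flows through seeded `SeedSequence` spawns
  so every artifact is bit-reproducible given (config, seed).
- Rewiring preserves the degree sequence and edge count exactly (asserted
  per use in tests), not the weighted strength sequence — weights travel
  with edges, the standard BCT behavior.

## Known limitations

- The generator's rate-budget conservation caps attainable pairwise
  correlation at ~1/partner-count; effect sizes on clustering are
  correspondingly modest at realistic densities.
- Template-matching cannot resolve events closer than a template length.
- The surrogate z test assumes approximate normality of the surrogate
  correlation distribution; for very short traces the empirical quantile
  test would be preferable.
- Interlayer "mean strength" pooling (both layers' node-level normalized
  strengths) is one of several defensible conventions.
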