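# Methods

## The problem

A neural population shows *nonlinear mixed selectivity* (NMS) for two
experimental variables when its response to a combination of them is not the
sum of its responses to each variable alone — an interaction effect in its
tuning.  In multivoxel data the natural multivariate statement is a
*difference in differences*: the difference vector between the activity
patterns for two values of one variable (say, two stimulus categories)
changes across values of the other variable (say, two task contexts).

Two standard observations motivate a dedicated test.  First, a *drop in
cross-decoding* (training a classifier in one context, testing in the other)
is neither necessary nor sufficient for an interaction: an oblique but
purely additive geometry can break cross-decoding without any interaction,
and an interaction can leave cross-decoding intact when the patterns stay on
the correct side of the trained boundary.  Second, single voxels are noisy
and may carry heterogeneous interactions that cancel in a univariate
average.  *Pattern difference decoding* addresses both.

## Pattern difference decoding

For a dataset of block-wise voxel patterns labeled with run, task (2
levels), and category (8 levels):

1. z-score every block across voxels (mean 0, SD 1, divisor n−1).  This
   removes per-block amplitude and offset confounds; the divisor choice is a
   uniform rescaling and cannot change max-margin decisions.
2. Direction A — *category differences across tasks*: within each run, for
   each unordered category pair, form the difference vector (smaller label
   minus larger, a fixed global convention).  Train a linear SVM (C = 1) to
   classify the task of each difference vector, per category pair, under
   run-respecting cross-validation; average over the 28 pairs.
3. Direction B — *task differences across categories*: within each adjacent
   run pair (which contains one run of each task), for each category, form
   the between-task difference vector.  Classify the category of each
   vector, pairwise over the 28 category pairs, same CV; average.
4. The final statistic is the mean of the two directions (both test the same
   interaction; their per-participant accuracies are strongly correlated).
   Chance is 0.5; above-chance accuracy implies a systematic multivariate
   interaction.

Difference vectors pair blocks *within* a run (or within an adjacent run
pair), so run-level additive artifacts cancel in the subtraction.

### Cross-validation

Runs alternate tasks, with the two middle runs sharing a task so that
neither task occurs systematically earlier in a session; consequently every
adjacent run pair (2i−1, 2i) contains one run per task.  Analyses confined
to one task use leave-one-run-out CV; analyses whose training set needs both
tasks leave out one adjacent run pair at a time.  Cross-context decoding
trains on all-but-one fold of the training context (rotating) so that the
training-set size matches the within-context analysis — otherwise the
cross-decoding ratio would be biased by data quantity alone — and tests on
every block of the other context.  Training on the full context at once is
available via `DecodingSpec(cross_train_full=True)`.  Exact-zero decision
values are resolved by a seeded coin flip.

### Cross-decoding ratio

To compare the generalization drop across regions with different baseline
decodability: ratio = (between − .5) / (within − .5); 1 means full transfer,
below 1 a drop.  A participant with within-context accuracy ≤ .5 has an
undefined ratio and is flagged and excluded from the ratio test (with a log
entry), never silently dropped.  A probit variant Φ⁻¹(between)/Φ⁻¹(within)
is provided for users worried that accuracy is a nonlinear function of
pattern separation; Φ⁻¹(.5) = 0, so no baseline subtraction is needed there.

### Per-participant permutation test

The difference-vector labels are permuted 1000 times by default and the
decoding repeated under each relabeling; p is the proportion of permuted
accuracies strictly higher than the observed one ("proportion higher"
rule; a bias-corrected (1+b)/(1+N) variant sits behind a flag for users
who need p > 0).

The relabeling is one *block-level* null transformation per iteration —
within each adjacent run pair, swap the two runs' task assignments with
probability 1/2 and permute the category labels — pushed forward exactly
through the difference-vector construction: task contexts swap and
between-task difference vectors negate (the fixed subtraction convention
reverses) under a run swap; category contexts and category-pair
memberships are remapped (with a sign flip where the pair's lexicographic
subtraction order reverses) under the category permutation.  Both analysis
directions, every pairwise problem and every CV fold — training and test —
inherit the *same* relabeling.

This coherence is what makes the test calibrated: the observed statistic
carries a single labeling through folds, through block-sharing (hence
correlated) pairwise problems, and through the two averaged directions,
so its null distribution is wider than an average over independent
per-fold, per-problem or per-direction shuffles.  Shuffling only the
training labels (a scheme sometimes described in the decoding literature)
additionally scores the permuted classifier against test labels it never
saw; measured on exchangeable null data these simplifications reject at
2–5× the nominal rate at desk-scale designs.  The training-only variant is
retained behind ``permute_scope="training_only"`` for literal
reproduction; the default coherent scheme measures a false-positive rate
of 0.04–0.05 at the nominal .05 with KS-uniform null p-values.  With main
effects present the block-level swaps are exactly null-preserving for the
means (by the z-scored additive construction) and approximate for
higher-order structure, as for any interaction permutation test in the
presence of main effects.

### Group-level Bayesian evidence

Per-participant correct counts k_j of n_j enter a hierarchical model

    k_j ~ Binomial(n_j, pi_j),   logit(pi_j) ~ Normal(mu, sigma^2),
    mu ~ Normal(0, 10^2),        sigma ~ half-Normal(2),

and the evidence for above-chance decoding is the posterior odds
p(mu > 0) / p(mu < 0).  The posterior is computed deterministically:
Gauss–Hermite quadrature (41 nodes) integrates out each participant effect,
and a 2-D grid over (mu, sigma) — with the tail integrals done in log space,
exact for log-linear segments — yields the sign probabilities.  The grid is
refined once and the relative change of the log-odds is the convergence
diagnostic; non-convergence raises rather than defaulting.  The cited
variational treatment of this hierarchy is reimplemented here in spirit, not
line by line: the priors above are this package's choice, validated against
an MCMC sampler on the identical model (test suite).  Counts, not rescaled
mean accuracies, enter the model; the result object also carries the mean
accuracy if a user prefers to rescale.

## Representational geometry

Pairwise linear decoding accuracy over all 16 category × task conditions
(120 pairs) defines a condition RDM.  For visualization the accuracies are
chance-referenced (subtract .5, clip negatives to 0) and embedded with
classical (Torgerson) MDS — deterministic, exact for Euclidean inputs, with
axes canonicalized so each axis's largest-magnitude coordinate is positive.
For inference no subtraction or clipping is applied: each participant's
28-entry within-task category similarity vector is correlated with the
average vector of the *remaining* participants, same task (within) and
opposite task (between).  The group mean within-task correlation is the
noise ceiling; each participant's variance explained is
(between / mean-within)².  A value of 1 means the task leaves the category
geometry unchanged; values below 1 mean the representational content itself
changes.  Negative between-task correlations are squared as-is (sign
reported separately) since squaring discards sign and the one-tailed test
direction is unaffected.  Second-order structure (region × task) uses
correlation distance 1 − r between similarity vectors.

Estimator caveat: the squared ratio is upward-biased under measurement
noise (E[r²] = E[r]² + var r).  At the reliability levels produced by the
default generator (ceiling r ≈ 0.65–0.7) the bias is ~2%; at low
reliability it grows, which is why cross-region comparisons should use the
reliability-corrected measure rather than raw between-task correlations.

## Frequentist scaffold

Each region's decoding analyses form a fixed family of 12 tests (category
decoding per task, between tasks, overall; task decoding; category-vs-task
contrast; both cross-decoding analyses, their drop tests and the category
ratio test; pattern difference decoding), corrected together by
Benjamini–Hochberg at q = .05.  One-tailed tests are used where only one
direction is meaningful (vs chance; drop tests; ratio < 1; variance
explained < 1), two-tailed where either direction is of interest.  The
geometry-change family is corrected separately.  Sector statistics average
the *final* per-region, per-participant values (e.g. ratios, not the
accuracies entering them), so each region contributes equally.

## The synthetic cohort generator

No generative model of voxel tuning is given by the analyses themselves;
every distributional choice below is a stand-in whose purpose is to give
the pipeline ground truth, not to model hemodynamics.

Each block pattern is `baseline + category template + task template
(+ interaction) + iid Gaussian noise`.  Templates are drawn once per cohort
and carried into each participant's voxel space by a random rotation of the
zero-mean subspace, so the cohort shares one representational geometry
(as human cohorts roughly do) while voxel-level tuning is idiosyncratic.

Defaults and why:

| parameter | default | rationale |
| --- | --- | --- |
| participants | 13 | the emulated study design |
| runs per task | 10 | ditto (alternating, middle repeat) |
| categories | 8 | ditto; one block per category per run |
| voxels | 100 | typical ROI scale for this kind of analysis |
| category_gain | 0.22 | within-task pairwise decoding ≈ 0.70–0.76, the ventral-ROI range |
| task_gain | 0.11 | task decoding weaker than category decoding, as observed empirically |
| noise_sd | 1.0 | unit-noise convention; gains are per-voxel RMS relative to it |
| geometry_dim | 2 | category geometry spanned by few latent axes; yields RDM reliability r ≈ 0.74–0.77 |
| seed | — | identical config ⇒ bit-identical cohort |

Geometry regimes: `additive` (no interaction; task adds a common shift),
`oblique` (additive, but the shift runs 1.5 half-separations along one
category axis, defeating cross-decoding without any interaction),
`rotation` (each latent axis tilted by `interaction_gain` radians into a
fresh orthogonal voxel dimension — an exact isometry: interaction present,
content preserved), and `reshape` (category templates rescaled by
exp(interaction_gain · g_c), g_c a shared standard-normal draw per
category: interaction present and pairwise distances altered).  Rotation
and reshape mirror the ventral-like and dorsal-like outcomes respectively.

With `normalize_additivity_domain="znormed"` (default) the additive null is
made exact in the analyzed space: templates are centered across voxels,
category templates share one norm, task templates are orthogonal to the
category span with equal norms across tasks.  Per-block z-scoring is
equivariant under rotations of the zero-mean subspace, so under this
construction the expected difference vectors are exactly
context-independent and pattern-difference decoding has nothing systematic
to find.  With `"raw"`, additivity holds in raw units and z-scoring can
introduce a small condition-dependent rescaling (a real concern for real
data, which is why the option exists).

What the generator does *not* emulate: hemodynamic dynamics and temporal
autocorrelation, spatial noise correlations between voxels, session/run
drifts beyond what differencing cancels, Latin-square block ordering (block
order within a run is a seeded permutation; order is irrelevant to every
implemented analysis), and attentional or behavioral variability.  Passing
calibration on these cohorts therefore demonstrates correctness of the
*analysis chain*, not robustness to all properties of real data.

## Toy geometries

Four deterministic two-signal-dimension datasets (embedded in 12 voxels
with zero-mean decoy dimensions, 16 runs per task, noise SD 0.05) realize
the 2×2 table of {cross-decoding succeeds, fails} × {interaction present,
absent}: an additive rectangle, an oblique parallelogram (shift = 1.5
category separations), a symmetric stretch (interaction with preserved
generalization), and a reversed difference vector (interaction with
inverted cross-decoding).  These are analyzed with normalization disabled:
z-scoring a 2-informative-dimension pattern would destroy the constructed
geometry.

## Numerical and design choices

- Linear SVM via libsvm (scikit-learn `SVC(kernel="linear", C=1)`);
  no voxel selection of any kind.
- Classical MDS rather than stress minimization: deterministic and exact on
  Euclidean inputs; degenerate all-zero RDMs embed at the origin with a
  warning.
- Study-condition sizes used in the calibration tests: the additive null
  cohort at the full design; rotation cohort at gain 0.6 rad; reshape
  cohort at gain 0.4; a graded-reshaping cohort with per-participant gains
  0 to 0.8.  These values produce interaction effect sizes
  (pattern-difference accuracies ≈ 0.52–0.55) in the range real regions
  show.  Permutation calibration runs on reduced single-participant null
  designs (4 categories, 6 runs per task, 16 voxels) whose statistic is
  fine-grained enough for the strict tie rule to stay calibrated; designs
  with only 2 categories show residual discreteness inflation and are used
  only where the Kolmogorov–Smirnov check's granularity suffices.
- Every random draw descends from one pipeline seed through named
  substreams (`derive_seed(seed, name)`), so stages are independently
  re-runnable and reruns are byte-identical.

## Known limitations

- The permutation test's strict "proportion higher" rule is slightly
  anti-conservative on coarse grids (ties); the bias-corrected variant is
  one flag away.
- The variance-explained estimator is noise-biased upward near 1 (see
  above); simulation-based expectations should be compared at matched
  reliability.
- Posterior odds for far-above-chance cohorts are astronomically large and
  numerically exact only in the log domain; downstream consumers should
  treat them as evidence categories, not precise numbers.
- Only 2-task, block-wise designs are supported; no trial-level designs,
  nonlinear kernels, multiclass decoding, or searchlights.
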