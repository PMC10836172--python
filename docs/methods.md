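# Methods

This note documents the models implemented in `gradlex`, the synthetic
data they are exercised on, the numerical conventions, and the places
where the design was genuinely open.

## The statistical pipeline

### Effect maps

**BOLD-style route.** Word events enter an event-related design matrix as
parametric regressors: a boxcar at each included event (content word,
sentence position ≥ 6) with amplitude equal to the centred/scaled
parameter value and duration either fixed at 1 s (`fixed_1s`, the default,
appropriate when presentation duration is confounded with word length) or
the actual presentation duration (`actual_duration`). Categorical
part-of-speech regressors cover all word events; sentence-level regressors
(complex/simple sentence, presentation order) span whole sentences; a
fixation/cue regressor covers the second before each sentence. All task
regressors are convolved with a canonical double-gamma HRF (gamma shapes
6 and 16, undershoot ratio 6, 32-s support, peak-normalised) on a fine
grid (dt = 0.1 s) and sampled at scan onsets; each is paired with its
temporal derivative. High-pass filtering at 100 s is implemented as a
discrete-cosine drift basis appended as nuisance regressors — projection
onto the same subspace as filtering the data, but easier to test. Motion
and scrubbing regressors can be appended as pre-made columns; they are
never computed here. First-level fits are ordinary least squares per
parcel; the group map is a one-sample t across participants per parcel
(summary-statistics approach), converted to a two-tailed p and then to a
z carrying the sign of the mean, capped at |8| so degenerate
between-participant variance cannot produce infinities.

Vertex-level group maps can be averaged into parcels with the
field-of-view rule: vertices whose interpolated mask weight fell below
.75 are dropped, and a parcel is kept only if at least 25% of its
vertices survive.

**MEG-style route.** Per parcel and 100-ms window, a linear mixed model
`activation ~ length + old20 + logfreq + semsim + position + POS +
complexity + order + (1 | participant)`, REML-fit with statsmodels'
MixedLM. An item random effect is deliberately absent: with one
observation per item and parcel it overfits (singular fits), so the model
follows the parsimonious-mixed-model practice of dropping it. When the
participant variance component itself converges to the boundary, the
parcel is refit by ordinary least squares and flagged; forcing the
component to zero reproduces the OLS solution exactly, which the tests
exploit. One test cross-checks the REML estimates and standard errors
against lme4 through Rscript.

**Duration control.** Presentation duration tracks word length closely
(r ≈ .9 in the generator, by construction). All models are therefore
refit with duration substituted for length, and any effect other than word
length is reported significant only when it passes in both versions.

### Gradient alignment and spin inference

Before alignment, each map is sign-normalised: if strictly more than half
of the included parcel values are negative, the whole map is negated (a
tie leaves it unchanged). Positive gradient associations then always mean
"stronger effect towards the heteromodal end" regardless of raw effect
direction — the device that lets fMRI and MEG agree on *location* while
disagreeing on *direction*.

The alignment model is least squares of map value on gradient ×
hemisphere, with hemisphere coded −½/+½ so the gradient main effect is
the across-hemisphere mean slope and the interaction the slope
difference. Quadratic (adds g²) and k-step families (equal-count gradient
bins within hemisphere, treatment-coded) use the same machinery.

Spin null: each permutation draws a rotation uniformly from SO(3) (via a
normalised quaternion), applies it to the left hemisphere's spherical
centroids and its x-mirror conjugate to the right, and reassigns parcels
one-to-one by greedy nearest-neighbour matching over globally sorted
candidate pairs. Unlike independent nearest-neighbour matching, this is a
bijection, so every permuted map preserves the per-hemisphere value
multiset and the null is exchangeable in the multiset sense. One spin set
per atlas is shared by all parameters, windows, and contrasts. The
p-value convention is two-sided with the +1 correction,
p = 2·min(r⁺+1, r⁻+1)/(n+1), floored at 2/(n+1) and rendered "< floor"
at the floor; a one-sided variant implements the
exceeds-the-95th-percentile reading. Interactions are spin-tested only
when their parametric p < .05 (a screening rule; spin inference carries
the error control for everything reported).

### Model comparison and dissociation

Step-versus-linear comparison scores both least-squares fits under the
Gaussian maximum-likelihood convention, AIC = n·log(RSS/n) + 2k and
BIC = n·log(RSS/n) + k·log n with k counting coefficients plus the
variance; the shared constant cancels in differences. Verdict on
Δ = step − linear: linear favoured iff ΔAIC > 4 **and** ΔBIC > 4; step
favoured iff both < −4; otherwise indeterminate. When the linear model is
not clearly favoured, pairwise step-level contrasts get spin p-values.

Dissociation ANOVAs stack sign-normalised maps in long form (parcel ×
level, level = parameter or time window) and compute Type-II F statistics
for gradient × level and gradient × level × hemisphere by nested residual
sums of squares, sharing the full model's mean squared error (verified
against statsmodels `anova_lm`). Parcels are treated as fixed repeated
units without a parcel random effect; the spin null, not the parametric
F distribution, provides the error control. Follow-ups are gated
hierarchically: pairwise contrasts only after the omnibus passes its spin
test, per-hemisphere contrasts only after the three-way term does. The
duration-control rule applies to dissociations as well.

## The synthetic-data generator

The generator produces everything the pipeline consumes, with the
statistical structure the models assume:

- **Lexicon.** Unique letter strings, lengths uniform on [3, 10], with
  deterministic Zipf rank-frequency counts (exponent 1.0, ~10⁷ tokens at
  rank 1). Words are drawn as orthographic families — a base string plus
  a heavy-tailed number (Poisson mixtures, up to ~25) of one-to-two-edit
  variants — because uniform random strings make OLD20 an almost
  deterministic function of length (r ≈ .99), collapsing two predictors
  into one; with families, r(length, OLD20) ≈ 0.35 and all variance
  inflation factors stay below 2.
- **Embeddings.** Each word gets a topic (8 topics by default); its
  unit-norm vector is coherence·centroid + (1−coherence)·noise
  (coherence 0.8, dimension 50). Vectors are type-level; the (word,
  occurrence) key structure accepts contextualised vectors from outside.
- **Sentences.** 60 sentences of 9–15 words; each has a dominant topic,
  content words drawn from it with probability 0.8, function words from
  the Zipf head; presentation duration 0.16 + 0.09·letters + N(0, 0.1²) s
  clipped to [0.16, 1.4] (yielding the length-duration confound,
  r ≈ .9); 1-s fixation before and 2-s blank after each sentence. With
  these conditions ~250 content trials per participant survive the
  position ≥ 6 filter, matching the intended scale of ~240.
- **Atlas.** A deterministic Fibonacci lattice of 175 centroids per
  hemisphere on each hemisphere's unit sphere, right mirroring left. The
  gradient is the anterior-posterior coordinate plus a smooth Gaussian
  field, min-max rescaled to [0, 1] exactly.
- **Effect profiles.** Per-parcel sensitivity = shape(g) + ε, shape
  linear/2-step/3-step/null, with ε a zero-mean Gaussian field with
  exponential covariance over chordal distance between (mirror-folded)
  centroids, length scale 0.3 rad by default; length scale 0 gives white
  noise for estimator-correctness checks.
- **Responses.** MEG-style: activation = Σ sensitivity·z-feature +
  participant intercept (sd 1) + trial noise (sd 1), 12–20 participants.
  BOLD-style: design × sensitivities + AR(1) noise (φ = 0.4, marginal sd
  1, TR 2 s).

What the generator does **not** emulate: real spatial covariance of
BOLD/MEG noise (only AR(1) in time and exponential kernels in space),
contextualised embedding dynamics within a sentence, item-level
variability, oscillatory MEG structure, morphology/phonology of real
lexicons, and between-participant stimulus differences (all participants
read the same material, as in the fixed-stimulus design). Passing tests
therefore certify the statistical machinery — estimator correctness,
calibration, decision rules — on data satisfying the models' assumptions,
not the robustness of the scientific conclusion to real-data violations
of them.

## Numerical conventions and edge cases

- All randomness flows from one integer seed through CRC32-named
  substreams of numpy's SeedSequence; identical seeds give identical
  outputs everywhere, including the spin set.
- Edit distances use edlib for ASCII input with a pure-Python dynamic
  program as the general-alphabet fallback; OLD20 excludes exact
  (case-folded) self-matches and averages the 20 smallest distances
  value-wise, so lexicon order is irrelevant.
- Log frequency is log₁₀ per million with add-one count smoothing (a raw
  variant exists and rejects zero counts).
- Zero-residual ("degenerate") fits carry an explicit flag instead of
  infinite t; their spin p is reported at the floor via the one-sided
  +∞ convention.
- Design matrices are checked for rank after excluding identically zero
  columns (an empty study is representable); dependent columns are named
  via pivoted QR.
- Standardisation uses the sample (ddof = 1) standard deviation over
  included events only, and is idempotent.
- Group z values are capped at |8|; exact zero between-participant
  variance warns and caps.
- Equal-count step bins use within-hemisphere quantiles (an equal-width
  option exists); every bin × hemisphere cell must hold ≥ 5 parcels.

## Problem sizes

The bundled study runs at 350 parcels, 12 participants, one 100-ms
window, and 500 spin permutations; the calibration experiments use a
300-parcel atlas with 200–500 null datasets and 100 replicate maps. These
sizes were chosen so the whole analysis reruns from scratch in about a
minute while leaving Monte-Carlo error well below the decision margins;
every size is a parameter and scales up without code changes.

## Known limitations

- Rotation-based spin tests are approximate: measured false-positive
  rates at α = .05 on smooth null maps sit around 0.04–0.08 depending on
  atlas and seed — mildly liberal in the worst case. Replacing greedy with
  optimal (Hungarian) assignment does not change this, so it is a
  property of the rotation null itself, consistent with what is known
  about spin tests on parcellated data.
- The MEG route fits each parcel independently; no spatial regularisation
  or multiple-comparison correction across parcels is applied (the
  gradient-alignment stage, not the per-parcel maps, is the inferential
  target).
- The fMRI group model is the summary-statistics one-sample t; a full
  mixed-effects group GLM is out of scope.
- Whether predictors should be standardised within participant rather
  than pooled is an open modelling choice; pooled is the default here
  (all participants see identical stimuli, making the distinction moot
  for the synthetic studies).
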