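# Methods

## The measurement model

A vignette v shown to respondent r is a set M(v) of 2–4 messages from
distinct categories of the 36-message instrument. The respondent's 1–9
rating is collapsed to a top-3-box indicator on the 0/100 scale
(7–9 → 100, otherwise 0), and the analysis model is linear in message
presence:

    E[y_rv] = β0_r + Σ_{m ∈ M(v)} β_rm .

β0_r (the additive constant) is the respondent's baseline propensity, in
percentage points, to put a vignette in the top band when no particular
message is driving them; β_rm is the percentage-point change attributable to
message m. The 0/100 coding (rather than 0/1) is deliberate: coefficients
then read directly in percentage points, the scale on which group results
for this methodology are conventionally printed, where constants in the
40–60 range are typical and a coefficient of roughly six or more is treated
as meaningful against group standard errors near four. That heuristic is
reported as a flag column only; genuine inference uses OLS standard errors
and two-sided t-tests on the pooled system.

## Design generation and identifiability

With complete one-message-per-category profiles, the sum of each category's
six dummies equals one in every row and the model above is unidentifiable.
The generator therefore uses incomplete vignettes: a 48-slot template with
sizes 2/3/4 in equal numbers (144 slots, so each of the 36 messages appears
exactly 4 times per respondent), at most one message per category per
vignette, and each (category, within-category index) slot used equally
often. Each respondent receives the template under an independent uniform
permutation of message indices within every category plus a random vignette
order. Row and within-category column permutations leave rank and
conditioning unchanged, so template validation (rank 37) covers all
respondents; cross-respondent uniqueness of the permutation records is
checked explicitly.

Because the design's purpose is statistical independence of the predictors,
the generator draws up to 100 candidate templates and keeps the
best-conditioned feasible one, scored by the mean of
sqrt(diag((AᵀA)⁻¹)) over the 36 message coefficients (A = [1 | X]); an
infeasibility error names the violated constraint. Typical selected
templates have a mean SE factor near 0.9, i.e. an individual-level
coefficient standard error of ≈ 0.9·σ_obs, against an orthogonal-design
lower bound of ≈ 0.5·σ_obs — with 48 rows and 37 parameters there is little
room below that. D-optimal search is out of scope.

## The synthetic respondent generator

A mindset profile is (constant c, utilities β) on the percentage-point
scale; the bundled reference profiles are the three published ED mindsets
(constants 44/56/29, base sizes 38/38/36, nine listed utilities each, all
other utilities zero). A simulated respondent in group g draws a personal
constant c_r ~ Normal(c_g, sd) with sd = 5 pp by default — panel respondents
differ far more in overall generosity than in message-specific preferences,
and 5 pp keeps every predictor in the unclamped linear region — and rates
each vignette by a linear-probability mechanism: with probability
clamp((c_r + Σβ_m)/100, 0, 1) the rating is uniform on {7,8,9}, otherwise
uniform on {1..6}. The raw 1–9 values exist only so binarization has
realistic input; an ordinal response model is not attempted because the
analysis consumes only the binarized outcome.

This mechanism makes the binarized response conditionally Bernoulli with
mean equal to the linear predictor, so every OLS stage downstream is
*unbiased* for the generating parameters (verified by the replicate tests).
What it does not emulate is within-respondent rating consistency: a real
panelist's 48 ratings are highly correlated given their personal tastes,
whereas here each vignette is an independent coin flip. That choice has a
large consequence, quantified next.

## What is and is not recoverable at study scale

The binarized outcome has per-observation sd σ_obs = 100·sqrt(p(1−p)) ≈ 50
pp for p near 0.5. An individual model estimated from 48 such observations
with 37 parameters therefore carries per-coefficient noise of roughly
0.9·50 ≈ 45 pp, while the between-mindset coefficient signal of the
reference profiles has an sd of only ≈ 2.2 pp across the 36 messages. Any
response mechanism whose binarized expectation equals the linear predictor
is marginally Bernoulli, so this noise floor is a property of the estimand,
not of the generator settings. Consequences, all reproduced by the test
suite at study scale (112 respondents, 48 vignettes):

- **Individual and pooled estimates are unbiased.** Mean fitted constants
  over replicates recover the generating constants; the total-panel model
  recovers the base-size-weighted mixture of the three profiles.
- **Mindset recovery from individual coefficients fails.** k-means on
  correlation distance sees noise ~45 pp per coordinate against ~2 pp of
  structure; adjusted Rand index against the generating partition is ≈ 0,
  matched cluster constants collapse toward the overall mean (≈ 43), and
  strongly mindset-specific coefficients (e.g. the role-clarity message,
  −7/9/0) attenuate toward their mixture mean (≈ 0.7). The corresponding
  recovery and k-selection acceptance tests are expected to fail and are
  retained, unweakened, as a faithful record of this identifiability limit.
- **Split-half reliability of group coefficients lands near 0.7–0.8**, not
  higher: the mixture coefficient signal (sd ≈ 0.9 pp over messages) is
  comparable to the half-panel pooled standard error (≈ 4 pp), and the
  half-vs-total correlation is bounded by sqrt((s² + σ²/2)/(s² + σ²))
  accordingly. Published real-data values above 0.85 imply substantially
  stronger per-respondent signal than an independent-Bernoulli mechanism
  can carry.
- **Clustering machinery is correct where signal exists**: with noiseless
  duplicated profiles ARI = 1 across seeds, silhouette selection finds the
  true k on separated synthetic profiles, and ANOVA/Tukey agree with
  textbook sums of squares.

This is a substantive methodological observation, not a software
limitation: segmenting respondents on individual-level OLS coefficients
from ~48 binary observations requires within-person consistency (or effect
sizes an order of magnitude larger) to be statistically meaningful. The
significant ANOVA contrasts that emerge between clusters fit on pure noise
are selection effects of the clustering itself and should not be read as
evidence of real segmentation.

## Clustering details

k-means under 1 − Pearson-r is implemented as Euclidean k-means on
row-standardized coefficient vectors (centered, unit norm): for such
vectors ‖u − v‖² = 2(1 − r), so the objectives are monotonically
equivalent and the centroid update stays closed-form. Standardization is
also what the metric implies about scale: a respondent's assignment is
invariant to affine rescaling of their coefficients. Zero-variance
coefficient vectors (e.g. a respondent who rated everything identically)
have no correlation to anything and raise an error rather than being
silently placed. Restarts default to 50, seeds are always recorded, and
clusters are relabeled largest-first for stable output. k is either fixed
(default 3) or chosen by mean silhouette under the same distance over
k ∈ 2..6, with a warning when even the best silhouette is below 0.25.
ANOVA and Tukey HSD compare per-respondent coefficients across mindsets —
the only reading under which a between-mindset test is well-posed —
with messages of degenerate (zero) within-group variance flagged rather
than failing. Recovery experiments match clusters to generating profiles by
Hungarian assignment on centroid–profile correlation.

## PVI construction

The typing tool converts six messages into agree/disagree questions. The
answer model: a virtual member of mindset g agrees with question m iff
β_gm + ε > 0, ε ~ Normal(0, answer_noise_sd) — zero is the natural boundary
between a message that drives satisfaction and one that does not, and the
noise (default 10 pp) stands in for individual deviation from the group
model. Subset search is Monte-Carlo: 2000 random 6-subsets plus a greedy
subset of the largest between-mindset spreads, each scored by simulating
5000 virtual respondents per mindset and assigning each of the 64 answer
patterns to its modal mindset (ties toward the larger base size). The
2⁶ = 64-entry pattern table is exhaustive by construction, so assignment of
a new individual is a total, deterministic lookup. At the published
coefficient spreads (max 16 pp) and noise sd 10, the attainable simulated
accuracy is ≈ 0.68 — an exhaustive sweep of the informative 6-of-9 subsets
confirms this ceiling — rising to 1.0 as the answer noise shrinks.

## Reproducibility and problem sizes

All stages consume explicit seeds; the pipeline derives per-stage seeds
from one master seed via a seed sequence, echoes them with every effective
default into a manifest, and writes CSVs with fixed float formatting so a
rerun of the same config is byte-identical. Tests and the acceptance script
run at the study's own scale — 112 respondents × 48 vignettes — since each
full pipeline takes only seconds; replicate-based checks use 10–200
replicates, enough to hold Monte-Carlo error well inside the asserted
tolerances.

## Known limitations

- The generator models no demographic covariates, nonresponse, or
  order/learning effects.
- No ordinal or logistic alternative to OLS on the binarized outcome is
  provided; for the published methodology OLS *is* the method.
- Instruments are accepted generically at n_cat × n_msg, but only the 6×6
  shape is exercised by the bundled instrument and the study-scale tests.
- The multiple-testing question in the per-message ANOVA table (36 tests)
  is left to the reader; no correction is applied, matching the reporting
  convention the package mirrors.
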