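# Methods

This note documents the models, conventions and numerical choices behind the
package, and what its synthetic studies do and do not establish about real
data.

## Generative model

A synthetic study is built around a trials × factors latent matrix
`F`. The five factors mirror the composite dimensions (Difficulty,
Autobiographical, SceneConstruction, OthersRelevant, SelfRelevant). Factor
columns are standard normal with a configurable correlation matrix; by
default Difficulty correlates 0.5 with SelfRelevant and Autobiographical, so
the Difficulty-confound machinery (VIF screening, residualization) has real
structure to remove. Per-condition mean shifts are added afterwards; by
default target conditions (those designed to demand episodic projection) sit
+1.0 SD higher on Autobiographical and +0.7 SD on SceneConstruction.

**Ratings.** Rater j's rating of strategy s on trial t is
`clamp(round(mu + Lambda[s]·F[t] + b_j + eps), 1, 7)` with baseline mu = 3.5,
per-rater bias b_j ~ N(0, 0.5²) and noise eps ~ N(0, 1.2²). Rounding-then-
clamping keeps a linear latent model underneath a 1–7 Likert surface; a
`discretize=False` switch gives the continuous version for closed-form
checks. Loadings are block-structured: each composite member loads on its own
factor, 1.1 for most members but 0.85 for the (Facts, Difficulty) pair. The
weaker pair is deliberate: the dendrogram-cut convention preserves every
cluster at least as tight as that pair, so the generator makes it the
loosest of the five real clusters — the analogous empirical observation is
what motivated the cut. The four probes outside the canonical composites get
split or weak loadings (e.g. Loc_People 0.5 on Scene and 0.5 on Others),
which makes their cluster attachment weak and unstable between replications.

**Cohort design.** Trials are interleaved over conditions so each block of 30
consecutive trials holds five per condition; each rater cohort rates one
block plus six shared trials (one per condition), i.e. 30–36 trials per
rater, with 25 raters/cohort in the first pseudo-experiment and 50 in the
second. Contaminated raters are injected at configurable rates
(straight-liner 5%, stereotyped cycle 4%, late drop-off 3%, under-time 7%,
out-of-age 1%) with their type recorded for detector scoring.

**Network responses.** The vertex beta for trial t is
`W[net(v)]·F[t] + eta[net(v), t] + c_{subject, net} + eps_{t,v}` with
network loadings W (DN-A ← Scene 1.0, FPN-B ← Difficulty 1.0, FPN-A ←
Difficulty 0.6, DN-B ← Others 0.35, LANG/CING-OPER 0), trial-level network
noise `eta` shared across subjects (true response variance the behavioral
factors do not explain), a per-subject network offset (sd 0.3), per-subject
per-trial noise (sd 1.8) and vertex noise (sd 0.5). The `eta` sds are set
from the closed form `r = a / sqrt(a² + sigma² + s²/n_subjects)` so the
group-level factor–network correlations sit near 0.6 (DN-A), 0.7 (FPN-B),
0.5 (FPN-A) and 0.3 (DN-B); the observed pipeline values land a few
hundredths lower because Likert discretization attenuates the composite side.
The per-subject trial noise puts the network split-half reliability over 10
subjects in the high 0.7s–0.9 range. Vertex labels are contiguous blocks of
100 vertices per network with small subject-specific boundary jitter — a
cheap stand-in for individualized parcellations that preserves the only
property the analysis uses (a vertex→network map), not cortical geometry.

**Response times.** `rt = 9.0 + 1.5·Difficulty_t + u_t + eps`, floored at
0.5 s, with a per-trial effect u_t ~ N(0, 1.75²) shared by all raters
(question length, option ambiguity) and rater noise sd 3.0. The shared trial
effect is what keeps the trial-mean RT vs Difficulty correlation in the
mid-0.6s instead of saturating once rater noise averages away
(1.5/sqrt(1.5² + 1.75²) ≈ 0.65). Outliers above 60 s occur at rate 0.0017
and are excluded before trial means, matching the analysis convention.

**BOLD mode.** Optionally the generator emits design-consistent time series
`Y = X_trials·B + noise` so the GLM stage can be exercised end to end; there
is no attempt at realistic fMRI noise spectra or hemodynamic variability.

## Quality control

Exclusion reasons follow a fixed precedence: age first, then (left to right,
as in the study's summary tables) duration, zero-click trials, missed
checks, patterned responding; each excluded rater gets exactly one reason,
and `enrolled = included + Σ exclusions` is asserted per cohort. A survey
duration *equal to* the 20-minute threshold excludes (the boundary case is
documented in the original tables). The default age bounds are (18, 28), the
stated recruitment rule. Single soft infractions (one missed check, missing
feedback) are flagged but do not exclude.

The patterned-responding detector replaces a human visualization step, so
its thresholds are design choices tuned on the generator (and exposed in
`PatternParams`): rule (a) flags when ≥ 80% of trials have zero within-trial
rating variance; rule (b) when one exact rating sequence recurs on ≥ 80% of
trials; rule (c) finds the trailing run of within-trial-constant trials and
flags when it covers ≥ 20% of the survey while earlier trials are mostly
non-constant. Rule (c) is changepoint-style rather than a fixed tail window
because a drop-off that starts mid-survey otherwise leaks into the "early"
window and masks itself. At defaults the detector scores recall ≥ 0.95 with
false-positive rate < 5% on generator output.

The cohort check is a one-way ANOVA of per-participant mean ratings
(averaged over the shared trials and the 13 probes with common anchors) on
cohort. This is the simplest model yielding one F per experiment; the
response/df structure of the original report is not reconstructible from the
participant counts, so no attempt is made to mimic its printed df.

## Clustering and composites

Strategy correlations are Pearson over the 180 z-scored trial means
(z-scoring uses the sample sd, n−1, making [1,2,3] → [−1,0,1] exact;
zero-variance rows become zeros with a warning). Clustering is Ward
minimum-variance linkage on d = 1 − r (scipy's `linkage(..., "ward")` on a
condensed distance matrix, the same recursion as R's `hclust` ward.D2);
leaves are pre-sorted lexicographically so exact merge-height ties resolve
deterministically. d = 1 − r rather than sqrt(2(1−r)) is a monotone
transformation at this scale and does not change merge order. An exhaustive
Lance–Williams agglomeration oracle verifies the linkage on ≤ 6 leaves.

The dendrogram is cut just above the merge height of the smallest cluster
containing the reference pair (Facts, Difficulty), preserving every cluster
at least as tight as that pair. Replicated clusterings are reconciled by
intersecting co-membership graphs: two strategies stay linked iff they share
a cluster in *both* samples; composites are connected components of size
≥ 2; singletons and the configured manual exclusions (Specificity,
Moral_Principles — probes whose weak association motivated manual removal)
drop out. Composite scores are exact sums of member z-rows, so they are
invariant to constant offsets in any raw strategy.

## Reliability conventions

Split-half reliability halves the units (raters for composites, scanned
subjects for networks), correlates the two half-mean vectors across trials,
Fisher-z-averages per-split correlations, and applies Spearman–Brown
(2r/(1+r)). Averaging before adjustment is the default; adjusting each
split first is available (`aggregation="sb_before_mean"`). Network
reliability enumerates all 126 balanced splits of 10 subjects; composite
reliability draws 1,000 random balanced splits over the first 36 raters per
trial (the unit cap reproduces the original convention and keeps repeated
administrations from inflating one half). Odd unit counts drop one unit at
random per split, since the prophecy formula's length-doubling logic needs
balanced halves. Explainable variance is the product of the two measures'
adjusted reliabilities; observed R² is reported as a fraction of that
ceiling, with a warning (not an error) if it exceeds 1.

## GLM and aggregation

The design has one boxcar (10 s on, onsets every 20 s, TR = 1 s, 612
volumes per run) convolved with a canonical double-gamma HRF (peak 6 s,
undershoot 16 s, ratio 1/6), plus intercept and linear drift. The nuisance
set is deliberately minimal — whole-brain signal regression belongs to the
out-of-scope preprocessing. Betas are per-vertex OLS with an explicit
full-rank check; precomputed betas can be supplied directly, which is how
the default pipeline mirrors an analysis that starts from beta maps.
Network responses are unweighted means over member vertices, then arithmetic
means over subjects.

## Associations

Correlation CIs use the Fisher z transform,
`tanh(atanh(r) ± 1.96/sqrt(n−3))`; this choice reproduces the three
printed worked-example intervals at two decimals and attains ~95% null
coverage in simulation. LMG relative importance is computed by subset
weighting — `share_j = Σ_S w(|S|)[R²(S∪j) − R²(S)]` with
`w(k) = k!(p−k−1)!/p!` — which equals the explicit average over all p!
entry orders (asserted to 1e−10 in tests) at a fraction of the cost;
enumeration is capped at 8 regressors. VIFs are 1/(1−R²_j) with the
conventional >3 flag; the default network models use the Difficulty,
SceneConstruction and OthersRelevant composites, the screened set that
leaves no residual multicollinearity. Residualization replaces each other
composite by its OLS residuals on Difficulty (with intercept), guaranteeing
exact orthogonality to the covariate.

Extreme-trial contrasts take the top/bottom 10 trials by composite score
(ties broken by trial id; Scene contrasts restricted to control-condition
trials so they are orthogonal to the task's original design), average the
betas, and score the map against the subject's own target-network border by
mean-inside minus mean-outside and by Dice between the top-q vertices and
the label (q = label size). These overlap statistics are this package's
quantification of what the original workflow assessed visually. The
"quadrant" subset test standardizes the Difficulty-residualized
Autobiographical and SceneConstruction scores over control trials, ranks
trials by their difference, takes the 7 most extreme on each side, and runs
a Welch t test on the target network's group response — an explicit,
reproducible reading of a selection that was originally done by eye.

## What the synthetic studies do and do not show

Passing tests demonstrate that every stage recovers the structure it is
pointed at when that structure is present, at realistic sample sizes and
noise levels, and that the inferential machinery is calibrated (CI coverage,
type-I error). They do not validate the substantive neuroscience claims on
real data: the generator's labels are contiguous blocks (so contrast-map
Dice values are near-ceiling in a way real cortical geometry would not be),
its rating noise is homogeneous across raters and probes, and the
latent-factor model is exactly linear. Reported quantities from any real
dataset would inherit none of these simplifications.

## Problem sizes

Default synthetic studies use 180 trials, 25/50 raters per cohort in the two
pseudo-experiments, 10 subjects and 600 vertices — the study-condition
scale. Unit tests run a reduced study (60 trials, 8/12 raters, 4 subjects,
120 vertices), and simulation-based checks use 1,000 replicates; these sizes
keep the full suite and the acceptance script in the minutes range while
leaving Monte-Carlo error well inside the asserted tolerances.
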