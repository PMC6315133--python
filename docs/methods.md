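# Methods

## Task environments and item sets

Stimuli are 5-dimensional binary cue profiles (±1 per cue), 32 in total.
The additive environment assigns criterion c = 15 + Σ wᵢCᵢ with weights
(5, 4, 3, 2, 1), spanning [0, 30]; the multiplicative environment assigns
c = 2 + 3·exp(Σ wᵢCᵢ / 6). Both order all profiles identically (the
multiplicative rule is a strictly increasing transform of the weighted sum),
so the environments differ in learnability, not in ordinal structure.

Item roles follow the study design: memorized exemplars (M, instructed
conditions, 6), training exemplars (T, spontaneous conditions, 16),
screening-phase new items (S, 6), the two extreme profiles (E, all-low and
all-high — extrapolation probes whose criteria bracket the training range),
scanner-phase new items (N), and criterion-free baseline items. The
published item tables exist only as figures, so `generate_design` draws
role sets algorithmically under the documented constraints: roles are
mutually disjoint, extremes are pinned to the two extreme profiles, and
scanner-phase items never occur among memorized or training items.
Transcribed item tables can be loaded with `read_items` (criteria are
validated against the environment on load).

Two constraints are added beyond the counts. First, the scanner-phase set
(N ∪ E) must keep the linear model identifiable with any single item held
out, and the training set must be full rank — otherwise leave-one-out and
projective fitting would be ill-posed for some folds; draws are rejected
until both hold. Second, the number of scanner-phase new items defaults to
8, which makes the four spontaneous roles (16 + 6 + 2 + 8) exactly
partition the 32-profile space; the source design does not state this
count.

## Judgment models

CAM predicts k + Σ ωᵢCᵢ. EBM predicts the similarity-weighted mean of a
pool of stored (profile, criterion) exemplars, with the original context
model's multiplicative similarity: mismatching on cue i multiplies
similarity by sᵢ ∈ [0, 1]. Predictions are convex combinations of pool
criteria, hence bounded by the stored criterion range — the property that
makes extrapolation items diagnostic between the models. Model outputs are
never clipped or rounded; response discretization belongs to the agents'
response model only. The exemplar pool is an explicit argument: memorized
items for instructed conditions (including EBM fits to instructed-rule
agents, which assume the same six memorized exemplars), training items for
spontaneous conditions.

## Estimation

CAM is estimated by ordinary least squares (the analytic minimizer of the
same squared-error loss a simplex search would target); rank-deficient cue
designs raise an error naming the offending dimensions. EBM similarities
are estimated by Nelder–Mead simplex search on the unconstrained logistic
reparameterization u = logit(s), with seeded Latin-hypercube restarts
(default 10 for a full fit), loss tolerance 1e-8. The uniform-similarity
vector s = (1,…,1) — whose prediction is the pool mean — is always
evaluated as a candidate, so the fit never loses to that baseline. Fitted
similarities are floored at 1e-6: below that the model is behaviorally at
its exact-match-retrieval limit, and exact zeros would leave predictions
for fully mismatching probes undefined (0/0). Failure of every restart to
converge is reported as a warning and flagged on the result, never
silently ignored.

Leave-one-out cross-validation folds over unique items by default (each
presentation of the held-out item is scored), with an option for
event-level folds. EBM folds warm-start at the full-data solution plus two
fresh Latin-hypercube starts per fold — the full 10-restart search per fold
would multiply runtime roughly fourfold for no measurable change in
held-out RMSD on this task size. Projective fits estimate on exactly the
final three training blocks and score frozen parameters on the test phase.
Strategy classification takes the smaller RMSD, with ties declared below a
1e-6 RMSD margin.

## Synthetic agents and cohorts

Agents are stationary: a rule agent responds from fixed CAM parameters (the
environment's true intercept and weights — an idealized trained learner), an
exemplar agent from fixed EBM parameters with each sᵢ drawn uniformly from
[0.1, 0.5] (mismatch clearly discounted but not annihilating; draws near 1
would make the agent respond with the pool mean everywhere and be
unidentifiable). Responses are model prediction plus Gaussian noise
(sd 2.0 — placing trained agents at the task's learning criterion of block
RMSE < 2), clipped to the 0–30 scale, then rounded to integers (the
response device stepped through whole numbers). The training phase runs
16-item feedback blocks until a block's RMSE against the criteria falls
below 2, capped at 40 blocks (640 trials); the cohort generator additionally
enforces a minimum of three blocks so that late-training projective
estimation is always defined — stationary agents can satisfy the criterion
in the first block, which real learners cannot. Instructed agents skip
training and screening. Scanner-phase judgments repeat each N ∪ E item
three times; screening repeats its 24 items twice.

What the generator does **not** emulate: learning dynamics within training
(agents do not improve), the 0–100 % response scale of the real screening
phase (all phases use the 0–30 criterion scale, avoiding an unspecified
rescaling), individual differences in noise level, and sequential effects.
Passing recovery tests therefore show that the estimation and comparison
machinery works when the generating process is one of the two models — not
that human judges are stationary model instances.

ROI contrast values are generated by the latent-correlation construction
y = ρ·z(f) + √(1−ρ²)·ε against standardized fit values, exact in
population, with a multi-covariate generalization (systematic part
Z·R⁻¹ρ) used by the pipeline to prescribe simultaneous correlations to both
models' RMSDs. Subject-level statistic volumes are i.i.d. Gaussian noise
with a constant effect added inside planted active regions, so effect /
noise-sd is the voxelwise Cohen's d.

## Second-level statistics

Pearson correlations carry t-distributed p values; one-tailed p is reported
for the observed direction. Dependent correlations sharing one variable are
compared with the Meng–Rosenthal–Rubin z-test; the correlation between the
two non-shared variables (here: between the two models' RMSDs) is an
explicit argument, computed from the fit table by the pipeline, and the
correlation triple is checked for positive semidefiniteness. Both one- and
two-tailed p values are attached; the pipeline reports two-tailed by
default. Independent-group correlations use the Fisher z comparison.

Conjunction testing takes the voxelwise maximum of the per-test
uncorrected p values (a conjunction-null test: significance requires all
constituent effects) and applies Benjamini–Hochberg FDR over all finite
voxels; under the complete null the max-p statistic is conservative (CDF p²
for two uniform inputs), so its realized error rate sits below q. The BH
step is the plain step-up procedure without dependency correction, matching
common voxelwise practice. Zero-variance voxels get t = 0, p = 1 in group
maps and NaN in correlation maps, and NaN voxels are excluded from FDR
families. Sphere ROIs average voxels whose center-to-center distance from
the peak is within the radius (default 5 mm), inclusive; voxel indices are
0-based with mm = origin + index·voxel_size.

The 2×2 mixed ANOVA (model fit within, condition between) is computed via
pingouin; for the two-level within factor the interaction F equals the
squared two-sample t on within-subject difference scores, an identity the
tests verify independently. A design with zero interaction sum of squares
reports F = 0, p = 1 rather than 0/0. Bonferroni thresholds are α/m with m
the configured family size (two hypotheses — one per model — per ROI in the
pipeline).

## Pipeline and problem sizes

`run_study` fans a single seed into independent substreams (cohort, ROI,
volumes) via `numpy.random.SeedSequence.spawn`, so staged CLI runs
reproduce the monolithic run exactly. Default sizes: cohort 74 (19, 19, 16,
20), LOOCV with 5 restarts for full fits, 12³ statistic grids with a
central planted region at d = 1.5. Study-level checks use 20 recovery
cohorts of 10 + 10 agents (projective fits, the screening-phase procedure),
10⁴-replicate null calibrations for the dependent-correlation z (n = 74)
and the conjunction FDR (20³ grids), and 200 ROI noise draws around one
fitted 74-agent cohort for the correlation dissociation; the cohort is
fitted once because re-fitting would only re-sample the fixed fit-value
distribution the ROI generator conditions on.

## Known limitations

* Agents are stationary; nothing here speaks to learning-curve shape.
* The similarity-parameter range [0.1, 0.5] is a design choice; exemplar
  agents drawn near the top of the range are nearly linear and can be
  classified as rule users at noise sd 2 — visible as a small off-diagonal
  count in cohort classification tables.
* The conjunction machinery implements voxel-level FDR only; cluster-extent
  or random-field inference is out of scope.
* The ANOVA is restricted to the two-level-within mixed design actually
  used; general unbalanced mixed models are out of scope.
* Volumes use a plain-text container; neuroimaging formats (NIfTI) are
  deliberately not required.
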