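# Methods

## The task and its design quantities

The experimental phase presents 7 stimulus durations (2.0–5.0 s in 0.5 s
steps) crossed with 4 sound conditions (semantic category environmental vs
human × valence pleasant vs unpleasant), once each per block, over 8
blocks: 224 trials. Orders are pseudo-randomized under the constraint that
no two consecutive trials share a condition. The constraint is enforced
within blocks by default; participants take breaks between blocks, so
cross-boundary enforcement is optional (`cross_block_constraint=True` for
back-to-back presentation). Scheduling is shuffle-and-check with a bounded
retry budget (10,000 per block), falling back to most-constrained-first
randomized backtracking; with 7 trials per condition in a 28-trial block a
valid order always exists, and both strategies are deterministic given the
seed. Inter-trial intervals are continuous-uniform on [1, 3] s. Within a
block, each condition's seven duration cells alternate between its two
exemplars round-robin from a seeded offset — the design itself does not
constrain exemplar balance, so this is the least-committal balanced choice.
Training is 16 trials (8 exemplars × the 2 reference durations) and the
pass rule is strictly more than 80 % correct, i.e. at least 13 of 16.

## The generative observer model

Each synthetic responder owns an internal clock in the scalar-expectancy
(pacemaker–accumulator) tradition. A stimulus of duration `t` in condition
`c` produces a subjective duration

    tau ~ Normal(g_c * t, (w_c * g_c * t)^2)

`g_c` is a per-condition pacemaker gain: arousal opens the pulse gate
(g > 1, durations feel longer → lower bisection point), attentional
capture closes it (g < 1 → duration underestimation). `w_c` is the Weber
coefficient; the proportionality of noise SD to elapsed time is the scalar
property. The response is "long" iff `tau` exceeds a fixed, memory-derived
criterion `c`; on lapse trials (probability λ, default 0.05, matching the
sub-unity upper asymptotes typical of patient psychometric curves) the
response is uniform over the two alternatives. Lapses are symmetric, and
the criterion does not drift trial-to-trial (drift is an extension point).
A log-normal noise law is selectable since the linear-Normal choice is a
convention, not a measurement.

The analytic response curve is
P(long|t) = λ/2 + (1−λ)·Φ((g·t − c)/(w·g·t)). It crosses 0.5 at
BP = c/g, and its quartile spread gives Weber's ratio
WR = 2x/(1−x²) with x = w·z₀.₇₅. Both relations invert in closed form
(`params_from_targets`: g = c/BP\*, w = x/z₀.₇₅ with
x = WR\*/(1+√(1+WR\*²))), so cohorts are specified directly by target
(BP, WR) per group × condition. Condition effects enter only through the
gain, keeping BP modulation orthogonal to discrimination sensitivity.

**Cohort defaults.** The six groups (healthy controls, typical Alzheimer's
disease, and the logopenic, nonfluent and semantic primary-progressive-
aphasia variants plus behavioural-variant FTD) default to the published
group × condition mean BP/WR pattern at the published analysis-cohort sizes
(24/11/8/8/11/8). Between-participant spread is BP SD 0.5 s and
multiplicative WR spread 0.25 (typical of the reported group SDs), split
evenly between a participant-level offset shared across conditions (which
the mixed model's random intercept absorbs) and condition-specific
variation. Covariates: age and MMSE per group from the reported
demographics; total intracranial volume ~ Normal(1400, 130) mL
(conventional adult values — the study reports none). Valence ratings are
Normal per condition around the reported means (26/74/25/68, SDs
20/16/18/18), truncated to [0, 100]. Working-memory span is coupled
negatively to a participant's mean BP and nonverbal executive score
negatively to mean WR, with noise calibrated so the patient-cohort rank
correlations land near the reported magnitudes (≈ −0.3 to −0.45);
questionnaire/control-task scores have no group differences, so the
confound screen should stay silent. What the generator does **not**
emulate: acoustics, training-phase failure dynamics, response times,
within-session drift, and any covariance structure beyond the couplings
above — passing tests therefore validate the pipeline's statistical
machinery under a faithful parametric idealization, not the full
complexity of clinical data.

## Psychometric estimation

Responses are tabulated per condition × duration (proportion long = count
of long responses / number of blocks) and fitted by penalized maximum
likelihood with

    P(long | t) = gamma + (1 - gamma - lambda) * F(z(t))

Three sigmoid families are available. The default, `scaled_normal`, uses
z = (t−α)/(β·t) — the scalar-timing form in which β is itself a Weber
coefficient and the curve is properly asymmetric in t. The classical
constant-scale `logistic` and `cumulative_normal` (z = (t−α)/β) are
selectable and carry closed-form quantiles (logistic:
q₇₅−q₂₅ = 2β·ln 3; normal: 1.349β) used as test oracles. The scaled
family is the default because, in recovery simulations at the
experiment's own trial counts, the symmetric families showed a
systematic bisection-point bias near the edges of the 2–5 s range (the
fitted lapse absorbs the unsaturated upper tail), inflating the median
BP error at BP ≈ 4.3 s beyond 0.15 s, whereas the scaled family recovers
all tested targets with median error ≈ 0.10–0.12 s.

Guess and lapse are hard-bounded at 0.25 and penalized toward 0 with a
Beta(1, 20)-shaped log-penalty (19·log(1−x)); with seven design points an
unpenalized asymptote trades freely against slope and is effectively
unidentifiable. Optimization is L-BFGS-B from a fixed 5×3 grid of starts
(deterministic given data); all-short/all-long data are flagged, not
raised. BP, q₂₅ and q₇₅ are obtained by bisection (tolerance 1e-8 s) on
the **full** curve including asymptotes — consistent with reading the 0.5
crossing off a plotted curve — and WR = (q₇₅−q₂₅)/BP with natural-log
transform for modelling. Curves whose asymptotes prevent a crossing of
0.25/0.5/0.75 are flagged `fit_ok=False`; participants with any failed
condition are excluded listwise from group models, with counts logged.

Per-participant valence ratings re-assign condition valence (mean rating
≥ 50 → pleasant) before tabulation, mirroring the individual-rating
correction step; reassignments are logged.

**Recovery benchmark.** At 8 trials per cell, 200 simulated observers per
setting: median |BP̂ − BP| ≤ 0.15 s for BP ∈ {3.0, 3.5, 4.3} (pooling the
two WR settings), and the median recovered WR within ±25 % of each target
WR ∈ {0.18, 0.25} (pooling BP settings). The pointwise relative WR error
of a single 56-trial fit has an intrinsic binomial floor near 30 % — the
benchmark therefore checks the central tendency of the estimator, which
is what group-level analyses consume.

## Group inference

The mixed model is `bp ~ group * category * valence` (full factorial —
the reported two- and three-way interaction tests imply all interactions
were present) with a participant random intercept, fitted by REML via
statsmodels MixedLM; Wald z tests on fixed effects. Weber's ratio is
modelled as log WR (its residuals are right-skewed on the raw scale).
Post hoc comparisons are pairwise z contrasts of estimated marginal means
with equal cell weights (balanced-design convention); p values are raw by
default with an optional Holm adjustment, reflecting the apparent original
practice of uncorrected post hocs. Confound screening uses one-way ANOVA
when Levene's test and a Shapiro screen of pooled residuals both pass
(fixed α = 0.05 thresholds, so runs are reproducible), Kruskal–Wallis
otherwise; constants are reported degenerate. Exploratory correlations are
Spearman by default, Pearson when both marginals pass the normality
screen; pairs with < 4 complete observations are skipped. The deviation
score is BP − 3.5 s (arithmetic mean of the references): positive =
duration underestimation.

## ROI association

For each condition, Δ(patient) = mean control BP − patient BP. Per region,
`volume ~ delta + diagnosis(5 levels) + age + tiv + mmse` by OLS; the Δ
slope's t is the statistic of interest, and one model is run per condition
(the per-condition assessment reading of the original design). Direction
bookkeeping: if the cohort-mean Δ for a condition is positive, a negative
slope indicates atrophy, and vice versa (`atrophy_direction`).

Family-wise error over the pre-specified right-hemisphere family (dlPFC,
insula/operculum, inferior parietal, SMA, precuneus — represented as named
columns, not geometry) is controlled by max-|t| permutation: Δ is permuted
within diagnosis strata (diagnosis is in the model; unstratified
permutation is available with a warning), each observed |t| is referred to
the permutation distribution of the familywise max, and adjusted p values
are floored at the raw p so the correction can only be conservative (and a
family of one is returned uncorrected). Bonferroni is available as the
closed-form alternative. A synthetic-voxel mode assigns each region a grid
of voxel columns and applies the cluster-forming threshold (p < 0.001
uncorrected) before peak-level max-|t| FWE within the region family —
voxel-based morphometry's statistical skeleton at desk scale; image
processing itself is out of scope.

Planted-effect defaults mirror the reported associations (precuneus ←
environmental-pleasant, insula ← human-unpleasant, inferior parietal ←
human-pleasant) with slope magnitude 0.8 volume-units per second and
residual SD 0.4, signed per the atrophy convention. At n = 46 patients the
analytic non-centrality (slope·SD(Δ)/noise·√dof ≈ 5) puts single-region
power near 1, so the 80 %-recovery requirement is met with margin rather
than sitting on a knife edge.

## Numerical and reproducibility choices

All randomness flows from one root seed through named substreams
(CRC-tagged `SeedSequence` spawn keys), so any stage can be re-run in
isolation; the pipeline writes byte-identical CSVs on re-run and a
manifest with SHA-256 checksums, per-stage counts and the config hash.
CSVs are UTF-8, "." decimal, empty-field missing values, floats at 12
significant digits. Simulation sizes in the test suite are chosen to give
tight Monte-Carlo error at interactive timescales: 500 replicates for
type-I calibration (acceptance band: nominal 5 % ± 3 binomial SEs), 200
for family-wise error (one-sided 0.05 + 2 SE bound), 100 for
planted-effect recovery, 499 permutations per test, 200 observers per
recovery setting.

## Known limitations

- The simulator is an idealization; real cohorts have heavier-tailed
  individual variation, non-stationary lapsing and criterion drift.
- The original study's Bayesian toolbox configuration for curve fitting is
  unreported; numerical equivalence with its fitted values is not claimed,
  only agreement of the definitions (0.5 crossing, quartile-spread WR).
- Mixed-model Wald z tests are asymptotic; with 8-participant groups,
  small-sample corrections (Satterthwaite/Kenward–Roger) would be the
  conservative upgrade and are not implemented.
- ROI-level volumes stand in for voxel maps; spatial smoothness, cluster
  geometry and atlas definitions are not modelled beyond the
  synthetic-voxel mode's threshold-then-max logic.
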