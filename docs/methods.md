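# Methods

This note documents the models implemented in `genesetdyn`, the parameter
defaults and why they were chosen, the numerical conventions, what the
synthetic-data generators do and do not emulate, and the design choices
made where the methodology left room.

## Per-sample gene-set scoring (FAIME.α)

For sample *j* with *n* measured genes, expression values are ranked
ascending (rank *n* = most highly expressed; ties receive mean fractional
ranks, which keeps each column's rank sum at exactly n(n+1)/2). Ranks are
re-scaled to s(x, α)ⱼ = r(x)ⱼ·e^{α(r(x)ⱼ/n − 1)} and the score of set *i*
is mean(s, x ∈ set i) − mean(s, x ∉ set i), the complement running over
**all** other measured genes (the literal reading of "outside the set";
restricting the complement to genes appearing in some gene-set would make
each score depend on the collection, not just the set).

The soft threshold α ≥ 0 controls how sharply weights favour the top of
the ranking. α = 0 degenerates to a difference of mean ranks; the default
α = 5 (presets 1, 5, 10) balances sensitivity against type-I error on
small sets — the simulation harness below reproduces the comparison. The
null hypothesis of a score is that weighted ranks inside and outside the
set are exchangeable.

Consequences worth noting:

- Scores are invariant under any strictly increasing per-sample transform,
  so log2 intensities and raw RNA-seq counts are both acceptable; no log
  transform is applied or needed before ranking.
- Raising α concentrates a set's activity on its top-ranked members. The
  score of a set holding the single top gene increases monotonically in α;
  a top-k set's score generally does **not** — it peaks and then decays
  toward n/k as the weights extinguish all but the very top gene. The
  package therefore makes no monotonicity claim beyond the top-1 case.
- Probe-level matrices are collapsed to one row per gene by keeping the
  probe with the highest mean expression across samples (ties: first probe
  in input order, for reproducibility). Gene symbols are matched exactly
  and case-sensitively; set members that are not measured are dropped and
  logged, never imputed. Sets with fewer than `min_size` (default 5)
  measured genes are removed.
- Missing expression values are rejected outright rather than imputed; an
  explicit failure beats a silently biased rank.
- GSVA/ssGSEA are not re-implemented: any externally computed
  gene-set × sample matrix can be wrapped (`external_profile`) or any
  callable with the scorer signature plugged in, and flows through
  normalization, DNM and survival analysis unchanged.

## Inter-dataset normalization

Each sample column f·ⱼ of a profile with N gene-sets is transformed to
(fᵢ − μ)/σ with μ the column mean and σ the **population** standard
deviation (divisor N — the divisor the defining formula spells out).
Columns are handled independently, which has two consequences: normalizing
per dataset and then merging is *identical* to merging and then
normalizing (so no ordering flag is needed), and a constant column is a
hard error naming the offending sample. Merging refuses profiles whose
gene-set universes differ, because silently intersecting rows would change
N and break comparability; row order is canonicalized by sorting set
names.

## Simulation harness

Expression under the null/alternative is drawn from the additive model
y_ab = α_a + β_ab + e_ab with per-gene baseline α_a ~ N(0,1) and cell
noise e_ab ~ N(0,1). The group effect β is drawn independently per cell:
N(0,1) everywhere except the differentially expressed fraction φ of the
planted DE set, which gets N(m, 0.5) in group 1 and N(0, 0.5) in group 2.
(Drawing β once per gene per group with σ = 1 would give every null gene a
true group shift within a replicate and make the nominal 5% type-I error
unattainable by construction; the per-cell reading keeps the non-DE set
genuinely null, which is what a type-I-error evaluation requires.)

Defaults mirror the reference study design: p = 5000 genes, set sizes
x ∈ {10, 20, 30, 80, 100}, φ ∈ {0.5, 0.8}, effects m ∈ {0.5, 1}, group
sizes n ∈ {10, 20, 40, 60, 80, 100}, 1000 replicates, FDR 0.05. Each
replicate scores the planted DE and non-DE sets and compares groups with a
two-sample, two-sided, equal-variance t-test (Welch available via config).
Power is the fraction of replicates whose DE-set p-value survives
Benjamini–Hochberg adjustment **across replicates** at FDR 0.05 (a
per-replicate variant exists behind `bh_across_reps=False`); type-I error
is the fraction of unadjusted non-DE p-values below 0.05. A master seed
spawns per-replicate child seeds, so results are bitwise reproducible.
Replicates with degenerate score variance contribute p = 1 and are logged.

The routine studies shipped with the package run scaled down — p = 2000
genes, 200 replicates for calibration, 500 for power curves — sizes chosen
so the whole battery re-runs in minutes on one CPU while keeping the
3-binomial-SE calibration band around 5% at ±4.6 points.

## Dynamic network mechanism analysis

Given a normalized profile with ≥2 sample groups and a designated control
(reference) group, per group t:

1. **Candidates**: the top ⌈q·N⌉ sets by score SD across the group's
   samples (default q = 0.05; ceiling so the cut never rounds to empty;
   ties broken by descending SD then name).
2. **Modules**: complete-linkage agglomerative clustering on the distance
   1 − PCC between candidate score vectors within the group, cut at height
   1 − r_crit, where r_crit inverts the two-sided correlation t-test at
   the module significance level (default p = 0.01, df = m − 2 for m
   samples; m = 20 gives r_crit ≈ 0.561). Under complete linkage a cut at
   1 − r_crit bounds every cluster's diameter, so "every intra-module pair
   is individually significant" holds as a theorem, not a heuristic — this
   is why the cut height was derived from the pair test rather than chosen
   freely. Singleton clusters are discarded. The methodology names the
   clustering and the significance level but not how they combine; this
   construction is the package's resolution. "Correlation of SDs" is read
   as Pearson correlation of score vectors (an SD is a scalar per set;
   correlating scalars is undefined).
3. **Controls**: among all scored sets outside the module, the n with the
   highest max |PCC| to any member, computed in the control group (default
   n = 5 for pathway/motif-scale collections, 20 for CGP-scale ones; ties
   by name; a short pool is returned whole with a warning).
4. **Combined score**: S = SD·PCC_in/PCC_out with SD the mean member score
   SD, PCC_in the mean absolute member-pair correlation, PCC_out the mean
   absolute member–control correlation, all within group t (absolute
   correlations and the in-group PCC_out convention follow the dynamical
   network biomarker literature). PCC_out is floored at 1e-6 (flagged) to
   keep the ratio finite.

All groups, including the control group, are analyzed; the module with the
globally largest S wins and names the critical group. Exact score ties go
to the lexicographically lowest group label and are flagged.

Under the null (independent score vectors) some two-member module almost
always forms when the candidate list is large — with k candidates,
~0.01·k(k−1)/2 pairs are expected significant at the default level — so
module *existence* is not evidence by itself; the combined score and its
cross-group contrast carry the inference. What the procedure does control
is the false-positive **pair** rate at the per-pair level.

**Three-set overlap probability.** The significance of n genes shared
among the winning module's sets (sizes A, B, C; background N, default
22 000 human genes) is

p(n) = Σₖ [C(A,k)·C(N−A,B−k)/C(N,B)] · [C(A+B−2k,n−k)·C(N−A−B+2k,C−n+k)/C(N,C)]

— the probability that the first two sets share exactly k genes times the
hypergeometric probability that the third set hits exactly n − k of the
A + B − 2k genes belonging to exactly one of them. Both factors are proper
hypergeometric mass functions, so p ∈ [0,1], p sums to one over n, and the
degenerate case A = B = C = n = N gives exactly 1. Terms with impossible
binomial arguments vanish. Evaluation is exact integer/rational arithmetic
with a float returned. The counted event is "genes in exactly two of the
three sets"; genes covered by all three are not separately modelled — a
known approximation of this classical decomposition.

## RXA-GSP survival indicator

Candidate control sets are screened on a training cohort by univariate Cox
regression of survival on the set's score: kept iff p < 0.01 **and** the
coefficient is positive (higher control score ⇒ worse outcome). Each
retained set's coefficient, and each signature set's, is estimated once on
the training cohort and frozen before any application to validation
cohorts (the API takes coefficient dictionaries, so accidental retraining
is structurally impossible; a per-sample coefficient is unidentifiable, so
one coefficient per set is the only estimable reading).

The per-patient indicator is I = f(S) − f(C) with f(G) = Σ_{i∈G} wᵢ·yᵢ.
`compute_indicator` applies whatever weights it is given (swapping S and C
negates I exactly). The shipped training convention sets w = −coef for
signature sets and w = +coef for controls, making I the negative of the
patient's total univariate Cox risk: I < 0 ⇒ high risk ⇒ predicted poor
outcome. This is the only weighting under which the construction has its
intended meaning — signature sets are protective (negative coefficients),
so weighting them by the raw signed coefficient would produce
risk(S) − risk(C), a contrast of two hazard contributions that cancels for
clearly good and clearly poor patients alike. Patients with I exactly 0
join the good stratum (arbitrary, configurable); patients missing any
required score are dropped and logged.

Strata are compared with the two-sided asymptotic chi-square log-rank test
and Kaplan–Meier step tables are exported. The empirical significance of
an observed log-rank p is the fraction of X random, disjoint gene-set
groups of matched cardinality — excluding the observed S and C themselves,
redrawn independently per iteration — whose re-trained, re-stratified
log-rank p' is ≤ the observed one (default X = 2000; an empirical p of 0
is reported as "< 1/X"). Degenerate draws (a stratum with fewer than two
patients) contribute p' = 1.

The permutation loop needs tens of thousands of univariate Cox fits and
log-rank tests, so the package carries vectorized implementations of both:
Newton iteration on the Breslow partial likelihood (centred covariate,
analytic gradient/Hessian via cumulative sums over the descending-time
ordering, tied times sharing their full risk set) and the standard
two-group log-rank statistic. Both are cross-checked against lifelines in
the test suite — the log-rank agrees to ~1e-9; the Cox fit agrees to ~1e-5
on tie-free data and differs only through the Breslow-vs-Efron tie
correction otherwise. lifelines remains the implementation behind the
Kaplan–Meier export.

## Synthetic data generators

`generate_multigroup_dataset` emulates the *structure* the pipeline
targets, not real AML data: background expression is i.i.d. N(0,1);
gene-sets are disjoint consecutive gene blocks (overlap-free by design so
that module recovery is unambiguous); a planted module's member genes, in
the target group only, share a per-sample latent factor,

    x = inflation · (√ρ·F + √(1−ρ)·G_s) + τ·ε,

giving set-level score correlation ρ in expectation and inflated
within-group variance (defaults ρ = 0.8, inflation 2, τ = 0.5). Dataset
heterogeneity is simulated by per-(gene, dataset) additive offsets
(SD 0.3) plus a per-dataset global scale (0.8–1.25) — the kind of platform
effect the z-normalization absorbs. Default group sizes 23/77/59 mirror
the three sorted populations of the motivating meta-analysis. Everything
is deterministic under the spec seed.

`generate_survival_cohort` draws exponential event times with log-hazard
linear in designated gene-set scores — the simplest model satisfying
proportional hazards, i.e. exactly the assumption the Cox machinery under
test makes — with independent exponential censoring whose rate is matched
to the requested censoring fraction at the baseline hazard (the realized
event fraction shifts slightly when hazards are planted). A second mode
plants a fixed hazard ratio between the two strata defined by the sign of
(mean C score − mean S score), the structure the indicator is designed to
recover.

What passing tests on these fixtures shows: the pipeline recovers planted
covariance/hazard structure of the stated magnitudes at the stated sample
sizes. What they cannot show: robustness to real expression marginals,
platform-specific noise beyond location/scale, overlapping gene-sets, or
non-proportional hazards.

## Numerical conventions and edge cases

- Rank ties: mean fractional ranks (exact rank-sum invariant).
- Probe-collapse ties: first probe in input order.
- Top-SD cut: ceiling; ties by descending SD then name.
- Control-selection ties: by name.
- Critical-group score ties: lowest group label, flagged.
- PCC_out floor: 1e-6, flagged.
- Overlap sum: impossible binomials contribute 0.
- z-normalization: σ = 0 is a hard error naming the sample.
- Cox non-convergence: set excluded from screening / weight 0, logged.
- Seeds: every stochastic routine takes one integer seed; per-replicate
  child seeds come from numpy SeedSequence spawning.

## Known limitations

- The overlap probability models genes in exactly two of three sets;
  triple-covered genes are folded into the pairwise terms.
- The empirical p-value resolution is 1/X; values of 0 mean "< 1/X".
- Breslow tie handling makes the fast Cox coefficients differ slightly
  from Efron-based fits when event times are heavily tied.
- Multivariate clinical adjustment, batch correction beyond the
  z-transform, competitive enrichment p-values, and network drawing are
  out of scope; node/edge lists are exported for external rendering.
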