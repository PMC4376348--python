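# genesetdyn

Function-centric analysis of bulk and single-cell transcriptomes on the
scale of **gene-sets** rather than genes: per-sample soft-threshold gene-set
scoring, cross-dataset normalization of gene-set profiles, a simulation
harness for scorer calibration, discovery of critical co-fluctuating
gene-set modules across sample groups (dynamic network mechanism analysis),
and a personalized survival indicator built from pairs of gene-set groups.

The motivating setting is meta-analysis of sorted cell populations — e.g.
leukemic stem cell (LSC)-enriched, LSC-depleted, and normal hematopoietic
stem cell (HSC) samples in acute myeloid leukemia — pooled from many labs
and platforms, where single-gene signatures fail to reproduce and only genes
measured by every platform can be compared. Condensing each sample into
gene-set scores makes the datasets commensurable and the findings
functionally interpretable.

## The methods

**FAIME.α scoring.** For sample *j* with *n* measured genes, expression is
converted to ranks *r(x)ⱼ* (rank *n* = most highly expressed), then to a
soft-thresholded scale

    s(x, α)ⱼ = r(x)ⱼ · w(x, α),   w(x, α) = exp(α · (r(x)ⱼ/n − 1))

and the score of gene-set *i* is the difference of the mean of *s* over
genes inside the set and the mean over all other measured genes. The
exponent α ≥ 0 is a soft threshold: α = 0 reduces to a difference of mean
ranks, while larger α concentrates the score on the most highly expressed
genes, suppressing noise from low-expressed genes (default α = 5; presets
1, 5, 10). Because only per-sample ranks enter, the score is invariant to
any strictly increasing transform of a sample's values — log2 microarray
intensities and raw RNA-seq counts are equally valid inputs.

**Inter-dataset normalization.** Each sample column of a gene-set profile
is z-transformed over its *N* gene-set scores (population standard
deviation, divisor *N*), making profiles from disparate platforms directly
comparable, symmetric, and zero-centered.

**Dynamic network mechanism (DNM) analysis.** Within each sample group:
keep the top 5% of gene-sets by score SD; cluster them by complete-linkage
hierarchical clustering on the distance 1 − PCC, cutting at 1 − r_crit so
that every intra-module pair is significantly correlated (default two-sided
p ≤ 0.01); pick the n control sets outside the module most correlated with
it in the reference group; score each module S = SD·PCC_in/PCC_out. The
globally best module marks the **critical group** — the population sitting
at a transition, where a small set of functions co-fluctuates strongly.
Gene sharing among the winning module's sets is quantified by an exact
three-set hypergeometric overlap probability.

**RXA-GSP prognosis.** Given signature sets S and screened control sets C
(univariate Cox p < 0.01 with positive coefficient on a training cohort),
each patient gets an indicator I = f(S) − f(C), a contrast of
coefficient-weighted score sums. I > 0 marks predicted good outcome, I < 0
poor; strata are compared by log-rank, and the log-rank p receives an
empirical significance by re-running the whole training/stratification on X
random gene-set groups of matched sizes (default X = 2000).

## Worked example

Everything below runs on synthetic data from the built-in generator: three
sorted groups (23 HSC+, 77 LSC+, 59 LSC− samples, two simulated platforms),
80 gene-sets over 2000 genes, with a 3-set module planted in LSC−
(score correlation 0.8, 2× SD inflation).

```python
import genesetdyn as g
from genesetdyn.rxa import train_indicator_weights

spec = g.FixtureSpec(seed=7)
expr, sets = g.generate_multigroup_dataset(spec)
profile = g.z_normalize(g.score_dataset(expr, sets, g.ScoringConfig(alpha=5.0)))
result = g.identify_critical_group(profile, g.DNMConfig(control_group="HSC+"))
win = result.winning_module
print(result.critical_group, win.members)
print(f"S = {win.sd_mean:.3f} * {win.pcc_in:.3f} / {win.pcc_out:.3f} = {win.score:.2f}")
```

prints

```
LSC- ('SET001', 'SET002', 'SET003')
S = 3.046 * 0.562 / 0.117 = 14.68
```

— the planted module and its group are recovered, and the combined score
decomposes into high member variability (mean SD 3.05), strong intra-module
correlation (0.56), and weak correlation with controls (0.12). A three-set
overlap of 6 genes among sets of sizes 10, 12, 8 against a 22 000-gene
background would have probability `g.overlap_pvalue(10, 12, 8, 22000, 6)`
= 7.8e-16 — sharing on that scale is essentially impossible by chance.

Survival: plant protective hazards on the module sets and adverse hazards
on some controls, screen, train, and stratify:

```python
spec.loghazard = {"SET001": -0.4, "SET002": -0.4, "SET003": -0.4,
                  "SET057": 0.6, "SET017": 0.6, "SET016": 0.6}
cohort = g.generate_survival_cohort(spec, profile)
screen = g.select_prognostic_controls(cohort, list(win.controls))
s_w, c_w = train_indicator_weights(cohort, list(win.members), screen.selected)
res = g.stratify_and_test(g.compute_indicator(cohort, s_w, c_w), cohort)
emp, _ = g.empirical_pvalue(cohort, res.logrank_p, (len(s_w), len(c_w)),
                            list(profile.sets), X=200, seed=7,
                            exclude=(tuple(s_w), tuple(c_w)))
print(screen.selected, res.logrank_p, emp)
```

prints

```
['SET017', 'SET016'] 3.60e-16 0.0  (< 1/X = 0.005)
```

— only the two controls carrying a genuine adverse hazard survive the
screen (Cox p 0.0012 and 3e-6, positive coefficients), the indicator strata
(69 good / 90 poor) separate survival at log-rank p = 3.6e-16, and none of
200 random gene-set pairings does as well.

The same pipeline is available from the shell:

```bash
genesetdyn fixtures --outdir study/
genesetdyn score --expr study/expr.tsv --gmt study/sets.gmt \
    --annot study/annot.tsv --alpha 5 --out profile.tsv
genesetdyn normalize --profile profile.tsv --out profile_z.tsv
genesetdyn dnm --profile profile_z.tsv --annot study/annot.tsv \
    --control-group HSC+ --out dnm.json
genesetdyn rxa --profile profile_z.tsv --survival study/surv.tsv \
    --dnm dnm.json --x 2000 --seed 7 --out rxa.json
```

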