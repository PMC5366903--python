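# Methods

## Coordinates and conventions

All internal coordinates are 0-based, half-open. CNV tables on disk use the
1-based inclusive dialect common in array-CNV reports (converted on read and
write); gene annotation is accepted as BED, which is already 0-based
half-open. Only autosomes are analysed: records on X/Y/MT are dropped with a
logged count, while any other unknown chromosome label is treated as an
error, since it usually indicates a build mismatch rather than an expected
sex-chromosome record.

## Consensus merging

Raw per-caller calls are merged per sample. Two same-type calls are the same
event when their reciprocal overlap (`min` of the two mutual overlap
fractions) reaches the threshold (default 0.4, inclusive). Merging is single
linkage over these pairwise edges: connected components may therefore contain
pairs below the threshold, which is the standard behaviour of merge tools
built on pairwise criteria and is the reproducibility-relevant choice a user
should know about. Components supported by fewer than `min_callers`
(default 2) distinct algorithms are discarded. The consensus interval is the
union span of the members; the common core (intersection) is kept as a
diagnostic and is `None` when chaining leaves no shared base. Edges never
join a duplication to a deletion: one event cannot be both a gain and a loss.

Confidence filtering (default floor 5, strict `<` excluded) applies only to
the one caller configured as confidence-reporting; calls without a
confidence value always pass. This mirrors pipelines where exactly one
algorithm emits a log Bayes Factor.

A note on threshold monotonicity: raising the reciprocal threshold refines
the single-linkage partition (components only split), but the *count* of
consensus events can go up or down, because a split can turn one qualifying
component into two. The property suite asserts the refinement, not a count
inequality.

## CNV regions

Across samples, same-type consensus CNVs cluster into CNVRs when the overlap
covers at least 40% of at least one of the two events — deliberately
asymmetric, so a small polymorphic CNV nested inside a larger event always
joins its region. Every connected component is a region, **including
singletons** (`count_singletons=True` by default): per-group region pools of
the size this analysis reports are only arithmetically possible when
unshared CNVs count as regions, so the "at least two CNVs" phrasing of the
region definition is read as the merge condition, not an existence filter.
The strict reading is one flag away.

Sharing between groups is co-membership in one region from a single
clustering of all samples of a tissue, not post-hoc span overlap; the
per-sample rate divides a group's region pool by its sample count within
that tissue. Inheritance labelling of a placental CNV reuses the consensus
reciprocal threshold against same-family parental CNVs (no separate knob):
`maternal`/`paternal` on a match (maternal precedence if both parents match,
matching the single-label convention of inheritance columns in published
tables), `somatic` when both parents are genotyped and negative, and the
disjunctive `paternal_or_somatic`/`maternal_or_somatic` when only one parent
was genotyped and it is negative.

## Burden statistics

Burden is counted per sample from consensus union spans (events and
cumulative Mb, split dup/del). Two-group comparisons run Shapiro–Wilk on
each group at `alpha_normality = 0.05` (the gate alpha and the n ≥ 3 guard
are package decisions — groups too small or constant fail the gate) and use
Welch's *t* only when both groups pass; otherwise the two-sided Wilcoxon
rank-sum test, with the exact null distribution when both n ≤ 25 and there
are no ties, else the normal approximation with tie and continuity
correction (the behaviour of R's `wilcox.test` defaults, which scipy's
`mannwhitneyu` reproduces under this selection). Fisher's exact test is
two-sided by the point-probability rule. No multiple-testing correction is
applied anywhere; reported p-values are unadjusted, and reports record which
test the gate selected.

`percent_change` returns the exact percentage; rounding to whole percent
happens only at report formatting.

## Chromosome context

Window width is `w = round(window_frac · L)` with `window_frac = 0.05`.
Subtelomeric windows are `[0, w)` and `[L − w, L)` — 5% at *each* end;
the pericentromeric window is `[c − w, c + w)` clipped to the chromosome
(total 10% for a mid-chromosome centromere; acrocentric centromeres clip at
0). This is the literal per-side reading of the window definitions; the
alternative 2.5%-per-side reading is a single `window_frac` change.
Membership is any-overlap (≥ 1 bp), not containment — the weakest consistent
reading of "mapped to" — and a CNV overlapping both window types carries
both flags but is counted once under pericentromeric > subtelomeric >
interstitial precedence, so context tables count each CNV once. Large means
strictly longer than 300 kb.

## Expression linkage

Gene classes are determined solely by any-overlap with CNVR spans, strand
ignored (CNVs are unstranded). The `both` class stays in the partition but
is excluded from del/dup subgroup contrasts (it is typically tiny). Class
contrasts compare per-gene median FPKM over a declared sample set ("all" or
"term-only" style subsets are both supported) with a two-sided rank-sum
test.

Size factors follow the median-of-ratios definition: genes with any zero
count are excluded, each sample's counts are divided by the gene's geometric
mean, and the sample's factor is the median ratio; factors are *not*
rescaled to unit product, matching the standard definition. Carrier analysis
z-scores each gene over the union of carriers and non-carriers, skips
zero-variance genes (counted, with reasons) and supports per-gene and pooled
modes — pooling concatenates carrier and non-carrier z-scores across genes
into one rank-sum test, which is the higher-power option when most CNVs are
singletons; neither mode is claimed to be canonical.

Density plots use a Gaussian kernel with bandwidth chosen by biased
cross-validation (the BCV2 criterion minimised over a bracket around the
normal-reference rule, with Silverman's rule as fall-back on degenerate data
or non-convergence; inputs above 2,000 points are subsampled because the
criterion is quadratic). Plots are diagnostics only — no analysis decision
depends on them.

## Synthetic cohorts

The generator's defaults encode the study design the analysis targets:
placental groups of 10 (pregnancy loss), 3 (loss couples reaching live
birth), 9 (first trimester) and 8 (term) samples with mean placental CNV
counts 9 / 7 / 15 / 31 and duplication fractions 0.30 / 0.43 / 0.53 / 0.80
(chosen so group medians and dup/del splits match the published burden
table); trio parents for loss and term families (fathers genotyped with
probability 0.56 in the loss group, reflecting the missing paternal
samples), mother-only duos for first trimester; parental means 8.8–9.1 with
duplication fraction 0.25. CNV lengths are log-normal (median 60 kb,
σ = 1.0, floor 1 kb), which puts roughly 5% of events above 300 kb — in the
range of the published parental large-CNV fractions. A pool of 40
polymorphic loci is shared by all groups (each CNV is drawn from the pool
with probability 0.3); placentas inherit each parental CNV with probability
0.2 and the somatic Poisson mean is reduced by the expected inherited count
so group means are preserved. The three default callers detect events with
probabilities 0.85 / 0.80 / 0.90, jitter breakpoints with 2–3 kb Gaussian
noise, add one false positive per genome, and the third reports a
confidence score (true calls ~N(15, 6), false positives ~N(8, 4), so the
floor of 5 removes mostly noise).

Randomness: one global seed spawns four substreams (cohort, callers, genes,
expression, in that order), so any stage can be regenerated independently
and interleaving stages cannot perturb one another.

Two generator properties matter for interpretation:

* **Within one sample, same-type true CNVs never overlap** (rejection
  sampling, 100 attempts, event skipped on saturation). Real per-sample call
  sets share this property, and it makes the noiseless-caller setting an
  exact identity: consensus output equals truth interval-for-interval.
* **Gene-length selection bias.** Genes overlapping a CNV are biased long,
  and FPKM is length-normalised, so even with every expression effect
  disabled the CNV-gene classes sit slightly *below* the background in FPKM.
  Null-calibration checks therefore run on count medians (length-free); the
  deletion-prone baseline fold is recovered in FPKM space in settings where
  coverage is high enough that length selection is weak. This bias is a real
  feature of this style of analysis, not only of the simulation.

What the generator does **not** emulate: SNP-level intensity data (no
B-allele frequency or log-R ratio), aneuploidy, mosaicism, batch effects in
expression, or linkage between CNV loci. Passing recovery tests therefore
demonstrates the correctness of the merge/cluster/test logic under the
declared noise model, not the calling performance of any real algorithm on
array data.

## Problem sizes

The default test suite and the acceptance script run cohorts of the study's
size (30 placentas + 46 parents), one 100-sample single-group cohort for the
caller closed-form check (~2,500 true CNVs), 1,000 random instances of up to
200 calls for the clustering oracles, an exhaustive Fisher enumeration for
table totals up to 30, and 200 replicate cohorts for the burden-contrast
recovery; the whole suite completes in well under five minutes on one CPU.

## Known limitations

* Single-linkage chaining can produce regions much wider than any member;
  the intersection diagnostic and the per-member table make this visible but
  the package does not split chained regions.
* The rank-sum exact/asymptotic switch follows sample size and ties only; no
  permutation option is provided.
* Inheritance labelling considers consensus CNVs only — a parental variant
  missed by two of three callers is invisible, inflating `somatic` labels at
  realistic detection probabilities.
* The expression model draws per-gene baselines independently of genomic
  position, so it cannot emulate co-expression of neighbouring genes inside
  one region.
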