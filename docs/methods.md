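# Methods

## Problem and model

Oncogenic NTRK1/2/3 fusions place an intact kinase domain under a 5'
partner's promoter; in structural-variant-poor data they leave an indirect
footprint — overexpression of the 3' partner together with a (often
5'-partial) deletion of it and/or a deletion of a known 5' partner gene.
`cryptkin` codes this footprint for NTRK3 in colorectal-cancer cohorts as
two additive indicator scores per sample:

```
NFS1 = [NTRK3 deleted] + [any 5' partner deleted] + [NTRK3 expression high]   (0–3)
NFS2 = [NTRK3 deleted] + [NTRK3 expression high]                              (0–2)
```

with "high" states at the cut scores 3 and 2. NFS1-high logically implies
NFS2-high. A gene counts as deleted when at least one copy-number segment
overlaps its locus — closed 1-based intervals, any partial overlap — with a
segment mean (log2 copy-ratio) at or below −0.3. Among qualifying segments
the minimum mean is reported as supporting evidence. An optional strict
mode restricts the interrogated interval to the strand-aware 5' half of the
gene; the default interrogates the whole locus, because the biological
motivation (5'-partial deletion) does not change what constitutes deletion
evidence. The 5' partner registry (ETV6, TPM3, TPR, SQSTM1, EML4, MYH9,
MYO5A, GRCh38 coordinates) is plain data and user-overridable.

## Preprocessing

Expression enters the scoring chain per cohort as: symmetric winsorization
(per-gene total trimmed mass, defaults 0.15 for NTRK1/NTRK3 and 0.30 for
NTRK2, half per tail; linear/type-7 quantiles), then min-max normalization
to [0, 1]. The phrase "trimmed mass" is ambiguous between per-tail and
total conventions; both are reachable (`NormalizationRecipe.per_tail`),
total is the default. A constant vector min-max-normalizes to all 0.5 by
convention. Cohorts are normalized independently and then pooled; the
cohort label is kept as a regression covariate, and a bias report tests
every variable for cohort effects (one-way ANOVA for continuous,
chi-square for categorical). Dichotomization is per-gene at the pooled
median, ties assigned "low" (deterministic); a pooled-across-genes median
is available as a config switch. The rank-based inverse-normal transform
uses mid-ranks and the Van der Waerden proportion r/(n+1) before the
standard-normal quantile map, so tied inputs map to equal outputs and no
rank reaches the quantile function's poles.

Winsorize-then-normalize is *nearly* idempotent on its own output: with
linear quantile interpolation the re-computed tail quantile sits a fraction
of one inter-order-statistic gap inside the clamped mass, so a second pass
moves tail values by O(gap), not zero. This is inherent to the type-7
convention and is documented rather than patched.

## Statistics

Standard tests are delegated to scipy/statsmodels/lifelines: tie-corrected
Spearman (exact permutation p by full rank-permutation enumeration for
n < 10, t-approximation otherwise), Pearson chi-square without continuity
correction, one-way ANOVA, Brown–Mood K-sample median test (ties counted
below, matching the dichotomization rule), OLS and binary logistic
regression (constant and collinear design columns dropped and reported;
separation flagged from non-convergence or exploding coefficients), and
the two-group log-rank test with Kaplan–Meier curves. Benjamini–Hochberg
adjustment is implemented directly (step-up, capped at 1) and applied
within an analysis block — all clinical variables against one outcome —
never across blocks. Missing values are handled pairwise-complete with
`n_used` reported per test. Survival is univariate log-rank only;
stage-adjusted survival independence is out of scope (logistic adjustment
on the event indicator is the available approximation).

## Enrichment engine

The weighted-KS enrichment score increments the running sum by
|score|^p / Σ|score|^p at set members and decrements by 1/(N − N_h) at
non-members; ES is the extremum of larger magnitude, with the positive
extremum preferred on a magnitude tie within 1e-12 (a deterministic rule
shared with the brute-force oracle used in tests). p = 1 is the default
weight; p = 0 reduces exactly to the classic KS deviation between hit and
miss positional CDFs. The ranking metric default is signal-to-noise with
each class SD floored at max(0.2·|mean|, 0.2); t-statistic and log2-ratio
metrics are available. Gene ties in rankings break lexicographically by
symbol (genes are pre-sorted and the score sort is stable), making
permutation results bit-reproducible given a seed.

Significance: phenotype permutation (labels reshuffled, the entire ranking
recomputed per permutation; requires ≥ 7 samples per class, otherwise the
engine logs a switch to gene-set permutation) or gene-set permutation
(random same-size sets against the fixed ranking). Nominal p is the
same-sign tail fraction of permuted ES; when no permutation matches the
observed sign, p is reported as 1/(n_perm + 1). NES divides ES by the mean
|ES| of same-sign permutations of the same set. FDR is the canonical
sign-pooled ratio of tails on normalized scores, followed by q-value-style
monotone smoothing within each sign class (a set's FDR is the minimum
estimate over all thresholds that reject it), which guarantees FDR
non-increasing in |NES|. Over-representation is a one-sided Fisher exact
test with Haldane +0.5 continuity correction for the odds ratio whenever a
cell is zero, BH across sets, and a volcano export of (log2 OR,
−log10 adjusted p).

Because the two cohorts profile unequal gene panels, enrichment runs per
cohort; the leading edge from one cohort can be re-tested as a derived
gene set on the other (covered by a test).

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
colorectal genomes. Defaults (one-time choices): fusion fraction 0.085;
subtype mix CIN/MSI/GS = 0.65/0.15/0.20; methylation slope −1.0 per beta
unit on Beta(2, 2) beta values (anti-correlated methylation–expression for
all three NTRK genes); NTRK2 dose effect +0.5 per copy-number category
step; subtype-structured expression (NTRK1 +0.5 noise-SD in the MSI
subtype, NTRK2/3 outside it) and subtype-conditioned clinical covariates
(MSI status, location, BRAF, TP53, FGA, TMB, aneuploidy), so categorical
associations at n = 800 are well powered; exponential survival independent
of everything else (survival tests are true nulls). A planted fusion is a
segment covering the 5' half of NTRK3 (NTRK3 is minus-strand, so the
high-coordinate half) with mean Uniform(−1.2, −0.35), a full-locus deletion
of one random partner at the same mean distribution, and an NTRK3
expression shift of +3 noise SDs. Background segments have means inside
(−0.25, 0.25), so no background event can cross the −0.3 threshold: every
deletion call traces to a planted event, and the NFS2-high rate is a
direct estimator of the planted fraction. What passing tests therefore
show is parameter recovery and calibration under the assumed structure —
not robustness to focal-deletion landscapes, panel-specific normalization
artefacts, or expression–copy-number couplings beyond the linear ones
planted.

## Problem sizes and numerical choices

Tests and the acceptance script use two cohorts of 400 samples (pooled
n = 800, matching the desk-scale recovery design), 200–500 background
genes, a 1000-gene universe with 1000 phenotype permutations for the
planted-enrichment check, 500 replicates for null calibration of the test
battery, and 1000 randomized configurations for the deletion-caller
oracle. Permutation scoring is vectorized (class sums via matrix products,
one stable argsort per permutation), so the full suite runs in well under
a minute of compute for the enrichment parts. Degenerate inputs are
defined, not crashed on: empty segment lists yield negative deletion
calls, constant vectors have NaN Spearman rho, all-identical expression
winsorizes to itself, and a gene set equal to the whole universe is
rejected (the miss decrement is undefined).

## Known limitations

Cox modelling, probe-level methylation, breakpoint-precise fusion
reconstruction, RNA-level fusion detection, batch correction beyond the
cohort covariate, and web-service gene-set retrieval are out of scope.
The denominators of real exports (expression vs segment sample sets) can
differ; the pipeline always reports the joined denominator it used rather
than assuming one.
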