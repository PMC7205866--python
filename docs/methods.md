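# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical conventions that make every run deterministic.

## Plate normalization and the hit-calling funnel

Arrayed-screen measurements are normalized per plate and per channel with a
robust Z-score: location = median, spread = 1.4826 × MAD, computed over the
plate's *sample* wells only (SMARTpool or duplex reagents). Controls are
scored against the same location/spread but never contribute to it, so a bad
control cannot distort the plate. "Robust" is taken at its word: screens
routinely contain strong phenotypic outliers, and median/MAD estimates are
insensitive to them where mean/SD estimates are not; a `center="mean"`,
`scale="sd"` switch exists for comparison. A plate/channel whose MAD is zero
(all sample wells identical) has no meaningful spread and aborts with a
`DegeneratePlateError` naming the plate — never a silent fallback.
Percent-of-control (100 × value / plate non-targeting median) is reported
for interpretability but never gated on: the often-quoted percent
equivalents of Z cutoffs are dataset-specific correlates, not independent
thresholds.

Funnel defaults: primary hits at z_count ≥ 2; triage at z_EdU ≥ 1.5 AND
z_area ≤ −2 (both boundaries inclusive; OR-combination available — the
AND reading is the stricter and more conservative of the two); confirmed
hits need ≥ 2 of 4 duplexes with z_count ≥ 2 on the duplex plates' own
normalization (a stricter tri-channel recapitulation mode is available).
"Top N" selection for deconvolution ranks by z_count descending with a
lexicographic gene-symbol tie-break, so output is reproducible. Genes with
no duplex records are recorded as untested, not failed.

The expression filter removes genes whose raw RNA-seq count is 0 in **all**
replicates (the all-zero reading; an any-zero mode exists). Genes absent
from the count table are conservatively retained — dropping them silently
would delete evidence. Unexpressed genes cannot produce an on-target
knockdown phenotype, so excluding them up front removes a whole class of
false positives before any statistics are computed.

Seed flagging: published screen reports rarely specify the seed-analysis
procedure in full, so this package fixes one and documents it. Every 7-mer
seed shared by recapitulating duplexes of ≥ 2 distinct hit genes is tested
for enrichment among recapitulating-hit duplexes relative to the screened
library (hypergeometric upper tail), BH-adjusted across tested seeds. A gene
is flagged only when *every* recapitulating duplex carries an enriched seed
(adjusted p < 0.05) — i.e. when no on-target-looking support remains. Genes
with any clean duplex keep their hit status unflagged. Missing seed
sequences skip flagging with a logged warning; nothing is fabricated.

## Clonality/subclonality ratio and the permutation null

Multiple mutations in one gene in one patient collapse to a single event;
when clonal and subclonal events co-occur the label defaults to clonal (the
earliest-timing interpretation; configurable). Genes enter the analysis when
mutated in ≥ 3 distinct patients. The ratio's denominator can be zero; the
default policy treats such ratios as undefined and excludes them from set
summaries while reporting how many were excluded — no probability mass is
invented. Alternatives (cap-at-numerator, a symmetric (n_c+1)/(n_s+1)
pseudocount) are selectable.

The null draws `n_perm` gene sets of the observed size uniformly without
replacement from the universe — by default all genes passing the same
≥ 3-patient filter in the same cohort, so observed and null sets face
identical ascertainment. The primary summary is the mean of defined ratios
(skewness is available as a sensitivity analysis); the one-sided right-tail
p uses the add-one estimator (1 + #{null ≥ observed}) / (1 + n_perm), which
is never zero and makes the p-value honest at any n_perm. Sampling is
vectorized (the set is the arg-partition of i.i.d. uniforms) and bitwise
reproducible given the spec's seed.

## Single-sample enrichment score

For each sample, genes are ranked by expression (average ranks for ties;
highest expression → rank N), and the walk order is descending expression
with a lexicographic gene tie-break so output is deterministic. The score is
the summed difference between the weighted ECDF of in-set genes — weights
|rank|^alpha with alpha = 0.25, the cited single-sample method's
convention — and the unweighted ECDF of out-of-set genes. The score is not
divided by the gene count by default; `normalize=True` divides by N.
Duplicate symbols are aggregated by maximum expression before ranking
(mean available). A set covering every matrix gene leaves the out-of-set
ECDF undefined and is rejected, as is an empty intersection. Because the
statistic depends only on ranks, any strictly monotone per-sample transform
leaves the score unchanged — a property the tests assert.

Group comparisons use the one-sided Wilcoxon rank-sum test, exact by
enumeration when the pooled size is ≤ 12 without ties, otherwise the normal
approximation with tie correction. Reference-group selection (e.g. excluding
patients with alterations in the genes of interest) is an explicit
sample-list input, never hard-coded cohort logic.

## Metabolite differential statistics

Pooled-median normalization divides each sample by its median feature
abundance and rescales by the grand median, equalizing per-sample medians
while preserving units; the operation is idempotent. Tests default to
Student's pooled-variance t on log2 abundances — peak areas are
approximately log-normal, so the log scale is where a t-test's assumptions
are closest to holding; raw-scale and Welch variants are selectable.
Zero-variance features with equal means get t = 0, p = 1 by convention.
Significance is BH-adjusted q < 0.05. "Common" features are significant in
*both* senescence-vs-proliferating contrasts (intersection; union
selectable), and condition-specific sets additionally require a positive
mean log fold change. Sample exclusions (a failed replicate, say) are an
input-manifest concern, never auto-detected.

## Synthetic generators: what they emulate and what they do not

All generators are pure functions of their configuration, seed included.

**Screen.** 384-well plates with controls in the first two columns
(16 non-targeting, 8 positive, 8 empty per plate), one SMARTpool well per
gene, and per-plate multiplicative effects. Channel noise is log-normal
(cell counts rounded); planted escape genes shift all three channels,
sign-correct (count ↑, EdU ↑, area ↓), by `effect_size_mads` log-scale SDs —
for log-normal noise the log-scale SD equals the robust 1.4826 × MAD spread
of the log values, so planted effects are threshold-interpretable. The
default plants 50 escape genes among 1,000 at 5 MADs with 75%-active
duplexes; at that strength per-channel passage is near-certain and the
recovery ceiling is the analytic two-of-four binomial P(≥2 of 4 | 0.75) =
0.949. Duplex plates cover every gene so any triage outcome can be
deconvoluted. Not emulated: spatial plate artifacts beyond a scalar plate
effect, image-level features, edge effects — so passing recovery tests says
the statistics are correct, not that real plates are this clean.

**Cohort.** 120 patients × 400 genes, 5% per-gene mutation probability
(≈ 6 carriers/gene), background mutations clonal with probability 0.5 and
36 planted drivers with 0.85. Real cohorts have correlated mutations,
variable per-patient burden and CCF-derived label uncertainty; none of that
is modeled — the generator tests the ratio/permutation machinery, not
clonality inference.

**Expression.** Log-normal matrix with a planted additive shift (natural-log
units) of the signature genes in the shifted samples. **Metabolites.** 150
features, three conditions, planted shifts in log-scale SD units for common
and condition-specific sets. The planted fraction is deliberately small
(≈ 13%): pooled-median normalization assumes most features are unchanged,
and a generator violating that would manufacture spurious differentials.

## Test design for planted-truth recovery

Exact recovery assertions depend on power. At triplicates per group and a
3-SD planted shift, the BH-corrected per-feature power is far below 1
(noncentral-t ncp = 3·√(3/2)⁻¹ ≈ 3.7 at 4 df against a BH threshold near
p = 0.013), so "recovered = planted" is not the expected outcome at that
design point. The metabolite recovery test and the demonstration conditions
in the acceptance script therefore run the generator at a 4-SD shift with 6
replicates per group, where exact recovery is the high-probability outcome;
the generator's own defaults (3 SD, triplicates) remain the realistic small
GC-MS design. The screen recovery test runs at the generator defaults.

## Determinism and problem sizes

Every stochastic step flows from an explicit seed (`numpy.random.default_rng`);
the acceptance script derives independent per-stage seeds from its single
`--seed` via `SeedSequence`. Sorting is total everywhere (ties broken
lexicographically), booleans serialize as 0/1, and run metadata carries the
resolved configuration and its hash but no timestamps, so identical runs are
byte-identical. Default problem sizes (1,000-gene screen, 120-patient
cohort, 5,000 × 40 expression matrix, 10,000–100,000 permutations) run the
full pipeline end to end in well under a minute on one CPU.

## Known limitations

No spatial plate-effect correction (B-score/loess) beyond per-plate robust
Z; no CCF inference or phylogenetics upstream of the clonality table; no
differential-expression modeling upstream of the pre-ranked metric; no
gene-symbol alias resolution at I/O boundaries; the seed-flagging procedure
is this package's fixed, documented choice rather than a community standard.
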