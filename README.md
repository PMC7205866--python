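# senescreen

Analysis toolkit for genome-wide senescence-escape RNAi screens and their
downstream statistics. It was built around the computational workflow of
AKT-induced senescence (AIS) escape studies: cells driven into senescence by
chronic PI3K/AKT/mTORC1 activation are knocked down gene by gene in arrayed
384-well plates, and the genes whose loss lets cells re-enter the cycle are
called, confirmed, and then interrogated in tumor cohorts and expression
data. The package is aimed at computational biologists who need these stages
as tested, importable building blocks rather than one-off scripts.

## What it computes

**Robust-Z hit calling with duplex deconvolution** (`senescreen.screen`).
Each plate channel (cell count, mean EdU intensity, mean nuclear area) is
normalized per plate with a robust Z-score,

    z = (x − median) / (1.4826 · MAD),

estimated on sample wells only; control wells are scored but never shape the
estimate. The funnel is: *primary* hits with z_count ≥ 2 among expressed
genes (genes with raw count 0 in all RNA-seq replicates are excluded up
front), *triaged* hits additionally restoring proliferation markers
(z_EdU ≥ 1.5 and z_area ≤ −2), and *confirmed* hits for which ≥ 2 of the 4
individual siRNA duplexes reproduce the pooled phenotype. A hypergeometric
shared-seed enrichment test flags hits whose support looks like 7-mer
seed-driven off-target activity.

**Clonality/subclonality ratio with a permutation null**
(`senescreen.clonality`). For a gene G in a cohort with clonal/subclonal
mutation calls,

    ratio(G) = #patients with a clonal mutation in G
             / #patients with a subclonal mutation in G,

after collapsing multiple events per (patient, gene) to one. A candidate
set's mean ratio is compared against random same-size gene sets drawn from
the cohort universe; the one-sided empirical p uses the add-one rule
p = (1 + #{null ≥ observed}) / (1 + n_perm).

**Single-sample signature scoring** (`senescreen.signature`). A rank-based
single-sample enrichment score per sample (difference between the weighted
ECDF of in-set genes, weights |rank|^0.25, and the unweighted ECDF of
out-of-set genes, summed over the descending-expression walk), plus a
one-sided Wilcoxon rank-sum group comparison, and the small quantification
formulas: RPKM, the 2^(−ΔΔCt) qPCR fold change, and the
log2FC × −log10(p) pre-ranked metric with a mean-raw-count ≥ 20 floor.

**Metabolite differential statistics** (`senescreen.diffstats`).
Pooled-median normalization, per-feature Student (or Welch) t-tests on log2
abundances, Benjamini–Hochberg FDR, and the common / condition-specific
significant-set partition.

**Synthetic data with planted truth** (`senescreen.simulate`). Every stage
has a seed-reproducible generator (plates with plate effects and planted
escape genes, cohorts with planted clonal drivers, expression with a planted
signature shift, metabolites with planted differentials) so the whole
pipeline is testable without downloads.

## Worked example

`examples/screen_hit_calling.py` simulates a 300-gene screen with 15 planted
escape genes and runs the full funnel:

```
genes screened:        300
expressed:             285
primary hits (Z>=2):   23
triaged hits:          15
confirmed (>=2 of 4):  15
planted escape genes recovered: 15/15
```

23 genes clear the primary cell-number cutoff (planted genes plus a handful
of plate-noise false positives); triage on EdU and nuclear area removes the
noise; duplex deconvolution confirms all 15 planted genes and nothing else.
The other examples (`clonality_permutation.py`, `signature_scoring.py`,
`metabolite_differential.py`) demonstrate the remaining stages the same way.

A thin CLI mirrors the library for shell use, e.g.

```bash
senescreen simulate screen --out scratch/demo --seed 1
senescreen screen run scratch/demo/primary_wells.tsv \
    --duplex-wells scratch/demo/duplex_wells.tsv \
    --counts scratch/demo/counts.tsv --out scratch/demo/run
```

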