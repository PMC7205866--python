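"""Single-sample gene-set enrichment scoring and small expression formulas.

The single-sample enrichment score (ssGSEA-style) ranks each sample's genes
by expression and walks the ranking, accumulating the difference between a
rank-weighted empirical CDF of in-set genes and the unweighted empirical CDF
of out-of-set genes; the score is the integrated (summed) difference.  With
weight exponent ``alpha`` and per-sample expression ranks r (highest
expression -> rank N, ties averaged), walking positions i = 1..N in
descending-expression order:

    ES = sum_i [ P_in(i) - P_out(i) ]
    P_in(i)  = sum_{g in set, pos(g) <= i} r_g^alpha / sum_{g in set} r_g^alpha
    P_out(i) = #{g not in set, pos(g) <= i} / (N - |set|)

Purely rank-based: any strictly monotone transform of a sample's values
leaves its score unchanged.  Group comparisons use a one-sided Wilcoxon
rank-sum test.  Also here: RPKM, the 2^(-ddCt) qPCR fold change, and the
log2FC x -log10(p) pre-ranked metric with a mean-raw-count floor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class GeneSet:
    """A named gene collection (GMT line). Symbols are uppercased on load."""

    name: str
    genes: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


def aggregate_duplicates(expr: pd.DataFrame, policy: str = "max") -> pd.DataFrame:
    """Collapse duplicate gene symbols by max (default) or mean expression."""
    if policy not in ("max", "mean"):
        raise ValueError(f"unknown duplicate policy {policy!r}")
    if expr.index.is_unique:
        return expr
    return expr.groupby(level=0).agg(policy)


def ssgsea_score(
    expr: pd.DataFrame,
    gs: GeneSet,
    alpha: float = 0.25,
    normalize: bool = False,
    duplicate_policy: str = "max",
) -> pd.DataFrame:
    """Per-sample single-sample enrichment score for one gene set.

    ``expr`` is a gene x sample matrix of non-negative expression values.
    Gene symbols are uppercased and duplicates aggregated before ranking.
    Ranking ties take the average rank for the weight and are ordered
    lexicographically by gene symbol in the walk, so output is deterministic.
    ``normalize=True`` divides the score by the number of ranked genes.

    Returns a sample-indexed frame with ``es`` and ``n_set_genes_present``.
    """
    expr = expr.copy()
    expr.index = expr.index.astype(str).str.upper().str.strip()
    expr = aggregate_duplicates(expr, duplicate_policy)
    genes = expr.index
    in_set = genes.isin(gs.genes)
    k = int(in_set.sum())
    n = len(genes)
    if k == 0:
        raise ValueError(f"no gene of set {gs.name!r} is present in the matrix")
    if k == n:
        raise ValueError(
            f"gene set {gs.name!r} covers every gene in the matrix; "
            "the out-of-set ECDF is undefined"
        )
    scores = {}
    for sample in expr.columns:
        col = expr[sample]
        ranks = col.rank(method="average").to_numpy()  # highest expression -> N
        order = np.lexsort((genes.to_numpy(), -col.to_numpy()))
        in_ord = in_set[order]
        w = np.where(in_ord, np.abs(ranks[order]) ** alpha, 0.0)
        cum_in = np.cumsum(w) / w.sum()
        cum_out = np.cumsum(~in_ord) / (n - k)
        es = float(np.sum(cum_in - cum_out))
        if normalize:
            es /= n
        scores[sample] = es
    out = pd.DataFrame({"es": pd.Series(scores)})
    out.index.name = "sample"
    out["n_set_genes_present"] = k
    return out


def compare_groups(
    scores: pd.Series,
    group_a: Sequence[str],
    group_b: Sequence[str],
    exact_max_n: int = 12,
) -> float:
    """One-sided Wilcoxon rank-sum p for group A scoring higher than group B.

    Exact enumeration when the combined size is <= ``exact_max_n`` and there
    are no ties; otherwise the normal approximation with tie correction.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)}")
    a = scores.loc[group_a].to_numpy(dtype=float)
    b = scores.loc[group_b].to_numpy(dtype=float)
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= exact_max_n and no_ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="greater", method=method).pvalue)


def rpkm(count, gene_length_bp, library_size):
    """Reads per kilobase of transcript per million mapped reads.

    RPKM = count / (gene_length_bp / 1e3 * library_size / 1e6).  Vectorized.
    """
    count = np.asarray(count, dtype=float)
    length = np.asarray(gene_length_bp, dtype=float)
    lib = np.asarray(library_size, dtype=float)
    if np.any(length <= 0):
        raise ValueError("gene length must be positive")
    if np.any(lib <= 0):
        raise ValueError("library size must be positive")
    if np.any(count < 0):
        raise ValueError("counts must be non-negative")
    out = count / (length / 1e3 * lib / 1e6)
    return float(out) if out.ndim == 0 else out


def ddct_fold_change(dct_target, dct_reference):
    """qPCR relative fold change 2^(-ddCt), ddCt = dCt_target - dCt_reference."""
    ddct = np.asarray(dct_target, dtype=float) - np.asarray(dct_reference, dtype=float)
    if not np.all(np.isfinite(ddct)):
        raise ValueError("dCt inputs must be finite")
    out = 2.0 ** (-ddct)
    return float(out) if out.ndim == 0 else out


def prerank_metric(
    genes: Sequence[str],
    log2fc: Sequence[float],
    pvalue: Sequence[float],
    mean_raw_count: Sequence[float],
    min_count: float = 20.0,
) -> pd.DataFrame:
    """Pre-ranked gene list for enrichment tools: metric = log2FC x -log10(p).

    Genes with mean raw count below ``min_count`` are dropped before ranking.
    Output is sorted by metric descending with a lexicographic gene tie-break.
    A p-value of exactly 0 is rejected (the metric is undefined); floor such
    p-values upstream (e.g. to the smallest representable p) before calling.
    """
    genes = list(genes)
    fc = np.asarray(log2fc, dtype=float)
    p = np.asarray(pvalue, dtype=float)
    cnt = np.asarray(mean_raw_count, dtype=float)
    if not (len(genes) == len(fc) == len(p) == len(cnt)):
        raise ValueError("gene, log2fc, pvalue and count vectors must align")
    if np.any(p <= 0) or np.any(p > 1):
        if np.any(p == 0):
            raise ValueError(
                "p-value of 0 makes the metric undefined; floor p upstream"
            )
        raise ValueError("p-values must lie in (0, 1]")
    keep = cnt >= min_count
    table = pd.DataFrame(
        {"gene": np.asarray(genes, dtype=object)[keep], "metric": fc[keep] * -np.log10(p[keep])}
    )
    table = table.sort_values(["gene"]).sort_values(
        "metric", ascending=False, kind="stable"
    )
    return table.reset_index(drop=True)
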