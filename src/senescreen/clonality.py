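"""Per-gene clonality/subclonality ratios and a random-gene-set permutation null.

Multi-region tumor sequencing classifies each mutation as clonal (present in
every cancer cell, hence early in the tumor's evolution) or subclonal (present
in a subset, hence late).  For a gene G across a patient cohort,

    ratio(G) = (# patients with a clonal mutation in G)
             / (# patients with a subclonal mutation in G)

so early drivers show high ratios.  A candidate gene set's mean ratio is
compared against an empirical null built by repeatedly drawing random gene
sets of the same size from a gene universe and recomputing the summary;
the one-sided right-tail p uses the add-one estimator so p is never 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

CLONALITY_LABELS = frozenset({"clonal", "subclonal"})

MUTATION_COLUMNS = ["patient_id", "gene", "clonality"]


def collapse_events(raw: pd.DataFrame, precedence: str = "clonal") -> pd.DataFrame:
    """Collapse multiple mutations per (patient, gene) into a single event.

    When a patient carries both clonal and subclonal events in the same gene
    the collapsed label follows ``precedence`` (default ``"clonal"``: the
    earliest-timing interpretation).
    """
    missing = [c for c in MUTATION_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"mutation table is missing columns: {missing}")
    bad = set(raw["clonality"]) - CLONALITY_LABELS
    if bad:
        raise ValueError(f"unknown clonality labels: {sorted(bad)}")
    if precedence not in CLONALITY_LABELS:
        raise ValueError(f"precedence must be 'clonal' or 'subclonal', got {precedence!r}")
    if raw.empty:
        return raw[MUTATION_COLUMNS].copy()
    other = "subclonal" if precedence == "clonal" else "clonal"

    def pick(labels: pd.Series) -> str:
        return precedence if (labels == precedence).any() else other

    collapsed = (
        raw.groupby(["patient_id", "gene"], sort=True)["clonality"]
        .agg(pick)
        .reset_index()
    )
    return collapsed[MUTATION_COLUMNS]


def filter_genes(collapsed: pd.DataFrame, min_patients: int = 3) -> list[str]:
    """Genes mutated in >= ``min_patients`` distinct patients.

    Every row of a collapsed table carries a clonal-or-subclonal label, so
    the >= 1 classified-event requirement is implied.  Returns a sorted list.
    """
    if collapsed.empty:
        return []
    n_patients = collapsed.groupby("gene")["patient_id"].nunique()
    return sorted(n_patients.index[n_patients >= min_patients])


def clonality_ratios(
    collapsed: pd.DataFrame,
    genes: Iterable[str] | None = None,
    zero_policy: str = "undefined",
) -> pd.DataFrame:
    """Per-gene patient counts and clonality/subclonality ratio.

    ``zero_policy`` governs genes with no subclonal patients:

    - ``"undefined"`` (default): ratio is NaN and the gene is excluded from
      set summaries;
    - ``"cap"``: ratio capped at the clonal patient count;
    - ``"pseudocount"``: (n_clonal + 1) / (n_subclonal + 1) for every gene.

    Genes absent from the table get counts 0 and a NaN ratio (never 0).
    """
    if zero_policy not in ("undefined", "cap", "pseudocount"):
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    if collapsed.empty:
        counts = pd.DataFrame(columns=["n_clonal_patients", "n_subclonal_patients"], dtype=int)
        counts.index.name = "gene"
    else:
        counts = (
            collapsed.assign(is_clonal=collapsed["clonality"] == "clonal")
            .groupby("gene")
            .agg(
                n_clonal_patients=("is_clonal", "sum"),
                n_subclonal_patients=("is_clonal", lambda s: (~s).sum()),
            )
            .astype(int)
        )
    if genes is not None:
        counts = counts.reindex(sorted(set(genes)), fill_value=0)
        counts.index.name = "gene"
    nc = counts["n_clonal_patients"].to_numpy(dtype=float)
    ns = counts["n_subclonal_patients"].to_numpy(dtype=float)
    if zero_policy == "pseudocount":
        ratio = (nc + 1.0) / (ns + 1.0)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(ns > 0, nc / np.where(ns > 0, ns, 1.0), np.nan)
        if zero_policy == "cap":
            ratio = np.where((ns == 0) & (nc > 0), nc, ratio)
    ratio = np.where(nc + ns == 0, np.nan, ratio)  # absent gene -> undefined
    out = counts.copy()
    out["ratio"] = ratio
    out["included"] = nc + ns > 0
    return out


def clonality_ratio(collapsed: pd.DataFrame, gene: str, zero_policy: str = "undefined") -> pd.Series:
    """Single-gene convenience wrapper around :func:`clonality_ratios`."""
    return clonality_ratios(collapsed, genes=[gene], zero_policy=zero_policy).loc[gene]


def _summarize(ratios: np.ndarray, stat: str) -> float:
    defined = ratios[np.isfinite(ratios)]
    if defined.size == 0:
        raise ValueError("all ratios in the set are undefined")
    if stat == "mean":
        return float(defined.mean())
    if stat == "skewness":
        return float(stats.skew(defined))
    raise ValueError(f"unknown summary stat {stat!r}")


def set_summary(
    collapsed: pd.DataFrame,
    genes: Sequence[str],
    stat: str = "mean",
    zero_policy: str = "undefined",
) -> tuple[float, int]:
    """Summary (mean or skewness) of a gene set's defined ratios.

    Returns ``(value, n_ignored)`` where ``n_ignored`` counts genes whose
    ratio was undefined and excluded.  Raises if every ratio is undefined.
    """
    table = clonality_ratios(collapsed, genes=genes, zero_policy=zero_policy)
    ratios = table["ratio"].to_numpy(dtype=float)
    value = _summarize(ratios, stat)
    return value, int(np.isnan(ratios).sum())


@dataclass(frozen=True)
class PermutationSpec:
    """Configuration of the random-gene-set null."""

    universe: tuple[str, ...]
    set_size: int = 36
    n_perm: int = 100_000
    summary_stat: str = "mean"
    seed: int = 0
    zero_policy: str = "undefined"

    def __post_init__(self) -> None:
        object.__setattr__(self, "universe", tuple(self.universe))
        if self.set_size > len(self.universe):
            raise ValueError(
                f"set_size {self.set_size} exceeds universe size {len(self.universe)}"
            )
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


@dataclass
class PermutationResult:
    observed: float
    p: float
    null_summaries: np.ndarray
    n_ignored: int
    spec: PermutationSpec = field(repr=False)


def permutation_pvalue(
    collapsed: pd.DataFrame,
    observed_set: Sequence[str],
    spec: PermutationSpec,
) -> PermutationResult:
    """Right-tail empirical p of a gene set's ratio summary vs. random sets.

    Draws ``spec.n_perm`` uniform without-replacement sets of ``set_size``
    genes from the universe, computes the summary for each, and returns

        p = (1 + #{null >= observed}) / (1 + n_perm)

    (add-one rule, so p is in (0, 1]).  Null draws whose summary is undefined
    (no gene in the draw has a defined ratio) are kept in the denominator but
    carry no right-tail mass.  Bitwise reproducible for a fixed spec.
    """
    observed_set = sorted(set(observed_set))
    outside = set(observed_set) - set(spec.universe)
    if outside:
        raise ValueError(f"observed genes outside the universe: {sorted(outside)}")
    observed, n_ignored = set_summary(
        collapsed, observed_set, stat=spec.summary_stat, zero_policy=spec.zero_policy
    )
    universe = list(spec.universe)
    table = clonality_ratios(collapsed, genes=universe, zero_policy=spec.zero_policy)
    ratio_arr = table.loc[universe, "ratio"].to_numpy(dtype=float)
    rng = np.random.default_rng(spec.seed)
    m = len(universe)
    null = np.empty(spec.n_perm, dtype=float)
    chunk = 10_000
    for start in range(0, spec.n_perm, chunk):
        size = min(chunk, spec.n_perm - start)
        # uniform without-replacement sets: smallest `set_size` of iid uniforms
        u = rng.random((size, m))
        idx = np.argpartition(u, spec.set_size - 1, axis=1)[:, : spec.set_size]
        sets = ratio_arr[idx]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            if spec.summary_stat == "mean":
                null[start : start + size] = np.nanmean(sets, axis=1)
            elif spec.summary_stat == "skewness":
                null[start : start + size] = stats.skew(sets, axis=1, nan_policy="omit")
            else:
                raise ValueError(f"unknown summary stat {spec.summary_stat!r}")
    exceed = int(np.sum(null >= observed))  # NaN compares False
    p = (1.0 + exceed) / (1.0 + spec.n_perm)
    return PermutationResult(
        observed=observed, p=p, null_summaries=null, n_ignored=n_ignored, spec=spec
    )
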