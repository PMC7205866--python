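"""Arrayed RNAi screen hit calling.

The screen measures three phenotype channels per well of a 384-well plate —
cell count, mean EdU incorporation intensity (S-phase re-entry) and mean
nuclear area (senescent nuclei are enlarged).  Wells are normalized per plate
with a robust Z-score (median center, 1.4826 x MAD scale) computed over the
plate's sample wells; controls are scored against the same location/spread but
never contribute to it.  Hit calling is a funnel:

1. primary hits  — expressed genes whose cell-number Z >= ``z_count_min``;
2. triaged hits  — primary hits that additionally restore proliferation
   markers (EdU Z >= ``z_edu_min`` and nuclear-area Z <= ``z_area_max``);
3. confirmed hits — triaged genes for which >= ``min_recapitulating_duplexes``
   of the four individual siRNA duplexes reproduce the pooled phenotype.

Genes whose transcript is undetected (raw count 0 in every RNA-seq replicate)
are excluded before hit statistics, since a knockdown phenotype for an
unexpressed gene must be off-target.  A shared-seed enrichment test flags
confirmed hits whose supporting duplexes all carry a library-enriched 7-mer
seed (a signature of microRNA-like off-target activity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .diffstats import bh_adjust

logger = logging.getLogger(__name__)

#: channel column -> robust-Z output column
CHANNELS: dict[str, str] = {
    "cell_count": "z_count",
    "edu_intensity": "z_edu",
    "nuclear_area": "z_area",
}

#: channel column -> percent-of-control output column
PCT_COLUMNS: dict[str, str] = {
    "cell_count": "pct_count",
    "edu_intensity": "pct_edu",
    "nuclear_area": "pct_area",
}

SAMPLE_CLASSES = frozenset({"smartpool", "duplex"})
REAGENT_CLASSES = SAMPLE_CLASSES | {"control_nontargeting", "control_positive", "empty"}

WELL_COLUMNS = [
    "plate_id", "well", "reagent_id", "gene", "reagent_class",
    "cell_count", "edu_intensity", "nuclear_area", "duplex_index", "seed_seq",
]


class DegeneratePlateError(ValueError):
    """A plate/channel whose sample wells have zero robust spread (MAD = 0)."""


@dataclass(frozen=True)
class ScreenThresholds:
    """Cutoffs of the hit-calling funnel, all on the robust-Z scale.

    The percent-of-control equivalents sometimes quoted for such cutoffs are
    dataset-specific correlates; gating happens on Z only.
    """

    z_count_min: float = 2.0
    z_edu_min: float = 1.5
    z_area_max: float = -2.0
    min_recapitulating_duplexes: int = 2
    triage_combine: str = "and"  # "and" | "or"

    def __post_init__(self) -> None:
        if not self.z_count_min > 0:
            raise ValueError("z_count_min must be > 0")
        if not self.z_area_max < 0:
            raise ValueError("z_area_max must be < 0")
        if self.triage_combine not in ("and", "or"):
            raise ValueError(f"triage_combine must be 'and' or 'or', got {self.triage_combine!r}")
        if self.min_recapitulating_duplexes < 1:
            raise ValueError("min_recapitulating_duplexes must be >= 1")


def robust_z(values, center: str = "median", scale: str = "mad") -> np.ndarray:
    """Robust Z-score of ``values``: (x - location) / spread.

    Parameters
    ----------
    values
        1-D numeric sequence, length >= 2, all finite.
    center
        ``"median"`` (default) or ``"mean"``.
    scale
        ``"mad"`` (1.4826 x median absolute deviation, default) or ``"sd"``
        (sample standard deviation).

    Raises
    ------
    DegeneratePlateError
        If the spread estimate is zero (e.g. all values identical).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("robust_z requires a 1-D vector of length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("robust_z requires finite values")
    if center == "median":
        loc = np.median(x)
    elif center == "mean":
        loc = np.mean(x)
    else:
        raise ValueError(f"unknown center policy {center!r}")
    if scale == "mad":
        spread = 1.4826 * np.median(np.abs(x - np.median(x)))
    elif scale == "sd":
        spread = np.std(x, ddof=1)
    else:
        raise ValueError(f"unknown scale policy {scale!r}")
    if spread == 0:
        raise DegeneratePlateError("zero spread: values are identical up to MAD = 0")
    return (x - loc) / spread


def _validate_wells(wells: pd.DataFrame, min_sample_wells: int) -> None:
    missing = [c for c in WELL_COLUMNS if c not in wells.columns]
    if missing:
        raise ValueError(f"well table is missing required columns: {missing}")
    bad_class = set(wells["reagent_class"]) - REAGENT_CLASSES
    if bad_class:
        raise ValueError(f"unknown reagent_class values: {sorted(bad_class)}")
    for plate_id, plate in wells.groupby("plate_id", sort=False):
        if plate["well"].duplicated().any():
            dup = plate.loc[plate["well"].duplicated(), "well"].tolist()
            raise ValueError(f"plate {plate_id!r}: duplicate well positions {dup}")
        scored = plate[plate["reagent_class"] != "empty"]
        if (scored["reagent_class"] == "control_nontargeting").sum() < 1:
            raise ValueError(f"plate {plate_id!r} has no non-targeting control wells")
        n_sample = scored["reagent_class"].isin(SAMPLE_CLASSES).sum()
        if n_sample < min_sample_wells:
            raise ValueError(
                f"plate {plate_id!r} has only {n_sample} sample wells "
                f"(< {min_sample_wells}); robust statistics undefined"
            )
        for ch in CHANNELS:
            vals = scored[ch].to_numpy(dtype=float)
            if not np.all(np.isfinite(vals)):
                bad = scored.loc[~np.isfinite(vals), "well"].tolist()
                raise ValueError(f"plate {plate_id!r}: missing {ch} values in wells {bad}")


def normalize_plates(
    wells: pd.DataFrame,
    center: str = "median",
    scale: str = "mad",
    min_sample_wells: int = 8,
) -> pd.DataFrame:
    """Per-plate robust-Z and percent-of-control normalization.

    Sample wells (SMARTpool or duplex reagents) define each plate/channel's
    location and spread; control wells are scored against those estimates but
    excluded from them.  Empty wells are dropped.  Percent-of-control is
    100 x value / (plate non-targeting median), so a well sitting exactly at
    the non-targeting median scores 100.

    Returns a copy of the scored wells with ``z_*`` and ``pct_*`` columns.
    """
    _validate_wells(wells, min_sample_wells)
    out = []
    for plate_id, plate in wells.groupby("plate_id", sort=False):
        scored = plate[plate["reagent_class"] != "empty"].copy()
        is_sample = scored["reagent_class"].isin(SAMPLE_CLASSES).to_numpy()
        is_nt = (scored["reagent_class"] == "control_nontargeting").to_numpy()
        for ch, zcol in CHANNELS.items():
            vals = scored[ch].to_numpy(dtype=float)
            sample_vals = vals[is_sample]
            if center == "median":
                loc = np.median(sample_vals)
            else:
                loc = np.mean(sample_vals)
            if scale == "mad":
                spread = 1.4826 * np.median(np.abs(sample_vals - np.median(sample_vals)))
            else:
                spread = np.std(sample_vals, ddof=1)
            if spread == 0:
                raise DegeneratePlateError(
                    f"plate {plate_id!r}, channel {ch!r}: zero robust spread (MAD = 0)"
                )
            scored[zcol] = (vals - loc) / spread
            nt_median = np.median(vals[is_nt])
            if nt_median == 0:
                raise ValueError(
                    f"plate {plate_id!r}, channel {ch!r}: non-targeting median is 0"
                )
            scored[PCT_COLUMNS[ch]] = 100.0 * vals / nt_median
        out.append(scored)
    return pd.concat(out, ignore_index=True)


def expression_filter(
    counts: pd.DataFrame,
    genes: Iterable[str] | None = None,
    zero_rule: str = "all",
    absent_policy: str = "expressed",
) -> pd.Series:
    """Mark genes as expressed/not-expressed from a raw-count matrix.

    ``counts`` is gene-indexed with one column per biological replicate.
    Under the default ``zero_rule="all"`` a gene is *not* expressed iff its
    raw count is 0 in all replicates; ``"any"`` marks a gene unexpressed if
    any replicate is 0.  Genes in ``genes`` that are absent from the matrix
    follow ``absent_policy`` (default ``"expressed"``: conservatively
    retained; ``"not_expressed"`` drops them).
    """
    vals = counts.to_numpy()
    if vals.size and (np.any(vals < 0) or not np.allclose(vals, np.round(vals))):
        raise ValueError("raw counts must be non-negative integers")
    if counts.shape[1] < 1:
        raise ValueError("count matrix needs at least one replicate column")
    if zero_rule == "all":
        unexpressed = (counts == 0).all(axis=1)
    elif zero_rule == "any":
        unexpressed = (counts == 0).any(axis=1)
    else:
        raise ValueError(f"unknown zero_rule {zero_rule!r}")
    expressed = ~unexpressed
    if genes is None:
        return expressed
    if absent_policy not in ("expressed", "not_expressed"):
        raise ValueError(f"unknown absent_policy {absent_policy!r}")
    default = absent_policy == "expressed"
    return pd.Series(
        {g: bool(expressed.get(g, default)) for g in genes}, name="expressed"
    )


def call_primary_hits(
    z: pd.DataFrame,
    expressed: Mapping[str, bool] | pd.Series,
    thresholds: ScreenThresholds = ScreenThresholds(),
    absent_policy: str = "expressed",
) -> pd.DataFrame:
    """Aggregate per-gene Z-scores from SMARTpool wells and call primary hits.

    A gene with several pool wells gets the mean Z per channel.  Primary hit:
    expressed and ``z_count >= z_count_min`` (boundary inclusive).  Genes
    filtered as not-expressed are never hits, whatever their Z.

    Returns a gene-indexed frame with z_count/z_edu/z_area, ``expressed`` and
    ``primary_hit`` columns, sorted by gene symbol.
    """
    pools = z[z["reagent_class"] == "smartpool"]
    if pools.empty:
        raise ValueError("no smartpool wells in the normalized table")
    agg = pools.groupby("gene")[["z_count", "z_edu", "z_area"]].mean()
    default = absent_policy == "expressed"
    expr = pd.Series(
        [bool(expressed.get(g, default)) for g in agg.index],
        index=agg.index, name="expressed",
    )
    hits = agg.copy()
    hits["expressed"] = expr
    hits["primary_hit"] = expr & (hits["z_count"] >= thresholds.z_count_min)
    return hits.sort_index()


def triage_hits(
    hits: pd.DataFrame, thresholds: ScreenThresholds = ScreenThresholds()
) -> pd.DataFrame:
    """Triage primary hits on the EdU and nuclear-area channels.

    Both boundaries are inclusive.  With ``triage_combine="and"`` (default) a
    hit must restore both proliferation markers; ``"or"`` accepts either.
    """
    out = hits.copy()
    edu_ok = out["z_edu"] >= thresholds.z_edu_min
    area_ok = out["z_area"] <= thresholds.z_area_max
    combined = (edu_ok & area_ok) if thresholds.triage_combine == "and" else (edu_ok | area_ok)
    out["triaged_hit"] = out["primary_hit"] & combined
    return out


def rank_hits(hits: pd.DataFrame, flag: str = "triaged_hit") -> pd.DataFrame:
    """Order flagged hits by cell-number Z descending, gene symbol tie-break."""
    sel = hits[hits[flag]].copy()
    sel = sel.sort_index().sort_values("z_count", ascending=False, kind="stable")
    return sel


def top_hits(hits: pd.DataFrame, n: int, flag: str = "triaged_hit") -> list[str]:
    """Top ``n`` flagged genes under the deterministic ranking."""
    return rank_hits(hits, flag=flag).index[:n].tolist()


def confirm_deconvolution(
    duplex_z: pd.DataFrame,
    triaged_genes: Iterable[str],
    thresholds: ScreenThresholds = ScreenThresholds(),
    require_all_channels: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Confirm triaged genes by individual-duplex recapitulation.

    A duplex recapitulates the pooled phenotype iff its cell-number Z meets
    the primary cutoff (with ``require_all_channels=True`` the EdU and
    nuclear-area triage cutoffs must hold as well).  A gene is confirmed iff
    at least ``min_recapitulating_duplexes`` of its tested duplexes (max 4)
    recapitulate.  Genes with no duplex records are recorded as untested
    (``n_duplexes_tested = 0``), not failed.

    Returns ``(per_gene, per_duplex)`` frames; ``per_duplex`` carries one row
    per tested duplex with a ``recapitulates`` flag (input to seed flagging).
    """
    triaged = sorted(set(triaged_genes))
    dup = duplex_z[
        (duplex_z["reagent_class"] == "duplex") & duplex_z["gene"].isin(triaged)
    ].copy()
    recap = dup["z_count"] >= thresholds.z_count_min
    if require_all_channels:
        recap &= (dup["z_edu"] >= thresholds.z_edu_min) & (
            dup["z_area"] <= thresholds.z_area_max
        )
    dup["recapitulates"] = recap
    per_gene = pd.DataFrame(index=pd.Index(triaged, name="gene"))
    counts = dup.groupby("gene").agg(
        n_duplexes_tested=("duplex_index", "nunique"),
        n_duplexes_recapitulating=("recapitulates", "sum"),
    )
    per_gene = per_gene.join(counts).fillna(0).astype(int)
    if (per_gene["n_duplexes_tested"] > 4).any():
        raise ValueError("a gene has more than 4 distinct duplexes")
    per_gene["confirmed_hit"] = (
        per_gene["n_duplexes_recapitulating"] >= thresholds.min_recapitulating_duplexes
    )
    untested = per_gene.index[per_gene["n_duplexes_tested"] == 0]
    if len(untested):
        logger.warning("%d triaged genes had no duplex records (left untested)", len(untested))
    return per_gene, dup.reset_index(drop=True)


def seed_flag(
    library: pd.DataFrame,
    per_duplex: pd.DataFrame,
    hit_genes: Iterable[str],
    alpha: float = 0.05,
) -> pd.Series:
    """Flag hit genes whose support is explainable by shared-seed off-targets.

    ``library`` lists every screened duplex (columns ``reagent_id``, ``gene``,
    ``seed_seq``); ``per_duplex`` is the duplex detail from
    :func:`confirm_deconvolution`.  Every 7-mer seed shared by recapitulating
    duplexes of >= 2 distinct hit genes is tested for enrichment among the
    recapitulating-hit duplexes relative to the whole library (hypergeometric
    upper tail, BH-adjusted across tested seeds).  A gene is flagged iff it
    has >= 1 recapitulating duplex and *every* one of them carries a seed with
    adjusted p < ``alpha`` — i.e. no on-target-looking support remains.
    """
    hit_genes = sorted(set(hit_genes))
    flags = pd.Series(False, index=pd.Index(hit_genes, name="gene"), name="seed_flagged")
    lib = library.dropna(subset=["seed_seq"]) if "seed_seq" in library.columns else pd.DataFrame()
    if lib.empty or len(lib) < len(library):
        if lib.empty:
            logger.warning("no seed sequences in the library; seed flagging skipped")
            return flags
        logger.warning(
            "%d library duplexes lack seed sequences; they are ignored in enrichment",
            len(library) - len(lib),
        )
    recap = per_duplex[per_duplex["recapitulates"] & per_duplex["gene"].isin(hit_genes)]
    recap = recap.merge(
        lib[["reagent_id", "seed_seq"]], on="reagent_id", how="left", suffixes=("", "_lib")
    )
    if "seed_seq" not in recap.columns or recap["seed_seq"].isna().all():
        logger.warning("recapitulating duplexes carry no seed sequences; flagging skipped")
        return flags
    recap = recap.dropna(subset=["seed_seq"])
    shared = (
        recap.groupby("seed_seq")["gene"].nunique().loc[lambda s: s >= 2].index
    )
    if len(shared) == 0:
        return flags
    M = len(lib)                      # library duplexes with a seed
    n = len(recap)                    # recapitulating duplexes of hit genes
    lib_seed_counts = lib["seed_seq"].value_counts()
    hit_seed_counts = recap["seed_seq"].value_counts()
    pvals = []
    for seed in shared:
        K = int(lib_seed_counts[seed])
        k = int(hit_seed_counts.get(seed, 0))
        pvals.append(stats.hypergeom.sf(k - 1, M, K, n))
    qvals = bh_adjust(np.asarray(pvals))
    enriched = {s for s, q in zip(shared, qvals) if q < alpha}
    for gene, grp in recap.groupby("gene"):
        flags[gene] = bool(len(grp)) and grp["seed_seq"].isin(enriched).all()
    return flags


def seed_enrichment_pvalue(M: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric p for ``k`` of ``n`` drawn hits carrying a
    seed present on ``K`` of ``M`` library duplexes."""
    return float(stats.hypergeom.sf(k - 1, M, K, n))


def assemble_hit_table(
    triaged: pd.DataFrame,
    confirmation: pd.DataFrame | None = None,
    seed_flags: pd.Series | None = None,
) -> pd.DataFrame:
    """Merge the funnel stages into one gene-indexed hit table.

    Output columns: z_count, z_edu, z_area, expressed, primary_hit,
    triaged_hit, n_duplexes_tested, n_duplexes_recapitulating, confirmed_hit,
    seed_flagged.  Confirmation requires triage: a confirmed flag from the
    duplex stage only survives for triaged genes, preserving funnel
    monotonicity confirmed => triaged => primary => expressed.
    """
    out = triaged.copy()
    for col, default in (
        ("n_duplexes_tested", 0),
        ("n_duplexes_recapitulating", 0),
        ("confirmed_hit", False),
        ("seed_flagged", False),
    ):
        out[col] = default
    if confirmation is not None and not confirmation.empty:
        common = confirmation.index.intersection(out.index)
        out.loc[common, "n_duplexes_tested"] = confirmation.loc[common, "n_duplexes_tested"]
        out.loc[common, "n_duplexes_recapitulating"] = confirmation.loc[
            common, "n_duplexes_recapitulating"
        ]
        out.loc[common, "confirmed_hit"] = (
            confirmation.loc[common, "confirmed_hit"] & out.loc[common, "triaged_hit"]
        )
    if seed_flags is not None and len(seed_flags):
        common = seed_flags.index.intersection(out.index)
        out.loc[common, "seed_flagged"] = seed_flags.loc[common]
    out["confirmed_hit"] = out["confirmed_hit"].astype(bool)
    out["seed_flagged"] = out["seed_flagged"].astype(bool)
    return out.sort_index()
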