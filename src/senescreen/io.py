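"""Readers, writers and the reproducible end-to-end screen pipeline.

Conventions: TSV/CSV tables with a mandatory header row (delimiter
auto-detected between tab and comma, or forced), booleans serialized as 0/1,
missing values as empty fields, UTF-8 throughout.  Gene symbols are
uppercased and whitespace-stripped at every boundary; no alias resolution is
attempted.  Every pipeline run writes a resolved-configuration JSON sidecar
next to its outputs so a rerun with identical inputs and seed reproduces the
outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .signature import GeneSet
from .screen import (
    ScreenThresholds, WELL_COLUMNS, assemble_hit_table, call_primary_hits,
    confirm_deconvolution, expression_filter, normalize_plates, seed_flag,
    top_hits, triage_hits,
)

logger = logging.getLogger(__name__)

WELL_SCHEMA: dict[str, type] = {
    "plate_id": str, "well": str, "reagent_id": str, "gene": str,
    "reagent_class": str, "cell_count": float, "edu_intensity": float,
    "nuclear_area": float, "duplex_index": float, "seed_seq": str,
}

HIT_BOOL_COLUMNS = ["expressed", "primary_hit", "triaged_hit", "confirmed_hit", "seed_flagged"]


def _detect_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def clean_symbol(s):
    return None if s is None or (isinstance(s, float) and np.isnan(s)) else str(s).strip().upper()


def read_table(path, schema: Mapping[str, type], sep: str | None = None) -> pd.DataFrame:
    """Schema-validated delimited table with named-column errors."""
    path = Path(path)
    sep = sep or _detect_sep(path)
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required column(s) {missing}")
    for col, typ in schema.items():
        if typ is float:
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError) as exc:
                bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
                row = int(np.flatnonzero(bad)[0]) + 2 if bad.any() else "?"
                raise ValueError(
                    f"{path.name}: column {col!r} is not numeric (first bad row {row})"
                ) from exc
    logger.info("read %s: %d rows, %d columns", path.name, len(df), df.shape[1])
    return df


def read_well_table(path, sep: str | None = None) -> pd.DataFrame:
    """Per-well screen table -> validated well frame (genes uppercased)."""
    df = read_table(path, WELL_SCHEMA, sep=sep)
    df = df[WELL_COLUMNS].copy()
    df["gene"] = df["gene"].map(clean_symbol)
    return df


def read_expression_table(path, sep: str | None = None) -> pd.DataFrame:
    """Gene x sample expression/count TSV, first column = gene symbol."""
    path = Path(path)
    df = pd.read_csv(path, sep=sep or _detect_sep(path), index_col=0)
    if df.shape[1] < 1:
        raise ValueError(f"{path.name}: no sample columns")
    df.index = df.index.map(clean_symbol)
    if df.index.has_duplicates:
        logger.warning("%s: duplicate gene symbols present (aggregate before scoring)", path.name)
    return df


def read_gct(path) -> pd.DataFrame:
    """GCT 1.2 expression matrix (read-only)."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise ValueError(f"{path.name}: not a GCT 1.2 file (got {version!r})")
        n_rows, n_cols = (int(x) for x in fh.readline().split()[:2])
        df = pd.read_csv(fh, sep="\t")
    if df.shape[0] != n_rows or df.shape[1] - 2 != n_cols:
        raise ValueError(f"{path.name}: dimensions disagree with the GCT header")
    df = df.drop(columns=[df.columns[1]]).set_index(df.columns[0])
    df.index = df.index.map(clean_symbol)
    return df


def read_gmt(path) -> list[GeneSet]:
    """GMT gene-set file: name <tab> description <tab> member...  per line."""
    sets = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno} has fewer than 3 fields")
            name, desc, *members = fields
            cleaned = [clean_symbol(m) for m in members if m.strip()]
            unique = frozenset(cleaned)
            if len(unique) < len(cleaned):
                logger.warning(
                    "%s: line %d (%s) has duplicate members; deduplicated", path, lineno, name
                )
            sets.append(GeneSet(name=name, genes=unique, description=desc))
    return sets


def write_gmt(sets: Iterable[GeneSet], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.genes)]) + "\n")


def write_hit_table(hits: pd.DataFrame, path) -> None:
    """Hit table TSV, one row per gene, booleans as 0/1."""
    out = hits.copy()
    for col in HIT_BOOL_COLUMNS:
        if col in out.columns:
            out[col] = out[col].astype(int)
    out.to_csv(path, sep="\t", index=True, index_label="gene", float_format="%.10g")


def read_mutation_table(
    path,
    sep: str | None = None,
    patient_col: str = "patient_id",
    gene_col: str = "gene",
    clonality_col: str = "clonality",
) -> pd.DataFrame:
    """Mutation TSV; MAF-like files map Hugo_Symbol/Tumor_Sample_Barcode."""
    path = Path(path)
    df = pd.read_csv(path, sep=sep or _detect_sep(path))
    if gene_col not in df.columns and "Hugo_Symbol" in df.columns:
        gene_col = "Hugo_Symbol"
    if patient_col not in df.columns and "Tumor_Sample_Barcode" in df.columns:
        patient_col = "Tumor_Sample_Barcode"
    for col in (patient_col, gene_col, clonality_col):
        if col not in df.columns:
            raise ValueError(f"{path.name}: missing required column {col!r}")
    out = df[[patient_col, gene_col, clonality_col]].copy()
    out.columns = ["patient_id", "gene", "clonality"]
    out["gene"] = out["gene"].map(clean_symbol)
    out["clonality"] = out["clonality"].str.strip().str.lower()
    return out


def write_metadata(path, config: Mapping, seed: int | None = None) -> None:
    """Run-metadata sidecar: version, resolved config and its hash, seed.

    Deliberately carries no timestamps so identical runs are byte-identical.
    """
    resolved = json.dumps(config, sort_keys=True, default=str)
    meta = {
        "tool": "senescreen",
        "version": __version__,
        "seed": seed,
        "config": json.loads(resolved),
        "config_sha256": hashlib.sha256(resolved.encode()).hexdigest(),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_screen_pipeline(
    wells: pd.DataFrame,
    duplex_wells: pd.DataFrame | None,
    counts: pd.DataFrame | None,
    out_dir,
    thresholds: ScreenThresholds = ScreenThresholds(),
    top_n: int | None = None,
    seed: int | None = None,
    config: Mapping | None = None,
) -> pd.DataFrame:
    """Normalize -> call -> triage -> deconvolute -> seed-flag -> write.

    ``counts`` (raw-count matrix) drives the expression filter; when absent
    every gene is treated as expressed.  ``top_n`` restricts deconvolution to
    the top-ranked triaged genes (cell-number Z descending, lexicographic
    tie-break).  Writes ``hits.tsv``, ``normalized_wells.tsv`` and
    ``run_metadata.json`` into ``out_dir`` and returns the hit table.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    z = normalize_plates(wells)
    expressed = (
        expression_filter(counts) if counts is not None else pd.Series(dtype=bool)
    )
    hits = call_primary_hits(z, expressed, thresholds)
    hits = triage_hits(hits, thresholds)
    triaged = top_hits(hits, top_n) if top_n else hits.index[hits["triaged_hit"]].tolist()
    confirmation, per_duplex, flags = None, None, None
    if duplex_wells is not None and len(duplex_wells):
        dz = normalize_plates(duplex_wells)
        confirmation, per_duplex = confirm_deconvolution(dz, triaged, thresholds)
        library = duplex_wells[duplex_wells["reagent_class"] == "duplex"][
            ["reagent_id", "gene", "seed_seq"]
        ]
        confirmed = confirmation.index[confirmation["confirmed_hit"]]
        flags = seed_flag(library, per_duplex, confirmed)
    table = assemble_hit_table(hits, confirmation, flags)
    z.to_csv(out_dir / "normalized_wells.tsv", sep="\t", index=False, float_format="%.10g")
    write_hit_table(table, out_dir / "hits.tsv")
    write_metadata(
        out_dir / "run_metadata.json",
        dict(config or {}, thresholds=vars(thresholds), top_n=top_n),
        seed=seed,
    )
    return table
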