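"""Seed-reproducible synthetic inputs with planted ground truth.

Every pipeline stage gets a generator that emulates the structure of its
real-world input at desk scale: 384-well screen plates with plate effects and
planted escape genes, 4-duplex deconvolution plates with partially active
duplexes, patient cohorts with per-gene clonal fractions and a planted
early-driver set, expression matrices with a planted signature up-shift, and
grouped metabolite matrices with planted differential features.  Each
generator is a pure function of its configuration (including the seed) and
returns the planted truth alongside the data, so recovery metrics are
computable without manual input.

Noise families: log-normal on all screen channels (cell counts rounded to
integers) and on expression/metabolite values.  Planted effects are expressed
in units of the noise distribution's log-scale SD, which for log-normal noise
equals the robust (1.4826 x MAD) spread of the log values — so an
``effect_size_mads`` of 4 plants a shift four robust SDs above the plate
location on the log scale, threshold-interpretable after per-plate robust-Z
normalization.
"""

from __future__ import annotations

import dataclasses
import json
import string
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .signature import GeneSet

# channel -> (log-scale mean, log-scale sd, escape-effect sign)
# Senescent baseline: few cells, low EdU, enlarged nuclei; escape raises
# count and EdU and shrinks nuclear area.
CHANNEL_PARAMS: dict[str, tuple[float, float, int]] = {
    "cell_count": (np.log(200.0), 0.15, +1),
    "edu_intensity": (np.log(400.0), 0.20, +1),
    "nuclear_area": (np.log(150.0), 0.10, -1),
}


@dataclass
class PlantedTruth:
    """Ground-truth labels serialized alongside every synthetic dataset."""

    escape_genes: list[str] | None = None
    unexpressed_genes: list[str] | None = None
    duplex_active: dict[str, list[bool]] | None = None
    driver_genes: list[str] | None = None
    signature_genes: list[str] | None = None
    signature_samples: list[str] | None = None
    differential_features: dict[str, list[str]] | None = None

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {k: v for k, v in dataclasses.asdict(self).items() if v is not None},
                fh, indent=2, sort_keys=True,
            )
            fh.write("\n")


@dataclass(frozen=True)
class ScreenSimConfig:
    """Arrayed-screen generator settings.

    Defaults plant 50 escape genes among 1,000 at a 5-MAD three-channel
    effect with 75%-active duplexes — a reduced-scale screen with planted
    truth strong enough that the default thresholds should recover it.
    (At exactly 4 MAD the per-channel pass probabilities of ~0.97 compound
    with the 0.949 two-of-four duplex ceiling to an expected confirmation
    sensitivity below 0.9; 5 MAD keeps each channel near-certain so the
    duplex binomial dominates.)
    """

    n_genes: int = 1000
    n_escape: int = 50
    wells_per_plate: int = 384
    n_nontargeting: int = 16
    n_positive: int = 8
    n_empty: int = 8
    effect_size_mads: float = 5.0
    plate_effect_sd: float = 0.1
    duplex_active_prob: float = 0.75
    decoy_active_prob: float = 0.05
    unexpressed_frac: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_escape > self.n_genes:
            raise ValueError("n_escape cannot exceed n_genes")
        if not self.effect_size_mads > 0:
            raise ValueError("effect_size_mads must be positive")
        if not 0 < self.duplex_active_prob <= 1:
            raise ValueError("duplex_active_prob must lie in (0, 1]")
        n_ctrl = self.n_nontargeting + self.n_positive + self.n_empty
        if self.wells_per_plate - n_ctrl < 8:
            raise ValueError("infeasible layout: fewer than 8 sample wells per plate")


def _well_names(n: int, n_cols: int = 24) -> list[str]:
    rows = string.ascii_uppercase
    return [f"{rows[i // n_cols]}{i % n_cols + 1:02d}" for i in range(n)]


def _channel_values(
    rng: np.random.Generator,
    n: int,
    shifts: np.ndarray,
    plate_effect: Mapping[str, float],
    effect_mads: float,
) -> dict[str, np.ndarray]:
    """Log-normal channel values; ``shifts`` is a 0/1 escape indicator."""
    out = {}
    for ch, (mu, sd, sign) in CHANNEL_PARAMS.items():
        log_vals = (
            mu
            + plate_effect[ch]
            + sign * effect_mads * sd * shifts
            + sd * rng.standard_normal(n)
        )
        vals = np.exp(log_vals)
        if ch == "cell_count":
            vals = np.maximum(np.round(vals), 0.0)
        out[ch] = vals
    return out


def _layout_plate(
    rng: np.random.Generator,
    cfg: ScreenSimConfig,
    plate_id: str,
    reagents: pd.DataFrame,
    escape_like: np.ndarray,
) -> pd.DataFrame:
    """One plate: controls in the first two columns, reagents filling the rest.

    ``reagents`` rows carry reagent_id/gene/reagent_class/duplex_index/seed_seq;
    ``escape_like`` marks reagents that express the planted escape phenotype.
    """
    names = _well_names(cfg.wells_per_plate)
    n_ctrl = cfg.n_nontargeting + cfg.n_positive + cfg.n_empty
    classes = (
        ["control_nontargeting"] * cfg.n_nontargeting
        + ["control_positive"] * cfg.n_positive
        + ["empty"] * cfg.n_empty
    )
    rows = []
    shift_flags = []
    for i, cls in enumerate(classes):
        rows.append(
            dict(plate_id=plate_id, well=names[i], reagent_id=f"{cls}_{i}",
                 gene=None, reagent_class=cls, duplex_index=None, seed_seq=None)
        )
        shift_flags.append(1.0 if cls == "control_positive" else 0.0)
    for j, (_, rg) in enumerate(reagents.iterrows()):
        rows.append(
            dict(plate_id=plate_id, well=names[n_ctrl + j], reagent_id=rg["reagent_id"],
                 gene=rg["gene"], reagent_class=rg["reagent_class"],
                 duplex_index=rg["duplex_index"], seed_seq=rg["seed_seq"])
        )
        shift_flags.append(1.0 if escape_like[j] else 0.0)
    plate = pd.DataFrame(rows)
    plate_effect = {
        ch: rng.normal(0.0, cfg.plate_effect_sd) for ch in CHANNEL_PARAMS
    }
    values = _channel_values(
        rng, len(plate), np.asarray(shift_flags), plate_effect, cfg.effect_size_mads
    )
    for ch, vals in values.items():
        plate[ch] = vals
    return plate


def simulate_screen(
    cfg: ScreenSimConfig = ScreenSimConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Primary SMARTpool plates, duplex deconvolution plates, a raw-count
    matrix for the expression filter, and the planted truth.

    Duplex plates cover every library gene (4 duplexes each); duplexes of
    escape genes are active with ``duplex_active_prob``, others with
    ``decoy_active_prob``.  A fraction of non-escape genes gets an all-zero
    count row, exercising the expression filter without masking planted truth.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = [f"GENE{i + 1:04d}" for i in range(cfg.n_genes)]
    escape = sorted(rng.choice(genes, size=cfg.n_escape, replace=False).tolist())
    escape_set = set(escape)
    non_escape = [g for g in genes if g not in escape_set]
    n_unexpr = int(round(cfg.unexpressed_frac * cfg.n_genes))
    n_unexpr = min(n_unexpr, len(non_escape))
    unexpressed = sorted(rng.choice(non_escape, size=n_unexpr, replace=False).tolist())

    # primary screen: one SMARTpool well per gene
    pool_reagents = pd.DataFrame(
        {
            "reagent_id": [f"{g}_pool" for g in genes],
            "gene": genes,
            "reagent_class": "smartpool",
            "duplex_index": None,
            "seed_seq": None,
        }
    )
    pool_escape = np.array([g in escape_set for g in genes])
    primary = _assemble_plates(rng, cfg, "PP", pool_reagents, pool_escape)

    # duplex screen: 4 duplexes per gene, Bernoulli activity
    bases = np.array(list("ACGT"))
    duplex_active: dict[str, list[bool]] = {}
    d_rows = []
    d_active = []
    for g in genes:
        p = cfg.duplex_active_prob if g in escape_set else cfg.decoy_active_prob
        active = rng.random(4) < p
        duplex_active[g] = active.tolist()
        for i in range(4):
            seed_seq = "".join(rng.choice(bases, size=7))
            d_rows.append(
                dict(reagent_id=f"{g}_d{i + 1}", gene=g, reagent_class="duplex",
                     duplex_index=i + 1, seed_seq=seed_seq)
            )
            d_active.append(active[i])
    duplex_reagents = pd.DataFrame(d_rows)
    duplex = _assemble_plates(rng, cfg, "DP", duplex_reagents, np.asarray(d_active))

    # raw-count matrix, 3 biological replicates
    lam = np.exp(rng.normal(4.0, 1.0, size=cfg.n_genes))
    counts = pd.DataFrame(
        rng.poisson(lam[:, None], size=(cfg.n_genes, 3)),
        index=pd.Index(genes, name="gene"),
        columns=["rep1", "rep2", "rep3"],
    )
    counts.loc[unexpressed] = 0
    # expressed genes whose Poisson draw happened to be all zero would blur
    # the planted truth; bump one replicate
    drawn_zero = (counts == 0).all(axis=1) & ~counts.index.isin(unexpressed)
    counts.loc[drawn_zero, "rep1"] = 1

    truth = PlantedTruth(
        escape_genes=escape,
        unexpressed_genes=unexpressed,
        duplex_active=duplex_active,
    )
    return primary, duplex, counts, truth


def _assemble_plates(
    rng: np.random.Generator,
    cfg: ScreenSimConfig,
    prefix: str,
    reagents: pd.DataFrame,
    escape_like: np.ndarray,
) -> pd.DataFrame:
    per_plate = cfg.wells_per_plate - (cfg.n_nontargeting + cfg.n_positive + cfg.n_empty)
    plates = []
    for start in range(0, len(reagents), per_plate):
        block = reagents.iloc[start : start + per_plate]
        plate_id = f"{prefix}{start // per_plate + 1:03d}"
        plates.append(
            _layout_plate(rng, cfg, plate_id, block, escape_like[start : start + per_plate])
        )
    return pd.concat(plates, ignore_index=True)


@dataclass(frozen=True)
class CohortSimConfig:
    """Patient-cohort generator with a planted early-driver gene set.

    Defaults: 120 patients x 400 genes, 5% per-gene mutation probability
    (about six carriers per gene), background mutations clonal half the time
    and the 36 planted drivers clonal 85% of the time.
    """

    n_patients: int = 120
    n_genes: int = 400
    background_clonal_frac: float = 0.5
    driver_genes: int = 36
    driver_clonal_frac: float = 0.85
    mutation_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.driver_genes > self.n_genes:
            raise ValueError("driver_genes cannot exceed n_genes")
        if self.driver_clonal_frac < self.background_clonal_frac:
            raise ValueError(
                "driver_clonal_frac must be >= background_clonal_frac "
                "for a planted enrichment scenario"
            )


def simulate_cohort(
    cfg: CohortSimConfig = CohortSimConfig(),
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Patient x gene clonal/subclonal mutation table with planted drivers."""
    rng = np.random.default_rng(cfg.seed)
    genes = [f"GENE{i + 1:04d}" for i in range(cfg.n_genes)]
    patients = [f"PAT{i + 1:03d}" for i in range(cfg.n_patients)]
    drivers = sorted(rng.choice(genes, size=cfg.driver_genes, replace=False).tolist())
    driver_set = set(drivers)
    mutated = rng.random((cfg.n_patients, cfg.n_genes)) < cfg.mutation_rate
    clonal_frac = np.array(
        [cfg.driver_clonal_frac if g in driver_set else cfg.background_clonal_frac
         for g in genes]
    )
    clonal = rng.random((cfg.n_patients, cfg.n_genes)) < clonal_frac[None, :]
    pi, gi = np.nonzero(mutated)
    table = pd.DataFrame(
        {
            "patient_id": [patients[i] for i in pi],
            "gene": [genes[j] for j in gi],
            "clonality": np.where(clonal[pi, gi], "clonal", "subclonal"),
        }
    )
    return table, PlantedTruth(driver_genes=drivers)


def simulate_expression(
    n_genes: int = 5000,
    n_samples: int = 40,
    signature: GeneSet | None = None,
    n_signature: int = 50,
    shifted_samples: Sequence[str] | None = None,
    shift: float = 1.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Log-normal expression matrix with a planted signature up-shift.

    The signature genes' (natural-)log expression is raised by ``shift`` in
    the shifted samples (default: the first half of the cohort).  Passing
    ``shifted_samples=[]`` returns the baseline matrix unchanged — identical
    to the shift-free generator at the same seed.
    """
    rng = np.random.default_rng(seed)
    genes = [f"GENE{i + 1:05d}" for i in range(n_genes)]
    samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    if signature is None:
        members = rng.choice(genes, size=n_signature, replace=False)
        signature = GeneSet("ESCAPE_SIGNATURE", frozenset(members), "planted signature")
    sig_genes = sorted(g for g in genes if g in signature.genes)
    if shifted_samples is None:
        shifted_samples = samples[: n_samples // 2]
    shifted_samples = list(shifted_samples)
    gene_mu = rng.normal(3.0, 1.0, size=n_genes)
    log_vals = gene_mu[:, None] + rng.normal(0.0, 1.0, size=(n_genes, n_samples))
    expr = pd.DataFrame(
        np.exp(log_vals), index=pd.Index(genes, name="gene"), columns=samples
    )
    if shifted_samples and sig_genes:
        expr.loc[sig_genes, shifted_samples] *= np.exp(shift)
    truth = PlantedTruth(signature_genes=sig_genes, signature_samples=shifted_samples)
    return expr, truth


@dataclass(frozen=True)
class MetaboliteSimConfig:
    """Grouped metabolite-abundance generator with planted differentials.

    Defaults mirror a small GC-MS experiment: three conditions with three
    replicates each, 150 measured features of which a small fraction is
    planted with shifts of ``effect_sd`` log-scale SDs in the senescent
    conditions (both for common features, one each for the
    condition-specific sets).  Keeping the planted fraction small matters:
    pooled-median normalization assumes most features are unchanged, and a
    generator that shifts a large share of features would bias every
    sample's median and manufacture spurious differentials.
    """

    n_features: int = 150
    n_per_group: int = 3
    groups: tuple[str, str, str] = ("proliferating", "AIS", "OIS")
    n_common: int = 12
    n_ais_only: int = 4
    n_ois_only: int = 4
    effect_sd: float = 3.0
    log_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_common + self.n_ais_only + self.n_ois_only > self.n_features:
            raise ValueError("planted feature sets exceed n_features")


def simulate_metabolites(
    cfg: MetaboliteSimConfig = MetaboliteSimConfig(),
) -> tuple[pd.DataFrame, pd.Series, PlantedTruth]:
    """Feature x sample abundance matrix, sample->group labels, planted truth."""
    rng = np.random.default_rng(cfg.seed)
    features = [f"M{i + 1:03d}" for i in range(cfg.n_features)]
    ref, ais, ois = cfg.groups
    samples, labels = [], []
    for grp in cfg.groups:
        for r in range(cfg.n_per_group):
            samples.append(f"{grp}_{r + 1}")
            labels.append(grp)
    groups = pd.Series(labels, index=samples, name="group")
    planted = rng.choice(
        features, size=cfg.n_common + cfg.n_ais_only + cfg.n_ois_only, replace=False
    )
    common = sorted(planted[: cfg.n_common])
    ais_only = sorted(planted[cfg.n_common : cfg.n_common + cfg.n_ais_only])
    ois_only = sorted(planted[cfg.n_common + cfg.n_ais_only :])
    feat_mu = rng.normal(8.0, 1.0, size=cfg.n_features)
    shift = np.zeros((cfg.n_features, len(samples)))
    delta = cfg.effect_sd * cfg.log_sd
    fidx = {f: i for i, f in enumerate(features)}
    for j, s in enumerate(samples):
        grp = groups[s]
        if grp == ais:
            up = common + ais_only
        elif grp == ois:
            up = common + ois_only
        else:
            up = []
        for f in up:
            shift[fidx[f], j] = delta
    log_vals = feat_mu[:, None] + shift + rng.normal(0.0, cfg.log_sd, size=shift.shape)
    matrix = pd.DataFrame(
        np.exp(log_vals), index=pd.Index(features, name="feature"), columns=samples
    )
    truth = PlantedTruth(
        differential_features={
            "common": common, "ais_specific_up": ais_only, "ois_specific_up": ois_only
        }
    )
    return matrix, groups, truth
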