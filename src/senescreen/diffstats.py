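"""Two-group differential statistics for metabolite abundance matrices.

Peak-area matrices are normalized so every sample shares the same median
abundance (pooled-median normalization), then each feature is tested between
two condition groups with a Student (pooled-variance) or Welch t-test on
log2 abundances, with Benjamini-Hochberg control of the false discovery rate.
Set logic classifies significant features as common to two contrasts or
specific to one.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def median_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Equalize per-sample medians of a feature x sample abundance matrix.

    Each sample (column) is divided by its own median feature abundance and
    rescaled by the grand median (median of the per-sample medians), so the
    output keeps the input's units and the operation is idempotent.
    """
    vals = values.to_numpy(dtype=float)
    if np.any(vals <= 0) or not np.all(np.isfinite(vals)):
        raise ValueError("abundances must be positive and finite")
    sample_medians = values.median(axis=0)
    grand = float(np.median(sample_medians))
    return values / sample_medians * grand


def t_test_per_feature(
    values: pd.DataFrame,
    groups: pd.Series,
    contrast: tuple[str, str],
    variance_policy: str = "pooled",
    log_transform: bool = True,
) -> pd.DataFrame:
    """Two-sided t-test per feature between ``contrast[0]`` and ``contrast[1]``.

    ``groups`` maps sample id -> condition label.  By default abundances are
    log2-transformed before testing (standard for peak areas); the reported
    ``mean_log_fc`` is the difference of group means of log2 values (i.e.
    log2 fold change of geometric means).  With ``log_transform=False`` the
    test runs on the raw scale and ``mean_log_fc`` is log2 of the ratio of
    arithmetic means.  Features with zero variance in both groups and equal
    means get t = 0, p = 1 by convention.
    """
    a_label, b_label = contrast
    a_samples = [s for s in values.columns if groups.get(s) == a_label]
    b_samples = [s for s in values.columns if groups.get(s) == b_label]
    if len(a_samples) < 2 or len(b_samples) < 2:
        raise ValueError(
            f"each group needs >= 2 samples (got {len(a_samples)} {a_label!r}, "
            f"{len(b_samples)} {b_label!r})"
        )
    if variance_policy not in ("pooled", "welch"):
        raise ValueError(f"unknown variance_policy {variance_policy!r}")
    a = values[a_samples].to_numpy(dtype=float)
    b = values[b_samples].to_numpy(dtype=float)
    if log_transform:
        if np.any(a <= 0) or np.any(b <= 0):
            raise ValueError("log transform requires positive abundances")
        la, lb = np.log2(a), np.log2(b)
        mean_log_fc = la.mean(axis=1) - lb.mean(axis=1)
        ta, tb = la, lb
    else:
        mean_log_fc = np.log2(a.mean(axis=1) / b.mean(axis=1))
        ta, tb = a, b
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # zero-variance features
        t, p = stats.ttest_ind(ta, tb, axis=1, equal_var=(variance_policy == "pooled"))
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        logger.info("%d features with zero variance in both groups: t=0, p=1", degenerate.sum())
        t = np.where(degenerate, 0.0, t)
        p = np.where(degenerate, 1.0, p)
    return pd.DataFrame(
        {"mean_log_fc": mean_log_fc, "t_stat": t, "p": p}, index=values.index
    )


def bh_adjust(p: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    arr = np.asarray(list(p) if not isinstance(p, np.ndarray) else p, dtype=float)
    if arr.size == 0:
        return arr
    if np.any(arr < 0) or np.any(arr > 1) or not np.all(np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def differential(
    values: pd.DataFrame,
    groups: pd.Series,
    contrast: tuple[str, str],
    alpha: float = 0.05,
    variance_policy: str = "pooled",
    log_transform: bool = True,
) -> pd.DataFrame:
    """t-test + BH adjustment + significance call for one contrast."""
    res = t_test_per_feature(values, groups, contrast, variance_policy, log_transform)
    res["q"] = bh_adjust(res["p"].to_numpy())
    res["significant"] = res["q"] < alpha
    return res


class SignificantSets(NamedTuple):
    common: frozenset
    ais_specific_up: frozenset
    ois_specific_up: frozenset


def significant_sets(
    r_ais: pd.DataFrame,
    r_ois: pd.DataFrame,
    alpha: float = 0.05,
    common_mode: str = "intersection",
) -> SignificantSets:
    """Partition significant features into common and condition-specific sets.

    ``common`` = significant (q < alpha) in both contrasts (``"union"`` mode
    accepts either).  ``ais_specific_up`` = significant in the AIS contrast
    only, with positive mean log fold change; symmetric for OIS.
    """
    if not r_ais.index.equals(r_ois.index):
        raise ValueError("the two contrasts cover different feature lists")
    sig_a = r_ais["q"] < alpha
    sig_o = r_ois["q"] < alpha
    if common_mode == "intersection":
        common = sig_a & sig_o
    elif common_mode == "union":
        common = sig_a | sig_o
    else:
        raise ValueError(f"unknown common_mode {common_mode!r}")
    ais_only = sig_a & ~sig_o & (r_ais["mean_log_fc"] > 0)
    ois_only = sig_o & ~sig_a & (r_ois["mean_log_fc"] > 0)
    return SignificantSets(
        common=frozenset(r_ais.index[common]),
        ais_specific_up=frozenset(r_ais.index[ais_only]),
        ois_specific_up=frozenset(r_ois.index[ois_only]),
    )
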