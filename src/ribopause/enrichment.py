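"""Label-free co-IP enrichment: QC filter, log2 + validity filter,
left-shifted normal imputation, and per-protein two-group Student's t-test.

The pipeline order is fixed — qc_filter, log2_and_validity_filter,
impute_missing, enrichment_test — and enforced by the input contracts of
each step (imputation requires a log2-scale table, the test requires a
complete one). Proteins quantified in only one group survive the validity
filter and get the other group imputed, which is exactly how
presence/absence interactors become significant.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

FLAG_COLUMNS = ("contaminant", "reverse", "only_identified_by_site")
DEFAULT_WIDTH = 0.3
DEFAULT_DOWNSHIFT = 1.8
DEFAULT_MIN_VALID = 2


def _sample_columns(groups: Mapping[str, Sequence[str]]) -> list[str]:
    cols: list[str] = []
    for g in groups.values():
        cols.extend(g)
    return cols


def _check_groups(table: pd.DataFrame, groups: Mapping[str, Sequence[str]]) -> None:
    if len(groups) != 2:
        raise ValueError(f"exactly 2 groups required, got {len(groups)}")
    for name, cols in groups.items():
        if len(cols) < 2:
            raise ValueError(f"group {name!r} has {len(cols)} replicates; need >= 2")
        missing = [c for c in cols if c not in table.columns]
        if missing:
            raise ValueError(f"group {name!r} references missing sample columns: {missing}")


def qc_filter(table: pd.DataFrame, flag_columns: Sequence[str] = FLAG_COLUMNS) -> pd.DataFrame:
    """Drop rows flagged contaminant, reverse, or only-identified-by-site."""
    missing = [c for c in flag_columns if c not in table.columns]
    if missing:
        raise ValueError(f"quant table is missing flag columns: {missing}")
    flagged = table[list(flag_columns)].astype(bool).any(axis=1)
    if flagged.any():
        logger.info("qc_filter removed %d flagged rows", int(flagged.sum()))
    return table.loc[~flagged].reset_index(drop=True)


def log2_and_validity_filter(
    table: pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
    min_valid: int = DEFAULT_MIN_VALID,
) -> pd.DataFrame:
    """log2-transform intensities; keep rows with >= min_valid values in some group."""
    _check_groups(table, groups)
    if any(min_valid > len(cols) for cols in groups.values()):
        raise ValueError(f"min_valid {min_valid} exceeds a group's replicate count")
    cols = _sample_columns(groups)
    values = table[cols]
    if (values <= 0).any().any():
        bad = values.columns[(values <= 0).any()].tolist()
        raise ValueError(f"non-positive intensities in columns {bad}; corrupt upstream table")
    out = table.copy()
    out[cols] = np.log2(values)
    keep = pd.Series(False, index=out.index)
    for gcols in groups.values():
        keep |= out[list(gcols)].notna().sum(axis=1) >= min_valid
    logger.info("validity filter kept %d / %d rows", int(keep.sum()), len(out))
    return out.loc[keep].reset_index(drop=True)


def impute_missing(
    table: pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
    width: float = DEFAULT_WIDTH,
    downshift: float = DEFAULT_DOWNSHIFT,
    seed: int = 0,
    per_sample: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill missing log2 values from a down-shifted, narrowed normal.

    Per sample column (the default), missing entries are drawn from
    ``Normal(mean - downshift * SD, (width * SD)^2)`` using that column's
    observed mean and SD. ``per_sample=False`` pools all observed values in
    the table instead. Returns the completed table and a boolean mask of
    imputed cells.
    """
    _check_groups(table, groups)
    cols = _sample_columns(groups)
    rng = np.random.default_rng(seed)
    out = table.copy()
    mask = pd.DataFrame(False, index=table.index, columns=cols)

    if not per_sample:
        pooled = table[cols].to_numpy().ravel()
        pooled = pooled[~np.isnan(pooled)]
        if len(pooled) < 2:
            raise ValueError("fewer than 2 observed values in the whole table")
        g_mean, g_sd = float(np.mean(pooled)), float(np.std(pooled, ddof=1))

    for col in cols:
        observed = table[col].dropna()
        if per_sample:
            if len(observed) < 2:
                raise ValueError(f"column {col!r} has < 2 observed values; SD undefined")
            mean, sd = float(observed.mean()), float(observed.std(ddof=1))
        else:
            mean, sd = g_mean, g_sd
        missing = table[col].isna()
        n = int(missing.sum())
        if n:
            draws = rng.normal(mean - downshift * sd, width * sd, size=n)
            out.loc[missing, col] = draws
            mask.loc[missing, col] = True
    return out, mask


def enrichment_test(
    table: pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
    equal_var: bool = True,
    adjust: str = "none",
    imputation_mask: pd.DataFrame | None = None,
    protein_column: str = "protein_id",
) -> pd.DataFrame:
    """Two-sided per-protein t-test on a complete log2 table.

    Student's (equal-variance) test by default; ``equal_var=False`` gives
    Welch. ``adjust="bh"`` adds Benjamini-Hochberg q-values. Output carries
    volcano coordinates (``log2_difference``, ``neg_log10_p``), where
    log2_difference = first-group mean minus second-group mean.
    """
    _check_groups(table, groups)
    if adjust not in ("none", "bh"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    (name1, cols1), (name2, cols2) = groups.items()
    a = table[list(cols1)].to_numpy(dtype=float)
    b = table[list(cols2)].to_numpy(dtype=float)
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("table still contains missing values; impute first")

    mean1, mean2 = a.mean(axis=1), b.mean(axis=1)
    diff = mean1 - mean2
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)

    # zero within-group variance in both groups: t is 0/0
    degenerate = np.isnan(t)
    t = np.where(degenerate & (diff == 0), 0.0, t)
    p = np.where(degenerate & (diff == 0), 1.0, p)
    # zero variance with unequal means: infinitely significant, keep p in (0, 1]
    p = np.where(np.isnan(p) | (p == 0.0), np.finfo(float).tiny, p)

    result = pd.DataFrame(
        {
            protein_column: table[protein_column].to_numpy(),
            f"mean_log2_{name1}": mean1,
            f"mean_log2_{name2}": mean2,
            "log2_difference": diff,
            "t_statistic": t,
            "p_value": p,
            "neg_log10_p": -np.log10(p),
            "degenerate": degenerate,
        }
    )
    if imputation_mask is not None:
        for name, cols in groups.items():
            result[f"n_imputed_{name}"] = imputation_mask[list(cols)].sum(axis=1).to_numpy()
    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        result["q_value"] = multipletests(result["p_value"], method="fdr_bh")[1]
    return result


def run_enrichment(
    table: pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
    min_valid: int = DEFAULT_MIN_VALID,
    width: float = DEFAULT_WIDTH,
    downshift: float = DEFAULT_DOWNSHIFT,
    seed: int = 0,
    equal_var: bool = True,
    adjust: str = "none",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full workflow in the fixed order; returns (results, imputation mask)."""
    filtered = qc_filter(table)
    transformed = log2_and_validity_filter(filtered, groups, min_valid=min_valid)
    complete, mask = impute_missing(transformed, groups, width=width, downshift=downshift, seed=seed)
    results = enrichment_test(
        complete, groups, equal_var=equal_var, adjust=adjust, imputation_mask=mask
    )
    return results, mask
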