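"""Benjamini-Hochberg FDR adjustment and differential-expression selection.

The selection rule retains features with linear fold change >= ``fc_linear_min``
(evaluated on the log2 scale) and BH-adjusted p-value <= ``q_max``; both
comparisons are inclusive.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

FEATURE_CLASSES = ("gene", "miRNA", "lncRNA")

#: Default thresholds: linear fold change >= 1.5, BH q <= 0.01. An
#: alternative fold-change cut of 2.0 (|log2FC| >= 1) is used by some
#: reports; both are plain parameters here.
DEFAULT_FC_LINEAR_MIN = 1.5
DEFAULT_Q_MAX = 0.01

DE_TABLE_COLUMNS = ("feature_id", "feature_class", "log2fc", "pvalue", "qvalue")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Implements the step-up definition directly: with the m valid p-values
    sorted ascending, ``q_(i) = min_{j >= i} p_(j) * m / j`` capped at 1,
    mapped back to the original positions.

    NaN entries are excluded from m (they would silently deflate every
    adjusted value otherwise), returned as NaN, and reported via a warning.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValidationError("bh_adjust expects a 1-d sequence of p-values")
    nan_mask = np.isnan(p)
    valid = p[~nan_mask]
    if np.any((valid < 0) | (valid > 1)):
        bad = valid[(valid < 0) | (valid > 1)][0]
        raise ValidationError(f"p-value {bad!r} outside [0, 1]")
    if nan_mask.any():
        warnings.warn(
            f"bh_adjust: {int(nan_mask.sum())} NaN p-value(s) excluded from m",
            stacklevel=2,
        )
    out = np.full_like(p, np.nan)
    m = valid.size
    if m == 0:
        return out
    order = np.argsort(valid, kind="mergesort")
    ranked = valid[order] * m / np.arange(1, m + 1)
    q = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    adjusted = np.empty(m)
    adjusted[order] = q
    out[~nan_mask] = adjusted
    return out


def validate_de_table(table: pd.DataFrame, require_qvalue: bool = True) -> None:
    """Check DE-table schema and per-class feature-id uniqueness."""
    required = list(DE_TABLE_COLUMNS if require_qvalue else DE_TABLE_COLUMNS[:-1])
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValidationError(f"DE table missing column(s): {', '.join(missing)}")
    bad_class = set(table["feature_class"]) - set(FEATURE_CLASSES)
    if bad_class:
        raise ValidationError(f"unknown feature_class value(s): {sorted(bad_class)}")
    dup = table.duplicated(subset=["feature_class", "feature_id"])
    if dup.any():
        first = table.loc[dup, "feature_id"].iloc[0]
        raise ValidationError(f"duplicate feature_id within a class: {first!r}")
    for col in ("pvalue", "qvalue") if require_qvalue else ("pvalue",):
        vals = table[col].to_numpy(dtype=float)
        finite = vals[~np.isnan(vals)]
        if np.any((finite < 0) | (finite > 1)):
            raise ValidationError(f"{col} outside [0, 1]")


def select_de(
    table: pd.DataFrame,
    fc_linear_min: float = DEFAULT_FC_LINEAR_MIN,
    q_max: float = DEFAULT_Q_MAX,
) -> pd.DataFrame:
    """Subset of ``table`` passing both thresholds, in input order.

    Retains rows with ``2**|log2fc| >= fc_linear_min`` and
    ``qvalue <= q_max`` (both inclusive). The fold-change comparison is
    done on the log2 scale, which is exact for thresholds stored as
    ``log2(fc_linear_min)``.
    """
    if fc_linear_min <= 0:
        raise ValidationError("fc_linear_min must be positive")
    if not 0 <= q_max <= 1:
        raise ValidationError("q_max must lie in [0, 1]")
    validate_de_table(table)
    lfc = table["log2fc"].to_numpy(dtype=float)
    q = table["qvalue"].to_numpy(dtype=float)
    keep = (np.abs(lfc) >= np.log2(fc_linear_min)) & (q <= q_max)
    return table.loc[keep].copy()


def two_group_test(
    log_values: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    feature_class: str = "gene",
) -> pd.DataFrame:
    """Convenience per-feature Welch t-test on log-scale values.

    Intended only for end-to-end runs on synthetic data; this is not a
    moderated (limma/DESeq2-style) test and makes no shrinkage of any kind.
    Returns a DE table with log2fc = mean(A) - mean(B).
    """
    if feature_class not in FEATURE_CLASSES:
        raise ValidationError(f"unknown feature_class {feature_class!r}")
    a = log_values[group_a].to_numpy(dtype=float)
    b = log_values[group_b].to_numpy(dtype=float)
    lfc = a.mean(axis=1) - b.mean(axis=1)
    _, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    return pd.DataFrame(
        {
            "feature_id": log_values.index.astype(str),
            "feature_class": feature_class,
            "log2fc": lfc,
            "pvalue": p,
            "qvalue": bh_adjust(p),
        }
    ).reset_index(drop=True)
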