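"""Two-group nonparametric statistics and qPCR relative-expression summaries.

Everything downstream that compares low-grade (LGG) against high-grade (HGG)
glioma samples funnels through this module: the Mann-Whitney U test, the
Benjamini-Hochberg false-discovery-rate step-up, 2^-dCt relative expression
against a housekeeping gene, fold changes of group means, and per-gram
T-cell density normalization.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CtRecord",
    "GroupComparison",
    "relative_expression",
    "mann_whitney_u",
    "bh_fdr",
    "fold_change",
    "cells_per_gram",
    "compare_expression",
]

#: Largest min(n) for which the exact U-distribution is enumerated.
EXACT_MAX_N = 8


@dataclass(frozen=True)
class CtRecord:
    """One qPCR measurement: a threshold-cycle value for a gene in a sample."""

    sample_id: str
    group: str
    gene: str
    ct: float | None

    def __post_init__(self) -> None:
        if self.ct is not None and not (self.ct > 0):
            raise ValueError(f"Ct must be positive when present, got {self.ct}")


@dataclass(frozen=True)
class GroupComparison:
    """Per-feature two-group result: U statistic, raw p, BH q, fold change."""

    feature: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    fold_change: float | None
    u_statistic: float | None
    p_value: float | None
    q_value: float | None = None


def relative_expression(
    ct_table: pd.DataFrame, housekeeping_gene: str = "GAPDH"
) -> pd.DataFrame:
    """Compute 2^-dCt relative expression per sample x gene.

    dCt = Ct_gene - Ct_housekeeping within each sample; the housekeeping gene
    itself is dropped from the output. A missing target Ct propagates to a
    missing value (never imputed to zero).

    Parameters
    ----------
    ct_table
        Long-format table with columns ``sample_id, group, gene, ct``.
    housekeeping_gene
        Reference gene; every sample must carry one Ct row for it.

    Returns
    -------
    DataFrame with columns ``sample_id, group, gene, value`` where
    ``value = 2 ** -(ct_gene - ct_housekeeping)``.
    """
    required = {"sample_id", "group", "gene", "ct"}
    missing_cols = required - set(ct_table.columns)
    if missing_cols:
        raise ValueError(f"Ct table missing columns: {sorted(missing_cols)}")

    hk = ct_table[ct_table["gene"] == housekeeping_gene]
    hk_by_sample = hk.dropna(subset=["ct"]).set_index("sample_id")["ct"]
    samples = ct_table["sample_id"].unique()
    lacking = [s for s in samples if s not in hk_by_sample.index]
    if lacking:
        raise ValueError(
            f"housekeeping gene {housekeeping_gene!r} has no Ct for "
            f"sample(s): {', '.join(map(str, lacking))}"
        )

    targets = ct_table[ct_table["gene"] != housekeeping_gene].copy()
    delta = targets["ct"].to_numpy(dtype=float) - hk_by_sample.reindex(
        targets["sample_id"]
    ).to_numpy(dtype=float)
    targets["value"] = np.power(2.0, -delta)
    return targets[["sample_id", "group", "gene", "value"]].reset_index(drop=True)


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Uses the exact null distribution (enumeration over rank configurations)
    when ``min(n_x, n_y) <= 8`` and there are no ties across the pooled
    sample; otherwise the normal approximation with tie correction and
    continuity correction. When every pooled value is identical the test is
    degenerate and p = 1 is returned with U = n_x * n_y / 2.

    Returns
    -------
    (U, p) where U is the statistic for ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")

    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return x.size * y.size / 2.0, 1.0

    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and min(x.size, y.size) <= EXACT_MAX_N:
        method = "exact"
    else:
        method = "asymptotic"
    res = _sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_fdr(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotone enforcement.

    ``q_i = min_{j: p_j >= p_i} (m * p_j / rank_j)`` capped at 1. Order of
    the input is preserved in the output.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def fold_change(mean_a: float, mean_b: float, decimals: int = 1) -> float:
    """Ratio ``mean_a / mean_b`` rounded half-away-from-zero.

    Matches conventional printed-table rounding, which rounds 0.25 to 0.3
    at one decimal (banker's rounding would give 0.2).
    """
    if mean_b == 0:
        raise ZeroDivisionError("fold change undefined: denominator mean is 0")
    ratio = mean_a / mean_b
    factor = 10**decimals
    return math.copysign(math.floor(abs(ratio) * factor + 0.5), ratio) / factor


def cells_per_gram(cell_count: float, tissue_mass_g: float) -> float:
    """T cells per gram of tumor tissue (count normalized by sample mass)."""
    if tissue_mass_g <= 0:
        raise ValueError(f"tissue mass must be positive, got {tissue_mass_g}")
    return cell_count / tissue_mass_g


def compare_expression(
    values: pd.DataFrame,
    group_a: str,
    group_b: str,
    value_column: str = "value",
    fdr: bool = True,
    fold_change_decimals: int = 1,
) -> pd.DataFrame:
    """Per-gene two-group comparison of expression values.

    For every gene present in both groups: Mann-Whitney U two-sided p, BH
    q across the gene panel (one FDR family per call), and the fold change
    of group means (group_a mean / group_b mean). Genes absent from one
    group are skipped with a warning. Genes with fewer than two samples in
    a group are still tested but flagged in the ``flag`` column.

    Parameters
    ----------
    values
        Long table with columns ``group, gene`` and `value_column`.
    group_a, group_b
        Labels of the two groups to compare (numerator group first).
    """
    out_rows = []
    for gene in sorted(values["gene"].unique()):
        sub = values[values["gene"] == gene].dropna(subset=[value_column])
        a = sub.loc[sub["group"] == group_a, value_column].to_numpy(float)
        b = sub.loc[sub["group"] == group_b, value_column].to_numpy(float)
        if a.size == 0 or b.size == 0:
            warnings.warn(
                f"gene {gene!r} absent from one group; comparison skipped",
                stacklevel=2,
            )
            continue
        flag = "" if (a.size >= 2 and b.size >= 2) else "small_group"
        u, p = mann_whitney_u(a, b)
        mean_a, mean_b = float(a.mean()), float(b.mean())
        try:
            fc = fold_change(mean_a, mean_b, decimals=fold_change_decimals)
        except ZeroDivisionError:
            fc = np.nan
            flag = (flag + ";" if flag else "") + "zero_denominator"
        out_rows.append(
            {
                "gene": gene,
                "n_a": a.size,
                "n_b": b.size,
                "mean_a": mean_a,
                "mean_b": mean_b,
                "fold_change": fc,
                "U": u,
                "p": p,
                "flag": flag,
            }
        )
    out = pd.DataFrame(
        out_rows,
        columns=[
            "gene", "n_a", "n_b", "mean_a", "mean_b",
            "fold_change", "U", "p", "flag",
        ],
    )
    if fdr and len(out):
        out.insert(len(out.columns) - 1, "q", bh_fdr(out["p"].to_numpy()))
    elif len(out):
        out.insert(len(out.columns) - 1, "q", np.nan)
    return out
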