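"""Biotin pull-down enrichment-ratio analysis.

The central statistic is the enrichment ratio

    ER = (bait pull-down / control pull-down) / (bait input / control input)

computed per gene on FPKM-like abundances; genes with ER above a cutoff
(default 1.2, strict) are pull-down candidates. Candidates whose
expression also drops upon miRNA overexpression (log2FC < 0, optionally
gated on a differential-expression flag) are called potential targets.
Shifts of target-set fold-change distributions against background are
tested with the two-sample Kolmogorov-Smirnov test on their CDFs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

LIBRARY_ROLES = ("bait_pd", "ctrl_pd", "bait_input", "ctrl_input")


class InputError(ValueError):
    pass


def filter_expressed(table: pd.DataFrame, min_level: float = 0.1) -> pd.DataFrame:
    """Drop genes not expressed above ``min_level`` in any library.

    Retains exactly the genes with abundance > ``min_level`` (strict) in at
    least one column; idempotent, and the output index is a subset of the
    input index.
    """
    if table.empty:
        raise InputError("expression table is empty")
    if min_level < 0:
        raise InputError("min_level must be >= 0")
    keep = (table > min_level).any(axis=1)
    return table.loc[keep]


def enrichment_ratio(
    table: pd.DataFrame,
    pseudocount: float = 0.01,
    er_cutoff: float = 1.2,
) -> pd.DataFrame:
    """Per-gene enrichment ratio and candidate call.

    ``table`` must carry the four library columns ``bait_pd, ctrl_pd,
    bait_input, ctrl_input`` over one shared gene index. With pseudocount
    eps,

        ER = ((bait_pd+eps)/(ctrl_pd+eps)) / ((bait_input+eps)/(ctrl_input+eps))

    and ``candidate`` is ER > ``er_cutoff`` (strict: ER exactly at the
    cutoff is not a candidate). ``pseudocount=0`` is allowed when all
    denominators are positive.
    """
    missing = [c for c in LIBRARY_ROLES if c not in table.columns]
    if missing:
        raise InputError(f"missing library columns: {missing}")
    if (table[list(LIBRARY_ROLES)] < 0).any().any():
        raise InputError("abundances must be >= 0")
    eps = pseudocount
    if eps == 0 and ((table["ctrl_pd"] == 0) | (table["ctrl_input"] == 0)).any():
        raise InputError("zero denominators require a positive pseudocount")
    er = ((table["bait_pd"] + eps) / (table["ctrl_pd"] + eps)) / (
        (table["bait_input"] + eps) / (table["ctrl_input"] + eps)
    )
    return pd.DataFrame({"er": er, "candidate": er > er_cutoff}, index=table.index)


def log2fc_table(
    oe: pd.Series, oe_ctrl: pd.Series, pseudocount: float = 1.0
) -> pd.Series:
    """Per-gene log2 fold change of overexpression vs control abundances,
    log2((oe + pseudo) / (ctrl + pseudo))."""
    if not oe.index.equals(oe_ctrl.index):
        raise InputError("oe and control tables must cover the same genes")
    if (oe < 0).any() or (oe_ctrl < 0).any():
        raise InputError("abundances must be >= 0")
    return np.log2((oe + pseudocount) / (oe_ctrl + pseudocount)).rename("log2fc")


def flag_de(
    log2fc: pd.Series,
    fdr: Optional[pd.Series] = None,
    oe: Optional[pd.Series] = None,
    oe_ctrl: Optional[pd.Series] = None,
    lfc_cutoff: float = 1.0,
    fdr_cutoff: float = 0.001,
) -> pd.DataFrame:
    """Differential-expression flags: |log2FC| > ``lfc_cutoff`` (strict)
    AND FDR < ``fdr_cutoff``.

    When no FDR column is supplied, a simple stand-in is computed from the
    abundances: a per-gene two-sided binomial count test (rounded
    abundances, expected split from the two library totals) with
    Benjamini-Hochberg adjustment. This stand-in is not the differential
    test a full read-level pipeline would run; supply externally computed
    FDR values to reproduce one.
    """
    if fdr is None:
        if oe is None or oe_ctrl is None:
            raise InputError("either fdr or the two abundance columns are required")
        x = np.rint(oe.to_numpy(float)).astype(np.int64)
        y = np.rint(oe_ctrl.to_numpy(float)).astype(np.int64)
        p0 = x.sum() / max(x.sum() + y.sum(), 1)
        pvals = np.array(
            [
                stats.binomtest(int(xi), int(xi + yi), p0).pvalue if xi + yi > 0 else 1.0
                for xi, yi in zip(x, y)
            ]
        )
        fdr = pd.Series(multipletests(pvals, method="fdr_bh")[1], index=log2fc.index)
    flag = (log2fc.abs() > lfc_cutoff) & (fdr < fdr_cutoff)
    return pd.DataFrame({"log2fc": log2fc, "fdr": fdr, "de_flag": flag})


def define_potential_targets(
    records: pd.DataFrame, require_de: bool = False
) -> pd.DataFrame:
    """Potential targets: enriched in the pull-down and decreased upon
    overexpression.

    ``records`` must carry ``candidate`` and ``log2fc`` columns (and
    ``de_flag`` when ``require_de``). The returned table adds a boolean
    ``potential_target`` column: candidate AND log2fc < 0, optionally also
    gated on a negative-sign DE flag.
    """
    needed = {"candidate", "log2fc"} | ({"de_flag"} if require_de else set())
    missing = needed - set(records.columns)
    if missing:
        raise InputError(f"missing columns: {sorted(missing)}")
    hit = records["candidate"] & (records["log2fc"] < 0)
    if require_de:
        hit &= records["de_flag"]
    out = records.copy()
    out["potential_target"] = hit
    return out


@dataclass(frozen=True)
class CdfComparison:
    """Two-sample KS comparison of a target set against background."""

    statistic: float  # sup |F_t - F_b|, in [0, 1]
    p_value: float
    direction: str  # 'down', 'up' or 'none': sign of median(target)-median(background)
    n_target: int
    n_background: int


def cdf_shift_test(
    target_values: Sequence[float],
    background_values: Sequence[float],
    alternative: str = "two-sided",
) -> CdfComparison:
    """Kolmogorov-Smirnov test for a CDF shift of target values relative to
    background (e.g. log2FC of pulled-down genes vs all genes)."""
    t = np.asarray(target_values, float)
    b = np.asarray(background_values, float)
    if len(t) < 5 or len(b) < 5:
        raise InputError("both samples need >= 5 values")
    res = stats.ks_2samp(t, b, alternative=alternative)
    diff = np.median(t) - np.median(b)
    direction = "none" if diff == 0 else ("up" if diff > 0 else "down")
    return CdfComparison(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        direction=direction,
        n_target=len(t),
        n_background=len(b),
    )


def cutoff_sweep(
    records: pd.DataFrame, cutoffs: Sequence[float]
) -> pd.DataFrame:
    """Target sets at increasing ER cutoffs.

    ``records`` needs ``er`` and ``log2fc`` columns; ``cutoffs`` must be
    ascending. Higher cutoffs give nested (smaller or equal) sets; the
    summary reports set size, median log2FC and a KS comparison against
    all genes for each cutoff.
    """
    if list(cutoffs) != sorted(cutoffs):
        raise InputError("cutoffs must be ascending")
    rows = []
    background = records["log2fc"].to_numpy(float)
    for c in cutoffs:
        sel = records[records["er"] > c]
        row: Dict[str, object] = {
            "cutoff": c,
            "n_genes": len(sel),
            "median_log2fc": float(sel["log2fc"].median()) if len(sel) else np.nan,
        }
        if len(sel) >= 5:
            cmp = cdf_shift_test(sel["log2fc"].to_numpy(float), background)
            row["ks_statistic"], row["ks_p"] = cmp.statistic, cmp.p_value
        else:
            row["ks_statistic"], row["ks_p"] = np.nan, np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def plot_cdf(
    value_sets: Dict[str, Sequence[float]], path: str, xlabel: str = "log2 fold change"
) -> None:
    """Write a cumulative-distribution plot of several value sets (one line
    per set) to ``path``. Requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for name, values in value_sets.items():
        v = np.sort(np.asarray(values, float))
        ax.step(v, np.arange(1, len(v) + 1) / len(v), where="post", label=name)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("cumulative fraction")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
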