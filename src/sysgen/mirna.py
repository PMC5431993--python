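"""miRNA-mRNA integration.

Candidate regulatory interactions are database-predicted miRNA-target
pairs whose expression shows a significant negative Pearson correlation
across the shared samples. Correlation p-values use the t transform at
n - 2 degrees of freedom; the default test is one-sided against r < 0,
which matches the biology (miRNAs repress their targets). BH false
discovery rate adjustment is computed across the database-supported
pairs only, and a pair is selected when r < 0 and FDR < the cutoff.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .meta import bh_fdr

__all__ = ["correlate_pairs", "filter_and_select", "integrate"]


def correlate_pairs(
    mrna_expr: pd.DataFrame,
    mirna_expr: pd.DataFrame,
    pairs: pd.DataFrame | None = None,
    sidedness: str = "one_sided_negative",
) -> pd.DataFrame:
    """Pearson correlation of miRNA-mRNA pairs with p-values.

    With ``pairs`` (columns ``mirna_id``, ``gene_id``) only those
    combinations are scored; otherwise all mirna x gene combinations.
    ``sidedness`` is ``one_sided_negative`` (lower tail, tests r < 0)
    or ``two_sided``. Sample columns must match exactly.
    """
    if list(mrna_expr.columns) != list(mirna_expr.columns):
        raise ValueError("mRNA and miRNA matrices have mismatched samples")
    if sidedness not in ("one_sided_negative", "two_sided"):
        raise ValueError("sidedness must be one_sided_negative or two_sided")
    n = mrna_expr.shape[1]

    def _z(m: pd.DataFrame) -> np.ndarray:
        a = m.to_numpy(dtype=float)
        return (a - a.mean(axis=1, keepdims=True)) / a.std(
            axis=1, keepdims=True
        )

    gz = pd.DataFrame(_z(mrna_expr), index=mrna_expr.index)
    mz = pd.DataFrame(_z(mirna_expr), index=mirna_expr.index)
    if pairs is None:
        pairs = pd.DataFrame(
            [(m, g) for m in mirna_expr.index for g in mrna_expr.index],
            columns=["mirna_id", "gene_id"],
        )
    r = np.einsum(
        "ij,ij->i",
        mz.loc[pairs["mirna_id"]].to_numpy(),
        gz.loc[pairs["gene_id"]].to_numpy(),
    ) / n
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    if sidedness == "one_sided_negative":
        p = stats.t.cdf(t, df=n - 2)
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    out = pairs.copy()
    out["r"] = r
    out["p_cor"] = p
    return out


def filter_and_select(
    pairs: pd.DataFrame,
    target_table: pd.DataFrame,
    fdr_cut: float = 0.05,
) -> pd.DataFrame:
    """Database filter + FDR selection of negative interactions.

    Correlated pairs are restricted to those present in the target
    database; BH adjustment runs across exactly that restricted set; a
    pair is selected iff r < 0 and FDR < ``fdr_cut``. The database
    prediction p-value (``p_database``) is carried through unaltered
    when present.
    """
    key = ["mirna_id", "gene_id"]
    merged = pairs.merge(target_table.drop_duplicates(key), on=key, how="inner")
    if merged.empty:
        warnings.warn("no correlated pair is supported by the target table")
        merged["fdr"] = pd.Series(dtype=float)
        merged["selected"] = pd.Series(dtype=bool)
        return merged
    merged = merged.reset_index(drop=True)
    merged["fdr"] = bh_fdr(merged["p_cor"].to_numpy())
    merged["selected"] = (merged["r"] < 0) & (merged["fdr"] < fdr_cut)
    return merged


def integrate(
    mrna_expr: pd.DataFrame,
    mirna_expr: pd.DataFrame,
    target_table: pd.DataFrame,
    fdr_cut: float = 0.05,
    sidedness: str = "one_sided_negative",
) -> pd.DataFrame:
    """Correlate the database-predicted pairs and select interactions."""
    pairs = correlate_pairs(
        mrna_expr,
        mirna_expr,
        pairs=target_table[["mirna_id", "gene_id"]],
        sidedness=sidedness,
    )
    return filter_and_select(pairs, target_table, fdr_cut=fdr_cut)
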