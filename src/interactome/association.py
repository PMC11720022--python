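"""Spearman rank correlation among selected genes' expression.

Pairwise Spearman rho with average-rank tie handling; p-values from the
t-approximation on n-2 degrees of freedom (exact permutation is
impractical at cohort scale).  Pairs with rho above a "strong" threshold
(default 0.8) are flagged in the long-format output; the flag is
report-level only, never a filter.  A constant gene vector has no rank
ordering, so its off-diagonal correlations are reported as missing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from interactome.io import ValidationError, atomic_write

__all__ = ["correlation_long", "spearman_matrix", "write_correlations"]

STRONG_RHO = 0.8


def spearman_matrix(
    expr: pd.DataFrame, genes: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rho and p among ``genes`` across samples.

    Returns (rho, p) DataFrames, symmetric with unit diagonal on rho.
    Off-diagonal entries involving constant genes are NaN (undefined).
    """
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise ValidationError(f"genes absent from expression matrix: {missing[:5]}")
    if len(genes) < 2:
        raise ValidationError("need at least two genes to correlate")
    data = expr.loc[genes].to_numpy(float).T  # samples x genes
    if data.shape[0] < 3:
        raise ValidationError("Spearman correlation needs >= 3 samples")
    import warnings

    with warnings.catch_warnings():
        # constant genes are reported as missing downstream, by design
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho, p = stats.spearmanr(data, axis=0)
    if np.ndim(rho) == 0:  # scipy collapses the two-variable case to a scalar
        r, pv = float(rho), float(p)
        rho = np.array([[1.0, r], [r, 1.0]])
        p = np.array([[0.0, pv], [pv, 0.0]])
    idx = pd.Index(genes, name="gene")
    rho_df = pd.DataFrame(rho, index=idx, columns=idx)
    p_df = pd.DataFrame(p, index=idx, columns=idx)
    np.fill_diagonal(rho_df.values, 1.0)
    np.fill_diagonal(p_df.values, 0.0)
    return rho_df, p_df


def correlation_long(
    rho: pd.DataFrame, p: pd.DataFrame, strong_threshold: float = STRONG_RHO
) -> pd.DataFrame:
    """Unique upper-triangle pairs as a long table with a 'strong' flag."""
    rows = []
    genes = list(rho.index)
    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            r = rho.loc[a, b]
            rows.append(
                {
                    "gene_a": a,
                    "gene_b": b,
                    "rho": r,
                    "p": p.loc[a, b],
                    "strong": bool(r > strong_threshold) if pd.notna(r) else False,
                }
            )
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "rho", "p", "strong"])


def write_correlations(long_table: pd.DataFrame, path) -> None:
    with atomic_write(path) as tmp:
        long_table.to_csv(tmp, index=False)
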