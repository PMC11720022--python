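"""Two-compartment deconvolution of bulk expression by tumor purity.

Bulk expression of each gene is modeled as a purity-weighted mixture of a
tumor-compartment mean and a stroma-compartment mean, assumed constant
across samples:

    e_bulk[g, i] ~= p_i * e_T[g] + (1 - p_i) * e_S[g]

Each gene is fit independently by non-negative least squares on the
design matrix [p, 1-p], giving compartment means that respect the
nonnegativity of expression.  The fit is unidentifiable only when purity
is constant across the used samples (the two design columns become
collinear), which is rejected.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from interactome.io import ValidationError, validate_expression

__all__ = ["deconvolve"]

logger = logging.getLogger(__name__)


def deconvolve(
    expr: pd.DataFrame,
    purity: pd.Series,
    min_nonzero_frac: float = 0.0,
) -> pd.DataFrame:
    """Estimate per-gene tumor/stroma compartment means from bulk mixtures.

    Parameters
    ----------
    expr
        Nonnegative gene x sample expression matrix.
    purity
        Tumor purity in [0, 1] per sample.  Must cover the expression
        samples; samples without purity are dropped (logged).
    min_nonzero_frac
        Optional gene pre-filter: drop genes whose fraction of nonzero
        values falls below this threshold (default 0, no filtering).

    Returns
    -------
    DataFrame indexed by gene with columns ``e_tumor``, ``e_stroma`` and
    ``residual_ss`` (attained sum of squared residuals); the number of
    samples used is stored in ``.attrs["n_samples_used"]``.
    """
    if expr.empty:
        raise ValidationError("empty expression matrix")
    validate_expression(expr)
    purity = purity.dropna()
    if ((purity < 0) | (purity > 1)).any():
        raise ValidationError("purity values outside [0, 1]")

    shared = [s for s in expr.columns if s in purity.index]
    dropped = len(expr.columns) - len(shared)
    if dropped:
        logger.info("dropping %d samples without purity", dropped)
    if not shared:
        raise ValidationError("no overlap between expression samples and purity")
    expr = expr[shared]
    p = purity.loc[shared].to_numpy(float)
    if np.unique(p).size < 2:
        raise ValidationError(
            "constant purity across samples: the two-compartment fit is "
            "unidentifiable (design columns p and 1-p are collinear)"
        )

    if min_nonzero_frac > 0:
        frac = (expr.to_numpy() > 0).mean(axis=1)
        keep = frac >= min_nonzero_frac
        logger.info("gene filter: keeping %d of %d genes", int(keep.sum()), len(keep))
        expr = expr.loc[keep]
        if expr.empty:
            raise ValidationError("no genes survive the min-nonzero-frac filter")

    design = np.column_stack([p, 1.0 - p])
    values = expr.to_numpy(float)
    e_tumor = np.empty(len(expr))
    e_stroma = np.empty(len(expr))
    residual_ss = np.empty(len(expr))
    for row, y in enumerate(values):
        coef, rnorm = nnls(design, y)
        e_tumor[row], e_stroma[row] = coef
        residual_ss[row] = rnorm * rnorm

    out = pd.DataFrame(
        {"e_tumor": e_tumor, "e_stroma": e_stroma, "residual_ss": residual_ss},
        index=expr.index.copy(),
    )
    out.attrs["n_samples_used"] = len(shared)
    return out
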