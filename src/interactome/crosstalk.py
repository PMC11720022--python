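"""Relative Crosstalk (RC) scoring of ligand-receptor pairs.

Under mass action, the complex concentration of a ligand-receptor pair is
proportional to [L][R]/K_D.  With compartment mean expression standing in
for concentration and a K_D assumed uniform across pairs and samples, the
RC score for a source->target compartment axis is the fraction of the
total interaction product that axis accounts for.  For ligand tumor/
stroma means L_T, L_S and receptor means R_T, R_S:

    D       = L_T*R_S + L_T*R_T + L_S*R_S + L_S*R_T
    rc_ts   = L_T * R_S / D        (tumor ligand -> stroma receptor)

and analogously for tt, st, ss.  The four scores sum to one, and the
denominator factorizes as (L_T + L_S) * (R_T + R_S), so each score is the
product of a ligand compartment fraction and a receptor compartment
fraction.  The K_D constant cancels algebraically; it is kept as an
explicit parameter to preserve the mass-action derivation and make the
cancellation testable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from interactome.io import ValidationError

__all__ = ["AXES", "CrosstalkConfig", "extract_axis_genes", "rc_scores"]

logger = logging.getLogger(__name__)

AXES = ("tt", "ts", "st", "ss")


@dataclass(frozen=True)
class CrosstalkConfig:
    """RC scoring parameters.

    kd_inverse : uniform 1/K_D applied to every interaction product;
        mathematically cancels out of the scores (must be > 0).
    top_k : pairs taken per axis when extracting axis gene sets.
    zero_policy : what to do when a pair's denominator is zero (gene absent
        from both compartments): "undefined" drops the pair from scoring,
        "uniform" assigns 0.25 to each axis.
    """

    kd_inverse: float = 1.0
    top_k: int = 15
    zero_policy: str = "undefined"

    def validate(self) -> None:
        if self.kd_inverse <= 0:
            raise ValidationError("kd_inverse must be positive")
        if self.top_k < 1:
            raise ValidationError("top_k must be >= 1")
        if self.zero_policy not in ("undefined", "uniform"):
            raise ValidationError("zero_policy must be 'undefined' or 'uniform'")


def rc_scores(
    profiles: pd.DataFrame,
    catalog: pd.DataFrame,
    config: CrosstalkConfig | None = None,
) -> pd.DataFrame:
    """Score every catalog pair on the four tumor/stroma axes.

    Pairs whose ligand or receptor is absent from ``profiles`` are dropped
    with a logged count.  Returns one row per retained pair with columns
    ligand, receptor, rc_tt/ts/st/ss, rank_tt/ts/st/ss (dense rank by
    descending score among defined pairs) and a ``defined`` flag.
    """
    config = config or CrosstalkConfig()
    config.validate()
    if (profiles[["e_tumor", "e_stroma"]].to_numpy() < 0).any():
        raise ValidationError("negative compartment profile values")
    for col in ("ligand", "receptor"):
        complexed = catalog[col].astype(str).str.contains(r"\+")
        if complexed.any():
            raise ValidationError(
                "multi-subunit complex entries are not supported in RC scoring: "
                f"{catalog.loc[complexed, col].tolist()[:5]}"
            )

    known = set(profiles.index)
    keep = catalog["ligand"].isin(known) & catalog["receptor"].isin(known)
    if (~keep).any():
        logger.info("dropping %d pairs with genes absent from profiles", int((~keep).sum()))
    retained = catalog.loc[keep].reset_index(drop=True)
    if retained.empty:
        raise ValidationError("no catalog pair has both genes in the profiles")

    lt = profiles.loc[retained["ligand"], "e_tumor"].to_numpy(float)
    ls = profiles.loc[retained["ligand"], "e_stroma"].to_numpy(float)
    rt = profiles.loc[retained["receptor"], "e_tumor"].to_numpy(float)
    rs = profiles.loc[retained["receptor"], "e_stroma"].to_numpy(float)

    kdi = config.kd_inverse
    products = {
        "tt": kdi * lt * rt,
        "ts": kdi * lt * rs,
        "st": kdi * ls * rt,
        "ss": kdi * ls * rs,
    }
    denom = sum(products.values())
    defined = denom > 0

    table = retained[["ligand", "receptor"]].copy()
    for axis in AXES:
        score = np.full(len(table), np.nan)
        np.divide(products[axis], denom, out=score, where=defined)
        if config.zero_policy == "uniform":
            score[~defined] = 0.25
        table[f"rc_{axis}"] = score
    table["defined"] = defined if config.zero_policy == "undefined" else True

    for axis in AXES:
        ranks = table.loc[table["defined"], f"rc_{axis}"].rank(
            method="dense", ascending=False
        )
        table[f"rank_{axis}"] = ranks.reindex(table.index)
    return table


def extract_axis_genes(
    table: pd.DataFrame, config: CrosstalkConfig | None = None
) -> dict[str, set[str]]:
    """Union of ligand/receptor genes of the top-k pairs per axis.

    Pairs are ordered by descending score, ties broken by ascending
    (ligand, receptor) for determinism.  Returns a dict keyed by axis code
    plus ``"all"`` for the overall union.
    """
    config = config or CrosstalkConfig()
    config.validate()
    defined = table[table["defined"].astype(bool)]
    if defined.empty:
        raise ValidationError("no defined pairs to extract genes from")
    out: dict[str, set[str]] = {}
    union: set[str] = set()
    for axis in AXES:
        top = defined.sort_values(
            [f"rc_{axis}", "ligand", "receptor"],
            ascending=[False, True, True],
            kind="mergesort",
        ).head(config.top_k)
        genes = set(top["ligand"]) | set(top["receptor"])
        out[axis] = genes
        union |= genes
    out["all"] = union
    return out
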