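"""Consensus gene selection across named evidence sets.

Genes supported by at least ``min_sets`` independent evidence sources
(co-expression hub genes, cell-cell communication signaling genes,
RC-derived crosstalk genes, ...) form the consensus list.  Matching is
exact after uppercasing and whitespace stripping; no alias resolution.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

import pandas as pd

from interactome.io import ValidationError

__all__ = ["consensus_genes"]


def _normalize(symbols: Iterable[str]) -> set[str]:
    out = {str(s).strip().upper() for s in symbols}
    out.discard("")
    return out


def consensus_genes(
    evidence: Mapping[str, Iterable[str]], min_sets: int = 2
) -> pd.DataFrame:
    """Genes appearing in at least ``min_sets`` of the evidence sets.

    Returns a DataFrame with columns ``gene``, ``n_sets`` and ``sources``
    (semicolon-joined set names), ordered by membership count descending
    then gene symbol — a deterministic ordering.
    """
    if len(evidence) < 2:
        raise ValidationError("consensus needs at least two evidence sets")
    if min_sets < 2 or min_sets > len(evidence):
        raise ValidationError(
            f"min_sets must lie in [2, {len(evidence)}], got {min_sets}"
        )
    normalized = {name: _normalize(genes) for name, genes in evidence.items()}
    membership: dict[str, list[str]] = {}
    for name in sorted(normalized):
        for gene in normalized[name]:
            membership.setdefault(gene, []).append(name)
    rows = [
        {"gene": gene, "n_sets": len(sources), "sources": ";".join(sources)}
        for gene, sources in membership.items()
        if len(sources) >= min_sets
    ]
    table = pd.DataFrame(rows, columns=["gene", "n_sets", "sources"])
    return table.sort_values(
        ["n_sets", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
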