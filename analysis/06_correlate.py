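#!/usr/bin/env python
"""Spearman rank correlation among the consensus genes' bulk expression,
flagging strongly positive pairs (rho > 0.8).
"""

from pathlib import Path

from interactome import io as iio
from interactome.association import correlation_long, spearman_matrix, write_correlations

ROOT = Path(__file__).resolve().parent.parent
OUTDIR = ROOT / "results" / "analysis"


def main() -> None:
    expr = iio.read_expression(OUTDIR / "simulated" / "expression.tsv")
    genes = sorted(iio.read_gene_set(OUTDIR / "consensus_genes.txt"))

    rho, p = spearman_matrix(expr, genes)
    table = correlation_long(rho, p)
    write_correlations(table, OUTDIR / "correlations.csv")

    strong = table[table["strong"]]
    print(f"{len(table)} gene pairs among {len(genes)} consensus genes")
    print(f"{len(strong)} strong positive pairs (rho > 0.8)")
    head = table.reindex(table["rho"].abs().sort_values(ascending=False).index).head(5)
    print(head.to_string(index=False))
    print(f"wrote {OUTDIR / 'correlations.csv'}")


if __name__ == "__main__":
    main()
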