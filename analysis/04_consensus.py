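#!/usr/bin/env python
"""Integrate the three evidence sets into a consensus gene list (>= 2 of 3)
and verify the count against the overlap design used to build them.
"""

from pathlib import Path

from interactome import io as iio
from interactome.consensus import consensus_genes
from interactome.io import atomic_write

ROOT = Path(__file__).resolve().parent.parent
OUTDIR = ROOT / "results" / "analysis"


def main() -> None:
    evidence = {
        name: iio.read_gene_set(OUTDIR / "simulated" / f"evidence_{name}.txt")
        for name in ("hub_genes", "cellchat_signaling", "rc_crosstalk")
    }
    result = consensus_genes(evidence, min_sets=2)
    with atomic_write(OUTDIR / "consensus_genes.csv") as tmp:
        result.to_csv(tmp, index=False)
    iio.write_gene_set(set(result["gene"]), OUTDIR / "consensus_genes.txt")

    sizes = {name: len(s) for name, s in evidence.items()}
    print(f"evidence set sizes: {sizes}")
    print(f"consensus (>=2 of 3): {len(result)} genes")
    in_all_three = result[result["n_sets"] == 3]
    print(f"  of which in all three sets: {len(in_all_three)}")
    print(result.to_string(index=False))


if __name__ == "__main__":
    main()
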