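#!/usr/bin/env python
"""High-confidence PPI filtering and the BC-protein x RBP bipartite network.

Keeps experimental/database edges at score >= 0.9, extracts the cross-set
network, and reports interactor counts and degree-ranked hubs. Reads
results/synthetic/; writes results/ppi/.
"""

from pathlib import Path

import pandas as pd

from rbprior.genesets import load_gmt
from rbprior.ppi import extract_bipartite, filter_edges, interactor_counts

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    outdir = ROOT / "ppi"
    outdir.mkdir(parents=True, exist_ok=True)
    edges = pd.read_csv(ROOT / "synthetic" / "ppi.tsv", sep="\t")
    sets = load_gmt(ROOT / "synthetic" / "genesets" / "genesets.gmt")

    kept = filter_edges(edges)
    kept.to_csv(outdir / "filtered_edges.tsv", sep="\t", index=False)
    print(f"kept {len(kept)} of {len(edges)} edges (experimental/database, score >= 0.9)")

    net = extract_bipartite(kept, set(sets["bc"]), set(sets["rbp"]))
    n_bc, n_rbp, hubs = interactor_counts(net)
    print(f"{n_bc} BC proteins interact with {n_rbp} RBPs")
    if hubs:
        top, deg = hubs[0]
        print(f"top hub: {top} with {deg} RBP partners")
    pd.DataFrame(hubs, columns=["bc_protein", "n_rbp_partners"]).to_csv(
        outdir / "hubs.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [(a, b, d["score"]) for a, b, d in net.graph.edges(data=True)],
        columns=["gene_a", "gene_b", "score"],
    ).to_csv(outdir / "bipartite_edges.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
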