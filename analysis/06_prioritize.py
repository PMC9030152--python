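#!/usr/bin/env python
"""Four-criteria intersection: the headline prioritization.

Combines the quartile of most-altered RBPs, the PPI criterion, the IHC
overexpression criterion and the essential union into per-gene evidence
vectors; intersects them; compares the prioritized set with the planted
truth. Reads results/synthetic/ plus the stage outputs of 02-05; writes
results/prioritized/.
"""

import json
from pathlib import Path

import pandas as pd

from rbprior.prioritize import build_evidence, intersect, venn_counts_frame
from rbprior.genesets import load_gmt
from rbprior.synthetic import GroundTruth

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    outdir = ROOT / "prioritized"
    outdir.mkdir(parents=True, exist_ok=True)
    rbp_genes = set(load_gmt(ROOT / "synthetic" / "genesets" / "genesets.gmt")["rbp"])

    quartile = set(pd.read_csv(ROOT / "alterations" / "first_quartile.tsv", sep="\t")["gene"])
    consensus = pd.read_csv(ROOT / "ihc" / "consensus.tsv", sep="\t")
    deltas = dict(zip(consensus["gene"], consensus["delta"].astype(int)))
    bipartite = pd.read_csv(ROOT / "ppi" / "bipartite_edges.tsv", sep="\t")
    ppi_genes = (set(bipartite["gene_a"]) | set(bipartite["gene_b"])) & rbp_genes
    combined = pd.read_csv(ROOT / "dependency" / "combined.tsv", sep="\t")
    essential = set(combined["gene"])

    evidence = build_evidence(rbp_genes, quartile, ppi_genes,
                              {g: deltas.get(g, 0) for g in rbp_genes}, essential)
    result = intersect(evidence)
    evidence.to_csv(outdir / "evidence.tsv", sep="\t", index=False)
    venn_counts_frame(result).to_csv(outdir / "venn.tsv", sep="\t", index=False)

    truth = GroundTruth.from_json((ROOT / "synthetic" / "truth.json").read_text())
    print(f"criterion sizes: quartile={len(quartile)}, ppi={len(ppi_genes)}, "
          f"ihc_up={sum(d >= 1 for d in deltas.values())}, essential={len(essential)}")
    print(f"prioritized ({len(result.prioritized)}): {', '.join(result.prioritized)}")
    print(f"planted truth: {', '.join(sorted(truth.planted_progressors))}")
    print(f"near-miss (first three criteria, not essential): {len(result.near_miss)}")
    (outdir / "prioritized.json").write_text(json.dumps(
        {"prioritized": list(result.prioritized), "near_miss": list(result.near_miss)}, indent=2))


if __name__ == "__main__":
    main()
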