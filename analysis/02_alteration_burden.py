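#!/usr/bin/env python
"""Alteration-burden profiling of the simulated cohort.

Compares per-patient burden across the three gene sets with Mann-Whitney U
tests, breaks events down by category, and selects the first quartile of
most progression-altered RBPs. Reads results/synthetic/ (run 01 first);
writes results/alterations/.
"""

from pathlib import Path

import pandas as pd

from rbprior import alterations as alt
from rbprior.genesets import GeneSet, load_gmt

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    indir = ROOT / "synthetic"
    outdir = ROOT / "alterations"
    outdir.mkdir(parents=True, exist_ok=True)
    calls = pd.read_csv(indir / "alterations.tsv", sep="\t")
    samples = pd.read_csv(indir / "samples.tsv", sep="\t")
    sets = {name: GeneSet(name, frozenset(genes))
            for name, genes in load_gmt(indir / "genesets" / "genesets.gmt").items()}

    burdens = {name: alt.burden_per_patient(calls, gs, samples["sample_id"])
               for name, gs in sets.items()}
    rows = []
    for a, b in (("rbp", "noncancer"), ("bc", "noncancer"), ("rbp", "bc")):
        res = alt.mann_whitney(burdens[a], burdens[b])
        rows.append({"set_a": a, "set_b": b, "u": res.u_statistic, "p": res.p_value, "method": res.method})
        print(f"burden {a} vs {b}: U={res.u_statistic:.0f}  p={res.p_value:.3g}")
    pd.DataFrame(rows).to_csv(outdir / "geneset_comparisons.tsv", sep="\t", index=False)

    breakdown = alt.category_breakdown(calls, sets["rbp"])
    breakdown.rename_axis("category").to_csv(outdir / "category_breakdown.tsv", sep="\t")
    print("RBP event categories:", ", ".join(f"{c}={f:.1%}" for c, f in breakdown.items() if f > 0))

    for group in ("subtype", "stage"):
        alt.burden_by_group(calls, samples, group).rename_axis(group).to_csv(
            outdir / f"burden_by_{group}.tsv", sep="\t"
        )

    counts = alt.count_per_gene(calls, alt.PROGRESSION, sets["rbp"])
    counts.rename_axis("gene").to_csv(outdir / "progression_counts.tsv", sep="\t")
    quartile = alt.first_quartile_genes(counts)
    pd.Series(sorted(quartile), name="gene").to_csv(outdir / "first_quartile.tsv", sep="\t", index=False)
    print(f"first-quartile selection: {len(quartile)} of {len(counts)} RBPs")


if __name__ == "__main__":
    main()
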