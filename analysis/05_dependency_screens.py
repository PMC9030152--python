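#!/usr/bin/env python
"""Essentiality calling from the two loss-of-function screens.

Calls essential RBPs per screen (mean score <= -0.5), combines the screens
by union/intersection, and derives per-subtype essential and exclusive
sets. Reads results/synthetic/; writes results/dependency/.
"""

from pathlib import Path

import pandas as pd

from rbprior.dependency import call_essential, combine_screens, essential_by_subtype

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    indir = ROOT / "synthetic"
    outdir = ROOT / "dependency"
    outdir.mkdir(parents=True, exist_ok=True)
    rnai = pd.read_csv(indir / "dep_rnai.tsv", sep="\t", index_col=0)
    crispr = pd.read_csv(indir / "dep_crispr.tsv", sep="\t", index_col=0)
    annotations = pd.read_csv(indir / "cell_lines.tsv", sep="\t")

    calls = {"rnai": call_essential(rnai, screen="rnai"), "crispr": call_essential(crispr, screen="crispr")}
    for name, c in calls.items():
        c.table.to_csv(outdir / f"calls_{name}.tsv", sep="\t", index=False)
        top = c.table.nsmallest(5, "mean_score")
        print(f"{name}: {len(c.essential_genes)} essential RBPs; strongest depletions "
              + ", ".join(f"{r.gene} ({r.mean_score:.2f})" for r in top.itertuples()))

    sets = combine_screens(calls["rnai"], calls["crispr"])
    print(f"union {len(sets['union'])}, both screens {len(sets['intersection'])}")
    pd.DataFrame({"gene": sorted(sets["union"]),
                  "in_rnai": [g in sets["rnai"] for g in sorted(sets["union"])],
                  "in_crispr": [g in sets["crispr"] for g in sorted(sets["union"])]}).to_csv(
        outdir / "combined.tsv", sep="\t", index=False)

    by, exclusives, skipped = essential_by_subtype(crispr, annotations[annotations["cell_line"].isin(crispr.index)])
    rows = [{"subtype": s, "n_essential": len(g), "n_exclusive": len(exclusives[s])} for s, g in sorted(by.items())]
    pd.DataFrame(rows).to_csv(outdir / "by_subtype.tsv", sep="\t", index=False)
    print("per-subtype essential RBPs:", ", ".join(f"{r['subtype']}={r['n_essential']}" for r in rows))


if __name__ == "__main__":
    main()
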