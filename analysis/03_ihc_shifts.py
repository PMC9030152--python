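#!/usr/bin/env python
"""Immunohistochemical consensus levels and tumor-vs-normal shift classes.

Builds the per-gene consensus from tumor samples, classifies shifts,
tabulates the normal x tumor level matrix, and counts up/downregulated
RBPs. Reads results/synthetic/; writes results/ihc/.
"""

from pathlib import Path

import pandas as pd

from rbprior.ihc import classify_profiles, crosstab_levels

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    outdir = ROOT / "ihc"
    outdir.mkdir(parents=True, exist_ok=True)
    ihc = pd.read_csv(ROOT / "synthetic" / "ihc.tsv", sep="\t")
    profiles, excluded = classify_profiles(ihc)
    profiles.to_csv(outdir / "consensus.tsv", sep="\t", index=False)
    crosstab_levels(profiles).to_csv(outdir / "level_crosstab.tsv", sep="\t")

    by_class = profiles["class"].value_counts()
    print("shift classes:", ", ".join(f"{k}={v}" for k, v in by_class.items()))
    print(f"upregulated (>= 2 levels): {by_class.get('upregulated', 0)}; "
          f"downregulated: {by_class.get('downregulated', 0)}")
    if excluded:
        print(f"excluded for missing tissue data: {len(excluded)}")


if __name__ == "__main__":
    main()
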