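"""Four-criteria evidence integration and candidate intersection.

Each gene in the analysis universe gets a boolean evidence vector:

  c1_quartile  — top quartile of profile-matching alteration counts
  c2_ppi       — at least one high-confidence interaction with a BC protein
  c3_ihc       — immunohistochemical shift toward the profile's direction
  c4_essential — member of the across-screens essential union

The progression direction uses the progression alteration profile and an
IHC shift of >= +1; the suppression direction mirrors it (suppression
profile, shift <= -1). Prioritized candidates satisfy all four criteria;
the near-miss set satisfies the first three but not essentiality.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import pandas as pd

__all__ = ["CRITERIA", "PrioritizationResult", "build_evidence", "intersect"]

CRITERIA = ("c1_quartile", "c2_ppi", "c3_ihc", "c4_essential")


class PrioritizeError(ValueError):
    pass


@dataclass(frozen=True)
class PrioritizationResult:
    prioritized: tuple[str, ...]
    near_miss: tuple[str, ...]
    venn_counts: dict[frozenset[str], int]

    @property
    def n_with_any_evidence(self) -> int:
        return sum(self.venn_counts.values())


def build_evidence(
    universe: "set[str] | list[str]",
    quartile_genes: set[str],
    ppi_genes: set[str],
    ihc_delta: Mapping[str, int],
    essential_genes: set[str],
    direction: str = "progression",
) -> pd.DataFrame:
    """Evidence vector per gene in the universe.

    ``ihc_delta`` must cover the whole universe (genes without an IHC
    profile should be resolved upstream — typically excluded from the
    universe or given delta 0); a gap raises with the missing genes listed.
    """
    if direction not in ("progression", "suppression"):
        raise PrioritizeError(f"unknown direction {direction!r}")
    universe = sorted(set(universe))
    missing = [g for g in universe if g not in ihc_delta]
    if missing:
        raise PrioritizeError(f"genes without IHC delta: {missing[:10]}{'...' if len(missing) > 10 else ''}")
    if direction == "progression":
        c3 = {g: ihc_delta[g] >= 1 for g in universe}
    else:
        c3 = {g: ihc_delta[g] <= -1 for g in universe}
    return pd.DataFrame(
        {
            "gene": universe,
            "c1_quartile": [g in quartile_genes for g in universe],
            "c2_ppi": [g in ppi_genes for g in universe],
            "c3_ihc": [c3[g] for g in universe],
            "c4_essential": [g in essential_genes for g in universe],
            "direction": direction,
        }
    )


def intersect(evidence: pd.DataFrame) -> PrioritizationResult:
    """Intersect the four criteria into prioritized / near-miss / Venn counts.

    Venn counts cover the 15 non-empty criterion combinations; a gene is
    counted under exactly the set of criteria it satisfies, so the counts
    sum to the number of genes with at least one criterion.
    """
    missing = set(CRITERIA) - set(evidence.columns)
    if missing:
        raise PrioritizeError(f"evidence frame lacks {sorted(missing)}")
    df = evidence.sort_values("gene")
    mask = df[list(CRITERIA)].to_numpy(dtype=bool)
    genes = df["gene"].to_list()

    prioritized = [g for g, row in zip(genes, mask) if row.all()]
    near_miss = [g for g, row in zip(genes, mask) if row[0] and row[1] and row[2] and not row[3]]

    venn: dict[frozenset[str], int] = {
        frozenset(combo): 0
        for r in range(1, 5)
        for combo in combinations(CRITERIA, r)
    }
    for row in mask:
        key = frozenset(c for c, v in zip(CRITERIA, row) if v)
        if key:
            venn[key] += 1
    return PrioritizationResult(
        prioritized=tuple(prioritized), near_miss=tuple(near_miss), venn_counts=venn
    )


def venn_counts_frame(result: PrioritizationResult) -> pd.DataFrame:
    """Venn counts as a tidy frame (one row per criterion combination)."""
    rows = [
        {"criteria": "+".join(sorted(k)), "n_genes": v}
        for k, v in sorted(result.venn_counts.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))
    ]
    return pd.DataFrame(rows)
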