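"""Ordinal immunohistochemistry consensus and tumor-vs-normal shift calling.

Protein levels live on the 4-level ordinal scale used by tissue atlases:
not detected (0) < low (1) < medium (2) < high (3). A gene's tumor consensus
is the modal level over its tumor samples, with ties broken toward the
higher level (the tie rule is symmetric across genes and documented; the
manual consensus it stands in for published only the frequency principle).

The shift class compares tumor consensus with the normal-tissue level:
a two-or-more level change is up/downregulated, a one-level change is
moderate, zero is unchanged.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "LEVELS",
    "LEVEL_NAMES",
    "ShiftClass",
    "consensus_level",
    "classify_shift",
    "overexpression_flag",
    "classify_profiles",
    "crosstab_levels",
]

LEVELS: Mapping[str, int] = {"not_detected": 0, "low": 1, "medium": 2, "high": 3}
LEVEL_NAMES = tuple(LEVELS)  # index == ordinal value


class IHCError(ValueError):
    pass


@dataclass(frozen=True)
class ShiftClass:
    label: str  # upregulated | moderate_up | unchanged | moderate_down | downregulated
    delta: int


def _as_ordinal(level: "int | str") -> int:
    if isinstance(level, str):
        if level not in LEVELS:
            raise IHCError(f"unknown IHC level {level!r}")
        return LEVELS[level]
    level = int(level)
    if not 0 <= level <= 3:
        raise IHCError(f"IHC level {level} outside 0..3")
    return level


def consensus_level(tumor_levels: Iterable["int | str"]) -> int:
    """Modal tumor level; among tied modes the higher level wins."""
    values = [_as_ordinal(v) for v in tumor_levels]
    if not values:
        raise IHCError("no tumor levels to form a consensus")
    freq = Counter(values)
    top = max(freq.values())
    return max(level for level, n in freq.items() if n == top)


def classify_shift(normal_level: "int | str", tumor_consensus: "int | str") -> ShiftClass:
    """Label the tumor-minus-normal ordinal difference."""
    delta = _as_ordinal(tumor_consensus) - _as_ordinal(normal_level)
    if delta >= 2:
        label = "upregulated"
    elif delta == 1:
        label = "moderate_up"
    elif delta == 0:
        label = "unchanged"
    elif delta == -1:
        label = "moderate_down"
    else:
        label = "downregulated"
    return ShiftClass(label=label, delta=delta)


def overexpression_flag(delta: int) -> bool:
    """At least one ordinal level toward overexpression."""
    return delta >= 1


def classify_profiles(ihc: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Consensus + shift classification for every gene in a long IHC table.

    Expects columns (gene, tissue, sample_id, level) with tissue in
    {normal, tumor} and level as a label or ordinal. Genes lacking either a
    normal measurement or any tumor sample are excluded and reported.

    Returns a per-gene frame (gene, normal, tumor_consensus, delta, class)
    and the list of excluded genes.
    """
    required = {"gene", "tissue", "level"}
    if not required.issubset(ihc.columns):
        raise IHCError(f"IHC table lacks columns {sorted(required - set(ihc.columns))}")
    rows = []
    excluded: list[str] = []
    for gene, group in ihc.groupby("gene"):
        normals = group.loc[group["tissue"] == "normal", "level"]
        tumors = group.loc[group["tissue"] == "tumor", "level"]
        if normals.empty or tumors.empty:
            excluded.append(str(gene))
            continue
        normal = _as_ordinal(normals.iloc[0])
        tumor = consensus_level(tumors)
        shift = classify_shift(normal, tumor)
        rows.append(
            {
                "gene": gene,
                "normal": normal,
                "tumor_consensus": tumor,
                "delta": shift.delta,
                "class": shift.label,
            }
        )
    frame = pd.DataFrame(rows, columns=["gene", "normal", "tumor_consensus", "delta", "class"])
    return frame.sort_values("gene").reset_index(drop=True), sorted(excluded)


def crosstab_levels(profiles: pd.DataFrame) -> pd.DataFrame:
    """4x4 gene-count matrix of normal level (rows) x tumor consensus (cols).

    Entries sum to the number of classified genes; the diagonal holds the
    unchanged genes.
    """
    table = pd.crosstab(profiles["normal"], profiles["tumor_consensus"])
    table = table.reindex(index=range(4), columns=range(4), fill_value=0)
    table.index = pd.Index(LEVEL_NAMES, name="normal")
    table.columns = pd.Index(LEVEL_NAMES, name="tumor")
    return table
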