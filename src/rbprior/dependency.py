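"""Essentiality calling from loss-of-function dependency screens.

A dependency matrix is cell lines x genes with one gene-level fitness score
per line (CERES-style for CRISPR, DEMETER2-style for RNAi); strongly
negative means the line depends on the gene. A gene is called essential
when its mean score across the considered lines is at or below minus the
threshold (default 0.5, inclusive) — i.e. a depletion of magnitude >= 0.5.

Screens are combined by plain set algebra (union / intersection obey
inclusion-exclusion exactly), and per-subtype calls restrict the mean to
that subtype's cell lines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EssentialityCalls",
    "call_essential",
    "essential_set",
    "combine_screens",
    "essential_by_subtype",
    "intersection_from_counts",
    "union_from_counts",
]


class DependencyError(ValueError):
    pass


@dataclass(frozen=True)
class EssentialityCalls:
    """Per-gene calls for one screen plus genes excluded for lacking data."""

    screen: str
    table: pd.DataFrame  # columns: gene, mean_score, essential, n_lines
    excluded: tuple[str, ...]

    @property
    def essential_genes(self) -> set[str]:
        return set(self.table.loc[self.table["essential"], "gene"])


def call_essential(
    matrix: pd.DataFrame,
    lines: "list[str] | pd.Index | None" = None,
    threshold: float = 0.5,
    screen: str = "screen",
) -> EssentialityCalls:
    """Call essential genes from mean dependency scores over a line subset.

    ``matrix`` is indexed by cell line with one column per gene; missing
    scores are allowed and ignored in the mean. Genes with no non-missing
    score in the subset are excluded and reported.
    """
    if threshold <= 0:
        raise DependencyError("threshold must be positive")
    if lines is not None:
        if len(lines) == 0:
            raise DependencyError("empty cell-line subset")
        missing = set(lines) - set(matrix.index)
        if missing:
            raise DependencyError(f"cell lines absent from matrix: {sorted(missing)}")
        matrix = matrix.loc[list(lines)]
    n_lines = matrix.notna().sum(axis=0)
    means = matrix.mean(axis=0, skipna=True)
    excluded = tuple(sorted(n_lines.index[n_lines == 0]))
    kept = n_lines.index[n_lines > 0]
    table = pd.DataFrame(
        {
            "gene": kept,
            "mean_score": means.loc[kept].to_numpy(),
            "essential": (means.loc[kept] <= -threshold).to_numpy(),
            "n_lines": n_lines.loc[kept].to_numpy(),
        }
    ).sort_values("gene").reset_index(drop=True)
    return EssentialityCalls(screen=screen, table=table, excluded=excluded)


def essential_set(calls: EssentialityCalls) -> set[str]:
    return calls.essential_genes


def combine_screens(
    calls_rnai: "EssentialityCalls | set[str]",
    calls_crispr: "EssentialityCalls | set[str]",
) -> dict[str, set[str]]:
    """Union / intersection accounting across the two screens."""
    a = calls_rnai.essential_genes if isinstance(calls_rnai, EssentialityCalls) else set(calls_rnai)
    b = calls_crispr.essential_genes if isinstance(calls_crispr, EssentialityCalls) else set(calls_crispr)
    return {"rnai": a, "crispr": b, "union": a | b, "intersection": a & b}


def intersection_from_counts(n_a: int, n_b: int, n_union: int) -> int:
    """|A ∩ B| from per-screen counts and the combined total (inclusion-exclusion)."""
    n_both = n_a + n_b - n_union
    if n_both < 0:
        raise DependencyError("counts violate inclusion-exclusion")
    return n_both


def union_from_counts(n_a: int, n_b: int, n_both: int) -> int:
    """|A ∪ B| from per-screen counts and the both-screens count."""
    if n_both > min(n_a, n_b):
        raise DependencyError("intersection exceeds a screen count")
    return n_a + n_b - n_both


def essential_by_subtype(
    matrix: pd.DataFrame,
    annotations: pd.DataFrame,
    threshold: float = 0.5,
    screen: str = "screen",
) -> tuple[dict[str, set[str]], dict[str, set[str]], list[str]]:
    """Per-subtype essential sets plus subtype-exclusive genes.

    ``annotations`` maps cell_line -> subtype. Subtypes with zero lines in
    the matrix are excluded and reported. A gene is exclusive to subtype s
    when it is essential in s and in no other subtype.
    """
    if not {"cell_line", "subtype"}.issubset(annotations.columns):
        raise DependencyError("cell-line annotations need columns cell_line, subtype")
    by_subtype: dict[str, set[str]] = {}
    skipped: list[str] = []
    for subtype, group in annotations.groupby("subtype"):
        lines = [ln for ln in group["cell_line"] if ln in matrix.index]
        if not lines:
            skipped.append(str(subtype))
            continue
        by_subtype[str(subtype)] = call_essential(
            matrix, lines=lines, threshold=threshold, screen=screen
        ).essential_genes
    exclusives = {
        s: genes - set().union(*(g for t, g in by_subtype.items() if t != s), set())
        for s, genes in by_subtype.items()
    }
    return by_subtype, exclusives, sorted(skipped)
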