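"""Alteration-burden profiling and rank-based gene-set comparison.

The atom is one (sample, gene, category) call in the cBioPortal style; the
six-category vocabulary is closed. Two alteration profiles group categories
by their usual tumor-biological direction: progression-type events
(amplification, mRNA upregulation, plus mutations and fusions, which occur
in both directions) and suppression-type events (deep deletion, mRNA
downregulation, mutations, fusions). Mutations and fusions deliberately
count toward both profiles.

Burdens are event counts normalized by gene-set size (per patient) or by
group size (per subtype / stage). Gene sets are compared with a
Mann-Whitney U test; the quartile selector returns the most-altered top 25%
of genes with boundary ties included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genesets import GeneSet

__all__ = [
    "CATEGORIES",
    "PROGRESSION",
    "SUPPRESSION",
    "ProfileSpec",
    "RankTestResult",
    "validate_calls",
    "count_per_gene",
    "burden_per_patient",
    "burden_by_group",
    "mann_whitney",
    "first_quartile_genes",
    "category_breakdown",
]

CATEGORIES = (
    "amplification",
    "deep_deletion",
    "mrna_up",
    "mrna_down",
    "mutation",
    "fusion",
)


class AlterationError(ValueError):
    pass


@dataclass(frozen=True)
class ProfileSpec:
    name: str
    categories: frozenset[str]

    def __post_init__(self) -> None:
        unknown = self.categories - set(CATEGORIES)
        if unknown:
            raise AlterationError(f"profile {self.name!r} has unknown categories {sorted(unknown)}")


PROGRESSION = ProfileSpec("progression", frozenset({"amplification", "mrna_up", "fusion", "mutation"}))
SUPPRESSION = ProfileSpec("suppression", frozenset({"deep_deletion", "mrna_down", "fusion", "mutation"}))

PROFILES = {"progression": PROGRESSION, "suppression": SUPPRESSION}


@dataclass(frozen=True)
class RankTestResult:
    """Mann-Whitney U outcome: U counts (x > y) pairs plus half-ties."""

    u_statistic: float
    p_value: float
    method: str  # "exact" | "normal_approx"


def validate_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Check schema, category vocabulary and triple uniqueness."""
    required = {"sample_id", "gene", "category"}
    missing = required - set(calls.columns)
    if missing:
        raise AlterationError(f"alteration table lacks columns {sorted(missing)}")
    bad = calls.loc[~calls["category"].isin(CATEGORIES)]
    if len(bad):
        row = bad.iloc[0]
        raise AlterationError(
            f"unknown category {row['category']!r} at sample={row['sample_id']!r} gene={row['gene']!r}"
        )
    if calls.duplicated(["sample_id", "gene", "category"]).any():
        raise AlterationError("duplicate (sample, gene, category) rows")
    return calls


def count_per_gene(
    calls: pd.DataFrame,
    profile: ProfileSpec,
    gene_universe: "GeneSet | set[str] | None" = None,
) -> pd.Series:
    """Number of profile-matching events per gene.

    When a gene universe is supplied, genes with zero events appear with
    count 0 and counting is restricted to the universe.
    """
    validate_calls(calls)
    sub = calls[calls["category"].isin(profile.categories)]
    counts = sub.groupby("gene").size()
    if gene_universe is not None:
        universe = sorted(gene_universe.genes if isinstance(gene_universe, GeneSet) else gene_universe)
        counts = counts.reindex(universe, fill_value=0)
    return counts.astype(int).rename(f"n_{profile.name}")


def burden_per_patient(
    calls: pd.DataFrame,
    geneset: GeneSet,
    sample_ids: "pd.Index | list[str] | None" = None,
) -> pd.Series:
    """Per-patient event count within a gene set, corrected by set size.

    ``sample_ids``, when given, fixes the patient universe so that patients
    with no events contribute a burden of 0.
    """
    if len(geneset) == 0:
        raise AlterationError("empty gene set")
    validate_calls(calls)
    sub = calls[calls["gene"].isin(geneset.genes)]
    burden = sub.groupby("sample_id").size() / len(geneset)
    if sample_ids is not None:
        burden = burden.reindex(pd.Index(sample_ids, name="sample_id"), fill_value=0.0)
    return burden.rename(f"burden_{geneset.name}")


def burden_by_group(calls: pd.DataFrame, samples: pd.DataFrame, group: str) -> pd.Series:
    """Event count per group label, corrected by the number of patients in it.

    ``group`` is a column of the sample annotation table (subtype or stage).
    Labels without samples do not appear.
    """
    if group not in samples.columns:
        raise AlterationError(f"sample annotations lack column {group!r}")
    validate_calls(calls)
    labels = samples.set_index("sample_id")[group]
    n_per_group = labels.value_counts()
    events = calls["sample_id"].map(labels).value_counts()
    burden = (events.reindex(n_per_group.index, fill_value=0) / n_per_group).sort_index()
    return burden.rename(f"burden_by_{group}")


def mann_whitney(x, y) -> RankTestResult:
    """Two-sided Mann-Whitney U comparison of two burden samples.

    The exact null distribution is used for tie-free samples with both sizes
    <= 8; otherwise the normal approximation with tie and continuity
    corrections. U is reported for ``x`` (pairs x>y plus half-ties), so
    U_x + U_y = n1*n2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise AlterationError("empty sample in rank test")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    if tie_free and x.size <= 8 and y.size <= 8:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        method = "normal_approx"
    return RankTestResult(u_statistic=float(res.statistic), p_value=float(res.pvalue), method=method)


def first_quartile_genes(counts: pd.Series) -> set[str]:
    """Genes in the top quartile of alteration counts.

    The threshold is the 75th percentile of the count distribution (linear
    interpolation between order statistics); genes whose count ties the
    threshold are included, so the result has at least ceil(N/4) members.
    """
    if len(counts) == 0:
        raise AlterationError("empty count map")
    threshold = float(np.percentile(counts.to_numpy(dtype=float), 75))
    return set(counts.index[counts >= threshold])


def category_breakdown(calls: pd.DataFrame, geneset: GeneSet | None = None) -> pd.Series:
    """Fraction of events per category, restricted to a gene set if given.

    An empty selection yields an all-zero breakdown (flagged by summing to 0
    rather than 1).
    """
    validate_calls(calls)
    sub = calls if geneset is None else calls[calls["gene"].isin(geneset.genes)]
    frac = sub["category"].value_counts(normalize=True)
    return frac.reindex(CATEGORIES, fill_value=0.0).rename("fraction")
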