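"""Gene-set loading, deduplication and driver-catalog cross-tabulation.

Gene sets arrive either as GMT (one set per line: name, description, then
gene symbols) or as two-column TSV (symbol, stable id). Gene identity for
deduplication is the stable id when present, falling back to the
case-normalized symbol; two entries are considered the same gene when they
share either key, which is how annotation-driven duplicates (two stable ids
resolving to one symbol, or vice versa) surface in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "GeneSet",
    "DriverCatalog",
    "DedupReport",
    "load_and_dedup",
    "load_gmt",
    "write_gmt",
    "crosstab_roles",
]

ROLES = ("oncogene", "tumor_suppressor", "unknown")


class GeneSetError(ValueError):
    """Malformed or empty gene-set input."""


@dataclass(frozen=True)
class GeneSet:
    """A named set of genes; ``stable_ids`` maps symbol -> stable id where known."""

    name: str
    genes: frozenset[str]
    stable_ids: dict[str, str] = field(default_factory=dict, compare=False)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


@dataclass(frozen=True)
class DedupReport:
    """Pairs of (kept, dropped) symbols collapsed during deduplication."""

    collapsed: tuple[tuple[str, str], ...]

    def __len__(self) -> int:
        return len(self.collapsed)


def _norm(symbol: str) -> str:
    return symbol.strip().upper()


def load_and_dedup(path: str | Path, name: str | None = None) -> tuple[GeneSet, DedupReport]:
    """Load a gene set from GMT or two-column TSV and collapse duplicates.

    Entries sharing a stable id, or sharing a case-normalized symbol, are
    collapsed onto the first-seen entry. Returns the deduplicated set and a
    report listing each (kept, dropped) pair.

    Raises
    ------
    GeneSetError
        If the file is empty or a line is malformed (with its line number).
    """
    path = Path(path)
    entries = _read_entries(path)
    if not entries:
        raise GeneSetError(f"{path}: empty gene-set file")

    kept_by_symbol: dict[str, str] = {}
    kept_by_id: dict[str, str] = {}
    stable_ids: dict[str, str] = {}
    order: list[str] = []
    collapsed: list[tuple[str, str]] = []
    for symbol, stable_id in entries:
        key_sym = _norm(symbol)
        match = kept_by_symbol.get(key_sym)
        if match is None and stable_id:
            match = kept_by_id.get(stable_id)
        if match is not None:
            collapsed.append((match, symbol))
            continue
        kept_by_symbol[key_sym] = symbol
        if stable_id:
            kept_by_id[stable_id] = symbol
            stable_ids[symbol] = stable_id
        order.append(symbol)

    return (
        GeneSet(name=name or path.stem, genes=frozenset(order), stable_ids=stable_ids),
        DedupReport(collapsed=tuple(collapsed)),
    )


def _read_entries(path: Path) -> list[tuple[str, str | None]]:
    entries: list[tuple[str, str | None]] = []
    lines = path.read_text().splitlines()
    if lines and len(lines[0].rstrip("\n").split("\t")) > 2 and not lines[0].startswith("#"):
        # GMT dialect: a single line carries the whole set
        for lineno, line in enumerate(lines, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise GeneSetError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
            entries.extend((g, None) for g in fields[2:] if g)
        return entries
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) == 1:
            entries.append((fields[0], None))
        elif len(fields) == 2:
            entries.append((fields[0], fields[1] or None))
        else:
            raise GeneSetError(f"{path}:{lineno}: expected 1-2 tab-separated fields, got {len(fields)}")
    return entries


def load_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file into ``{set name: gene set}``."""
    out: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise GeneSetError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
        out[fields[0]] = {g for g in fields[2:] if g}
    return out


def write_gmt(sets: dict[str, Iterable[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *sorted(genes)]) + "\n")


@dataclass(frozen=True)
class DriverCatalog:
    """Cancer-driver catalog: gene -> role per cancer-type label."""

    entries: pd.DataFrame  # columns: gene, role, cancer_type

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DriverCatalog":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"gene", "role", "cancer_type"}
        if not required.issubset(df.columns):
            raise GeneSetError(f"{path}: catalog needs columns {sorted(required)}")
        return cls(entries=df)

    def __post_init__(self) -> None:
        bad = set(self.entries["role"]) - set(ROLES)
        if bad:
            raise GeneSetError(f"unknown driver roles: {sorted(bad)}")
        if self.entries.duplicated(["gene", "cancer_type"]).any():
            raise GeneSetError("catalog assigns multiple roles to one (gene, cancer_type)")

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.entries["gene"])

    def cancer_types(self) -> frozenset[str]:
        return frozenset(self.entries["cancer_type"])


def crosstab_roles(rbps: GeneSet, catalog: DriverCatalog, cancer_type: str) -> pd.DataFrame:
    """Cross-tabulate catalog RBPs by (in-type vs other-type) x driver role.

    Each gene in ``rbps & catalog`` is counted exactly once: under the given
    cancer type when the catalog lists it for that type (with that entry's
    role), otherwise under "other" with the role of its first catalog entry.
    Cell counts therefore sum to ``|rbps ∩ catalog|``.
    """
    if cancer_type not in catalog.cancer_types():
        raise GeneSetError(f"unknown cancer_type {cancer_type!r}")
    shared = rbps.genes & catalog.genes
    table = pd.DataFrame(0, index=[cancer_type, "other"], columns=list(ROLES), dtype=int)
    entries = catalog.entries.sort_values(["gene", "cancer_type"])
    for gene, group in entries[entries["gene"].isin(shared)].groupby("gene"):
        in_type = group[group["cancer_type"] == cancer_type]
        if len(in_type):
            table.loc[cancer_type, in_type["role"].iloc[0]] += 1
        else:
            table.loc["other", group["role"].iloc[0]] += 1
    return table
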