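"""Synthetic cohort, tissue-atlas, screen and network generator.

Every input table the prioritization pipeline consumes is generated here
with planted ground truth, so each downstream stage has a known answer:

* an alteration-call cohort in which a handful of planted progressor RBPs
  carry strongly boosted amplification / mRNA-upregulation rates (and
  planted suppressors boosted deletion / downregulation rates);
* an immunohistochemistry table in which planted progressors shift two or
  more ordinal levels above their normal-tissue level;
* two dependency-screen matrices in which planted genes score around a
  strongly negative mean while background genes hover around zero;
* a scored PPI edge list that guarantees each planted gene one
  highest-confidence experimental edge to a BC protein, a functional
  network of Erdős–Rényi noise plus one planted clique, and a complex
  catalog naming that clique.

Determinism: every output table draws from its own RNG stream derived from
the master seed and a fixed per-table label, so adding or re-ordering
tables never perturbs the others and a fixed config reproduces its outputs
byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .alterations import CATEGORIES
from .genesets import write_gmt
from .ihc import LEVEL_NAMES

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "make_truth",
    "simulate_cohort",
    "simulate_ihc",
    "simulate_dependency",
    "simulate_networks",
    "simulate_all",
    "write_all",
]

SUBTYPES = ("Normal", "LumA", "LumB", "Her2", "Basal")
STAGES = ("I", "II", "III", "IV")
CELL_SUBTYPES = ("LumA", "LumB", "Her2", "Basal")

# Relative frequency of each alteration category among background events,
# echoing the dominance of mRNA upregulation and amplification in breast
# tumors; scaled so the per-(sample, gene) event probability matches
# alteration_rate_background.
CATEGORY_MIX = {
    "mrna_up": 0.55,
    "amplification": 0.15,
    "mutation": 0.12,
    "mrna_down": 0.10,
    "deep_deletion": 0.05,
    "fusion": 0.03,
}

PLANTED_COMPLEX_NAME = "SPLICEOSOME_PLANTED"


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generative model; defaults are the study conditions."""

    seed: int = 0
    n_patients: int = 994
    set_sizes: tuple[int, int, int, int] = (200, 40, 40, 60)  # rbp, bc, noncancer, cdg
    n_planted_progressors: int = 5
    n_planted_suppressors: int = 5
    alteration_rate_background: float = 0.02
    progressor_boost: float = 10.0
    n_tumor_ihc_samples: int = 12
    n_cell_lines: int = 30
    essential_mean: float = -1.5
    score_noise_sd: float = 0.2
    noise_edge_prob: float = 0.05
    planted_complex_size: int = 12
    ppi_background_edges: int = 400
    subtype_proportions: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)
    stage_proportions: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    # gene-set-level rate multipliers (rbp, bc, noncancer): cancer-related
    # sets are modestly more altered than the non-cancer baseline
    set_rate_multipliers: tuple[float, float, float] = (2.0, 2.0, 1.0)

    def __post_init__(self) -> None:
        counts = (
            self.n_patients,
            *self.set_sizes,
            self.n_planted_progressors,
            self.n_planted_suppressors,
            self.n_tumor_ihc_samples,
            self.n_cell_lines,
            self.planted_complex_size,
        )
        if any(c <= 0 for c in counts):
            raise ConfigError("all counts must be > 0")
        if not 0.0 <= self.alteration_rate_background <= 1.0:
            raise ConfigError("alteration_rate_background must be in [0, 1]")
        if not 0.0 <= self.noise_edge_prob <= 1.0:
            raise ConfigError("noise_edge_prob must be in [0, 1]")
        if self.n_planted_progressors + self.n_planted_suppressors > self.set_sizes[0]:
            raise ConfigError("planted genes exceed the RBP set size")
        if self.planted_complex_size > self.set_sizes[0]:
            raise ConfigError("planted complex larger than the RBP set")
        for props, expect in ((self.subtype_proportions, len(SUBTYPES)), (self.stage_proportions, len(STAGES))):
            if len(props) != expect:
                raise ConfigError("proportion vector has wrong length")
            if abs(sum(props) - 1.0) > 1e-6:
                raise ConfigError("proportions must sum to 1")

    @property
    def n_rbp(self) -> int:
        return self.set_sizes[0]

    @property
    def n_bc(self) -> int:
        return self.set_sizes[1]

    @property
    def n_noncancer(self) -> int:
        return self.set_sizes[2]

    @property
    def n_cdg(self) -> int:
        return self.set_sizes[3]


@dataclass(frozen=True)
class GroundTruth:
    planted_progressors: frozenset[str]
    planted_suppressors: frozenset[str]
    planted_complex: frozenset[str]

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted_progressors": sorted(self.planted_progressors),
                "planted_suppressors": sorted(self.planted_suppressors),
                "planted_complex": sorted(self.planted_complex),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        data = json.loads(text)
        return cls(
            planted_progressors=frozenset(data["planted_progressors"]),
            planted_suppressors=frozenset(data["planted_suppressors"]),
            planted_complex=frozenset(data["planted_complex"]),
        )


_STREAMS = {"truth": 1, "cohort": 2, "ihc": 3, "dep_rnai": 4, "dep_crispr": 5, "networks": 6, "catalog": 7}


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), _STREAMS[stream]])


def gene_universe(config: SimulationConfig) -> dict[str, list[str]]:
    """Disjoint gene-id lists per simulated set (rbp / bc / noncancer)."""
    return {
        "rbp": [f"RBP{i:04d}" for i in range(1, config.n_rbp + 1)],
        "bc": [f"BCG{i:03d}" for i in range(1, config.n_bc + 1)],
        "noncancer": [f"NON{i:03d}" for i in range(1, config.n_noncancer + 1)],
    }


def make_truth(config: SimulationConfig) -> GroundTruth:
    """Deterministically pick planted genes and the planted complex."""
    rng = _rng(config, "truth")
    rbps = gene_universe(config)["rbp"]
    picked = rng.choice(len(rbps), size=config.n_planted_progressors + config.n_planted_suppressors, replace=False)
    progressors = frozenset(rbps[i] for i in picked[: config.n_planted_progressors])
    suppressors = frozenset(rbps[i] for i in picked[config.n_planted_progressors :])
    rest = [g for g in rbps if g not in progressors and g not in suppressors]
    n_extra = max(config.planted_complex_size - len(progressors), 0)
    extra = rng.choice(len(rest), size=n_extra, replace=False)
    complex_members = frozenset(progressors) | {rest[i] for i in extra}
    return GroundTruth(
        planted_progressors=progressors,
        planted_suppressors=suppressors,
        planted_complex=frozenset(complex_members),
    )


def _category_rates(config: SimulationConfig, genes: list[str], truth: GroundTruth, multiplier: float) -> pd.DataFrame:
    base = {c: CATEGORY_MIX[c] * config.alteration_rate_background * multiplier for c in CATEGORIES}
    rates = pd.DataFrame({c: np.full(len(genes), base[c]) for c in CATEGORIES}, index=genes)
    boost = config.progressor_boost
    prog = [g for g in genes if g in truth.planted_progressors]
    supp = [g for g in genes if g in truth.planted_suppressors]
    rates.loc[prog, ["amplification", "mrna_up"]] *= boost
    rates.loc[supp, ["deep_deletion", "mrna_down"]] *= boost
    return rates.clip(upper=1.0)


def simulate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Alteration-call long table + sample annotations + ground truth.

    Events are independent Bernoulli draws per (sample, gene, category);
    planted progressors get ``progressor_boost``-fold amplification and
    mRNA-upregulation rates (suppressors the mirror categories).
    """
    truth = make_truth(config)
    rng = _rng(config, "cohort")
    universe = gene_universe(config)
    sample_ids = [f"S{i:04d}" for i in range(1, config.n_patients + 1)]

    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "subtype": rng.choice(SUBTYPES, size=config.n_patients, p=config.subtype_proportions),
            "stage": rng.choice(STAGES, size=config.n_patients, p=config.stage_proportions),
        }
    )

    frames = []
    for set_name, multiplier in zip(("rbp", "bc", "noncancer"), config.set_rate_multipliers):
        genes = universe[set_name]
        rates = _category_rates(config, genes, truth, multiplier)
        for category in CATEGORIES:
            p = rates[category].to_numpy()
            hits = rng.random((config.n_patients, len(genes))) < p[None, :]
            rows, cols = np.nonzero(hits)
            if len(rows):
                frames.append(
                    pd.DataFrame(
                        {
                            "sample_id": np.array(sample_ids, dtype=object)[rows],
                            "gene": np.array(genes, dtype=object)[cols],
                            "category": category,
                        }
                    )
                )
    if frames:
        calls = pd.concat(frames, ignore_index=True)
        calls = calls.sort_values(["sample_id", "gene", "category"]).reset_index(drop=True)
    else:
        calls = pd.DataFrame(columns=["sample_id", "gene", "category"])
    return calls, samples, truth


# Per-sample ordinal shift distributions on the 0-3 scale (values, probs)
_BACKGROUND_SHIFT = (np.array([-1, 0, 1]), np.array([0.1, 0.8, 0.1]))
_PLANTED_UP_SHIFT = (np.array([2, 3]), np.array([0.6, 0.4]))
_PLANTED_DOWN_SHIFT = (np.array([-3, -2]), np.array([0.4, 0.6]))


def simulate_ihc(config: SimulationConfig, truth: GroundTruth) -> pd.DataFrame:
    """Long IHC table (gene, tissue, sample_id, level) over the RBP set.

    Planted progressors draw their normal level from {not detected, low}
    and shift +2/+3 per tumor sample (clamped to the scale), so the planted
    signal survives the ordinal bounds; suppressors mirror this from
    {medium, high}. Background genes mostly keep their level.
    """
    rng = _rng(config, "ihc")
    genes = gene_universe(config)["rbp"]
    rows = []
    for gene in genes:
        if gene in truth.planted_progressors:
            normal = int(rng.choice([0, 1]))
            shift_values, shift_probs = _PLANTED_UP_SHIFT
        elif gene in truth.planted_suppressors:
            normal = int(rng.choice([2, 3]))
            shift_values, shift_probs = _PLANTED_DOWN_SHIFT
        else:
            normal = int(rng.choice([0, 1, 2, 3], p=[0.15, 0.2, 0.45, 0.2]))
            shift_values, shift_probs = _BACKGROUND_SHIFT
        rows.append({"gene": gene, "tissue": "normal", "sample_id": "N0001", "level": LEVEL_NAMES[normal]})
        shifts = rng.choice(shift_values, size=config.n_tumor_ihc_samples, p=shift_probs)
        tumor_levels = np.clip(normal + shifts, 0, 3)
        for i, lvl in enumerate(tumor_levels, start=1):
            rows.append(
                {"gene": gene, "tissue": "tumor", "sample_id": f"T{i:04d}", "level": LEVEL_NAMES[int(lvl)]}
            )
    return pd.DataFrame(rows, columns=["gene", "tissue", "sample_id", "level"])


def simulate_dependency(
    config: SimulationConfig, truth: GroundTruth
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Two cell-line x gene dependency matrices plus cell-line subtypes.

    Background genes score Normal(0, sd); planted progressor and suppressor
    genes score Normal(essential_mean, sd) in both screens.
    """
    genes = gene_universe(config)["rbp"]
    planted = truth.planted_progressors | truth.planted_suppressors
    means = np.array([config.essential_mean if g in planted else 0.0 for g in genes])

    matrices = {}
    annotations = []
    for screen, prefix in (("dep_rnai", "R"), ("dep_crispr", "C")):
        rng = _rng(config, screen)
        lines = [f"{prefix}{i:03d}" for i in range(1, config.n_cell_lines + 1)]
        scores = rng.normal(means[None, :], config.score_noise_sd, size=(config.n_cell_lines, len(genes)))
        matrices[screen] = pd.DataFrame(scores, index=pd.Index(lines, name="cell_line"), columns=genes)
        annotations.append(
            pd.DataFrame({"cell_line": lines, "subtype": rng.choice(CELL_SUBTYPES, size=len(lines))})
        )
    cell_lines = pd.concat(annotations, ignore_index=True)
    return matrices["dep_rnai"], matrices["dep_crispr"], cell_lines


def simulate_networks(
    config: SimulationConfig, truth: GroundTruth
) -> tuple[pd.DataFrame, nx.Graph, dict[str, set[str]]]:
    """Scored PPI edge list, functional network and complex catalog.

    PPI: each planted gene receives one guaranteed experimental edge with
    score >= 0.9 to a BC-set protein; background edges draw mixed channels
    and scores Uniform(0.4, 0.95). Functional network: Erdős–Rényi noise at
    ``noise_edge_prob`` over the whole gene universe plus the planted
    clique. Catalog: the planted complex under a fixed name plus decoys.
    """
    rng = _rng(config, "networks")
    universe = gene_universe(config)
    all_genes = universe["rbp"] + universe["bc"] + universe["noncancer"]

    # --- PPI edge list -----------------------------------------------------
    ppi_rows = []
    bc_genes = universe["bc"]
    for gene in sorted(truth.planted_progressors | truth.planted_suppressors):
        partner = bc_genes[int(rng.integers(len(bc_genes)))]
        ppi_rows.append(
            {"gene_a": partner, "gene_b": gene, "channel": "experimental", "score": round(float(rng.uniform(0.9, 0.99)), 3)}
        )
    channels = ("experimental", "database", "textmining", "coexpression", "other")
    for _ in range(config.ppi_background_edges):
        a, b = rng.choice(len(all_genes), size=2, replace=False)
        ppi_rows.append(
            {
                "gene_a": all_genes[int(a)],
                "gene_b": all_genes[int(b)],
                "channel": channels[int(rng.integers(len(channels)))],
                "score": round(float(rng.uniform(0.4, 0.95)), 3),
            }
        )
    ppi = pd.DataFrame(ppi_rows, columns=["gene_a", "gene_b", "channel", "score"])

    # --- functional network ------------------------------------------------
    funcnet = nx.Graph()
    funcnet.add_nodes_from(all_genes)
    n = len(all_genes)
    if config.noise_edge_prob > 0:
        upper = rng.random((n, n)) < config.noise_edge_prob
        for i, j in zip(*np.nonzero(np.triu(upper, k=1))):
            funcnet.add_edge(all_genes[i], all_genes[j], weight=round(float(rng.uniform(0.5, 3.0)), 3))
    for a, b in combinations(sorted(truth.planted_complex), 2):
        funcnet.add_edge(a, b, weight=round(float(rng.uniform(1.5, 3.0)), 3))

    # --- complex catalog ---------------------------------------------------
    catalog: dict[str, set[str]] = {PLANTED_COMPLEX_NAME: set(truth.planted_complex)}
    for i in range(1, 6):
        size = int(rng.integers(6, 15))
        members = rng.choice(len(all_genes), size=size, replace=False)
        catalog[f"DECOY_COMPLEX_{i}"] = {all_genes[int(j)] for j in members}
    return ppi, funcnet, catalog


def simulate_driver_catalog(config: SimulationConfig, truth: GroundTruth) -> pd.DataFrame:
    """CDG catalog TSV rows (gene, role, cancer_type).

    Drawn from BC genes (annotated to breast cancer) and RBP genes
    (annotated to other cancer types), with oncogene / tumor-suppressor /
    unknown roles; planted progressors are always included so the disease
    network filter keeps them.
    """
    rng = _rng(config, "catalog")
    universe = gene_universe(config)
    n_bc_drivers = min(14, config.n_bc, config.n_cdg)
    bc_pick = rng.choice(config.n_bc, size=n_bc_drivers, replace=False)
    bc_drivers = [universe["bc"][i] for i in bc_pick]
    n_rbp_drivers = config.n_cdg - n_bc_drivers
    pool = [g for g in universe["rbp"] if g not in truth.planted_progressors]
    picked = rng.choice(len(pool), size=max(n_rbp_drivers - config.n_planted_progressors, 0), replace=False)
    rbp_drivers = sorted(truth.planted_progressors) + [pool[i] for i in picked]
    roles = ("oncogene", "tumor_suppressor", "unknown")
    rows = [
        {"gene": g, "role": roles[int(rng.choice(3, p=[0.2, 0.3, 0.5]))], "cancer_type": "breast"}
        for g in bc_drivers
    ]
    rows += [
        {"gene": g, "role": roles[int(rng.choice(3, p=[0.15, 0.15, 0.7]))], "cancer_type": "other"}
        for g in rbp_drivers
    ]
    return pd.DataFrame(rows, columns=["gene", "role", "cancer_type"])


def simulate_all(config: SimulationConfig) -> dict:
    """Run every generator and return the named tables in one bundle."""
    calls, samples, truth = simulate_cohort(config)
    ihc = simulate_ihc(config, truth)
    dep_rnai, dep_crispr, cell_lines = simulate_dependency(config, truth)
    ppi, funcnet, catalog = simulate_networks(config, truth)
    drivers = simulate_driver_catalog(config, truth)
    return {
        "config": config,
        "truth": truth,
        "alterations": calls,
        "samples": samples,
        "ihc": ihc,
        "dep_rnai": dep_rnai,
        "dep_crispr": dep_crispr,
        "cell_lines": cell_lines,
        "ppi": ppi,
        "funcnet": funcnet,
        "complexes": catalog,
        "drivers": drivers,
        "genesets": gene_universe(config),
    }


def write_all(bundle: dict, outdir: str | Path) -> None:
    """Write every simulated table to ``outdir`` in its plain-text format."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle["alterations"].to_csv(outdir / "alterations.tsv", sep="\t", index=False)
    bundle["samples"].to_csv(outdir / "samples.tsv", sep="\t", index=False)
    bundle["ihc"].to_csv(outdir / "ihc.tsv", sep="\t", index=False)
    bundle["dep_rnai"].to_csv(outdir / "dep_rnai.tsv", sep="\t")
    bundle["dep_crispr"].to_csv(outdir / "dep_crispr.tsv", sep="\t")
    bundle["cell_lines"].to_csv(outdir / "cell_lines.tsv", sep="\t", index=False)
    bundle["ppi"].to_csv(outdir / "ppi.tsv", sep="\t", index=False)
    nx.to_pandas_edgelist(bundle["funcnet"]).rename(
        columns={"source": "gene_a", "target": "gene_b"}
    )[["gene_a", "gene_b", "weight"]].to_csv(outdir / "funcnet.tsv", sep="\t", index=False)
    write_gmt(bundle["complexes"], outdir / "complexes.gmt")
    genesets_dir = outdir / "genesets"
    genesets_dir.mkdir(exist_ok=True)
    write_gmt({k: v for k, v in bundle["genesets"].items()}, genesets_dir / "genesets.gmt")
    bundle["drivers"].to_csv(outdir / "drivers.tsv", sep="\t", index=False)
    (outdir / "truth.json").write_text(bundle["truth"].to_json())
    (outdir / "config.json").write_text(json.dumps(asdict(bundle["config"]), indent=2, default=list))
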