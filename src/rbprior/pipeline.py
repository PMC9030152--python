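"""End-to-end orchestration: simulate -> burden -> IHC -> PPI -> screens ->
intersection -> complex detection, with every intermediate table written to
the output directory and a structured run report at the end.

Each stage runs inside a named guard so a failure surfaces as
``PipelineError("<stage>: ...")`` rather than a bare traceback from deep in
a library call.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import alterations as alt
from . import dependency as dep
from . import ihc as ihc_mod
from . import netcluster, ppi, prioritize
from .synthetic import SimulationConfig, simulate_all, write_all

__all__ = ["RunConfig", "RunReport", "PipelineError", "run_all"]


class PipelineError(RuntimeError):
    pass


@dataclass(frozen=True)
class RunConfig:
    """One artifact describing a full pipeline run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    min_ppi_score: float = 0.9
    ppi_channels: tuple[str, ...] = ("experimental", "database")
    dependency_threshold: float = 0.5
    quartile_percentile: float = 75.0
    direction: str = "progression"
    mcode_node_score_cutoff: float = 0.1
    mcode_fluff: float = 0.0
    mcode_haircut: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_ppi_score <= 1.0:
            raise PipelineError("min_ppi_score must be in [0, 1]")
        if self.dependency_threshold <= 0:
            raise PipelineError("dependency_threshold must be > 0")
        if not 0.0 < self.quartile_percentile < 100.0:
            raise PipelineError("quartile_percentile must be in (0, 100)")
        if self.direction not in ("progression", "suppression"):
            raise PipelineError(f"unknown direction {self.direction!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**{
            **data.get("simulation", {}),
            **({"set_sizes": tuple(data["simulation"]["set_sizes"])} if "set_sizes" in data.get("simulation", {}) else {}),
        })
        rest = {k: v for k, v in data.items() if k != "simulation"}
        if "ppi_channels" in rest:
            rest["ppi_channels"] = tuple(rest["ppi_channels"])
        return cls(simulation=sim, **rest)


@dataclass
class RunReport:
    """Serializable account of one pipeline run."""

    version: str
    config: dict
    timestamp: float
    stage_counts: dict = field(default_factory=dict)
    criterion_sizes: dict = field(default_factory=dict)
    prioritized: list = field(default_factory=list)
    near_miss: list = field(default_factory=list)
    top_complex: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        return cls(**json.loads(text))

    def comparable(self) -> dict:
        """Report content with the timestamp stripped, for determinism checks.

        Normalized through JSON so tuple/list distinctions do not matter.
        """
        data = json.loads(json.dumps(asdict(self), default=str))
        data.pop("timestamp")
        return data

    def to_text(self) -> str:
        lines = [
            f"rbprior {self.version} run report",
            f"direction: {self.config.get('direction')}",
            "stage row counts: " + ", ".join(f"{k}={v}" for k, v in self.stage_counts.items()),
            "criterion sizes: " + ", ".join(f"{k}={v}" for k, v in self.criterion_sizes.items()),
            f"prioritized ({len(self.prioritized)}): {', '.join(self.prioritized) or '-'}",
            f"near-miss ({len(self.near_miss)}): {', '.join(self.near_miss) or '-'}",
        ]
        if self.top_complex:
            lines.append(
                "top complex: {n_members} members, {n_edges} edges, best catalog match "
                "{catalog_name} ({n_matched}/{n_members} matched)".format(**self.top_complex)
            )
        return "\n".join(lines) + "\n"


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise PipelineError(f"{name}: {exc}") from exc

        return wrapped

    return deco


def run_all(config: RunConfig, outdir: str | Path) -> RunReport:
    """Execute the full prioritization pipeline on a simulated cohort.

    Writes all simulated inputs and per-stage outputs under ``outdir`` and
    returns the run report (also written as report.json / report.txt).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(
        version=__version__,
        config={**asdict(config), "simulation": asdict(config.simulation)},
        timestamp=time.time(),
    )

    bundle = _stage("simulate")(simulate_all)(config.simulation)
    _stage("simulate")(write_all)(bundle, outdir / "inputs")
    truth = bundle["truth"]
    report.truth = json.loads(truth.to_json())
    rbp_genes = set(bundle["genesets"]["rbp"])
    bc_genes = set(bundle["genesets"]["bc"])
    report.stage_counts["alteration_calls"] = int(len(bundle["alterations"]))
    report.stage_counts["samples"] = int(len(bundle["samples"]))

    # alteration profiling
    profile = alt.PROFILES[config.direction]
    counts = _stage("alterations")(alt.count_per_gene)(bundle["alterations"], profile, rbp_genes)
    quartile = _stage("alterations")(alt.first_quartile_genes)(counts)
    counts.rename_axis("gene").to_csv(outdir / "gene_counts.tsv", sep="\t")
    report.criterion_sizes["c1_quartile"] = len(quartile)

    # IHC shift classification
    profiles, excluded = _stage("ihc")(ihc_mod.classify_profiles)(bundle["ihc"])
    profiles.to_csv(outdir / "ihc_consensus.tsv", sep="\t", index=False)
    deltas = dict(zip(profiles["gene"], profiles["delta"].astype(int)))
    if config.direction == "progression":
        flagged = {g for g, d in deltas.items() if d >= 1}
    else:
        flagged = {g for g, d in deltas.items() if d <= -1}
    report.criterion_sizes["c3_ihc"] = len(flagged)
    report.stage_counts["ihc_excluded_genes"] = len(excluded)

    # PPI filtering and bipartite extraction
    filtered = _stage("ppi")(ppi.filter_edges)(
        bundle["ppi"], frozenset(config.ppi_channels), config.min_ppi_score
    )
    filtered.to_csv(outdir / "ppi_filtered.tsv", sep="\t", index=False)
    net = _stage("ppi")(ppi.extract_bipartite)(filtered, bc_genes, rbp_genes)
    ppi_rbps = net.right_with_edges()
    report.criterion_sizes["c2_ppi"] = len(ppi_rbps)
    report.stage_counts["ppi_edges_filtered"] = int(len(filtered))

    # dependency screens
    calls_rnai = _stage("depscreen")(dep.call_essential)(
        bundle["dep_rnai"], threshold=config.dependency_threshold, screen="rnai"
    )
    calls_crispr = _stage("depscreen")(dep.call_essential)(
        bundle["dep_crispr"], threshold=config.dependency_threshold, screen="crispr"
    )
    screens = dep.combine_screens(calls_rnai, calls_crispr)
    pd.DataFrame(
        {"gene": sorted(screens["union"]), "in_rnai": [g in screens["rnai"] for g in sorted(screens["union"])],
         "in_crispr": [g in screens["crispr"] for g in sorted(screens["union"])]}
    ).to_csv(outdir / "essential_union.tsv", sep="\t", index=False)
    report.criterion_sizes["c4_essential"] = len(screens["union"])
    report.stage_counts["essential_rnai"] = len(screens["rnai"])
    report.stage_counts["essential_crispr"] = len(screens["crispr"])
    report.stage_counts["essential_both"] = len(screens["intersection"])

    # four-criteria intersection
    evidence = _stage("prioritize")(prioritize.build_evidence)(
        rbp_genes, quartile, ppi_rbps, {g: deltas.get(g, 0) for g in rbp_genes},
        screens["union"], config.direction,
    )
    result = _stage("prioritize")(prioritize.intersect)(evidence)
    evidence.to_csv(outdir / "evidence.tsv", sep="\t", index=False)
    prioritize.venn_counts_frame(result).to_csv(outdir / "venn.tsv", sep="\t", index=False)
    report.prioritized = list(result.prioritized)
    report.near_miss = list(result.near_miss)

    # disease network + MCODE + catalog annotation
    cdg_genes = set(bundle["drivers"]["gene"])
    seeds = result.prioritized or tuple(sorted(truth.planted_progressors))
    disease_net, missing_seeds = _stage("cluster")(netcluster.build_disease_network)(
        bundle["funcnet"], seeds, rbp_genes, cdg_genes
    )
    complexes = _stage("cluster")(netcluster.mcode_find_complexes)(
        disease_net,
        node_score_cutoff=config.mcode_node_score_cutoff,
        fluff=config.mcode_fluff,
        haircut=config.mcode_haircut,
    )
    report.stage_counts["disease_network_nodes"] = disease_net.number_of_nodes()
    report.stage_counts["disease_network_edges"] = disease_net.number_of_edges()
    report.stage_counts["n_complexes"] = len(complexes)
    rows = [
        {"complex_id": i, "seed": c.seed_node, "score": round(c.score, 4), "members": ",".join(sorted(c.members))}
        for i, c in enumerate(complexes, start=1)
    ]
    pd.DataFrame(rows, columns=["complex_id", "seed", "score", "members"]).to_csv(
        outdir / "complexes.tsv", sep="\t", index=False
    )
    if complexes:
        top = complexes[0]
        match = netcluster.annotate_complex(top.members, bundle["complexes"])
        sub = disease_net.subgraph(top.members)
        report.top_complex = {
            "n_members": len(top.members),
            "n_edges": sub.number_of_edges(),
            "members": sorted(top.members),
            "catalog_name": match.catalog_name if match else None,
            "n_matched": match.n_matched if match else 0,
            "coverage": round(match.coverage, 4) if match else 0.0,
        }

    (outdir / "report.json").write_text(report.to_json())
    (outdir / "report.txt").write_text(report.to_text())
    return report
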