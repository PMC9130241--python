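"""End-to-end orchestration: simulate or load -> DE -> consensus -> network
-> enrichment -> survival -> subnetworks, with a reproducibility manifest.

Every stage writes plain files under the output directory so any step can
be audited or re-run in isolation, and the manifest records per-stage
counts in the style of a results section (DEGs per class, pairs retained,
triples per trend, nodes/edges/hubs, enriched terms, survival genes).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .diffexpr import (
    CountsMatrix, de_analysis, deg_directions, read_counts_tsv,
    tmm_norm_factors, heatmap_matrix, volcano_coordinates, write_de_table,
)
from .enrichment import enrich, read_gmt, write_gmt
from .interactions import (
    InteractionTable, consensus_targets, filter_pairs_to_de,
    load_interaction_table, write_consensus,
)
from .network import (
    assemble_triples, build_graph, export_network, extract_subnetwork,
    find_hubs, network_summary, split_by_direction,
)
from .simulate import SimConfig, simulate_all
from .survival import read_clinical_tsv, screen_survival_genes

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "validate_config", "run_pipeline"]

RNA_CLASSES = ("lncRNA", "miRNA", "mRNA")


@dataclass
class PipelineConfig:
    """Thresholds, input locations (or a simulation block) and output directory."""

    outdir: str
    seed: int = 0
    simulation: SimConfig | None = None
    counts_paths: dict[str, str] | None = None   # class -> counts TSV
    sample_sheet: str | None = None
    lnc_mir_path: str | None = None
    mir_mrna_paths: dict[str, str] | None = None  # source label -> TSV
    gmt_path: str | None = None
    survival_expression_path: str | None = None
    clinical_path: str | None = None
    fc_threshold: float = 2.0
    fdr_threshold: float = 0.05
    min_sources: int = 3
    hub_threshold: int = 5
    enrichment_alpha: float = 0.05
    survival_alpha: float = 0.05
    dichotomize_rule: str = "median"
    dichotomize_q: float = 0.5

    def violations(self) -> list[str]:
        """All constraint violations, not just the first."""
        v = []
        if not self.outdir:
            v.append("outdir is required")
        for name in ("fc_threshold", "fdr_threshold", "enrichment_alpha", "survival_alpha"):
            if getattr(self, name) <= 0:
                v.append(f"{name} must be positive")
        if self.min_sources < 1:
            v.append("min_sources must be >= 1")
        if self.hub_threshold < 0:
            v.append("hub_threshold must be >= 0")
        if self.dichotomize_rule not in ("median", "quantile"):
            v.append(f"unknown dichotomize_rule {self.dichotomize_rule!r}")
        have_files = self.counts_paths is not None
        if self.simulation is None and not have_files:
            v.append("exactly one of a simulation block or counts_paths is required (neither given)")
        if self.simulation is not None and have_files:
            v.append("exactly one of a simulation block or counts_paths is required (both given)")
        if have_files:
            missing = [c for c in RNA_CLASSES if c not in (self.counts_paths or {})]
            if missing:
                v.append(f"counts_paths missing classes: {missing}")
            for name in ("sample_sheet", "lnc_mir_path", "mir_mrna_paths",
                         "gmt_path", "survival_expression_path", "clinical_path"):
                if getattr(self, name) is None:
                    v.append(f"{name} is required when loading from files")
        return v


@dataclass
class RunManifest:
    config: dict
    version: str
    seed: int
    counts: dict = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


class ConfigError(ValueError):
    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("invalid pipeline config:\n" + "\n".join(f"- {v}" for v in violations))


def validate_config(path) -> PipelineConfig:
    """Load a YAML/JSON config file, reporting every violation at once."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(["config file must contain a mapping"])
    violations = []
    sim = raw.pop("simulation", None)
    sim_cfg = None
    if sim is not None:
        try:
            sim_cfg = SimConfig(**sim)
        except (TypeError, ValueError) as err:
            violations.append(f"simulation block: {err}")
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        violations.append(f"unknown config keys: {sorted(unknown)}")
    try:
        cfg = PipelineConfig(**{k: v for k, v in raw.items() if k in known}, simulation=sim_cfg)
    except TypeError as err:
        raise ConfigError(violations + [str(err)]) from None
    violations += cfg.violations()
    if violations:
        raise ConfigError(violations)
    return cfg


def _load_inputs(cfg: PipelineConfig):
    counts = {
        cls: read_counts_tsv(cfg.counts_paths[cls], cfg.sample_sheet)
        for cls in RNA_CLASSES
    }
    lnc_mir = load_interaction_table(cfg.lnc_mir_path, "lnc_mir")
    mir_mrna = [
        load_interaction_table(p, label) for label, p in cfg.mir_mrna_paths.items()
    ]
    genesets = read_gmt(cfg.gmt_path, universe=counts["mRNA"].gene_ids)
    expr = pd.read_csv(cfg.survival_expression_path, sep="\t", index_col=0)
    clinical = read_clinical_tsv(cfg.clinical_path)
    return counts, None, (lnc_mir, mir_mrna), genesets, (expr, clinical)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage in order and write all intermediates plus the manifest.

    Identical config + seed gives identical manifest counts. A stage
    failure aborts with the stage named.
    """
    violations = config.violations()
    if violations:
        raise ConfigError(violations)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config={k: v for k, v in asdict(config).items()},
        version=__version__,
        seed=config.seed,
        started=datetime.now(timezone.utc).isoformat(),
    )
    stage = "input"
    try:
        if config.simulation is not None:
            sim = config.simulation
            if sim.seed != config.seed:
                sim = SimConfig(**{**asdict(sim), "seed": config.seed})
            counts, truth, (lnc_mir, mir_mrna), genesets, (expr, clinical) = simulate_all(sim)
            if truth is not None:
                (outdir / "truth.json").write_text(json.dumps({
                    "de_genes": truth.de_genes,
                    "triples": truth.triples,
                    "enriched_set": truth.enriched_set,
                    "survival_genes": truth.survival_genes,
                }, indent=2))
        else:
            counts, truth, (lnc_mir, mir_mrna), genesets, (expr, clinical) = _load_inputs(config)

        stage = "differential_expression"
        degs = {}
        de_counts = {}
        for cls, cm in counts.items():
            res = de_analysis(cm, fc_threshold=config.fc_threshold,
                              fdr_threshold=config.fdr_threshold)
            write_de_table(res, outdir / f"de_{cls}.tsv")
            volcano_coordinates(res).to_csv(outdir / f"volcano_{cls}.tsv", sep="\t", index=False)
            factors = tmm_norm_factors(cm)
            sig = res[res["direction"] != "ns"]["gene"]
            hm = heatmap_matrix(cm, factors).loc[sig]
            hm.to_csv(outdir / f"heatmap_{cls}.tsv", sep="\t")
            degs[cls] = deg_directions(res)
            de_counts[cls] = {
                "degs": len(degs[cls]),
                "up": int((res["direction"] == "up").sum()),
                "down": int((res["direction"] == "down").sum()),
                "dispersion": float(res.attrs["dispersion"]),
            }
        manifest.counts["differential_expression"] = de_counts

        stage = "consensus_targets"
        cmap = consensus_targets(mir_mrna, min_sources=min(config.min_sources, len(mir_mrna)))
        write_consensus(cmap, outdir / "consensus_mir_mrna.tsv")
        lm_pairs, mg_pairs = filter_pairs_to_de(
            lnc_mir, cmap, degs["lncRNA"], degs["miRNA"], degs["mRNA"]
        )
        manifest.counts["interactions"] = {
            "consensus_pairs": len(cmap.pairs),
            "lnc_mir_de": len(lm_pairs),
            "mir_mrna_de": len(mg_pairs),
        }

        stage = "network"
        triples = assemble_triples(lm_pairs, mg_pairs, degs)
        by_trend = split_by_direction(triples)
        manifest.counts["triples"] = {
            "total": len(triples),
            "HLH": len(by_trend["HLH"]),
            "LHL": len(by_trend["LHL"]),
            "discordant": len(triples) - len(by_trend["HLH"]) - len(by_trend["LHL"]),
        }
        networks = {}
        net_counts = {}
        for trend, tri in by_trend.items():
            if not tri:
                net_counts[trend] = {"nodes": 0, "edges": 0, "hubs": 0}
                continue
            g = build_graph(tri, trend=trend)
            networks[trend] = g
            export_network(g, outdir / f"network_{trend}.graphml", "graphml")
            export_network(g, outdir / f"network_{trend}.sif", "sif")
            export_network(g, outdir / f"network_{trend}.json", "json")
            net_counts[trend] = network_summary(g, config.hub_threshold)
        manifest.counts["networks"] = net_counts
        pd.DataFrame([c for c in net_counts.values() if "trend" in c]).to_csv(
            outdir / "network_summary.tsv", sep="\t", index=False
        )

        stage = "enrichment"
        enr_counts = {}
        for trend, g in networks.items():
            mrnas = [d["label"] for _, d in g.nodes(data=True) if d["node_type"] == "mRNA"]
            if not mrnas:
                enr_counts[trend] = 0
                continue
            res = enrich(mrnas, genesets, alpha=config.enrichment_alpha)
            res.to_csv(outdir / f"enrichment_{trend}.tsv", sep="\t", index=False)
            enr_counts[trend] = int(res["significant"].sum()) if len(res) else 0
        manifest.counts["enrichment"] = enr_counts

        stage = "survival"
        surv_counts = {}
        subnet_counts = {}
        for trend, g in networks.items():
            mrnas = [d["label"] for _, d in g.nodes(data=True) if d["node_type"] == "mRNA"]
            present = [m for m in mrnas if m in expr.index]
            if not present:
                surv_counts[trend] = 0
                continue
            res = screen_survival_genes(
                expr.loc[present], clinical, alpha=config.survival_alpha,
                rule=config.dichotomize_rule, q=config.dichotomize_q,
            )
            res.to_csv(outdir / f"survival_{trend}.tsv", sep="\t", index=False)
            surv_counts[trend] = len(res)
            if len(res):
                sub = extract_subnetwork(g, res["gene"].tolist())
                export_network(sub, outdir / f"subnetwork_{trend}.graphml", "graphml")
                subnet_counts[trend] = network_summary(sub, config.hub_threshold)
        manifest.counts["survival_genes"] = surv_counts
        manifest.counts["subnetworks"] = subnet_counts
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest.finished = datetime.now(timezone.utc).isoformat()
    manifest.to_json(outdir / "manifest.json")
    return manifest


def manifest_counts(manifest: RunManifest) -> dict:
    """The deterministic part of a manifest (everything except timestamps)."""
    return manifest.counts
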