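"""End-to-end orchestration: ratios -> clustering -> CCCN -> CFN -> PCN -> analyses.

Every stage writes an independently loadable artifact into the output
directory, and a run manifest records the config snapshot, input
checksums, seeds, and per-stage counts so a run can be reproduced
bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from ptmnet import analysis, cccn, cfn, pcn, ptm_io, synthetic

logger = logging.getLogger(__name__)

STAGES = ("ratios", "cluster", "cccn", "cfn", "pcn", "enrich")


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


@dataclass
class PipelineConfig:
    """All inputs, outputs, thresholds and seeds for a pipeline run.

    Defaults match the conventional analysis values: +/-100 ratio cap,
    1.17 log2 drug-effect threshold, -0.5 negative-correlation cutoff,
    >= 2 observations per affected site, >= 3 affected sites per tested
    cluster, alpha 0.05, top-30 GO gene pairs, MST cut at mean + 1 SD.
    """

    out_dir: str = "ptmnet_run"
    ptm_table: str | None = None
    annotation: str | None = None
    ppi: list[str] = field(default_factory=list)
    pathways: str | None = None
    go_map: str | None = None
    groups: dict = field(default_factory=dict)
    cap: float = 100.0
    log2_threshold: float = 1.17
    neg_threshold: float = -0.5
    min_obs: int = 2
    min_affected: int = 3
    alpha: float = 0.05
    top_n: int = 30
    cut_sigma: float = 1.0
    perplexity: float = 30.0
    min_overlap: int = 3
    seeds: dict = field(
        default_factory=lambda: {"euclidean": 42, "spearman": 43, "sed": 44}
    )
    simulate: dict | None = None  # synthetic quick-start parameters

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.cap <= 1:
            raise ConfigError("cap must be > 1")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.top_n < 1:
            raise ConfigError("top_n must be >= 1")
        if self.simulate is None:
            for name in ("ptm_table", "annotation"):
                if getattr(self, name) is None:
                    raise ConfigError(f"config field {name!r} is required")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def export_network(graph: nx.Graph, path: str | Path, fmt: str = "graphml") -> None:
    """Write a graph as GraphML or paired node/edge TSVs.

    Non-scalar attributes (e.g. provenance tuples) are serialized as
    ';'-joined strings; attribute names are stable across versions.
    """
    path = Path(path)
    if fmt == "graphml":
        clean = graph.copy()
        for _, data in clean.nodes(data=True):
            for k, v in list(data.items()):
                if isinstance(v, (tuple, list, set, frozenset)):
                    data[k] = ";".join(map(str, sorted(v) if isinstance(v, (set, frozenset)) else v))
        for _, _, data in clean.edges(data=True):
            for k, v in list(data.items()):
                if isinstance(v, (tuple, list, set, frozenset)):
                    data[k] = ";".join(map(str, sorted(v) if isinstance(v, (set, frozenset)) else v))
        nx.write_graphml(clean, path)
    elif fmt == "tsv":
        nodes = pd.DataFrame(
            [{"node": n, **graph.nodes[n]} for n in graph.nodes]
        )
        edges = pd.DataFrame(
            [{"source": u, "target": v, **d} for u, v, d in graph.edges(data=True)]
        )
        nodes.to_csv(path.with_suffix(".nodes.tsv"), sep="\t", index=False)
        edges.to_csv(path.with_suffix(".edges.tsv"), sep="\t", index=False)
    else:
        raise ValueError(f"unsupported format {fmt!r}; supported: graphml, tsv")


def load_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(path)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return the run manifest (also written to disk).

    A stage failure aborts the run with the failing stage named; outputs
    of completed stages are retained in ``out_dir``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": "0.1.0",
        "config": dataclasses.asdict(config),
        "inputs": {},
        "stages": {},
    }

    if config.simulate is not None:
        sim_cfg = synthetic.SimulationConfig(**config.simulate)
        sim_dir = out / "inputs"
        paths = synthetic.write_all(sim_cfg, sim_dir)
        config.ptm_table = str(paths["ptm_table"])
        config.annotation = str(paths["annotation"])
        config.ppi = [str(paths["ppi"])]
        config.pathways = str(paths["pathways"])
        config.go_map = str(paths["go_map"])
        manifest["config"]["simulate_resolved"] = dataclasses.asdict(sim_cfg)

    for name in ("ptm_table", "annotation", "pathways", "go_map"):
        value = getattr(config, name)
        if value:
            manifest["inputs"][name] = _checksum(Path(value))
    for p in config.ppi:
        manifest["inputs"][f"ppi:{Path(p).name}"] = _checksum(Path(p))

    stage = "ratios"
    try:
        table, annotation = ptm_io.load_ptm_table(config.ptm_table, config.annotation)
        ratio_table = ptm_io.compute_ratios(table, annotation, cap=config.cap)
        ptm_io.write_ratio_table(ratio_table, out / "ratios.tsv")
        groups = ptm_io.define_sample_groups(annotation, config.groups or {})
        if not groups:
            # default: one group per drug over all cell lines
            drugs = sorted(
                annotation.loc[~annotation["is_control"], "drug"].unique()
            )
            groups = ptm_io.define_sample_groups(
                annotation, {f"all.{d}": {"drug": d} for d in drugs}
            )
        manifest["stages"]["ratios"] = {
            "n_sites": len(ratio_table.keys),
            "n_treated_samples": ratio_table.log2_ratios.shape[1],
            "n_groups": len(groups),
        }

        stage = "cluster"
        assignment, partitions = cccn.cluster_pipeline(
            ratio_table,
            seeds=config.seeds,
            perplexity=config.perplexity,
            cut_sigma=config.cut_sigma,
            min_overlap=config.min_overlap,
        )
        assignment.to_frame().to_csv(out / "clusters.tsv", sep="\t", index=False)
        manifest["stages"]["cluster"] = {
            "n_retained": len(assignment.labels),
            "n_clusters": int(assignment.labels.nunique()),
            "seeds": dict(config.seeds),
        }

        stage = "cccn"
        ptm_graph = cccn.build_ptm_cccn(
            assignment,
            ratio_table,
            neg_threshold=config.neg_threshold,
            min_overlap=config.min_overlap,
        )
        export_network(ptm_graph, out / "cccn.graphml")
        protein_net = cccn.collapse_to_protein_cccn(ptm_graph, ratio_table)
        export_network(protein_net.graph, out / "protein_cccn.graphml")
        manifest["stages"]["cccn"] = {
            "n_ptm_nodes": ptm_graph.number_of_nodes(),
            "n_ptm_edges": ptm_graph.number_of_edges(),
            "n_protein_nodes": protein_net.graph.number_of_nodes(),
        }

        stage = "cfn"
        cfn_graph = None
        if config.ppi:
            ppi_net = cfn.load_ppi_edges(config.ppi)
            cfn_graph = cfn.filter_cfn(ppi_net, assignment, ratio_table, groups)
            export_network(cfn_graph, out / "cfn.graphml")
            cores = analysis.kcore_decomposition(cfn_graph)
            cores.rename_axis("gene").to_frame().to_csv(out / "cfn_cores.tsv", sep="\t")
            manifest["stages"]["cfn"] = {
                "n_ppi_edges": len(ppi_net),
                "n_cfn_edges": cfn_graph.number_of_edges(),
                "n_cfn_nodes": cfn_graph.number_of_nodes(),
                "max_core": int(cores.max()) if len(cores) else 0,
            }

        stage = "pcn"
        if config.pathways:
            pathway_sets = pcn.load_pathways(config.pathways)
            go_map = pcn.load_go_map(config.go_map) if config.go_map else {}
            edge_table, summary = pcn.build_pcn(
                assignment,
                pathway_sets,
                go_map,
                ratio_table.keys,
                pcn.PCNConfig(top_n=config.top_n),
            )
            edge_table.to_csv(out / "pcn_edges.tsv", sep="\t", index=False)
            manifest["stages"]["pcn"] = summary

        stage = "enrich"
        enrich_frames = []
        threshold = analysis.threshold_matrix(
            ratio_table, groups, threshold=config.log2_threshold
        )
        threshold.to_csv(out / "threshold_matrix.tsv", sep="\t", index_label="site")
        for grp in groups:
            if len(grp) == 0:
                continue
            affected = ptm_io.affected_site_ids(
                ratio_table, grp, config.min_obs, config.log2_threshold
            )
            affected = [s for s in affected if s in assignment.labels.index]
            result = analysis.cluster_enrichment(
                assignment, affected, config.min_affected, config.alpha
            )
            result.insert(0, "group", grp.name)
            enrich_frames.append(result)
        enrichment = (
            pd.concat(enrich_frames, ignore_index=True)
            if enrich_frames
            else pd.DataFrame()
        )
        enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        manifest["stages"]["enrich"] = {
            "n_tests": len(enrichment),
            "n_significant": int(enrichment["significant"].sum())
            if len(enrichment)
            else 0,
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str)
    )
    return manifest
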