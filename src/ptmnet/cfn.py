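"""Cluster-filtered network (CFN): PPIs filtered by PTM co-clustering.

A merged, provenance-tracked protein-protein interaction edge list is
filtered so that an interaction between proteins A and B survives only
when some PTM of A and some PTM of B fall in the same final CCCN
cluster.  This discards the bulk of the context-free interactome and
keeps the interactions supported by coordinated PTM responses in the
experiment at hand.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from ptmnet.cccn import ClusterAssignment
from ptmnet.ptm_io import RatioTable, SampleGroup

logger = logging.getLogger(__name__)

#: interaction types treated as directed (A acts on B)
DIRECTED_TYPES = frozenset({"kinase-substrate"})


@dataclass
class PPINetwork:
    """Merged PPI edge list.

    Undirected (physical/pathway) edges are stored with endpoints in
    lexicographic order; kinase-substrate edges keep their direction.
    Duplicate rows are merged with provenance union.
    """

    edges: pd.DataFrame  # gene_a, gene_b, interaction_type, sources, weight,
    #                      directed, self_loop

    def __len__(self) -> int:
        return len(self.edges)

    def genes(self) -> set[str]:
        return set(self.edges["gene_a"]) | set(self.edges["gene_b"])


def load_ppi_edges(
    paths: Sequence[str | Path] | str | Path,
    alias_map: dict[str, str] | None = None,
) -> PPINetwork:
    """Read and merge one or more PPI edge-list TSVs.

    Expected columns: geneA, geneB, type, source, weight (header names
    are matched case-insensitively; missing type defaults to
    ``physical``, missing weight to 1.0).  Malformed rows are skipped
    with a logged count.  ``alias_map`` optionally rewrites gene symbols
    before merging.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    records: dict[tuple, dict] = {}
    n_bad = 0
    for path in paths:
        df = pd.read_csv(path, sep="\t", dtype=str)
        cols = {c.lower().replace("_", ""): c for c in df.columns}
        a_col = cols.get("genea", df.columns[0])
        b_col = cols.get("geneb", df.columns[1])
        t_col = cols.get("interactiontype", cols.get("type"))
        s_col = cols.get("source")
        w_col = cols.get("weight")
        for _, row in df.iterrows():
            a, b = row[a_col], row[b_col]
            if pd.isna(a) or pd.isna(b) or not str(a).strip() or not str(b).strip():
                n_bad += 1
                continue
            a, b = str(a).strip().upper(), str(b).strip().upper()
            if alias_map:
                a = alias_map.get(a, a)
                b = alias_map.get(b, b)
            itype = str(row[t_col]) if t_col and pd.notna(row.get(t_col)) else "physical"
            source = str(row[s_col]) if s_col and pd.notna(row.get(s_col)) else str(path)
            try:
                weight = float(row[w_col]) if w_col and pd.notna(row.get(w_col)) else 1.0
            except (TypeError, ValueError):
                n_bad += 1
                continue
            directed = itype in DIRECTED_TYPES
            if not directed and b < a:
                a, b = b, a
            key = (a, b, itype)
            rec = records.setdefault(
                key,
                {
                    "gene_a": a,
                    "gene_b": b,
                    "interaction_type": itype,
                    "sources": set(),
                    "weight": weight,
                    "directed": directed,
                    "self_loop": a == b,
                },
            )
            rec["sources"].add(source)
            rec["weight"] = max(rec["weight"], weight)
    if n_bad:
        logger.warning("skipped %d malformed PPI rows", n_bad)
    edges = pd.DataFrame(records.values()) if records else pd.DataFrame(
        columns=[
            "gene_a",
            "gene_b",
            "interaction_type",
            "sources",
            "weight",
            "directed",
            "self_loop",
        ]
    )
    if len(edges):
        edges["sources"] = edges["sources"].map(lambda s: tuple(sorted(s)))
        edges = edges.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)
    return PPINetwork(edges=edges)


def gene_cluster_map(
    assignment: ClusterAssignment, ratio_table: RatioTable
) -> dict[str, set[int]]:
    """Map each gene to the set of final clusters containing its PTMs.

    Ambiguous PTMs count for every candidate gene in their ambiguity
    group (the most permissive reading of the co-cluster filter).
    """
    key_map = ratio_table.key_map()
    out: dict[str, set[int]] = {}
    for site, cluster in assignment.labels.items():
        for gene in key_map[site].ambiguity_group:
            out.setdefault(gene, set()).add(int(cluster))
    return out


def filter_cfn(
    ppi: PPINetwork,
    assignment: ClusterAssignment,
    ratio_table: RatioTable,
    groups: Iterable[SampleGroup] = (),
) -> nx.Graph:
    """Retain PPI edges between proteins with co-clustered PTMs.

    Nodes are annotated with per-group median PTM log2 changes (median
    over all the gene's PTM ratios in the group's samples).
    """
    if len(assignment.labels) == 0:
        warnings.warn("empty cluster assignment: CFN is empty", stacklevel=2)
        return nx.Graph()
    clusters_of = gene_cluster_map(assignment, ratio_table)
    g = nx.Graph()
    kept = dropped = 0
    for _, row in ppi.edges.iterrows():
        a, b = row["gene_a"], row["gene_b"]
        ca = clusters_of.get(a)
        cb = clusters_of.get(b)
        if ca and cb and ca & cb:
            if g.has_edge(a, b):
                prev = g[a][b]
                prev["sources"] = tuple(sorted(set(prev["sources"]) | set(row["sources"])))
            else:
                g.add_edge(
                    a,
                    b,
                    interaction_type=row["interaction_type"],
                    sources=row["sources"],
                    weight=float(row["weight"]),
                    directed=bool(row["directed"]),
                )
            kept += 1
        else:
            dropped += 1
    logger.info("CFN filter kept %d / %d PPI edges", kept, kept + dropped)

    groups = list(groups)
    if groups:
        key_map = ratio_table.key_map()
        sites_of: dict[str, list[str]] = {}
        for site in ratio_table.log2_ratios.index:
            for gene in key_map[site].ambiguity_group:
                sites_of.setdefault(gene, []).append(site)
        for node in g.nodes:
            sites = sites_of.get(node, [])
            for grp in groups:
                cols = [
                    s for s in grp.sample_ids if s in ratio_table.log2_ratios.columns
                ]
                vals = ratio_table.log2_ratios.loc[sites, cols].to_numpy().ravel()
                vals = vals[np.isfinite(vals)]
                g.nodes[node][f"median_{grp.name}"] = (
                    float(np.median(vals)) if len(vals) else float("nan")
                )
    return g
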