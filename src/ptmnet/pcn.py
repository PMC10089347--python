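"""Pathway crosstalk network (PCN): scoring pathway pairs by PTM co-clustering.

Three complementary pathway-pair scores are computed:

* **Cluster Pathway Evidence (CPE)** -- for cluster *i* and pathway *j*,

      CPE(i, j) = sum over proteins k in pathway j of
                  n_PTMs(k, i) / (n_pathways(k) * |cluster i|)

  where ``n_PTMs(k, i)`` counts PTMs of protein k in cluster i
  (ambiguous PTMs contribute 1/|ambiguity group| to each candidate),
  ``n_pathways(k)`` is the number of pathways in the full collection
  containing k, and |cluster i| is the cluster size.  The **PTM cluster
  weight** of a pathway pair sums CPE of both pathways over every
  cluster where both are represented, then normalizes by the global
  maximum so weights fall in [0, 1].
* **GO similarity** -- the mean Otsuka-Ochiai (cosine) similarity of GO
  Biological Process term sets over the top-N most similar cross-pathway
  gene pairs (N=30 by default), after removing shared genes.
* **Jaccard similarity** of the pathway gene sets.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ptmnet.cccn import ClusterAssignment
from ptmnet.ptm_io import PTMKey

logger = logging.getLogger(__name__)


@dataclass
class PCNConfig:
    top_n: int = 30  # gene pairs averaged in pathway GO similarity
    keep_zero_weight: bool = False
    one_to_one: bool = False  # greedy matching variant of GO similarity

    def __post_init__(self) -> None:
        if self.top_n < 1:
            raise ValueError(f"top_n must be >= 1, got {self.top_n}")


def load_pathways(gmt_path: str | Path) -> dict[str, set[str]]:
    """Read pathway gene sets from a GMT file (name, description, genes...)."""
    pathways: dict[str, set[str]] = {}
    with open(gmt_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                if line.strip():
                    warnings.warn(
                        f"{gmt_path}:{lineno}: skipping pathway with empty gene set",
                        stacklevel=2,
                    )
                continue
            name = parts[0]
            genes = {g.strip().upper() for g in parts[2:] if g.strip()}
            if not genes:
                warnings.warn(
                    f"{gmt_path}:{lineno}: skipping pathway {name!r} with empty gene set",
                    stacklevel=2,
                )
                continue
            if name in pathways:
                raise ValueError(f"duplicate pathway name: {name!r}")
            pathways[name] = genes
    return pathways


def load_go_map(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column gene -> GO term TSV (GAF-subset: columns 3 and 5)."""
    go_map: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("!") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 5 and parts[4].startswith("GO:"):
                gene, term = parts[2], parts[4]  # GAF subset
            else:
                gene, term = parts[0], parts[1]
            go_map.setdefault(gene.strip().upper(), set()).add(term.strip())
    return go_map


def cluster_pathway_evidence(
    assignment: ClusterAssignment,
    pathways: Mapping[str, set[str]],
    ptm_keys: Iterable[PTMKey],
) -> pd.DataFrame:
    """CPE matrix (clusters x pathways).

    The pathway count in the denominator is taken over the full loaded
    collection; proteins listed in a pathway but absent from the data
    contribute zero.
    """
    if len(assignment.labels) == 0:
        raise ValueError("empty cluster assignment")
    keys = {k.site_id: k for k in ptm_keys}
    cluster_ids = sorted(assignment.labels.unique())
    cluster_pos = {c: i for i, c in enumerate(cluster_ids)}
    sizes = assignment.labels.value_counts()

    pathway_count: dict[str, int] = {}
    for genes in pathways.values():
        for g in genes:
            pathway_count[g] = pathway_count.get(g, 0) + 1

    # per-gene, per-cluster PTM counts with ambiguity down-weighting
    gene_cluster: dict[str, np.ndarray] = {}
    for site, cluster in assignment.labels.items():
        key = keys.get(site)
        if key is None:
            raise KeyError(f"assignment references unknown PTM {site!r}")
        share = 1.0 / len(key.ambiguity_group)
        for gene in key.ambiguity_group:
            vec = gene_cluster.setdefault(gene, np.zeros(len(cluster_ids)))
            vec[cluster_pos[cluster]] += share

    names = list(pathways)
    cpe = np.zeros((len(cluster_ids), len(names)))
    size_vec = np.array([sizes[c] for c in cluster_ids], dtype=float)
    for j, name in enumerate(names):
        for gene in pathways[name]:
            vec = gene_cluster.get(gene)
            if vec is None:
                continue
            cpe[:, j] += vec / (pathway_count[gene] * size_vec)
    return pd.DataFrame(cpe, index=cluster_ids, columns=names)


def ptm_cluster_weight(
    cpe: pd.DataFrame, keep_zero: bool = False
) -> pd.DataFrame:
    """Pathway-pair edge table with raw CPE sums and normalized weights.

    For each pathway pair the raw weight sums CPE(cluster, A) +
    CPE(cluster, B) over every cluster where both pathways have nonzero
    CPE; normalized weights divide by the global maximum raw weight.
    """
    A = cpe.to_numpy()
    I = (A > 0).astype(float)
    # raw[p, q] = sum_c I[c,p] I[c,q] (A[c,p] + A[c,q]); A is 0 wherever I is 0
    raw = A.T @ I + I.T @ A
    names = list(cpe.columns)
    order = np.argsort(names)
    rows = []
    for ii in range(len(names)):
        for jj in range(ii + 1, len(names)):
            p, q = order[ii], order[jj]
            r = raw[p, q]
            if r > 0 or keep_zero:
                rows.append((names[p], names[q], float(r)))
    table = pd.DataFrame(rows, columns=["pathway_a", "pathway_b", "raw_cpe_sum"])
    if len(table) == 0 or table["raw_cpe_sum"].max() == 0:
        if len(table) == 0:
            warnings.warn("all CPE values are zero: empty PCN edge table", stacklevel=2)
        table["ptm_cluster_weight"] = 0.0
        return table
    table["ptm_cluster_weight"] = table["raw_cpe_sum"] / table["raw_cpe_sum"].max()
    return table


def shared_cluster_evidence(
    cpe: pd.DataFrame, pathway_a: str, pathway_b: str
) -> pd.Series:
    """Per-cluster CPE(A) + CPE(B) over clusters where both are represented."""
    a = cpe[pathway_a]
    b = cpe[pathway_b]
    both = (a > 0) & (b > 0)
    return (a + b)[both]


def gene_go_similarity(
    gene_a: str, gene_b: str, go_map: Mapping[str, set[str]]
) -> float:
    """Otsuka-Ochiai (cosine) similarity of two genes' GO term sets."""
    sa = go_map.get(gene_a, set())
    sb = go_map.get(gene_b, set())
    if not sa or not sb:
        return 0.0
    return len(sa & sb) / math.sqrt(len(sa) * len(sb))


def pathway_go_similarity(
    genes_a: set[str],
    genes_b: set[str],
    go_map: Mapping[str, set[str]],
    top_n: int = 30,
    one_to_one: bool = False,
) -> float:
    """Mean gene GO similarity over the top-N cross-pathway gene pairs.

    Shared genes are removed from both sets first, so the score reflects
    annotation similarity of *distinct* genes.  With fewer than ``top_n``
    cross pairs, all pairs are averaged.  ``one_to_one`` greedily matches
    each gene at most once instead of ranking raw pairs.
    """
    shared = genes_a & genes_b
    a = sorted(genes_a - shared)
    b = sorted(genes_b - shared)
    if not a or not b:
        return 0.0
    sims = [
        (gene_go_similarity(ga, gb, go_map), ga, gb) for ga in a for gb in b
    ]
    sims.sort(key=lambda t: (-t[0], t[1], t[2]))
    if one_to_one:
        used_a: set[str] = set()
        used_b: set[str] = set()
        chosen = []
        for s, ga, gb in sims:
            if ga in used_a or gb in used_b:
                continue
            chosen.append(s)
            used_a.add(ga)
            used_b.add(gb)
            if len(chosen) == top_n:
                break
        values = chosen
    else:
        values = [s for s, _, _ in sims[:top_n]]
    return float(np.mean(values)) if values else 0.0


def pathway_jaccard(genes_a: set[str], genes_b: set[str]) -> float:
    """|A n B| / |A u B|."""
    union = genes_a | genes_b
    if not union:
        return 0.0
    return len(genes_a & genes_b) / len(union)


def build_pcn(
    assignment: ClusterAssignment,
    pathways: Mapping[str, set[str]],
    go_map: Mapping[str, set[str]],
    ptm_keys: Iterable[PTMKey],
    config: PCNConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Build the full PCN edge table and its summary statistics.

    Nodes are pathways with at least one PTM-bearing protein in the
    data; edges are pathway pairs with nonzero PTM cluster weight
    (unless ``keep_zero_weight``).  Density is edges / C(n, 2).
    """
    config = config or PCNConfig()
    ptm_keys = list(ptm_keys)
    observed_genes: set[str] = set()
    for k in ptm_keys:
        observed_genes.update(k.ambiguity_group)
    nodes = {
        name for name, genes in pathways.items() if genes & observed_genes
    }
    cpe = cluster_pathway_evidence(assignment, pathways, ptm_keys)
    table = ptm_cluster_weight(cpe[sorted(nodes)], keep_zero=config.keep_zero_weight)
    go_sims = []
    jaccards = []
    for _, row in table.iterrows():
        ga, gb = pathways[row["pathway_a"]], pathways[row["pathway_b"]]
        go_sims.append(
            pathway_go_similarity(
                ga, gb, go_map, top_n=config.top_n, one_to_one=config.one_to_one
            )
        )
        jaccards.append(pathway_jaccard(ga, gb))
    table["go_sim"] = go_sims
    table["jaccard"] = jaccards
    n = len(nodes)
    possible = n * (n - 1) // 2
    summary = {
        "n_pathways_loaded": len(pathways),
        "n_nodes": n,
        "n_edges": len(table),
        "n_possible_edges": possible,
        "density": len(table) / possible if possible else float("nan"),
    }
    return table, summary


def pcn_density(n_nodes: int, n_edges: int) -> float:
    """Edge density over C(n, 2) possible pathway pairs."""
    possible = n_nodes * (n_nodes - 1) // 2
    if possible == 0:
        raise ValueError("density undefined for fewer than 2 nodes")
    return n_edges / possible


def filter_pcn(
    edge_table: pd.DataFrame,
    weight_min: float | None = None,
    jaccard_max: float | None = None,
    jaccard_min: float | None = None,
) -> pd.DataFrame:
    """Threshold the PCN edge table (bounds are combined with AND).

    ``weight_min`` keeps rows with PTM cluster weight strictly above the
    bound; ``jaccard_max`` keeps rows at or below (``jaccard_max=0``
    keeps only zero-overlap pairs); ``jaccard_min`` keeps rows strictly
    above.
    """
    if (
        jaccard_min is not None
        and jaccard_max is not None
        and jaccard_min > jaccard_max
    ):
        warnings.warn("contradictory Jaccard bounds: empty table", stacklevel=2)
        return edge_table.iloc[0:0]
    mask = pd.Series(True, index=edge_table.index)
    if weight_min is not None:
        mask &= edge_table["ptm_cluster_weight"] > weight_min
    if jaccard_max is not None:
        mask &= edge_table["jaccard"] <= jaccard_max
    if jaccard_min is not None:
        mask &= edge_table["jaccard"] > jaccard_min
    return edge_table.loc[mask]
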