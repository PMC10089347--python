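"""Downstream analyses on CCCN/CFN graphs.

Cluster enrichment for drug-affected PTMs (one-sided Fisher exact test
with Benjamini-Hochberg correction), composite shortest-path subnetworks
between two pathway gene sets, "mutual friends" intermediates, k-core
decomposition with cross-network core comparison, and the -1/0/+1
threshold matrices used for cluster heatmaps.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ptmnet.cccn import ClusterAssignment
from ptmnet.ptm_io import RatioTable, SampleGroup

logger = logging.getLogger(__name__)


def cluster_enrichment(
    assignment: ClusterAssignment,
    affected_sites: Iterable[str],
    min_affected: int = 3,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test clusters for over-representation of drug-affected PTMs.

    For each cluster with at least ``min_affected`` affected sites a 2x2
    contingency table (affected/unaffected x in/out of cluster) is
    tested with a one-sided Fisher exact test for enrichment; p-values
    are BH-corrected across the tested clusters.
    """
    affected = set(affected_sites)
    unknown = affected - set(assignment.labels.index)
    if unknown:
        raise ValueError(
            f"affected sites not in the cluster assignment: {sorted(unknown)[:5]}"
        )
    total = len(assignment.labels)
    n_affected_total = len(affected)
    rows = []
    for cid, members in assignment.clusters().items():
        in_cluster = set(members)
        a = len(in_cluster & affected)
        if a < min_affected:
            continue
        b = n_affected_total - a  # affected elsewhere
        c = len(in_cluster) - a  # unaffected in cluster
        d = total - a - b - c  # unaffected elsewhere
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append((cid, a, b, c, d, p))
    if not rows:
        warnings.warn(
            f"no cluster has >= {min_affected} affected sites", stacklevel=2
        )
        return pd.DataFrame(
            columns=[
                "cluster",
                "affected_in",
                "affected_out",
                "unaffected_in",
                "unaffected_out",
                "p_value",
                "p_adjusted",
                "significant",
            ]
        )
    result = pd.DataFrame(
        rows,
        columns=[
            "cluster",
            "affected_in",
            "affected_out",
            "unaffected_in",
            "unaffected_out",
            "p_value",
        ],
    )
    _, adjusted, _, _ = multipletests(result["p_value"], method="fdr_bh")
    result["p_adjusted"] = adjusted
    result["significant"] = result["p_adjusted"] < alpha
    return result.sort_values("p_adjusted", kind="stable").reset_index(drop=True)


def composite_shortest_paths(
    graph: nx.Graph,
    set_a: Iterable[str],
    set_b: Iterable[str],
    weight: str | None = None,
) -> tuple[nx.Graph, int]:
    """Union of all shortest paths between two gene sets.

    Every (a, b) cross pair contributes all of its shortest paths
    (unweighted by default); the returned subgraph is the union of their
    nodes and edges.  Returns the subgraph and the number of unreachable
    cross pairs.
    """
    a_nodes = sorted(set(set_a) & set(graph.nodes))
    b_nodes = sorted(set(set_b) & set(graph.nodes))
    if not a_nodes or not b_nodes:
        raise ValueError("both gene sets must intersect the graph's nodes")
    sub = nx.Graph()
    skipped = 0
    for a in a_nodes:
        for b in b_nodes:
            if a == b:
                continue
            try:
                paths = nx.all_shortest_paths(graph, a, b, weight=weight)
                for path in paths:
                    nx.add_path(sub, path)
            except nx.NetworkXNoPath:
                skipped += 1
    if skipped:
        logger.info("composite_shortest_paths: %d unreachable pairs", skipped)
    for n in sub.nodes:
        sub.nodes[n].update(graph.nodes[n])
    for u, v in sub.edges:
        sub[u][v].update(graph[u][v])
    return sub, skipped


def mutual_friends(
    graph: nx.Graph, set_a: Iterable[str], set_b: Iterable[str]
) -> set[str]:
    """Nodes outside both sets adjacent to >= 1 member of each set."""
    a = set(set_a)
    b = set(set_b)
    friends = set()
    for node in graph.nodes:
        if node in a or node in b:
            continue
        neighbors = set(graph.neighbors(node))
        if neighbors & a and neighbors & b:
            friends.add(node)
    return friends


def simplify_graph(graph: nx.Graph) -> nx.Graph:
    """Drop self loops and collapse duplicate edges between vertex pairs."""
    simple = nx.Graph(graph)  # collapses multi-edges if graph is a multigraph
    simple.remove_edges_from(nx.selfloop_edges(simple))
    return simple


def kcore_decomposition(graph: nx.Graph) -> pd.Series:
    """Core number per node via iterative peeling of the simplified graph."""
    simple = simplify_graph(graph)
    cores = nx.core_number(simple)
    return pd.Series(cores, name="core", dtype=int).sort_index()


def core_overlap(
    cores_a: pd.Series,
    cores_b: pd.Series,
    high_a: tuple[int, int],
    high_b: tuple[int, int],
) -> tuple[pd.DataFrame, set[str]]:
    """Cross-tabulate core membership of two networks; extract the common core.

    Returns the matrix of |{genes with core i in A} n {genes with core j
    in B}| and the set of genes inside the designated high-core ranges
    of both networks.
    """
    levels_a = sorted(cores_a.unique())
    levels_b = sorted(cores_b.unique())
    matrix = pd.DataFrame(0, index=levels_a, columns=levels_b)
    shared = set(cores_a.index) & set(cores_b.index)
    for gene in shared:
        matrix.loc[cores_a[gene], cores_b[gene]] += 1
    lo_a, hi_a = high_a
    lo_b, hi_b = high_b
    common = {
        g
        for g in shared
        if lo_a <= cores_a[g] <= hi_a and lo_b <= cores_b[g] <= hi_b
    }
    return matrix, common


def threshold_matrix(
    ratio_table: RatioTable,
    groups: Sequence[SampleGroup],
    threshold: float = 1.17,
    min_obs: int = 1,
) -> pd.DataFrame:
    """Sites x sample-groups matrix over {-1, 0, +1}.

    +1 where the group median log2 ratio exceeds ``threshold``, -1 where
    it is below ``-threshold``, 0 otherwise (including all-missing
    rows).  Rows are ordered by descending row sum, ties broken
    lexicographically by site id.
    """
    cols = {}
    for grp in groups:
        med = ratio_table.group_median(grp.sample_ids)
        n_obs = ratio_table.n_observed(grp.sample_ids)
        sign = pd.Series(0, index=med.index, dtype=int)
        ok = n_obs >= min_obs
        sign[ok & (med > threshold)] = 1
        sign[ok & (med < -threshold)] = -1
        cols[grp.name] = sign
    matrix = pd.DataFrame(cols)
    order = sorted(
        matrix.index, key=lambda site: (-matrix.loc[site].sum(), site)
    )
    return matrix.loc[order]


def path_network_similarity(
    subgraphs: Mapping[str, nx.Graph] | Sequence[nx.Graph],
) -> pd.DataFrame:
    """Pairwise Jaccard similarity of subnetwork node sets."""
    if isinstance(subgraphs, Mapping):
        names = list(subgraphs)
        node_sets = [set(subgraphs[n].nodes) for n in names]
    else:
        names = [f"network_{i}" for i in range(len(subgraphs))]
        node_sets = [set(g.nodes) for g in subgraphs]
    if len(names) < 2:
        raise ValueError("need at least 2 subgraphs to compare")
    n = len(names)
    out = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            union = node_sets[i] | node_sets[j]
            jac = len(node_sets[i] & node_sets[j]) / len(union) if union else 0.0
            out[i, j] = out[j, i] = jac
    return pd.DataFrame(out, index=names, columns=names)


def plot_threshold_heatmap(matrix: pd.DataFrame, path: str | None = None):
    """Minimal heatmap of a -1/0/+1 threshold matrix (blue/black/yellow)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    fig, ax = plt.subplots(
        figsize=(max(3, 0.5 * matrix.shape[1]), max(3, 0.12 * matrix.shape[0]))
    )
    cmap = ListedColormap(["#2166ac", "#111111", "#ffd700"])
    ax.imshow(matrix.to_numpy(), cmap=cmap, vmin=-1, vmax=1, aspect="auto")
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=90, fontsize=7)
    ax.set_yticks([])
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
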