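"""Co-cluster correlation network (CCCN) construction.

PTM response profiles are compared under three dissimilarity metrics --
pairwise-complete Euclidean distance, Spearman dissimilarity, and a
hybrid Spearman-Euclidean dissimilarity (SED) -- each embedded into
three dimensions with Barnes-Hut t-SNE.  Clusters are cut from the
Euclidean minimum spanning tree of each embedding, and the final
partition is the common refinement (intersection) of the three
embedding-level partitions: two PTMs co-cluster only if they co-cluster
in all three embeddings.

The CCCN graph joins co-clustered PTMs with Spearman-correlation-
weighted edges and additionally records strongly negative correlations
(< -0.5 by default) between different PTM types on the same protein,
the signature of reciprocally antagonistic modification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import TSNE

from ptmnet.ptm_io import RatioTable

logger = logging.getLogger(__name__)

METRICS = ("euclidean", "spearman", "sed")


@dataclass
class DissimilarityMatrix:
    metric: str
    values: pd.DataFrame  # square, symmetric, zero diagonal

    @property
    def index(self) -> pd.Index:
        return self.values.index


@dataclass
class Embedding:
    metric: str
    coordinates: pd.DataFrame  # PTMs x 3
    seed: int
    perplexity: float


@dataclass
class ClusterAssignment:
    """Final PTM partition (intersection of the three embeddings)."""

    labels: pd.Series  # site_id -> cluster id (int)

    @property
    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    def clusters(self) -> dict[int, list[str]]:
        return {
            int(cid): list(members.index)
            for cid, members in self.labels.groupby(self.labels)
        }

    def to_frame(self) -> pd.DataFrame:
        return self.labels.rename("cluster").rename_axis("site").reset_index()


def retained_sites(ratio_table: RatioTable, min_samples: int = 2) -> pd.Index:
    """Sites observed (finite ratio) in at least ``min_samples`` samples."""
    counts = ratio_table.log2_ratios.notna().sum(axis=1)
    dropped = int((counts < min_samples).sum())
    if dropped:
        logger.info(
            "excluding %d sites observed in fewer than %d samples",
            dropped,
            min_samples,
        )
    return ratio_table.log2_ratios.index[counts >= min_samples]


def _pairwise_complete_euclidean(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Euclidean distance over shared finite entries, scaled to the full
    sample count (R ``dist`` convention).  Returns (distances, overlap counts).
    """
    mask = np.isfinite(X)
    Xz = np.where(mask, X, 0.0)
    M = mask.astype(float)
    sq = Xz**2
    # sum over shared positions of xi^2, xj^2 and xi*xj
    s_ii = sq @ M.T
    cross = Xz @ Xz.T
    d2 = s_ii + s_ii.T - 2.0 * cross
    counts = M @ M.T
    m = X.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        d2 = np.where(counts > 0, d2 * (m / counts), np.nan)
    d2 = np.clip(d2, 0.0, None)
    return np.sqrt(d2), counts


def spearman_correlation(
    ratios: pd.DataFrame, min_overlap: int = 3
) -> pd.DataFrame:
    """Pairwise-complete Spearman correlation between PTM profiles.

    Pairs sharing fewer than ``min_overlap`` finite samples are NaN.
    """
    return ratios.T.corr(method="spearman", min_periods=min_overlap)


def dissimilarity_matrices(
    ratio_table: RatioTable,
    min_overlap: int = 3,
    min_samples: int = 2,
) -> dict[str, DissimilarityMatrix]:
    """Compute the Euclidean, Spearman, and SED dissimilarity matrices.

    Spearman dissimilarity is (1 - rho) / 2 in [0, 1].  SED is
    sqrt(E_norm * spearman_dis) with the Euclidean matrix normalized by
    its finite maximum, combining magnitude and rank-shape information
    in [0, 1].  Pairs with fewer than ``min_overlap`` shared
    observations are set to the matrix maximum so they never look close.
    """
    idx = retained_sites(ratio_table, min_samples)
    if len(idx) < 2:
        raise ValueError("need at least 2 retained PTMs to compute dissimilarities")
    ratios = ratio_table.log2_ratios.loc[idx]
    X = ratios.to_numpy(dtype=float)

    eu, counts = _pairwise_complete_euclidean(X)
    rho = spearman_correlation(ratios, min_overlap).to_numpy()
    sp = (1.0 - rho) / 2.0

    degenerate = counts < min_overlap
    out: dict[str, DissimilarityMatrix] = {}
    for name, mat in (("euclidean", eu), ("spearman", sp)):
        m = mat.copy()
        invalid = degenerate | ~np.isfinite(m)
        np.fill_diagonal(invalid, False)
        finite_max = np.nanmax(np.where(invalid, np.nan, m))
        if not np.isfinite(finite_max):
            raise ValueError("no valid PTM pairs; cannot build dissimilarities")
        m[invalid] = finite_max
        np.fill_diagonal(m, 0.0)
        m = (m + m.T) / 2.0
        out[name] = DissimilarityMatrix(
            metric=name, values=pd.DataFrame(m, index=idx, columns=idx)
        )

    e_norm = out["euclidean"].values.to_numpy()
    emax = e_norm.max()
    if emax > 0:
        e_norm = e_norm / emax
    sed = np.sqrt(e_norm * out["spearman"].values.to_numpy())
    np.fill_diagonal(sed, 0.0)
    out["sed"] = DissimilarityMatrix(
        metric="sed", values=pd.DataFrame(sed, index=idx, columns=idx)
    )
    return out


def embed_tsne(
    dissimilarity: DissimilarityMatrix,
    seed: int,
    perplexity: float = 30.0,
) -> Embedding:
    """3D Barnes-Hut t-SNE on a precomputed dissimilarity matrix."""
    n = len(dissimilarity.index)
    limit = (n - 1) / 3.0
    if perplexity >= limit:
        suggested = max(1.0, np.floor(limit) - 1.0)
        raise ValueError(
            f"perplexity {perplexity} infeasible for n={n}; "
            f"must be < (n-1)/3 = {limit:.1f} (try {suggested:g})"
        )
    tsne = TSNE(
        n_components=3,
        metric="precomputed",
        init="random",
        random_state=seed,
        perplexity=perplexity,
        method="barnes_hut",
    )
    coords = tsne.fit_transform(dissimilarity.values.to_numpy())
    return Embedding(
        metric=dissimilarity.metric,
        coordinates=pd.DataFrame(
            coords, index=dissimilarity.index, columns=["x", "y", "z"]
        ),
        seed=seed,
        perplexity=perplexity,
    )


def mst_clusters(embedding: Embedding, cut_sigma: float = 1.0) -> pd.Series:
    """Cluster embedded points by cutting long minimum-spanning-tree edges.

    The Euclidean MST over the embedded coordinates is built, edges
    longer than mean + ``cut_sigma`` * SD of the MST edge lengths are
    removed, and clusters are the resulting connected components.
    """
    coords = embedding.coordinates.to_numpy()
    n = len(coords)
    if n < 2:
        raise ValueError("need at least 2 points to cluster")
    dist = squareform(pdist(coords))
    # shift by a tiny epsilon and hand csgraph an explicitly sparse
    # matrix: zero entries mean "no edge" there, but coincident points
    # (distance 0) must stay connected in the tree
    eps = max(dist.max(), 1.0) * 1e-12
    shifted = dist + eps
    np.fill_diagonal(shifted, 0.0)
    mst = minimum_spanning_tree(coo_matrix(shifted)).tocoo()
    lengths = mst.data - eps
    cutoff = lengths.mean() + cut_sigma * lengths.std()
    keep = lengths <= cutoff
    adj = coo_matrix(
        (np.ones(int(keep.sum())), (mst.row[keep], mst.col[keep])), shape=(n, n)
    )
    _, labels = connected_components(adj, directed=False)
    return pd.Series(labels, index=embedding.coordinates.index, name=embedding.metric)


def intersect_partitions(*partitions: pd.Series) -> ClusterAssignment:
    """Common refinement of embedding-level partitions.

    Two PTMs receive the same final cluster id iff they share a cluster
    in every input partition; ids are dense integers ordered by first
    appearance.
    """
    if len(partitions) < 1:
        raise ValueError("need at least one partition")
    first = partitions[0].index
    for p in partitions[1:]:
        if not first.equals(p.index):
            raise ValueError("partitions must share an identical PTM index")
    combo = pd.MultiIndex.from_arrays([p.to_numpy() for p in partitions])
    codes, _ = pd.factorize(combo)
    return ClusterAssignment(labels=pd.Series(codes, index=first, name="cluster"))


def build_ptm_cccn(
    assignment: ClusterAssignment,
    ratio_table: RatioTable,
    neg_threshold: float = -0.5,
    min_overlap: int = 3,
) -> nx.Graph:
    """Build the PTM-level CCCN graph.

    Co-cluster edges form a clique within each final cluster, weighted
    by pairwise-complete Spearman correlation (0 when fewer than
    ``min_overlap`` shared samples).  Negative cross-type edges join
    different PTM types on the same protein whenever their correlation
    falls below ``neg_threshold``, regardless of cluster membership.
    """
    idx = assignment.labels.index
    key_map = ratio_table.key_map()
    ratios = ratio_table.log2_ratios.loc[idx]
    rho = spearman_correlation(ratios, min_overlap)

    g = nx.Graph()
    for site in idx:
        key = key_map[site]
        g.add_node(
            site,
            protein=key.protein,
            mod_type=key.mod_type,
            cluster=int(assignment.labels[site]),
        )

    for members in assignment.clusters().values():
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                w = rho.at[a, b]
                g.add_edge(
                    a,
                    b,
                    weight=float(w) if np.isfinite(w) else 0.0,
                    edge_type="co-cluster",
                )

    # reciprocally antagonistic cross-type edges on the same protein
    by_protein: dict[str, list[str]] = {}
    for site in idx:
        by_protein.setdefault(key_map[site].protein, []).append(site)
    for sites in by_protein.values():
        for i, a in enumerate(sites):
            for b in sites[i + 1 :]:
                if key_map[a].mod_type == key_map[b].mod_type:
                    continue
                w = rho.at[a, b]
                if np.isfinite(w) and w < neg_threshold:
                    if g.has_edge(a, b):
                        g[a][b]["negative_cross_type"] = True
                    else:
                        g.add_edge(
                            a,
                            b,
                            weight=float(w),
                            edge_type="negative-cross-type",
                        )
    return g


@dataclass
class ProteinCCCN:
    """Protein-level collapse of the PTM CCCN."""

    graph: nx.Graph
    node_values: pd.DataFrame  # genes x samples, summed PTM log2 ratios


def collapse_to_protein_cccn(
    cccn: nx.Graph,
    ratio_table: RatioTable,
    min_experiments: int = 2,
    missing_as_zero: bool = True,
) -> ProteinCCCN:
    """Merge co-clustered PTMs into protein (gene) nodes.

    Per-sample node values are the sum of member PTM log2 ratios
    (missing treated as 0 by default); gene-gene edge weights are the
    sum of co-cluster edge weights between their PTMs.  Genes whose PTMs
    were observed in fewer than ``min_experiments`` samples are dropped.
    """
    sites = [n for n in cccn.nodes]
    gene_of = {n: cccn.nodes[n]["protein"] for n in sites}
    ratios = ratio_table.log2_ratios.loc[sites]

    gene_index = pd.Series({s: gene_of[s] for s in sites})
    # "detected in >= min_experiments samples": samples where any member
    # PTM of the gene has a finite ratio
    n_samples_per_gene = (
        ratios.notna().groupby(gene_index).sum().gt(0).sum(axis=1)
    )
    kept_genes = set(n_samples_per_gene.index[n_samples_per_gene >= min_experiments])

    filled = ratios.fillna(0.0) if missing_as_zero else ratios
    sums = filled.groupby(gene_index).sum(min_count=0 if missing_as_zero else 1)
    node_values = sums.loc[sorted(kept_genes)]

    g = nx.Graph()
    for gene in node_values.index:
        g.add_node(gene, total=float(node_values.loc[gene].sum()))
    for a, b, data in cccn.edges(data=True):
        if data.get("edge_type") != "co-cluster":
            continue
        ga, gb = gene_of[a], gene_of[b]
        if ga == gb or ga not in kept_genes or gb not in kept_genes:
            continue
        w = data.get("weight", 0.0)
        if g.has_edge(ga, gb):
            g[ga][gb]["weight"] += w
        else:
            g.add_edge(ga, gb, weight=w)
    return ProteinCCCN(graph=g, node_values=node_values)


def cluster_pipeline(
    ratio_table: RatioTable,
    seeds: dict[str, int] | None = None,
    perplexity: float = 30.0,
    cut_sigma: float = 1.0,
    min_overlap: int = 3,
) -> tuple[ClusterAssignment, dict[str, pd.Series]]:
    """Dissimilarities -> three embeddings -> MST cuts -> intersection."""
    seeds = seeds or {"euclidean": 42, "spearman": 43, "sed": 44}
    dissims = dissimilarity_matrices(ratio_table, min_overlap=min_overlap)
    partitions: dict[str, pd.Series] = {}
    for metric in METRICS:
        emb = embed_tsne(dissims[metric], seed=seeds[metric], perplexity=perplexity)
        partitions[metric] = mst_clusters(emb, cut_sigma=cut_sigma)
    assignment = intersect_partitions(*[partitions[m] for m in METRICS])
    return assignment, partitions
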