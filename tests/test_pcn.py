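"""Cluster Pathway Evidence, PTM cluster weight, GO and Jaccard similarity."""

import numpy as np
import pandas as pd
import pytest

from ptmnet import cccn, pcn, ptm_io


def brute_force_cpe(labels, pathways, keys):
    """Triple loop over clusters x pathways x proteins, straight from the
    definition; independent of the vectorized implementation."""
    key_of = {k.site_id: k for k in keys}
    cluster_ids = sorted(set(labels.values()))
    sizes = {c: sum(1 for v in labels.values() if v == c) for c in cluster_ids}
    pathway_count = {}
    for genes in pathways.values():
        for g in genes:
            pathway_count[g] = pathway_count.get(g, 0) + 1
    out = pd.DataFrame(0.0, index=cluster_ids, columns=list(pathways))
    for c in cluster_ids:
        for name, genes in pathways.items():
            total = 0.0
            for gene in genes:
                n_ptms = 0.0
                for site, cl in labels.items():
                    if cl != c:
                        continue
                    key = key_of[site]
                    if gene in key.ambiguity_group:
                        n_ptms += 1.0 / len(key.ambiguity_group)
                if gene in pathway_count and n_ptms:
                    total += n_ptms / (pathway_count[gene] * sizes[c])
            out.loc[c, name] = total
    return out


def random_instance(rng):
    n_clusters = int(rng.integers(1, 21))
    n_pathways = int(rng.integers(1, 11))
    n_genes = int(rng.integers(3, 15))
    genes = [f"G{i}" for i in range(n_genes)]
    keys = []
    labels = {}
    for i in range(int(rng.integers(2, 40))):
        gene = genes[int(rng.integers(n_genes))]
        group = (gene,)
        if rng.random() < 0.3:
            other = genes[int(rng.integers(n_genes))]
            if other != gene:
                group = (gene, other)
        key = ptm_io.PTMKey(gene, i + 1, "Y", "phospho", group)
        keys.append(key)
        labels[key.site_id] = int(rng.integers(n_clusters))
    pathways = {}
    for p in range(n_pathways):
        size = int(rng.integers(1, n_genes + 1))
        pathways[f"P{p}"] = set(rng.choice(genes, size=size, replace=False))
    return labels, pathways, keys


class TestClusterPathwayEvidence:
    def test_two_ptms_in_cluster_of_four_single_pathway(self):
        keys = [ptm_io.PTMKey("A", i, "Y", "phospho") for i in range(1, 3)]
        keys += [ptm_io.PTMKey("B", i, "Y", "phospho") for i in range(1, 3)]
        labels = pd.Series(0, index=[k.site_id for k in keys])
        cpe = pcn.cluster_pathway_evidence(
            cccn.ClusterAssignment(labels=labels), {"P": {"A"}}, keys
        )
        assert cpe.loc[0, "P"] == pytest.approx(0.5)  # 2 / (1 pathway * 4)

    def test_five_pathways_one_ptm_cluster_of_ten(self):
        keys = [ptm_io.PTMKey("A", 1, "Y", "phospho")]
        keys += [ptm_io.PTMKey("X", i, "Y", "phospho") for i in range(1, 10)]
        labels = pd.Series(0, index=[k.site_id for k in keys])
        pathways = {f"P{i}": {"A"} for i in range(5)}
        cpe = pcn.cluster_pathway_evidence(
            cccn.ClusterAssignment(labels=labels), pathways, keys
        )
        assert cpe.loc[0, "P0"] == pytest.approx(0.02)  # 1 / (5 * 10)

    def test_ambiguous_ptm_contributes_half_to_each_candidate(self):
        keys = [ptm_io.PTMKey("A", 1, "Y", "phospho", ("A", "B"))]
        keys += [ptm_io.PTMKey("C", i, "Y", "phospho") for i in range(1, 4)]
        labels = pd.Series(0, index=[k.site_id for k in keys])
        cpe = pcn.cluster_pathway_evidence(
            cccn.ClusterAssignment(labels=labels),
            {"PA": {"A"}, "PB": {"B"}},
            keys,
        )
        assert cpe.loc[0, "PA"] == pytest.approx(0.5 / (1 * 4))
        assert cpe.loc[0, "PB"] == pytest.approx(0.5 / (1 * 4))

    def test_absent_protein_contributes_zero(self):
        keys = [ptm_io.PTMKey("A", 1, "Y", "phospho")]
        labels = pd.Series(0, index=[k.site_id for k in keys])
        cpe = pcn.cluster_pathway_evidence(
            cccn.ClusterAssignment(labels=labels), {"P": {"NOTSEEN"}}, keys
        )
        assert cpe.loc[0, "P"] == 0.0

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        labels, pathways, keys = random_instance(rng)
        expected = brute_force_cpe(labels, pathways, keys)
        got = pcn.cluster_pathway_evidence(
            cccn.ClusterAssignment(labels=pd.Series(labels)), pathways, keys
        )
        got = got.reindex(index=expected.index, fill_value=0.0)
        assert np.allclose(got.to_numpy(), expected.to_numpy(), atol=1e-12)


class TestPTMClusterWeight:
    def test_pair_without_shared_cluster_omitted(self):
        cpe = pd.DataFrame({"A": [1.0, 0.0], "B": [0.0, 1.0], "C": [1.0, 1.0]})
        table = pcn.ptm_cluster_weight(cpe)
        pairs = set(zip(table.pathway_a, table.pathway_b))
        assert ("A", "B") not in pairs
        assert {("A", "C"), ("B", "C")} <= pairs

    def test_maximum_pair_normalizes_to_one(self):
        cpe = pd.DataFrame({"A": [0.5, 0.5], "B": [0.5, 0.1], "C": [0.01, 0.0]})
        table = pcn.ptm_cluster_weight(cpe)
        assert table.ptm_cluster_weight.max() == pytest.approx(1.0)
        assert (table.ptm_cluster_weight <= 1.0).all()
        assert (table.ptm_cluster_weight > 0.0).all()

    def test_raw_sum_over_shared_clusters(self):
        cpe = pd.DataFrame({"A": [0.2, 0.3, 0.0], "B": [0.1, 0.0, 0.5]})
        table = pcn.ptm_cluster_weight(cpe)
        # only cluster 0 has both pathways; raw = 0.2 + 0.1
        assert table.raw_cpe_sum.iloc[0] == pytest.approx(0.3)

    def test_all_zero_cpe_warns_empty(self):
        cpe = pd.DataFrame({"A": [0.0], "B": [0.0]})
        with pytest.warns(UserWarning, match="empty"):
            table = pcn.ptm_cluster_weight(cpe)
        assert len(table) == 0


class TestGeneGOSimilarity:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({"t1", "t2"}, {"t1", "t2"}, 1.0),
            ({"t1"}, {"t2"}, 0.0),
            ({"t1", "t2", "t3", "t4"}, {"t1", "t2", "t5", "t6"}, 0.5),
            (set(), {"t1"}, 0.0),
        ],
    )
    def test_ochiai_examples(self, a, b, expected):
        go_map = {"ga": a, "gb": b}
        assert pcn.gene_go_similarity("ga", "gb", go_map) == pytest.approx(expected)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(0)
        universe = [f"t{i}" for i in range(10)]
        for _ in range(30):
            go_map = {
                "a": set(rng.choice(universe, rng.integers(0, 8), replace=False)),
                "b": set(rng.choice(universe, rng.integers(0, 8), replace=False)),
            }
            s_ab = pcn.gene_go_similarity("a", "b", go_map)
            s_ba = pcn.gene_go_similarity("b", "a", go_map)
            assert s_ab == s_ba
            assert 0.0 <= s_ab <= 1.0
            if s_ab == 1.0:
                assert go_map["a"] == go_map["b"]


class TestPathwayGOSimilarity:
    def test_no_genes_left_after_intersection_removal(self):
        go_map = {"a": {"t"}, "b": {"t"}}
        assert pcn.pathway_go_similarity({"a"}, {"a", "b"}, go_map) == 0.0

    def test_fewer_pairs_than_top_n_averages_all(self):
        go_map = {
            "a1": {"t1", "t2", "x1", "x2", "x3"},
            "a2": {"t1", "t2", "y1", "y2", "y3"},
            "b1": {"t1", "t2", "z1", "z2", "z3"},
            "b2": {"t1", "t2", "w1", "w2", "w3"},
        }
        # every cross pair shares 2 of 5 terms: Ochiai = 2/5 = 0.4
        sim = pcn.pathway_go_similarity({"a1", "a2"}, {"b1", "b2"}, go_map, top_n=30)
        assert sim == pytest.approx(0.4)

    def test_identically_annotated_disjoint_pathways_score_one(self):
        go_map = {g: {"t1", "t2"} for g in "abcd"}
        assert pcn.pathway_go_similarity({"a", "b"}, {"c", "d"}, go_map) == 1.0

    def test_top_n_keeps_best_pairs_only(self):
        go_map = {
            "a1": {"t1"},
            "a2": {"x"},
            "b1": {"t1"},
            "b2": {"y"},
        }
        # pairs: (a1,b1)=1, others 0; top_n=1 -> 1.0; all four -> 0.25
        assert pcn.pathway_go_similarity({"a1", "a2"}, {"b1", "b2"}, go_map, top_n=1) == 1.0
        assert pcn.pathway_go_similarity(
            {"a1", "a2"}, {"b1", "b2"}, go_map, top_n=30
        ) == pytest.approx(0.25)


class TestPathwayJaccard:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({"a", "b"}, {"a", "b"}, 1.0),
            ({"a"}, {"b"}, 0.0),
            ({"a", "b", "c"}, {"b", "c", "d"}, 0.5),
        ],
    )
    def test_examples(self, a, b, expected):
        assert pcn.pathway_jaccard(a, b) == pytest.approx(expected)


class TestLoadPathways:
    def test_three_line_gmt(self, tmp_path):
        path = tmp_path / "p.gmt"
        path.write_text(
            "P1\tdesc\tEGFR\tGRB2\nP2\tdesc\tGAPDH\nP3\tdesc\tALDOA\tENO1\n"
        )
        pathways = pcn.load_pathways(path)
        assert len(pathways) == 3
        assert pathways["P1"] == {"EGFR", "GRB2"}

    def test_duplicate_pathway_name_raises(self, tmp_path):
        path = tmp_path / "p.gmt"
        path.write_text("P1\tdesc\tEGFR\nP1\tdesc\tGRB2\n")
        with pytest.raises(ValueError, match="duplicate"):
            pcn.load_pathways(path)

    def test_empty_gene_set_skipped_with_warning(self, tmp_path):
        path = tmp_path / "p.gmt"
        path.write_text("P1\tdesc\n P2\tdesc\tEGFR\n".replace(" P2", "P2"))
        with pytest.warns(UserWarning, match="empty gene set"):
            pathways = pcn.load_pathways(path)
        assert list(pathways) == ["P2"]


class TestBuildAndFilterPCN:
    def test_density_matches_formula(self, suite):
        table, summary = pcn.build_pcn(
            suite.assignment, suite.pathways, suite.go_map, suite.ratio_table.keys
        )
        n = summary["n_nodes"]
        assert summary["n_possible_edges"] == n * (n - 1) // 2
        assert summary["density"] == pytest.approx(
            summary["n_edges"] / summary["n_possible_edges"]
        )

    def test_identity_filter(self, suite):
        table, _ = pcn.build_pcn(
            suite.assignment, suite.pathways, suite.go_map, suite.ratio_table.keys
        )
        assert len(pcn.filter_pcn(table, weight_min=0.0)) == len(table)

    def test_jaccard_max_zero_keeps_zero_overlap_only(self, suite):
        table, _ = pcn.build_pcn(
            suite.assignment, suite.pathways, suite.go_map, suite.ratio_table.keys
        )
        filtered = pcn.filter_pcn(table, jaccard_max=0.0)
        assert (filtered.jaccard == 0.0).all()
        assert len(filtered) == (table.jaccard == 0).sum()

    def test_weight_min_above_max_empties_table(self, suite):
        table, _ = pcn.build_pcn(
            suite.assignment, suite.pathways, suite.go_map, suite.ratio_table.keys
        )
        assert len(pcn.filter_pcn(table, weight_min=1.5)) == 0

    def test_contradictory_jaccard_bounds_warn_empty(self, suite):
        table, _ = pcn.build_pcn(
            suite.assignment, suite.pathways, suite.go_map, suite.ratio_table.keys
        )
        with pytest.warns(UserWarning, match="contradictory"):
            out = pcn.filter_pcn(table, jaccard_min=0.5, jaccard_max=0.1)
        assert len(out) == 0


def test_planted_crosstalk_pairs_outweigh_background(suite):
    """Planted crosstalk pathway pairs carry more PTM cluster weight than
    non-planted pairs with zero gene overlap."""
    table, _ = pcn.build_pcn(
        suite.assignment, suite.pathways, suite.go_map, suite.ratio_table.keys
    )
    planted = {tuple(sorted(p)) for p in suite.truth.crosstalk_pairs}
    pairs = list(zip(table.pathway_a, table.pathway_b))
    is_planted = pd.Series([p in planted for p in pairs], index=table.index)
    background = (~is_planted) & (table.jaccard == 0)
    assert is_planted.sum() == len(planted)
    assert (
        table.loc[is_planted, "ptm_cluster_weight"].mean()
        > table.loc[background, "ptm_cluster_weight"].mean()
    )


def test_go_similarity_tracks_gene_overlap_more_than_weight_does():
    """Qualitative correlation structure: when GO terms track pathway
    membership and response modules cut across the pathway collection,
    GOSim correlates with Jaccard more strongly than PTM cluster weight
    does."""
    import scipy.stats as st

    from ptmnet import synthetic, ptm_io

    cfg = synthetic.SimulationConfig(
        seed=9,
        n_proteins=150,
        n_clusters=8,
        n_pathways=40,
        pathway_size=(10, 25),
        module_layout="interleaved",
    )
    table, ann, truth = synthetic.simulate_ptm_data(cfg)
    _, pathways, go_map = synthetic.simulate_networks(cfg, truth)
    rt = ptm_io.compute_ratios(table, ann)
    assignment = cccn.ClusterAssignment(labels=truth.partition)
    edge_table, _ = pcn.build_pcn(assignment, pathways, go_map, rt.keys)
    r_weight = st.pearsonr(edge_table.ptm_cluster_weight, edge_table.jaccard)[0]
    r_go = st.pearsonr(edge_table.go_sim, edge_table.jaccard)[0]
    assert abs(r_go) > abs(r_weight)
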