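"""Shared fixtures: toy tables and the fixed-seed synthetic suite."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
import pytest

from ptmnet import cccn, cfn, ptm_io, synthetic

#: perplexity used throughout on the ~150-PTM synthetic suite
#: (the library default of 30 is sized for thousands of PTMs)
SUITE_PERPLEXITY = 20.0


def make_annotation(
    cell_lines=("H3122",), drugs=("crizotinib",), n_reps=2, n_ctrl=2
) -> pd.DataFrame:
    rows = []
    for line in cell_lines:
        for r in range(1, n_ctrl + 1):
            rows.append((f"{line}_DMSO_r{r}", line, "DMSO", r, True))
        for drug in drugs:
            for r in range(1, n_reps + 1):
                rows.append((f"{line}_{drug}_r{r}", line, drug, r, False))
    return pd.DataFrame(
        rows, columns=["sample_id", "cell_line", "drug", "replicate", "is_control"]
    )


def make_ratio_table(values: dict[str, list[float]], keys=None) -> ptm_io.RatioTable:
    """Ratio table straight from per-site log2 values (NaN allowed)."""
    n = len(next(iter(values.values())))
    cols = [f"s{i}" for i in range(n)]
    df = pd.DataFrame(values, index=cols).T
    if keys is None:
        keys = []
        for i, site in enumerate(values):
            gene = site.split("_")[0]
            keys.append(
                ptm_io.PTMKey(
                    protein=gene,
                    position=i + 1,
                    residue="Y",
                    mod_type="phospho",
                )
            )
        df.index = [k.site_id for k in keys]
    return ptm_io.RatioTable(keys=keys, log2_ratios=df.astype(float))


@dataclass
class SyntheticSuite:
    config: synthetic.SimulationConfig
    table: ptm_io.PTMSiteTable
    annotation: pd.DataFrame
    truth: synthetic.GroundTruth
    ppi: pd.DataFrame
    pathways: dict[str, set[str]]
    go_map: dict[str, set[str]]
    ratio_table: ptm_io.RatioTable
    assignment: cccn.ClusterAssignment
    partitions: dict[str, pd.Series]


@pytest.fixture(scope="session")
def suite() -> SyntheticSuite:
    """Fixed-seed synthetic world plus a full clustering run (seed 1)."""
    config = synthetic.SimulationConfig(seed=1)
    table, annotation, truth = synthetic.simulate_ptm_data(config)
    ppi, pathways, go_map = synthetic.simulate_networks(config, truth)
    ratio_table = ptm_io.compute_ratios(table, annotation)
    assignment, partitions = cccn.cluster_pipeline(
        ratio_table, perplexity=SUITE_PERPLEXITY
    )
    return SyntheticSuite(
        config=config,
        table=table,
        annotation=annotation,
        truth=truth,
        ppi=ppi,
        pathways=pathways,
        go_map=go_map,
        ratio_table=ratio_table,
        assignment=assignment,
        partitions=partitions,
    )


@pytest.fixture(scope="session")
def suite_cfn(suite, tmp_path_factory):
    """CFN built from the suite's PPI edge list."""
    path = tmp_path_factory.mktemp("ppi") / "ppi.tsv"
    synthetic.write_ppi_edges(suite.ppi, path)
    network = cfn.load_ppi_edges(path)
    graph = cfn.filter_cfn(network, suite.assignment, suite.ratio_table)
    return network, graph
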