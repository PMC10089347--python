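"""Synthetic multi-PTM perturbation data with planted ground truth.

The generator emulates the structure of a drug-perturbation SEPTM
(sequential enrichment of PTMs) experiment: blocks of co-regulated PTMs
across drug x cell-line conditions, up to three PTM types per protein,
MS-style missingness, ambiguous peptide-to-protein assignment, a PPI
graph denser within planted modules, overlapping pathway gene sets, and
GO term sets correlated with pathway membership.

Each planted cluster (module) of proteins responds in its own random
subset of drug x cell-line conditions (its condition "barcode"),
mimicking TKIs matched to specific driver kinases.  In responsive
conditions the shared latent log2 response is drawn from
Normal(sign * effect_size, 1) with a fixed per-cluster sign
(drug-inhibited vs drug-induced modules); elsewhere the module is quiet
(Normal(0, 1)).  Treated abundances are the log-normal control baseline
times 2^(response + noise); every stage of the pipeline can therefore be
checked against the planted partition, crosstalk pairs, and PPI module
labels returned as :class:`GroundTruth`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ptmnet.ptm_io import PTMKey, PTMSiteTable


@dataclass
class SimulationConfig:
    """Parameters of the planted world.

    Defaults describe a small but realistic experiment: 60 proteins in 6
    co-regulated modules, 1-4 PTMs each, five cell lines each treated
    with two drugs (2 replicates) plus DMSO controls (2 replicates,
    giving 20 treatment:control ratio columns), a 3.0 log2-unit mean
    response against 0.5 log2 units of replicate noise, and 15% missing
    measurements.
    """

    n_proteins: int = 60
    ptms_per_protein: tuple[int, int] = (1, 4)  # inclusive uniform range
    mod_type_probs: dict = field(
        default_factory=lambda: {"phospho": 0.4, "acetyl": 0.3, "ubiquitin": 0.3}
    )
    n_clusters: int = 6
    cell_lines: tuple[str, ...] = ("H3122", "PC9", "HCC78", "H2286", "H1781")
    drugs: tuple[str, ...] = ("crizotinib", "erlotinib")
    n_replicates: int = 2
    n_control_replicates: int = 2
    effect_size: float = 3.0  # mean |log2 response| of a module
    condition_response_prob: float = 0.6  # fraction of conditions a module responds to
    noise_sd: float = 0.5  # replicate-level log2 noise
    missing_rate: float = 0.15
    intensity_dependent_missing: bool = False
    ambiguity_rate: float = 0.05
    n_pathways: int = 12
    pathway_size: tuple[int, int] = (8, 14)
    pathway_overlap: float = 0.2
    n_crosstalk_pairs: int = 2
    crosstalk_zero_overlap: bool = True
    ppi_within_module_density: float = 0.4
    ppi_background_density: float = 0.05
    go_terms_per_gene: int = 6
    n_go_terms: int = 80
    go_pathway_bias: float = 0.85
    #: "blocks": response modules align with functional neighborhoods
    #: (pathway-coherent clusters); "interleaved": modules cut across
    #: functional space, as when drug response is orthogonal to the
    #: pathway collection
    module_layout: str = "blocks"
    seed: int = 0

    def validate(self) -> None:
        for name in ("ppi_within_module_density", "ppi_background_density"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0 <= self.missing_rate < 1:
            raise ValueError(f"missing_rate must be in [0, 1), got {self.missing_rate}")
        if self.n_clusters > self.n_proteins:
            raise ValueError(
                "n_clusters cannot exceed n_proteins "
                f"({self.n_clusters} > {self.n_proteins})"
            )
        if 2 * self.n_crosstalk_pairs > self.n_clusters:
            raise ValueError("need at least two planted modules per crosstalk pair")
        if abs(sum(self.mod_type_probs.values()) - 1) > 1e-9:
            raise ValueError("mod_type_probs must sum to 1")
        if self.module_layout not in ("blocks", "interleaved"):
            raise ValueError(
                f"module_layout must be 'blocks' or 'interleaved', "
                f"got {self.module_layout!r}"
            )


@dataclass
class GroundTruth:
    """Planted structure recorded for validation."""

    partition: pd.Series  # site_id -> planted cluster id
    module_of_gene: dict[str, int]
    crosstalk_pairs: list[tuple[str, str]] = field(default_factory=list)
    within_module_edges: set[tuple[str, str]] = field(default_factory=set)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "partition": self.partition.to_dict(),
            "module_of_gene": self.module_of_gene,
            "crosstalk_pairs": [list(p) for p in self.crosstalk_pairs],
            "within_module_edges": sorted(list(e) for e in self.within_module_edges),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _gene_name(i: int) -> str:
    return f"GENE{i:03d}"


def simulate_ptm_data(
    config: SimulationConfig,
) -> tuple[PTMSiteTable, pd.DataFrame, GroundTruth]:
    """Generate abundances, sample annotation, and planted ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = [_gene_name(i) for i in range(config.n_proteins)]
    if config.module_layout == "blocks":
        # contiguous blocks of the gene ordering: the functional
        # neighborhoods used for pathways align with co-response
        module_of_gene = {
            g: i * config.n_clusters // config.n_proteins for i, g in enumerate(genes)
        }
    else:
        # response modules cut across functional space
        module_of_gene = {g: i % config.n_clusters for i, g in enumerate(genes)}

    # sample layout: per cell line, DMSO controls + each drug x replicates
    rows = []
    for line in config.cell_lines:
        for r in range(1, config.n_control_replicates + 1):
            rows.append((f"{line}_DMSO_r{r}", line, "DMSO", r, True))
        for drug in config.drugs:
            for r in range(1, config.n_replicates + 1):
                rows.append((f"{line}_{drug}_r{r}", line, drug, r, False))
    annotation = pd.DataFrame(
        rows, columns=["sample_id", "cell_line", "drug", "replicate", "is_control"]
    )
    conditions = [(l, d) for l in config.cell_lines for d in config.drugs]

    # one latent log2 response per cluster per condition, fixed sign per
    # cluster; each module responds in its own random subset of drug x
    # cell-line conditions (its "barcode"), mimicking TKIs matched to
    # specific driver kinases, and is quiet (mean 0) elsewhere
    signs = np.where(np.arange(config.n_clusters) % 2 == 0, -1.0, 1.0)
    # distinct modules must be distinguishable in principle: resample a
    # barcode that comes within Hamming distance 3 of an existing one
    min_hamming = min(3, max(1, len(conditions) // 3))
    barcodes: list[np.ndarray] = []
    for c in range(config.n_clusters):
        for _ in range(200):
            active = rng.random(len(conditions)) < config.condition_response_prob
            if not active.any():
                active[int(rng.integers(len(conditions)))] = True
            if all((active != prev).sum() >= min_hamming for prev in barcodes):
                break
        barcodes.append(active)
    response = {}
    for c in range(config.n_clusters):
        for cond, is_active in zip(conditions, barcodes[c]):
            mean = signs[c] * config.effect_size if is_active else 0.0
            response[(c, cond)] = rng.normal(mean, 1.0)

    residue_for = {"phospho": "Y", "acetyl": "K", "ubiquitin": "K"}
    mods = list(config.mod_type_probs)
    probs = np.array([config.mod_type_probs[m] for m in mods])

    keys: list[PTMKey] = []
    planted: list[int] = []
    lo, hi = config.ptms_per_protein
    for gi, gene in enumerate(genes):
        n_ptms = int(rng.integers(lo, hi + 1))
        positions = rng.choice(np.arange(1, 2000), size=n_ptms, replace=False)
        for pos in sorted(positions):
            mod = mods[rng.choice(len(mods), p=probs)]
            group = (gene,)
            if rng.random() < config.ambiguity_rate:
                other = genes[int(rng.integers(config.n_proteins))]
                if other != gene:
                    group = (gene, other)
            keys.append(
                PTMKey(
                    protein=gene,
                    position=int(pos),
                    residue=residue_for[mod],
                    mod_type=mod,
                    ambiguity_group=group,
                )
            )
            planted.append(module_of_gene[gene])

    n_sites = len(keys)
    sample_ids = annotation["sample_id"].tolist()
    baseline = 2.0 ** rng.normal(16.0, 1.0, size=n_sites)  # MS intensity scale
    data = np.empty((n_sites, len(sample_ids)))
    for j, (_, srow) in enumerate(annotation.iterrows()):
        noise = rng.normal(0.0, config.noise_sd, size=n_sites)
        if srow["is_control"]:
            data[:, j] = baseline * 2.0 ** noise
        else:
            cond = (srow["cell_line"], srow["drug"])
            resp = np.array([response[(c, cond)] for c in planted])
            data[:, j] = baseline * 2.0 ** (resp + noise)

    if config.missing_rate > 0:
        if config.intensity_dependent_missing:
            # low-abundance measurements drop out preferentially; mean
            # dropout equals missing_rate
            ranks = pd.DataFrame(data).rank(axis=None).to_numpy().reshape(data.shape)
            p = 2.0 * config.missing_rate * (1.0 - ranks / ranks.max())
            p = np.clip(p, 0.0, 0.95)
        else:
            p = np.full(data.shape, config.missing_rate)
        data[rng.random(data.shape) < p] = np.nan

    abundances = pd.DataFrame(
        data, index=pd.Index([k.site_id for k in keys], name="site"), columns=sample_ids
    )
    truth = GroundTruth(
        partition=pd.Series(planted, index=abundances.index, name="planted"),
        module_of_gene=module_of_gene,
    )
    return PTMSiteTable(keys=keys, abundances=abundances), annotation, truth


def simulate_networks(
    config: SimulationConfig,
    ground_truth: GroundTruth,
) -> tuple[pd.DataFrame, dict[str, set[str]], dict[str, set[str]]]:
    """Generate a PPI edge list, pathway gene sets, and a gene->GO map.

    PPI edges appear with probability ``ppi_within_module_density``
    between genes of the same planted module and
    ``ppi_background_density`` otherwise.  Each planted crosstalk pair
    of pathways splits one module's genes into two disjoint gene sets,
    so the pair shares a responsive PTM cluster while (optionally)
    sharing zero genes.  GO terms are drawn preferentially from
    per-pathway term pools, so genes in the same pathway share terms at
    an elevated rate.
    """
    config.validate()
    # separate stream so network structure is independent of the PTM draw
    rng = np.random.default_rng(config.seed + 1)
    genes = sorted(ground_truth.module_of_gene)
    module = ground_truth.module_of_gene

    ppi_rows = []
    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            within = module[a] == module[b]
            dens = (
                config.ppi_within_module_density
                if within
                else config.ppi_background_density
            )
            if rng.random() < dens:
                ppi_rows.append((a, b, "physical", "synthetic", 1.0))
                if within:
                    ground_truth.within_module_edges.add((a, b))
    ppi = pd.DataFrame(
        ppi_rows, columns=["gene_a", "gene_b", "interaction_type", "source", "weight"]
    )

    # planted crosstalk pathway pairs: each pair splits the genes of two
    # whole modules between its two pathways, so the pair shares (at
    # least) two responsive clusters while sharing no genes
    pathways: dict[str, set[str]] = {}
    for t in range(config.n_crosstalk_pairs):
        set_a: set[str] = set()
        set_b: set[str] = set()
        for m in (2 * t, 2 * t + 1):
            members = [g for g in genes if module[g] == m]
            perm = list(rng.permutation(members))
            half = len(perm) // 2
            set_a |= set(perm[:half])
            set_b |= set(perm[half:])
        if not config.crosstalk_zero_overlap and set_a and set_b:
            set_a.add(next(iter(set_b)))
        name_a, name_b = f"CROSSTALK{t}A", f"CROSSTALK{t}B"
        pathways[name_a] = set_a
        pathways[name_b] = set_b
        ground_truth.crosstalk_pairs.append((name_a, name_b))

    # background pathways live in a continuous "functional neighborhood":
    # genes sit on a unit circle, each pathway draws most of its members
    # near a random center, and (below) genes are annotated with GO terms
    # tied to their own position.  Pathways with nearby centers therefore
    # share both genes and annotation structure, in a graded way, as real
    # pathway collections do.
    lo, hi = config.pathway_size
    n_background = config.n_pathways - 2 * config.n_crosstalk_pairs
    if n_background < 0:
        raise ValueError("n_pathways too small for the requested crosstalk pairs")
    if hi > len(genes):
        raise ValueError(
            f"pathway size up to {hi} infeasible for {len(genes)} genes"
        )
    position = {g: i / len(genes) for i, g in enumerate(genes)}
    pos_vec = np.array([position[g] for g in genes])
    sigma = 0.06  # width of a functional neighborhood on the unit circle
    local_frac = float(np.clip(4.0 * config.pathway_overlap, 0.0, 0.95))
    for p in range(n_background):
        size = int(rng.integers(lo, hi + 1))
        center = rng.random()
        d = np.abs(pos_vec - center)
        d = np.minimum(d, 1.0 - d)  # circular distance
        w = np.exp(-(d**2) / (2.0 * sigma**2))
        n_local = min(int(round(local_frac * size)), size)
        members: set[str] = set()
        if n_local:
            picks = rng.choice(len(genes), size=n_local, replace=False, p=w / w.sum())
            members = {genes[i] for i in picks}
        rest = [g for g in genes if g not in members]
        members |= set(rng.choice(rest, size=size - len(members), replace=False))
        pathways[f"PATHWAY{p:02d}"] = members

    # GO annotation: each gene draws most of its terms from a window of
    # the term list centered at its own circle position
    terms = [f"GO:{i:07d}" for i in range(1, config.n_go_terms + 1)]
    term_sigma = max(2.0, 0.06 * config.n_go_terms)
    go_map: dict[str, set[str]] = {g: set() for g in genes}
    if config.go_terms_per_gene > 0:
        for g in genes:
            center = position[g] * config.n_go_terms
            for _ in range(config.go_terms_per_gene):
                if rng.random() < config.go_pathway_bias:
                    i = int(round(rng.normal(center, term_sigma))) % config.n_go_terms
                else:
                    i = int(rng.integers(config.n_go_terms))
                go_map[g].add(terms[i])
    return ppi, pathways, go_map


# ---------------------------------------------------------------------------
# file writers (the generator emits the same formats the pipeline reads)


def write_ptm_table(table: PTMSiteTable, path: str | Path) -> None:
    meta = pd.DataFrame(
        {
            "Gene": [";".join(k.ambiguity_group) for k in table.keys],
            "Position": [k.position for k in table.keys],
            "Residue": [k.residue for k in table.keys],
            "ModType": [k.mod_type for k in table.keys],
        },
        index=table.abundances.index,
    )
    pd.concat([meta, table.abundances], axis=1).to_csv(path, sep="\t", index=False)


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.to_csv(path, sep="\t", index=False)


def write_ppi_edges(ppi: pd.DataFrame, path: str | Path) -> None:
    ppi.to_csv(path, sep="\t", index=False)


def write_gmt(pathways: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(pathways):
            genes = "\t".join(sorted(pathways[name]))
            fh.write(f"{name}\tsynthetic\t{genes}\n")


def write_go_map(go_map: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(go_map):
            for term in sorted(go_map[gene]):
                fh.write(f"{gene}\t{term}\n")


def write_all(
    config: SimulationConfig, out_dir: str | Path
) -> dict[str, Path]:
    """Simulate everything and write the standard input files to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, annotation, truth = simulate_ptm_data(config)
    ppi, pathways, go_map = simulate_networks(config, truth)
    paths = {
        "ptm_table": out / "ptm_table.tsv",
        "annotation": out / "annotation.tsv",
        "ppi": out / "ppi_edges.tsv",
        "pathways": out / "pathways.gmt",
        "go_map": out / "go_annotations.tsv",
        "ground_truth": out / "ground_truth.json",
        "config": out / "sim_config.json",
    }
    write_ptm_table(table, paths["ptm_table"])
    write_annotation(annotation, paths["annotation"])
    write_ppi_edges(ppi, paths["ppi"])
    write_gmt(pathways, paths["pathways"])
    write_go_map(go_map, paths["go_map"])
    truth.to_json(paths["ground_truth"])
    cfg = asdict(config)
    cfg["within_module_edges"] = len(truth.within_module_edges)
    Path(paths["config"]).write_text(json.dumps(cfg, indent=1, default=list))
    return paths
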