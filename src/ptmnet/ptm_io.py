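"""Parsing of PTM quantitation tables and treatment:control ratio computation.

The input is a site-by-sample abundance table (one row per unique PTM
site, one column per mass-spectrometry sample) plus a sample annotation
sheet mapping samples to cell line, drug, replicate, and control status.
Ratios of drug-treated to control abundance are computed per cell line,
capped at +/-100-fold, and stored as signed log2 values: a site that
drops from 8 to 2 is stored as -2.0, not log2(0.25), so that the +/-1.17
(2.25-fold) drug-effect thresholds are symmetric around zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MOD_TYPES = frozenset({"phospho", "acetyl", "ubiquitin"})

#: columns that must precede the sample columns in a PTM table
REQUIRED_COLUMNS = ("Gene", "Position", "Residue", "ModType")

#: log2(2.25) rounded to two decimals, the conventional 2.25-fold cutoff
DEFAULT_LOG2_THRESHOLD = 1.17


@dataclass(frozen=True)
class PTMKey:
    """Identity of a single modification site.

    ``ambiguity_group`` lists every gene symbol the underlying peptide
    is consistent with; ``protein`` is its first member and the primary
    assignment used when collapsing to protein-level values.
    """

    protein: str
    position: int
    residue: str
    mod_type: str
    ambiguity_group: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.mod_type not in MOD_TYPES:
            raise ValueError(
                f"mod_type {self.mod_type!r} not in {sorted(MOD_TYPES)}"
            )
        if not self.ambiguity_group:
            object.__setattr__(self, "ambiguity_group", (self.protein,))
        elif self.ambiguity_group[0] != self.protein:
            raise ValueError(
                "protein must be the first member of ambiguity_group: "
                f"{self.protein!r} vs {self.ambiguity_group}"
            )

    @property
    def site_id(self) -> str:
        """Stable string id, e.g. ``EGFR_Y1197_phospho``."""
        return f"{self.protein}_{self.residue}{self.position}_{self.mod_type}"


@dataclass
class PTMSiteTable:
    """Sites x samples abundance matrix with typed site keys."""

    keys: list[PTMKey]
    abundances: pd.DataFrame  # index = site_id, columns = sample ids

    def __post_init__(self) -> None:
        if len(self.keys) != len(self.abundances):
            raise ValueError("row count must equal number of keys")

    @property
    def site_ids(self) -> list[str]:
        return [k.site_id for k in self.keys]

    def key_map(self) -> dict[str, PTMKey]:
        return {k.site_id: k for k in self.keys}


@dataclass
class RatioTable:
    """Signed, capped log2 treated:control ratios (sites x treated samples)."""

    keys: list[PTMKey]
    log2_ratios: pd.DataFrame  # index = site_id, columns = treated sample ids
    cap: float = 100.0

    def key_map(self) -> dict[str, PTMKey]:
        return {k.site_id: k for k in self.keys}

    def n_observed(self, sample_ids: Sequence[str]) -> pd.Series:
        """Per-site count of finite ratios over the given samples."""
        cols = [s for s in sample_ids if s in self.log2_ratios.columns]
        return self.log2_ratios[cols].notna().sum(axis=1)

    def group_median(self, sample_ids: Sequence[str]) -> pd.Series:
        cols = [s for s in sample_ids if s in self.log2_ratios.columns]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return self.log2_ratios[cols].median(axis=1)


@dataclass
class SampleGroup:
    """Named set of treated samples, e.g. ``h3122.criz`` or ``all.drug``."""

    name: str
    sample_ids: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.sample_ids)


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, dtype=str)


def load_annotation(path: str | Path) -> pd.DataFrame:
    """Read a sample annotation TSV and validate its invariants."""
    ann = _read_table(path)
    required = {"sample_id", "cell_line", "drug", "replicate", "is_control"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    ann["replicate"] = ann["replicate"].astype(int)
    ann["is_control"] = ann["is_control"].astype(str).str.lower().isin(
        {"true", "1", "yes"}
    )
    if ann["sample_id"].duplicated().any():
        dupes = ann.loc[ann["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_ids in annotation: {dupes}")
    treated_lines = set(ann.loc[~ann["is_control"], "cell_line"])
    control_lines = set(ann.loc[ann["is_control"], "cell_line"])
    orphans = treated_lines - control_lines
    if orphans:
        raise ValueError(
            f"cell lines with treated samples but no control: {sorted(orphans)}"
        )
    return ann.reset_index(drop=True)


def load_ptm_table(
    path: str | Path,
    annotation_path: str | Path,
    ambiguity_delim: str = ";",
) -> tuple[PTMSiteTable, pd.DataFrame]:
    """Load a PTM quantitation table and its sample annotation.

    The table must carry the columns ``Gene``, ``Position``, ``Residue``,
    ``ModType`` followed by one abundance column per sample.  ``Gene``
    entries may be delimiter-separated lists of candidate symbols for
    peptides that map to several proteins; the first symbol is the
    primary assignment.
    """
    raw = _read_table(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"PTM table missing required columns: {missing}")
    annotation = load_annotation(annotation_path)
    sample_cols = [c for c in raw.columns if c not in REQUIRED_COLUMNS]
    known = set(annotation["sample_id"])
    unknown = [c for c in sample_cols if c not in known]
    if unknown:
        raise ValueError(
            f"abundance columns without sample annotation: {unknown}"
        )

    keys: list[PTMKey] = []
    seen: set[tuple] = set()
    for _, row in raw.iterrows():
        group = tuple(
            g.strip() for g in str(row["Gene"]).split(ambiguity_delim) if g.strip()
        )
        key = PTMKey(
            protein=group[0],
            position=int(row["Position"]),
            residue=str(row["Residue"]),
            mod_type=str(row["ModType"]),
            ambiguity_group=group,
        )
        ident = (key.protein, key.position, key.residue, key.mod_type)
        if ident in seen:
            raise ValueError(f"duplicate PTM key: {ident}")
        seen.add(ident)
        keys.append(key)

    abundances = raw[sample_cols].apply(pd.to_numeric, errors="coerce")
    abundances.index = pd.Index([k.site_id for k in keys], name="site")
    if (abundances.to_numpy() < 0).any():
        raise ValueError("abundances must be nonnegative")
    return PTMSiteTable(keys=keys, abundances=abundances), annotation


def compute_ratios(
    table: PTMSiteTable,
    annotation: pd.DataFrame,
    cap: float = 100.0,
) -> RatioTable:
    """Compute signed, capped log2 treated:control ratios.

    For each treated sample the control baseline is the arithmetic mean
    of same-cell-line control replicates (missing controls ignored).
    Fold change is treated/control when the site goes up and
    -(control/treated) when it goes down; the magnitude is capped at
    ``cap`` before the log2 transform, so every stored value satisfies
    |r| <= log2(cap).  Entries where the treated value or every control
    is missing, or where the control mean is zero, are left missing.
    """
    if cap <= 1:
        raise ValueError(f"cap must be > 1, got {cap}")
    ann = annotation.set_index("sample_id")
    treated = [s for s in table.abundances.columns if not ann.loc[s, "is_control"]]
    out = pd.DataFrame(
        np.nan, index=table.abundances.index, columns=treated, dtype=float
    )
    for sample in treated:
        line = ann.loc[sample, "cell_line"]
        ctrl_cols = [
            s
            for s in table.abundances.columns
            if ann.loc[s, "is_control"] and ann.loc[s, "cell_line"] == line
        ]
        if not ctrl_cols:
            logger.warning("sample %s: no control columns for %s", sample, line)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            ctrl_mean = table.abundances[ctrl_cols].mean(axis=1)
        t = table.abundances[sample]
        n_zero = int(((ctrl_mean == 0) & t.notna()).sum())
        if n_zero:
            logger.warning(
                "sample %s: %d sites with zero control mean set missing",
                sample,
                n_zero,
            )
        valid = t.notna() & ctrl_mean.notna() & (ctrl_mean > 0) & (t > 0)
        fold = pd.Series(np.nan, index=t.index)
        up = valid & (t >= ctrl_mean)
        down = valid & (t < ctrl_mean)
        fold[up] = t[up] / ctrl_mean[up]
        fold[down] = -(ctrl_mean[down] / t[down])
        capped = fold.clip(lower=-cap, upper=cap)
        out[sample] = np.sign(capped) * np.log2(capped.abs())
    return RatioTable(keys=list(table.keys), log2_ratios=out, cap=cap)


def define_sample_groups(
    annotation: pd.DataFrame,
    config: Mapping[str, Mapping],
) -> list[SampleGroup]:
    """Resolve a group configuration into lists of treated sample ids.

    Each config entry is either a selector ``{cell_line: ..., drug: ...}``
    (values may be single strings, lists, or ``"*"`` for any) or a
    composite ``{union: [group, ...]}`` referring to previously defined
    groups.  Only non-control samples are ever selected.
    """
    treated = annotation.loc[~annotation["is_control"]]
    groups: dict[str, SampleGroup] = {}
    for name, selector in config.items():
        unknown = set(selector) - {"cell_line", "drug", "union"}
        if unknown:
            raise ValueError(f"group {name!r}: unknown selector keys {sorted(unknown)}")
        if "union" in selector:
            continue  # resolved below, so unions may reference any group
        mask = pd.Series(True, index=treated.index)
        for field_name in ("cell_line", "drug"):
            wanted = selector.get(field_name, "*")
            if wanted in ("*", None):
                continue
            if isinstance(wanted, str):
                wanted = [wanted]
            mask &= treated[field_name].isin(wanted)
        groups[name] = SampleGroup(
            name=name, sample_ids=tuple(treated.loc[mask, "sample_id"])
        )
    pending = {n: s for n, s in config.items() if "union" in s}
    while pending:
        resolved_any = False
        for name, selector in list(pending.items()):
            if not all(ref in groups for ref in selector["union"]):
                continue
            members: list[str] = []
            for ref in selector["union"]:
                members.extend(s for s in groups[ref].sample_ids if s not in members)
            groups[name] = SampleGroup(name=name, sample_ids=tuple(members))
            del pending[name]
            resolved_any = True
        if not resolved_any:
            name, selector = next(iter(pending.items()))
            missing = [r for r in selector["union"] if r not in groups]
            raise ValueError(
                f"group {name!r}: union refers to undefined group(s) {missing}"
            )
    for name in config:
        if len(groups[name]) == 0:
            warnings.warn(f"sample group {name!r} is empty", stacklevel=2)
    return [groups[name] for name in config]


def flag_drug_affected(
    ratio_table: RatioTable,
    group: SampleGroup,
    min_obs: int = 2,
    log2_threshold: float = DEFAULT_LOG2_THRESHOLD,
) -> pd.Series:
    """Classify each site as ``up``, ``down`` or ``none`` for a sample group.

    A site is drug-affected when it has at least ``min_obs`` finite
    ratios in the group and the group median exceeds the log2 threshold
    in magnitude (default 1.17, i.e. 2.25-fold).
    """
    if len(group) == 0:
        raise ValueError(f"sample group {group.name!r} is empty")
    n_obs = ratio_table.n_observed(group.sample_ids)
    med = ratio_table.group_median(group.sample_ids)
    status = pd.Series("none", index=ratio_table.log2_ratios.index, dtype=object)
    enough = n_obs >= min_obs
    status[enough & (med > log2_threshold)] = "up"
    status[enough & (med < -log2_threshold)] = "down"
    return status


def affected_site_ids(
    ratio_table: RatioTable,
    group: SampleGroup,
    min_obs: int = 2,
    log2_threshold: float = DEFAULT_LOG2_THRESHOLD,
) -> list[str]:
    """Site ids flagged up or down for the group (convenience wrapper)."""
    status = flag_drug_affected(ratio_table, group, min_obs, log2_threshold)
    return status.index[status != "none"].tolist()


def write_ratio_table(ratio_table: RatioTable, path: str | Path) -> None:
    """Serialize a ratio table to TSV (key columns then sample columns)."""
    meta = pd.DataFrame(
        {
            "Gene": [";".join(k.ambiguity_group) for k in ratio_table.keys],
            "Position": [k.position for k in ratio_table.keys],
            "Residue": [k.residue for k in ratio_table.keys],
            "ModType": [k.mod_type for k in ratio_table.keys],
        },
        index=ratio_table.log2_ratios.index,
    )
    pd.concat([meta, ratio_table.log2_ratios], axis=1).to_csv(
        path, sep="\t", index_label="site"
    )


def read_ratio_table(path: str | Path, cap: float = 100.0) -> RatioTable:
    raw = pd.read_csv(path, sep="\t", index_col="site")
    keys = []
    for _, row in raw.iterrows():
        group = tuple(str(row["Gene"]).split(";"))
        keys.append(
            PTMKey(
                protein=group[0],
                position=int(row["Position"]),
                residue=str(row["Residue"]),
                mod_type=str(row["ModType"]),
                ambiguity_group=group,
            )
        )
    sample_cols = [c for c in raw.columns if c not in REQUIRED_COLUMNS]
    return RatioTable(
        keys=keys, log2_ratios=raw[sample_cols].astype(float), cap=cap
    )
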