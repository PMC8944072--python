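"""Gene-level association score tables and CpG-site aggregation.

A :class:`GeneScoreTable` holds one p-value per gene (optionally an effect
direction and fold change); site-level tables (e.g. CpG differential
methylation results) are reduced to gene level by taking each gene's best
(minimum) site p-value, which both reproduces the "any nominally
significant site" membership rule and yields a total gene ranking.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .graph import Network, normalize_gene

logger = logging.getLogger(__name__)

EFFECT_DIRECTIONS = ("up", "down", "none")


class EmptyTableError(ValueError):
    """Raised when an operation would produce or consume an empty table."""


@dataclass
class GeneScoreTable:
    """Per-gene p-values for one dataset.

    ``data`` has index = gene identifier (unique), columns ``p_value``
    (all in [0, 1], no missing) and optionally ``effect_direction`` and
    ``fold_change``.
    """

    data: pd.DataFrame
    dataset_name: str = "dataset"

    def __post_init__(self) -> None:
        if "p_value" not in self.data.columns:
            raise ValueError("score table requires a p_value column")
        p = self.data["p_value"]
        if p.isna().any():
            raise ValueError("missing p-values are not allowed")
        if ((p < 0) | (p > 1)).any():
            raise ValueError("p-values must lie in [0, 1]")
        if not self.data.index.is_unique:
            # collapse multi-row genes to their minimum p-value, mirroring
            # the site-level aggregation rule
            n_dup = int(self.data.index.duplicated().sum())
            logger.warning(
                "%s: %d duplicate gene rows collapsed to min p", self.dataset_name, n_dup
            )
            self.data = (
                self.data.sort_values("p_value").groupby(level=0).first().sort_index()
            )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def genes(self) -> set[str]:
        return set(self.data.index)

    def p_value(self, gene: str) -> float:
        return float(self.data.at[gene, "p_value"])

    @classmethod
    def from_records(
        cls,
        records: dict[str, float] | Iterable[tuple[str, float]],
        dataset_name: str = "dataset",
    ) -> "GeneScoreTable":
        if isinstance(records, dict):
            records = records.items()
        genes, ps = zip(*records) if records else ((), ())
        df = pd.DataFrame({"p_value": ps}, index=pd.Index(genes, name="gene"))
        return cls(df, dataset_name)

    @classmethod
    def read_tsv(
        cls, path: str | Path, dataset_name: str | None = None, casefold: bool = True
    ) -> "GeneScoreTable":
        """Read a headered TSV with columns gene, p_value[, fold_change, ...]."""
        df = pd.read_csv(path, sep="\t", comment="#")
        if "gene" not in df.columns or "p_value" not in df.columns:
            raise ValueError(f"{path}: expected 'gene' and 'p_value' columns")
        df["gene"] = df["gene"].astype(str).map(lambda g: normalize_gene(g, casefold))
        df = df.set_index("gene")
        return cls(df, dataset_name or Path(path).stem)

    def write_tsv(self, path: str | Path) -> None:
        out = self.data.sort_index()
        out.to_csv(path, sep="\t", index_label="gene", float_format="%.10g")


@dataclass
class SiteScoreTable:
    """Site-level (e.g. CpG) p-values with an optional mapped gene per site.

    ``data`` columns: ``site``, ``p_value``, ``gene`` (NaN/empty when the
    site maps to no gene).
    """

    data: pd.DataFrame
    dataset_name: str = "sites"

    def __post_init__(self) -> None:
        required = {"site", "p_value", "gene"}
        if not required <= set(self.data.columns):
            raise ValueError(f"site table requires columns {sorted(required)}")
        p = self.data["p_value"]
        if ((p < 0) | (p > 1)).any() or p.isna().any():
            raise ValueError("site p-values must lie in [0, 1] and be present")

    @classmethod
    def read_tsv(
        cls, path: str | Path, dataset_name: str | None = None, casefold: bool = True
    ) -> "SiteScoreTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        if "gene" in df.columns:
            df["gene"] = df["gene"].map(
                lambda g: normalize_gene(str(g), casefold) if pd.notna(g) and str(g) else None
            )
        else:
            df["gene"] = None
        return cls(df, dataset_name or Path(path).stem)


def aggregate_sites_to_genes(
    sites: SiteScoreTable, rule: str = "min_p"
) -> GeneScoreTable:
    """Reduce site-level p-values to gene level.

    ``min_p`` (the only rule currently offered; kept as a parameter so
    alternative combiners can be added) assigns each gene the minimum
    p-value over its mapped sites. Unmapped sites are excluded with a
    logged count.
    """
    if rule != "min_p":
        raise ValueError(f"unknown aggregation rule {rule!r}")
    df = sites.data
    unmapped = df["gene"].isna() | (df["gene"].astype(str) == "")
    if unmapped.any():
        logger.info(
            "%s: %d unmapped sites excluded", sites.dataset_name, int(unmapped.sum())
        )
    mapped = df.loc[~unmapped]
    if mapped.empty:
        raise EmptyTableError("no mapped sites to aggregate")
    per_gene = mapped.groupby("gene")["p_value"].min()
    out = per_gene.to_frame().rename_axis("gene")
    return GeneScoreTable(out, sites.dataset_name)


def nominal_genes(table: GeneScoreTable, alpha: float = 0.05) -> set[str]:
    """Genes with p strictly below ``alpha`` (nominal significance)."""
    if not (0 < alpha <= 1):
        raise ValueError("alpha must lie in (0, 1]")
    p = table.data["p_value"]
    return set(p.index[p < alpha])


def overlap_summary(
    tables: Sequence[GeneScoreTable], alpha: float = 0.05
) -> pd.DataFrame:
    """Venn partition of the nominal gene sets of several datasets.

    Returns one row per region of the Venn diagram: binary membership flags
    per dataset, the region count, and the sorted member list. Region
    counts sum to the size of the union.
    """
    if len(tables) < 2:
        raise ValueError("overlap_summary needs at least two tables")
    names = [t.dataset_name for t in tables]
    sets = [nominal_genes(t, alpha) for t in tables]
    union = set().union(*sets)
    membership: dict[tuple[int, ...], list[str]] = {}
    for g in union:
        key = tuple(int(g in s) for s in sets)
        membership.setdefault(key, []).append(g)
    rows = []
    for key in itertools.product((1, 0), repeat=len(tables)):
        if not any(key):
            continue
        members = sorted(membership.get(key, []))
        rows.append(
            dict(zip(names, key))
            | {"count": len(members), "genes": ",".join(members)}
        )
    return pd.DataFrame(rows)


def restrict_to_network(table: GeneScoreTable, net: Network) -> GeneScoreTable:
    """Keep only genes present in the network (the "found in the PPI" step)."""
    present = table.data.index.isin(net.graph.nodes)
    kept = table.data.loc[present]
    logger.info(
        "%s: %d of %d scored genes found in %s",
        table.dataset_name,
        len(kept),
        len(table.data),
        net.name,
    )
    if kept.empty:
        logger.warning("%s: no scored genes present in the network", table.dataset_name)
    return GeneScoreTable(kept.copy(), table.dataset_name)
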