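"""Local hypergeometric gene-set enrichment with an explicit background.

Runs entirely from files — GMT collections and plain gene lists — so the
analysis is reproducible offline. The background is stated, not implied
(typically the gene universe of the interactome's largest connected
component); query and target genes outside it are dropped before testing.
Multiple testing is controlled by Benjamini-Hochberg, and raw p-values are
always reported alongside so another correction can be re-applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .graph import normalize_gene

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions, GMT-backed."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    name: str = "collection"

    def __len__(self) -> int:
        return len(self.sets)

    @classmethod
    def read_gmt(
        cls, path: str | Path, casefold: bool = True, name: str | None = None
    ) -> "GeneSetCollection":
        sets: dict[str, frozenset[str]] = {}
        descriptions: dict[str, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"{path}:{lineno}: GMT rows need >= 3 columns")
                set_name, desc, *genes = fields
                if set_name in sets:
                    raise ValueError(f"{path}:{lineno}: duplicate set name {set_name!r}")
                sets[set_name] = frozenset(
                    normalize_gene(g, casefold) for g in genes if g.strip()
                )
                descriptions[set_name] = desc
        return cls(sets=sets, descriptions=descriptions, name=name or Path(path).stem)

    def write_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for set_name in sorted(self.sets):
                genes = "\t".join(sorted(self.sets[set_name]))
                fh.write(f"{set_name}\t{self.descriptions.get(set_name, '')}\t{genes}\n")


def read_gene_list(path: str | Path, casefold: bool = True) -> set[str]:
    """Plain-text gene list, one identifier per line, '#' comments skipped."""
    out = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(normalize_gene(line, casefold))
    return out


def hypergeometric_overlap_test(
    query: Iterable[str], target: Iterable[str], background: Iterable[str]
) -> dict:
    """Upper-tail hypergeometric overlap of two gene sets in a background.

    With N = |background|, K = |target ∩ background|, n = |query ∩
    background| and k = |query ∩ target ∩ background|, returns
    P(X >= k). Members outside the background are dropped with logged
    counts so the urn model is well-posed.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background")
    query, target = set(query), set(target)
    dropped_q = len(query - background)
    dropped_t = len(target - background)
    if dropped_q or dropped_t:
        logger.info(
            "hypergeometric test: dropped %d query / %d target genes outside background",
            dropped_q,
            dropped_t,
        )
    query &= background
    target &= background
    overlap = query & target
    N, K, n, k = len(background), len(target), len(query), len(overlap)
    p = float(hypergeom.sf(k - 1, N, K, n))
    return {
        "k": k,
        "K": K,
        "n": n,
        "N": N,
        "p_value": p,
        "overlap_genes": sorted(overlap),
    }


@dataclass
class EnrichmentResult:
    """Per-set enrichment rows, sorted by raw p-value."""

    data: pd.DataFrame
    query_name: str
    background_size: int
    correction: str

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.data[self.data["p_adjusted"] < alpha]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# query\t{self.query_name}\n")
            fh.write(f"# background_size\t{self.background_size}\n")
            fh.write(f"# correction\t{self.correction}\n")
            self.data.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def enrich_collection(
    query: Iterable[str],
    collection: GeneSetCollection,
    background: Iterable[str],
    correction: str = "benjamini_hochberg",
    min_set: int = 3,
    max_set: int = 1000,
    query_name: str = "query",
) -> EnrichmentResult:
    """Hypergeometric enrichment of a query against every collection set.

    Sets are size-filtered to [min_set, max_set] *after* restriction to
    the background; Benjamini-Hochberg adjustment runs over the tested
    sets only, and significance is flagged at adjusted p < 0.05.
    """
    if correction != "benjamini_hochberg":
        raise ValueError(f"unknown correction {correction!r}")
    if min_set > max_set:
        raise ValueError("min_set must be <= max_set")
    if not len(collection):
        raise ValueError("empty collection")
    background = set(background)
    query = set(query) & background
    if not query:
        raise ValueError("no query genes inside the background")
    rows = []
    for set_name in sorted(collection.sets):
        target = collection.sets[set_name] & background
        if not (min_set <= len(target) <= max_set):
            continue
        res = hypergeometric_overlap_test(query, target, background)
        rows.append(
            {
                "set_name": set_name,
                "overlap_k": res["k"],
                "set_size": res["K"],
                "query_size": res["n"],
                "background_size": res["N"],
                "p_raw": res["p_value"],
                "overlap_genes": ",".join(res["overlap_genes"]),
            }
        )
    data = pd.DataFrame(
        rows,
        columns=[
            "set_name",
            "overlap_k",
            "set_size",
            "query_size",
            "background_size",
            "p_raw",
            "overlap_genes",
        ],
    )
    if len(data):
        _, adj, _, _ = multipletests(data["p_raw"], method="fdr_bh")
        data["p_adjusted"] = adj
        data["significant"] = data["p_adjusted"] < 0.05
        data = data.sort_values(
            ["p_raw", "set_name"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        data["p_adjusted"] = pd.Series(dtype=float)
        data["significant"] = pd.Series(dtype=bool)
    return EnrichmentResult(
        data=data,
        query_name=query_name,
        background_size=len(background),
        correction=correction,
    )


def multi_set_enrichment_matrix(
    queries: Mapping[str, Iterable[str]],
    collection: GeneSetCollection,
    background: Iterable[str],
    min_set: int = 3,
    max_set: int = 1000,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.Series]:
    """Adjusted-p matrix (gene set × query) plus per-set significance counts.

    Each query is enriched (and BH-adjusted) independently; the counts
    series supports "significant in at least m queries" filtering.
    """
    if len(queries) < 2:
        raise ValueError("need at least two query sets")
    background = set(background)
    columns = {}
    for qname, qgenes in queries.items():
        result = enrich_collection(
            qgenes,
            collection,
            background,
            min_set=min_set,
            max_set=max_set,
            query_name=qname,
        )
        columns[qname] = result.data.set_index("set_name")["p_adjusted"]
    matrix = pd.DataFrame(columns).sort_index()
    counts = (matrix < alpha).sum(axis=1)
    counts.name = "n_queries_significant"
    return matrix, counts


def filter_matrix(
    matrix: pd.DataFrame, counts: pd.Series, min_queries: int, alpha: float = 0.05
) -> pd.DataFrame:
    """View of the matrix keeping sets significant in >= min_queries queries.

    Non-significant cells are blanked (NaN), mirroring the published
    table layout where a cell shows the adjusted p only when significant.
    """
    kept = matrix.loc[counts[counts >= min_queries].index]
    return kept.where(kept < alpha)
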