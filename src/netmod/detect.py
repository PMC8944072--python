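"""Active-module detection by p-value threshold sweep.

Genes are ranked by association p-value; for an increasing sequence of
cutoffs t the set {genes with p < t present in the network} is formed, its
induced largest connected component (LCC) measured, and the size compared
against random gene sets of the same size (degree-matched by default) to
give a z-score. The module is the LCC with z above ``z_min`` whose size
falls in a reasonable-module band (30-100 by default); among qualifying
rows the highest z wins, ties resolved toward the smallest threshold so
the module is built from the smallest p-values. The sweep stops early once
the LCC outgrows ``hard_cap``, at which point no reasonable module can
appear at higher cutoffs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _kernels
from .graph import Network
from .nulls import NullModelConfig, bins_for, null_statistics, z_score
from .scores import GeneScoreTable, restrict_to_network

logger = logging.getLogger(__name__)


class EmptyGridError(ValueError):
    """No admissible thresholds below the requested maximum."""


@dataclass(frozen=True)
class SelectionRule:
    """Module acceptance rule: significance and size band.

    Defaults implement the published convention: z above 1.6, module size
    between 30 and 100 genes, and a sweep early stop once the LCC exceeds
    300 genes (already far too large for a coherent disease module).
    """

    z_min: float = 1.6
    size_min: int = 30
    size_max: int = 100
    hard_cap: int = 300

    def __post_init__(self) -> None:
        if not (0 < self.size_min <= self.size_max < self.hard_cap):
            raise ValueError("require 0 < size_min <= size_max < hard_cap")


@dataclass
class SweepRow:
    threshold: float
    n_genes_below: int
    lcc_size: int
    null_mean: float
    null_sd: float
    z_score: float | None  # None when the null is degenerate (sd == 0)
    lcc_members: frozenset[str]


@dataclass
class SweepResult:
    rows: list[SweepRow]
    dataset_name: str
    null_config: NullModelConfig

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class Module:
    members: frozenset[str]
    threshold: float
    z_score: float
    lcc_size: int
    dataset_name: str
    provenance: dict = field(default_factory=dict)


@dataclass
class NoModuleReport:
    """Structured negative result: no sweep row satisfied the rule."""

    dataset_name: str
    n_rows: int
    nearest_miss: list[dict]
    rule: SelectionRule


def make_threshold_grid(
    table: GeneScoreTable, max_threshold: float = 0.05, max_points: int = 60
) -> np.ndarray:
    """Data-driven strict-cutoff grid over the observed p-values.

    Each distinct p-value at or below ``max_threshold`` is bumped to the
    midpoint toward the next distinct p-value so that, used as a strict
    cutoff (p < t), it admits its own gene; the grid is thinned evenly to
    at most ``max_points`` thresholds.
    """
    if len(table) == 0:
        raise EmptyGridError("empty score table")
    if not (0 < max_threshold <= 1):
        raise ValueError("max_threshold must lie in (0, 1]")
    ps = np.unique(table.data["p_value"].to_numpy())
    admissible = ps[ps <= max_threshold]
    if admissible.size == 0:
        raise EmptyGridError(f"no p-values at or below {max_threshold}")
    cuts = np.empty(admissible.size)
    for i, p in enumerate(admissible):
        later = ps[ps > p]
        if later.size:
            cuts[i] = (p + later[0]) / 2
        elif p < 1.0:
            cuts[i] = p + (1.0 - p) / 2
        else:  # p == 1 can never pass a strict cutoff
            cuts[i] = np.inf
    cuts = cuts[np.isfinite(cuts)]
    if cuts.size == 0:
        raise EmptyGridError("no strict cutoff can admit the observed p-values")
    if cuts.size > max_points:
        # even thinning that always retains the largest cutoff (so the most
        # inclusive gene set stays reachable even at max_points == 1)
        idx = np.unique(
            np.round(np.linspace(cuts.size - 1, 0, max_points)).astype(int)
        )
        cuts = cuts[idx]
    return cuts


def run_sweep(
    net: Network,
    table: GeneScoreTable,
    grid: np.ndarray,
    null: NullModelConfig,
    rule: SelectionRule = SelectionRule(),
    rng: np.random.Generator | None = None,
) -> SweepResult:
    """One SweepRow per threshold, with early stop past ``rule.hard_cap``.

    The null set size at each threshold equals the number of sub-threshold
    genes present in the network (the observed selection is mirrored, not
    the LCC size), and the degree-matched draws match that gene set's
    degree-bin histogram.
    """
    if len(grid) == 0:
        raise EmptyGridError("empty threshold grid")
    if rng is None:
        rng = null.rng()
    table = restrict_to_network(table, net)
    if len(table) == 0:
        raise ValueError("no scored genes present in the network")
    order, index, indptr, indices = net.csr()
    genes = table.data.index.to_numpy()
    pvals = table.data["p_value"].to_numpy()
    gene_idx = np.array([index[g] for g in genes], dtype=np.int64)
    bins = bins_for(net, null)

    rows: list[SweepRow] = []
    for t in np.sort(np.asarray(grid, dtype=float)):
        below = pvals < t
        members = gene_idx[below]
        k = int(members.size)
        if k == 0:
            continue
        lcc_nodes = _lcc_member_indices(net, members)
        lcc_size = len(lcc_nodes)
        counts = bins.counts_for(members)
        null_sizes = null_statistics(
            bins, counts, None, null.n_samples, rng, _kernels.STAT_LCC
        )
        z, mean, sd = z_score(lcc_size, null_sizes)
        if z is None:
            logger.info(
                "%s: degenerate null (sd=0) at threshold %.4g", table.dataset_name, t
            )
        rows.append(
            SweepRow(
                threshold=float(t),
                n_genes_below=k,
                lcc_size=lcc_size,
                null_mean=mean,
                null_sd=sd,
                z_score=z,
                lcc_members=frozenset(order[i] for i in lcc_nodes),
            )
        )
        if lcc_size > rule.hard_cap:
            logger.info(
                "%s: early stop at threshold %.4g (LCC %d > hard cap %d)",
                table.dataset_name,
                t,
                lcc_size,
                rule.hard_cap,
            )
            break
    return SweepResult(rows=rows, dataset_name=table.dataset_name, null_config=null)


def _lcc_member_indices(net: Network, members: np.ndarray) -> list[int]:
    """Node indices of the largest connected induced component (lexicographic tie-break)."""
    import networkx as nx

    order, _, _, _ = net.csr()
    names = [order[i] for i in members]
    sub = net.graph.subgraph(names)
    if sub.number_of_nodes() == 0:
        return []
    comp = max(nx.connected_components(sub), key=lambda c: (len(c), min(c)))
    index = {g: i for i, g in enumerate(order)}
    return [index[g] for g in comp]


def select_module(
    sweep: SweepResult, rule: SelectionRule = SelectionRule()
) -> Module | NoModuleReport:
    """Apply the acceptance rule to a sweep.

    Eligible rows have a defined z strictly above ``z_min`` and an LCC
    size inside [size_min, size_max]; the highest z wins, with ties broken
    toward the smallest threshold. When nothing qualifies a
    :class:`NoModuleReport` lists the nearest misses.
    """
    if not sweep.rows:
        raise ValueError("empty sweep")
    eligible = [
        r
        for r in sweep.rows
        if r.z_score is not None
        and r.z_score > rule.z_min
        and rule.size_min <= r.lcc_size <= rule.size_max
    ]
    if eligible:
        best = max(eligible, key=lambda r: (r.z_score, -r.threshold))
        return Module(
            members=best.lcc_members,
            threshold=best.threshold,
            z_score=best.z_score,
            lcc_size=best.lcc_size,
            dataset_name=sweep.dataset_name,
            provenance={
                "null_method": sweep.null_config.method,
                "n_samples": sweep.null_config.n_samples,
                "seed": sweep.null_config.seed,
                "rule": vars(rule),
            },
        )
    scored = sorted(
        (r for r in sweep.rows if r.z_score is not None),
        key=lambda r: -r.z_score,
    )
    nearest = [
        {
            "threshold": r.threshold,
            "lcc_size": r.lcc_size,
            "z_score": r.z_score,
            "reasons": _miss_reasons(r, rule),
        }
        for r in scored[:3]
    ]
    return NoModuleReport(
        dataset_name=sweep.dataset_name,
        n_rows=len(sweep.rows),
        nearest_miss=nearest,
        rule=rule,
    )


def _miss_reasons(row: SweepRow, rule: SelectionRule) -> list[str]:
    reasons = []
    if row.z_score is None or row.z_score <= rule.z_min:
        reasons.append(f"z <= {rule.z_min}")
    if row.lcc_size < rule.size_min:
        reasons.append(f"size < {rule.size_min}")
    if row.lcc_size > rule.size_max:
        reasons.append(f"size > {rule.size_max}")
    return reasons


def detect_module(
    net: Network,
    table: GeneScoreTable,
    null: NullModelConfig = NullModelConfig(),
    rule: SelectionRule = SelectionRule(),
    max_threshold: float = 0.05,
    max_points: int = 60,
    rng: np.random.Generator | None = None,
) -> tuple[Module | NoModuleReport, SweepResult]:
    """Grid → sweep → selection, returning both the verdict and the trace."""
    table = restrict_to_network(table, net)
    grid = make_threshold_grid(table, max_threshold=max_threshold, max_points=max_points)
    sweep = run_sweep(net, table, grid, null, rule, rng=rng)
    return select_module(sweep, rule), sweep


def write_sweep_trace(sweep: SweepResult, path: str | Path) -> None:
    """Threshold-vs-z trace (plot-data file for the cutoff/z curve)."""
    with open(path, "w") as fh:
        fh.write("threshold\tn_genes\tlcc_size\tnull_mean\tnull_sd\tz\n")
        for r in sweep.rows:
            z = f"{r.z_score:.6g}" if r.z_score is not None else "NA"
            fh.write(
                f"{r.threshold:.10g}\t{r.n_genes_below}\t{r.lcc_size}\t"
                f"{r.null_mean:.6g}\t{r.null_sd:.6g}\t{z}\n"
            )


def write_module(module: Module, path_prefix: str | Path) -> tuple[Path, Path]:
    """Gene list (one per line) plus a JSON provenance block."""
    prefix = Path(path_prefix)
    genes_path = prefix.with_suffix(".genes.txt")
    meta_path = prefix.with_suffix(".json")
    with open(genes_path, "w") as fh:
        for g in sorted(module.members):
            fh.write(g + "\n")
    with open(meta_path, "w") as fh:
        json.dump(
            {
                "dataset": module.dataset_name,
                "threshold": module.threshold,
                "z_score": module.z_score,
                "lcc_size": module.lcc_size,
                "provenance": module.provenance,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    return genes_path, meta_path
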