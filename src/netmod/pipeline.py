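"""End-to-end orchestration: data → modules → connectivity → enrichment.

One :func:`run_pipeline` call reproduces the full analysis graph for a set
of datasets over one interactome: per-dataset module detection, all
pairwise inter-module connectivity tests, interactor extraction, the union
component export, disease-gene overlap and connectivity tests, enrichment
of the modules and the per-direction interactor sets, and (optionally)
cross-interactome robustness. Every stage derives its own random substream
from the run seed, so a config snapshot reproduces a run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .connectivity import (
    edge_type_composition_test,
    find_interactors,
    gene_set_connectivity,
    inter_module_significance,
    union_component,
    write_connectivity_report,
    write_interactor_table,
)
from .detect import (
    Module,
    NoModuleReport,
    SelectionRule,
    detect_module,
    write_module,
    write_sweep_trace,
)
from .enrichment import (
    GeneSetCollection,
    enrich_collection,
    filter_matrix,
    hypergeometric_overlap_test,
    multi_set_enrichment_matrix,
    read_gene_list,
)
from .graph import Network, export_subnetwork, largest_connected_component, load_edge_list
from .nulls import NullModelConfig
from .robustness import cross_ppi_robustness
from .scores import GeneScoreTable

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated run configuration (see ``config.yaml`` written by simulate)."""

    network_path: Path
    score_paths: list[tuple[Path, str]]  # (path, dataset label)
    output_dir: Path
    seed: int = 0
    network_dialect: str = "generic"
    physical_path: Path | None = None
    null: NullModelConfig = field(default_factory=NullModelConfig)
    rule: SelectionRule = field(default_factory=SelectionRule)
    max_threshold: float = 0.05
    max_points: int = 60
    collections: list[Path] = field(default_factory=list)
    background_mode: str = "network_lcc"  # or a gene-list file path
    correction: str = "benjamini_hochberg"
    min_set: int = 3
    max_set: int = 1000
    disease_gene_lists: list[Path] = field(default_factory=list)
    robustness_networks: list[tuple[Path, str, str]] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = path.parent

        def resolve(p: str) -> Path:
            q = Path(p)
            return q if q.is_absolute() else base / q

        null_raw = raw.get("null_model", {})
        sel_raw = dict(raw.get("selection", {}))
        max_threshold = sel_raw.pop("max_threshold", 0.05)
        max_points = sel_raw.pop("max_points", 60)
        enr = raw.get("enrichment", {})
        background = enr.get("background", "network_lcc")
        cfg = cls(
            network_path=resolve(raw["network"]["path"]),
            network_dialect=raw["network"].get("dialect", "generic"),
            physical_path=(
                resolve(raw["network"]["physical_path"])
                if raw["network"].get("physical_path")
                else None
            ),
            score_paths=[
                (resolve(s["path"]), s.get("name", Path(s["path"]).stem))
                for s in raw["scores"]
            ],
            output_dir=resolve(raw.get("output_dir", "run")),
            seed=int(raw.get("seed", 0)),
            null=NullModelConfig(
                method=null_raw.get("method", "degree_binned"),
                n_samples=int(null_raw.get("n_samples", 10_000)),
                min_bin_size=int(null_raw.get("min_bin_size", 100)),
                seed=int(raw.get("seed", 0)),
            ),
            rule=SelectionRule(**sel_raw) if sel_raw else SelectionRule(),
            max_threshold=float(max_threshold),
            max_points=int(max_points),
            collections=[resolve(p) for p in enr.get("collections", [])],
            background_mode=(
                background if background == "network_lcc" else str(resolve(background))
            ),
            correction=enr.get("correction", "benjamini_hochberg"),
            min_set=int(enr.get("min_set", 3)),
            max_set=int(enr.get("max_set", 1000)),
            disease_gene_lists=[resolve(p) for p in raw.get("disease_gene_lists", [])],
            robustness_networks=[
                (resolve(n["path"]), n.get("dialect", "generic"), n.get("name", Path(n["path"]).stem))
                for n in raw.get("robustness_networks", [])
            ],
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        """Fail fast: every referenced input must exist before any computation."""
        missing = [
            p
            for p in (
                [self.network_path]
                + [p for p, _ in self.score_paths]
                + self.collections
                + self.disease_gene_lists
                + [p for p, _, _ in self.robustness_networks]
                + ([self.physical_path] if self.physical_path else [])
                + (
                    [Path(self.background_mode)]
                    if self.background_mode != "network_lcc"
                    else []
                )
            )
            if not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(f"missing input files: {[str(p) for p in missing]}")


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([seed, stage])


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full analysis; returns the run directory.

    Layout: modules/, connectivity/, interactors/, enrichment/,
    robustness/ (when alternative networks are given), manifest.json,
    summary.txt. Stage failures abort, leaving a manifest that records
    the stages completed so far.
    """
    config.validate()
    out = Path(config.output_dir)
    for sub in ("modules", "connectivity", "interactors", "enrichment"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "null_model": vars(config.null),
        "selection_rule": vars(config.rule),
        "inputs": {
            "network": str(config.network_path),
            "scores": {name: str(p) for p, name in config.score_paths},
        },
        "stages": [],
        "outputs": {},
    }
    summary: list[str] = [f"netmod {__version__} run (seed {config.seed})", ""]

    def finish_stage(name: str, t0: float) -> None:
        manifest["stages"].append({"stage": name, "seconds": round(time.time() - t0, 3)})

    try:
        # ---- load inputs
        t0 = time.time()
        net = load_edge_list(
            config.network_path,
            dialect=config.network_dialect,
            physical_path=config.physical_path,
        )
        tables = [
            GeneScoreTable.read_tsv(p, dataset_name=name)
            for p, name in config.score_paths
        ]
        lcc = largest_connected_component(net)
        summary.append(
            f"network {net.name}: {net.number_of_nodes()} nodes, "
            f"{net.number_of_edges()} edges, LCC {lcc.size}"
        )
        finish_stage("load", t0)

        # ---- per-dataset module detection
        t0 = time.time()
        modules: dict[str, Module] = {}
        for i, table in enumerate(tables):
            rng = _stage_rng(config.seed, 100 + i)
            verdict, sweep = detect_module(
                net,
                table,
                null=config.null,
                rule=config.rule,
                max_threshold=config.max_threshold,
                max_points=config.max_points,
                rng=rng,
            )
            write_sweep_trace(sweep, out / "modules" / f"{table.dataset_name}.sweep.tsv")
            if isinstance(verdict, Module):
                modules[table.dataset_name] = verdict
                write_module(verdict, out / "modules" / table.dataset_name)
                summary.append(
                    f"module[{table.dataset_name}]: {verdict.lcc_size} genes, "
                    f"z={verdict.z_score:.3g} at threshold {verdict.threshold:.4g}"
                )
            else:
                with open(out / "modules" / f"{table.dataset_name}.no_module.json", "w") as fh:
                    json.dump(
                        {
                            "dataset": verdict.dataset_name,
                            "n_rows": verdict.n_rows,
                            "nearest_miss": verdict.nearest_miss,
                        },
                        fh,
                        indent=2,
                        sort_keys=True,
                    )
                summary.append(f"module[{table.dataset_name}]: no module found")
        finish_stage("detect", t0)

        module_sets = {name: set(m.members) for name, m in modules.items()}

        # ---- pairwise connectivity + interactors + union component
        t0 = time.time()
        names = sorted(module_sets)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                rng = _stage_rng(config.seed, 200 + i * len(names) + names.index(b))
                res = inter_module_significance(
                    net, module_sets[a], module_sets[b], null=config.null, rng=rng
                )
                res.labels = (a, b)
                write_connectivity_report(
                    res, out / "connectivity" / f"{a}__{b}.tsv"
                )
                if res.observed.total >= 1:
                    comp = edge_type_composition_test(res.observed, net)
                    with open(
                        out / "connectivity" / f"{a}__{b}.edge_types.json", "w"
                    ) as fh:
                        json.dump(comp, fh, indent=2, sort_keys=True)
                summary.append(
                    f"connectivity[{a}~{b}]: {res.observed.total} cross edges, "
                    f"p={res.empirical_p:.3g}, z={res.z_score:.3g}"
                    if res.z_score is not None
                    else f"connectivity[{a}~{b}]: degenerate null"
                )
        if len(module_sets) >= 2:
            interactors = find_interactors(net, module_sets)
            write_interactor_table(
                interactors, module_sets, out / "interactors" / "interactors.tsv"
            )
            interactors.pair_summary.to_csv(
                out / "interactors" / "pair_summary.tsv", sep="\t", index=False
            )
            summary.append(f"interactors: {len(interactors.genes())} genes")
            view, annotation = union_component(net, module_sets)
            if view.size:
                export_subnetwork(
                    net,
                    view.member_nodes,
                    out / "connectivity" / "union_component",
                    annotations={
                        g: {"modules": "|".join(mods)} for g, mods in annotation.items()
                    },
                )
                summary.append(f"union component: {view.size} genes")
        finish_stage("connectivity", t0)

        # ---- background for enrichment / overlap tests
        if config.background_mode == "network_lcc":
            background = set(lcc.member_nodes)
        else:
            background = read_gene_list(config.background_mode)
        manifest["background_size"] = len(background)

        # ---- disease-gene analyses
        t0 = time.time()
        for j, dg_path in enumerate(config.disease_gene_lists):
            disease_genes = read_gene_list(dg_path)
            label = Path(dg_path).stem
            overlaps = {}
            for name, genes in module_sets.items():
                overlaps[name] = hypergeometric_overlap_test(
                    genes, disease_genes, background
                )
            rng = _stage_rng(config.seed, 300 + j)
            try:
                conn = gene_set_connectivity(
                    net, disease_genes, null=config.null, rng=rng
                )
                conn_block = {
                    "observed": conn.observed_value,
                    "statistic": conn.statistic,
                    "z": conn.z_score,
                    "empirical_p": conn.empirical_p,
                }
            except ValueError:
                conn_block = None
            with open(out / "enrichment" / f"disease_overlap.{label}.json", "w") as fh:
                json.dump(
                    {"overlaps": overlaps, "connectivity": conn_block},
                    fh,
                    indent=2,
                    sort_keys=True,
                )
        finish_stage("disease_genes", t0)

        # ---- enrichment of the module and interactor gene sets
        t0 = time.time()
        queries: dict[str, set[str]] = {
            f"module:{name}": genes for name, genes in module_sets.items()
        }
        if len(module_sets) >= 2:
            interactors = find_interactors(net, module_sets)
            for (home, target), grp in interactors.data.groupby(
                ["home_module", "target_module"]
            ):
                queries[f"interactors:{home}->{target}"] = set(grp["gene"])
        for coll_path in config.collections:
            collection = GeneSetCollection.read_gmt(coll_path)
            for qname, qgenes in sorted(queries.items()):
                try:
                    result = enrich_collection(
                        qgenes,
                        collection,
                        background,
                        correction=config.correction,
                        min_set=config.min_set,
                        max_set=config.max_set,
                        query_name=qname,
                    )
                except ValueError:
                    continue
                safe = qname.replace(":", "_").replace("->", "_to_")
                result.write_tsv(
                    out / "enrichment" / f"{collection.name}.{safe}.tsv"
                )
            if len(queries) >= 2:
                matrix, counts = multi_set_enrichment_matrix(
                    queries,
                    collection,
                    background,
                    min_set=config.min_set,
                    max_set=config.max_set,
                )
                matrix.to_csv(
                    out / "enrichment" / f"{collection.name}.matrix.tsv",
                    sep="\t",
                    float_format="%.6g",
                )
                counts.to_csv(
                    out / "enrichment" / f"{collection.name}.counts.tsv", sep="\t"
                )
                filtered = filter_matrix(matrix, counts, min_queries=4)
                filtered.to_csv(
                    out / "enrichment" / f"{collection.name}.matrix.min4.tsv",
                    sep="\t",
                    float_format="%.6g",
                )
        finish_stage("enrichment", t0)

        # ---- robustness in alternative interactomes
        if config.robustness_networks and modules:
            t0 = time.time()
            (out / "robustness").mkdir(exist_ok=True)
            alt_nets = [
                load_edge_list(p, dialect=d, name=n)
                for p, d, n in config.robustness_networks
            ]
            for j, (name, module) in enumerate(sorted(modules.items())):
                rng = _stage_rng(config.seed, 400 + j)
                report = cross_ppi_robustness(
                    module.members, alt_nets, null=config.null, rng=rng
                )
                report.write_tsv(out / "robustness" / f"{name}.tsv")
            finish_stage("robustness", t0)
    finally:
        manifest["outputs"] = {
            str(p.relative_to(out)): _digest(p)
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.name not in ("manifest.json", "summary.txt")
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        with open(out / "summary.txt", "w") as fh:
            fh.write("\n".join(summary) + "\n")
    return out
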