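# netmod — active-module detection and connectivity analysis on typed interactomes

`netmod` implements a network-medicine pipeline for linking gene-level
association results (e.g. differential-methylation or differential-expression
p-values) to *disease modules* on a protein–protein interaction (PPI) network
whose edges are typed `physical`, `functional`, or `both`. It is aimed at
systems-biology analysts who have per-gene p-values from one or more studies
and want to ask: do the top-ranked genes form a significantly connected
subnetwork, and are the modules from different studies wired to each other
more than chance allows?

## The method

**Module detection (threshold sweep).** Genes are ranked by p-value. For an
increasing sequence of cutoffs *t* (data-driven: each observed p-value bumped
to the midpoint toward the next, so `p < t` admits it), the pipeline forms
the gene set *S(t) = {g : p_g < t}*, measures the size *L(t)* of the largest
connected component (LCC) induced by *S(t)*, and standardizes it against
random gene sets of the same size:

    z(t) = (L(t) − μ_null(t)) / σ_null(t)

where the null draws (default 10⁴ per threshold) preserve the degree
composition of *S(t)* via ascending-degree bins of ≥ 100 nodes — the standard
guard against hub-driven connectivity. The **module** is the LCC with
`z > 1.6` and size in [30, 100]; among qualifying rows the highest z wins,
ties going to the smallest threshold. The sweep stops early once the LCC
exceeds 300 genes. An abstention ("no module") is a first-class result.

**Inter-module statistics.** For two modules A, B the pipeline tallies
cross edges by type, tests the count against jointly resampled degree-matched
disjoint surrogate pairs (add-one empirical p-value `(r+1)/(n+1)` and z),
extracts *interactors* (genes of one module with ≥ 1 direct edge into
another), and tests edge-type bias with a hypergeometric draw from the
network-wide typed-edge population. A within-set variant scores the
connectivity of an arbitrary gene list (e.g. literature disease genes).

**Robustness and enrichment.** A module can be re-scored on alternative
interactomes (induced LCC vs degree-matched null per network), and any gene
set can be tested for overlap against GMT collections with an explicit
background (default: the interactome's LCC gene universe) under
Benjamini–Hochberg correction.

**Synthetic scenarios.** A generator produces the study design end to end:
a clustered scale-free network (preferential attachment with triad
formation), three planted connected modules with excess internal density,
Beta(a, 1) p-values on planted genes vs Uniform(0, 1) background, and
planted excess cross edges between module pairs — with serialized ground
truth, so every stage is testable offline.

## Worked example

```
netmod simulate --out scen --seed 5
netmod netstats scen/network.tsv
netmod run --config scen/config.yaml --out scen/run
```

`simulate` writes the default study scenario: a 2,000-gene clustered
scale-free interactome with three planted modules of 50, 37, and 64 genes
(one "exposure" and two "disease" datasets) and 40 extra functional edges
wired from the exposure module to each disease module. `netstats` prints:

```
nodes	2000
edges	6071
edges_physical	1952
edges_functional	3474
edges_both	645
lcc_size	2000
```

i.e. 6,071 typed edges (~32% physical, ~57% functional, ~11% both, the
configured composition) on a fully connected network. The pipeline run
writes `modules/` (per-dataset sweep traces and module gene lists with JSON
provenance), `connectivity/` (pairwise cross-edge reports and edge-type
tests), `interactors/`, `enrichment/`, a `manifest.json` with SHA-256
digests of every output, and a human-readable `summary.txt`:

```
netmod 0.1.0 run (seed 5)

network network: 2000 nodes, 6071 edges, LCC 2000
module[exposure]: 33 genes, z=18.7 at threshold 0.006306
module[disease1]: 30 genes, z=14.5 at threshold 0.01268
module[disease2]: 38 genes, z=27.4 at threshold 0.005963
connectivity[disease1~disease2]: 0 cross edges, p=1, z=-2.15
connectivity[disease1~exposure]: 33 cross edges, p=0.0001, z=8.85
connectivity[disease2~exposure]: 19 cross edges, p=0.0012, z=3.98
interactors: 62 genes
union component: 101 genes
```

Reading the numbers: each dataset yields a significantly connected module
(z far above the 1.6 acceptance line, sizes inside the 30–100 band at small
p-value cutoffs). The exposure module is wired to both disease modules far
above degree-matched expectation (33 and 19 cross edges, permutation
p ≈ 10⁻⁴ and 1.2×10⁻³) — these are the planted links — while the two
disease modules, between which nothing was planted, show zero cross edges
and a null-consistent result (p = 1). Sixty-two interactor genes carry the
module-to-module links, and the module union forms one 101-gene connected
component. Identical config + seed reproduces every table byte-for-byte.

The same operations are importable as a library
(`netmod.detect_module`, `netmod.inter_module_significance`,
`netmod.find_interactors`, `netmod.enrich_collection`, ...), all returning
plain dataclasses and pandas DataFrames.

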