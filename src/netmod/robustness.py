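"""Cross-interactome robustness: does a module stay connected elsewhere?

A module detected on one interactome is re-evaluated on alternative PPI
networks: its genes are mapped into each network (explicit identifier
mapping files only — no fuzzy matching), the induced LCC measured, and the
size scored against degree-matched random sets of the same mapped-gene
count. A module whose connectedness is an artifact of one network's
peculiarities will not reproduce a significant z elsewhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .graph import Network
from .nulls import NullModelConfig, bins_for, null_statistics, z_score

logger = logging.getLogger(__name__)

# z threshold reused from the module selection rule for coherence; the
# choice of criterion is an assumption and is labelled in the output.
DEFAULT_Z_MIN = 1.6


@dataclass
class RobustnessReport:
    """One row per network: mapped genes, LCC size, z, significance flag."""

    data: pd.DataFrame
    module_size: int
    z_min: float

    def write_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        with open(path, "w") as fh:
            fh.write(f"# module_size\t{self.module_size}\n")
            fh.write(f"# significance_criterion\tz > {self.z_min} (assumption)\n")
            out.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def cross_ppi_robustness(
    module_genes: Iterable[str],
    networks: Sequence[Network],
    null: NullModelConfig = NullModelConfig(),
    id_mappings: Mapping[str, Mapping[str, str]] | None = None,
    z_min: float = DEFAULT_Z_MIN,
    rng: np.random.Generator | None = None,
) -> RobustnessReport:
    """Evaluate a module's connectedness in each alternative network.

    ``id_mappings`` optionally maps, per network name, the module's
    identifiers into that network's identifier scheme. Networks in which
    no module gene maps are reported as not assessable rather than
    failing the whole analysis.
    """
    module_genes = set(module_genes)
    if not module_genes:
        raise ValueError("empty module")
    if not networks:
        raise ValueError("need at least one network")
    if rng is None:
        rng = null.rng()
    rows = []
    for net in networks:
        mapping = (id_mappings or {}).get(net.name)
        genes = (
            {mapping.get(g, g) for g in module_genes} if mapping else set(module_genes)
        )
        mapped = genes & net.nodes
        missing = len(module_genes) - len(mapped)
        if missing:
            logger.info("%s: %d module genes not found", net.name, missing)
        if not mapped:
            rows.append(
                {
                    "network": net.name,
                    "genes_found": 0,
                    "lcc_size": 0,
                    "null_mean": np.nan,
                    "null_sd": np.nan,
                    "z_score": np.nan,
                    "significant": False,
                    "assessable": False,
                }
            )
            continue
        _, index, indptr, indices = net.csr()
        idx = np.array(sorted(index[g] for g in mapped), dtype=np.int64)
        lcc_size = _kernels.induced_lcc_size(indptr, indices, idx)
        bins = bins_for(net, null)
        null_sizes = null_statistics(
            bins, bins.counts_for(idx), None, null.n_samples, rng, _kernels.STAT_LCC
        )
        z, mean, sd = z_score(lcc_size, null_sizes)
        rows.append(
            {
                "network": net.name,
                "genes_found": len(mapped),
                "lcc_size": lcc_size,
                "null_mean": mean,
                "null_sd": sd,
                "z_score": np.nan if z is None else z,
                "significant": bool(z is not None and z > z_min),
                "assessable": True,
            }
        )
    return RobustnessReport(
        data=pd.DataFrame(rows), module_size=len(module_genes), z_min=z_min
    )
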