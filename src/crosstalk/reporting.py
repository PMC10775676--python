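"""Run-level reporting: Venn partition of per-population DEG sets and
z-scored heatmap matrices with hierarchical clustering order."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .de import ExpressionMatrix


@dataclass
class VennPartition:
    """The 7 disjoint regions of three gene sets, keyed by the sorted tuple
    of set labels whose intersection (and nothing more) the region is."""

    labels: tuple[str, str, str]
    regions: dict[tuple[str, ...], list[str]]
    totals: dict[str, int]

    def region(self, *labels: str) -> list[str]:
        return self.regions[tuple(sorted(labels))]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"region": "&".join(key), "n_genes": len(genes), "genes": ",".join(genes)}
            for key, genes in sorted(self.regions.items())
        ]
        return pd.DataFrame(rows)


def venn_partition(
    set_a: Iterable[str],
    set_b: Iterable[str],
    set_c: Iterable[str],
    labels: Sequence[str] = ("EC", "PC", "NG"),
) -> VennPartition:
    """Exact 7-region partition of three gene sets.

    Region totals are recomputed from the partition and asserted against
    the input cardinalities, so any bookkeeping error fails loudly.
    """
    sets = {labels[0]: set(set_a), labels[1]: set(set_b), labels[2]: set(set_c)}
    la, lb, lc = labels
    regions: dict[tuple[str, ...], list[str]] = {}
    regions[tuple(sorted((la, lb, lc)))] = sorted(sets[la] & sets[lb] & sets[lc])
    for x, y in ((la, lb), (la, lc), (lb, lc)):
        z = ({la, lb, lc} - {x, y}).pop()
        regions[tuple(sorted((x, y)))] = sorted((sets[x] & sets[y]) - sets[z])
    for x in (la, lb, lc):
        others = [sets[y] for y in (la, lb, lc) if y != x]
        regions[(x,)] = sorted(sets[x] - others[0] - others[1])

    totals = {
        x: sum(len(genes) for key, genes in regions.items() if x in key)
        for x in (la, lb, lc)
    }
    # hard consistency checks: disjointness and reconstruction
    all_region_genes = [g for genes in regions.values() for g in genes]
    assert len(all_region_genes) == len(set(all_region_genes)), "regions overlap"
    assert set(all_region_genes) == sets[la] | sets[lb] | sets[lc], "union mismatch"
    for x in (la, lb, lc):
        assert totals[x] == len(sets[x]), f"total mismatch for {x}"
    return VennPartition((la, lb, lc), regions, totals)


@dataclass
class HeatmapSpec:
    gene_order: list[str]
    sample_order: list[str]
    values: pd.DataFrame  # z-scored, rows in gene_order
    linkage_method: str
    metric: str
    excluded_genes: list[str]


def heatmap_matrix(
    expr: ExpressionMatrix | pd.DataFrame,
    genes: Sequence[str],
    samples: Sequence[str] | None = None,
    linkage_method: str = "average",
    metric: str = "correlation",
) -> HeatmapSpec:
    """Per-gene z-scored expression with a deterministic clustering order.

    Rows are z-scored (mean 0, SD 1); genes with zero variance are excluded
    and reported.  Genes are clustered agglomeratively on the chosen metric
    and returned in dendrogram leaf order; input genes are sorted by id
    before clustering so leaf order is reproducible under ties.
    """
    df = expr.values if isinstance(expr, ExpressionMatrix) else expr
    genes = sorted(set(genes) & set(df.index))
    cols = list(samples) if samples is not None else list(df.columns)
    sub = df.loc[genes, cols]
    sd = sub.std(axis=1, ddof=0)
    excluded = sorted(sub.index[sd == 0])
    sub = sub.loc[sd > 0]
    if len(sub) < 2:
        raise ValueError("need at least 2 genes with nonzero variance")
    z = sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1, ddof=0), axis=0)
    dist = pdist(z.to_numpy(), metric=metric)
    Z = linkage(dist, method=linkage_method)
    order = [z.index[i] for i in leaves_list(Z)]
    return HeatmapSpec(
        gene_order=order,
        sample_order=cols,
        values=z.loc[order],
        linkage_method=linkage_method,
        metric=metric,
        excluded_genes=excluded,
    )
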