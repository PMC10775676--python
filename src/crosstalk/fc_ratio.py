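"""Cell-type fold-change-ratio statistic: genes whose between-population
fold change is altered in lesion relative to control.

For an ordered pair of populations (A, B), differential expression A vs B is
computed separately within the lesion and the control condition.  The gene
universe is the union of genes passing the DEG gates in either condition;
for each such gene the statistic is the difference of log2 fold-change
magnitudes between conditions (the fold-change ratio on the log scale),
z-scored over the universe.  Genes at or beyond 1.96 SD above the mean are
flagged as cell-type-related genes altered under the disease state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .de import DEGSet, gate_degs


@dataclass
class FCRatioParams:
    alpha: float = 0.1
    fc_min: float = 1.5
    z_threshold: float = 1.96
    #: "abs_diff" takes |log2FC_lesion| - |log2FC_control| (difference of
    #: magnitudes); "signed_diff" takes the signed difference of log2FCs.
    magnitude_mode: str = "abs_diff"

    def __post_init__(self) -> None:
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be positive")
        if self.magnitude_mode not in ("abs_diff", "signed_diff"):
            raise ValueError(f"unknown magnitude_mode {self.magnitude_mode!r}")


class DegenerateUniverseError(ValueError):
    """The fold-change-ratio z-score is undefined (tiny universe or zero SD)."""


def compute_fc_ratio(
    de_lesion_ab: pd.DataFrame,
    de_control_ab: pd.DataFrame,
    params: FCRatioParams | None = None,
    pair: tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    """Fold-change-ratio table for one ordered population pair.

    Both inputs are DE result tables (A vs B within one condition) over the
    same gene universe.  Genes significant in only one condition contribute
    their estimated (not zeroed) log2FC on the non-significant side.

    Returns a DataFrame indexed by gene with columns pair, log2fc_lesion,
    log2fc_control, source, delta, z, flagged; only genes in the gated
    universe appear.
    """
    params = params or FCRatioParams()
    common = de_lesion_ab.index.intersection(de_control_ab.index)
    if len(common) != len(de_lesion_ab) or len(common) != len(de_control_ab):
        raise ValueError("lesion and control DE tables must cover the same genes")

    gated_lesion = set(gate_degs(de_lesion_ab, params.alpha, params.fc_min).genes)
    gated_control = set(gate_degs(de_control_ab, params.alpha, params.fc_min).genes)
    universe = sorted(gated_lesion | gated_control)
    if len(universe) < 2:
        raise DegenerateUniverseError(
            f"universe has {len(universe)} genes; the z-score needs at least 2"
        )

    lfc_l = de_lesion_ab.loc[universe, "log2fc"].to_numpy()
    lfc_c = de_control_ab.loc[universe, "log2fc"].to_numpy()
    if params.magnitude_mode == "abs_diff":
        delta = np.abs(lfc_l) - np.abs(lfc_c)
    else:
        delta = lfc_l - lfc_c
    sd = float(np.std(delta, ddof=1))
    if sd == 0:
        raise DegenerateUniverseError(
            "all fold-change-ratio values identical; z-score undefined"
        )
    z = (delta - delta.mean()) / sd
    source = [
        "both" if g in gated_lesion and g in gated_control
        else ("lesion_only" if g in gated_lesion else "control_only")
        for g in universe
    ]
    return pd.DataFrame(
        {
            "pair": f"{pair[0]}_vs_{pair[1]}",
            "log2fc_lesion": lfc_l,
            "log2fc_control": lfc_c,
            "source": source,
            "delta": delta,
            "z": z,
            "flagged": z >= params.z_threshold,
        },
        index=pd.Index(universe, name="gene"),
    )


def attribute_altered_genes(
    fc_tables: Mapping[tuple[str, str], pd.DataFrame],
    deg_sets: Mapping[str, DEGSet],
) -> dict[str, list[str]]:
    """Assign flagged genes to cell types.

    A gene is attributed to cell type A iff it is flagged in at least one
    pair involving A and it is a member of A's own lesion-vs-control DEG
    set.  A gene may be attributed to several cell types.
    """
    out: dict[str, set[str]] = {ct: set() for ct in deg_sets}
    for (a, b), table in fc_tables.items():
        flagged = set(table.index[table["flagged"]])
        for ct in (a, b):
            if ct in deg_sets:
                out[ct] |= flagged & set(deg_sets[ct].genes)
    return {ct: sorted(genes) for ct, genes in out.items()}


def write_fc_ratio_table(table: pd.DataFrame, path) -> None:
    table.reset_index().to_csv(path, sep="\t", index=False)
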