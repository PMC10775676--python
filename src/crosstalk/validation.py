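"""Sorted-population identity validation via marker genes.

Each sorted population's identity is checked by querying its marker genes
(selected at >= 70% sensitivity from reference atlases) within the
population's one-vs-rest differential profile, conditions pooled.  A
population is confirmed when at least half of its testable markers are
significantly up-regulated under the usual DEG gates; the rule and its
thresholds are configuration, since different marker panels warrant
different stringency.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .de import Contrast, ExpressionMatrix, fit_moderated_de, gate_degs
from .io import MarkerSet


class InsufficientMarkersError(ValueError):
    pass


@dataclass
class ValidationReport:
    cell_type: str
    n_markers_tested: int
    n_markers_upregulated: int
    fraction_up: float
    confirmed: bool
    markers_up: list[str]


def validate_population(
    expr: ExpressionMatrix,
    samples: pd.DataFrame,
    markers: MarkerSet,
    alpha: float = 0.1,
    fc_min: float = 1.5,
    min_fraction: float = 0.5,
    min_markers: int = 3,
    min_sensitivity: float = 0.7,
    include_batch: bool = False,
) -> ValidationReport:
    """One-vs-rest marker query for one population.

    Fits the moderated DE contrast (this cell type) vs (all other cell
    types, conditions pooled), gates at (alpha, fc_min), and confirms the
    population when the fraction of tested markers that are gated-up
    reaches ``min_fraction``.
    """
    cell_types = sorted(samples["cell_type"].unique())
    if markers.cell_type not in cell_types:
        raise ValueError(f"cell type {markers.cell_type!r} absent from sample table")
    others = [ct for ct in cell_types if ct != markers.cell_type]

    tested = [
        g for g in markers.usable_genes(min_sensitivity) if g in expr.values.index
    ]
    if len(tested) < min_markers:
        raise InsufficientMarkersError(
            f"insufficient markers for {markers.cell_type}: "
            f"{len(tested)} detected, {min_markers} required"
        )

    contrast = Contrast(
        {"cell_type": markers.cell_type},
        {"cell_type": others},
        include_batch=include_batch,
        name=f"{markers.cell_type} vs rest",
    )
    table = fit_moderated_de(expr, samples, contrast)
    degs = gate_degs(table, alpha=alpha, fc_min=fc_min, contrast=contrast.name)
    up = set(degs.up())
    markers_up = [g for g in tested if g in up]
    fraction = len(markers_up) / len(tested)
    return ValidationReport(
        cell_type=markers.cell_type,
        n_markers_tested=len(tested),
        n_markers_upregulated=len(markers_up),
        fraction_up=fraction,
        confirmed=fraction >= min_fraction,
        markers_up=markers_up,
    )


def validation_summary(reports: list[ValidationReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_type": r.cell_type,
                "n_markers_tested": r.n_markers_tested,
                "n_markers_upregulated": r.n_markers_upregulated,
                "fraction_up": r.fraction_up,
                "confirmed": r.confirmed,
            }
            for r in reports
        ]
    )
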