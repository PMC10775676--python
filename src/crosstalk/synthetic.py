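"""Synthetic sorted-population RNA-seq datasets with planted ground truth.

The generator emulates the study design this pipeline targets: three
FACS-sorted brain cell populations (endothelial cells ``EC``, pericytes
``PC``, neuroglia ``NG``) from lesion and non-lesional control subjects,
with two technical replicates per library and one lesion-EC library missing.
Counts are negative-binomial with a log-normal baseline, a mean-dispersion
trend, per-batch log2 offsets and log-normal library-size factors.  Planted
structure -- population markers, condition DEGs per cell type, and
ligand-receptor circuits active only in lesion -- is returned as ground
truth so every downstream stage has a parameter-recovery test surface.

Counts are post-quantification; read-level artefacts (alignment loss, UMI
structure, contamination) are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CountMatrix, LRDatabase, LRInteraction, MarkerSet


class ConfigurationError(ValueError):
    """Invalid synthetic-dataset configuration."""


@dataclass
class PlantedCircuit:
    """A ligand-receptor circuit switched on in the lesion condition.

    Ligand subunits are boosted in the sender population and receptor
    subunits in the receiver population, both by ``condition_effect_log2fc``
    log2 units in lesion samples only.  ``constitutive_log2fc`` applies the
    same sender/receiver boost in both conditions, modelling signaling that
    is present in healthy tissue as well; a circuit can combine both (a
    constitutive axis further amplified in lesion).  Optional agonist genes
    are boosted in the receiver alongside the receptor; antagonist genes
    are left at baseline.
    """

    ligand_genes: list[str]
    receptor_genes: list[str]
    sender: str
    receiver: str
    condition_effect_log2fc: float = 4.0
    pathway: str = "VEGF"
    agonist_genes: list[str] = field(default_factory=list)
    antagonist_genes: list[str] = field(default_factory=list)
    constitutive_log2fc: float = 0.0

    def all_genes(self) -> list[str]:
        return (
            self.ligand_genes + self.receptor_genes
            + self.agonist_genes + self.antagonist_genes
        )


def _default_circuits() -> list[PlantedCircuit]:
    # the emulated signaling landscape: a constitutive VEGF-like paracrine
    # axis (pericyte ligand onto the endothelial receptor) further amplified
    # in lesion, a second VEGF-pathway axis from neuroglia switched on only
    # in lesion (so the pathway's architecture changes between conditions),
    # NOTCH- and EphB-like endothelial autocrine circuits active only in
    # lesion, and a constitutive ECM-like axis identical in both conditions
    return [
        PlantedCircuit(
            ligand_genes=["LIG_VEGFA"],
            receptor_genes=["REC_KDR"],
            sender="PC",
            receiver="EC",
            condition_effect_log2fc=2.0,
            constitutive_log2fc=3.0,
            pathway="VEGF",
        ),
        PlantedCircuit(
            ligand_genes=["LIG_VEGFB"],
            receptor_genes=["REC_KDR"],
            sender="NG",
            receiver="EC",
            condition_effect_log2fc=4.0,
            pathway="VEGF",
        ),
        PlantedCircuit(
            ligand_genes=["LIG_DLL4"],
            receptor_genes=["REC_NOTCH4"],
            sender="EC",
            receiver="EC",
            condition_effect_log2fc=4.0,
            pathway="NOTCH",
        ),
        PlantedCircuit(
            ligand_genes=["LIG_EFNB2"],
            receptor_genes=["REC_EPHB4"],
            sender="EC",
            receiver="EC",
            condition_effect_log2fc=4.0,
            pathway="EPHB",
        ),
        PlantedCircuit(
            ligand_genes=["LIG_COL4A1"],
            receptor_genes=["REC_ITGA1", "REC_ITGB1"],
            sender="NG",
            receiver="PC",
            condition_effect_log2fc=0.0,
            constitutive_log2fc=3.0,
            pathway="ECM",
        ),
        PlantedCircuit(
            ligand_genes=["LIG_COL4A2"],
            receptor_genes=["REC_ITGA1", "REC_ITGB1"],
            sender="PC",
            receiver="NG",
            condition_effect_log2fc=0.0,
            constitutive_log2fc=3.0,
            pathway="ECM",
        ),
    ]


@dataclass
class SyntheticConfig:
    """Generator configuration; defaults mirror the emulated study design."""

    n_genes: int = 2000
    cell_types: Sequence[str] = ("EC", "PC", "NG")
    n_subjects_lesion: int = 6
    n_subjects_control: int = 4
    tech_replicates: int = 2
    n_markers_per_type: int = 30
    marker_log2fc: float = 4.0
    n_degs_per_type: int = 50
    deg_log2fc: float = 2.0
    lr_circuits: list[PlantedCircuit] = field(default_factory=_default_circuits)
    batch_sd: float = 0.25
    n_batches: int = 2
    nb_dispersion: tuple[float, float] = (1.0, 0.05)  # phi(m) = a/m + b
    baseline_log_mean_mu: float = 4.0
    baseline_log_mean_sd: float = 1.2
    #: planted-effect genes (markers, DEGs, circuit subunits) draw their
    #: baseline with this fraction of the log-SD, so a boosted gene perturbs
    #: but never dominates library composition
    planted_baseline_sd_factor: float = 0.5
    library_size_sd: float = 0.2
    seed: int = 0
    drop_samples: list[tuple[str, str, str]] = field(
        default_factory=lambda: [("lesion", "EC", "L6")]
    )

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if not self.cell_types:
            raise ConfigurationError("cell_types must be non-empty")
        if len(set(self.cell_types)) != len(self.cell_types):
            raise ConfigurationError("cell_types must be unique")
        if self.tech_replicates < 1:
            raise ConfigurationError("tech_replicates must be >= 1")
        if self.marker_log2fc < 0:
            raise ConfigurationError("marker_log2fc must be non-negative")
        if min(self.n_subjects_lesion, self.n_subjects_control) < 1:
            raise ConfigurationError("need at least one subject per condition")
        for circ in self.lr_circuits:
            if circ.sender not in self.cell_types or circ.receiver not in self.cell_types:
                raise ConfigurationError(
                    f"circuit sender/receiver must be configured cell types: "
                    f"{circ.sender}->{circ.receiver}"
                )
            if not circ.ligand_genes or not circ.receptor_genes:
                raise ConfigurationError("circuit subunit lists must be non-empty")


@dataclass
class GroundTruth:
    """What was planted: marker/DEG assignments, circuits and batches."""

    marker_assignments: dict[str, str]
    deg_assignments: dict[str, tuple[str, float]]
    circuit_table: list[PlantedCircuit]
    batch_assignments: dict[str, str]

    def markers_of(self, cell_type: str) -> list[str]:
        return sorted(g for g, ct in self.marker_assignments.items() if ct == cell_type)

    def degs_of(self, cell_type: str) -> dict[str, float]:
        return {
            g: lfc for g, (ct, lfc) in self.deg_assignments.items() if ct == cell_type
        }

    def to_dict(self) -> dict:
        return {
            "marker_assignments": self.marker_assignments,
            "deg_assignments": {g: list(v) for g, v in self.deg_assignments.items()},
            "circuit_table": [asdict(c) for c in self.circuit_table],
            "batch_assignments": self.batch_assignments,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            marker_assignments=dict(d["marker_assignments"]),
            deg_assignments={g: (v[0], float(v[1])) for g, v in d["deg_assignments"].items()},
            circuit_table=[PlantedCircuit(**c) for c in d["circuit_table"]],
            batch_assignments=dict(d["batch_assignments"]),
        )


def _build_sample_frame(config: SyntheticConfig) -> pd.DataFrame:
    rows = []
    subjects = [("lesion", f"L{i + 1}") for i in range(config.n_subjects_lesion)]
    subjects += [("control", f"C{i + 1}") for i in range(config.n_subjects_control)]
    dropped = {tuple(t) for t in config.drop_samples}
    for si, (cond, subj) in enumerate(subjects):
        batch = f"B{si % config.n_batches + 1}"
        for ct in config.cell_types:
            if (cond, ct, subj) in dropped:
                continue
            for rep in range(1, config.tech_replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{cond}_{ct}_{subj}_r{rep}",
                        "condition": cond,
                        "cell_type": ct,
                        "subject": subj,
                        "batch": batch,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows)


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[CountMatrix, pd.DataFrame, GroundTruth]:
    """Draw one synthetic dataset.

    Returns the count matrix, the sample metadata table and the planted
    ground truth.  Counts for gene g, sample s are NB with mean

        ``exp(base_g) * 2**(planted effects + batch offset) * libfactor_s``

    and gene-wise dispersion ``a/mean + b`` evaluated at the baseline mean.
    All randomness derives from ``config.seed``; a fixed seed reproduces the
    dataset byte-for-byte.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    samples = _build_sample_frame(config)
    n_samples = len(samples)

    # gene universe: background pool plus any circuit genes not already named
    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    circuit_genes: list[str] = []
    for circ in config.lr_circuits:
        for g in circ.all_genes():
            if g not in gene_ids and g not in circuit_genes:
                circuit_genes.append(g)
    gene_ids = gene_ids + circuit_genes
    n_genes = len(gene_ids)
    gene_index = {g: i for i, g in enumerate(gene_ids)}

    # planted assignments drawn from the background pool, disjointly
    pool = rng.permutation(config.n_genes)
    cursor = 0
    marker_assignments: dict[str, str] = {}
    deg_assignments: dict[str, tuple[str, float]] = {}
    for ct in config.cell_types:
        for _ in range(config.n_markers_per_type):
            marker_assignments[gene_ids[pool[cursor]]] = ct
            cursor += 1
    for ct in config.cell_types:
        for j in range(config.n_degs_per_type):
            sign = 1.0 if j % 2 == 0 else -1.0
            deg_assignments[gene_ids[pool[cursor]]] = (ct, sign * config.deg_log2fc)
            cursor += 1
    if cursor > config.n_genes:
        raise ConfigurationError(
            "n_genes too small for the requested markers and DEGs"
        )

    base_log = rng.normal(config.baseline_log_mean_mu, config.baseline_log_mean_sd, n_genes)
    planted_ids = set(marker_assignments) | set(deg_assignments)
    planted_ids |= {g for c in config.lr_circuits for g in c.all_genes()}
    planted_rows = np.array([gene_index[g] for g in sorted(planted_ids)], dtype=int)
    if planted_rows.size:
        base_log[planted_rows] = rng.normal(
            config.baseline_log_mean_mu,
            config.baseline_log_mean_sd * config.planted_baseline_sd_factor,
            planted_rows.size,
        )
    base_mean = np.exp(base_log)

    batch_levels = sorted(samples["batch"].unique())
    batch_offset_by_level = dict(
        zip(batch_levels, rng.normal(0.0, config.batch_sd, len(batch_levels)))
    )
    batch_offsets = samples["batch"].map(batch_offset_by_level).to_numpy()
    lib_factors = np.exp(rng.normal(0.0, config.library_size_sd, n_samples))

    log2_effect = np.zeros((n_genes, n_samples))
    is_lesion = (samples["condition"] == "lesion").to_numpy()
    ct_arr = samples["cell_type"].to_numpy()
    for g, ct in marker_assignments.items():
        log2_effect[gene_index[g], ct_arr == ct] += config.marker_log2fc
    for g, (ct, lfc) in deg_assignments.items():
        log2_effect[gene_index[g], is_lesion & (ct_arr == ct)] += lfc
    # circuit boosts set a gene's level rather than stack: a subunit shared
    # by several circuits (e.g. a receptor with two ligands) takes the
    # maximum boost over its circuit roles per sample
    circuit_effect = np.zeros_like(log2_effect)
    for circ in config.lr_circuits:
        eff = circ.condition_effect_log2fc
        base_eff = circ.constitutive_log2fc
        for g in circ.ligand_genes:
            sender = ct_arr == circ.sender
            boost = base_eff * sender + eff * (is_lesion & sender)
            circuit_effect[gene_index[g]] = np.maximum(circuit_effect[gene_index[g]], boost)
        for g in circ.receptor_genes + circ.agonist_genes:
            receiver = ct_arr == circ.receiver
            boost = base_eff * receiver + eff * (is_lesion & receiver)
            circuit_effect[gene_index[g]] = np.maximum(circuit_effect[gene_index[g]], boost)
    log2_effect += circuit_effect

    mean = (
        base_mean[:, None]
        * np.exp2(log2_effect + batch_offsets[None, :])
        * lib_factors[None, :]
    )
    a, b = config.nb_dispersion
    phi = a / base_mean + b  # gene-wise dispersion: var = m + phi m^2
    size = 1.0 / phi
    p = size[:, None] / (size[:, None] + mean)
    counts = rng.negative_binomial(size[:, None], p)

    matrix = CountMatrix(pd.DataFrame(counts, index=gene_ids, columns=samples["sample_id"]))
    truth = GroundTruth(
        marker_assignments=marker_assignments,
        deg_assignments=deg_assignments,
        circuit_table=list(config.lr_circuits),
        batch_assignments=dict(zip(samples["sample_id"], samples["batch"])),
    )
    return matrix, samples, truth


def marker_sets(truth: GroundTruth, cell_types: Sequence[str] | None = None) -> dict[str, MarkerSet]:
    """Planted markers as MarkerSet objects (sensitivity 1.0)."""
    cts = cell_types or sorted({ct for ct in truth.marker_assignments.values()})
    return {
        ct: MarkerSet(ct, truth.markers_of(ct), {g: 1.0 for g in truth.markers_of(ct)})
        for ct in cts
    }


def build_lr_database(
    truth: GroundTruth,
    background_genes: Sequence[str],
    n_decoys: int = 10,
    seed: int = 0,
) -> LRDatabase:
    """LR interaction table containing the planted circuits plus decoys.

    Decoy interactions pair background genes with no planted condition
    effect, one per decoy pathway, so that permutation significance has a
    null set to calibrate against.
    """
    rng = np.random.default_rng(seed)
    planted = {g for c in truth.circuit_table for g in c.all_genes()}
    planted |= set(truth.marker_assignments) | set(truth.deg_assignments)
    eligible = [g for g in background_genes if g not in planted]
    records = []
    for i, circ in enumerate(truth.circuit_table):
        records.append(
            LRInteraction(
                interaction_id=f"planted_{i}_{'_'.join(circ.ligand_genes)}",
                ligand_subunits=list(circ.ligand_genes),
                receptor_subunits=list(circ.receptor_genes),
                agonists=list(circ.agonist_genes),
                antagonists=list(circ.antagonist_genes),
                pathway=circ.pathway,
            )
        )
    picks = rng.choice(len(eligible), size=(n_decoys, 2), replace=False)
    for i in range(n_decoys):
        lig, rec = eligible[picks[i, 0]], eligible[picks[i, 1]]
        records.append(
            LRInteraction(
                interaction_id=f"decoy_{i}_{lig}_{rec}",
                ligand_subunits=[lig],
                receptor_subunits=[rec],
                agonists=[],
                antagonists=[],
                pathway=f"DECOY{i % 3 + 1}",
            )
        )
    return LRDatabase(records)
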