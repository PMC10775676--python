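"""End-to-end orchestration: simulate -> validate -> DE -> fold-change
ratio -> ligand-receptor inference -> enrichment -> reporting.

`run_pipeline` chains every stage on one synthetic dataset and writes all
result tables to a directory.  Output is deterministic for a fixed
configuration seed: rerunning with the same config yields byte-identical
files.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import io as cio
from .de import Contrast, fit_moderated_de, gate_degs, normalize_counts, write_de_table
from .enrichment import activation_zscore, gsea_collection, make_ranked_list, ora_collection
from .fc_ratio import FCRatioParams, attribute_altered_genes, compute_fc_ratio, write_fc_ratio_table
from .io import GeneSetCollection
from .lr import LRModelParams, aggregate_pathway, pathway_distance, permutation_significance
from .reporting import heatmap_matrix, venn_partition
from .synthetic import SyntheticConfig, build_lr_database, generate_dataset, marker_sets
from .validation import validate_population, validation_summary

CONDITIONS = ("lesion", "control")


def synthetic_gene_sets(truth, universe=None, rng_seed: int = 0, n_decoys: int = 3,
                        decoy_size: int = 25) -> GeneSetCollection:
    """Gene sets derived from the planted truth plus random decoy sets.

    Per population, a signed set of its planted condition-DEGs (sign = the
    planted direction), so activation calls and enrichment have a positive
    control; decoy sets draw from unplanted universe genes.
    """
    import numpy as np

    rng = np.random.default_rng(rng_seed)
    sets: dict[str, list[str]] = {}
    signs: dict[str, dict[str, int]] = {}
    cts = sorted({ct for ct, _ in truth.deg_assignments.values()})
    for ct in cts:
        degs = truth.degs_of(ct)
        name = f"PLANTED_{ct}_RESPONSE"
        sets[name] = sorted(degs)
        signs[name] = {g: (1 if lfc > 0 else -1) for g, lfc in degs.items()}
    if universe is not None:
        planted = set(truth.deg_assignments) | set(truth.marker_assignments)
        pool = sorted(set(universe) - planted)
        for i in range(n_decoys):
            picks = rng.choice(len(pool), size=min(decoy_size, len(pool)), replace=False)
            sets[f"DECOY_SET_{i + 1}"] = sorted(pool[j] for j in picks)
    return GeneSetCollection(sets, signs)


def run_pipeline(
    config: SyntheticConfig,
    out_dir: str | Path,
    lr_params: LRModelParams | None = None,
    fc_params: FCRatioParams | None = None,
    alpha: float = 0.1,
    fc_min: float = 1.5,
    gsea_perm: int = 100,
) -> dict:
    """Run every stage on one simulated dataset; returns a summary dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lr_params = lr_params or LRModelParams(seed=config.seed)
    fc_params = fc_params or FCRatioParams()

    # --- simulate -----------------------------------------------------
    counts, samples, truth = generate_dataset(config)
    cio.write_counts(counts, out / "counts.tsv")
    cio.write_sample_table(samples, out / "samples.tsv")
    cio.write_ground_truth(truth, out / "ground_truth.json")
    expr = normalize_counts(counts)
    cell_types = list(config.cell_types)

    # --- population validation ---------------------------------------
    reports = [
        validate_population(expr, samples, ms)
        for ms in marker_sets(truth, cell_types).values()
    ]
    vs = validation_summary(reports)
    vs.to_csv(out / "validation.tsv", sep="\t", index=False)

    # --- per-population lesion vs control DE --------------------------
    de_tables: dict[str, pd.DataFrame] = {}
    deg_sets = {}
    for ct in cell_types:
        contrast = Contrast(
            {"condition": "lesion", "cell_type": ct},
            {"condition": "control", "cell_type": ct},
            include_batch=True,
            name=f"lesion.{ct} vs control.{ct}",
        )
        table = fit_moderated_de(expr, samples, contrast)
        de_tables[ct] = table
        deg_sets[ct] = gate_degs(table, alpha=alpha, fc_min=fc_min, contrast=contrast.name)
        write_de_table(table, out / f"de_{ct}.tsv")

    # --- fold-change ratio across population pairs --------------------
    fc_tables = {}
    for a, b in itertools.combinations(cell_types, 2):
        per_cond = {}
        for cond in CONDITIONS:
            contrast = Contrast(
                {"condition": cond, "cell_type": a},
                {"condition": cond, "cell_type": b},
                include_batch=True,
                name=f"{cond}.{a} vs {cond}.{b}",
            )
            per_cond[cond] = fit_moderated_de(expr, samples, contrast)
        fc_tables[(a, b)] = compute_fc_ratio(
            per_cond["lesion"], per_cond["control"], fc_params, pair=(a, b)
        )
        write_fc_ratio_table(fc_tables[(a, b)], out / f"fcratio_{a}_{b}.tsv")
    altered = attribute_altered_genes(fc_tables, deg_sets)
    (out / "altered_genes.json").write_text(json.dumps(altered, indent=1, sort_keys=True) + "\n")

    # --- ligand-receptor inference ------------------------------------
    database = build_lr_database(truth, counts.gene_ids, seed=config.seed)
    cio.write_lr_database(database, out / "lr_database.tsv")
    tensors = {}
    networks = {}
    for cond in CONDITIONS:
        tensor = permutation_significance(expr, samples, cond, database, lr_params,
                                          cell_types=cell_types)
        tensors[cond] = tensor
        tensor.to_csv(out / f"lr_{cond}.tsv", sep="\t", index=False)
        networks[cond] = aggregate_pathway(tensor, alpha=lr_params.alpha)
    try:
        distances = pathway_distance(networks["lesion"], networks["control"])
    except ValueError:
        distances = pd.DataFrame(
            columns=["pathway", "similarity", "x_lesion", "y_lesion",
                     "x_control", "y_control", "distance"]
        )
    distances.to_csv(out / "pathway_distance.tsv", sep="\t", index=False)

    # --- enrichment on planted + decoy gene sets ----------------------
    collection = synthetic_gene_sets(truth, universe=counts.gene_ids, rng_seed=config.seed)
    cio.write_gene_sets(collection, out / "gene_sets.gmt")
    universe = counts.gene_ids
    enrich_rows = []
    for ct in cell_types:
        ora = ora_collection(deg_sets[ct].genes, collection, universe)
        ora.insert(0, "cell_type", ct)
        ora.insert(1, "mode", "ora")
        enrich_rows.append(ora)
    pd.concat(enrich_rows, ignore_index=True).to_csv(out / "enrichment_ora.tsv", sep="\t", index=False)
    zs_rows = []
    for ct in cell_types:
        for name, signed in collection.signs.items():
            z, call = activation_zscore(de_tables[ct], signed, alpha=alpha, fc_min=fc_min)
            zs_rows.append({"cell_type": ct, "set_name": name, "z": z, "call": call})
    pd.DataFrame(zs_rows).to_csv(out / "enrichment_activation.tsv", sep="\t", index=False)
    gsea_rows = []
    for ct in cell_types:
        ranked = make_ranked_list(de_tables[ct])
        res = gsea_collection(ranked, collection, n_perm=gsea_perm, seed=config.seed)
        res.insert(0, "cell_type", ct)
        gsea_rows.append(res)
    pd.concat(gsea_rows, ignore_index=True).to_csv(out / "enrichment_gsea.tsv", sep="\t", index=False)

    # --- reporting -----------------------------------------------------
    ct_a, ct_b, ct_c = cell_types[:3] if len(cell_types) >= 3 else (
        list(cell_types) + [cell_types[-1]] * (3 - len(cell_types))
    )
    venn = venn_partition(
        deg_sets[ct_a].genes, deg_sets[ct_b].genes, deg_sets[ct_c].genes,
        labels=(ct_a, ct_b, ct_c),
    )
    venn.to_frame().to_csv(out / "venn.tsv", sep="\t", index=False)
    (out / "venn_totals.json").write_text(
        json.dumps(venn.totals, indent=1, sort_keys=True) + "\n"
    )
    union_degs = sorted(set().union(*(deg_sets[ct].genes for ct in cell_types)))
    if len(union_degs) >= 2:
        spec = heatmap_matrix(expr, union_degs)
        spec.values.to_csv(out / "heatmap.tsv", sep="\t")

    return {
        "n_samples": len(samples),
        "validation": {r.cell_type: r.confirmed for r in reports},
        "n_degs": {ct: len(deg_sets[ct]) for ct in cell_types},
        "n_altered": {ct: len(g) for ct, g in altered.items()},
        "venn_totals": venn.totals,
        "n_significant_lr": {
            cond: int((tensors[cond]["q"] < lr_params.alpha).sum()) for cond in CONDITIONS
        },
        "pathway_distances": dict(zip(distances["pathway"], distances["distance"])),
    }
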