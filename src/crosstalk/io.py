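"""Readers, writers and validated containers for the pipeline's file formats.

The pipeline starts at a gene x sample count matrix; everything upstream of
quantification (FASTQ, alignment, FACS vendor files) is out of scope.  Counts
come in as TSV/CSV (dense, genes in rows, header row of sample ids) or as an
MTX triplet with sidecar row/column name files.  Sample metadata, marker
lists and the ligand-receptor database are TSV; gene sets are GMT; ground
truth from the simulator round-trips through JSON.

Gene identifiers are opaque case-sensitive strings; no alias resolution is
attempted.  Counts must be integral and non-negative -- fractional
quantification estimates are rejected rather than silently rounded, because
the downstream model transforms counts explicitly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class FormatError(ValueError):
    """Raised when an input file violates the documented format contract."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Integer gene x sample count matrix, the pipeline's entry point.

    ``counts`` is a genes-by-samples DataFrame with unique string indices and
    non-negative integer values.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise FormatError(f"duplicate gene id: {dup!r}")
        if df.columns.duplicated().any():
            dup = df.columns[df.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        values = df.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            frac = values != np.floor(values)
            if frac.any():
                g, s = np.argwhere(frac)[0]
                raise FormatError(
                    f"non-integer count at gene {df.index[g]!r}, "
                    f"sample {df.columns[s]!r}: {values[g, s]}"
                )
            df = df.astype(np.int64)
            object.__setattr__(self, "counts", df)
            values = df.to_numpy()
        if values.size and (values < 0).any():
            g, s = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative count at gene {df.index[g]!r}, sample {df.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


SAMPLE_COLUMNS = ("sample_id", "condition", "cell_type", "subject", "batch", "replicate")


def validate_sample_table(samples: pd.DataFrame, counts: CountMatrix | None = None) -> pd.DataFrame:
    """Check a sample metadata table and return it indexed by sample_id.

    Required columns: sample_id, condition, cell_type, subject, batch,
    replicate.  When ``counts`` is given, every sample id must match a
    count-matrix column (and vice versa).
    """
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise FormatError(f"sample table missing columns: {missing}")
    if samples["sample_id"].duplicated().any():
        dup = samples["sample_id"][samples["sample_id"].duplicated()].iloc[0]
        raise FormatError(f"duplicate sample_id: {dup!r}")
    for col in ("condition", "cell_type"):
        if samples[col].isna().any() or (samples[col].astype(str) == "").any():
            raise FormatError(f"empty values in required column {col!r}")
    out = samples.set_index("sample_id", drop=False)
    if counts is not None:
        tbl, mat = set(out.index), set(counts.sample_ids)
        if tbl != mat:
            raise FormatError(
                f"sample table / count matrix mismatch: only in table {sorted(tbl - mat)}, "
                f"only in matrix {sorted(mat - tbl)}"
            )
        out = out.loc[counts.sample_ids]
    return out


@dataclass
class MarkerSet:
    """Marker genes for one sorted population, with per-gene sensitivity.

    Sensitivity is the fraction of cells of the target population expressing
    the marker in reference atlases; validation uses markers with
    sensitivity >= 0.7.
    """

    cell_type: str
    genes: list[str]
    sensitivity: dict[str, float] = field(default_factory=dict)

    def usable_genes(self, min_sensitivity: float = 0.7) -> list[str]:
        return [
            g for g in self.genes
            if self.sensitivity.get(g, 1.0) >= min_sensitivity
        ]


@dataclass
class LRInteraction:
    interaction_id: str
    ligand_subunits: list[str]
    receptor_subunits: list[str]
    agonists: list[str]
    antagonists: list[str]
    pathway: str


@dataclass
class LRDatabase:
    """Ligand-receptor interaction annotation: multi-subunit ligands and
    receptors plus soluble agonist/antagonist cofactors, grouped by pathway."""

    records: list[LRInteraction]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.interaction_id in seen:
                raise FormatError(f"duplicate interaction_id: {rec.interaction_id!r}")
            seen.add(rec.interaction_id)
            if not rec.ligand_subunits or not rec.receptor_subunits:
                raise FormatError(f"empty subunit list in {rec.interaction_id!r}")
            if not rec.pathway:
                raise FormatError(f"empty pathway for {rec.interaction_id!r}")

    def pathways(self) -> list[str]:
        return sorted({r.pathway for r in self.records})

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class GeneSetCollection:
    """Named gene sets; optionally signed (+1 activating / -1 inhibiting)."""

    sets: dict[str, list[str]]
    signs: dict[str, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} has no members")
        for name, signed in self.signs.items():
            bad = {g: s for g, s in signed.items() if s not in (+1, -1)}
            if bad:
                raise FormatError(f"gene set {name!r} has signs outside {{+1,-1}}: {bad}")

    def __iter__(self):
        return iter(self.sets.items())

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# Count matrix I/O
# ---------------------------------------------------------------------------

def read_counts(path: str | Path, format: str | None = None) -> CountMatrix:
    """Read a count matrix from TSV, CSV or MTX triplet.

    For ``mtx``, ``path`` names the ``.mtx`` file and the row/column name
    files are ``<stem>.genes.txt`` / ``<stem>.samples.txt`` alongside it.
    Format is inferred from the suffix when not given.
    """
    path = Path(path)
    if format is None:
        format = {".tsv": "tsv", ".csv": "csv", ".mtx": "mtx", ".txt": "tsv"}.get(
            path.suffix.lower(), "tsv"
        )
    if format not in ("tsv", "csv", "mtx"):
        raise FormatError(f"unknown count format {format!r}")
    if format == "mtx":
        mat = scipy.io.mmread(path)
        genes = (path.with_suffix("").parent / (path.stem + ".genes.txt")).read_text().split()
        samples = (path.with_suffix("").parent / (path.stem + ".samples.txt")).read_text().split()
        dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
        if dense.shape != (len(genes), len(samples)):
            raise FormatError(
                f"MTX shape {dense.shape} does not match name files "
                f"({len(genes)} genes, {len(samples)} samples)"
            )
        df = pd.DataFrame(dense, index=genes, columns=samples)
    else:
        sep = "\t" if format == "tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
    return CountMatrix(df)


def write_counts(counts: CountMatrix, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = {".tsv": "tsv", ".csv": "csv", ".mtx": "mtx"}.get(path.suffix.lower(), "tsv")
    if format == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(counts.counts.to_numpy()))
        (path.parent / (path.stem + ".genes.txt")).write_text("\n".join(counts.gene_ids) + "\n")
        (path.parent / (path.stem + ".samples.txt")).write_text("\n".join(counts.sample_ids) + "\n")
    else:
        counts.counts.to_csv(path, sep="\t" if format == "tsv" else ",")


def read_sample_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject": str, "batch": str})
    return validate_sample_table(df)


def write_sample_table(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Marker lists
# ---------------------------------------------------------------------------

def read_markers(path: str | Path) -> dict[str, MarkerSet]:
    """Read marker lists from TSV with columns cell_type, gene, sensitivity."""
    df = pd.read_csv(path, sep="\t")
    for col in ("cell_type", "gene"):
        if col not in df.columns:
            raise FormatError(f"marker table missing column {col!r}")
    out: dict[str, MarkerSet] = {}
    for ct, grp in df.groupby("cell_type", sort=True):
        sens = (
            dict(zip(grp["gene"], grp["sensitivity"].astype(float)))
            if "sensitivity" in grp.columns
            else {}
        )
        out[str(ct)] = MarkerSet(str(ct), list(grp["gene"].astype(str)), sens)
    return out


def write_markers(markers: Mapping[str, MarkerSet], path: str | Path) -> None:
    rows = [
        {"cell_type": ms.cell_type, "gene": g, "sensitivity": ms.sensitivity.get(g, 1.0)}
        for ms in markers.values()
        for g in ms.genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# LR database
# ---------------------------------------------------------------------------

_LR_COLUMNS = (
    "interaction_id", "ligand_subunits", "receptor_subunits",
    "agonists", "antagonists", "pathway",
)


def _split_units(cell: object) -> list[str]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return []
    text = str(cell).strip()
    if not text:
        return []
    return [part.strip() for part in text.split("+") if part.strip()]


def read_lr_database(path: str | Path) -> LRDatabase:
    """Read a ligand-receptor database TSV.

    Multi-gene fields are '+'-delimited (e.g. receptor ``ITGA+ITGB``); empty
    agonist/antagonist fields become empty cofactor lists.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _LR_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"LR database missing columns: {missing}")
    records = []
    for _, row in df.iterrows():
        lig = _split_units(row["ligand_subunits"])
        rec = _split_units(row["receptor_subunits"])
        if not lig:
            raise FormatError(f"empty ligand field in {row['interaction_id']!r}")
        if not rec:
            raise FormatError(f"empty receptor field in {row['interaction_id']!r}")
        records.append(
            LRInteraction(
                interaction_id=row["interaction_id"].strip(),
                ligand_subunits=lig,
                receptor_subunits=rec,
                agonists=_split_units(row["agonists"]),
                antagonists=_split_units(row["antagonists"]),
                pathway=row["pathway"].strip(),
            )
        )
    return LRDatabase(records)


def write_lr_database(db: LRDatabase, path: str | Path) -> None:
    rows = [
        {
            "interaction_id": r.interaction_id,
            "ligand_subunits": "+".join(r.ligand_subunits),
            "receptor_subunits": "+".join(r.receptor_subunits),
            "agonists": "+".join(r.agonists),
            "antagonists": "+".join(r.antagonists),
            "pathway": r.pathway,
        }
        for r in db.records
    ]
    pd.DataFrame(rows, columns=list(_LR_COLUMNS)).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: set name, description, then member genes per line.

    Members may carry a ``:+1`` / ``:-1`` suffix for directional (signed)
    sets; plain members in a signed set default to +1.
    """
    sets: dict[str, list[str]] = {}
    signs: dict[str, dict[str, int]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"line {lineno}: gene set has zero members")
        name = parts[0]
        if name in sets:
            raise FormatError(f"line {lineno}: duplicate set name {name!r}")
        members: list[str] = []
        signed: dict[str, int] = {}
        has_signs = False
        for token in parts[2:]:
            token = token.strip()
            if not token:
                continue
            if token.endswith(":+1") or token.endswith(":-1"):
                gene, sign = token[:-3], int(token[-2:])
                has_signs = True
            else:
                gene, sign = token, +1
            members.append(gene)
            signed[gene] = sign
        if not members:
            raise FormatError(f"line {lineno}: gene set {name!r} has zero members")
        sets[name] = members
        if has_signs:
            signs[name] = signed
    return GeneSetCollection(sets, signs)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    lines = []
    for name, members in collection.sets.items():
        if name in collection.signs:
            signed = collection.signs[name]
            tokens = [f"{g}:{signed[g]:+d}" for g in members]
        else:
            tokens = list(members)
        lines.append("\t".join([name, "na"] + tokens))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Ground truth JSON
# ---------------------------------------------------------------------------

def write_ground_truth(truth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=1, sort_keys=True) + "\n")


def read_ground_truth(path: str | Path):
    from .synthetic import GroundTruth

    return GroundTruth.from_dict(json.loads(Path(path).read_text()))
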