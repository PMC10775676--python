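"""Ligand-receptor communication inference among labeled populations.

Sorted bulk libraries stand in for the annotated clusters of a single-cell
workflow: each population's expression profile is the summary (mean or
trimmed mean) of its samples' linear-scale normalized expression within one
condition.  The communication probability of an interaction from a sender
to a receiver population follows a saturating mass-action (Hill, exponent
1) form on the product of ligand and receptor unit expression, where the
unit expression of a multi-subunit ligand or receptor is the geometric
mean of its subunits (zero if any subunit is absent).  Soluble agonists
multiply the probability by ``1 + A/(kh + A)`` and antagonists by
``kh/(kh + I)``, both evaluated on the receiver profile.

Significance is by permutation: cell-type labels are shuffled across the
condition's samples, probabilities recomputed, and the one-sided empirical
p-value BH-corrected across all (sender, receiver, interaction) triples of
the condition.  Significant interaction probabilities are summed per
pathway into sender x receiver network matrices; networks from both
conditions are embedded jointly into two dimensions by classical
multidimensional scaling of their cosine dissimilarities, and a pathway's
between-condition distance is the Euclidean distance between its lesion
and control points in that shared plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .de import ExpressionMatrix, bh_fdr
from .io import LRDatabase, LRInteraction


@dataclass
class LRModelParams:
    kh: float = 0.5
    n_perm: int = 1000
    seed: int = 0
    alpha: float = 0.05
    summary: str = "mean"  # or "trimmed_mean"
    trim: float = 0.2

    def __post_init__(self) -> None:
        if self.kh <= 0:
            raise ValueError("kh must be positive")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.summary not in ("mean", "trimmed_mean"):
            raise ValueError(f"unknown summary {self.summary!r}")


@dataclass
class PopulationProfile:
    """Per-population summary expression (genes x cell types, linear scale)."""

    condition: str
    values: pd.DataFrame

    @property
    def cell_types(self) -> list[str]:
        return list(self.values.columns)


def _trimmed_mean(x: np.ndarray, trim: float) -> np.ndarray:
    """Row-wise trimmed mean removing ceil(n*trim) values from each end.

    With fewer than 3 values per row, falls back to the plain mean.
    """
    n = x.shape[1]
    cut = math.ceil(n * trim)
    if n - 2 * cut < 1:
        return x.mean(axis=1)
    xs = np.sort(x, axis=1)
    return xs[:, cut : n - cut].mean(axis=1)


def _summarize(x: np.ndarray, params: LRModelParams) -> np.ndarray:
    if params.summary == "trimmed_mean":
        return _trimmed_mean(x, params.trim)
    return x.mean(axis=1)


def build_population_profile(
    expr: ExpressionMatrix,
    samples: pd.DataFrame,
    condition: str,
    params: LRModelParams | None = None,
    cell_types: list[str] | None = None,
    genes: list[str] | None = None,
) -> PopulationProfile:
    """Summarize linear-scale expression per population within a condition."""
    params = params or LRModelParams()
    cts = cell_types or sorted(samples["cell_type"].unique())
    cond = samples[samples["condition"] == condition]
    linear = expr.linear()
    if genes is not None:
        linear = linear.loc[genes]
    cols = {}
    for ct in cts:
        ids = cond.loc[cond["cell_type"] == ct, "sample_id"]
        if len(ids) == 0:
            raise ValueError(f"no samples for cell type {ct!r} in condition {condition!r}")
        cols[ct] = _summarize(linear[ids].to_numpy(), params)
    return PopulationProfile(condition, pd.DataFrame(cols, index=linear.index))


def unit_expression(values: pd.Series, subunits: list[str]) -> float:
    """Geometric mean of subunit expression; 0 if any subunit is 0 or absent."""
    if not subunits:
        raise ValueError("empty subunit list")
    vals = np.array([float(values.get(g, 0.0)) for g in subunits])
    if (vals <= 0).any():
        return 0.0
    return float(np.exp(np.mean(np.log(vals))))


def communication_probability(
    profile: PopulationProfile,
    interaction: LRInteraction,
    params: LRModelParams | None = None,
) -> pd.DataFrame:
    """Probability matrix over (sender, receiver) for one interaction.

    P = clamp( L*R/(kh + L*R) * (1 + A/(kh+A)) * kh/(kh+I), 0, 1 ) with L
    the sender's ligand unit expression and R, A, I the receiver's
    receptor, agonist and antagonist unit expressions (A = I = 0 when the
    cofactor lists are empty).
    """
    params = params or LRModelParams()
    kh = params.kh
    cts = profile.cell_types
    L = np.array([unit_expression(profile.values[ct], interaction.ligand_subunits) for ct in cts])
    R = np.array([unit_expression(profile.values[ct], interaction.receptor_subunits) for ct in cts])
    if interaction.agonists:
        A = np.array([unit_expression(profile.values[ct], interaction.agonists) for ct in cts])
    else:
        A = np.zeros(len(cts))
    if interaction.antagonists:
        I = np.array([unit_expression(profile.values[ct], interaction.antagonists) for ct in cts])
    else:
        I = np.zeros(len(cts))
    lr = np.outer(L, R)  # sender x receiver
    base = lr / (kh + lr)
    agonist = 1.0 + A / (kh + A)
    antagonist = kh / (kh + I)
    P = np.clip(base * agonist[None, :] * antagonist[None, :], 0.0, 1.0)
    return pd.DataFrame(P, index=cts, columns=cts)


def _profiles_for_labels(
    linear: np.ndarray, labels: np.ndarray, cts: list[str], params: LRModelParams
) -> np.ndarray:
    out = np.empty((linear.shape[0], len(cts)))
    for j, ct in enumerate(cts):
        out[:, j] = _summarize(linear[:, labels == ct], params)
    return out


def _interaction_probability(
    prof: np.ndarray, gene_index: dict[str, int], interaction: LRInteraction, kh: float
) -> np.ndarray:
    def unit(genes: list[str]) -> np.ndarray:
        rows = [gene_index.get(g) for g in genes]
        if any(r is None for r in rows):
            return np.zeros(prof.shape[1])
        sub = prof[[r for r in rows], :]
        with np.errstate(divide="ignore"):
            logs = np.where(sub > 0, np.log(np.maximum(sub, 1e-300)), -np.inf)
        return np.where((sub <= 0).any(axis=0), 0.0, np.exp(logs.mean(axis=0)))

    L = unit(interaction.ligand_subunits)
    R = unit(interaction.receptor_subunits)
    lr = np.outer(L, R)
    P = lr / (kh + lr)
    if interaction.agonists:
        A = unit(interaction.agonists)
        P = P * (1.0 + A / (kh + A))[None, :]
    if interaction.antagonists:
        I = unit(interaction.antagonists)
        P = P * (kh / (kh + I))[None, :]
    return np.clip(P, 0.0, 1.0)


def permutation_significance(
    expr: ExpressionMatrix,
    samples: pd.DataFrame,
    condition: str,
    database: LRDatabase,
    params: LRModelParams | None = None,
    cell_types: list[str] | None = None,
) -> pd.DataFrame:
    """Observed probabilities with permutation p and BH q per triple.

    Returns a long-format DataFrame with columns condition, sender,
    receiver, interaction, pathway, prob, p, q.  The null shuffles
    cell-type labels across the condition's samples (subject structure
    ignored: each sorted library is an independent unit); the one-sided
    p-value is (1 + #{P_perm >= P_obs}) / (1 + n_perm).
    """
    params = params or LRModelParams()
    cts = cell_types or sorted(samples.loc[samples["condition"] == condition, "cell_type"].unique())
    cond = samples[samples["condition"] == condition]
    if len(cond) < 2:
        raise ValueError(f"need >= 2 samples in condition {condition!r}")
    rng = np.random.default_rng(params.seed)

    db_genes = sorted({g for rec in database for g in rec.ligand_subunits + rec.receptor_subunits + rec.agonists + rec.antagonists})
    db_genes = [g for g in db_genes if g in expr.values.index]
    gene_index = {g: i for i, g in enumerate(db_genes)}
    linear = expr.linear().loc[db_genes, cond["sample_id"]].to_numpy()
    labels = cond["cell_type"].to_numpy()
    for ct in cts:
        if not (labels == ct).any():
            raise ValueError(f"no samples for cell type {ct!r} in condition {condition!r}")

    obs_prof = _profiles_for_labels(linear, labels, cts, params)
    obs = {
        rec.interaction_id: _interaction_probability(obs_prof, gene_index, rec, params.kh)
        for rec in database
    }

    exceed = {rid: np.zeros_like(P) for rid, P in obs.items()}
    for _ in range(params.n_perm):
        perm_labels = rng.permutation(labels)
        prof = _profiles_for_labels(linear, perm_labels, cts, params)
        for rec in database:
            P = _interaction_probability(prof, gene_index, rec, params.kh)
            exceed[rec.interaction_id] += P >= obs[rec.interaction_id]

    rows = []
    for rec in database:
        P = obs[rec.interaction_id]
        pvals = (1.0 + exceed[rec.interaction_id]) / (1.0 + params.n_perm)
        for i, sender in enumerate(cts):
            for j, receiver in enumerate(cts):
                rows.append(
                    {
                        "condition": condition,
                        "sender": sender,
                        "receiver": receiver,
                        "interaction": rec.interaction_id,
                        "pathway": rec.pathway,
                        "prob": P[i, j],
                        "p": pvals[i, j],
                    }
                )
    tensor = pd.DataFrame(rows)
    tensor["q"] = bh_fdr(tensor["p"].to_numpy())
    return tensor


def aggregate_pathway(
    tensor: pd.DataFrame, alpha: float = 0.05
) -> dict[str, pd.DataFrame]:
    """Sum significant (q < alpha) interaction probabilities per pathway.

    Returns pathway -> sender x receiver weight matrix; pathways whose
    matrix is all zero are dropped.
    """
    cts = sorted(set(tensor["sender"]) | set(tensor["receiver"]))
    sig = tensor[tensor["q"] < alpha]
    out: dict[str, pd.DataFrame] = {}
    for pathway, grp in sig.groupby("pathway", sort=True):
        W = pd.DataFrame(0.0, index=cts, columns=cts)
        for _, row in grp.iterrows():
            W.at[row["sender"], row["receiver"]] += row["prob"]
        if (W.to_numpy() > 0).any():
            out[str(pathway)] = W
    return out


# ---------------------------------------------------------------------------
# Shared 2-D embedding and pathway distances
# ---------------------------------------------------------------------------

def network_similarity(w1: pd.DataFrame, w2: pd.DataFrame) -> float:
    """Cosine similarity of flattened, L1-normalized network matrices."""
    a = w1.to_numpy().ravel().astype(float)
    b = w2.to_numpy().ravel().astype(float)
    if a.sum() == 0 or b.sum() == 0:
        return 0.0
    a = a / a.sum()
    b = b / b.sum()
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


def classical_mds(D: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS of a symmetric distance matrix.

    Double-centers -D^2/2 and keeps the top eigenpairs; negative eigenvalues
    are truncated at zero.  Sign convention: in each output coordinate the
    entry of largest absolute value is made positive, so the embedding is
    deterministic.
    """
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:n_components]
    coords = np.zeros((n, n_components))
    for k, idx in enumerate(order):
        lam = max(vals[idx], 0.0)
        col = vecs[:, idx] * np.sqrt(lam)
        pivot = np.argmax(np.abs(col))
        if col[pivot] < 0:
            col = -col
        coords[:, k] = col
    return coords


def pathway_distance(
    networks_lesion: dict[str, pd.DataFrame],
    networks_control: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Between-condition pathway distances in the shared 2-D embedding.

    All (pathway, condition) networks are embedded jointly from their
    pairwise cosine dissimilarities; the reported distance, for each pathway
    present in both conditions, is the Euclidean distance between its
    lesion and control points.  Larger distance means a larger change in
    the pathway's communication architecture between conditions.
    """
    points = [(p, "lesion", W) for p, W in sorted(networks_lesion.items())]
    points += [(p, "control", W) for p, W in sorted(networks_control.items())]
    if len(points) < 2:
        raise ValueError("need at least 2 pathway networks to embed")
    n = len(points)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = 1.0 - network_similarity(points[i][2], points[j][2])
    coords = classical_mds(D, 2)
    index = {(p, c): i for i, (p, c, _) in enumerate(points)}
    shared = sorted(set(networks_lesion) & set(networks_control))
    rows = []
    for p in shared:
        i, j = index[(p, "lesion")], index[(p, "control")]
        rows.append(
            {
                "pathway": p,
                "similarity": network_similarity(points[i][2], points[j][2]),
                "x_lesion": coords[i, 0],
                "y_lesion": coords[i, 1],
                "x_control": coords[j, 0],
                "y_control": coords[j, 1],
                "distance": float(np.linalg.norm(coords[i] - coords[j])),
            }
        )
    columns = ["pathway", "similarity", "x_lesion", "y_lesion",
               "x_control", "y_control", "distance"]
    if not rows:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame(rows)[columns].sort_values(
        "distance", ascending=False, kind="stable"
    ).reset_index(drop=True)
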