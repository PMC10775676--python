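"""Gene-set statistics: over-representation, directional activation calls,
and preranked set enrichment.

These operate on user-supplied gene-set collections (GMT); no pathway
database content is bundled.  Three complementary statistics are provided:

* ``ora_test`` -- hypergeometric upper-tail over-representation of a set in
  a selected gene list against a universe.
* ``activation_zscore`` -- a directional concordance score over a signed
  set (+1 activating, -1 inhibiting members): z = sum(concordance)/sqrt(n)
  over the set's differentially expressed members, with calls activated at
  z >= 2 and inhibited at z <= -2.  This is the simple concordance form;
  causal-network edge weighting and bias correction are not reproduced.
* ``gsea_preranked`` -- the weighted Kolmogorov-Smirnov-like running-sum
  enrichment score over a ranked gene list with a gene-label permutation
  null and sign-matched normalization (NES).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .de import bh_fdr, gate_degs
from .io import GeneSetCollection


@dataclass
class EnrichmentResult:
    set_name: str
    k: int  # overlap
    K: int  # set size within the universe
    n: int  # selected size
    N: int  # universe size
    p: float
    q: float = float("nan")
    activation_z: float = float("nan")
    call: str = "none"


def ora_test(selected: Iterable[str], gene_set: Iterable[str], universe: Iterable[str],
             set_name: str = "") -> EnrichmentResult:
    """Hypergeometric upper-tail over-representation test.

    p = P(X >= k) for X ~ Hypergeom(N, K, n) with N the universe size, K
    the set size within the universe, n the selected size and k the
    overlap.  ``selected`` must be a subset of ``universe``.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    sel = set(selected)
    if not sel <= uni:
        raise ValueError("selected genes must be a subset of the universe")
    members = set(gene_set) & uni
    k = len(sel & members)
    p = float(hypergeom.sf(k - 1, len(uni), len(members), len(sel)))
    return EnrichmentResult(set_name, k, len(members), len(sel), len(uni), min(p, 1.0))


def ora_collection(
    selected: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
) -> pd.DataFrame:
    """ORA across a collection with BH correction; one row per set."""
    uni = set(universe)
    results = [
        ora_test(selected, members, uni, set_name=name)
        for name, members in collection
        if set(members) & uni
    ]
    if not results:
        return pd.DataFrame(columns=["set_name", "k", "K", "n", "N", "p", "q"])
    q = bh_fdr([r.p for r in results])
    rows = []
    for r, qv in zip(results, q):
        r.q = float(qv)
        rows.append(vars(r))
    return pd.DataFrame(rows).drop(columns=["activation_z", "call"])


def activation_zscore(
    de_table: pd.DataFrame,
    signed_set: Mapping[str, int],
    alpha: float = 0.1,
    fc_min: float = 1.5,
) -> tuple[float, str]:
    """Directional activation z-score over a signed gene set.

    For each set member that is a gated DEG, concordance is
    sign(log2fc) * sign(member); z = sum(concordance) / sqrt(count).
    Calls: activated iff z >= 2, inhibited iff z <= -2, else none.  With
    zero overlapping DEGs, z is NaN and the call is "none".
    """
    degs = gate_degs(de_table, alpha=alpha, fc_min=fc_min)
    overlap = [g for g in signed_set if g in degs]
    if not overlap:
        return float("nan"), "none"
    conc = np.array(
        [np.sign(de_table.at[g, "log2fc"]) * signed_set[g] for g in overlap]
    )
    z = float(conc.sum() / np.sqrt(len(conc)))
    if z >= 2:
        call = "activated"
    elif z <= -2:
        call = "inhibited"
    else:
        call = "none"
    return z, call


# ---------------------------------------------------------------------------
# Preranked GSEA
# ---------------------------------------------------------------------------

def make_ranked_list(de_table: pd.DataFrame, metric: str = "signed_logp") -> pd.Series:
    """Ranking statistic per gene, sorted descending (ties by gene id).

    ``signed_logp`` (default): sign(log2fc) * -log10(p).  ``log2fc`` ranks
    by the fold change alone.
    """
    if metric == "signed_logp":
        p = np.maximum(de_table["p"].to_numpy(), 1e-300)
        stat = np.sign(de_table["log2fc"].to_numpy()) * -np.log10(p)
    elif metric == "log2fc":
        stat = de_table["log2fc"].to_numpy()
    else:
        raise ValueError(f"unknown ranking metric {metric!r}")
    s = pd.Series(stat, index=de_table.index, name="stat")
    order = sorted(s.index, key=lambda g: (-s[g], g))
    return s.loc[order]


def enrichment_score(ranked: pd.Series, gene_set: Iterable[str], weight: float = 1.0) -> float:
    """Signed maximum deviation of the weighted running sum.

    Hits step up by |stat|^weight (normalized over hits); misses step down
    by 1/(N - K).  With weight 0 the score is the classic KS-like statistic
    in [-1, 1].
    """
    members = set(gene_set) & set(ranked.index)
    N, K = len(ranked), len(members)
    if K == 0:
        raise ValueError("gene set does not intersect the ranking")
    if K == N:
        raise ValueError("gene set covers the entire ranking")
    is_hit = np.array([g in members for g in ranked.index])
    weights = np.abs(ranked.to_numpy()) ** weight
    hit_w = np.where(is_hit, weights, 0.0)
    total = hit_w.sum()
    if total == 0:  # all member stats zero: fall back to unweighted steps
        hit_w = is_hit.astype(float)
        total = hit_w.sum()
    steps = hit_w / total - (~is_hit) / (N - K)
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def gsea_preranked(
    ranked: pd.Series,
    gene_set: Iterable[str],
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict[str, float]:
    """Preranked enrichment with a gene-label permutation null.

    The null redraws the set's positions uniformly among the ranked genes.
    NES = ES / mean(|null ES| of the same sign); the empirical p-value uses
    the same-sign null portion with the +1 correction.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    members = [g for g in gene_set if g in ranked.index]
    es = enrichment_score(ranked, members, weight)
    rng = np.random.default_rng(seed)
    genes = np.asarray(ranked.index)
    K = len(set(members))
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = enrichment_score(ranked, rng.choice(genes, size=K, replace=False), weight)
    same_sign = null[null >= 0] if es >= 0 else null[null < 0]
    if same_sign.size == 0 or np.mean(np.abs(same_sign)) == 0:
        nes = float("nan")
        p = 1.0 / (1.0 + n_perm)
    else:
        nes = es / float(np.mean(np.abs(same_sign)))
        p = (1.0 + np.sum(np.abs(same_sign) >= abs(es))) / (1.0 + same_sign.size)
    return {"es": es, "nes": nes, "p": float(p), "n_hits": K}


def gsea_collection(
    ranked: pd.Series,
    collection: GeneSetCollection,
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Preranked GSEA across a collection with BH correction."""
    rows = []
    for name, members in collection:
        inter = [g for g in members if g in ranked.index]
        if not inter or len(set(inter)) == len(ranked):
            continue
        res = gsea_preranked(ranked, members, weight=weight, n_perm=n_perm, seed=seed)
        res["set_name"] = name
        rows.append(res)
    if not rows:
        return pd.DataFrame(columns=["set_name", "es", "nes", "p", "q", "n_hits"])
    df = pd.DataFrame(rows)
    df["q"] = bh_fdr(df["p"].to_numpy())
    return df[["set_name", "es", "nes", "p", "q", "n_hits"]]
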