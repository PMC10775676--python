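"""Normalization and empirical-Bayes moderated differential expression.

The model is the standard small-sample workhorse for sorted-population bulk
RNA-seq: counts are transformed to log2 counts-per-million with a
pseudocount, each gene is fit by ordinary least squares on a design of
[intercept, group indicator, batch indicators], and per-gene residual
variances are shrunk toward a common prior fitted by moment-matching the
scaled-F / log-chi-square theory (the digamma/trigamma inversion).  The
moderated t gains degrees of freedom ``d0 + d_g`` and the usual robustness
at 2-6 samples per group.  Precision weighting is deliberately omitted:
unweighted least squares on log-CPM is the documented model.

Differentially expressed genes (DEGs) are gated at FDR-corrected p < 0.1
and absolute fold change > 1.5 (strict inequalities), the thresholds used
throughout the downstream stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import polygamma
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix


class DesignError(ValueError):
    """Raised for unusable contrasts or rank-deficient designs."""


@dataclass
class ExpressionMatrix:
    """Log2-scale normalized expression (genes x samples)."""

    values: pd.DataFrame
    pseudocount: float = 0.5
    #: per-sample library size of the source counts, needed to undo the
    #: pseudocount on the linear scale
    library_sizes: pd.Series | None = None

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def linear(self) -> pd.DataFrame:
        """Linear-scale normalized expression (CPM), pseudocount removed,
        floored at zero."""
        lin = np.exp2(self.values)
        if self.library_sizes is not None:
            correction = (
                self.pseudocount * 1e6
                / (self.library_sizes + 2.0 * self.pseudocount)
            )
            lin = lin.sub(correction, axis=1)
        return lin.clip(lower=0.0)


def normalize_counts(counts: CountMatrix, pseudocount: float = 0.5) -> ExpressionMatrix:
    """Log2 counts-per-million with a pseudocount.

    value(g, s) = log2( (count + pc) / (libsize_s + 2 pc) * 1e6 ),
    libsize_s the column sum.  A pseudocount > 0 is required; an all-zero
    sample column is rejected by name.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    df = counts.counts.astype(float)
    libsize = df.sum(axis=0)
    zero = libsize[libsize == 0]
    if len(zero):
        raise ValueError(f"all-zero sample column(s): {list(zero.index)}")
    values = np.log2((df + pseudocount).div(libsize + 2.0 * pseudocount, axis=1) * 1e6)
    return ExpressionMatrix(values, pseudocount=pseudocount, library_sizes=libsize)


# ---------------------------------------------------------------------------
# Contrasts
# ---------------------------------------------------------------------------

Predicate = Mapping[str, object]


def _match(samples: pd.DataFrame, predicate: Predicate) -> np.ndarray:
    mask = np.ones(len(samples), dtype=bool)
    for col, want in predicate.items():
        if col not in samples.columns:
            raise DesignError(f"unknown sample column {col!r} in contrast predicate")
        if isinstance(want, (list, tuple, set, frozenset)):
            mask &= samples[col].isin(list(want)).to_numpy()
        else:
            mask &= (samples[col] == want).to_numpy()
    return mask


@dataclass
class Contrast:
    """Two disjoint sample groups defined by metadata predicates.

    A predicate maps sample-table columns to a required value (or list of
    values), e.g. ``{"condition": "lesion", "cell_type": "EC"}``.  The fitted
    coefficient is group_a minus group_b.  ``include_batch`` adds additive
    batch indicator columns to the design.
    """

    group_a: Predicate
    group_b: Predicate
    include_batch: bool = False
    name: str = ""

    def resolve(self, samples: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        a = _match(samples, self.group_a)
        b = _match(samples, self.group_b)
        if not a.any() or not b.any():
            raise DesignError(f"contrast {self.name or self.group_a} has an empty group")
        if (a & b).any():
            overlap = samples.loc[a & b, "sample_id"].tolist()
            raise DesignError(f"contrast groups overlap on samples {overlap}")
        return a, b

    @classmethod
    def from_string(cls, text: str, include_batch: bool = False) -> "Contrast":
        """Parse e.g. ``"lesion.EC vs control.EC"`` or ``"EC vs rest"``."""

        def parse_side(side: str) -> Predicate:
            parts = side.strip().split(".")
            if len(parts) == 2:
                return {"condition": parts[0], "cell_type": parts[1]}
            return {"cell_type": parts[0]}

        left, _, right = text.partition(" vs ")
        if not right:
            raise DesignError(f"cannot parse contrast {text!r}")
        return cls(parse_side(left), parse_side(right), include_batch=include_batch, name=text)


# ---------------------------------------------------------------------------
# Empirical-Bayes variance moderation
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    # Newton iteration on trigamma(x) = y; monotone decreasing, so start at
    # the asymptotic inverse 1/y + 0.5 and refine.
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Fit the scaled-F prior (d0, s0^2) to observed residual variances.

    Matches the first two moments of log s2 to the log-chi-square theory:
    e_g = log(s2_g) - digamma(d/2) + log(d/2) has mean log(s0^2) and excess
    variance trigamma(d0/2) over trigamma(d/2).  Genes with zero residual
    variance are excluded from fitting.  Returns (inf, s0^2) when the
    observed spread is at or below the theoretical sampling spread.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise DesignError("too few positive residual variances to fit a prior")
    z = np.log(s2[ok])
    e = z - polygamma(0, df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2.0))
    if e_var <= 0:
        # spread no larger than sampling theory predicts: variances look
        # homogeneous, so shrink fully to their (unbiased) arithmetic mean
        return np.inf, float(np.mean(s2[ok]))
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0_sq = float(np.exp(e_mean + polygamma(0, d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def fit_moderated_de(
    expr: ExpressionMatrix,
    samples: pd.DataFrame,
    contrast: Contrast,
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> pd.DataFrame:
    """Moderated differential expression for one contrast.

    Per gene: OLS on [intercept, group indicator, batch indicators], then
    empirical-Bayes shrinkage of the residual variance and a moderated t
    with ``d0 + d_g`` degrees of freedom; BH-adjusted q-values.

    ``prior_df``/``prior_var`` override the fitted prior (0 recovers the
    ordinary per-gene t; inf with a fixed ``prior_var`` uses that variance
    for every gene).

    Returns a DataFrame indexed by gene with columns
    log2fc, t, df_total, p, q.
    """
    a_mask, b_mask = contrast.resolve(samples)
    keep = a_mask | b_mask
    sub = samples.loc[keep]
    Y = expr.values.loc[:, sub["sample_id"]].to_numpy()
    n = keep.sum()

    group = a_mask[keep].astype(float)
    cols = [np.ones(n), group]
    if contrast.include_batch:
        batches = pd.get_dummies(sub["batch"], drop_first=True)
        for c in batches.columns:
            cols.append(batches[c].to_numpy(dtype=float))
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise DesignError(
            "design matrix is rank deficient (batch confounded with group?)"
        )
    df_resid = n - rank
    if df_resid < 1:
        raise DesignError(
            "no residual degrees of freedom; pool variance or add samples"
        )

    XtX_inv = np.linalg.inv(X.T @ X)
    beta = Y @ X @ XtX_inv.T  # genes x coefficients
    resid = Y - beta @ X.T
    s2 = (resid**2).sum(axis=1) / df_resid
    v = XtX_inv[1, 1]  # unscaled variance of the group coefficient
    log2fc = beta[:, 1]

    if prior_df is None:
        d0, s0_sq = estimate_variance_prior(s2, df_resid)
    else:
        d0 = float(prior_df)
        s0_sq = float(prior_var) if prior_var is not None else float(np.median(s2))
    if prior_var is not None:
        s0_sq = float(prior_var)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2
        df_total = float(df_resid)
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = float(d0 + df_resid)
    # information in the prior cannot exceed what the data carry: cap the
    # total df at the pooled residual df across genes
    df_total = float(min(df_total, df_resid * Y.shape[0]))

    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = log2fc / np.sqrt(s2_post * v)
    t_stat = np.where(np.isfinite(t_stat), t_stat, 0.0)
    p = 2.0 * t_dist.sf(np.abs(t_stat), df_total)
    q = bh_fdr(p)

    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "t": t_stat,
            "df_total": df_total,
            "p": p,
            "q": q,
        },
        index=expr.values.index,
    )


def bh_fdr(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# DEG gating
# ---------------------------------------------------------------------------

@dataclass
class DEGSet:
    """Genes passing the significance and fold-change gates for a contrast."""

    contrast: str
    genes: list[str]
    direction: dict[str, str] = field(default_factory=dict)

    def __contains__(self, gene: str) -> bool:
        return gene in self.direction

    def __len__(self) -> int:
        return len(self.genes)

    def up(self) -> list[str]:
        return [g for g in self.genes if self.direction[g] == "up"]

    def down(self) -> list[str]:
        return [g for g in self.genes if self.direction[g] == "down"]


def gate_degs(
    table: pd.DataFrame,
    alpha: float = 0.1,
    fc_min: float = 1.5,
    contrast: str = "",
) -> DEGSet:
    """Apply the DEG gates: q < alpha and |FC| > fc_min (both strict).

    ``fc_min`` is on the linear fold-change scale; the log2 cutoff is
    log2(fc_min).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if fc_min < 1:
        raise ValueError("fc_min must be >= 1")
    lfc_cut = np.log2(fc_min)
    mask = (table["q"] < alpha) & (table["log2fc"].abs() > lfc_cut)
    genes = list(table.index[mask])
    direction = {
        g: ("up" if table.at[g, "log2fc"] > 0 else "down") for g in genes
    }
    return DEGSet(contrast=contrast, genes=genes, direction=direction)


def write_de_table(table: pd.DataFrame, path) -> None:
    out = table.rename_axis("gene").reset_index()
    out.to_csv(path, sep="\t", index=False)
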