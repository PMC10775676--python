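# Methods

`crosstalk` analyses bulk RNA-seq of FACS-sorted cell populations —
endothelial cells (EC), pericytes (PC) and neuroglia (NG) — from lesional
versus non-lesional brain tissue. Each sorted population is a separate bulk
library, so the dataset behaves like a tiny, deeply-sequenced single-cell
experiment whose "clusters" are known from the sort. This note documents
the statistical models, their assumptions, the defaults, and what the
synthetic-data tests do and do not establish.

## Study design emulated by the generator

The default synthetic design is 3 populations x 2 conditions, 6 lesion and
4 control subjects, two technical replicates per library, and one lesion-EC
library dropped (a sequencing failure is part of the emulated design).
Subjects are assigned alternately to two batches so that batch is crossed
with condition and cell type, never confounded.

Counts for gene *g*, sample *s* are negative binomial with mean

    mu_gs = exp(base_g) * 2^(effect_gs + batch_s) * lib_s

and gene-wise dispersion `phi(m) = a/m + b` (defaults a = 1, b = 0.05)
evaluated at the baseline mean, giving the usual mean–variance coupling of
bulk RNA-seq. Baselines are log-normal (natural-log mean 4, SD 1.2);
batch offsets are Gaussian on the log2 scale (SD 0.25) shared across genes;
library-size factors are log-normal (SD 0.2). All randomness derives from
one integer seed; a fixed seed reproduces the dataset byte-for-byte.

Planted structure:

* **Markers** — 30 genes per population at +4 log2 in that population,
  both conditions.
* **Condition DEGs** — 50 genes per population at ±2 log2 (alternating
  sign) in lesion samples of that population only.
* **Ligand–receptor circuits** — six by default: a constitutive VEGF-like
  paracrine axis PC→EC (+3 log2 in both conditions, +2 more in lesion), a
  lesion-only second VEGF axis NG→EC (+4), lesion-only NOTCH-like and
  EphB-like EC autocrine circuits (+4), and two constitutive ECM-like
  circuits with a two-subunit integrin receptor. This landscape gives the
  downstream stages everything they must detect: lesion-specific circuits,
  a pathway whose architecture (set of sender→receiver edges) changes
  between conditions, and a pathway that does not.

Two deliberate rules keep the composition realistic. A gene serving several
circuits takes the **maximum** boost over its roles rather than the sum
(a receptor shared by two ligands is not twice as expressed), and
planted-effect genes draw their baselines with half the log-SD
(`planted_baseline_sd_factor = 0.5`): without this, a top-expressed
transcript boosted 16–32-fold can absorb a third of a library and shift
every other gene's CPM, which real sorted-population data does not show at
that magnitude. A *moderate* compositional shift from marker load remains,
intentionally — it is a genuine property of sorted populations, and the
tests tolerate it.

What the generator does **not** emulate: read-level artefacts (alignment
loss, UMI structure, contamination), subject-level random effects beyond
the batch offset, gene–gene correlation, and isoform structure. Passing
recovery tests therefore shows the pipeline's statistics behave correctly
under an honest NB model of the design — not that real-data preprocessing
choices are validated.

## Normalization and differential expression

Expression is log2 counts-per-million with pseudocount 0.5:
`log2((count + 0.5) / (libsize + 1) * 1e6)`. Precision weighting (voom) is
deliberately omitted: with 2–6 libraries per group the weights are noisy,
and unweighted least squares on log-CPM is the documented model.

Each gene is fit by OLS on `[intercept, group, batch indicators]` (batch
optional). Residual variances are shrunk by the classic empirical-Bayes
scheme: the scaled-F prior `(d0, s0^2)` is fitted by matching the first two
moments of `log s^2` through the digamma/trigamma theory (Newton inversion
of the trigamma function); when the observed spread of log-variances is at
or below the pure sampling spread the prior df is infinite and `s0^2` is
the arithmetic mean of the `s^2` (their unbiased pooled value). The
moderated t uses `d0 + d_g` degrees of freedom, capped at the pooled
residual df across genes — the prior cannot carry more information than the
data it was fit to. Genes with zero residual variance are excluded from
prior fitting but moderated with the fitted prior. A tiny fixture is
cross-checked against the Bioconductor reference implementation via Rscript
(t, p and df agree to 1e-6); the R package is an oracle only, never the
implementation.

DEG gates are strict: BH-adjusted q < 0.1 **and** |FC| > 1.5 (i.e.
|log2FC| > log2 1.5). Technical replicates are treated as independent
samples by default; collapsing to subject means is possible by pre-averaging
but is not the default, because the replicate-level model is what the
calibration suite validates.

## Cross-population fold-change ratio

For an ordered population pair (A, B), DE of A vs B is computed within each
condition. The universe U is the union of genes passing the DEG gates in
either condition; for g in U,

    delta_g = |log2FC_lesion(g)| − |log2FC_control(g)|

(`abs_diff`; a `signed_diff` mode is available for sensitivity analysis).
delta is z-scored over U with the sample SD, and genes with z ≥ 1.96 are
flagged — one-sided, because the question is *more* population-restricted
fold change under disease. Genes significant in only one condition
contribute their estimated (not zeroed) fold change on the other side.
Standardization is per-pair, not pooled across pairs. A flagged gene is
attributed to population A when some flagged pair involves A **and** the
gene is in A's own lesion-vs-control DEG set; the attribution rule is this
package's choice, exposed as code, since several rules are defensible.

Under an exactly Gaussian null the one-sided flag rate is the 2.5% tail,
and the acceptance suite verifies this with i.i.d. Gaussian ratio values.
On full-pipeline nulls the rate runs slightly low (~2.1%) because gating
truncates the delta distribution; this is expected and documented rather
than corrected.

## Population validation

Markers with at least 70% sensitivity are queried in each population's
one-vs-rest moderated DE profile (conditions pooled, same gates). A
population is confirmed when at least half of its testable markers
(minimum 3) are significantly up. The pass criterion (50%, 3) is a package
decision — the validation idea is the query, and different marker panels
warrant different stringency, so both knobs are parameters.

## Ligand–receptor communication

Population profiles are the per-population mean (optionally trimmed mean;
the trim removes `ceil(n·trim)` samples per tail) of linear-scale CPM
within one condition. The unit expression of a multi-subunit ligand or
receptor is the geometric mean of subunit values, zero if any subunit is
absent — a receptor missing one chain does not signal. The communication
probability of interaction i from sender S to receiver R is a saturating
mass-action (Hill, exponent 1) form

    P = L·R / (kh + L·R) × (1 + A/(kh + A)) × kh/(kh + I),   clamped to [0, 1]

with L the sender ligand unit, R, A, I the receiver receptor / agonist /
antagonist units and kh = 0.5. On the CPM scale P saturates near 1 for
well-expressed pairs; this is harmless because significance never reads P's
magnitude, only its rank under permutation, and P remains a strictly
monotone score of L·R. Significance per (sender, receiver, interaction)
triple: cell-type labels are shuffled across the condition's samples
(subject pairing ignored — each sorted library is an independent unit), P
recomputed `n_perm` times, `p = (1 + #{P_perm ≥ P_obs})/(1 + n_perm)`, BH
across all triples of the condition, gate q < 0.05. Note the p floor
`1/(n_perm + 1)`: with ~150 triples in the BH family, fewer than ~500
permutations cannot reach q < 0.05 at all; the default `n_perm = 1000`.

The test detects *population-specificity* of ligand–receptor expression. A
ubiquitous ligand meeting a receptor that is specific to one population is
significant toward that population in any condition — that is a property of
the statistic, not a false positive, and it is why planted-circuit tests
assert circuit-level behavior rather than raw significance counts.

Significant interaction probabilities are summed per pathway into
sender × receiver weight matrices W. Pathway similarity between any two
networks is the cosine of their flattened, L1-normalized W; all
(pathway, condition) networks are embedded jointly by classical (Torgerson)
MDS of `1 − similarity` — chosen over stochastic manifold learners so the
embedding is deterministic; signs are fixed by making the largest-|loading|
coordinate positive. A pathway's between-condition distance is the
Euclidean distance between its lesion and control points in that shared
plane; identical networks land at distance 0 to eigen-truncation tolerance.

## Enrichment

Three statistics over user-supplied GMT collections (no database content is
bundled):

* **ORA** — hypergeometric upper tail P(X ≥ k), BH across sets, default
  gate q < 0.01.
* **Activation z** — over a signed set's gated-DEG members,
  `z = Σ sign(log2FC)·sign(member) / sqrt(count)`; activated at z ≥ 2,
  inhibited at z ≤ −2 (boundaries inclusive). This is the plain concordance
  form; causal-network edge weights and bias corrections of commercial
  tools are intentionally not reproduced.
* **Preranked GSEA** — weighted running sum (hit steps |stat|^w normalized
  over hits, default w = 1; miss steps 1/(N−K)), ES the signed maximum
  deviation, gene-label permutation null, NES = ES / mean(|null ES| of the
  same sign), empirical p with the +1 correction. The default ranking
  statistic is `sign(log2FC) × −log10 p`; the exact composite is
  configurable because several are in common use. Ties rank lexically by
  gene id for determinism.

## Reporting

The three-way DEG Venn partition is exact set algebra over 7 regions with
hard internal assertions (regions disjoint, totals reconstruct input
cardinalities). Heatmap matrices are per-gene z-scores (zero-variance genes
excluded and reported) with average-linkage, correlation-distance
agglomerative clustering; genes are sorted by id before clustering so leaf
order is reproducible under ties.

## Problem sizes and determinism

Default analyses run at 2000 genes, 58 libraries, 1000 LR permutations.
The calibration suites use 3 seeds (null uniformity), 20 seeds (DEG and
marker recovery), 50 universes (flag-rate calibration) and 10 seeds at 1000
permutations (circuit recovery) — sizes chosen so Monte-Carlo error is
small against each margin being tested. Every stage is deterministic given
its seed; the full pipeline writes byte-identical output on reruns, which
the test suite asserts by hashing.

## Known limitations

* The LR probability model is this package's concrete instantiation of
  communication scoring; magnitudes are not comparable across datasets with
  different depth, only within a run.
* CPM normalization leaves sorted-population compositional shifts in the
  profiles; strongly asymmetric marker loads can tilt low-level fold
  changes between populations.
* The moderated model assumes roughly log-linear mean effects and common
  dispersion behavior; count-level GLMs (NB Wald/LRT) are out of scope.
* Attribution of flagged ratio genes to populations, and the validation
  pass rule, are documented package decisions, not community standards.
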