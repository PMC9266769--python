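# Methods

This note records the statistical models, the defaults and why they were
chosen, the numerical decisions, and what the synthetic-data benchmark
does and does not demonstrate. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Count model and differential expression

Counts are modelled as `K_ij ~ NB(mean = s_j μ_ij, dispersion α_i)` with
`Var = μ + α μ²` (the overdispersion parameterisation standard in
RNA-seq) and `log μ_ij = x_jᵀ β_i` on the log2 scale for reporting.

**Filtering.** Two pre-test filters: (i) total count across samples of
at least `min_total`, where `"auto"` sets the threshold to the size of
the smallest level of the primary factor — i.e. one count per sample of
the smallest group (14 under the default 17/14/27 design); (ii) an
annotation-completeness filter requiring chromosome, full name and a
cross-reference id, since several downstream steps (gender stratification
by chromosome, text retrieval) need them.

**Size factors** use the median-of-ratios estimator over genes with
all-positive counts — the de-facto standard for this model family. When
no such gene exists, an explicit error suggests the pseudo-reference
fallback flag (`allow_pseudo_reference`), which builds the geometric-mean
reference from positive counts only. Note that multiplying one sample's
counts by *c* scales its size factor by *c* only relative to the other
samples (the geometric-mean reference rescales too), and leaves the
fitted log2FC only approximately unchanged: the scaled sample carries
more likelihood weight. The exact invariance, tested as such, is under a
global rescaling of all size factors, which the intercept absorbs.

**Dispersions.** Per-gene method of moments on normalised counts
`y = K/s`, pooling within-group deviations so modelled group effects do
not inflate the estimate: `α̂ = (Var(y) − mean(1/s)·ȳ)/ȳ²`, floored at
1e-8 (sub-Poisson moments land on the floor). Across genes a trend
`α(μ) = a₀ + a₁/μ` is fitted by trimmed least squares on `1/μ`, and each
raw estimate is shrunk by an equal-weight log-space average with the
trend value — a deliberate simplification of empirical-Bayes dispersion
shrinkage: it preserves the two properties the pipeline relies on (the
shrunk value lies between raw and trend; stable behaviour at small
counts) without estimating a posterior width. Floor-level genes stay at
the floor rather than being pulled up by the trend.

**GLM fit.** All genes share one treatment-coded design matrix
(reference level alphabetically first unless configured; optional
covariate appended), so the IRLS iterations are vectorised across genes.
The offset is `log s_j`. Convergence is declared on a relative deviance
change below 1e-8 or a coefficient step below the same tolerance.
Fitted means are floored at `min_mu = 0.5` and the working response is
built from the floored mean: under complete separation (e.g. a
male-specific gene with zero counts in every female) the deviance
plateaus at a finite, large fold change whose SE still reflects the
information in the zero group — such genes test strongly significant, as
they should, instead of drifting to an infinite estimate with a
collapsing Wald statistic (the Hauck–Donner effect). Genes that still
fail to converge after 50 iterations are flagged and carry NaN results.
The Wald test is the ordinary `β = 0` null, two-sided normal; p-values
are floored at 1e-300 before any logarithm, and BH-adjusted (step-up,
clipped at 1, NaN propagated, inputs validated to (0, 1]).

**VST.** For the trend `α(μ) = a₀ + a₁/μ` the closed form

    v(q) = log2( (1 + a₁ + 2 a₀ q + 2 √(a₀ q (1 + a₁ + a₀ q))) / (4 a₀) ),   q = K/s

is finite at zero and approaches `log2 q` plus a constant for large
counts, so a two-fold change tends to a difference of 1. A
`log2(q + 1)` fallback is available behind a flag (and is used
automatically if the fitted `a₀` is non-positive). The contract is
asymptotic behaviour and variance flattening, both property-tested; no
bit-level agreement with any particular implementation is claimed.

**Gender-stratified follow-up.** Gender DE is assessed per sample
stratum with the same NB Wald machinery (strata with fewer than two
samples per gender are skipped with a warning); the union of gender-DE
genes is then re-tested for inflammation association per gender with
two-sample Wilcoxon tests on VST values, BH-adjusted per gender.
Y-linked genes are evaluated in males only. Genes are classified as
concordant, male-only or female-only up/down regulation from the
per-gender significance and the sign of the median VST difference.

**Wilcoxon.** `wilcoxon_two_sample` is a thin contract over
`scipy.stats.mannwhitneyu`: exact enumeration when `n₁ + n₂ ≤ 12` with
no ties, otherwise the normal approximation with tie and continuity
correction; identical pooled samples return p = 1. The exact branch is
verified against full enumeration in the tests.

## PCA

Correlation PCA: the top-k (default 500) genes by variance (ddof = 1;
boundary ties broken lexicographically by gene id for determinism) are
standardised per gene and decomposed by SVD; variance fractions are
eigenvalue shares, and at most `n_samples − 1` components are kept.
Constant genes cannot be scaled and are dropped with a warning.
Component/factor associations run the Wilcoxon test per component
(default first three), per unordered level pair, BH-adjusted over the
whole emitted table. All reports are invariant to component sign flips.

## Preranked enrichment

The rank metric is `sign(log2FC) · |log10 p|` with unadjusted p; zero
log2FC yields metric 0 (logged). Base 10 is a reporting choice — the
gene order, ES values and permutation p are invariant to the log base.
Ties are broken by |log2FC| then gene id so the ranking is strict and
deterministic.

ES is the maximum deviation of the running sum in which member genes add
`|r|^w` normalised over the set (default weight w = 1, the classic
weighted statistic; w = 0 gives the Kolmogorov–Smirnov form) and
non-members subtract `1/(N − N_hit)`. Because the running sum only
decreases between hits, both the observed ES and every permuted ES are
computed in O(set size) from the sorted hit positions; the O(N) running
sum survives in the tests as the independent oracle. A set equal to the
whole universe has ES = 1 by construction; a set whose members all carry
zero metric falls back to equal hit increments.

The null permutes gene labels (re-draws memberships uniformly): a
preranked list has no sample labels to permute. One stream of random
orderings is shared by all set sizes — the first k entries of a uniform
random permutation are a uniform k-subset — which makes 10⁴ permutations
cheap; the default `n_perm = 10000` is a desk-scale choice, configurable
upward. The permutation p is one-sided in the direction of the observed
ES **against the same-signed part of the null** with a +1 pseudocount;
conditioning on the sign keeps the null p uniform (the naive one-sided
tail would double the false-positive rate), which the calibration tests
verify. BH adjustment runs across tested sets; size bounds default to
5–500 after intersection with the ranked universe. Normalised enrichment
scores are out of scope: reporting uses BH-adjusted permutation p only.

Over-representation uses the exact upper-tail hypergeometric sum via
`scipy.stats.hypergeom`, verified against combinatorial enumeration.

## Term networks

**Wang similarity** propagates S-values from each term up all ancestor
paths (`S(term) = 1`, `S(parent) = max over edges of w_e · S(child)`
with is_a = 0.8 and part_of = 0.6, both configurable) and scores
`Σ shared (S_A + S_B) / (SV(A) + SV(B))`. **Simplification** sweeps
terms in ascending adjusted-p order and drops any term whose similarity
with an already-kept term exceeds the cutoff (default 0.7) — the most
significant representative of every redundant cluster survives; the
sweep is deterministic and idempotent.

**Kappa edges** are Cohen's kappa between binary gene-membership vectors
over a universe defaulting to the union of member genes (the convention
of functional-grouping tools; κ depends on this choice, so it is
logged). Edges require κ ≥ 0.2 by default. **Grouping** seeds a group
per term (the term plus its κ-neighbours), drops duplicate seeds and
seeds that strictly contain another seed, then merges any two groups
sharing at least half of the smaller group's terms until a fixpoint;
each term is labelled by the most significant representative among its
groups, and edge-less terms are singletons. Plain connected components
are available as an alternative. **Fusion**, applied with the stricter
p ≤ 0.01 cutoff for comparisons involving inflamed tissue, collapses an
enriched parent–child pair sharing at least 50% of the smaller term's
genes onto the more significant term (ties keep the deeper term). The
grouping and fusion procedures are property-tested stand-ins for the
unpublished internals of the interactive tools they emulate; their
behaviour is pinned by the tests, not by any external reference.

## Text analysis

Tokenisation keeps punctuation as separate tokens and keeps
hyphen/apostrophe/slash-joined words (nf-kappa-b, t-cell) intact;
lemmatisation is a dictionary lookup with identity fallback. Stopword
matching is case-insensitive and applied **after** lemmatisation, so an
inflected form whose lemma is stopworded is caught; the custom list
ships with words common in protein annotation (act, however, isoform,
mediate, play, resulting, target, …) and is configurable. Removed words
become empty pads that keep their positions: unigram tables exclude pads
and punctuation, while bigram positions require two adjacent countable
words — a pad or punctuation token breaks adjacency.

Keyness per word is the 2×2 χ² (word vs all other tokens, target vs
reference) with Yates correction clamped at zero, signed by the
relative-frequency direction; p-values use χ²(1). Collocations use the
2×2 adjacency table per bigram over all counted positions,
`λ = ln(n11·n22/(n12·n21))`, `z = λ/√(Σ 1/n_kl)`, with 0.5 added to all
cells only when some cell is zero.

## Synthetic data

The generator emulates the study conditions the pipeline targets: three
groups of 17 (inflamed UC), 14 (non-inflamed UC) and 27 (control)
samples with gender proportions 6/17, 6/14 and 10/27. Defaults: 2000
genes with log2 base means uniform on [2, 9]; dispersion trend
`α(μ) = 0.05 + 2/μ` (a mid-range overdispersion level chosen for
testability — the emulated study reports no dispersion estimates); size
factors log-uniform on [0.5, 2]; 100 planted DE genes with |log2FC|
uniform on [1, 2.5] and random sign on the inflamed-vs-control contrast;
8 Y-linked genes silent in females and 6 X-escape genes at double the
female mean (emulating chromosome-driven gender DE without real
genomes); 40 gene sets of 10–40 members of which a quarter are planted
from one DE direction (80% planted members); a GWAS list of 150 genes
drawn with odds 4 for planted DE genes; an ontology of a dozen internal
terms over the set ids with is_a/part_of edges; and 2–6 templated
annotation sentences per gene in which each DE direction's theme
vocabulary appears at five times the relative frequency of the opposite
group's.

All generators draw from named substreams of a single seed, so adding a
generator leaves the others' draws untouched and a config + seed pair
reproduces every output byte for byte. The ground-truth record (planted
effects, NB parameters, size factors, set directions, GWAS list, theme
vocabulary) is emitted alongside the data.

What the synthetic benchmark does **not** emulate: correlated genes,
GC/length biases, batch effects, outlier samples, realistic ontology
depth or annotation text, or library-specific quirks of real UniProt
prose. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated model, and calibration under
model-true data — not robustness to real-data violations of it.

## Numerical choices

- p-values floored at 1e-300 before logs; BH inputs validated to (0, 1].
- Dispersion floor 1e-8; trend intercept clamped to ≥ 1e-6.
- IRLS: deviance tolerance 1e-8, max 50 iterations, mean floor 0.5,
  coefficients clipped at |log2FC| = 30/ln 2; a tiny ridge (1e-6)
  stabilises the normal equations without materially biasing estimates.
- Count matrices are coerced to a canonical contiguous int64 layout so
  reductions are bit-reproducible whether data arrive from memory or
  disk.
- Deterministic tie-breaks throughout: gene id in rankings and variance
  selection, term id in simplification sweeps and group labels.
- Degenerate inputs: constant genes get the dispersion floor and are
  dropped from PCA; empty term memberships are excluded from the kappa
  network; identical Wilcoxon samples give p = 1; a set intersecting the
  universe nowhere is skipped and logged.

## Scale of the shipped experiments

The test suite and the acceptance script size their simulations for a
single CPU: 2000 genes for type-I error calibration, 800-gene studies ×
50 replicates at 10⁴ permutations for planted-set recovery, 100 text
replicates for keyness recovery, 200/500-replicate null batteries for
the Wilcoxon/GSEA/overlap calibrations. These sizes were chosen so each
battery gives stable rates (binomial SE a few percent) while the whole
suite completes in minutes; all of them are parameters, not limits of
the implementation — the engines scale to full-study sizes (tens of
thousands of genes, 5×10⁷ permutations) linearly.

## Known limitations

- Dispersion shrinkage is equal-weight rather than posterior-weighted;
  very low-count genes therefore track the trend more loosely than an
  empirical-Bayes estimator would.
- No independent filtering, outlier replacement or LFC shrinkage in the
  DE step (deliberately out of scope); DE counts on real data will
  differ from tools that apply them.
- The exact universe behind a GWAS overlap p-value matters; both the
  filtered and the annotated universes can be supplied, and the choice
  is reported alongside the result.
- The grouping/fusion variants approximate interactive network tools
  whose exact algorithms are unpublished; they are deterministic and
  tested, but not byte-compatible with those tools.
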