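# mucoseq

A reusable, fully tested pipeline for the downstream analysis of
case/control bulk RNA-seq studies of intestinal mucosa (and structurally
similar designs): differential expression on counts, unsupervised
structure, gene-set enrichment, ontology term networks, quantitative
text analysis of protein annotations, and GWAS-locus overlap — plus a
synthetic-data generator that plants known ground truth in every input
so the whole chain can be validated without any external download.

It is aimed at bioinformaticians who want the individual statistical
steps as importable, oracle-tested functions rather than a monolithic
workflow, and at methodologists who need a planted-truth benchmark for
this class of analysis.

## What it computes

**Differential expression.** Counts `K_ij` for gene *i*, sample *j* are
modelled as negative binomial with `Var = μ + α μ²`,
`mean = s_j · q_i · 2^(x_jᵀ β_i)`: `s_j` are median-of-ratios size
factors, `α_i` per-gene dispersions (method of moments, shrunk in log
space toward a fitted trend `α(μ) = a₀ + a₁/μ`), and `β_i` log2-scale
coefficients of a treatment-coded design (e.g. a combined
disease × inflammation `group` factor controlled for `gender`), fitted
by IRLS and tested with the Wald statistic `β̂/SE(β̂)`; p-values are
Benjamini–Hochberg adjusted. Genes are pre-filtered by a minimal total
count (automatically one count per sample of the smallest group) and by
annotation completeness. A variance-stabilising transformation (closed
form for the dispersion trend) feeds PCA and rank-based follow-ups,
including a gender-stratified Wilcoxon analysis of inflammation effects.

**PCA.** The 500 highest-variance genes, standardised to zero mean and
unit variance, are decomposed by SVD; component/factor associations use
the two-sample Wilcoxon test.

**Enrichment.** Genes are ranked by `r_g = sign(log2FC) · |log10 p|`,
sets are scored with the weighted Kolmogorov–Smirnov-like running sum
(ES), significance comes from a gene-label permutation null (one-sided
against the same-signed null with a +1 pseudocount), and the leading
edge (core enriched genes) is extracted at the running-sum extremum.
A hypergeometric over-representation test covers plain gene lists.

**Term networks.** Enriched ontology terms are compressed by Wang
semantic similarity (S-value propagation with is_a = 0.8,
part_of = 0.6; redundant pairs above 0.7 keep the more significant
term), linked by Cohen-kappa edges (κ ≥ 0.2) on shared gene content,
grouped by iterative merging, and — for inflamed-tissue comparisons —
additionally restricted to adjusted p ≤ 0.01 with parent–child term
fusion.

**Text keyness.** Per-gene functional annotation paragraphs are
tokenised, lemmatised and stopworded with *pad preservation* (removed
words leave empty slots so bigrams never span them; punctuation is
retained). Keyness between gene groups is the signed χ² with Yates
correction; bigram collocations are scored by the log odds ratio
`λ = ln(n11·n22/(n12·n21))` and its Wald z.

**GWAS overlap.** The union of DE and core enriched genes is tested for
overlap with a GWAS-locus gene list by an exact upper-tail
hypergeometric test, and each GWAS gene is classified
(DE-only / core-enriched-only / both / absent, with direction).

## Worked example

```bash
python examples/02_differential_expression.py
```

prints, for a seeded synthetic study of 2000 genes with 100 planted DE
genes across 17 + 14 + 27 samples:

```
count filter kept 2000 of 2000 genes
dispersion trend alpha(mu) = 0.048 + 1.89/mu (simulated with 0.05 + 2.0/mu)
DE genes at q <= 0.05: 102 (48 up, 54 down)
planted DE genes recovered: 98/100; false discoveries: 4
mean log2FC estimation error on recovered genes: -0.069
```

The dispersion trend recovers the simulated parameters, 98 of the 100
planted genes are detected at q ≤ 0.05 with 4 false discoveries (an
empirical FDR of about 4%, matching the nominal 5%), and the fold-change
estimates are nearly unbiased. The remaining examples walk through PCA
(`03`), enrichment with leading edges (`04`), the term network (`05`),
text keyness (`06`), GWAS overlap (`07`) and the complete pipeline with
its manifest and summary report (`08`). The same stages are available
from the shell:

```bash
mucoseq simulate --outdir study --seed 1
mucoseq all --config config.yaml
```

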