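"""Overlap of identified genes with a GWAS-locus gene list.

"Identified" genes are the union of DE genes (q <= 0.05) and core
enriched (leading-edge) genes.  The overlap with the GWAS list is tested
with an exact upper-tail hypergeometric test on the analysed universe,
and every GWAS gene is classified by how (and in which direction) it was
found.
"""

from mucoseq.containers import DesignSpec
from mucoseq.de import (
    estimate_dispersions,
    estimate_size_factors,
    filter_low_counts,
    fit_nb_wald,
)
from mucoseq.enrichment import compute_rank_metric, gsea_preranked
from mucoseq.gwas import category_counts, classify_gwas_genes, overlap_test
from mucoseq.simulate import SimulationConfig, simulate_all

study = simulate_all(SimulationConfig(rng_seed=1, n_genes=2000, n_de_genes=100))
cm = filter_low_counts(study.counts, "auto")
sf = estimate_size_factors(cm.counts)
disp, _ = estimate_dispersions(cm.counts, sf, groups=cm.samples["group"])
de = fit_nb_wald(cm, DesignSpec("group", ("UC.I", "Cntrl"), covariate="gender"),
                 sf, disp)
enr = gsea_preranked(compute_rank_metric(de), study.sets, n_perm=5000, seed=1)

core = enr.core_enriched_genes(0.05)
identified = set(de.significant(0.05).index) | core["up"] | core["down"]
identified &= set(cm.gene_ids)

res = overlap_test(identified, study.gwas_genes, set(cm.gene_ids))
print(f"universe {res.universe_size} genes; GWAS list {res.gwas_in_universe}; "
      f"identified {res.identified_count}")
print(f"overlap: {res.overlap_count} ({res.fraction_pct}% of GWAS genes), "
      f"hypergeometric p = {res.p:.3e}")
# The generator draws the GWAS list with odds 4 for planted DE genes, so
# a strongly significant overlap is the expected outcome.

classes = classify_gwas_genes({"uci_vs_cntrl": de.table}, {"uci_vs_cntrl": enr},
                              set(study.gwas_genes) & set(cm.gene_ids))
print("\nGWAS gene classification (category x direction):")
print(category_counts(classes).to_string(index=False))
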