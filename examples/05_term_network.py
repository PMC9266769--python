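"""Post-enrichment term processing: simplification, kappa network, groups.

Enriched ontology terms are first compressed by Wang semantic similarity
(the more significant member of every redundant pair survives), then
connected by Cohen-kappa edges on shared leading-edge gene content and
grouped with an iterative merge.
"""

from mucoseq.containers import DesignSpec
from mucoseq.de import (
    estimate_dispersions,
    estimate_size_factors,
    filter_low_counts,
    fit_nb_wald,
)
from mucoseq.enrichment import compute_rank_metric, gsea_preranked
from mucoseq.simulate import SimulationConfig, simulate_all
from mucoseq.termgraph import group_terms, kappa_edges, simplify_terms, wang_similarity

study = simulate_all(SimulationConfig(rng_seed=1, n_genes=2000, n_de_genes=100))
cm = filter_low_counts(study.counts, "auto")
sf = estimate_size_factors(cm.counts)
disp, _ = estimate_dispersions(cm.counts, sf, groups=cm.samples["group"])
de = fit_nb_wald(cm, DesignSpec("group", ("UC.I", "Cntrl"), covariate="gender"),
                 sf, disp)
enr = gsea_preranked(compute_rank_metric(de), study.sets, n_perm=5000, seed=1)

sig = enr.significant(0.05)
terms = sig["q"]
print(f"enriched terms entering the network: {len(terms)}")

pair = list(terms.index[:2])
if len(pair) == 2:
    sim = wang_similarity(study.dag, *pair)
    print(f"Wang similarity({pair[0]}, {pair[1]}) = {sim:.3f}")

kept = simplify_terms(terms, study.dag, cutoff=0.7)
print(f"after simplification at Wang similarity 0.7: {len(kept)} terms")

memberships = {t: set(enr.leading_edges[t]) for t in kept}
edges = kappa_edges(memberships, threshold=0.2)
print(f"kappa edges (kappa >= 0.2): {len(edges)}")
if len(edges):
    print(edges.round(3).head())

groups = group_terms(edges, terms.loc[kept])
n_groups = groups["group_label"].nunique()
print(f"functional groups: {n_groups} "
      "(each labelled by its most significant member term)")
print(groups.head(8))
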