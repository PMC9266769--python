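"""Overlap of identified genes with GWAS-locus gene lists."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass
class OverlapResult:
    """Hypergeometric overlap of identified genes with a GWAS gene list.

    ``identified`` is typically the union of DE genes (q <= 0.05) and
    core enriched (leading-edge) genes across the study comparisons.
    ``fraction_pct`` is the percentage of GWAS genes identified,
    reported with one decimal.
    """

    universe_size: int
    gwas_in_universe: int
    identified_count: int
    overlap_count: int
    p: float

    @property
    def fraction_pct(self) -> float:
        return round(100.0 * self.overlap_count / self.gwas_in_universe, 1)


def overlap_test(identified_genes, gwas_genes, universe) -> OverlapResult:
    """Upper-tail hypergeometric test of the identified/GWAS overlap.

    The universe is the set of analysed (filtered, annotated) genes;
    ``identified_genes`` must be a subset of it.  The p-value is the
    exact tail sum P(X >= overlap).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    identified = set(identified_genes)
    if not identified <= universe:
        extra = sorted(identified - universe)[:5]
        raise ValueError(f"identified genes outside the universe: {extra}")
    gwas = set(gwas_genes) & universe
    if not gwas:
        raise ValueError("GWAS gene list does not intersect the universe")
    overlap = len(identified & gwas)
    p = float(sps.hypergeom.sf(overlap - 1, len(universe), len(gwas), len(identified)))
    return OverlapResult(
        universe_size=len(universe),
        gwas_in_universe=len(gwas),
        identified_count=len(identified),
        overlap_count=overlap,
        p=min(p, 1.0),
    )


def classify_gwas_genes(
    de_tables: dict[str, pd.DataFrame],
    enrichment_results: dict[str, object],
    gwas_genes,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Label each GWAS gene per comparison by how it was identified.

    ``de_tables`` maps comparison name -> DE table (columns ``log2FC``,
    ``q``); ``enrichment_results`` maps comparison name -> an
    ``EnrichmentResult`` (its significant sets' leading edges define the
    core enriched genes, with direction from the ES sign).  Categories:
    ``de_only``, ``core_enriched_only``, ``both``, ``absent``; a gene
    whose DE direction conflicts with the direction of every leading
    edge containing it is labelled ``discordant`` (logged and counted).
    """
    gwas = sorted(set(gwas_genes), key=str)
    rows = []
    n_discordant = 0
    for comparison in sorted(set(de_tables) | set(enrichment_results)):
        de = de_tables.get(comparison)
        enr = enrichment_results.get(comparison)
        core: dict[str, set] = {"up": set(), "down": set()}
        if enr is not None:
            core = enr.core_enriched_genes(q_threshold)
        for gene in gwas:
            de_dir = None
            if de is not None and gene in de.index:
                row = de.loc[gene]
                if not np.isnan(row["q"]) and row["q"] <= q_threshold:
                    de_dir = "up" if row["log2FC"] > 0 else "down"
            core_dirs = {d for d in ("up", "down") if gene in core[d]}
            if de_dir and core_dirs:
                if de_dir in core_dirs:
                    category, direction = "both", de_dir
                else:
                    category, direction = "discordant", de_dir
                    n_discordant += 1
            elif de_dir:
                category, direction = "de_only", de_dir
            elif core_dirs:
                direction = "up" if "up" in core_dirs else "down"
                category = "core_enriched_only"
            else:
                category, direction = "absent", ""
            rows.append(
                {
                    "gene": gene,
                    "comparison": comparison,
                    "category": category,
                    "direction": direction,
                }
            )
    if n_discordant:
        logger.warning("%d discordant gene/comparison classifications", n_discordant)
    return pd.DataFrame(rows, columns=["gene", "comparison", "category", "direction"])


def category_counts(classes: pd.DataFrame) -> pd.DataFrame:
    """Counts per (comparison, category, direction)."""
    return (
        classes.groupby(["comparison", "category", "direction"], dropna=False)
        .size()
        .rename("count")
        .reset_index()
    )
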