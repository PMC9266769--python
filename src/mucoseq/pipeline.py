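"""End-to-end pipeline wiring, report assembly and manifest writing.

Stage order: count filter -> annotation filter -> size factors ->
dispersions -> per-comparison NB Wald DE (and the gender-stratified
follow-up) -> VST -> top-variance PCA with factor association ->
signed-log-p ranking -> preranked GSEA -> term simplification, kappa
network, grouping and (for inflamed comparisons) stricter-cutoff fusion
-> GWAS overlap and classification -> keyness/collocation text analysis
of the identified GWAS-related genes.  Every output is TSV/JSON and the
manifest records parameters, seeds and per-stage counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .containers import CountMatrix, DesignSpec
from .de import (
    estimate_dispersions,
    estimate_size_factors,
    filter_low_counts,
    filter_unannotated,
    fit_nb_wald,
    gender_stratified_procedure,
    vst,
)
from .enrichment import compute_rank_metric, gsea_preranked
from .gwas import category_counts, classify_gwas_genes, overlap_test
from .pca import pc_factor_association, run_pca, select_top_variance
from .simulate import SimulatedStudy
from .termgraph import fuse_related_terms, group_terms, kappa_edges, simplify_terms
from .text import build_corpus, collocations, keyness, unigram_counts

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


DEFAULT_COMPARISONS = (
    {
        "name": "uci_vs_cntrl",
        "factor": "group",
        "contrast": ("UC.I", "Cntrl"),
        "covariate": "gender",
        "inflamed": True,
    },
    {
        "name": "ucni_vs_cntrl",
        "factor": "group",
        "contrast": ("UC.nI", "Cntrl"),
        "covariate": "gender",
        "inflamed": False,
    },
)


@dataclass
class PipelineConfig:
    """Paths, comparisons, thresholds and seeds of one pipeline run.

    Thresholds: DE and enrichment significance at BH q <= ``q_threshold``;
    term networks of comparisons flagged ``inflamed`` use the stricter
    ``inflamed_term_p`` cutoff plus parent-child fusion; fold-change
    report tiers default to |log2FC| > 2 and > 3.32 (10-fold).
    """

    counts: str = "counts.tsv"
    samples: str = "samples.tsv"
    annotation: str | None = "annotation.tsv"
    sets: str = "sets.gmt"
    dag: str | None = "dag.tsv"
    function_text: str | None = "function_text.tsv"
    lemmas: str | None = "lemmas.tsv"
    stopwords: str | None = "stopwords.txt"
    gwas: str | None = "gwas_genes.txt"
    outdir: str = "results"
    comparisons: tuple = DEFAULT_COMPARISONS
    min_total: int | str = "auto"
    primary_factor: str = "group"
    q_threshold: float = 0.05
    inflamed_term_p: float = 0.01
    fc_tiers: tuple = (2.0, 3.32)
    pca_top: int = 500
    pca_components: int = 3
    n_perm: int = 10_000
    gsea_size_bounds: tuple = (5, 500)
    wang_cutoff: float = 0.7
    kappa_threshold: float = 0.2
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "comparisons" in data:
            data["comparisons"] = tuple(
                {**c, "contrast": tuple(c["contrast"])} for c in data["comparisons"]
            )
        return cls(**data)


def _load_inputs(cfg: PipelineConfig) -> dict:
    inputs = {
        "cm": mio.read_counts(cfg.counts, cfg.samples, cfg.annotation),
        "sets": mio.read_gmt(cfg.sets),
        "dag": mio.read_dag(cfg.dag) if cfg.dag else None,
        "gene_text": mio.read_gene_text(cfg.function_text) if cfg.function_text else None,
        "lemmas": mio.read_lemmas(cfg.lemmas) if cfg.lemmas else {},
        "stopwords": mio.read_gene_list(cfg.stopwords) if cfg.stopwords else [],
        "gwas": mio.read_gene_list(cfg.gwas) if cfg.gwas else None,
    }
    return inputs


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage from input files; see :func:`run_study_pipeline`."""
    return _run(_load_inputs(config), config)


def run_study_pipeline(
    study: SimulatedStudy, outdir, **overrides
) -> dict:
    """Run the full pipeline on an in-memory synthetic study."""
    cfg = PipelineConfig(outdir=str(outdir), **overrides)
    inputs = {
        "cm": study.counts,
        "sets": study.sets,
        "dag": study.dag,
        "gene_text": study.gene_text,
        "lemmas": study.lemmas,
        "stopwords": study.stopwords,
        "gwas": study.gwas_genes,
    }
    return _run(inputs, cfg)


def _write(df: pd.DataFrame, path: Path):
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t")


def _run(inputs: dict, cfg: PipelineConfig) -> dict:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": {
            k: v for k, v in dataclasses.asdict(cfg).items() if k != "comparisons"
        },
        "comparisons": [dict(c) for c in cfg.comparisons],
        "stages": [],
        "counts": {},
    }
    results: dict = {"config": cfg, "manifest": manifest}

    def stage(name):
        def deco(fn):
            try:
                fn()
            except Exception as exc:  # noqa: BLE001 - abort with stage name
                _write_manifest(manifest, outdir)
                raise StageError(name, exc) from exc
            manifest["stages"].append(name)
            logger.info("stage %s done", name)

        return deco

    cm0: CountMatrix = inputs["cm"]

    @stage("filter")
    def _filter():
        cm = filter_low_counts(cm0, cfg.min_total, cfg.primary_factor)
        manifest["counts"]["genes_after_count_filter"] = int(len(cm.gene_ids))
        if cm.annotation is not None:
            cm = filter_unannotated(cm)
        manifest["counts"]["genes_after_annotation_filter"] = int(len(cm.gene_ids))
        results["cm"] = cm

    @stage("normalisation")
    def _norm():
        cm = results["cm"]
        sf = estimate_size_factors(cm.counts)
        disp, trend = estimate_dispersions(
            cm.counts, sf, groups=cm.samples[cfg.primary_factor]
        )
        results.update(size_factors=sf, dispersions=disp, trend=trend)
        _write(sf.to_frame(), outdir / "size_factors.tsv")

    @stage("de")
    def _de():
        cm = results["cm"]
        de_tables = {}
        for comp in cfg.comparisons:
            design = DesignSpec(
                factor=comp["factor"],
                contrast=tuple(comp["contrast"]),
                covariate=comp.get("covariate"),
            )
            res = fit_nb_wald(
                cm, design, results["size_factors"], results["dispersions"]
            )
            de_tables[comp["name"]] = res
            _write(res.table, outdir / comp["name"] / "de_results.tsv")
            sig = res.significant(cfg.q_threshold)
            manifest["counts"][f"de_{comp['name']}_up"] = int((sig["log2FC"] > 0).sum())
            manifest["counts"][f"de_{comp['name']}_down"] = int(
                (sig["log2FC"] < 0).sum()
            )
        results["de"] = de_tables

    @stage("vst")
    def _vst():
        cm = results["cm"]
        results["vst"] = vst(cm.counts, results["size_factors"], results["trend"])

    @stage("gender_strata")
    def _gender():
        cm = results["cm"]
        strata = sorted(cm.samples[cfg.primary_factor].unique())
        de_by_stratum = {}
        for level in strata:
            sub = cm.subset_samples(
                cm.sample_ids[(cm.samples[cfg.primary_factor] == level).to_numpy()]
            )
            if sub.samples["gender"].value_counts().min() < 2:
                logger.warning("stratum %s has <2 samples per gender; skipped", level)
                continue
            design = DesignSpec(factor="gender", contrast=("male", "female"))
            sf = results["size_factors"].loc[sub.sample_ids]
            disp = results["dispersions"]
            de_by_stratum[level] = fit_nb_wald(sub, design, sf, disp)
        table = gender_stratified_procedure(
            cm, de_by_stratum, results["vst"], q_threshold=cfg.q_threshold
        )
        results["gender_table"] = table
        _write(table, outdir / "gender" / "gender_inflammation.tsv")
        manifest["counts"]["gender_de_union"] = int(len(table))

    @stage("pca")
    def _pca():
        genes = select_top_variance(results["vst"], min(cfg.pca_top, len(results["vst"])))
        pca = run_pca(results["vst"], genes)
        assoc = pc_factor_association(
            pca.scores,
            results["cm"].samples,
            n_components=cfg.pca_components,
        )
        results.update(pca=pca, pca_assoc=assoc)
        _write(pca.scores, outdir / "pca_scores.tsv")
        _write(
            pd.DataFrame(
                {"variance_fraction": pca.variance_fraction},
                index=[f"PC{i+1}" for i in range(len(pca.variance_fraction))],
            ),
            outdir / "pca_variance.tsv",
        )
        _write(assoc, outdir / "pca_assoc.tsv")

    @stage("gsea")
    def _gsea():
        enr = {}
        for i, comp in enumerate(cfg.comparisons):
            ranked = compute_rank_metric(results["de"][comp["name"]])
            res = gsea_preranked(
                ranked,
                inputs["sets"],
                n_perm=cfg.n_perm,
                size_bounds=tuple(cfg.gsea_size_bounds),
                seed=np.random.default_rng(cfg.seed + 1000 + i),
            )
            enr[comp["name"]] = res
            table = res.table.copy()
            table["leading_edge"] = [
                ",".join(map(str, res.leading_edges[s])) for s in table.index
            ]
            _write(table, outdir / comp["name"] / "enrichment.tsv")
            manifest["counts"][f"sets_tested_{comp['name']}"] = int(len(table))
            manifest["counts"][f"sets_significant_{comp['name']}"] = int(
                (table["q"] <= cfg.q_threshold).sum()
            )
        results["enrichment"] = enr

    @stage("terms")
    def _terms():
        dag = inputs["dag"]
        if dag is None:
            logger.info("no ontology provided; term stage skipped")
            return
        for comp in cfg.comparisons:
            res = results["enrichment"][comp["name"]]
            sig = res.significant(cfg.q_threshold)
            if not len(sig):
                continue
            terms = sig["q"]
            terms = terms[[t in dag for t in terms.index]]
            if comp.get("inflamed"):
                memberships = {t: set(res.leading_edges[t]) for t in terms.index}
                kept = fuse_related_terms(
                    terms, dag, memberships, p_cutoff=cfg.inflamed_term_p
                )
                terms = terms.loc[kept]
            simplified = simplify_terms(terms, dag, cutoff=cfg.wang_cutoff)
            terms = terms.loc[simplified]
            memberships = {t: set(res.leading_edges[t]) for t in terms.index}
            edges = kappa_edges(memberships, threshold=cfg.kappa_threshold)
            groups = group_terms(edges, terms)
            d = outdir / comp["name"]
            _write(pd.DataFrame({"term": simplified}).set_index("term"),
                   d / "simplified_terms.tsv")
            _write(edges.set_index(edges.columns[0]) if len(edges) else edges,
                   d / "term_network_edges.tsv")
            _write(groups, d / "term_groups.tsv")
            manifest["counts"][f"terms_retained_{comp['name']}"] = int(len(terms))

    @stage("gwas")
    def _gwas():
        gwas = inputs["gwas"]
        if gwas is None:
            logger.info("no GWAS list provided; overlap stage skipped")
            return
        cm = results["cm"]
        universe = set(cm.gene_ids)
        identified: set = set()
        de_tables = {}
        for comp in cfg.comparisons:
            res = results["de"][comp["name"]]
            de_tables[comp["name"]] = res.table
            identified |= set(res.significant(cfg.q_threshold).index)
            core = results["enrichment"][comp["name"]].core_enriched_genes(
                cfg.q_threshold
            )
            identified |= core["up"] | core["down"]
        identified &= universe
        overlap = overlap_test(identified, gwas, universe)
        classes = classify_gwas_genes(
            de_tables, results["enrichment"], set(gwas) & universe, cfg.q_threshold
        )
        results.update(gwas_overlap=overlap, gwas_classes=classes)
        _write(
            pd.DataFrame([dataclasses.asdict(overlap) | {"fraction_pct": overlap.fraction_pct}]),
            outdir / "gwas_overlap.tsv",
        )
        _write(classes.set_index("gene"), outdir / "gwas_gene_classes.tsv")
        _write(category_counts(classes).set_index("comparison"),
               outdir / "gwas_category_counts.tsv")
        manifest["counts"]["gwas_overlap"] = overlap.overlap_count
        manifest["counts"]["gwas_in_universe"] = overlap.gwas_in_universe

    @stage("text")
    def _text():
        if inputs["gene_text"] is None or "gwas_classes" not in results:
            logger.info("text inputs missing; text stage skipped")
            return
        classes = results["gwas_classes"]
        ident = classes[classes["category"] != "absent"]
        up = sorted(set(ident.loc[ident["direction"] == "up", "gene"]))
        down = sorted(set(ident.loc[ident["direction"] == "down", "gene"]))
        if not up or not down:
            logger.warning("one direction empty; text stage skipped")
            return
        groups = {g: "up" for g in up} | {g: "down" for g in down}
        corpus = build_corpus(
            inputs["gene_text"], groups, inputs["lemmas"], inputs["stopwords"]
        )
        uni = unigram_counts(corpus)
        key = keyness(uni.get("up", pd.Series(dtype=int)),
                      uni.get("down", pd.Series(dtype=int)))
        coll = collocations(corpus)
        results.update(keyness=key, collocations=coll, unigrams=uni)
        _write(uni, outdir / "unigrams.tsv")
        _write(key, outdir / "keyness.tsv")
        _write(coll.set_index("word1"), outdir / "collocations.tsv")

    @stage("report")
    def _report():
        summary = summarize_report(results, cfg)
        results["summary"] = summary
        (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))

    _write_manifest(manifest, outdir)
    return results


def _write_manifest(manifest: dict, outdir: Path):
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


def summarize_report(results: dict, cfg: PipelineConfig | None = None) -> dict:
    """Summary tables mirroring the study's reporting shapes.

    Up/down DE counts per comparison (asserted to partition the DE set),
    fold-change tier counts, and per-component plus cumulative PC
    variance percentages.
    """
    cfg = cfg or results.get("config") or PipelineConfig()
    summary: dict = {"comparisons": {}}
    for name, res in results.get("de", {}).items():
        sig = res.significant(cfg.q_threshold)
        up = int((sig["log2FC"] > 0).sum())
        down = int((sig["log2FC"] < 0).sum())
        zero = int((sig["log2FC"] == 0).sum())
        assert up + down + zero == len(sig), "up/down must partition the DE set"
        tiers = {
            f"abs_log2fc_gt_{cut}": int((sig["log2FC"].abs() > cut).sum())
            for cut in cfg.fc_tiers
        }
        summary["comparisons"][name] = {
            "n_de": int(len(sig)),
            "up": up,
            "down": down,
            "tiers": tiers,
        }
    if "pca" in results:
        frac = [float(f) for f in results["pca"].variance_fraction[: cfg.pca_components]]
        pct = [round(100 * f, 1) for f in frac]
        summary["pca"] = {
            "variance_pct": pct,
            "cumulative_pct": round(sum(100 * f for f in frac), 1),
        }
    if "gwas_overlap" in results:
        ov = results["gwas_overlap"]
        summary["gwas"] = {
            "overlap": ov.overlap_count,
            "gwas_in_universe": ov.gwas_in_universe,
            "fraction_pct": ov.fraction_pct,
            "p": ov.p,
        }
    return summary


def fold_change_tier_counts(log2fcs, cutoff: float) -> int:
    """Number of genes with |log2FC| above a cutoff (e.g. 3.32 = 10-fold)."""
    arr = np.asarray(log2fcs, dtype=float)
    return int((np.abs(arr) > cutoff).sum())
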