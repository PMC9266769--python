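"""Synthetic study generator with planted ground truth.

Emulates every input of the pipeline: NB-distributed counts with group
and gender effects and planted DE genes, gene sets with coordinated
shifts, a small is_a/part_of ontology DAG whose terms double as set
ids, themed functional-annotation paragraphs whose vocabulary differs
between up- and downregulated gene groups, and a GWAS-locus gene list
enriched for planted signal genes.

Counts follow ``K_ij ~ NB(mean = s_j * q_i * 2^(x_j . beta_i),
dispersion alpha_i)`` with ``Var = mu + alpha mu^2``, size factors
log-uniform in [0.5, 2] and a dispersion trend ``alpha(mu) = a0 +
a1/mu``.  All generators draw from named substreams of one seed, so
adding a generator does not shift the draws of the others, and a given
config + seed reproduces every output bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountMatrix
from .termgraph import OntologyDAG

#: default group sizes of the emulated study design
DEFAULT_GROUP_SIZES = {"UC.I": 17, "UC.nI": 14, "Cntrl": 27}
DEFAULT_GENDER_PROPORTIONS = {"UC.I": 6 / 17, "UC.nI": 6 / 14, "Cntrl": 10 / 27}

SHARED_VOCAB = (
    "receptor signal membrane complex kinase transcription expression "
    "pathway binding enzyme domain substrate nucleus cytoplasm tissue "
    "residue ligand cascade phosphorylation homeostasis differentiation "
    "proliferation adhesion secretion structure assembly repair growth "
    "division polymerase channel vesicle matrix surface factor subunit"
).split()

UP_THEME_VOCAB = (
    "cytokine chemokine neutrophil interferon interleukin epithelial "
    "defensin inflammation"
).split()

DOWN_THEME_VOCAB = (
    "mitochondrial oxidation electron carnitine transporter dehydrogenase "
    "ubiquinol absorption"
).split()

#: inflected forms used by the sentence templates, with their lemmas
LEMMA_DICT = {
    "mediates": "mediate",
    "mediated": "mediate",
    "binds": "bind",
    "regulates": "regulate",
    "regulated": "regulate",
    "plays": "play",
    "activates": "activate",
    "induces": "induce",
    "promotes": "promote",
    "controls": "control",
    "interacts": "interact",
    "involved": "involve",
    "acts": "act",
    "proteins": "protein",
    "cells": "cell",
    "responses": "response",
    "processes": "process",
    "targets": "target",
}

STANDARD_STOPWORDS = (
    "the a an and or of in to is with by for that this as on at its it "
    "be are was were from which required during both into through"
).split()

_VERBS = ("mediates", "binds", "regulates", "activates", "induces",
          "promotes", "controls", "interacts")


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent, named child stream of one base seed."""
    key = zlib.crc32(name.encode("utf8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Group sizes and gender proportions default to the emulated design
    (inflamed UC n=17, non-inflamed UC n=14, controls n=27).  Planted DE
    genes carry a nonzero log2 fold change for the inflamed-vs-control
    contrast; ``dispersion_params`` are the ``(a0, a1)`` of the trend
    ``alpha(mu) = a0 + a1/mu``; ``base_mean_log_range`` bounds log2 of
    the per-gene base mean.  ``gwas_enrichment_odds`` is the sampling
    odds of planted DE genes entering the GWAS list (1 = no enrichment).
    """

    n_genes: int = 2000
    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    gender_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_GENDER_PROPORTIONS)
    )
    n_de_genes: int = 100
    log2fc_range: tuple[float, float] = (1.0, 2.5)
    dispersion_params: tuple[float, float] = (0.05, 2.0)
    base_mean_log_range: tuple[float, float] = (2.0, 9.0)
    n_sets: int = 40
    set_size_range: tuple[int, int] = (10, 40)
    planted_set_fraction: float = 0.25
    n_gwas_genes: int = 150
    gwas_enrichment_odds: float = 4.0
    n_y_linked: int = 8
    n_x_escape: int = 6
    pseudogene_fraction: float = 0.05
    dag_n_internal: int = 12
    dag_depth: int = 3
    part_of_fraction: float = 0.2
    theme_weight: float = 5.0
    theme_rate_factor: float = 5.0
    sentences_range: tuple[int, int] = (2, 6)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_sets <= 0:
            raise ValueError("n_genes and n_sets must be positive")
        if any(n < 2 for n in self.group_sizes.values()):
            raise ValueError("every group needs at least 2 samples")
        if not 0 <= self.planted_set_fraction <= 1:
            raise ValueError("planted_set_fraction must lie in [0, 1]")
        if self.gwas_enrichment_odds < 1:
            raise ValueError("gwas_enrichment_odds must be >= 1")
        lo, hi = self.log2fc_range
        if not (np.isfinite(lo) and np.isfinite(hi)):
            raise ValueError("log2fc_range must be finite")
        if self.n_de_genes < 0 or self.n_de_genes > self.n_genes:
            raise ValueError("n_de_genes out of range")


@dataclass
class GroundTruth:
    """Planted signals, recorded as the generators run."""

    contrast: tuple[str, str] = ("UC.I", "Cntrl")
    de_log2fc: dict = field(default_factory=dict)  # gene -> signed log2FC
    y_linked: list = field(default_factory=list)
    x_escape: list = field(default_factory=list)
    base_mean: dict = field(default_factory=dict)
    dispersion: dict = field(default_factory=dict)
    size_factors: dict = field(default_factory=dict)
    enriched_sets: dict = field(default_factory=dict)  # set id -> "up"/"down"
    gwas_genes: list = field(default_factory=list)
    theme_vocabulary: dict = field(default_factory=dict)  # group -> words

    def de_genes(self, direction: str | None = None) -> list:
        if direction == "up":
            return sorted(g for g, b in self.de_log2fc.items() if b > 0)
        if direction == "down":
            return sorted(g for g, b in self.de_log2fc.items() if b < 0)
        return sorted(self.de_log2fc)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["contrast"] = list(d["contrast"])
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        d["contrast"] = tuple(d["contrast"])
        return cls(**d)


# ---------------------------------------------------------------------------
# counts


def simulate_counts(config: SimulationConfig) -> tuple[CountMatrix, GroundTruth]:
    """NB counts with group/gender effects and planted DE genes."""
    rng = substream(config.rng_seed, "counts")
    truth = GroundTruth()
    genes = [f"G{i:05d}" for i in range(config.n_genes)]

    # sample table: groups in declared order, deterministic gender counts
    sample_ids, group_col, gender_col = [], [], []
    for group in config.group_sizes:
        n = config.group_sizes[group]
        n_male = int(round(config.gender_proportions.get(group, 0.5) * n))
        for j in range(n):
            sample_ids.append(f"{group}_{j + 1:02d}")
            group_col.append(group)
            gender_col.append("male" if j < n_male else "female")
    samples = pd.DataFrame(
        {"group": group_col, "gender": gender_col}, index=pd.Index(sample_ids, name="sample")
    )

    # gene annotation; gender-effect genes get sex chromosomes
    truth.y_linked = genes[: config.n_y_linked]
    truth.x_escape = genes[config.n_y_linked : config.n_y_linked + config.n_x_escape]
    chrom = np.array(
        [str(1 + (i % 22)) for i in range(config.n_genes)], dtype=object
    )
    chrom[: config.n_y_linked] = "Y"
    chrom[config.n_y_linked : config.n_y_linked + config.n_x_escape] = "X"
    pseudo = rng.random(config.n_genes) < config.pseudogene_fraction
    annotation = pd.DataFrame(
        {
            "chromosome": chrom,
            "full_name": [f"protein coding locus {g}" for g in genes],
            "entrez": np.arange(10_000, 10_000 + config.n_genes),
            "pseudogene": pseudo,
        },
        index=pd.Index(genes, name="gene"),
    )

    # per-gene NB parameters on the trend alpha(mu) = a0 + a1/mu
    lo, hi = config.base_mean_log_range
    q = 2.0 ** rng.uniform(lo, hi, config.n_genes)
    a0, a1 = config.dispersion_params
    alpha = a0 + a1 / q
    s = 2.0 ** rng.uniform(-1.0, 1.0, len(sample_ids))  # log-uniform in [0.5, 2]

    # planted DE genes for the inflamed-vs-control contrast
    autosomal = np.arange(config.n_y_linked + config.n_x_escape, config.n_genes)
    beta = np.zeros(config.n_genes)
    if config.n_de_genes:
        de_idx = rng.choice(autosomal, size=config.n_de_genes, replace=False)
        mag = rng.uniform(*config.log2fc_range, config.n_de_genes)
        sign = np.where(rng.random(config.n_de_genes) < 0.5, 1.0, -1.0)
        beta[de_idx] = sign * mag
        truth.de_log2fc = {genes[i]: float(beta[i]) for i in sorted(de_idx)}

    inflamed = (samples["group"] == truth.contrast[0]).to_numpy(dtype=float)
    female = (samples["gender"] == "female").to_numpy(dtype=float)
    log2_mu = np.log2(q)[:, None] + beta[:, None] * inflamed[None, :]
    log2_mu = log2_mu + np.log2(s)[None, :]
    mu = 2.0 ** log2_mu
    # Y-linked genes are silent in females; X-escape genes run 2x higher
    mu[: config.n_y_linked][:, female.astype(bool)] = 0.0
    mu[config.n_y_linked : config.n_y_linked + config.n_x_escape] *= 2.0 ** (
        female[None, :]
    )

    r = 1.0 / np.maximum(alpha, 1e-12)[:, None] * np.ones_like(mu)
    pnb = r / (r + np.maximum(mu, 1e-300))
    counts = np.where(mu > 0, rng.negative_binomial(r, np.minimum(pnb, 1.0)), 0)
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=samples.index),
        samples=samples,
        annotation=annotation,
    )
    truth.base_mean = {g: float(q[i]) for i, g in enumerate(genes)}
    truth.dispersion = {g: float(alpha[i]) for i, g in enumerate(genes)}
    truth.size_factors = {sid: float(s[j]) for j, sid in enumerate(sample_ids)}
    return cm, truth


# ---------------------------------------------------------------------------
# gene sets


def simulate_gene_sets(
    config: SimulationConfig, truth: GroundTruth, genes=None
) -> dict[str, list]:
    """Gene sets in GMT spirit: planted sets drawn from one DE direction.

    A ``planted_set_fraction`` of the sets are drawn preferentially
    (80%) from planted DE genes of a single direction, alternating up
    and down; decoy sets are drawn uniformly.  Set ids double as
    ontology term ids so the term network stages can consume enrichment
    output directly.
    """
    rng = substream(config.rng_seed, "sets")
    if genes is None:
        genes = [f"G{i:05d}" for i in range(config.n_genes)]
    genes = list(genes)
    lo, hi = config.set_size_range
    n_planted = int(round(config.n_sets * config.planted_set_fraction))
    sets: dict[str, list] = {}
    up, down = truth.de_genes("up"), truth.de_genes("down")
    nonde = sorted(set(genes) - set(truth.de_log2fc))
    for i in range(config.n_sets):
        name = f"GO:SIM{i:04d}"
        size = int(rng.integers(lo, hi + 1))
        if i < n_planted and (up if i % 2 == 0 else down):
            pool = up if i % 2 == 0 else down
            n_sig = min(int(round(0.8 * size)), len(pool))
            members = list(rng.choice(pool, size=n_sig, replace=False))
            members += list(
                rng.choice(nonde, size=size - n_sig, replace=False)
            )
            truth.enriched_sets[name] = "up" if i % 2 == 0 else "down"
        else:
            members = list(rng.choice(genes, size=size, replace=False))
        sets[name] = sorted(members)
    return sets


# ---------------------------------------------------------------------------
# GWAS list


def simulate_gwas_list(config: SimulationConfig, truth: GroundTruth, genes=None) -> list:
    """GWAS-locus gene list enriched for planted DE genes.

    Weighted sampling without replacement (exponential-key method) with
    odds ``gwas_enrichment_odds`` for planted DE genes and 1 otherwise.
    """
    rng = substream(config.rng_seed, "gwas")
    if genes is None:
        genes = [f"G{i:05d}" for i in range(config.n_genes)]
    genes = list(genes)
    weights = np.array(
        [config.gwas_enrichment_odds if g in truth.de_log2fc else 1.0 for g in genes]
    )
    keys = rng.exponential(1.0, len(genes)) / weights
    order = np.argsort(keys)
    chosen = sorted(genes[i] for i in order[: config.n_gwas_genes])
    truth.gwas_genes = chosen
    return chosen


# ---------------------------------------------------------------------------
# ontology DAG and functional text


def simulate_dag(
    config: SimulationConfig, set_names
) -> tuple[list[tuple[str, str, str]], OntologyDAG]:
    """Single-rooted acyclic term graph covering all set ids.

    Internal terms form a random tree of bounded depth under the root;
    each set id hangs off a random term (root included at depth budget
    1), occasionally with a second parent.  Edges are ``is_a`` or
    ``part_of``.
    """
    rng = substream(config.rng_seed, "dag")
    root = "GO:ROOT"
    depth = {root: 0}
    edges: list[tuple[str, str, str]] = []
    internal = [root]
    for i in range(config.dag_n_internal):
        name = f"GO:INT{i:03d}"
        candidates = [t for t in internal if depth[t] < config.dag_depth - 1]
        parent = candidates[rng.integers(len(candidates))] if candidates else root
        rel = "part_of" if rng.random() < config.part_of_fraction else "is_a"
        edges.append((name, parent, rel))
        depth[name] = depth[parent] + 1
        internal.append(name)
    parents_pool = [t for t in internal if depth[t] < config.dag_depth]
    for name in set_names:
        parent = parents_pool[rng.integers(len(parents_pool))]
        rel = "part_of" if rng.random() < config.part_of_fraction else "is_a"
        edges.append((name, parent, rel))
        depth[name] = depth[parent] + 1
        if rng.random() < 0.2 and len(parents_pool) > 1:
            second = parents_pool[rng.integers(len(parents_pool))]
            if second != parent:
                edges.append((name, second, "is_a"))
    return edges, OntologyDAG.from_edges(edges)


def _draw_word(rng, shared, own_theme, other_theme, w_own, w_other) -> str:
    pool = list(shared) + list(own_theme) + list(other_theme)
    weights = np.concatenate(
        [
            np.ones(len(shared)),
            np.full(len(own_theme), w_own),
            np.full(len(other_theme), w_other),
        ]
    )
    weights = weights / weights.sum()
    return pool[rng.choice(len(pool), p=weights)]


def simulate_text(
    config: SimulationConfig, truth: GroundTruth, genes=None
) -> tuple[dict, dict, list]:
    """Themed functional-annotation paragraphs per gene.

    Genes planted as upregulated draw up-theme nouns at
    ``theme_rate_factor`` times the relative frequency of down-theme
    nouns and vice versa; background genes use the shared vocabulary
    only.  Each document is 2-6 templated sentences mixing inflected
    verbs (covered by the lemma dictionary), stopwords and punctuation.

    Returns (gene -> text, lemma dictionary, stopword list).
    """
    rng = substream(config.rng_seed, "text")
    if genes is None:
        genes = [f"G{i:05d}" for i in range(config.n_genes)]
    truth.theme_vocabulary = {"up": list(UP_THEME_VOCAB), "down": list(DOWN_THEME_VOCAB)}
    up, down = set(truth.de_genes("up")), set(truth.de_genes("down"))
    w_own = config.theme_weight
    w_other = config.theme_weight / config.theme_rate_factor
    lo, hi = config.sentences_range
    texts: dict = {}
    for gene in genes:
        if gene in up:
            own, other = UP_THEME_VOCAB, DOWN_THEME_VOCAB
            wo, wt = w_own, w_other
        elif gene in down:
            own, other = DOWN_THEME_VOCAB, UP_THEME_VOCAB
            wo, wt = w_own, w_other
        else:
            own, other = UP_THEME_VOCAB, DOWN_THEME_VOCAB
            wo = wt = w_other
        n_sent = int(rng.integers(lo, hi + 1))
        sentences = []
        for _ in range(n_sent):
            verb = _VERBS[rng.integers(len(_VERBS))]
            w1 = _draw_word(rng, SHARED_VOCAB, own, other, wo, wt)
            w2 = _draw_word(rng, SHARED_VOCAB, own, other, wo, wt)
            w3 = _draw_word(rng, SHARED_VOCAB, own, other, wo, wt)
            sentences.append(
                f"This protein {verb} the {w1} of {w2} and is involved in {w3}."
            )
        texts[gene] = " ".join(sentences)
    return texts, dict(LEMMA_DICT), list(STANDARD_STOPWORDS)


def simulate_dag_and_text(
    config: SimulationConfig, truth: GroundTruth, set_names=None, genes=None
):
    """Ontology DAG plus gene text, lemma dictionary and stopword list."""
    if set_names is None:
        set_names = [f"GO:SIM{i:04d}" for i in range(config.n_sets)]
    edges, dag = simulate_dag(config, set_names)
    texts, lemmas, stopwords = simulate_text(config, truth, genes)
    return edges, dag, texts, lemmas, stopwords


# ---------------------------------------------------------------------------
# bundle


@dataclass
class SimulatedStudy:
    """Every synthetic input of one study, plus its ground truth."""

    config: SimulationConfig
    counts: CountMatrix
    truth: GroundTruth
    sets: dict
    dag_edges: list
    dag: OntologyDAG
    gene_text: dict
    lemmas: dict
    stopwords: list
    gwas_genes: list


def simulate_all(config: SimulationConfig | None = None, **overrides) -> SimulatedStudy:
    """Generate the complete synthetic study from one config."""
    if config is None:
        config = SimulationConfig(**overrides)
    elif overrides:
        config = dataclasses.replace(config, **overrides)
    cm, truth = simulate_counts(config)
    sets = simulate_gene_sets(config, truth, genes=list(cm.gene_ids))
    gwas = simulate_gwas_list(config, truth, genes=list(cm.gene_ids))
    edges, dag, texts, lemmas, stopwords = simulate_dag_and_text(
        config, truth, set_names=sorted(sets), genes=list(cm.gene_ids)
    )
    return SimulatedStudy(
        config=config,
        counts=cm,
        truth=truth,
        sets=sets,
        dag_edges=edges,
        dag=dag,
        gene_text=texts,
        lemmas=lemmas,
        stopwords=stopwords,
        gwas_genes=gwas,
    )
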