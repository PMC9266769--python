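"""Readers and writers for the plain-text input/output dialects.

Counts, sample and annotation tables are TSV; gene sets use the GMT
convention (name, description, then member genes, tab-separated); the
ontology is a child/parent/relation edge list; functional text is a
two-column gene/text TSV; the lemma dictionary maps inflected form to
root form; gene lists and stopwords are one entry per line.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CountMatrix
from .simulate import GroundTruth, SimulatedStudy
from .termgraph import OntologyDAG


def read_counts(
    counts_path, samples_path, annotation_path=None, genes_path=None
) -> CountMatrix:
    """Load a count matrix from TSV or MatrixMarket plus its sample table.

    A ``.mtx`` file carries no identifiers, so it needs ``genes_path``
    (one gene id per line, matrix row order); sample ids come from the
    sample table's order.
    """
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    if str(counts_path).endswith(".mtx"):
        from scipy.io import mmread

        if genes_path is None:
            raise ValueError("MatrixMarket input needs genes_path for row ids")
        genes = read_gene_list(genes_path)
        m = mmread(counts_path)
        mat = np.asarray(m.todense()) if hasattr(m, "todense") else np.asarray(m)
        counts = pd.DataFrame(mat, index=genes, columns=samples.index)
    else:
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts.index.name = "gene"
    annotation = None
    if annotation_path is not None:
        annotation = pd.read_csv(annotation_path, sep="\t", index_col=0)
    return CountMatrix(counts=counts.astype(int), samples=samples, annotation=annotation)


def write_counts(cm: CountMatrix, counts_path, samples_path, annotation_path=None):
    cm.counts.to_csv(counts_path, sep="\t")
    cm.samples.to_csv(samples_path, sep="\t")
    if annotation_path is not None and cm.annotation is not None:
        cm.annotation.to_csv(annotation_path, sep="\t")


def read_gmt(path) -> dict[str, list]:
    sets: dict[str, list] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs name, description, genes")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list], path, descriptions: dict | None = None):
    lines = []
    for name in sorted(sets):
        desc = (descriptions or {}).get(name, "na")
        lines.append("\t".join([name, desc, *map(str, sets[name])]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_dag(path) -> OntologyDAG:
    edges = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected child<TAB>parent<TAB>relation")
        edges.append(tuple(parts))
    return OntologyDAG.from_edges(edges)


def write_dag(edges, path):
    lines = ["\t".join(e) for e in edges]
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_text(path) -> dict:
    out: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split("\t", 1)
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected gene<TAB>text")
        out[parts[0]] = parts[1]
    return out


def write_gene_text(texts: dict, path):
    lines = [f"{g}\t{texts[g]}" for g in sorted(texts)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_lemmas(path) -> dict:
    out: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected inflected<TAB>lemma")
        out[parts[0]] = parts[1]
    return out


def write_lemmas(lemmas: dict, path):
    lines = [f"{k}\t{lemmas[k]}" for k in sorted(lemmas)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_list(path) -> list:
    return [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]


def write_gene_list(genes, path):
    Path(path).write_text("\n".join(map(str, genes)) + "\n")


def write_study(study: SimulatedStudy, outdir) -> dict[str, Path]:
    """Write every synthetic input file; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {name: outdir / fname for name, fname in (
        ("counts", "counts.tsv"),
        ("samples", "samples.tsv"),
        ("annotation", "annotation.tsv"),
        ("sets", "sets.gmt"),
        ("dag", "dag.tsv"),
        ("function_text", "function_text.tsv"),
        ("lemmas", "lemmas.tsv"),
        ("stopwords", "stopwords.txt"),
        ("gwas", "gwas_genes.txt"),
        ("truth", "truth.json"),
    )}
    write_counts(study.counts, paths["counts"], paths["samples"], paths["annotation"])
    write_gmt(study.sets, paths["sets"])
    write_dag(study.dag_edges, paths["dag"])
    write_gene_text(study.gene_text, paths["function_text"])
    write_lemmas(study.lemmas, paths["lemmas"])
    paths["stopwords"].write_text("\n".join(study.stopwords) + "\n")
    write_gene_list(study.gwas_genes, paths["gwas"])
    paths["truth"].write_text(study.truth.to_json() + "\n")
    return paths


def read_truth(path) -> GroundTruth:
    return GroundTruth.from_json(Path(path).read_text())
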