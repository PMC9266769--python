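"""Post-enrichment term processing on an ontology DAG.

Covers Wang semantic similarity (edge-weighted S-value propagation),
redundancy simplification of enriched terms, Cohen-kappa edges between
term gene memberships, iterative functional grouping of the kappa
network, and parent-child term fusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

WANG_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


@dataclass
class OntologyDAG:
    """A rooted, acyclic term graph with typed child->parent edges."""

    graph: nx.DiGraph  # edges child -> parent, attribute "relation"

    def __post_init__(self) -> None:
        g = self.graph
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("ontology graph contains a cycle")
        roots = [t for t in g.nodes if g.out_degree(t) == 0]
        if len(roots) != 1:
            raise ValueError(f"expected a single root, found {len(roots)}")
        self.root = roots[0]
        for t in g.nodes:
            if t != self.root and not nx.has_path(g, t, self.root):
                raise ValueError(f"term {t!r} does not reach the root")

    @classmethod
    def from_edges(cls, edges) -> "OntologyDAG":
        """Build from an iterable of (child, parent, relation) triples."""
        g = nx.DiGraph()
        for child, parent, relation in edges:
            if relation not in WANG_WEIGHTS:
                raise ValueError(f"unknown edge relation {relation!r}")
            g.add_edge(child, parent, relation=relation)
        return cls(g)

    def __contains__(self, term) -> bool:
        return term in self.graph

    def ancestors(self, term) -> set:
        """All terms reachable from ``term`` by child->parent edges."""
        return nx.descendants(self.graph, term)

    def depth(self, term) -> int:
        """Shortest child->parent path length to the root."""
        return nx.shortest_path_length(self.graph, term, self.root)

    def parents(self, term) -> set:
        return set(self.graph.successors(term))


def _svalues(dag: OntologyDAG, term, weights: dict[str, float]) -> dict:
    """Wang S-values of ``term`` for itself and all its ancestors.

    ``S(term) = 1``; walking rootward, each ancestor receives the
    maximum over its incoming paths of the product of edge weights:
    ``S(parent) = max over child edges of w_e * S(child)``.
    """
    g = dag.graph
    nodes = {term} | dag.ancestors(term)
    sub = g.subgraph(nodes)
    s = {term: 1.0}
    for node in nx.topological_sort(sub):
        if node not in s:
            continue
        for _, parent, data in sub.out_edges(node, data=True):
            cand = weights[data["relation"]] * s[node]
            if cand > s.get(parent, 0.0):
                s[parent] = cand
    return s


def wang_similarity(
    dag: OntologyDAG, term_a, term_b, weights: dict[str, float] | None = None
) -> float:
    """Wang semantic similarity between two ontology terms.

    ``sim = sum over shared terms of (S_A(t) + S_B(t)) / (SV(A) + SV(B))``
    where SV is the sum of a term's S-values.  Lies in (0, 1]; equals 1
    for identical terms; decreases as the nearest common ancestor moves
    rootward.
    """
    if weights is None:
        weights = WANG_WEIGHTS
    for t in (term_a, term_b):
        if t not in dag:
            raise KeyError(f"term {t!r} not in the ontology")
    sa = _svalues(dag, term_a, weights)
    sb = _svalues(dag, term_b, weights)
    shared = set(sa) & set(sb)
    num = sum(sa[t] + sb[t] for t in shared)
    return num / (sum(sa.values()) + sum(sb.values()))


def simplify_terms(
    terms: pd.Series, dag: OntologyDAG, cutoff: float = 0.7,
    weights: dict[str, float] | None = None,
) -> list:
    """Compress redundant enriched terms by semantic similarity.

    ``terms`` maps term id -> adjusted p.  Terms are swept in ascending
    adjusted-p order (ties by term id); a term is kept unless its Wang
    similarity with an already-kept term exceeds ``cutoff``, so of every
    redundant pair the more significant term survives.  Deterministic
    and idempotent.
    """
    order = sorted(terms.index, key=lambda t: (terms[t], str(t)))
    kept: list = []
    for term in order:
        if all(wang_similarity(dag, term, other, weights) <= cutoff for other in kept):
            kept.append(term)
    return kept


def cohen_kappa(members_a: set, members_b: set, universe: set) -> float:
    """Cohen's kappa between two binary gene memberships over a universe."""
    n = len(universe)
    if n == 0:
        raise ValueError("empty universe")
    a11 = len(members_a & members_b)
    a10 = len(members_a - members_b)
    a01 = len(members_b - members_a)
    a00 = n - a11 - a10 - a01
    po = (a11 + a00) / n
    p_yes = ((a11 + a10) / n) * ((a11 + a01) / n)
    p_no = ((a01 + a00) / n) * ((a10 + a00) / n)
    pe = p_yes + p_no
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1.0 - pe)


def kappa_edges(
    memberships: dict[str, set],
    universe: set | None = None,
    threshold: float = 0.2,
) -> pd.DataFrame:
    """Kappa-score edges between terms with overlapping gene content.

    The universe defaults to the union of all member genes (the ClueGO
    convention; kappa depends on this choice, which is therefore
    logged).  Terms with empty membership are excluded.  An edge is
    retained when kappa >= threshold.
    """
    memberships = {t: set(m) for t, m in memberships.items()}
    empty = [t for t, m in memberships.items() if not m]
    for t in empty:
        logger.warning("term %r has empty membership; excluded from kappa network", t)
        del memberships[t]
    if universe is None:
        universe = set().union(*memberships.values()) if memberships else set()
        logger.info("kappa universe = union of memberships (%d genes)", len(universe))
    terms = sorted(memberships)
    rows = []
    for i, a in enumerate(terms):
        for b in terms[i + 1 :]:
            k = cohen_kappa(memberships[a], memberships[b], universe)
            if k >= threshold:
                rows.append({"term_a": a, "term_b": b, "kappa": k})
    return pd.DataFrame(rows, columns=["term_a", "term_b", "kappa"])


def group_terms(
    edges: pd.DataFrame,
    terms: pd.Series,
    merge_overlap: float = 0.5,
    method: str = "merge",
) -> pd.DataFrame:
    """Functional grouping of the kappa network.

    ``terms`` maps term id -> adjusted p (used for group labels).  With
    ``method="merge"`` (the ClueGO-inspired default), seed groups are
    each term plus its kappa neighbours; duplicate seeds and seeds that
    strictly contain another seed are dropped, then any two groups
    sharing at least ``merge_overlap`` of the smaller group's terms are
    merged until a fixpoint.  ``method="components"`` uses plain
    connected components.  Each term is assigned to the retained group
    whose representative (smallest adjusted p, ties by id) is most
    significant; terms with no edges are singletons.  The output is
    deterministic and independent of input order.
    """
    all_terms = sorted(terms.index, key=str)
    adj: dict = {t: set() for t in all_terms}
    for _, row in edges.iterrows():
        if row["term_a"] in adj and row["term_b"] in adj:
            adj[row["term_a"]].add(row["term_b"])
            adj[row["term_b"]].add(row["term_a"])

    def representative(group: frozenset):
        return min(group, key=lambda t: (terms[t], str(t)))

    if method == "components":
        g = nx.Graph()
        g.add_nodes_from(all_terms)
        g.add_edges_from(
            (r["term_a"], r["term_b"]) for _, r in edges.iterrows()
            if r["term_a"] in adj and r["term_b"] in adj
        )
        groups = [frozenset(c) for c in nx.connected_components(g)]
    elif method == "merge":
        seeds = {frozenset({t} | adj[t]) for t in all_terms if adj[t]}
        seeds = {
            s for s in seeds if not any(o < s for o in seeds)
        }  # drop strict supersets of another seed
        groups = sorted(seeds, key=lambda s: sorted(map(str, s)))
        changed = True
        while changed:
            changed = False
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    a, b = groups[i], groups[j]
                    shared = len(a & b)
                    if shared and shared / min(len(a), len(b)) >= merge_overlap:
                        merged = a | b
                        groups = [g for k, g in enumerate(groups) if k not in (i, j)]
                        groups.append(merged)
                        groups.sort(key=lambda s: sorted(map(str, s)))
                        changed = True
                        break
                if changed:
                    break
        groups.extend(frozenset({t}) for t in all_terms if not adj[t])
    else:
        raise ValueError(f"unknown grouping method {method!r}")

    assignment: dict = {}
    for t in all_terms:
        containing = [g for g in groups if t in g]
        if not containing:
            containing = [frozenset({t})]
        best = min(
            containing, key=lambda g: (terms[representative(g)], str(representative(g)))
        )
        assignment[t] = representative(best)
    return pd.DataFrame(
        {"term": all_terms, "group_label": [assignment[t] for t in all_terms]}
    ).set_index("term")


def fuse_related_terms(
    terms: pd.Series,
    dag: OntologyDAG,
    memberships: dict[str, set],
    p_cutoff: float = 0.05,
    share_threshold: float = 0.5,
) -> list:
    """Fuse enriched parent-child term pairs that share most genes.

    Terms above ``p_cutoff`` are dropped first (the stricter 0.01 cutoff
    is applied by the caller for comparisons involving inflamed tissue).
    Whenever a retained term and its direct parent are both enriched and
    share at least ``share_threshold`` of the smaller term's genes, the
    pair is fused keeping the smaller adjusted p (ties: the deeper
    term).  Fusions are applied repeatedly until stable.
    """
    alive = {t for t in terms.index if terms[t] <= p_cutoff and t in dag}
    changed = True
    while changed:
        changed = False
        for child in sorted(alive, key=lambda t: (terms[t], str(t))):
            if child not in alive:
                continue
            for parent in sorted(dag.parents(child), key=str):
                if parent not in alive:
                    continue
                mc = set(memberships.get(child, set()))
                mp = set(memberships.get(parent, set()))
                smaller = min(len(mc), len(mp))
                if smaller == 0:
                    continue
                if len(mc & mp) / smaller >= share_threshold:
                    if terms[child] < terms[parent]:
                        drop = parent
                    elif terms[parent] < terms[child]:
                        drop = child
                    else:  # tie: keep the deeper (more specific) term
                        drop = parent if dag.depth(child) >= dag.depth(parent) else child
                    alive.discard(drop)
                    changed = True
            if changed:
                break
    return sorted(alive, key=lambda t: (terms[t], str(t)))
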