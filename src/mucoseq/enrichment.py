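"""Preranked gene-set enrichment and over-representation analysis.

Genes are ranked by ``r_g = sign(log2FC) * |log10(p)|`` (upregulated
genes at the top).  The enrichment score of a set is the maximum
deviation of the weighted Kolmogorov-Smirnov-like running sum: member
("hit") genes add ``|r_g|^weight`` normalised over the set, non-members
subtract ``1/(N - N_hit)``.  The null is a gene-label (membership)
permutation — a preranked list has no sample labels to permute — and the
one-sided permutation p-value uses a +1 pseudocount.  Core enriched
(leading-edge) genes are the members at or before (positive ES) /
at or after (negative ES) the running-sum extremum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import DEResult
from .de import P_FLOOR, benjamini_hochberg

logger = logging.getLogger(__name__)


@dataclass
class RankedList:
    """Genes in descending metric order with their rank metric values."""

    genes: list
    metric: np.ndarray

    def __post_init__(self) -> None:
        self.metric = np.asarray(self.metric, dtype=float)
        if len(self.genes) != len(self.metric):
            raise ValueError("genes and metric differ in length")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class EnrichmentResult:
    """Per-set enrichment table plus leading-edge membership."""

    table: pd.DataFrame
    leading_edges: dict[str, list] = field(default_factory=dict)

    def significant(self, q_threshold: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["q"] <= q_threshold]

    def core_enriched_genes(self, q_threshold: float = 0.05) -> dict[str, set]:
        """Union of leading-edge genes of significant sets, split by ES sign."""
        out: dict[str, set] = {"up": set(), "down": set()}
        for name, row in self.significant(q_threshold).iterrows():
            key = "up" if row["ES"] >= 0 else "down"
            out[key] |= set(self.leading_edges.get(name, []))
        return out


def compute_rank_metric(de: DEResult | pd.DataFrame, log_base: float = 10.0) -> RankedList:
    """Signed-log-p ranking metric ``r_g = sign(log2FC) * |log(p)|``.

    Uses the unadjusted p-value floored at 1e-300.  Genes with a zero
    log2 fold change get metric 0 (logged).  Ties are broken by
    |log2FC| descending and then gene id, giving a strict deterministic
    order with upregulated genes at the top.
    """
    table = de.table if isinstance(de, DEResult) else de
    t = table.dropna(subset=["log2FC", "p"])
    p = np.maximum(t["p"].to_numpy(dtype=float), P_FLOOR)
    sign = np.sign(t["log2FC"].to_numpy(dtype=float))
    n_zero = int((sign == 0).sum())
    if n_zero:
        logger.info("%d genes with log2FC == 0 ranked at metric 0", n_zero)
    metric = sign * np.abs(np.log(p) / np.log(log_base))
    order = sorted(
        range(len(t)),
        key=lambda i: (-metric[i], -abs(t["log2FC"].iloc[i]), str(t.index[i])),
    )
    return RankedList(
        genes=[t.index[i] for i in order], metric=metric[np.array(order, dtype=int)]
    )


# ---------------------------------------------------------------------------
# running-sum machinery


def _es_from_positions(
    pos: np.ndarray, weights: np.ndarray, total_w: float, n: int
) -> tuple[float, int]:
    """ES and extremum position for one membership, O(set size).

    ``pos`` are sorted 0-based hit positions, ``weights`` the hit
    weights in ranking order at those positions.  Between hits the
    running sum only decreases, so the extrema lie just after a hit
    (candidate maxima) or just before one (candidate minima).
    Returns (ES, extremum position in the ranking).
    """
    k = len(pos)
    if k == 0:
        return 0.0, -1
    if k == n:
        return 1.0, n - 1
    if total_w <= 0:
        hit = np.full(k, 1.0 / k)
    else:
        hit = weights / total_w
    H = np.cumsum(hit)
    miss = 1.0 / (n - k)
    i = np.arange(1, k + 1)
    after = H - (pos + 1 - i) * miss  # value just after each hit
    before = np.concatenate([[0.0], H[:-1]]) - (pos - (i - 1)) * miss  # just before
    hi = int(np.argmax(after))
    lo = int(np.argmin(before))
    if after[hi] >= -before[lo]:
        return float(after[hi]), int(pos[hi])
    return float(before[lo]), int(pos[lo])


def _es_batch(pos: np.ndarray, absw: np.ndarray, n: int) -> np.ndarray:
    """ES for a batch of memberships given sorted position rows."""
    m, k = pos.shape
    if k >= n:
        return np.ones(m)
    miss = 1.0 / (n - k)
    i = np.arange(1, k + 1)
    w = absw[pos]
    tw = w.sum(axis=1)
    hit = np.where(tw[:, None] > 0, w / np.where(tw == 0, 1, tw)[:, None], 1.0 / k)
    H = np.cumsum(hit, axis=1)
    after = H - (pos + 1 - i) * miss
    before = np.concatenate([np.zeros((m, 1)), H[:, :-1]], axis=1) - (pos - (i - 1)) * miss
    amax = after.max(axis=1)
    bmin = before.min(axis=1)
    return np.where(amax >= -bmin, amax, bmin)


def _null_es_by_size(
    n: int, sizes, absw: np.ndarray, n_perm: int, rng: np.random.Generator
) -> dict[int, np.ndarray]:
    """Null ES distributions for every requested membership size.

    Memberships are drawn uniformly without replacement from the ``n``
    ranking positions (gene-label permutation).  One stream of random
    orderings is shared by all sizes: the first ``k`` entries of a
    uniform random permutation are a uniform ``k``-subset, so each draw
    serves every size at once.
    """
    sizes = sorted(set(int(k) for k in sizes if k < n))
    out = {k: np.empty(n_perm) for k in sizes}
    if not sizes:
        return out
    kmax = max(sizes)
    chunk = max(1, min(n_perm, 4_000_000 // max(n, 1)))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        keys = rng.random((m, n))
        order = np.argpartition(keys, kmax - 1, axis=1)[:, :kmax]
        # restore randomness of order within the prefix before slicing
        prefix_keys = np.take_along_axis(keys, order, axis=1)
        order = np.take_along_axis(order, np.argsort(prefix_keys, axis=1), axis=1)
        for k in sizes:
            pos = np.sort(order[:, :k], axis=1)
            out[k][done : done + m] = _es_batch(pos, absw, n)
        done += m
    return out


def gsea_preranked(
    ranked: RankedList,
    sets: dict[str, list],
    n_perm: int = 10_000,
    size_bounds: tuple[int, int] = (5, 500),
    weight: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> EnrichmentResult:
    """Preranked GSEA with a membership-permutation null.

    Sets are intersected with the ranked universe and kept when the
    intersection size lies within ``size_bounds``.  The permutation
    p-value is one-sided in the direction of the observed ES with a +1
    pseudocount in numerator and denominator; BH adjustment is applied
    across the tested sets.  Null distributions are shared between sets
    of equal size.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(ranked)
    index_of = {g: i for i, g in enumerate(ranked.genes)}
    absw = np.abs(ranked.metric) ** weight
    lo, hi = size_bounds
    kept: dict[str, np.ndarray] = {}
    for name in sorted(sets):
        members = [g for g in set(sets[name]) if g in index_of]
        if not members:
            logger.info("set %r has empty intersection with the universe; skipped", name)
            continue
        if lo <= len(members) <= hi:
            kept[name] = np.sort(np.array([index_of[g] for g in members]))
    null_cache = _null_es_by_size(
        n, (len(p) for p in kept.values()), absw, n_perm, rng
    )
    rows = []
    leading: dict[str, list] = {}
    for name, pos in kept.items():
        k = len(pos)
        w = absw[pos]
        es, ext = _es_from_positions(pos, w, float(w.sum()), n)
        null = null_cache.get(k, np.ones(n_perm))
        # one-sided in the direction of the observed ES, against the
        # same-signed part of the null (the standard GSEA convention;
        # keeps the null p uniform), with a +1 pseudocount
        if es >= 0:
            side = null[null >= 0]
            p = (1.0 + np.sum(side >= es)) / (len(side) + 1.0)
            le_pos = pos[pos <= ext]
        else:
            side = null[null < 0]
            p = (1.0 + np.sum(side <= es)) / (len(side) + 1.0)
            le_pos = pos[pos >= ext]
        leading[name] = [ranked.genes[i] for i in le_pos]
        rows.append({"set": name, "size": k, "ES": es, "p": p})
    table = pd.DataFrame(rows, columns=["set", "size", "ES", "p"])
    if len(table):
        table = table.set_index("set")
        table["q"] = benjamini_hochberg(table["p"])
        table["leading_edge_size"] = [len(leading[s]) for s in table.index]
    else:
        table = table.set_index("set")
        table["q"] = []
        table["leading_edge_size"] = []
    return EnrichmentResult(table=table, leading_edges=leading)


def over_representation(
    gene_list,
    sets: dict[str, list],
    universe,
    size_bounds: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation analysis of a gene list.

    For each set, the upper-tail probability of drawing at least the
    observed overlap when ``len(gene_list)`` genes are sampled from the
    universe; BH-adjusted across sets.
    """
    universe = set(universe)
    query = set(gene_list) & universe
    if len(set(gene_list)) == 0:
        raise ValueError("gene list is empty")
    if not query:
        raise ValueError("gene list does not intersect the universe")
    M, n_draw = len(universe), len(query)
    rows = []
    for name in sorted(sets):
        members = set(sets[name]) & universe
        K = len(members)
        if K == 0:
            continue
        if size_bounds is not None and not (size_bounds[0] <= K <= size_bounds[1]):
            continue
        overlap = len(members & query)
        p = float(sps.hypergeom.sf(overlap - 1, M, K, n_draw))
        rows.append(
            {"set": name, "set_size": K, "overlap": overlap, "p": min(p, 1.0)}
        )
    out = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p"])
    out = out.set_index("set")
    out["q"] = benjamini_hochberg(out["p"]) if len(out) else []
    return out
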