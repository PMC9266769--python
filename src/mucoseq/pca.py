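"""Unsupervised structure: top-variance gene selection, correlation PCA
and principal-component / factor association tests."""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd

from .containers import PCAResult
from .de import benjamini_hochberg, wilcoxon_two_sample

logger = logging.getLogger(__name__)


def select_top_variance(vst_values: pd.DataFrame, k: int = 500) -> pd.Index:
    """The ``k`` genes with the largest per-gene variance (ddof=1).

    Ties at the boundary are broken lexicographically by gene id so the
    selection is deterministic.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(vst_values):
        raise ValueError(f"k={k} exceeds the {len(vst_values)} available genes")
    var = vst_values.var(axis=1, ddof=1)
    order = sorted(var.index, key=lambda g: (-var[g], g))
    return pd.Index(order[:k])


def run_pca(vst_values: pd.DataFrame, genes=None) -> PCAResult:
    """PCA of samples on zero-centred, unit-variance expression values.

    Standardising each gene to unit variance makes this a PCA of the
    gene correlation structure.  Constant genes (variance 0) are dropped
    with a warning since they cannot be scaled.  Variance fractions are
    eigenvalue shares; the number of components is
    ``min(n_samples - 1, n_genes)``.
    """
    if genes is not None:
        vst_values = vst_values.loc[genes]
    n = vst_values.shape[1]
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    sd = vst_values.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        logger.warning("dropping %d constant genes from PCA", int(constant.sum()))
        vst_values = vst_values[~constant]
        sd = sd[~constant]
    if vst_values.empty:
        raise ValueError("no non-constant genes left for PCA")
    z = (vst_values.sub(vst_values.mean(axis=1), axis=0)).div(sd, axis=0)
    X = z.to_numpy().T / np.sqrt(n - 1)  # samples x genes
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    ncomp = min(n - 1, vst_values.shape[0])
    U, S, Vt = U[:, :ncomp], S[:ncomp], Vt[:ncomp]
    ev = S**2
    frac = ev / ev.sum()
    comp = [f"PC{i + 1}" for i in range(ncomp)]
    scores = pd.DataFrame(
        U * S * np.sqrt(n - 1), index=vst_values.columns, columns=comp
    )
    loadings = pd.DataFrame(Vt.T, index=vst_values.index, columns=comp)
    return PCAResult(
        scores=scores,
        loadings=loadings,
        variance_fraction=frac,
        selected_gene_ids=list(vst_values.index),
    )


def pc_factor_association(
    scores: pd.DataFrame,
    factors: pd.DataFrame,
    factor_names=None,
    n_components: int = 3,
) -> pd.DataFrame:
    """Wilcoxon tests of factor levels against principal-component scores.

    For every factor, every unordered pair of its levels and each of the
    first ``n_components`` components, the scores of the two level
    groups are compared with the two-sample Wilcoxon test; the emitted
    table is BH-adjusted as a whole.  Level pairs with fewer than two
    samples on either side are skipped with a log message; single-level
    factors contribute nothing.
    """
    if factor_names is None:
        factor_names = list(factors.columns)
    comps = [c for c in scores.columns[: n_components]]
    rows = []
    for fname in factor_names:
        fac = factors.loc[scores.index, fname].astype(str)
        levels = sorted(fac.unique())
        if len(levels) < 2:
            logger.info("factor %r has a single level; skipped", fname)
            continue
        for a, b in itertools.combinations(levels, 2):
            ia, ib = fac == a, fac == b
            if ia.sum() < 2 or ib.sum() < 2:
                logger.info("pair %s/%s of %r has <2 samples per level", a, b, fname)
                continue
            for comp in comps:
                W, p = wilcoxon_two_sample(
                    scores.loc[ia.to_numpy(), comp].to_numpy(),
                    scores.loc[ib.to_numpy(), comp].to_numpy(),
                )
                rows.append(
                    {
                        "factor": fname,
                        "level_a": a,
                        "level_b": b,
                        "component": comp,
                        "W": W,
                        "p": p,
                    }
                )
    out = pd.DataFrame(
        rows, columns=["factor", "level_a", "level_b", "component", "W", "p"]
    )
    out["q"] = benjamini_hochberg(out["p"]) if len(out) else []
    return out
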